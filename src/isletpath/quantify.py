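"""Per-islet, per-slide and cross-slide statistics, plus insulitis scoring.

Conventions that matter and are deliberate:

* Cross-slide dispersion is the **population** standard deviation (ddof = 0):
  the six sections characterize one donor block, not a sample from a larger
  cohort, and recomputing the published summary row of a comparable donor
  characterization only matches under ddof = 0.  This is nonstandard for
  sample statistics and is flagged here on purpose.
* Nullable columns (a marker absent from a staining combination) are excluded
  pairwise from both mean and SD.
* Report tables round areas, densities and percentages to 1 decimal; all
  internal arithmetic is full precision.
* An islet "infiltrated" by a marker means at least one such immune cell with
  nearest-islet distance ≤ the adjacency radius (default 15 µm, configurable
  — "immediately adjacent" is not quantified in the consensus definition);
  strict-interior counts (distance 0) are reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["IsletComposition", "ImmuneSummary", "SlideSummary",
           "InsulitisCriteria", "islet_composition", "pi_ins_ratio",
           "compute_density", "infiltration_stats", "score_insulitis",
           "aggregate_slides", "population_sd"]

DEFAULT_ADJACENCY_RADIUS_UM = 15.0


@dataclass
class InsulitisCriteria:
    """Consensus insulitis definition thresholds."""

    min_cd45: int = 15
    min_cd3: int = 6
    min_qualifying_islets: int = 3
    standard_islet_diameter_um: float = 150.0
    adjacency_radius_um: float = DEFAULT_ADJACENCY_RADIUS_UM
    pseudoatrophic_min_cells: int = 10   # islet size floor for the 0-INS rule

    def __post_init__(self) -> None:
        if min(self.min_cd45, self.min_cd3, self.min_qualifying_islets) <= 0:
            raise ValueError("insulitis thresholds must be positive")


@dataclass
class IsletComposition:
    islet_id: int
    n_cells: int
    area_um2: float
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def area_mm2(self) -> float:
        return self.area_um2 / 1e6

    @property
    def cell_density_per_mm2(self) -> float:
        return self.n_cells / self.area_mm2 if self.area_mm2 > 0 else math.nan

    def pct(self, key: str) -> float:
        """Percentage of islet cells in a class (0–100)."""
        return 100.0 * self.counts.get(key, 0) / self.n_cells

    def pct_of(self, key: str, denom_key: str) -> float:
        """Per-lineage percentage, e.g. PC2+ beta cells among beta cells."""
        denom = self.counts.get(denom_key, 0)
        return 100.0 * self.counts.get(key, 0) / denom if denom else math.nan


def islet_composition(islet, cells: pd.DataFrame,
                      enzyme_markers=("PC1/3", "PC2", "CPE")) -> IsletComposition:
    """Marker counts and percentages for one islet's member cells.

    ``islet`` provides id/polygon/cell_ids; ``cells`` is the labeled cell
    table.  Per-lineage enzyme counts use keys like ``"PC2+|beta"``.
    """
    sub = cells[cells["cell_id"].isin(islet.cell_ids)]
    n = len(sub)
    if n == 0:
        raise ValueError(f"islet {islet.id} has no member cells (the >=10 "
                         "cell filter should prevent this)")
    counts: dict[str, int] = {"n_cells": n}
    for col in ("INS+", "PI+", "GCG+", "CHGA+", "beta", "alpha",
                "CD45+", "CD3+", "CD3+CD8+", "CD3+CD8-"):
        if col in sub.columns:
            counts[col] = int(sub[col].astype(bool).sum())
    for enz in enzyme_markers:
        col = f"{enz}+"
        if col not in sub.columns:
            continue
        counts[col] = int(sub[col].astype(bool).sum())
        for lineage in ("beta", "alpha"):
            if lineage in sub.columns:
                counts[f"{col}|{lineage}"] = int(
                    (sub[col].astype(bool) & sub[lineage].astype(bool)).sum())
    return IsletComposition(islet_id=islet.id, n_cells=n,
                            area_um2=float(islet.polygon.area), counts=counts)


def pi_ins_ratio(comp: IsletComposition) -> float | None:
    """Proinsulin/insulin count ratio; undefined (None) when n_INS = 0."""
    n_ins = comp.counts.get("INS+", 0)
    n_pi = comp.counts.get("PI+", 0)
    if n_ins == 0:
        return None
    return n_pi / n_ins


def compute_density(count: float, area_mm2: float) -> float:
    """Cells per mm²; area 0 is undefined (NaN, flagged by the caller)."""
    if area_mm2 <= 0:
        return math.nan
    return count / area_mm2


@dataclass
class ImmuneSummary:
    """Counts, densities and spatial distribution for one immune marker."""

    marker: str
    n_tissue: int
    n_endocrine: int                  # strict interior (distance 0)
    n_endocrine_adjacent: int         # within or immediately adjacent
    n_exocrine: int
    density_tissue: float
    density_exocrine: float
    density_endocrine: float
    bin_counts: tuple[int, int, int, int, int]
    n_islets_infiltrated: int
    pct_islets_infiltrated: float


@dataclass
class SlideSummary:
    """The per-slide summary row (areas, islet stats, immune stats)."""

    slide_id: str
    tissue_area_mm2: float
    exocrine_area_mm2: float
    endocrine_area_mm2: float
    n_islets: int
    n_islet_cells: int
    n_beta: int | None                 # None when hormone markers absent
    n_alpha: int | None
    immune: dict[str, ImmuneSummary] = field(default_factory=dict)
    islet_table: pd.DataFrame | None = None
    pi_ins_ratios: list[float] = field(default_factory=list)

    @property
    def pct_beta(self) -> float | None:
        if self.n_beta is None or self.n_islet_cells == 0:
            return None
        return 100.0 * self.n_beta / self.n_islet_cells

    @property
    def pct_alpha(self) -> float | None:
        if self.n_alpha is None or self.n_islet_cells == 0:
            return None
        return 100.0 * self.n_alpha / self.n_islet_cells

    @property
    def median_pi_ins_ratio(self) -> float:
        vals = [r for r in self.pi_ins_ratios if r is not None]
        return float(np.median(vals)) if vals else math.nan

    def to_row(self) -> dict:
        row = {
            "slide_id": self.slide_id,
            "tissue_area_mm2": self.tissue_area_mm2,
            "exocrine_area_mm2": self.exocrine_area_mm2,
            "endocrine_area_mm2": self.endocrine_area_mm2,
            "n_islets": self.n_islets,
            "n_islet_cells": self.n_islet_cells,
            "n_beta": np.nan if self.n_beta is None else self.n_beta,
            "n_alpha": np.nan if self.n_alpha is None else self.n_alpha,
        }
        for m, s in self.immune.items():
            row[f"{m}_count"] = s.n_tissue
            row[f"{m}_endocrine_count"] = s.n_endocrine
            row[f"{m}_endocrine_adjacent_count"] = s.n_endocrine_adjacent
            row[f"{m}+/mm^2"] = s.density_tissue
            row[f"{m}_pct_islets_infiltrated"] = s.pct_islets_infiltrated
            for b, c in enumerate(s.bin_counts):
                row[f"{m}_bin{b}"] = c
        return row

    def check_identities(self, atol: float = 1e-9) -> None:
        """Assert the internal accounting identities of the summary."""
        assert abs(self.tissue_area_mm2 - self.exocrine_area_mm2
                   - self.endocrine_area_mm2) <= max(atol, 1e-9 * max(
                       self.tissue_area_mm2, 1.0)), "area identity violated"
        for s in self.immune.values():
            assert s.n_tissue == s.n_exocrine + s.n_endocrine, \
                f"{s.marker}: compartment counts do not sum"
            assert sum(s.bin_counts) == s.n_tissue, \
                f"{s.marker}: bin counts do not sum to total"


def infiltration_stats(islets, records: pd.DataFrame,
                       adjacency_radius_um: float = DEFAULT_ADJACENCY_RADIUS_UM):
    """Infiltration summary from distance records of one immune marker.

    An islet is infiltrated iff at least one cell has nearest-islet distance
    ≤ the adjacency radius (0 = inside).  Returns
    ``(n_infiltrated, pct_infiltrated, counts)`` with ``counts`` holding the
    strict-interior and within-or-adjacent endocrine counts.
    """
    n_islets = len(islets)
    d = records["distance_um"].to_numpy(dtype=float)
    near = records.loc[d <= adjacency_radius_um, "nearest_islet_id"]
    infiltrated = set(near.tolist())
    n_inf = len(infiltrated)
    pct = 100.0 * n_inf / n_islets if n_islets else math.nan
    counts = {
        "endocrine_strict": int((d == 0.0).sum()),
        "endocrine_adjacent": int((d <= adjacency_radius_um).sum()),
        "exocrine_strict": int((d > 0.0).sum()),
    }
    return n_inf, pct, counts


def score_insulitis(islet_stats: pd.DataFrame,
                    criteria: InsulitisCriteria | None = None) -> dict:
    """Consensus insulitis verdict from per-islet statistics.

    ``islet_stats`` needs one row per islet with columns ``islet_id``,
    ``equivalent_diameter_um``, ``n_cells``, and per-marker within-or-adjacent
    counts ``cd45_count`` / ``cd3_count`` (either may be absent) plus
    ``n_INS`` (INS+ member cells; absent when insulin was not stained).

    Verdict: insulitis iff ≥ ``min_qualifying_islets`` islets of at least the
    standard diameter carry ≥15 CD45+ or ≥6 CD3+ cells within/adjacent, AND at
    least one pseudoatrophic (insulin-deficient) islet exists.  With no immune
    marker available the verdict is "not assessable" rather than a silent
    negative.
    """
    crit = criteria or InsulitisCriteria()
    has_cd45 = "cd45_count" in islet_stats.columns
    has_cd3 = "cd3_count" in islet_stats.columns
    if not (has_cd45 or has_cd3):
        return {"insulitis": None, "assessable": False,
                "reason": "no CD45 or CD3 measurements",
                "qualifying_islet_ids": [], "pseudoatrophic_islet_ids": []}

    big = islet_stats["equivalent_diameter_um"].to_numpy(dtype=float) \
        >= crit.standard_islet_diameter_um
    immune_hit = np.zeros(len(islet_stats), dtype=bool)
    if has_cd45:
        immune_hit |= islet_stats["cd45_count"].to_numpy(dtype=float) \
            >= crit.min_cd45
    if has_cd3:
        immune_hit |= islet_stats["cd3_count"].to_numpy(dtype=float) \
            >= crit.min_cd3
    qualifying = islet_stats.loc[big & immune_hit, "islet_id"].tolist()

    if "n_INS" in islet_stats.columns:
        pseudo = islet_stats.loc[
            (islet_stats["n_INS"].to_numpy(dtype=float) == 0)
            & (islet_stats["n_cells"].to_numpy(dtype=float)
               >= crit.pseudoatrophic_min_cells), "islet_id"].tolist()
        pseudo_known = True
    else:
        pseudo, pseudo_known = [], False

    enough = len(qualifying) >= crit.min_qualifying_islets
    if enough and not pseudo_known:
        return {"insulitis": None, "assessable": False,
                "reason": "pseudoatrophic status requires INS staining",
                "qualifying_islet_ids": qualifying,
                "pseudoatrophic_islet_ids": []}
    verdict = bool(enough and len(pseudo) >= 1)
    return {"insulitis": verdict, "assessable": True,
            "qualifying_islet_ids": qualifying,
            "pseudoatrophic_islet_ids": pseudo}


def population_sd(values) -> float:
    """Population SD (ddof = 0) over non-null values."""
    v = np.asarray([x for x in values if x is not None and not
                    (isinstance(x, float) and math.isnan(x))], dtype=float)
    if len(v) == 0:
        return math.nan
    return float(np.std(v, ddof=0))


def aggregate_slides(rows: pd.DataFrame | list[dict]) -> pd.DataFrame:
    """Cohort mean ± population SD per numeric column, NA excluded pairwise.

    Returns a two-row frame indexed ``mean`` / ``sd`` (all-null columns NA).
    """
    df = pd.DataFrame(rows) if not isinstance(rows, pd.DataFrame) else rows
    if len(df) == 0:
        raise ValueError("need at least one slide summary")
    num = df.select_dtypes(include=[np.number])
    mean = num.mean(skipna=True)
    sd = num.apply(lambda c: population_sd(c.dropna().to_numpy())
                   if c.notna().any() else math.nan)
    return pd.DataFrame([mean, sd], index=["mean", "sd"])
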