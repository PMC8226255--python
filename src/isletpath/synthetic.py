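"""Synthetic multiplexed-immunofluorescence pancreas slides with ground truth.

The generator emulates, at a reduced physical scale, the structure of a
scanned pancreas section: one connected tissue region; islets of Langerhans as
quasi-circular clusters of endocrine cells (beta cells positive for insulin
and proinsulin, alpha cells for glucagon, all endocrine cells for chromogranin
A); scattered single endocrine cells and marker-negative acinar cells in the
exocrine parenchyma; and immune cells (CD45/CD3/CD8 membrane markers) placed
at controlled distances from the islets so that every spatial statistic the
pipeline computes has a recoverable target.

Cells are rendered as isotropic Gaussian blobs (sigma = radius / 2, clipped at
3 sigma); membrane markers add a ring profile at the cell boundary.  Every
random choice flows from a single seed through per-stage substreams, so a spec
generates bit-identical slides on repeated calls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely.affinity as saff
import shapely.geometry as sgeom
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from shapely.strtree import STRtree
from skimage.draw import polygon2mask

from .slide_io import Slide, write_objects_geojson

__all__ = ["SlideSpec", "TrueIslet", "GroundTruth", "generate_slide",
           "truth_summary", "truth_pixel_labels", "truth_training_points",
           "write_ground_truth"]

log = logging.getLogger(__name__)

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

#: markers rendered as membrane rings rather than cytoplasmic disks
MEMBRANE_MARKERS = frozenset({"CD45", "CD3", "CD8"})

#: proinsulin-processing enzymes (positivity is per-lineage probabilistic)
ENZYME_MARKERS = ("PC1/3", "PC2", "CPE")

# Five-band profile over the canonical distance bins [0,1), [1,50], (50,200],
# (200,500], >500 µm, shaped like the printed T-cell distribution of a whole
# section.  Scaled-down frames cannot reach the >500 µm band; specs for such
# frames set its weight to zero (see docs/methods.md).
DEFAULT_DISTANCE_WEIGHTS = (0.0006, 0.0716, 0.2314, 0.4661, 0.2303)

_BIN_EDGES = (1.0, 50.0, 200.0, 500.0)


def _bin_of(d: float) -> int:
    if d < _BIN_EDGES[0]:
        return 0
    if d <= _BIN_EDGES[1]:
        return 1
    if d <= _BIN_EDGES[2]:
        return 2
    if d <= _BIN_EDGES[3]:
        return 3
    return 4


@dataclass
class SlideSpec:
    """Parameters of one synthetic slide.

    Geometric quantities are in µm (converted with ``mpp``); densities are per
    mm² of exocrine tissue; intensities are arbitrary fluorescence units.
    """

    width_px: int = 1200
    height_px: int = 1200
    mpp: float = 1.0
    channels: tuple[str, ...] = ("Hoechst", "INS", "PI", "GCG", "CHGA",
                                 "CD45", "CD3", "CD8")
    tissue_fraction: float = 0.55
    tissue_elongation: float = 1.6
    n_islets: int = 12
    # per-islet endocrine cell count ~ log-uniform on [min, max]
    islet_cells_min: int = 5
    islet_cells_max: int = 300
    beta_fraction: float = 0.65
    alpha_fraction: float = 0.30
    enzyme_pos_prob: dict = field(default_factory=lambda: {
        "PC1/3": {"beta": 0.68, "alpha": 0.49},
        "PC2": {"beta": 0.62, "alpha": 0.58},
        "CPE": {"beta": 0.785, "alpha": 0.639},
    })
    scattered_endocrine_per_mm2: float = 8.0
    acinar_spacing_um: float = 18.0
    immune_density_per_mm2: dict = field(default_factory=lambda: {
        "CD45": 210.0, "CD3": 115.0})
    cd8_fraction: float = 0.45
    immune_distance_weights: tuple[float, ...] = DEFAULT_DISTANCE_WEIGHTS
    dim_immune_fraction: float = 0.0     # fraction of positives in a dim mode
    dim_intensity_scale: float = 0.25
    nucleus_radius_um: float = 3.5
    cell_radius_um: float = 6.0
    islet_cell_spacing_um: float = 9.5
    intensity_pos: float = 100.0
    intensity_neg: float = 2.0
    nuclear_intensity: float = 120.0
    background: float = 10.0
    noise_sd: float = 2.0
    min_cells_per_islet: int = 10        # analysis definition of an islet
    seed: int = 0

    def validate(self) -> None:
        if self.mpp <= 0:
            raise ValueError("mpp must be > 0")
        if not 0.0 <= self.tissue_fraction <= 1.0:
            raise ValueError("tissue_fraction must be in [0, 1]")
        for name in ("beta_fraction", "alpha_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.beta_fraction + self.alpha_fraction > 1.0 + 1e-12:
            raise ValueError("beta_fraction + alpha_fraction must be <= 1")
        if self.n_islets < 0:
            raise ValueError("n_islets must be >= 0")
        if not 1 <= self.islet_cells_min <= self.islet_cells_max:
            raise ValueError("need 1 <= islet_cells_min <= islet_cells_max")
        w = np.asarray(self.immune_distance_weights, dtype=float)
        if w.ndim != 1 or len(w) != 5 or (w < 0).any() or w.sum() <= 0:
            raise ValueError("immune_distance_weights must be 5 nonnegative "
                             "weights with positive sum")
        if "Hoechst" not in self.channels:
            raise ValueError("a Hoechst nuclear channel is required")

    @property
    def norm_distance_weights(self) -> np.ndarray:
        w = np.asarray(self.immune_distance_weights, dtype=float)
        return w / w.sum()

    @property
    def channel_map(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.channels)}


@dataclass
class TrueIslet:
    id: int
    polygon: sgeom.Polygon
    cell_ids: list[int]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class GroundTruth:
    """Exhaustive generative truth for one synthetic slide."""

    spec: SlideSpec
    tissue_polygon: sgeom.Polygon
    tissue_mask: np.ndarray          # rasterized, pixel-center convention
    islets: list[TrueIslet]          # qualifying islets (>= min_cells_per_islet)
    small_clusters: list[TrueIslet]  # endocrine clusters below the cutoff
    cells: pd.DataFrame
    achieved_n_islets: int
    requested_n_islets: int

    @property
    def islet_union(self):
        from shapely.ops import unary_union
        return unary_union([i.polygon for i in self.islets]) if self.islets \
            else sgeom.Polygon()


# --------------------------------------------------------------------------
# geometry helpers

def _tissue_polygon(spec: SlideSpec, rng: np.random.Generator) -> sgeom.Polygon:
    """Elongated star-convex blob scaled to the requested tissue fraction."""
    w_um = spec.width_px * spec.mpp
    h_um = spec.height_px * spec.mpp
    theta = np.linspace(0, 2 * math.pi, 128, endpoint=False)
    r = np.ones_like(theta)
    for k in range(2, 7):
        amp = rng.uniform(0.0, 0.05)
        phase = rng.uniform(0, 2 * math.pi)
        r += amp * np.cos(k * theta + phase)
    ex = math.sqrt(spec.tissue_elongation)
    xs = np.cos(theta) * r * ex
    ys = np.sin(theta) * r / ex
    poly = sgeom.Polygon(np.column_stack([xs, ys]))
    target = spec.tissue_fraction * w_um * h_um
    s = math.sqrt(target / poly.area)
    poly = saff.scale(poly, xfact=s, yfact=s, origin=(0, 0))
    poly = saff.translate(poly, xoff=w_um / 2, yoff=h_um / 2)
    frame = sgeom.box(2 * spec.mpp, 2 * spec.mpp, w_um - 2 * spec.mpp,
                      h_um - 2 * spec.mpp)
    poly = poly.intersection(frame)
    if poly.geom_type == "MultiPolygon":          # clipping split it: keep largest
        poly = max(poly.geoms, key=lambda g: g.area)
    return poly


def _rasterize(poly: sgeom.Polygon, shape: tuple[int, int],
               mpp: float) -> np.ndarray:
    """Mask of pixels whose centers lie inside the polygon."""
    def ring_to_rc(coords):
        a = np.asarray(coords)
        return np.column_stack([a[:, 1] / mpp - 0.5, a[:, 0] / mpp - 0.5])

    mask = polygon2mask(shape, ring_to_rc(poly.exterior.coords))
    for hole in poly.interiors:
        mask &= ~polygon2mask(shape, ring_to_rc(hole.coords))
    return mask


def _px_of(x_um: np.ndarray, y_um: np.ndarray, spec: SlideSpec):
    col = np.clip((np.asarray(x_um) / spec.mpp).astype(int), 0, spec.width_px - 1)
    row = np.clip((np.asarray(y_um) / spec.mpp).astype(int), 0, spec.height_px - 1)
    return row, col


def _sunflower(n: int, radius: float, rng: np.random.Generator,
               jitter: float = 0.8) -> np.ndarray:
    """Quasi-uniform disk packing (phyllotaxis layout) with small jitter."""
    i = np.arange(n)
    r = radius * np.sqrt((i + 0.5) / n)
    th = i * GOLDEN_ANGLE + rng.uniform(0, 2 * math.pi)
    pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
    pts += rng.uniform(-jitter, jitter, size=pts.shape)
    return pts


def _islet_radius(n_cells: int, spacing: float) -> float:
    return spacing * math.sqrt(n_cells / math.pi)


# --------------------------------------------------------------------------
# main generator

def generate_slide(spec: SlideSpec) -> tuple[Slide, GroundTruth]:
    """Render a slide from a spec; deterministic given ``spec.seed``."""
    spec.validate()
    streams = np.random.SeedSequence(spec.seed).spawn(6)
    rng_tissue, rng_islet, rng_cells, rng_immune, rng_enz, rng_noise = \
        (np.random.default_rng(s) for s in streams)

    shape = (spec.height_px, spec.width_px)
    tissue_poly = _tissue_polygon(spec, rng_tissue)
    tissue_mask = _rasterize(tissue_poly, shape, spec.mpp)
    dt_um = ndi.distance_transform_edt(tissue_mask) * spec.mpp

    # ---- islets -----------------------------------------------------------
    lo, hi = math.log(spec.islet_cells_min), math.log(spec.islet_cells_max)
    counts = np.exp(rng_islet.uniform(lo, hi, size=spec.n_islets))
    counts = np.maximum(1, np.round(counts)).astype(int)
    order = np.argsort(-counts)                      # place big islets first

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    placed_counts: list[int] = []
    pad, gap = 15.0, 30.0
    for idx in order:
        n = int(counts[idx])
        R = _islet_radius(n, spec.islet_cell_spacing_um)
        elig = np.flatnonzero(dt_um.ravel() >= R + pad)
        if elig.size == 0:
            log.warning("no room for an islet of %d cells (R=%.0f um)", n, R)
            continue
        ok = False
        for _ in range(400):
            flat = int(rng_islet.choice(elig))
            r_, c_ = divmod(flat, spec.width_px)
            cx, cy = (c_ + 0.5) * spec.mpp, (r_ + 0.5) * spec.mpp
            if all(math.hypot(cx - px, cy - py) >= R + pr + gap
                   for (px, py), pr in zip(centers, radii)):
                ok = True
                break
        if not ok:
            log.warning("islet placement failed after bounded retries "
                        "(achieved %d of %d)", len(centers), spec.n_islets)
            continue
        centers.append((cx, cy))
        radii.append(R)
        placed_counts.append(n)

    # ---- cells ------------------------------------------------------------
    rows: list[dict] = []
    markers = [m for m in spec.channels if m != "Hoechst"]

    def new_cell(x, y, kind, islet_id=-1, positive=(), dim=False):
        rec = {"cell_id": len(rows), "x_um": float(x), "y_um": float(y),
               "kind": kind, "islet_id": islet_id, "dim": bool(dim),
               "distance_um": np.nan, "distance_bin": -1}
        for m in markers:
            rec[f"{m}+"] = m in positive
        rows.append(rec)
        return rec["cell_id"]

    def endocrine_positive(kind: str, rng) -> set[str]:
        pos = {"CHGA"}
        if kind == "beta":
            pos |= {"INS", "PI"}
        elif kind == "alpha":
            pos |= {"GCG"}
        for enz in ENZYME_MARKERS:
            if enz in spec.channels and kind in ("beta", "alpha"):
                p = spec.enzyme_pos_prob.get(enz, {}).get(kind, 0.0)
                if rng.random() < p:
                    pos.add(enz)
        return pos & set(spec.channels)

    def sample_kind(rng) -> str:
        u = rng.random()
        if u < spec.beta_fraction:
            return "beta"
        if u < spec.beta_fraction + spec.alpha_fraction:
            return "alpha"
        return "other_endocrine"

    islets: list[TrueIslet] = []
    small: list[TrueIslet] = []
    for iid, ((cx, cy), R, n) in enumerate(zip(centers, radii, placed_counts)):
        pts = _sunflower(n, R, rng_cells) + np.array([cx, cy])
        ids = []
        for x, y in pts:
            kind = sample_kind(rng_cells)
            ids.append(new_cell(x, y, kind, islet_id=iid,
                                positive=endocrine_positive(kind, rng_enz)))
        hull = sgeom.MultiPoint([tuple(p) for p in pts]).convex_hull
        poly = hull.buffer(spec.cell_radius_um, quad_segs=8)
        islet = TrueIslet(id=iid, polygon=poly, cell_ids=ids)
        (islets if n >= spec.min_cells_per_islet else small).append(islet)

    islet_polys = [i.polygon for i in islets]
    islet_tree = STRtree(islet_polys) if islet_polys else None

    def nearest_islet(x, y) -> tuple[float, int]:
        if islet_tree is None:
            return math.nan, -1
        p = sgeom.Point(x, y)
        j = int(islet_tree.nearest(p))
        # envelope-nearest can be wrong for close calls: check a few candidates
        d = islet_polys[j].distance(p)
        for k, poly in enumerate(islet_polys):
            dk = poly.distance(p)
            if dk < d:
                d, j = dk, k
        return d, islets[j].id

    # acinar cells: jittered grid over the exocrine parenchyma
    sp = spec.acinar_spacing_um
    minx, miny, maxx, maxy = tissue_poly.bounds
    gx = np.arange(minx, maxx, sp)
    gy = np.arange(miny, maxy, sp)
    gxx, gyy = np.meshgrid(gx, gy)
    g = np.column_stack([gxx.ravel(), gyy.ravel()])
    g += rng_cells.uniform(-0.35 * sp, 0.35 * sp, size=g.shape)
    r_, c_ = _px_of(g[:, 0], g[:, 1], spec)
    inside = dt_um[r_, c_] >= 4.0
    all_small = islets + small
    if all_small:
        block = _rasterize_union(
            [i.polygon.buffer(spec.cell_radius_um + 4.0) for i in all_small],
            shape, spec.mpp)
        inside &= ~block[r_, c_]
    acinar_pts = g[inside]
    for x, y in acinar_pts:
        new_cell(x, y, "acinar")

    exocrine_mm2 = max(tissue_poly.area
                       - sum(i.polygon.area for i in all_small), 0.0) / 1e6

    occupied = np.array([[r["x_um"], r["y_um"]] for r in rows]) \
        if rows else np.empty((0, 2))
    occ_tree = cKDTree(occupied) if len(occupied) else None
    extra_pts: list[list[float]] = []

    def far_enough(x, y, min_d=7.0) -> bool:
        if occ_tree is not None:
            if occ_tree.query([x, y], k=1)[0] < min_d:
                return False
        if extra_pts:
            a = np.asarray(extra_pts)
            if np.min(np.hypot(a[:, 0] - x, a[:, 1] - y)) < min_d:
                return False
        return True

    # scattered single endocrine cells in the exocrine tissue
    n_scatter = int(round(spec.scattered_endocrine_per_mm2 * exocrine_mm2))
    tissue_flat = np.flatnonzero(tissue_mask.ravel())
    for _ in range(n_scatter):
        for _try in range(200):
            flat = int(rng_cells.choice(tissue_flat))
            r_, c_ = divmod(flat, spec.width_px)
            x = (c_ + 0.5) * spec.mpp + rng_cells.uniform(-0.5, 0.5) * spec.mpp
            y = (r_ + 0.5) * spec.mpp + rng_cells.uniform(-0.5, 0.5) * spec.mpp
            d, _ = nearest_islet(x, y)
            if (math.isnan(d) or d > spec.cell_radius_um + 4.0) and far_enough(x, y):
                kind = sample_kind(rng_cells)
                new_cell(x, y, f"scattered_{kind}",
                         positive=endocrine_positive(kind, rng_enz))
                extra_pts.append([x, y])
                break

    # ---- immune cells -----------------------------------------------------
    _place_immune(spec, rows, markers, islets, islet_polys, nearest_islet,
                  tissue_mask, dt_um, exocrine_mm2, far_enough, extra_pts,
                  rng_immune, new_cell)

    cells = pd.DataFrame(rows) if rows else _empty_cells(markers)

    gt = GroundTruth(spec=spec, tissue_polygon=tissue_poly,
                     tissue_mask=tissue_mask, islets=islets,
                     small_clusters=small, cells=cells,
                     achieved_n_islets=len(centers),
                     requested_n_islets=spec.n_islets)

    slide = _render(spec, cells, tissue_mask, rng_noise)
    return slide, gt


def _empty_cells(markers):
    cols = {"cell_id": pd.Series(dtype=int), "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float), "kind": pd.Series(dtype=str),
            "islet_id": pd.Series(dtype=int), "dim": pd.Series(dtype=bool),
            "distance_um": pd.Series(dtype=float),
            "distance_bin": pd.Series(dtype=int)}
    for m in markers:
        cols[f"{m}+"] = pd.Series(dtype=bool)
    return pd.DataFrame(cols)


def _rasterize_union(polys, shape, mpp):
    out = np.zeros(shape, dtype=bool)
    for p in polys:
        if p.geom_type == "MultiPolygon":
            for g in p.geoms:
                out |= _rasterize(g, shape, mpp)
        else:
            out |= _rasterize(p, shape, mpp)
    return out


def _place_immune(spec, rows, markers, islets, islet_polys, nearest_islet,
                  tissue_mask, dt_um, exocrine_mm2, far_enough, extra_pts,
                  rng, new_cell):
    dens = dict(spec.immune_density_per_mm2)
    n_cd3 = int(round(dens.pop("CD3", 0.0) * exocrine_mm2)) \
        if "CD3" in spec.channels else 0
    n_cd45 = int(round(dens.pop("CD45", 0.0) * exocrine_mm2)) \
        if "CD45" in spec.channels else 0
    if dens:
        raise ValueError(f"unsupported immune markers: {sorted(dens)}")
    n_cd8 = int(round(spec.cd8_fraction * n_cd3)) if "CD8" in spec.channels else 0
    n_cd45_only = max(n_cd45 - n_cd3, 0) if n_cd45 else 0

    sets = ([{"CD45"}] * n_cd45_only
            + [{"CD45", "CD3", "CD8"}] * n_cd8
            + [{"CD45", "CD3"}] * (n_cd3 - n_cd8))
    if not sets:
        return
    weights = spec.norm_distance_weights
    have_islets = len(islets) > 0
    if not have_islets:
        # no islets: distances undefined; scatter uniformly in tissue
        tissue_flat = np.flatnonzero(tissue_mask.ravel())
        for ms in sets:
            for _ in range(200):
                flat = int(rng.choice(tissue_flat))
                r_, c_ = divmod(flat, spec.width_px)
                x, y = (c_ + 0.5) * spec.mpp, (r_ + 0.5) * spec.mpp
                if far_enough(x, y):
                    break
            dim = rng.random() < spec.dim_immune_fraction
            new_cell(x, y, "immune", positive=ms & set(spec.channels), dim=dim)
            extra_pts.append([x, y])
        return

    bands = [(0.0, 1.0), (1.0, 50.0), (50.0, 200.0), (200.0, 500.0),
             (500.0, math.inf)]
    tissue_flat = np.flatnonzero(tissue_mask.ravel())

    def sample_in_band(b: int):
        lo_, hi_ = bands[b]
        for _ in range(4000):
            if b == 0:
                poly = islet_polys[rng.integers(len(islet_polys))]
                bx0, by0, bx1, by1 = poly.bounds
                x = rng.uniform(bx0, bx1)
                y = rng.uniform(by0, by1)
                if not poly.contains(sgeom.Point(x, y)):
                    continue
            elif math.isinf(hi_):
                flat = int(rng.choice(tissue_flat))
                r_, c_ = divmod(flat, spec.width_px)
                x = (c_ + 0.5 + rng.uniform(-0.5, 0.5)) * spec.mpp
                y = (r_ + 0.5 + rng.uniform(-0.5, 0.5)) * spec.mpp
            else:
                poly = islet_polys[rng.integers(len(islet_polys))]
                bx0, by0, bx1, by1 = poly.bounds
                x = rng.uniform(bx0 - hi_, bx1 + hi_)
                y = rng.uniform(by0 - hi_, by1 + hi_)
            r_, c_ = _px_of(x, y, spec)
            if not tissue_mask[r_, c_] or dt_um[r_, c_] < 4.0:
                continue
            d, nid = nearest_islet(x, y)
            if b == 0:
                if d != 0.0:
                    continue
            elif not (lo_ < d <= hi_ or (b == 1 and d == lo_)):
                continue
            if not far_enough(x, y):
                continue
            return x, y, d, nid
        raise ValueError(
            f"could not place an immune cell in distance band "
            f"{bands[b]} µm; the slide geometry cannot realize this band "
            "(shrink islet density, enlarge the frame, or zero its weight)")

    order = rng.permutation(len(sets))
    for i in order:
        b = int(rng.choice(5, p=weights))
        x, y, d, nid = sample_in_band(b)
        dim = rng.random() < spec.dim_immune_fraction
        cid = new_cell(x, y, "immune", positive=sets[i] & set(spec.channels),
                       dim=dim)
        rows[cid]["distance_um"] = d
        rows[cid]["distance_bin"] = _bin_of(d)
        rows[cid]["islet_id"] = nid if d == 0.0 else -1
        extra_pts.append([x, y])


# --------------------------------------------------------------------------
# rendering

def _stamp(img, x_um, y_um, sigma_um, amp, mpp, ring_r_um=None,
           ring_sigma_um=None, fill=1.0):
    """Add a clipped Gaussian blob (optionally with a membrane ring)."""
    reach = 3.0 * sigma_um if ring_r_um is None else \
        ring_r_um + 3.0 * ring_sigma_um
    half = max(int(math.ceil(reach / mpp)), 1)
    c0 = int(x_um / mpp)
    r0 = int(y_um / mpp)
    H, W = img.shape
    r_lo, r_hi = max(r0 - half, 0), min(r0 + half + 1, H)
    c_lo, c_hi = max(c0 - half, 0), min(c0 + half + 1, W)
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr = (np.arange(r_lo, r_hi) + 0.5) * mpp - y_um
    cc = (np.arange(c_lo, c_hi) + 0.5) * mpp - x_um
    d2 = rr[:, None] ** 2 + cc[None, :] ** 2
    if ring_r_um is None:
        blob = amp * np.exp(-d2 / (2.0 * sigma_um ** 2))
        blob[d2 > (3.0 * sigma_um) ** 2] = 0.0
    else:
        d = np.sqrt(d2)
        blob = amp * (fill * np.exp(-d2 / (2.0 * sigma_um ** 2))
                      + np.exp(-(d - ring_r_um) ** 2
                               / (2.0 * ring_sigma_um ** 2)))
        blob[d > reach] = 0.0
    img[r_lo:r_hi, c_lo:c_hi] += blob


def _render(spec: SlideSpec, cells: pd.DataFrame, tissue_mask: np.ndarray,
            rng: np.random.Generator) -> Slide:
    shape = (spec.height_px, spec.width_px)
    px = np.zeros((len(spec.channels),) + shape, dtype=np.float32)
    chan = spec.channel_map
    sig_nuc = spec.nucleus_radius_um / 2.0
    sig_cell = spec.cell_radius_um / 2.0
    ring_r = 0.8 * spec.cell_radius_um
    ring_sig = spec.cell_radius_um / 4.0

    for rec in cells.to_dict("records"):
        x, y = rec["x_um"], rec["y_um"]
        _stamp(px[chan["Hoechst"]], x, y, sig_nuc, spec.nuclear_intensity,
               spec.mpp)
        scale = spec.dim_intensity_scale if rec["dim"] else 1.0
        is_immune = rec["kind"] == "immune"
        for m in spec.channels:
            if m == "Hoechst":
                continue
            if rec.get(f"{m}+", False):
                amp = spec.intensity_pos * scale
            else:
                # faint nonspecific signal only in same-lineage channels
                lineage = MEMBRANE_MARKERS if is_immune else \
                    set(spec.channels) - MEMBRANE_MARKERS
                if m not in lineage or spec.intensity_neg <= 0:
                    continue
                amp = spec.intensity_neg
            if m in MEMBRANE_MARKERS:
                _stamp(px[chan[m]], x, y, sig_cell, amp, spec.mpp,
                       ring_r_um=ring_r, ring_sigma_um=ring_sig, fill=0.35)
            else:
                _stamp(px[chan[m]], x, y, sig_cell, amp, spec.mpp)

    bg = tissue_mask.astype(np.float32) * spec.background
    for c in range(len(spec.channels)):
        px[c] += bg
        if spec.noise_sd > 0:
            px[c] += rng.normal(0.0, spec.noise_sd,
                                size=shape).astype(np.float32)
    np.clip(px, 0.0, None, out=px)
    return Slide(pixels=px, mpp=spec.mpp, channel_map=dict(chan))


# --------------------------------------------------------------------------
# oracles / annotation stand-ins

def truth_summary(gt: GroundTruth, adjacency_radius_um: float = 15.0):
    """Per-slide summary computed directly from ground truth (no pixels).

    Serves as the oracle for end-to-end recovery tests.
    """
    from .quantify import ImmuneSummary, SlideSummary

    spec = gt.spec
    tissue_mm2 = gt.tissue_polygon.area / 1e6
    endo_mm2 = sum(i.polygon.area for i in gt.islets) / 1e6
    exo_mm2 = tissue_mm2 - endo_mm2

    cells = gt.cells
    islet_ids = {i.id for i in gt.islets}
    in_islet = cells["islet_id"].isin(islet_ids) & (cells["kind"] != "immune")
    islet_cells = cells[in_islet]
    n_islet_cells = len(islet_cells)
    n_beta = int((islet_cells["kind"] == "beta").sum())
    n_alpha = int((islet_cells["kind"] == "alpha").sum())

    immune = {}
    imm = cells[cells["kind"] == "immune"]
    for marker in ("CD45", "CD3", "CD8"):
        col = f"{marker}+"
        if col not in cells.columns:
            continue
        sub = imm[imm[col]]
        if len(sub) == 0 and marker not in spec.immune_density_per_mm2 \
                and not (marker == "CD8" and "CD3" in spec.immune_density_per_mm2):
            continue
        d = sub["distance_um"].to_numpy(dtype=float)
        bins = np.zeros(5, dtype=int)
        for b in sub["distance_bin"]:
            if b >= 0:
                bins[int(b)] += 1
        strict = int((d == 0.0).sum())
        adjacent = int((d <= adjacency_radius_um).sum())
        infiltrated = set(sub.loc[(sub["distance_um"] <= adjacency_radius_um),
                                  "islet_id"])
        # islet_id only recorded for interior cells; recompute adjacency ids
        n_infil = _count_infiltrated(gt, sub, adjacency_radius_um)
        immune[marker] = ImmuneSummary(
            marker=marker, n_tissue=len(sub),
            n_endocrine=strict, n_endocrine_adjacent=adjacent,
            n_exocrine=len(sub) - strict,
            density_tissue=len(sub) / tissue_mm2 if tissue_mm2 else math.nan,
            density_exocrine=(len(sub) - strict) / exo_mm2 if exo_mm2 else math.nan,
            density_endocrine=strict / endo_mm2 if endo_mm2 else math.nan,
            bin_counts=tuple(int(v) for v in bins),
            n_islets_infiltrated=n_infil,
            pct_islets_infiltrated=(100.0 * n_infil / len(gt.islets))
            if gt.islets else math.nan,
        )

    per_islet = []
    for islet in gt.islets:
        sub = cells[cells["cell_id"].isin(islet.cell_ids)]
        nb = int((sub["kind"] == "beta").sum())
        na = int((sub["kind"] == "alpha").sum())
        n_ins = int(sub["INS+"].sum()) if "INS+" in sub else 0
        n_pi = int(sub["PI+"].sum()) if "PI+" in sub else 0
        per_islet.append({"islet_id": islet.id, "n_cells": islet.n_cells,
                          "n_beta": nb, "n_alpha": na, "n_INS": n_ins,
                          "n_PI": n_pi,
                          "area_um2": islet.polygon.area})
    islet_table = pd.DataFrame(per_islet)

    return SlideSummary(
        slide_id=f"synthetic-seed{spec.seed}",
        tissue_area_mm2=tissue_mm2, exocrine_area_mm2=exo_mm2,
        endocrine_area_mm2=endo_mm2, n_islets=len(gt.islets),
        n_islet_cells=n_islet_cells,
        n_beta=n_beta if "INS" in spec.channels else None,
        n_alpha=n_alpha if "GCG" in spec.channels else None,
        immune=immune, islet_table=islet_table,
    )


def _count_infiltrated(gt: GroundTruth, sub: pd.DataFrame,
                       adjacency_radius_um: float) -> int:
    if not len(sub) or not gt.islets:
        return 0
    hit = set()
    pts = [sgeom.Point(x, y) for x, y in zip(sub["x_um"], sub["y_um"])]
    for islet in gt.islets:
        for p in pts:
            if islet.polygon.distance(p) <= adjacency_radius_um:
                hit.add(islet.id)
                break
    return len(hit)


def truth_pixel_labels(gt: GroundTruth, roi=None) -> np.ndarray:
    """Label image for pixel-classifier training: 1 = islet, 2 = not islet,
    0 = unlabeled (outside the ROI).

    Emulates the analyst drawing a small training ROI: by default the ROI is
    the bounding box of the first islet expanded by 60 µm (clipped to tissue).
    """
    spec = gt.spec
    labels = np.zeros(gt.tissue_mask.shape, dtype=np.uint8)
    islet_mask = _rasterize_union([i.polygon for i in gt.islets],
                                  gt.tissue_mask.shape, spec.mpp) \
        if gt.islets else np.zeros_like(gt.tissue_mask)
    if roi is None:
        if not gt.islets:
            raise ValueError("need at least one islet to derive a training ROI")
        ref = max(gt.islets, key=lambda i: i.n_cells)
        x0, y0, x1, y1 = ref.polygon.bounds
        pad = 60.0
        r0 = max(int((y0 - pad) / spec.mpp), 0)
        r1 = min(int((y1 + pad) / spec.mpp) + 1, spec.height_px)
        c0 = max(int((x0 - pad) / spec.mpp), 0)
        c1 = min(int((x1 + pad) / spec.mpp) + 1, spec.width_px)
        roi = (slice(r0, r1), slice(c0, c1))
    roi_mask = np.zeros_like(gt.tissue_mask)
    roi_mask[roi] = True
    roi_mask &= gt.tissue_mask
    labels[roi_mask & islet_mask] = 1
    labels[roi_mask & ~islet_mask] = 2
    return labels


def truth_training_points(gt: GroundTruth, detected: pd.DataFrame,
                          marker: str, n_per_class: int,
                          seed: int, gate_um: float = 5.0,
                          hard_negative_fraction: float = 0.5) -> pd.DataFrame:
    """Point annotations for the object classifier, derived from truth.

    Matches detected cells to ground-truth cells (nearest centroid within
    ``gate_um``) and samples ``n_per_class`` positives and negatives, playing
    the role of the analyst's manual training points.  As an analyst would,
    the ignore class is enriched with *hard* negatives — marker-negative cells
    of the same lineage (e.g. CD45+CD3− leucocytes when training CD3) — up to
    ``hard_negative_fraction`` of the negative points.
    """
    rng = np.random.default_rng(seed)
    truth_xy = gt.cells[["x_um", "y_um"]].to_numpy(dtype=float)
    tree = cKDTree(truth_xy)
    det_xy = detected[["centroid_x_um", "centroid_y_um"]].to_numpy(dtype=float)
    dist, idx = tree.query(det_xy, k=1)
    matched = dist <= gate_um
    col = f"{marker}+"
    truth_pos = gt.cells[col].to_numpy(dtype=bool)[idx]
    pos_ids = detected.loc[matched & truth_pos, "cell_id"].to_numpy()
    neg_mask = matched & ~truth_pos
    neg_ids = detected.loc[neg_mask, "cell_id"].to_numpy()
    if len(pos_ids) == 0 or len(neg_ids) == 0:
        raise ValueError(f"cannot derive training points for {marker}: "
                         "need both classes among matched cells")
    n_pos = min(n_per_class, len(pos_ids))
    n_neg = min(n_per_class, len(neg_ids))
    pick_pos = rng.choice(pos_ids, size=n_pos, replace=False)

    same_lineage = (gt.cells["kind"].to_numpy() == "immune")[idx] \
        if marker in MEMBRANE_MARKERS else np.ones(len(idx), dtype=bool)
    hard_ids = detected.loc[neg_mask & same_lineage, "cell_id"].to_numpy()
    n_hard = min(int(round(hard_negative_fraction * n_neg)), len(hard_ids))
    pick_hard = rng.choice(hard_ids, size=n_hard, replace=False)
    rest = np.setdiff1d(neg_ids, pick_hard)
    pick_rest = rng.choice(rest, size=min(n_neg - n_hard, len(rest)),
                           replace=False)
    pick_neg = np.concatenate([pick_hard, pick_rest])
    return pd.DataFrame({
        "cell_id": np.concatenate([pick_pos, pick_neg]),
        "class": [marker + "+"] * n_pos + ["ignore"] * len(pick_neg),
    })


# --------------------------------------------------------------------------
# on-disk truth

def write_ground_truth(gt: GroundTruth, out_dir: str | Path) -> None:
    """GeoJSON (tissue + islet polygons) and CSV cell table, in µm."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gt.cells.to_csv(out_dir / "truth_cells.csv", index=False)
    islets = [(i.id, i.polygon, {"classification": "Islet",
                                 "n_cells": i.n_cells})
              for i in gt.islets]
    tissue = [{"type": "Feature", "id": "tissue",
               "geometry": sgeom.mapping(gt.tissue_polygon),
               "properties": {"object_type": "annotation",
                              "classification": "Tissue"}}]
    write_objects_geojson(islets, [], out_dir / "truth_objects.geojson",
                          extra_features=tissue)
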