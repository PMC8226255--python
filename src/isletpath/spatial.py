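"""Distance of immune cells to the nearest islet, binning, and heatmaps.

Distances are Euclidean, from the cell centroid to the islet polygon (zero
for centroids inside an islet).  The five canonical bands are
[0, 1), [1, 50], (50, 200], (200, 500], (500, ∞) µm — the printed scheme
leaves exactly d = 1 unassigned, so the 1–50 band is closed at 1 to make the
partition total.  Band 0 is the intra-islet compartment; band 1 (1–50 µm,
about 3–5 acinar cell diameters) is the peri-islet area.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import shapely.geometry as sgeom

__all__ = ["DistanceBins", "CANONICAL_BINS", "distance_to_islets",
           "bin_distances", "render_heatmap"]


@dataclass(frozen=True)
class DistanceBins:
    """Edges (e₁..e₄) defining [0,e₁), [e₁,e₂], (e₂,e₃], (e₃,e₄], (e₄,∞)."""

    edges: tuple[float, float, float, float] = (1.0, 50.0, 200.0, 500.0)

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) != 4 or any(a >= b for a, b in zip(e, e[1:])) or e[0] <= 0:
            raise ValueError("edges must be 4 increasing positive values")

    @property
    def labels(self) -> tuple[str, ...]:
        e = self.edges
        return (f"[0, {e[0]:g})", f"[{e[0]:g}, {e[1]:g}]",
                f"({e[1]:g}, {e[2]:g}]", f"({e[2]:g}, {e[3]:g}]",
                f">{e[3]:g}")

    def bin_of(self, d: float) -> int:
        if d < 0:
            raise ValueError("distance must be >= 0")
        e = self.edges
        if d < e[0]:
            return 0
        if d <= e[1]:
            return 1
        if d <= e[2]:
            return 2
        if d <= e[3]:
            return 3
        return 4

    def bin_array(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        if (d < 0).any():
            raise ValueError("distances must be >= 0")
        e = self.edges
        out = np.full(d.shape, 4, dtype=int)
        out[d <= e[3]] = 3
        out[d <= e[2]] = 2
        out[d <= e[1]] = 1
        out[d < e[0]] = 0
        return out


CANONICAL_BINS = DistanceBins()

INTRA_ISLET_BIN = 0
PERI_ISLET_BIN = 1


def distance_to_islets(cells: pd.DataFrame, islets,
                       bins: DistanceBins = CANONICAL_BINS,
                       markers: list[str] | None = None) -> pd.DataFrame:
    """Per-cell distance records: distance to the nearest islet and its bin.

    ``cells`` needs centroid columns; ``islets`` is a list of objects with
    ``id``/``polygon``.  Returns a DataFrame (cell_id, distance_um,
    nearest_islet_id, distance_bin, plus any requested marker columns).
    Raises without islets — distance is undefined then.
    """
    if not islets:
        raise ValueError("distance undefined without islet annotations")
    polys = [i.polygon for i in islets]
    ids = [i.id for i in islets]
    xs = cells["centroid_x_um"].to_numpy(dtype=float)
    ys = cells["centroid_y_um"].to_numpy(dtype=float)
    n = len(cells)
    dist = np.empty(n)
    nearest = np.empty(n, dtype=int)
    for k in range(n):
        p = sgeom.Point(xs[k], ys[k])
        best_d, best_i = np.inf, -1
        for j, poly in enumerate(polys):
            d = poly.distance(p)
            if d < best_d:
                best_d, best_i = d, j
                if d == 0.0:
                    break
        dist[k] = best_d
        nearest[k] = ids[best_i]
    rec = pd.DataFrame({
        "cell_id": cells["cell_id"].to_numpy(),
        "distance_um": dist,
        "nearest_islet_id": nearest,
        "distance_bin": bins.bin_array(dist),
    })
    for m in (markers or []):
        col = m if m.endswith(("+", "-")) else f"{m}+"
        if col in cells.columns:
            rec[col] = cells[col].to_numpy(dtype=bool)
    return rec


def bin_distances(records: pd.DataFrame,
                  bins: DistanceBins = CANONICAL_BINS,
                  markers: list[str] | None = None) -> pd.DataFrame:
    """Per-marker histogram over the five bands (rows = bins).

    Column sums equal the per-marker record counts by construction.
    """
    b = bins.bin_array(records["distance_um"].to_numpy(dtype=float))
    marker_cols = [c for c in records.columns if c.endswith(("+", "-"))] \
        if markers is None else \
        [m if m.endswith(("+", "-")) else f"{m}+" for m in markers]
    out = {"bin": bins.labels}
    if not marker_cols:
        out["all"] = np.bincount(b, minlength=5)
    for col in marker_cols:
        sel = records[col].to_numpy(dtype=bool)
        out[col] = np.bincount(b[sel], minlength=5)
    return pd.DataFrame(out)


def render_heatmap(records: pd.DataFrame, cells: pd.DataFrame, islets,
                   extent_um: tuple[float, float], mpp: float,
                   path=None, clip_um: float = 250.0,
                   point_radius_px: int = 2) -> np.ndarray:
    """Distance heatmap raster: cells as dots colored by nearest-islet
    distance clipped to [0, clip_um] on a perceptually ordered colormap
    (turbo: 0 → black-blue, clip → red), islet outlines in white.

    Returns an RGB uint8 array of shape ``(extent_h/mpp, extent_w/mpp, 3)``;
    written as PNG when ``path`` is given.  Deterministic.
    """
    if len(records) == 0:
        raise ValueError("no distance records to render")
    from skimage.draw import disk as draw_disk
    from skimage.draw import polygon_perimeter

    w_um, h_um = extent_um
    H, W = int(round(h_um / mpp)), int(round(w_um / mpp))
    img = np.zeros((H, W, 3), dtype=np.uint8)
    cmap = plt.get_cmap("turbo")

    for islet in islets:
        xy = np.asarray(islet.polygon.exterior.coords)
        rr, cc = polygon_perimeter(
            np.clip(xy[:, 1] / mpp, 0, H - 1),
            np.clip(xy[:, 0] / mpp, 0, W - 1), shape=(H, W))
        img[rr, cc] = 255

    merged = records.merge(
        cells[["cell_id", "centroid_x_um", "centroid_y_um"]], on="cell_id")
    d = np.clip(merged["distance_um"].to_numpy(dtype=float), 0.0, clip_um)
    colors = (np.asarray(cmap(d / clip_um))[:, :3] * 255).astype(np.uint8)
    for (x, y), col in zip(merged[["centroid_x_um",
                                   "centroid_y_um"]].to_numpy(), colors):
        rr, cc = draw_disk((y / mpp, x / mpp), point_radius_px, shape=(H, W))
        img[rr, cc] = col
    if path is not None:
        plt.imsave(path, img)
    return img
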