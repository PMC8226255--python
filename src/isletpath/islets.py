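"""Islet segmentation: trainable pixel classification → islet objects.

A bagged decision-tree ensemble (a random forest, the classifier family
interactive digital-pathology tools default to) is trained on per-pixel
multiscale intensity features
inside a small labeled ROI, then applied across the whole tissue.  Predicted
islet pixels are grouped into connected components, holes are filled, each
component is polygonized, detected cells are attached by centroid, and — the
field's analysis convention — only components owning at least ``min_cells``
(default 10) cells become islet objects, which excludes scattered single
endocrine cells and small artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import shapely.geometry as sgeom
from scipy import ndimage as ndi
from skimage.measure import find_contours
from sklearn.ensemble import RandomForestClassifier

from .cells import CellDetectionResult
from .slide_io import Slide

__all__ = ["PixelClassifier", "IsletObject", "extract_pixel_features",
           "train_pixel_classifier", "create_islet_objects",
           "DEFAULT_SCALES_UM"]

#: Gaussian feature scales spanning nucleus-to-islet structure
DEFAULT_SCALES_UM = (1.0, 2.0, 4.0, 8.0)

ISLET_CLASS, IGNORE_CLASS = 1, 2


def extract_pixel_features(slide: Slide, roi=None,
                           scales_um=DEFAULT_SCALES_UM,
                           channels: list[str] | None = None) -> np.ndarray:
    """Per-pixel feature stack: raw intensity + Gaussian-smoothed intensity
    at each scale, per channel.  Returns (H, W, n_features) float32.

    ``roi`` is an optional ``(row_slice, col_slice)`` restriction; a ROI
    outside the image is an error.
    """
    if not len(scales_um):
        raise ValueError("scales_um must be nonempty")
    H, W = slide.shape
    if roi is not None:
        rs, cs = roi
        r0, r1, _ = rs.indices(H)
        c0, c1, _ = cs.indices(W)
        if (rs.start is not None and rs.start > H) or \
           (cs.start is not None and cs.start > W) or r0 >= r1 or c0 >= c1:
            raise ValueError(f"roi {roi} lies outside a {H}x{W} image")
    names = channels if channels is not None else slide.markers
    planes = []
    for m in names:
        ch = slide.channel(m).astype(np.float32)
        planes.append(ch)
        for s in scales_um:
            planes.append(ndi.gaussian_filter(ch, sigma=s / slide.mpp))
    stack = np.stack(planes, axis=-1)
    if roi is not None:
        stack = stack[roi[0], roi[1]]
    return stack


@dataclass
class PixelClassifier:
    """Trained per-pixel islet/ignore model plus its feature spec."""

    model: RandomForestClassifier
    scales_um: tuple[float, ...]
    channels: list[str]
    n_train_per_class: dict[int, int]
    seed: int
    training_accuracy: float = float("nan")
    version: str = "1"

    def predict_mask(self, slide: Slide, within: np.ndarray | None = None,
                     chunk_rows: int = 256) -> np.ndarray:
        """Boolean islet mask over the slide (restricted to ``within``)."""
        feats = extract_pixel_features(slide, scales_um=self.scales_um,
                                       channels=self.channels)
        H, W, F = feats.shape
        out = np.zeros((H, W), dtype=bool)
        mask = np.ones((H, W), dtype=bool) if within is None else within
        for r0 in range(0, H, chunk_rows):
            r1 = min(r0 + chunk_rows, H)
            sel = mask[r0:r1]
            if not sel.any():
                continue
            X = feats[r0:r1][sel]
            pred = self.model.predict(X) == ISLET_CLASS
            block = np.zeros(sel.shape, dtype=bool)
            block[sel] = pred
            out[r0:r1] = block
        return out

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "PixelClassifier":
        return joblib.load(path)


def train_pixel_classifier(features: np.ndarray, labels: np.ndarray,
                           seed: int = 0, scales_um=DEFAULT_SCALES_UM,
                           channels: list[str] | None = None,
                           n_estimators: int = 100, max_depth: int = 12,
                           max_per_class: int = 20_000) -> PixelClassifier:
    """Fit the tree ensemble on labeled pixels (1 = islet, 2 = ignore).

    ``features`` is an (H, W, F) stack aligned with the (H, W) label image;
    unlabeled pixels (0) are skipped.  Deterministic given ``seed``; class
    sizes above ``max_per_class`` are subsampled for tractability.
    """
    labels = np.asarray(labels)
    X = features.reshape(-1, features.shape[-1])
    y = labels.ravel()
    sel = y > 0
    X, y = X[sel], y[sel]
    present = np.unique(y)
    if not (ISLET_CLASS in present and IGNORE_CLASS in present):
        raise ValueError("need both islet and ignore examples")
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(y), dtype=bool)
    for cls in present:
        idx = np.flatnonzero(y == cls)
        if len(idx) > max_per_class:
            idx = rng.choice(idx, size=max_per_class, replace=False)
        keep[idx] = True
    X, y = X[keep], y[keep]
    model = RandomForestClassifier(n_estimators=n_estimators,
                                   max_depth=max_depth,
                                   random_state=int(seed) & 0x7FFFFFFF,
                                   n_jobs=1)
    model.fit(X, y)
    acc = float((model.predict(X) == y).mean())
    counts = {int(c): int((y == c).sum()) for c in present}
    return PixelClassifier(model=model, scales_um=tuple(scales_um),
                           channels=list(channels) if channels else [],
                           n_train_per_class=counts, seed=seed,
                           training_accuracy=acc)


@dataclass
class IsletObject:
    id: int
    polygon: sgeom.Polygon
    cell_ids: list[int] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def area_um2(self) -> float:
        return float(self.polygon.area)

    @property
    def equivalent_diameter_um(self) -> float:
        return 2.0 * float(np.sqrt(self.polygon.area / np.pi))


def _component_polygon(comp_mask: np.ndarray, offset_rc, mpp: float):
    padded = np.pad(comp_mask, 1)
    contours = find_contours(padded.astype(float), 0.5)
    if not contours:
        return None
    ext = max(contours, key=len)
    rr = ext[:, 0] - 1 + offset_rc[0]
    cc = ext[:, 1] - 1 + offset_rc[1]
    xy = np.column_stack([(cc + 0.5) * mpp, (rr + 0.5) * mpp])
    if len(xy) < 4:
        return None
    poly = sgeom.Polygon(xy)
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
    return poly if not poly.is_empty else None


def create_islet_objects(islet_mask: np.ndarray,
                         detection: CellDetectionResult,
                         min_cells: int = 10,
                         mpp: float | None = None):
    """Connected components → fill holes → polygonize → attach cells →
    drop components with fewer than ``min_cells`` cells.

    Returns ``(islets, endocrine_mask, cells)`` where ``endocrine_mask`` is
    the pixel-exact union of the retained islets (the endocrine compartment)
    and ``cells`` is the detection table with an ``islet_id`` column
    (−1 = exocrine).
    """
    mpp = mpp if mpp is not None else detection.mpp
    cells = detection.cells.copy()
    lab, n = ndi.label(islet_mask)
    if n == 0:
        cells["islet_id"] = -1
        return [], np.zeros_like(islet_mask, dtype=bool), cells

    # fill holes per component before the cell-count filter
    filled = ndi.binary_fill_holes(islet_mask)
    lab, n = ndi.label(filled)

    if len(cells):
        rr = np.clip((cells["centroid_y_um"].to_numpy() / mpp).astype(int),
                     0, lab.shape[0] - 1)
        cc = np.clip((cells["centroid_x_um"].to_numpy() / mpp).astype(int),
                     0, lab.shape[1] - 1)
        comp_of_cell = lab[rr, cc]
    else:
        comp_of_cell = np.empty(0, dtype=int)

    counts = np.bincount(comp_of_cell, minlength=n + 1)
    keep = [c for c in range(1, n + 1) if counts[c] >= min_cells]

    islets: list[IsletObject] = []
    endocrine = np.zeros_like(filled, dtype=bool)
    islet_id_of_comp = {}
    slices = ndi.find_objects(lab)
    for new_id, comp in enumerate(keep):
        sl = slices[comp - 1]
        comp_mask = lab[sl] == comp
        poly = _component_polygon(comp_mask, (sl[0].start, sl[1].start), mpp)
        if poly is None:
            continue
        endocrine[sl] |= comp_mask
        ids = cells.loc[comp_of_cell == comp, "cell_id"].tolist()
        islets.append(IsletObject(id=new_id, polygon=poly, cell_ids=ids))
        islet_id_of_comp[comp] = new_id

    assignment = np.full(len(cells), -1, dtype=int)
    for i, comp in enumerate(comp_of_cell):
        assignment[i] = islet_id_of_comp.get(int(comp), -1)
    cells["islet_id"] = assignment

    for islet in islets:
        assert islet.n_cells >= min_cells
    return islets, endocrine, cells
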