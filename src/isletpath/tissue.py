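"""Whole-tissue detection and compartment areas.

The tissue thresholder mirrors the common digital-pathology recipe: smooth the
unweighted mean of all channels, threshold it, drop small artifact components,
and fill holes.  Compartment arithmetic is pixel-exact by construction:
exocrine = tissue − endocrine, so areas always conserve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .slide_io import Slide

__all__ = ["ThresholderConfig", "TissueMask", "detect_tissue",
           "compartment_areas"]

log = logging.getLogger(__name__)


@dataclass
class ThresholderConfig:
    """Tissue thresholder settings (all physical units).

    threshold is on the mean-of-channels image after Gaussian smoothing; the
    default is calibrated for the synthetic renderer's default background.
    """

    smoothing_sigma_um: float = 4.0
    threshold: float = 5.0
    min_artifact_area_um2: float = 1e4
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.smoothing_sigma_um < 0:
            raise ValueError("smoothing_sigma_um must be >= 0")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


@dataclass
class TissueMask:
    mask: np.ndarray          # boolean H×W
    mpp: float
    n_components: int

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * self.mpp ** 2 / 1e6


def detect_tissue(slide: Slide, cfg: ThresholderConfig) -> TissueMask:
    """Threshold the smoothed mean-of-channels image into a tissue mask."""
    if slide.n_channels < 1:
        raise ValueError("slide has no channels")
    mean = slide.mean_image().astype(np.float64)
    sigma_px = cfg.smoothing_sigma_um / slide.mpp
    if sigma_px > 0:
        mean = ndi.gaussian_filter(mean, sigma=sigma_px)
    mask = mean > cfg.threshold

    if mask.any():
        lab, n = ndi.label(mask)
        if n:
            min_px = cfg.min_artifact_area_um2 / slide.mpp ** 2
            sizes = ndi.sum_labels(np.ones_like(lab, dtype=np.int64), lab,
                                   index=np.arange(1, n + 1))
            keep = np.flatnonzero(sizes >= min_px) + 1
            mask = np.isin(lab, keep)
        if cfg.fill_holes:
            mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        log.warning("tissue detection produced an empty mask")
        return TissueMask(mask=mask, mpp=slide.mpp, n_components=0)
    _, n = ndi.label(mask)
    return TissueMask(mask=mask, mpp=slide.mpp, n_components=int(n))


def compartment_areas(tissue: TissueMask,
                      islet_mask: np.ndarray) -> tuple[float, float, float]:
    """(tissue, exocrine, endocrine) areas in mm², pixel-exact.

    The endocrine mask is intersected with tissue so that the identity
    tissue = exocrine + endocrine holds exactly.
    """
    endo = np.asarray(islet_mask, dtype=bool) & tissue.mask
    px_area = tissue.mpp ** 2 / 1e6
    n_t = int(tissue.mask.sum())
    n_e = int(endo.sum())
    return n_t * px_area, (n_t - n_e) * px_area, n_e * px_area
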