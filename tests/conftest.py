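"""Shared fixtures: synthetic slides and pipeline runs reused across modules.

The expensive objects (a rendered slide, a full pipeline run) are
session-scoped so the suite pays for them once.  All randomness is fixed by
explicit seeds; hypothesis runs derandomized.
"""

import numpy as np
import pytest
from hypothesis import settings

from isletpath.pipeline import RunConfig, run_pipeline
from isletpath.synthetic import SlideSpec, generate_slide, truth_summary

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


# Band weights for small frames: a ~0.35 mm² section cannot contain exocrine
# farther than ~200 µm from every islet, so the far bands carry zero weight.
SMALL_WEIGHTS = (0.02, 0.28, 0.70, 0.0, 0.0)
# The 1.44 mm² recovery slide supports the 200-500 µm band as well.
E2E_WEIGHTS = (0.01, 0.12, 0.40, 0.47, 0.0)


def small_spec(**overrides) -> SlideSpec:
    base = dict(width_px=800, height_px=800, n_islets=8,
                islet_cells_min=12, islet_cells_max=120,
                immune_distance_weights=SMALL_WEIGHTS, seed=3)
    base.update(overrides)
    return SlideSpec(**base)


def e2e_spec(**overrides) -> SlideSpec:
    base = dict(width_px=1200, height_px=1200, n_islets=12,
                islet_cells_min=12, islet_cells_max=150,
                immune_distance_weights=E2E_WEIGHTS, seed=7)
    base.update(overrides)
    return SlideSpec(**base)


@pytest.fixture(scope="session")
def small_slide():
    """(slide, ground truth) for a 0.64 mm² frame with 8 islets."""
    return generate_slide(small_spec())


@pytest.fixture(scope="session")
def small_run(small_slide):
    """Full pipeline run on the small slide plus its truth oracle."""
    slide, gt = small_slide
    result = run_pipeline(slide, RunConfig(seed=1), truth=gt,
                          slide_id="small")
    return slide, gt, result, truth_summary(gt)


@pytest.fixture(scope="session")
def e2e_run():
    """End-to-end recovery run at the larger frame (the stress condition:
    more islets, both mid-range distance bands populated)."""
    spec = e2e_spec()
    slide, gt = generate_slide(spec)
    result = run_pipeline(slide, RunConfig(seed=2), truth=gt, slide_id="e2e")
    return spec, slide, gt, result, truth_summary(gt)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
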