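"""Published per-slide measurements of a non-diabetic donor characterization.

These printed tables are *inputs*: the raw slide images behind them were never
deposited, so the package reproduces the arithmetic relations among the
printed numbers (cohort means, population SDs, density and T-cell-subset
arithmetic, infiltration proportions) rather than the pixel-level counts.
Slide #6 was stained with chromogranin A instead of hormone markers, hence its
beta/alpha counts are NA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["slide_characterization_table", "immune_compartment_table",
           "TCELL_DISTANCE_BIN_COUNTS", "INFILTRATED_ISLETS",
           "CD45_ADJACENT", "TISSUE_AREA_CD45_SLIDE_MM2",
           "TISSUE_AREA_TCELL_SLIDE_MM2"]


def slide_characterization_table() -> pd.DataFrame:
    """Six-section endocrine/exocrine characterization (one donor block)."""
    rows = [
        ("1-PI/CD45/INS/GCG", 80.9, 79.8, 1.2, 260, 13625, 9571, 4537),
        ("2-INS/PI/GCG",      71.8, 70.6, 1.3, 262, 13129, 7581, 4163),
        ("3-INS/PC1/PI",      84.6, 83.4, 1.1, 234, 12441, 9040, 3401),
        ("4-INS/CPE/PI",      92.9, 91.7, 1.2, 273, 14616, 11682, 2934),
        ("5-INS/PC2/PI",     130.6, 128.3, 2.3, 432, 26655, 17579, 9076),
        ("6-CD3/CD8/CHGA",    75.0, 74.14, 0.9, 241, 13203, np.nan, np.nan),
    ]
    return pd.DataFrame(rows, columns=[
        "slide_id", "tissue_area_mm2", "exocrine_area_mm2",
        "endocrine_area_mm2", "n_islets", "n_islet_cells", "n_beta",
        "n_alpha"])


#: tissue area of the CD45 slide (#1) and the CD3/CD8 slide (#6), mm²
TISSUE_AREA_CD45_SLIDE_MM2 = 80.9
TISSUE_AREA_TCELL_SLIDE_MM2 = 75.0


def immune_compartment_table() -> pd.DataFrame:
    """Immune counts per compartment (CD45 from slide #1, T cells from #6)."""
    rows = [
        ("tissue",    17116, 8643, 3911),
        ("exocrine",  17098, 8639, 3909),
        ("endocrine",    18,    4,    2),
    ]
    return pd.DataFrame(rows, columns=["compartment", "n_CD45", "n_CD3",
                                       "n_CD8"])


#: printed T-cell counts in the distance bands [0,1), [1,50] and (200,500] µm
TCELL_DISTANCE_BIN_COUNTS = {
    "CD3": {0: 5, 1: 619, 3: 4029},
    "CD8": {0: 3, 1: 315, 3: 1728},
}

#: islets infiltrated by at least one cell of a marker / total islets
INFILTRATED_ISLETS = {"CD3": (4, 241), "CD8": (2, 241), "CD4": (2, 241)}

#: CD45+ cells found within or immediately adjacent to islets, of 260 islets
CD45_ADJACENT = (18, 260)
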