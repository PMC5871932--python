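"""Built-in reference datasets from the historical buckwheat breeding experiment.

These printed summary tables are inputs to the pipeline: the published
selection-index coefficients, the trait correlation matrices from the
historical field trial and the initial breeding population, the 2014
common-garden population summaries, and the marker-panel bookkeeping counts.
They let the evaluation and acceptance paths run fully offline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .index import SelectionIndexModel
from .simulate import nearest_correlation

TRAIT_NAMES = [
    "main_stem_length",
    "number_of_nodes",
    "days_to_first_flowering",
    "number_of_flower_clusters",
    "number_of_primary_branches",
    "thousand_seed_weight",
    "test_weight",
]

# published PCR coefficients (2 components, original trait scale)
INDEX_COEFFICIENTS = {
    "main_stem_length": 0.0550,
    "number_of_nodes": 0.0053,
    "days_to_first_flowering": 0.0011,
    "number_of_flower_clusters": 0.0728,
    "number_of_primary_branches": 0.0015,
    "thousand_seed_weight": -0.0001,
    "test_weight": 0.0306,
}


def selection_index_model() -> SelectionIndexModel:
    """Published selection index: fixed coefficients, no intercept."""
    return SelectionIndexModel(
        TRAIT_NAMES,
        np.array([INDEX_COEFFICIENTS[t] for t in TRAIT_NAMES]),
        intercept=0.0,
        n_components=2,
    )


# correlations of seed yield with the seven index traits (historical field trial)
YIELD_TRAIT_CORR = {
    "main_stem_length": 0.74,
    "number_of_nodes": 0.85,
    "days_to_first_flowering": 0.05,
    "number_of_flower_clusters": 0.66,
    "number_of_primary_branches": 0.52,
    "thousand_seed_weight": -0.22,
    "test_weight": 0.47,
}

# trait x trait correlations: upper triangle = historical field trial,
# lower triangle = initial breeding population
_UPPER = [
    [1.00, 0.85, 0.16, 0.53, 0.41, 0.13, 0.40],
    [np.nan, 1.00, 0.12, 0.75, 0.64, -0.22, 0.27],
    [np.nan, np.nan, 1.00, 0.18, 0.23, 0.54, 0.07],
    [np.nan, np.nan, np.nan, 1.00, 0.73, -0.13, 0.03],
    [np.nan, np.nan, np.nan, np.nan, 1.00, -0.37, -0.43],
    [np.nan, np.nan, np.nan, np.nan, np.nan, 1.00, 0.22],
    [np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 1.00],
]
_LOWER = [
    [1.00, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan],
    [0.56, 1.00, np.nan, np.nan, np.nan, np.nan, np.nan],
    [0.40, 0.27, 1.00, np.nan, np.nan, np.nan, np.nan],
    [0.36, 0.46, 0.26, 1.00, np.nan, np.nan, np.nan],
    [0.10, 0.16, 0.09, 0.40, 1.00, np.nan, np.nan],
    [0.16, 0.03, -0.04, 0.04, -0.02, 1.00, np.nan],
    [0.13, 0.26, 0.09, 0.31, 0.19, 0.24, 1.00],
]


def _symmetrize(tri: list[list[float]], upper: bool) -> np.ndarray:
    a = np.array(tri, dtype=float)
    out = np.where(np.isnan(a), a.T, a)
    if np.isnan(out).any():
        raise ValueError("triangle incomplete")
    return out if upper else out


def field_trial_trait_corr() -> pd.DataFrame:
    """7x7 trait correlation matrix from the historical field trial."""
    return pd.DataFrame(_symmetrize(_UPPER, True), index=TRAIT_NAMES, columns=TRAIT_NAMES)


def initial_population_trait_corr() -> pd.DataFrame:
    """7x7 trait correlation matrix observed in the initial breeding population."""
    return pd.DataFrame(_symmetrize(_LOWER, False), index=TRAIT_NAMES, columns=TRAIT_NAMES)


def target_architecture_corr() -> pd.DataFrame:
    """8x8 genetic-correlation target (yield + seven index traits),
    nearest-PSD repaired, for the synthetic trait architecture."""
    names = ["seed_yield"] + TRAIT_NAMES
    a = np.eye(8)
    a[1:, 1:] = field_trial_trait_corr().to_numpy()
    for j, t in enumerate(TRAIT_NAMES, start=1):
        a[0, j] = a[j, 0] = YIELD_TRAIT_CORR[t]
    return pd.DataFrame(nearest_correlation(a), index=names, columns=names)


# 2014 common-garden evaluation: population label -> (n, {column: (mean, sd)})
_EVAL_COLUMNS = TRAIT_NAMES + [
    "number_of_secondary_branches",
    "number_of_seeds_per_plant",
    "selection_index",
]

_EVAL_2014 = {
    "initial": (34, [(100.50, 17.72), (11.15, 1.44), (20.41, 1.23), (69.91, 23.78),
                     (4.44, 0.93), (29.27, 2.83), (565.92, 61.19), (7.41, 2.91),
                     (407.68, 181.60), (28.35, 3.09)]),
    "post_gs1_ps1": (30, [(112.20, 14.16), (11.87, 1.50), (21.27, 0.98), (82.70, 29.07),
                          (4.47, 0.97), (29.27, 3.10), (576.42, 47.24), (7.97, 2.30),
                          (452.33, 173.99), (29.92, 3.34)]),
    "post_gs2": (31, [(117.74, 15.28), (12.35, 1.30), (21.61, 1.56), (84.52, 25.19),
                      (4.55, 0.99), (30.39, 3.79), (616.43, 46.43), (8.16, 2.63),
                      (454.52, 137.11), (31.58, 2.81)]),
    "post_ps2": (34, [(117.91, 14.63), (12.18, 1.29), (21.15, 0.86), (90.12, 22.37),
                      (4.74, 0.96), (29.60, 2.92), (617.80, 26.58), (8.03, 2.12),
                      (524.94, 147.04), (32.04, 2.31)]),
    "post_gs3": (34, [(125.29, 16.77), (12.47, 1.35), (21.91, 1.38), (101.29, 24.75),
                      (4.82, 0.90), (28.37, 3.41), (600.67, 49.37), (9.00, 2.70),
                      (562.24, 137.70), (32.74, 2.25)]),
    "post_gs4": (35, [(133.14, 14.58), (12.94, 1.28), (22.31, 1.43), (100.94, 31.01),
                      (4.60, 1.06), (30.28, 2.70), (593.85, 49.00), (8.23, 1.78),
                      (539.00, 166.49), (32.90, 3.45)]),
    "post_ps3": (35, [(119.17, 12.46), (12.06, 1.64), (21.40, 2.74), (98.57, 34.04),
                      (4.74, 1.15), (29.91, 3.82), (613.63, 51.47), (9.00, 2.39),
                      (515.94, 115.81), (32.60, 2.74)]),
    "post_gs5": (35, [(130.89, 17.82), (13.26, 1.46), (21.91, 1.29), (123.51, 35.42),
                      (4.31, 0.87), (29.49, 3.13), (611.20, 46.57), (9.37, 1.96),
                      (556.40, 170.56), (34.99, 3.49)]),
    "post_gs6": (33, [(129.21, 16.37), (13.67, 1.55), (22.06, 2.01), (114.42, 28.73),
                      (4.85, 0.83), (28.46, 2.93), (612.75, 44.11), (9.21, 2.52),
                      (588.21, 167.63), (34.29, 3.12)]),
}

POPULATION_ORDER = list(_EVAL_2014)


def evaluation_summary_2014() -> pd.DataFrame:
    """Published per-population means/SDs (long format: one row per
    population x column with n, mean, sd)."""
    rows = []
    for label, (n, stats) in _EVAL_2014.items():
        for col, (mean, sd) in zip(_EVAL_COLUMNS, stats):
            rows.append({"population": label, "trait": col, "n": n, "mean": mean, "sd": sd})
    return pd.DataFrame(rows)


# marker-panel bookkeeping from the breeding experiment
MARKERS_GENOTYPED_AFTER_FIRST_YEAR = 14598
MARKERS_ON_LINKAGE_MAP = 1511
MAPPED_LOCI_TOTAL = 756
MAPPED_LOCI_POLYMORPHIC = 492
PANEL_SIZES_BY_CYCLE = {"GS2": 11480, "GS3": 6373, "GS4": 6225, "GS5": 4614, "GS6": 4417}
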