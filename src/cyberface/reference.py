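"""Published summary tables from the original 14-patient clinical cohort.

The raw patient videos are not publicly available; what is available are
the aggregated tables reported for that cohort.  They serve two purposes
here: as fixtures for the arithmetic identities the pipeline must satisfy
(interval columns summing to 100, difference grids, masked means
recomputable from component means by linearity), and as calibration
targets for the synthetic-cohort generator.
"""

from __future__ import annotations

import pandas as pd

from .emotions import EMOTIONS

_INTERVALS = list(range(1, 11))

_GRID_INCLUSION = {
    "happiness": [15.64, 24.10, 10.99, 12.20, 15.79, 5.10, 11.04, 10.99, 12.48, 8.40],
    "sadness": [25.68, 24.62, 29.71, 29.89, 32.32, 32.78, 36.70, 31.36, 26.97, 32.50],
    "anger": [22.78, 21.76, 13.92, 19.49, 14.84, 18.69, 18.36, 23.61, 30.77, 27.05],
    "surprise": [10.26, 9.19, 9.16, 9.41, 11.00, 9.65, 10.86, 8.26, 4.40, 3.76],
    "fear": [4.36, 5.79, 1.90, 2.93, 1.50, 1.72, 1.96, 0.51, 0.56, 7.33],
    "disgust": [1.94, 0.51, 0.51, 0.51, 1.58, 2.83, 2.88, 6.62, 7.05, 2.58],
    "contempt": [19.34, 14.03, 33.81, 25.57, 22.97, 29.24, 18.19, 18.66, 17.78, 18.39],
}

_GRID_EXCLUSION = {
    "happiness": [12.77, 14.95, 15.24, 20.00, 13.44, 14.07, 21.43, 27.25, 22.60, 32.70],
    "sadness": [26.77, 20.26, 21.90, 30.00, 25.79, 34.54, 30.80, 23.92, 27.29, 36.79],
    "anger": [24.15, 19.96, 15.71, 16.19, 13.41, 8.86, 14.29, 13.37, 6.70, 7.11],
    "surprise": [5.83, 15.49, 15.24, 12.86, 13.88, 21.21, 8.04, 13.44, 19.78, 20.44],
    "fear": [4.84, 2.89, 6.67, 4.29, 3.85, 2.86, 3.57, 3.37, 5.82, 0.71],
    "disgust": [2.38, 1.47, 0.48, 2.86, 1.90, 1.90, 3.57, 1.47, 0.00, 0.00],
    "contempt": [23.27, 24.98, 24.76, 13.81, 27.73, 16.56, 18.30, 17.18, 17.80, 2.25],
}

#: Group-mean total AUC per emotion (standardized frame axis).
_AUC_MEANS = {
    "inclusion": {
        "happiness": 186.40, "sadness": 300.23, "anger": 228.74,
        "surprise": 74.20, "fear": 44.86, "disgust": 35.52, "contempt": 204.70,
    },
    "exclusion": {
        "happiness": 257.26, "sadness": 320.21, "anger": 89.59,
        "surprise": 128.47, "fear": 50.88, "disgust": 35.37, "contempt": 193.72,
    },
}

#: Group-mean masked AUC (emotion + happiness) as printed; the inclusion
#: column is internally inconsistent with its component means by ~0.23
#: (a rounding artifact of the source table), the exclusion column is exact.
_MASKED_MEANS = {
    "inclusion": {
        "sadness": 486.87, "anger": 415.00, "surprise": 260.84,
        "fear": 231.49, "disgust": 222.15, "contempt": 391.34,
    },
    "exclusion": {
        "sadness": 577.47, "anger": 346.85, "surprise": 385.73,
        "fear": 308.14, "disgust": 292.63, "contempt": 450.98,
    },
}

#: The headline comparative-error example: happiness in the final interval
#: rose from 8.40% (inclusion) to 32.70% (exclusion).
COMPARATIVE_ERROR_EXAMPLE = {"p1": 8.40, "p2": 32.70, "n_observed": 14, "n_hypothetical": 20}

#: Need Threat Scale summary: mean (SD) per condition, n = 14.
NTS_SUMMARY = {"inclusion_mean": 78.50, "exclusion_mean": 110.57, "sd": 29.0, "n": 14}


def reference_interval_grids() -> dict[str, pd.DataFrame]:
    """The 7-emotion x 10-interval percentage grids per condition."""
    return {
        "inclusion": pd.DataFrame(_GRID_INCLUSION, index=_INTERVALS).T.loc[list(EMOTIONS)],
        "exclusion": pd.DataFrame(_GRID_EXCLUSION, index=_INTERVALS).T.loc[list(EMOTIONS)],
    }


def reference_auc_means() -> pd.DataFrame:
    """Group-mean total AUC per emotion and condition."""
    return pd.DataFrame(_AUC_MEANS).loc[list(EMOTIONS)]


def reference_masked_means() -> pd.DataFrame:
    """Group-mean masked AUC (emotion + happiness) per condition, as printed."""
    order = [e for e in EMOTIONS if e != "happiness"]
    return pd.DataFrame(_MASKED_MEANS).loc[order]
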