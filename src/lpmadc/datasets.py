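"""Published per-tumor response tables for two radiotherapy xenograft cohorts.

These are the reported per-tumor statistics from a preclinical diffusion-MRI
study of two colorectal carcinoma xenograft lines (LoVo and HCT116) given a
single 10 Gy radiotherapy fraction, with ADC measured at baseline and 72 h.
The raw imaging data are not publicly deposited, but the derived per-tumor
numbers — Z-score, responding-volume effect (%) and its 1-SD error (%) for
each treated tumor, leave-all-in and leave-one-out Z-scores for each control
tumor, and the conventional t-test Z-scores — are reproduced here so that
the package's arithmetic (Z = effect/error, root-sum-square cohort
combination, cohort summaries) can be exercised against real study numbers.

Each treated row is ``(tumor, z, effect_pct, error_pct)``; control rows are
``(tumor, z_all_in, z_loo)``.
"""

from __future__ import annotations

import numpy as np

#: Treated LoVo cohort: per-tumor Z, responding volume (%) and error (%).
LOVO_TREATED = [
    (1, 8.5, 45.98, 5.40),
    (2, 8.8, 44.59, 5.09),
    (3, 3.4, 35.64, 10.47),
    (4, 5.9, 31.37, 5.24),
    (5, 5.3, 40.41, 7.57),
    (6, 6.1, 35.77, 5.87),
    (7, 6.1, 65.75, 10.80),
    (8, 8.6, 68.64, 7.94),
    (9, 8.5, 55.51, 6.50),
    (10, 5.4, 27.57, 5.10),
]

#: Treated HCT116 cohort: per-tumor Z, responding volume (%) and error (%).
HCT116_TREATED = [
    (1, 3.5, 66.66, 19.01),
    (2, 3.1, 34.53, 11.30),
    (3, 10.3, 67.00, 6.53),
    (4, 7.5, 67.10, 8.97),
    (5, 7.2, 84.41, 11.80),
    (6, 7.3, 60.77, 8.35),
    (7, 3.9, 49.04, 12.36),
    (8, 8.3, 49.71, 6.01),
    (9, 7.3, 70.58, 9.67),
    (10, 20.1, 83.89, 4.18),
    (11, 4.9, 40.94, 8.32),
    (12, 9.9, 75.82, 7.61),
    (13, 3.7, 65.56, 17.87),
    (14, 9.7, 61.36, 6.35),
    (15, 2.5, 22.67, 8.93),
]

#: Control cohorts: per-tumor leave-all-in and leave-one-out Z-scores.
LOVO_CONTROL = [
    (1, 0.5, 1.2), (2, 1.1, 1.0), (3, 0.6, 0.5), (4, 2.9, 5.2),
    (5, 0.2, 0.0), (6, 0.8, 0.3), (7, 1.2, 0.4), (8, 0.9, 0.5),
]
HCT116_CONTROL = [
    (1, 0.5, 0.1), (2, 0.6, 0.3), (3, 0.8, 1.0), (4, 0.9, 0.7),
    (5, 0.2, 0.3), (6, 1.4, 1.8), (7, 0.8, 0.5), (8, 1.4, 2.2),
    (9, 1.7, 1.4), (10, 0.6, 0.8), (11, 1.0, 0.8), (12, 2.0, 3.5),
    (13, 0.3, 0.0),
]

#: Conventional-arm Z-scores per summary parameter (volume, mean ADC, IQR).
CONVENTIONAL_Z = {
    "lovo": [3.3, 3.5, 2.0],
    "hct116": [4.6, 4.3, 2.1],
}


def treated_table(cohort: str) -> np.ndarray:
    """Treated-cohort rows as a float array (tumor, z, effect, error)."""
    table = {"lovo": LOVO_TREATED, "hct116": HCT116_TREATED}[cohort]
    return np.asarray(table, dtype=float)


def control_z(cohort: str, which: str = "all_in") -> np.ndarray:
    """Control-cohort Z-scores, leave-all-in or leave-one-out."""
    table = {"lovo": LOVO_CONTROL, "hct116": HCT116_CONTROL}[cohort]
    col = {"all_in": 1, "loo": 2}[which]
    return np.asarray([row[col] for row in table], dtype=float)
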