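"""Published summary statistics packaged as reusable fixtures.

These are the group-level numbers from the 619-patient multicenter breast
cancer study the risk system was built on: per-grade contingency counts,
categorical frequencies by LN status, and the median/IQR of every
quantitative SWE parameter per LN group.  Contingency counts allow exact
recomputation of the study's rank and odds-ratio statistics; the median/IQR
summaries calibrate the synthetic-cohort generator.
"""

from __future__ import annotations

import numpy as np

from .grades import GradeContingency

__all__ = [
    "N_TOTAL",
    "N_POSITIVE",
    "N_NEGATIVE",
    "GRADE_CONTINGENCY",
    "STIFF_RIM_2X2",
    "BIRADS_BY_LN",
    "T_STAGE_BY_LN",
    "LOCATION_BY_LN",
    "SWE_MEDIAN_IQR",
    "FEATURE_CUTOFFS",
]

N_NEGATIVE = 445
N_POSITIVE = 174
N_TOTAL = 619

#: Risk grade (0-4) by LN status; rows of the published grade table.
GRADE_CONTINGENCY = GradeContingency(
    neg_counts=(39, 126, 142, 116, 22),
    pos_counts=(3, 30, 46, 64, 31),
)

#: Stiff-rim sign by LN status: rows (present, absent), columns (negative, positive).
STIFF_RIM_2X2 = np.array([[304, 143], [141, 31]])

#: BI-RADS category by LN status: rows (3, 4A, 4B, 4C, 5), columns (negative, positive).
BIRADS_BY_LN = np.array(
    [
        [8, 3],
        [57, 19],
        [111, 37],
        [191, 55],
        [78, 60],
    ]
)

#: Tumor T stage by LN status: rows (T1, T2_T3), columns (negative, positive).
T_STAGE_BY_LN = np.array([[244, 88], [201, 86]])

#: Tumor quadrant by LN status: rows (upper_outer, upper_inner, lower_outer,
#: lower_inner), columns (negative, positive).
LOCATION_BY_LN = np.array([[263, 101], [106, 34], [55, 29], [21, 10]])

#: Published median (q1-q3) of each quantitative SWE parameter, by LN group.
#: Keys are canonical cohort column names; values are (median, q1, q3) in kPa
#: (e_ratio dimensionless).
SWE_MEDIAN_IQR = {
    "negative": {
        "tumor_emean": (24.50, 17.88, 32.89),
        "tumor_emax": (115.03, 79.18, 165.53),
        "tumor_emin": (3.64, 1.67, 5.41),
        "tumor_esd": (15.02, 10.67, 21.64),
        "e_ratio": (5.61, 4.20, 7.31),
        "shell1_emean": (34.47, 25.88, 47.87),
        "shell1_emax": (140.54, 97.98, 207.07),
        "shell1_emin": (3.23, 1.05, 5.65),
        "shell1_esd": (22.92, 15.87, 31.86),
        "shell2_emean": (36.02, 26.27, 47.75),
        "shell2_emax": (147.05, 105.21, 212.23),
        "shell2_emin": (2.72, 0.90, 5.27),
        "shell2_esd": (22.63, 16.79, 32.33),
        "shell3_emean": (35.97, 25.60, 45.77),
        "shell3_emax": (147.68, 104.28, 209.37),
        "shell3_emin": (2.65, 0.98, 5.40),
        "shell3_esd": (22.23, 16.27, 31.31),
    },
    "positive": {
        "tumor_emean": (23.66, 18.00, 34.07),
        "tumor_emax": (110.05, 73.31, 163.98),
        "tumor_emin": (2.67, 1.18, 4.79),
        "tumor_esd": (14.67, 9.35, 22.11),
        "e_ratio": (5.24, 4.27, 7.39),
        "shell1_emean": (33.34, 25.75, 47.33),
        "shell1_emax": (131.76, 89.86, 194.43),
        "shell1_emin": (2.70, 1.01, 5.35),
        "shell1_esd": (21.91, 14.78, 30.08),
        "shell2_emean": (34.73, 25.13, 47.18),
        "shell2_emax": (146.00, 100.27, 199.41),
        "shell2_emin": (2.32, 0.83, 4.39),
        "shell2_esd": (22.11, 15.13, 30.31),
        "shell3_emean": (34.64, 23.77, 45.69),
        "shell3_emax": (146.00, 101.97, 202.73),
        "shell3_emin": (2.03, 0.66, 3.55),
        "shell3_esd": (21.42, 15.43, 28.84),
    },
}

#: Published operating cutoffs ("suspicious if <= cutoff") for the two
#: predictive quantitative features.
FEATURE_CUTOFFS = {"tumor_emin": 3.31, "shell3_emin": 3.52}


def check_totals() -> None:
    """Assert the fixtures' marginal totals match the published cohort sizes."""
    gc = GRADE_CONTINGENCY
    assert gc.n_negative == N_NEGATIVE and gc.n_positive == N_POSITIVE
    assert gc.n_total == N_TOTAL
    assert STIFF_RIM_2X2.sum() == N_TOTAL
    assert STIFF_RIM_2X2[:, 0].sum() == N_NEGATIVE
    assert BIRADS_BY_LN.sum() == N_TOTAL
    assert BIRADS_BY_LN[:, 1].sum() == N_POSITIVE
    assert T_STAGE_BY_LN.sum() == N_TOTAL
    assert LOCATION_BY_LN.sum() == N_TOTAL


check_totals()
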