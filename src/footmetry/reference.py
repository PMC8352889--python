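"""Published reference cohort summary for adult flexible flatfoot.

Mean and standard deviation of the 32 measurements over a published
clinical cohort of 21 adult flexible flatfeet scanned with cone-beam CT in
single-leg weight-bearing, with every foot segmented twice: by a
semi-automatic tool (dense, detailed meshes; "semi_auto" below) and by a
fully automatic tool (smooth, decimated meshes; "auto").  Angles in
degrees, heights in mm, FAO as % of foot length and in mm.

These numbers serve two purposes in this package: they parameterise the
flatfoot template of the synthetic generator, and they are the fixture for
the cohort-level consistency checks (threshold counts, arch-angle gaps,
convention identities).
"""

from __future__ import annotations

import pandas as pd

N_FEET = 21

# code: (semi_auto mean, semi_auto sd, auto mean, auto sd)
_TABLE = {
    "IL_TI":     (8.94, 5.93, 8.36, 5.76),
    "IL_TA":     (24.33, 7.49, 20.88, 7.28),
    "IL_CA":     (-8.83, 5.11, -7.77, 5.02),
    "IT_TA":     (27.38, 10.55, 27.00, 10.70),
    "IT_CA":     (5.91, 4.05, 5.18, 3.78),
    "RF_TICA":   (49.43, 24.73, 51.03, 29.09),
    "RL_TICA":   (17.59, 7.13, 16.00, 6.72),
    "RT_TICA":   (59.55, 22.44, 57.18, 24.33),
    "RF_TACA":   (86.34, 27.45, 93.09, 33.79),
    "RL_TACA":   (33.16, 6.53, 28.64, 6.22),
    "RT_TACA":   (-21.47, 10.71, -21.82, 10.20),
    "RF_TANA":   (74.29, 12.34, 75.92, 13.61),
    "RL_TANA":   (13.10, 12.04, 16.29, 11.76),
    "RT_TANA":   (-48.16, 13.12, -45.79, 12.88),
    "RL_CAM1":   (158.87, 8.63, 159.74, 8.36),
    "RL_TACAM1": (139.71, 8.37, 140.28, 7.99),
    "RL_TAM1":   (-12.12, 8.79, -8.50, 8.97),
    "RT_TAM1":   (-20.38, 11.23, -20.80, 12.12),
    "RT_M1M2":   (-13.09, 3.66, -12.38, 3.29),
    "FAO_%":     (13.32, 4.32, 13.36, 4.43),
    "FAO_mm":    (19.45, 6.68, 19.52, 6.77),
    "I3_CA":     (-8.77, 5.09, -7.73, 5.01),
    "I3_TA":     (21.29, 5.65, 18.18, 5.43),
    "R3_TICA":   (73.95, 6.97, 75.15, 6.74),
    "R3_TACA":   (37.54, 8.11, 34.45, 8.07),
    "R3_CAM1":   (157.77, 8.17, 158.33, 7.55),
    "R3_TAM1":   (22.93, 9.81, 22.58, 10.35),
    "R3_TANA":   (45.60, 8.93, 45.24, 8.89),
    "R3_TACAM1": (133.65, 6.61, 133.88, 6.28),
    "Hg_NA":     (24.22, 5.24, 23.97, 5.30),
    "Hg_CU":     (18.71, 3.57, 18.51, 3.57),
    "Hg_CM":     (18.55, 3.39, 18.46, 3.40),
}

#: Codes for which the published method comparison found no statistically
#: significant semi-automatic vs automatic difference (p >= 0.05).
NOT_SIGNIFICANT = (
    "IT_TA", "RF_TICA", "RT_TACA", "RF_TANA", "RT_TAM1",
    "FAO_%", "FAO_mm", "R3_CAM1", "R3_TAM1", "R3_TANA", "R3_TACAM1",
)


def reference_table() -> pd.DataFrame:
    """The reference cohort summary as a DataFrame indexed by code, with
    columns ``mean_semi_auto, sd_semi_auto, mean_auto, sd_auto``."""
    df = pd.DataFrame.from_dict(
        _TABLE, orient="index",
        columns=["mean_semi_auto", "sd_semi_auto", "mean_auto", "sd_auto"])
    df.index.name = "code"
    return df


def reference_means(method: str = "semi_auto") -> dict[str, float]:
    col = 0 if method == "semi_auto" else 2
    return {code: row[col] for code, row in _TABLE.items()}


def reference_sds(method: str = "semi_auto") -> dict[str, float]:
    col = 1 if method == "semi_auto" else 3
    return {code: row[col] for code, row in _TABLE.items()}
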