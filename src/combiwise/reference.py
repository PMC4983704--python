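"""Published screening summary statistics for the 58 candidate outcomes.

These are the printed cohort-level summaries from the outcome-comparison
study the composite scale was developed in: for each candidate biomarker,
the mean relative yearly change (%) and its SD, the sensitivity z-score
(mean/SD) and the one-sample-test p-value in the discovery cohort
(IPPOMS1, n = 35 primary-progressive MS), plus the step-down-Sidak
adjusted p-values in the two validation cohorts (IPPOMS2, n = 34
primary-progressive; RIVITALISE, n = 29 secondary-progressive) for the
biomarkers carried forward at p < 0.05.  Adjusted p-values were computed
over the family of 15 carried biomarkers.  The EDSS entry in RIVITALISE
was tested on the whole dataset because the outlier fences would have
removed about a third of that cohort.

They serve as published inputs for reproducibility checks (recomputing
z-scores from mean/SD, counting discovery and validation significances)
and supply the composite row's mean 9.10 / SD 13.23 used in the power
analysis.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = (
    "category",
    "biomarker",
    "mean_pct",
    "sd_pct",
    "z",
    "p_ippoms1",
    "p_adj_ippoms2",
    "p_adj_rivitalise",
    "whole_dataset",
)

# category, biomarker, mean Δ%, SD, z, p (IPPOMS1 raw),
# adjusted p (IPPOMS2), adjusted p (RIVITALISE), tested-on-whole-dataset flag
_ROWS = [
    ("clinical", "EDSS", 6.48, 14.15, 0.4580, 0.0116, 0.0109, 0.3293, True),
    ("clinical", "SNRS", -4.54, 8.71, 0.5212, 0.0046, 0.0052, 0.0766, False),
    ("clinical", "25FW", 64.52, 193.12, 0.3341, 0.0029, 0.1537, 0.3293, False),
    ("clinical", "9HPT", 18.73, 86.89, 0.2156, 0.1341, None, None, False),
    ("clinical", "PASAT", 5.72, 23.88, 0.2395, 0.3438, None, None, False),
    ("clinical", "MSFC", -11.24, 277.32, 0.0405, 0.3197, None, None, False),
    ("clinical", "SDMT", -2.26, 12.13, 0.1863, 0.2930, None, None, False),
    ("clinical", "CombiWISE", 9.10, 13.23, 0.6878, 0.0003, 0.0107, 0.0445, False),
    ("electrophysiological", "SumCMCT", 5.07, 21.18, 0.2394, 0.1852, None, None, False),
    ("volumetric", "V-SIENA", -0.70, 1.70, 0.4118, 0.0178, 0.0980, 0.6454, False),
    ("volumetric", "V-Brain", -0.12, 2.17, 0.0553, 0.9803, None, None, False),
    ("volumetric", "V-Ventricles", 3.45, 7.01, 0.4922, 0.0081, 0.0032, 0.0249, False),
    ("volumetric", "V-CorticalGM", 1.26, 15.71, 0.0802, 0.4792, None, None, False),
    ("volumetric", "V-Thalamus", -3.84, 8.86, 0.4334, 0.0084, 0.4416, 0.4314, False),
    ("volumetric", "V-CaudatePutamen", -1.61, 13.65, 0.1179, 0.3879, None, None, False),
    ("volumetric", "A-CS-Dens", -0.31, 23.04, 0.0135, 0.9418, None, None, False),
    ("oct", "OCT", -1.48, 4.72, 0.3136, 0.0970, None, None, False),
    ("qt1", "qT1-IC", 1.71, 4.84, 0.3533, 0.1155, None, None, False),
    ("qt1", "qT1-CC", 1.21, 5.64, 0.2145, 0.2507, None, None, False),
    ("qt1", "qT1-Caudate", 1.71, 5.84, 0.2928, 0.2369, None, None, False),
    ("qt1", "qT1-Putamen", 0.99, 5.47, 0.1810, 0.3304, None, None, False),
    ("qt1", "qT1-Thalamus", 2.09, 5.00, 0.4180, 0.0296, 0.6820, 0.4314, False),
    ("qt1", "qT1-Midbrain", 0.93, 5.22, 0.1782, 0.3394, None, None, False),
    ("qt1", "qT1-Pons", 0.00, 5.06, 0.0000, 0.9975, None, None, False),
    ("qt1", "qT1-Medulla", 0.19, 5.95, 0.0319, 0.8598, None, None, False),
    ("qt1", "qT1-SC-Dens", 1.46, 31.53, 0.0463, 0.1655, None, None, False),
    ("dti", "DTI-T-IC", 0.78, 9.56, 0.0816, 0.6584, None, None, False),
    ("dti", "DTI-II-IC", 3.69, 12.19, 0.3027, 0.1455, None, None, False),
    ("dti", "DTI-MD-IC", 2.23, 6.85, 0.3255, 0.0853, None, None, False),
    ("dti", "DTI-FA-IC", 2.47, 11.26, 0.2194, 0.4937, None, None, False),
    ("dti", "DTI-T-ICPost", 1.30, 11.15, 0.1166, 0.5279, None, None, False),
    ("dti", "DTI-II-ICPost", 2.66, 8.68, 0.3065, 0.1064, None, None, False),
    ("dti", "DTI-MD-ICPost", 1.89, 6.25, 0.3024, 0.1080, None, None, False),
    ("dti", "DTI-FA-ICPost", 1.24, 7.12, 0.1742, 0.7887, None, None, False),
    ("dti", "DTI-T-CC", -1.77, 14.81, 0.1195, 0.5172, None, None, False),
    ("dti", "DTI-II-CC", 1.69, 7.51, 0.2250, 0.4837, None, None, False),
    ("dti", "DTI-MD-CC", 0.59, 7.12, 0.0829, 0.6513, None, None, False),
    ("dti", "DTI-FA-CC", 1.40, 4.15, 0.3373, 0.1439, None, None, False),
    ("dti", "DTI-T-Caudate", 4.78, 8.89, 0.5377, 0.0063, 0.0032, 0.0783, False),
    ("dti", "DTI-II-Caudate", 3.14, 7.52, 0.4176, 0.0294, 0.0035, 0.0342, False),
    ("dti", "DTI-MD-Caudate", 4.06, 7.72, 0.5259, 0.0074, 0.0032, 0.0457, False),
    ("dti", "DTI-FA-Caudate", -2.48, 14.25, 0.1740, 0.3480, None, None, False),
    ("dti", "DTI-T-Putamen", 0.92, 7.16, 0.1285, 0.9322, None, None, False),
    ("dti", "DTI-II-Putamen", 2.18, 6.59, 0.3308, 0.0810, None, None, False),
    ("dti", "DTI-MD-Putamen", 1.40, 6.62, 0.2115, 0.5137, None, None, False),
    ("dti", "DTI-FA-Putamen", 7.27, 18.92, 0.3842, 0.0443, 0.0052, 0.6454, False),
    ("dti", "DTI-T-Thalamus", 1.16, 5.64, 0.2057, 0.2674, None, None, False),
    ("dti", "DTI-II-Thalamus", 1.63, 6.22, 0.2621, 0.1608, None, None, False),
    ("dti", "DTI-MD-Thalamus", 1.35, 5.40, 0.2500, 0.1817, None, None, False),
    ("dti", "DTI-FA-Thalamus", 2.21, 11.16, 0.1980, 0.2874, None, None, False),
    ("dti", "DTI-T-Midbrain", 3.17, 10.42, 0.3042, 0.1063, None, None, False),
    ("dti", "DTI-II-Midbrain", 3.40, 10.91, 0.3116, 0.1558, None, None, False),
    ("dti", "DTI-MD-Midbrain", 3.01, 7.99, 0.3767, 0.0484, 0.0433, 0.0018, False),
    ("dti", "DTI-FA-Midbrain", 1.60, 11.73, 0.1364, 0.8951, None, None, False),
    ("dti", "DTI-T-Medulla", 6.58, 10.61, 0.6202, 0.0020, 0.0034, 0.0157, False),
    ("dti", "DTI-II-Medulla", 2.13, 7.16, 0.2975, 0.1132, None, None, False),
    ("dti", "DTI-MD-Medulla", 4.46, 8.17, 0.5459, 0.0057, 0.0032, 0.0138, False),
    ("dti", "DTI-FA-Medulla", -5.19, 14.96, 0.3469, 0.0673, None, None, False),
]

#: Discovery-cohort sample size behind the composite row (one-sample tests).
IPPOMS1_N = 35

#: Composite-row summary used by the published power analysis.
COMBIWISE_MEAN_1YR = 9.10
COMBIWISE_SD_1YR = 13.23


def published_screening_table() -> pd.DataFrame:
    """The published per-biomarker screening summary as a DataFrame."""
    df = pd.DataFrame(_ROWS, columns=_COLUMNS)
    for col in ("p_adj_ippoms2", "p_adj_rivitalise"):
        df[col] = df[col].astype(float)
    return df
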