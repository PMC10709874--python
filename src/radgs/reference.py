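"""Reference cohort statistics used to parameterize synthetic data.

These are published class-conditional summary statistics (feature means and
standard deviations, lesion counts, and ReliefF relevance weights) for a
26-patient prostate mp-MRI radiomics cohort with prostatectomy-confirmed
Gleason grading. The patient data themselves are not publicly deposited; the
printed summaries below drive the synthetic feature-table generator and serve
as fixtures for the feature-selection rule.

Conventions
-----------
Two binary labeling tasks are covered:

* ``significant``: clinically significant cancer (Gleason 3+4 and above,
  ISUP grade >= 2) vs non-significant (Gleason 3+3, ISUP grade 1).
* ``grade``: Gleason 3+4 (ISUP grade 2) vs Gleason 4+3 and above
  (ISUP grade >= 3).

In the summary tables each entry is printed as "a/b". The source never states
the column order; here the first value is taken as the clinically-significant
(resp. Gleason 3+4) group, and :func:`significant_task_stats` /
:func:`grade_task_stats` accept ``swap=True`` to flip it.

Units: ADC in μm²/ms, T2 in ms, ALPHE in %/s as printed.
"""

from __future__ import annotations

#: Lesions per Gleason score in the reference cohort (50 lesions, 26 patients).
COHORT_COUNTS: dict[str, int] = {"3+3": 13, "3+4": 29, "4+3": 7, "4+5": 1}

#: Gleason score -> 3-class group tag used throughout the package.
GS_TO_GROUP: dict[str, str] = {"3+3": "3+3", "3+4": "3+4", "4+3": ">=4+3", "4+5": ">=4+3"}

#: ReliefF relevance weights per feature, clinically-significant vs
#: non-significant task. Positive weight = retained feature.
RELIEFF_WEIGHTS_SIGNIFICANT: dict[str, float] = {
    "ADC": 0.0237,
    "ALPHE": 0.0669,
    "T2": 0.0620,
    "ADC-IDM": -0.0014,
    "ADC-contrast": 0.0441,
    "ADC-correlation": -0.0053,
    "ADC-energy": -0.0162,
    "ADC-entropy": -0.0254,
    "ADC-homogeneity": 0.0195,
    "DCE-IDM": -0.0157,
    "DCE-contrast": -0.0069,
    "DCE-correlation": 0.0377,
    "DCE-energy": 0.0116,
    "DCE-entropy": 0.0282,
    "DCE-homogeneity": 0.0037,
    "T2-IDM": 0.0080,
    "T2-contrast": -0.0053,
    "T2-correlation": -0.0156,
    "T2-energy": 0.0067,
    "T2-entropy": 0.0413,
    "T2-homogeneity": 0.0307,
}

#: ReliefF relevance weights, Gleason 3+4 vs >=4+3 task.
RELIEFF_WEIGHTS_GRADE: dict[str, float] = {
    "ADC": -0.0449,
    "ALPHE": -0.0090,
    "T2": 0.0231,
    "ADC-IDM": -0.0128,
    "ADC-contrast": 0.0632,
    "ADC-correlation": 0.1528,
    "ADC-energy": -0.0169,
    "ADC-entropy": 0.0610,
    "ADC-homogeneity": 0.0128,
    "DCE-IDM": -0.0770,
    "DCE-contrast": -0.0474,
    "DCE-correlation": 0.0519,
    "DCE-energy": 0.0150,
    "DCE-entropy": -0.0450,
    "DCE-homogeneity": 0.0623,
    "T2-IDM": -0.0388,
    "T2-contrast": -0.0319,
    "T2-correlation": -0.0622,
    "T2-energy": -0.0471,
    "T2-entropy": -0.0014,
    "T2-homogeneity": -0.0387,
}

# Per-feature (mean, SD) printed as significant/non-significant. The texture
# magnitudes (e.g. an IDM of 316.57) imply the original co-occurrence counts
# were not normalized to probabilities; they are reproduced verbatim as class
# summaries and used only as sampling parameters, never compared against this
# package's normalized texture features.
_SIGNIFICANT_STATS: dict[str, tuple[float, float, float, float, float]] = {
    # name: (mean_sig, mean_nonsig, sd_sig, sd_nonsig, p_value)
    "ADC": (1.45, 1.27, 0.37, 0.16, 0.0103),
    "ALPHE": (7.43, 7.91, 0.71, 0.51, 0.0025),
    "T2": (104.21, 114.41, 25.81, 24.11, 0.0067),
    "ADC-contrast": (44.13, 32.29, 26.01, 16.55, 0.0262),
    "ADC-homogeneity": (41.12, 32.99, 15.31, 13.77, 0.0227),
    "DCE-correlation": (0.33, 0.44, 0.24, 0.19, 0.0120),
    "DCE-energy": (0.08, 0.02, 0.10, 0.03, 0.0035),
    "DCE-entropy": (0.29, 0.41, 0.15, 0.09, 0.0002),
    "DCE-homogeneity": (0.49, 0.42, 0.13, 0.08, 0.0122),
    "T2-IDM": (316.57, 190.29, 211.65, 143.17, 0.0047),
    "T2-energy": (0.03, 0.01, 0.03, 0.01, 0.0142),
    "T2-entropy": (0.51, 0.55, 0.11, 0.07, 0.0449),
    "T2-homogeneity": (0.55, 0.47, 0.08, 0.04, 0.0005),
}

# Printed as Gleason 3+4 / Gleason >=4+3.
_GRADE_STATS: dict[str, tuple[float, float, float, float, float]] = {
    "T2": (89.96, 109.36, 14.54, 26.19, 0.0012),
    "ADC-contrast": (26.77, 46.19, 13.27, 23.67, 0.0020),
    "ADC-correlation": (0.55, 0.41, 0.02, 0.14, 0.0001),
    "ADC-entropy": (0.32, 0.36, 0.04, 0.06, 0.0041),
    "ADC-homogeneity": (0.49, 0.46, 0.05, 0.06, 0.0399),
    "DCE-correlation": (0.14, 0.29, 0.19, 0.26, 0.0127),
    "DCE-energy": (0.15, 0.08, 0.06, 0.09, 0.0037),
    "DCE-homogeneity": (0.59, 0.52, 0.08, 0.13, 0.0167),
}


def _split(stats: dict[str, tuple[float, float, float, float, float]], swap: bool):
    first = {k: (v[0], v[2]) for k, v in stats.items()}
    second = {k: (v[1], v[3]) for k, v in stats.items()}
    return (second, first) if swap else (first, second)


def significant_task_stats(swap: bool = False):
    """(mean, SD) per feature for the significant-vs-nonsignificant task.

    Returns ``(significant, nonsignificant)`` dicts of feature -> (mean, sd).
    With ``swap=True`` the printed column order is inverted.
    """
    return _split(_SIGNIFICANT_STATS, swap)


def grade_task_stats(swap: bool = False):
    """(mean, SD) per feature for the 3+4 vs >=4+3 task.

    Returns ``(grade_3_4, grade_4_3_plus)`` dicts of feature -> (mean, sd).
    """
    return _split(_GRADE_STATS, swap)
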