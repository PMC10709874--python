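"""Canonical feature naming for the 21-feature radiomic vector.

The vector holds the ROI mean of each quantitative map (ADC in μm²/ms, the
DCE enhancement rate ALPHE, and T2 in ms) plus six GLCM texture features
(energy, entropy, contrast, correlation, homogeneity, IDM) per map, each
averaged over the four co-occurrence directions 0°, 45°, 90° and 135°.
"""

from __future__ import annotations

#: GLCM-derived texture features, in canonical order.
GLCM_FEATURE_NAMES: tuple[str, ...] = (
    "IDM",
    "contrast",
    "correlation",
    "energy",
    "entropy",
    "homogeneity",
)

#: ROI-mean features, one per quantitative map.
MAP_MEAN_FEATURES: tuple[str, ...] = ("ADC", "ALPHE", "T2")

#: Prefix used for a map's GLCM features (the DCE map's mean is named ALPHE
#: but its texture features carry the DCE- prefix).
MAP_GLCM_PREFIX: dict[str, str] = {"ADC": "ADC", "ALPHA": "DCE", "T2": "T2"}

#: Map name -> name of its ROI-mean feature.
MAP_MEAN_NAME: dict[str, str] = {"ADC": "ADC", "ALPHA": "ALPHE", "T2": "T2"}


def _build_feature_names() -> tuple[str, ...]:
    names = list(MAP_MEAN_FEATURES)
    for prefix in ("ADC", "DCE", "T2"):
        names.extend(f"{prefix}-{g}" for g in GLCM_FEATURE_NAMES)
    return tuple(names)


#: The canonical 21 feature names: 3 map means + 3 maps x 6 GLCM features.
FEATURE_NAMES: tuple[str, ...] = _build_feature_names()

assert len(FEATURE_NAMES) == 21
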