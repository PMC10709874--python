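"""Synthetic cohorts: class-parameterized feature tables and image phantoms.

The patient cohort behind the reference summary statistics is not publicly
deposited, so this module generates data with the statistical structure the
analysis assumes, at two levels:

* **Feature tables** — per-class independent normal draws of the named
  radiomic features, parameterized by printed class means/SDs (no feature
  covariance is published, so features are sampled independently; a
  documented simplification).

* **Image phantoms** — 2-D truth grids for ADC, T2 and the DCE enhancement
  model (A, alpha, beta), a star-convex true lesion, and a drawn ROI
  obtained by eroding the true lesion (radiologist ROIs under-cover the
  lesion). Per-pixel signal series are synthesized exactly from the three
  signal models and corrupted with additive Gaussian noise. The lesion
  interior carries class-dependent texture (blended smoothed random fields
  whose granularity and variance differ by Gleason group) and the rim
  between drawn ROI and true lesion carries the class texture scaled by
  ``margin_heterogeneity`` — inflating the ROI therefore admits pixels that
  are more informative about the class, which is the premise under test.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, gaussian_filter

from radgs import reference
from radgs.features import FEATURE_NAMES
from radgs.qmaps import (
    DEFAULT_BVALUES,
    DEFAULT_DCE_SPACING,
    DEFAULT_ECHO_TIMES,
    emm_curve,
    um2ms_to_mm2s,
)

__all__ = [
    "ConfigurationError",
    "GenerationError",
    "ClassProfile",
    "GeneratorConfig",
    "PhantomTruth",
    "PhantomCase",
    "gen_feature_table",
    "gen_phantom_truth",
    "gen_phantom_case",
    "gen_cohort",
    "significant_table_config",
    "grade_table_config",
    "default_phantom_config",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


class GenerationError(RuntimeError):
    """Generation failed for a given configuration."""


@dataclass
class ClassProfile:
    """Class-conditional feature distribution and lesion count.

    ``feature_means``/``feature_sds`` may be empty for phantom-only
    profiles (image phantoms draw their parameters from the built-in
    Gleason-group presets rather than from feature statistics).
    """

    label: str
    feature_means: dict[str, float] = field(default_factory=dict)
    feature_sds: dict[str, float] = field(default_factory=dict)
    n_lesions: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 0:
            raise ConfigurationError("n_lesions must be >= 0")
        for name, sd in self.feature_sds.items():
            if sd < 0:
                raise ConfigurationError(f"negative SD for feature {name!r}")
        unknown = set(self.feature_means) - set(FEATURE_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown feature names: {sorted(unknown)}")


@dataclass
class GeneratorConfig:
    """Everything the generators need; all randomness flows from rng_seed."""

    profiles: list[ClassProfile] = field(default_factory=list)
    image_shape: tuple[int, int] = (120, 120)
    #: additive signal noise SD per modality (absolute, signal units)
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"dwi": 10.0, "t2": 5.0, "dce": 1.0}
    )
    #: how much extra class texture sits in the rim between drawn ROI and
    #: true lesion (0 = rim carries no class texture)
    margin_heterogeneity: float = 2.0
    #: pixels eroded off the true lesion to form the drawn ROI
    roi_erosion: int = 2
    rng_seed: int = 0
    bvalues: np.ndarray = field(default_factory=lambda: DEFAULT_BVALUES.copy())
    echo_times: np.ndarray = field(default_factory=lambda: DEFAULT_ECHO_TIMES.copy())
    dce_n_frames: int = 60
    dce_spacing: float = DEFAULT_DCE_SPACING
    dce_baseline_frames: int = 3

    def __post_init__(self) -> None:
        if min(self.image_shape) <= 0:
            raise ConfigurationError("image_shape must be positive")
        if isinstance(self.noise_sd, (int, float)):
            self.noise_sd = {m: float(self.noise_sd) for m in ("dwi", "t2", "dce")}
        if any(v < 0 for v in self.noise_sd.values()):
            raise ConfigurationError("noise_sd must be >= 0")
        if self.margin_heterogeneity < 0:
            raise ConfigurationError("margin_heterogeneity must be >= 0")


@dataclass
class PhantomTruth:
    """Ground-truth grids for one phantom lesion."""

    adc_map: np.ndarray  # μm²/ms
    t2_map: np.ndarray  # ms
    emm_a: np.ndarray  # %
    emm_alpha: np.ndarray  # 1/s
    emm_beta: np.ndarray  # 1/s
    true_lesion_mask: np.ndarray
    drawn_roi_mask: np.ndarray
    label: str
    seed: int

    def __post_init__(self) -> None:
        if not np.all(self.true_lesion_mask[self.drawn_roi_mask]):
            raise GenerationError("drawn ROI must lie inside the true lesion")


@dataclass
class PhantomCase:
    """One cohort entry: truth maps, Gleason labels and optional signals."""

    truth: PhantomTruth
    gs: str  # Gleason score tag, e.g. "3+4"
    group: str  # 3-class group tag: "3+3", "3+4", ">=4+3"
    lesion_id: str
    dwi: np.ndarray | None = None
    t2_series: np.ndarray | None = None
    dce: np.ndarray | None = None


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def gen_feature_table(
    config: GeneratorConfig, features: list[str] | None = None
) -> pd.DataFrame:
    """Sample a labeled feature table from the class profiles.

    Each feature is drawn independently from the class-conditional normal
    distribution; rows carry a ``label`` column. Deterministic given
    ``config.rng_seed``. A profile missing a required feature raises a
    :class:`ConfigurationError` naming the feature.
    """
    if not config.profiles:
        raise ConfigurationError("no class profiles configured")
    if features is None:
        features = []
        for p in config.profiles:
            features.extend(f for f in p.feature_means if f not in features)
    for p in config.profiles:
        for f in features:
            if f not in p.feature_means or f not in p.feature_sds:
                raise ConfigurationError(
                    f"profile {p.label!r} lacks feature {f!r}"
                )
    rng = np.random.default_rng(config.rng_seed)
    frames = []
    for p in config.profiles:
        means = np.array([p.feature_means[f] for f in features])
        sds = np.array([p.feature_sds[f] for f in features])
        rows = means + sds * rng.standard_normal((p.n_lesions, len(features)))
        df = pd.DataFrame(rows, columns=features)
        df["label"] = p.label
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _profiles_from_stats(stats_pair, labels, counts) -> list[ClassProfile]:
    out = []
    for stats, label, n in zip(stats_pair, labels, counts):
        out.append(
            ClassProfile(
                label=label,
                feature_means={k: v[0] for k, v in stats.items()},
                feature_sds={k: v[1] for k, v in stats.items()},
                n_lesions=n,
            )
        )
    return out


def significant_table_config(
    n_significant: int = 37,
    n_nonsignificant: int = 13,
    seed: int = 0,
    swap: bool = False,
) -> GeneratorConfig:
    """Feature-table config for the clinically-significant task.

    Profiles carry the 13 reference features retained for this task, with
    the published class means/SDs; default counts match the reference
    cohort (37 significant vs 13 non-significant lesions).
    """
    pair = reference.significant_task_stats(swap=swap)
    return GeneratorConfig(
        profiles=_profiles_from_stats(
            pair, ("significant", "nonsignificant"), (n_significant, n_nonsignificant)
        ),
        rng_seed=seed,
    )


def grade_table_config(
    n_g34: int = 29, n_g43plus: int = 8, seed: int = 0, swap: bool = False
) -> GeneratorConfig:
    """Feature-table config for the Gleason 3+4 vs >=4+3 task (8 features)."""
    pair = reference.grade_task_stats(swap=swap)
    return GeneratorConfig(
        profiles=_profiles_from_stats(pair, ("3+4", ">=4+3"), (n_g34, n_g43plus)),
        rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# image phantoms
# ---------------------------------------------------------------------------

#: Per-Gleason-group lesion presets: mean parameter values (ADC μm²/ms,
#: T2 ms, alpha 1/s, A %), texture heterogeneity factor and texture
#: correlation length in pixels (higher grade = lower ADC/T2, faster
#: enhancement, stronger and finer-grained heterogeneity).
GROUP_PRESETS: dict[str, dict[str, float]] = {
    "3+3": dict(adc=1.30, t2=105.0, alpha=0.27, A=85.0, het=0.35, corr=2.5),
    "3+4": dict(adc=1.18, t2=96.0, alpha=0.30, A=92.0, het=0.65, corr=1.8),
    ">=4+3": dict(adc=1.08, t2=89.0, alpha=0.33, A=98.0, het=1.0, corr=1.2),
}

_BACKGROUND = dict(adc=1.80, t2=150.0, alpha=0.15, A=60.0)
_BETA = 0.006  # washout rate, 1/s, spatially constant
_PARAM_FLOOR = dict(adc=0.15, t2=20.0, alpha=0.02, A=5.0)
_S0 = dict(dwi=1000.0, t2=500.0, dce=200.0)
#: baseline interior texture as a fraction of the lesion mean
_BASE_TEXTURE_CV = 0.05


def _unit_field(rng: np.random.Generator, shape, corr: float) -> np.ndarray:
    """Smoothed Gaussian random field normalized to unit variance."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=corr)
    sd = f.std()
    return f / sd if sd > 0 else f


def _star_convex_mask(
    rng: np.random.Generator, shape: tuple[int, int], radius: float
) -> np.ndarray:
    """Random star-convex blob around a jittered image center."""
    h, w = shape
    cy = h / 2 + rng.uniform(-0.08, 0.08) * h
    cx = w / 2 + rng.uniform(-0.08, 0.08) * w
    amp = rng.normal(0.0, 0.08, size=4)
    phase = rng.uniform(0, 2 * np.pi, size=4)
    yy, xx = np.mgrid[0:h, 0:w]
    theta = np.arctan2(yy - cy, xx - cx)
    r_theta = radius * (
        1.0
        + sum(a * np.sin((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amp, phase)))
    )
    dist = np.hypot(yy - cy, xx - cx)
    return dist <= np.maximum(r_theta, 3.0)


def gen_phantom_truth(label: str, config: GeneratorConfig, seed: int) -> PhantomTruth:
    """Ground-truth maps and masks for one phantom lesion.

    The truth is drawn from its own random stream, so it is identical
    whether or not signals are later synthesized from it.
    """
    if label not in GROUP_PRESETS:
        raise GenerationError(f"unknown class label {label!r}")
    preset = GROUP_PRESETS[label]
    truth_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[0])
    shape = config.image_shape

    radius = min(shape) / 8.0
    lesion = _star_convex_mask(truth_rng, shape, radius)
    erosion = config.roi_erosion
    roi = lesion.copy()
    while erosion > 0:
        cand = binary_erosion(lesion, structure=np.ones((3, 3)), iterations=erosion)
        if cand.sum() >= 4:
            roi = cand
            break
        erosion -= 1
    rim = lesion & ~roi

    het = preset["het"]
    # Interior texture is nearly class-independent (a drawn ROI under-covers
    # the infiltrative margin where grade expresses most); the rim carries
    # the class heterogeneity, scaled by margin_heterogeneity. Per-ROI
    # min-max quantization cancels pure amplitude scaling, so the class is
    # encoded in the rim's granularity and in the rim/interior amplitude
    # ratio, both invisible until the ROI is inflated.
    amp_interior = _BASE_TEXTURE_CV * (1.0 + 0.2 * het)
    amp_rim = _BASE_TEXTURE_CV * config.margin_heterogeneity * (0.3 + 1.5 * het)
    corr_interior = 2.2 - 0.6 * het  # higher grade = slightly finer interior grain

    maps: dict[str, np.ndarray] = {}
    for key in ("adc", "t2", "alpha", "A"):
        bg = _BACKGROUND[key] * (1.0 + 0.02 * _unit_field(truth_rng, shape, 6.0))
        # per-lesion biological variability of the class mean
        mean = preset[key] * (1.0 + 0.10 * truth_rng.standard_normal())
        interior_tex = _unit_field(truth_rng, shape, corr_interior)
        rim_tex = _unit_field(truth_rng, shape, preset["corr"])
        grid = bg
        grid = np.where(lesion, mean * (1.0 + amp_interior * interior_tex), grid)
        grid = np.where(rim, mean * (1.0 + amp_rim * rim_tex), grid)
        maps[key] = np.maximum(grid, _PARAM_FLOOR[key])

    return PhantomTruth(
        adc_map=maps["adc"],
        t2_map=maps["t2"],
        emm_a=maps["A"],
        emm_alpha=maps["alpha"],
        emm_beta=np.full(shape, _BETA),
        true_lesion_mask=lesion,
        drawn_roi_mask=roi,
        label=label,
        seed=seed,
    )


def gen_phantom_case(
    label: str, config: GeneratorConfig, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, PhantomTruth]:
    """One phantom: (dwi, t2_series, dce) signal stacks plus ground truth.

    ``label`` is a 3-class group tag. Signals are generated exactly from the
    truth maps through the three signal models, then corrupted with the
    configured additive Gaussian noise; bit-identical given (config, seed).
    """
    truth = gen_phantom_truth(label, config, seed)
    noise_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    maps = {
        "adc": truth.adc_map,
        "t2": truth.t2_map,
        "alpha": truth.emm_alpha,
        "A": truth.emm_a,
    }

    b = np.asarray(config.bvalues, dtype=float)
    te = np.asarray(config.echo_times, dtype=float)
    n_base = config.dce_baseline_frames
    t_axis = np.arange(config.dce_n_frames) * config.dce_spacing
    t_post = t_axis - t_axis[n_base - 1]

    dwi = _S0["dwi"] * np.exp(-um2ms_to_mm2s(maps["adc"])[..., None] * b)
    t2s = _S0["t2"] * np.exp(-te / maps["t2"][..., None])
    pse = emm_curve(
        np.maximum(t_post, 0.0),
        maps["A"][..., None],
        maps["alpha"][..., None],
        truth.emm_beta[..., None],
    )
    dce = _S0["dce"] * (1.0 + pse / 100.0)

    for name, stack in (("dwi", dwi), ("t2", t2s), ("dce", dce)):
        sd = config.noise_sd[name]
        if sd > 0:
            stack += noise_rng.normal(0.0, sd, size=stack.shape)

    return dwi, t2s, dce, truth


def default_phantom_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Phantom cohort config with the reference per-class lesion counts."""
    profiles = [
        ClassProfile(label=gs, n_lesions=n) for gs, n in reference.COHORT_COUNTS.items()
    ]
    return GeneratorConfig(profiles=profiles, rng_seed=seed, **overrides)


def gen_cohort(config: GeneratorConfig, include_signals: bool = False) -> list[PhantomCase]:
    """Generate the configured cohort of phantom cases.

    Profiles are taken as Gleason-score classes (e.g. "3+4") mapped to the
    three analysis groups; each case gets a distinct seed derived from
    ``config.rng_seed`` by a fixed counter scheme. With
    ``include_signals=False`` only the truth maps are kept, which is much
    lighter when downstream analysis works from truth maps directly.
    """
    total = sum(p.n_lesions for p in config.profiles)
    if total == 0:
        raise GenerationError("cohort has zero lesions")
    cases: list[PhantomCase] = []
    counter = 0
    for p in config.profiles:
        group = reference.GS_TO_GROUP.get(p.label, p.label)
        if group not in GROUP_PRESETS:
            raise GenerationError(f"no phantom preset for class {p.label!r}")
        for _ in range(p.n_lesions):
            case_seed = (config.rng_seed * 1009 + counter) % (2**31)
            if include_signals:
                dwi, t2s, dce, truth = gen_phantom_case(group, config, case_seed)
            else:
                dwi = t2s = dce = None
                truth = gen_phantom_truth(group, config, case_seed)
            cases.append(
                PhantomCase(
                    truth=truth,
                    gs=p.label,
                    group=group,
                    lesion_id=f"lesion{counter:03d}",
                    dwi=dwi,
                    t2_series=t2s,
                    dce=dce,
                )
            )
            counter += 1
    return cases
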