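"""Synthetic radiomic cohorts for reproducible, download-free testing.

:func:`generate_cohort` emulates a two-class (benign/malignant) CT
radiomics cohort: 105 features in the standard class layout (shape 13,
GLDM 14, GLCM 23, NGTDM 5, first-order 18, GLSZM 16, GLRLM 16), four
designated informative features with a controllable standardized
class-mean separation, and pure-noise distractors for everything else.
The informative features mirror the real signature candidates:

* ``shape_Volume`` — log-normal, median near 1.8e3 mm^3 (a ~15 mm
  diameter nodule), class shift applied on the log scale;
* ``shape_SurfaceVolumeRatio`` — positive, near 0.5 /mm;
* ``glcm_SumEntropy`` — positive, near 4.5;
* ``glszm_LargeAreaLowGrayLevelEmphasis`` — positive, near 500.

Only the class-separation contract matters for testing; no attempt is
made to reproduce realistic inter-feature covariance (an optional
equicorrelation knob exists for redundancy-ranker tests).

:func:`generate_retest` produces noisy replicates for test-retest
reliability studies: calling it twice with different seeds on the same
base table yields a pair whose per-feature concordance has closed form
CCC = 1 / (1 + sd^2) under the additive-noise model.

Default cohort sizes follow the reference training cohort: 165
malignant and 35 benign nodules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from radiolik.core_tables import FeatureMeta, FeatureTable
from radiolik.likelihood import FeaturePair, LikelihoodModel, evaluate

__all__ = [
    "CLASS_LAYOUT",
    "INFORMATIVE_FEATURES",
    "SyntheticConfig",
    "generate_cohort",
    "generate_retest",
    "generate_from_model",
]

#: Per-class feature counts of the standard 105-feature panel.
CLASS_LAYOUT = {
    "shape": 13,
    "gldm": 14,
    "glcm": 23,
    "ngtdm": 5,
    "firstorder": 18,
    "glszm": 16,
    "glrlm": 16,
}

#: The four planted informative features and their marginal parameters:
#: (location, scale, log_scale?) — class shift is +effect_size * scale
#: for malignant samples (on the log scale for log-normal volume).
INFORMATIVE_FEATURES = {
    "shape_Volume": (7.48, 0.8, True),
    "shape_SurfaceVolumeRatio": (0.5, 0.08, False),
    "glcm_SumEntropy": (4.5, 0.7, False),
    "glszm_LargeAreaLowGrayLevelEmphasis": (500.0, 80.0, False),
}


@dataclass
class SyntheticConfig:
    """Cohort generation parameters.

    effect_size is the standardized class-mean separation of the four
    informative features; all other features are label-independent
    noise.  retest_noise_sd scales the per-feature replicate noise used
    by :func:`generate_retest` (as a fraction of the feature's own sd).
    """

    n_malignant: int = 165
    n_benign: int = 35
    seed: int = 0
    effect_size: float = 2.0
    retest_noise_sd: float = 0.3
    noise_correlation: float = 0.0
    informative_features: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.informative_features is not None:
            unknown = set(self.informative_features) - set(
                INFORMATIVE_FEATURES
            )
            if unknown:
                raise ValueError(
                    f"unknown informative features: {sorted(unknown)}"
                )
        if self.n_malignant <= 0 or self.n_benign <= 0:
            raise ValueError("both class sizes must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.retest_noise_sd < 0:
            raise ValueError("retest_noise_sd must be >= 0")
        if not 0.0 <= self.noise_correlation < 1.0:
            raise ValueError("noise_correlation must be in [0, 1)")


def _feature_names() -> list[str]:
    """The 105 panel names: informative ones plus numbered distractors."""
    names: list[str] = []
    informative_by_class: dict[str, list[str]] = {}
    for name in INFORMATIVE_FEATURES:
        cls = name.split("_", 1)[0]
        informative_by_class.setdefault(cls, []).append(name)
    for cls, count in CLASS_LAYOUT.items():
        planted = informative_by_class.get(cls, [])
        names.extend(planted)
        for i in range(count - len(planted)):
            names.append(f"{cls}_Noise{i + 1:02d}")
    return names


def generate_cohort(config: SyntheticConfig) -> FeatureTable:
    """Generate a labeled two-class cohort with the 105-feature panel.

    Deterministic given ``config.seed``.  Benign samples come first
    (ids ``b0001``...), then malignant (``m0001``...).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_benign + config.n_malignant
    labels = np.concatenate(
        [np.zeros(config.n_benign, int), np.ones(config.n_malignant, int)]
    )
    names = _feature_names()
    values = np.empty((n, len(names)))
    rho = config.noise_correlation
    shared = rng.standard_normal(n)  # common factor for equicorrelated noise
    planted = (
        set(INFORMATIVE_FEATURES)
        if config.informative_features is None
        else set(config.informative_features)
    )
    for j, name in enumerate(names):
        z = rng.standard_normal(n)
        if name in planted:
            loc, scale, log_scale = INFORMATIVE_FEATURES[name]
            shifted = z + config.effect_size * labels
            col = loc + scale * shifted
            if log_scale:
                col = np.exp(col)
            else:
                # truncate at a small positive floor; locations sit far
                # enough from zero that this almost never binds
                col = np.maximum(col, 1e-6)
        else:
            if rho > 0:
                z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * z
            col = z
        values[:, j] = col
    sample_ids = [f"b{i + 1:04d}" for i in range(config.n_benign)] + [
        f"m{i + 1:04d}" for i in range(config.n_malignant)
    ]
    return FeatureTable(
        sample_ids=sample_ids,
        values=values,
        features=[FeatureMeta.from_name(nm) for nm in names],
        labels=labels,
    )


def generate_retest(
    table: FeatureTable, retest_noise_sd: float, seed: int
) -> FeatureTable:
    """Perturb a table with per-feature-scaled replicate noise.

    Each feature receives independent Gaussian noise with standard
    deviation ``retest_noise_sd`` times that feature's own (population)
    sd.  Two replicates generated with different seeds from the same
    base table then have theoretical per-feature concordance
    CCC = 1 / (1 + retest_noise_sd^2).
    """
    if retest_noise_sd < 0:
        raise ValueError("retest_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    sds = table.values.std(axis=0)
    noise = rng.standard_normal(table.values.shape) * (retest_noise_sd * sds)
    return FeatureTable(
        sample_ids=list(table.sample_ids),
        values=table.values + noise,
        features=list(table.features),
        labels=None if table.labels is None else table.labels.copy(),
    )


def generate_from_model(
    model: LikelihoodModel,
    n: int,
    x1_range: Sequence[float],
    x2_range: Sequence[float],
    noise_sd: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample (x1, x2, y) data from a likelihood model's surface.

    x1 and x2 are uniform on their (positive) ranges; y is the model
    surface value plus Gaussian noise.  Supports parameter-recovery
    tests of :func:`radiolik.likelihood.fit`.
    """
    lo1, hi1 = x1_range
    lo2, hi2 = x2_range
    if not (0 < lo1 <= hi1 and 0 < lo2 <= hi2):
        raise ValueError("ranges must be positive and ordered")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    x1s = rng.uniform(lo1, hi1, n)
    x2s = rng.uniform(lo2, hi2, n)
    ys = np.array(
        [evaluate(model, FeaturePair(a, b)) for a, b in zip(x1s, x2s)]
    )
    if noise_sd > 0:
        ys = ys + rng.normal(0.0, noise_sd, n)
    return x1s, x2s, ys
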