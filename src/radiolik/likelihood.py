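"""The two diagnostic likelihood functional forms MLF I and MLF II.

Both models map a two-feature radiomic signature (x1, x2) to a
malignancy score y, trained so that y is near 0 for benign and near 1
for malignant tumors (thresholded downstream, by default at 0.51):

MLF I  (x1 = tumor volume, x2 = large area low gray level emphasis):

    y = a + b ln(x1) + c ln(x1^2) + d/x2 + e/x2^2 + f/x2^3 + g/x2^4

MLF II (x1 = surface-to-volume ratio, x2 = sum entropy):

    y = a + b x1 + c x1^2 + d x1^3 + e x1^4 + f ln(x2)

Both forms are linear in their coefficients, so fitting to a new cohort
is ordinary least squares on the basis-expanded design matrix; no
logistic link is applied to the 0/1 labels.  Note that the MLF I basis
as written is exactly collinear — ln(x1^2) = 2 ln(x1) — so its b and c
are individually unidentifiable; :func:`fit` returns the minimum-norm
solution and the combination b + 2c (and hence every prediction) is
identified.  An alternative reading of the second term as (ln x1)^2 is
available via ``squared_log=True``; the published coefficients belong
to the literal collinear form, which is the default.

:func:`pretrained` returns the published coefficient vectors at full
printed precision along with their reported average standard errors of
the y estimates (0.30 for MLF I, 0.20 for MLF II).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FeaturePair",
    "LikelihoodModel",
    "basis_mlf1",
    "basis_mlf2",
    "evaluate",
    "predict",
    "pretrained",
    "fit",
    "MLF1_COEFFICIENTS",
    "MLF2_COEFFICIENTS",
]

#: Published MLF I coefficients (a, b, c, d, e, f, g), full precision.
MLF1_COEFFICIENTS = (
    -2.45226185349294,
    0.568013700683048,
    -2.32311348575522e-02,
    -2.68371595182609e-02,
    3.61336660703077e-03,
    -1.08094045817984e-04,
    9.40291849279405e-07,
)

#: Published MLF II coefficients (a, b, c, d, e, f), full precision.
MLF2_COEFFICIENTS = (
    0.747801694861307,
    2.22684037581268,
    -5.58568390095777,
    3.631765847909,
    -0.730551994128231,
    1.28142101694647e-02,
)

_N_BASIS = {"MLF1": 7, "MLF2": 6}


@dataclass(frozen=True)
class FeaturePair:
    """One (x1, x2) signature-feature observation.

    x1 is the shape feature (volume in mm^3 for MLF I; surface-to-volume
    ratio in 1/mm for MLF II) and x2 the texture feature (LALGLE for
    MLF I; sum entropy for MLF II).  Both must be positive so that the
    logarithms and reciprocal powers are defined.
    """

    x1: float
    x2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x1) and np.isfinite(self.x2)):
            raise ValueError("feature values must be finite")


def basis_mlf1(pair: FeaturePair, *, squared_log: bool = False) -> np.ndarray:
    """MLF I basis vector (1, ln x1, ln(x1^2), 1/x2, ..., 1/x2^4).

    With ``squared_log=True`` the third element is (ln x1)^2 instead of
    ln(x1^2), breaking the literal form's exact collinearity.
    """
    if pair.x1 <= 0:
        raise ValueError(f"MLF1 requires x1 > 0, got {pair.x1}")
    if pair.x2 == 0:
        raise ValueError("MLF1 requires x2 != 0")
    lx = np.log(pair.x1)
    second = lx**2 if squared_log else 2.0 * lx
    r = 1.0 / pair.x2
    return np.array([1.0, lx, second, r, r**2, r**3, r**4])


def basis_mlf2(pair: FeaturePair) -> np.ndarray:
    """MLF II basis vector (1, x1, x1^2, x1^3, x1^4, ln x2)."""
    if pair.x2 <= 0:
        raise ValueError(f"MLF2 requires x2 > 0, got {pair.x2}")
    x = pair.x1
    return np.array([1.0, x, x**2, x**3, x**4, np.log(pair.x2)])


@dataclass
class LikelihoodModel:
    """A likelihood functional form with bound coefficients.

    Attributes
    ----------
    form_id
        ``"MLF1"`` or ``"MLF2"``.
    coefficients
        (a, ..., g) for MLF1 (length 7) or (a, ..., f) for MLF2
        (length 6).
    residual_se
        Average standard error of the y estimates, when known.
    x1_feature, x2_feature
        Names of the feature columns bound to x1 and x2.
    squared_log
        MLF1 only: use the (ln x1)^2 variant basis.
    """

    form_id: str
    coefficients: np.ndarray
    residual_se: float | None = None
    x1_feature: str | None = None
    x2_feature: str | None = None
    squared_log: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.form_id not in _N_BASIS:
            raise ValueError(f"unknown form id {self.form_id!r}")
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        expected = _N_BASIS[self.form_id]
        if self.coefficients.shape != (expected,):
            raise ValueError(
                f"{self.form_id} needs {expected} coefficients, "
                f"got {self.coefficients.size}"
            )
        if self.residual_se is not None and not np.isfinite(self.residual_se):
            raise ValueError("residual_se must be finite")

    def basis(self, pair: FeaturePair) -> np.ndarray:
        if self.form_id == "MLF1":
            return basis_mlf1(pair, squared_log=self.squared_log)
        return basis_mlf2(pair)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "form_id": self.form_id,
            "coefficients": [repr(float(c)) for c in self.coefficients],
            "residual_se": self.residual_se,
            "x1_feature": self.x1_feature,
            "x2_feature": self.x2_feature,
            "squared_log": self.squared_log,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LikelihoodModel":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        payload = json.loads(text)
        return cls(
            form_id=payload["form_id"],
            coefficients=np.array(
                [float(c) for c in payload["coefficients"]]
            ),
            residual_se=payload.get("residual_se"),
            x1_feature=payload.get("x1_feature"),
            x2_feature=payload.get("x2_feature"),
            squared_log=payload.get("squared_log", False),
        )


def pretrained(form_id: str) -> LikelihoodModel:
    """The published model for ``form_id`` at full printed precision."""
    if form_id == "MLF1":
        return LikelihoodModel(
            form_id="MLF1",
            coefficients=np.array(MLF1_COEFFICIENTS),
            residual_se=0.30,
            x1_feature="shape_Volume",
            x2_feature="glszm_LargeAreaLowGrayLevelEmphasis",
        )
    if form_id == "MLF2":
        return LikelihoodModel(
            form_id="MLF2",
            coefficients=np.array(MLF2_COEFFICIENTS),
            residual_se=0.20,
            x1_feature="shape_SurfaceVolumeRatio",
            x2_feature="glcm_SumEntropy",
        )
    raise ValueError(f"unknown form id {form_id!r}")


def evaluate(model: LikelihoodModel, pair: FeaturePair) -> float:
    """Malignancy score y = coefficients . basis(pair); unbounded real."""
    return float(model.coefficients @ model.basis(pair))


def predict(
    model: LikelihoodModel,
    x1s: Sequence[float],
    x2s: Sequence[float],
    *,
    clip_eps: float | None = None,
) -> np.ndarray:
    """Vectorized :func:`evaluate` over paired feature vectors.

    ``clip_eps``, when given, floors non-positive feature values at that
    small positive constant instead of erroring — a robustness escape
    hatch for pipeline use on noisy tables.
    """
    x1s = np.asarray(x1s, dtype=float)
    x2s = np.asarray(x2s, dtype=float)
    if x1s.shape != x2s.shape:
        raise ValueError("x1s and x2s must have equal length")
    if clip_eps is not None:
        x1s = np.maximum(x1s, clip_eps)
        x2s = np.maximum(x2s, clip_eps)
    return np.array(
        [evaluate(model, FeaturePair(a, b)) for a, b in zip(x1s, x2s)]
    )


def _design_matrix(
    form_id: str,
    x1s: np.ndarray,
    x2s: np.ndarray,
    squared_log: bool,
) -> np.ndarray:
    rows = []
    for a, b in zip(x1s, x2s):
        pair = FeaturePair(float(a), float(b))
        if form_id == "MLF1":
            rows.append(basis_mlf1(pair, squared_log=squared_log))
        else:
            rows.append(basis_mlf2(pair))
    return np.array(rows)


def fit(
    form_id: str,
    x1s: Sequence[float],
    x2s: Sequence[float],
    ys: Sequence[float],
    *,
    squared_log: bool = False,
    x1_feature: str | None = None,
    x2_feature: str | None = None,
) -> LikelihoodModel:
    """Least-squares fit of a likelihood form to (x1, x2, y) data.

    The forms are linear in their coefficients, so the minimum-RSS
    solution is ordinary least squares on the basis-expanded design
    matrix.  When the design is rank-deficient (always, for the literal
    MLF1 basis) the minimum-norm solution is returned; predictions are
    invariant to the deficiency and the identifiable combination b + 2c
    is recovered exactly.

    residual_se = sqrt(RSS / (n - p_eff)) with p_eff the design rank.
    """
    if form_id not in _N_BASIS:
        raise ValueError(f"unknown form id {form_id!r}")
    x1s = np.asarray(x1s, dtype=float)
    x2s = np.asarray(x2s, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if not (x1s.shape == x2s.shape == ys.shape) or x1s.ndim != 1:
        raise ValueError("x1s, x2s, ys must be 1-D of equal length")
    p = _N_BASIS[form_id]
    n = x1s.size
    if n < p:
        raise ValueError(f"need at least {p} observations, got {n}")
    X = _design_matrix(form_id, x1s, x2s, squared_log)
    coef, _, rank, _ = np.linalg.lstsq(X, ys, rcond=None)
    resid = ys - X @ coef
    rss = float(resid @ resid)
    dof = n - rank
    residual_se = float(np.sqrt(rss / dof)) if dof > 0 else 0.0
    return LikelihoodModel(
        form_id=form_id,
        coefficients=coef,
        residual_se=residual_se,
        x1_feature=x1_feature,
        x2_feature=x2_feature,
        squared_log=squared_log,
    )
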