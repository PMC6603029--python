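"""Test-retest reliability and discriminability screening.

Radiomic features are sensitive to acquisition and segmentation noise,
so before any ranking the feature set is reduced by two gates applied as
a conjunction:

1. **Reliability** — Lin's concordance correlation coefficient (CCC)
   between paired test-retest measurements must exceed ``ccc_min``
   (default 0.85).  The CCC combines precision (Pearson correlation)
   with accuracy (penalties for mean and variance shifts):

       CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)

   Population (1/n) moments are the default, matching Lin's original
   estimator; sample (1/(n-1)) moments are available via a flag.

2. **Discriminability** — a Kruskal-Wallis rank test of the feature
   against the binary benign/malignant label must be significant at
   level ``alpha`` (default 0.05).

A feature is retained only if it passes every gate that was requested.
No multiple-testing correction is applied to the Kruskal-Wallis
p-values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from radiolik.core_tables import FeatureTable

__all__ = [
    "ReliabilityReport",
    "concordance_correlation",
    "kruskal_wallis_p",
    "reliability_filter",
]


def concordance_correlation(
    x: Sequence[float], y: Sequence[float], *, sample_moments: bool = False
) -> float:
    """Lin's concordance correlation coefficient between paired vectors.

    Parameters
    ----------
    x, y
        Paired measurements of equal length >= 2.
    sample_moments
        Use 1/(n-1) variance/covariance estimators instead of the
        default population (1/n) moments.

    Returns
    -------
    float in [-1, 1].

    Raises
    ------
    ValueError
        On length mismatch, n < 2, or when both vectors are constant
        with equal means (the coefficient is then undefined 0/0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    ddof = 1 if sample_moments else 0
    vx = x.var(ddof=ddof)
    vy = y.var(ddof=ddof)
    mean_diff = x.mean() - y.mean()
    denom = vx + vy + mean_diff**2
    if denom == 0.0:
        raise ValueError(
            "CCC undefined: both vectors constant with equal means"
        )
    cov = ((x - x.mean()) * (y - y.mean())).sum() / (n - ddof)
    ccc = 2.0 * cov / denom
    # guard tiny float excursions outside [-1, 1]
    return float(min(1.0, max(-1.0, ccc)))


def kruskal_wallis_p(
    values: Sequence[float], groups: Sequence
) -> float:
    """Kruskal-Wallis H-test p-value of ``values`` across ``groups``.

    Mid-ranks are used for ties with the standard tie correction; the
    p-value comes from the chi-square approximation with
    (number of groups - 1) degrees of freedom.  When every observation
    is identical the statistic degenerates (tie correction divides by
    zero); the test then carries no evidence against the null and p = 1
    is returned with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape or values.ndim != 1:
        raise ValueError("values and groups must be 1-D of equal length")
    if values.size == 0:
        raise ValueError("empty input")
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if np.all(values == values[0]):
        warnings.warn(
            "all values tied; Kruskal-Wallis degenerate, returning p = 1",
            stacklevel=2,
        )
        return 1.0
    stat, p = stats.kruskal(*samples)
    return float(p)


@dataclass
class ReliabilityReport:
    """Per-feature CCC / Kruskal-Wallis screening results."""

    names: list[str]
    ccc: list[float | None]
    kw_p: list[float | None]
    retained: list[bool]
    ccc_min: float = 0.85
    alpha: float = 0.05
    ccc_tested: bool = field(default=True)
    kw_tested: bool = field(default=True)

    @property
    def retained_features(self) -> list[str]:
        return [n for n, r in zip(self.names, self.retained) if r]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.names,
                "ccc": [math.nan if c is None else c for c in self.ccc],
                "kw_p": [math.nan if p is None else p for p in self.kw_p],
                "retained": self.retained,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def reliability_filter(
    table: FeatureTable,
    retest: tuple[FeatureTable, FeatureTable] | None = None,
    ccc_min: float = 0.85,
    alpha: float = 0.05,
    *,
    sample_moments: bool = False,
) -> ReliabilityReport:
    """Screen features by test-retest CCC and Kruskal-Wallis p-value.

    Parameters
    ----------
    table
        The cohort table; must carry labels when the Kruskal-Wallis
        gate is requested (``alpha`` is not None).
    retest
        A pair of paired tables (scan A, scan B) over the same sample
        ids and features; CCC is computed per feature between them.
        When absent the CCC gate is skipped.
    ccc_min
        Strict lower bound for retention (``ccc > ccc_min``); pass
        ``None`` to skip the reliability gate.
    alpha
        Strict upper significance bound (``kw_p < alpha``); pass
        ``None`` to skip the discriminability gate.

    Returns
    -------
    ReliabilityReport
        Per-feature CCC, p-value, and the conjunction retained flag.
    """
    names = table.feature_names
    do_ccc = ccc_min is not None and retest is not None
    do_kw = alpha is not None
    if ccc_min is not None and retest is None:
        do_ccc = False  # no retest data: reliability gate cannot run
    if do_kw and table.labels is None:
        raise ValueError(
            "Kruskal-Wallis gate requested but table has no labels"
        )
    if retest is not None:
        a, b = retest
        if a.feature_names != names or b.feature_names != names:
            raise ValueError("retest tables must share the cohort's features")
        if a.sample_ids != b.sample_ids:
            raise ValueError("retest tables must be paired on sample ids")

    cccs: list[float | None] = []
    kw_ps: list[float | None] = []
    retained: list[bool] = []
    for j, name in enumerate(names):
        c: float | None = None
        p: float | None = None
        ok = True
        if do_ccc:
            a, b = retest  # type: ignore[misc]
            try:
                c = concordance_correlation(
                    a.values[:, j], b.values[:, j],
                    sample_moments=sample_moments,
                )
            except ValueError:
                c = None
            ok = ok and (c is not None and c > ccc_min)
        if do_kw:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = kruskal_wallis_p(table.values[:, j], table.labels)
            ok = ok and (p < alpha)
        cccs.append(c)
        kw_ps.append(p)
        retained.append(ok)
    return ReliabilityReport(
        names=list(names),
        ccc=cccs,
        kw_p=kw_ps,
        retained=retained,
        ccc_min=ccc_min if ccc_min is not None else float("nan"),
        alpha=alpha if alpha is not None else float("nan"),
        ccc_tested=do_ccc,
        kw_tested=do_kw,
    )
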