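"""Ordination (PCA) of binary profiles and Mandel h/k consistency checks.

Mandel's h standardizes each group mean against the spread of group means;
Mandel's k compares each group's standard deviation to the pooled (RMS)
standard deviation.  Critical values follow the Wilrich / ISO 5725
closed forms:

    h_crit(p, alpha) = (p-1) t / sqrt(p (p - 2 + t^2)),
        t the Student quantile at 1 - alpha/2 with p-2 df
    k_crit(p, n, alpha) = sqrt(p / (1 + (p-1)/F)),
        F the upper-alpha F quantile with (n-1, (p-1)(n-1)) df
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PcaResult:
    """Principal components of a mean-centered matrix."""

    scores: np.ndarray                       # observations x components
    loadings: np.ndarray                     # features x components
    explained_variance_fraction: np.ndarray  # per component, non-increasing
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        index = list(self.row_labels) or None
        return pd.DataFrame(self.scores, index=index, columns=cols)


def pca(X, n_components: int | None = None,
        row_labels: Sequence[str] = (),
        col_labels: Sequence[str] = ()) -> PcaResult:
    """PCA by singular value decomposition of the column-centered matrix.

    No variance scaling is applied (binary profiles share a scale).  Sign
    convention: within each component the loading of largest magnitude is
    positive.  Raises on a constant matrix (zero total variance).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a matrix with at least two rows")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components is None:
        n_components = max_rank
    if not 1 <= n_components <= max_rank:
        raise ValueError(
            f"n_components must be in [1, {max_rank}], got {n_components}"
        )
    centered = X - X.mean(axis=0)
    total_var = float(np.sum(centered ** 2))
    if total_var == 0.0:
        raise ValueError("matrix is constant: zero total variance")
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    explained = (svals ** 2) / total_var
    loadings = vt[:n_components].T
    # fix signs so the largest-|loading| entry of each component is positive
    for c in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, c]))
        if loadings[pivot, c] < 0:
            loadings[:, c] *= -1.0
    scores = centered @ loadings
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=explained[:n_components],
        row_labels=tuple(row_labels),
        col_labels=tuple(col_labels),
    )


def mandel_h(group_means: Sequence[float]) -> np.ndarray:
    """Standardized deviations of group means: (mean_i - grand) / sd."""
    means = np.asarray(group_means, dtype=float)
    p = means.size
    if p < 3:
        raise ValueError("Mandel's h needs at least 3 groups")
    grand = means.mean()
    s = means.std(ddof=1)
    if s == 0.0:
        raise ValueError("zero between-group variance")
    h = (means - grand) / s
    _assert_h_identities(h)
    return h


def mandel_k(group_sds: Sequence[float]) -> np.ndarray:
    """Ratios of each group sd to the pooled root-mean-square sd."""
    sds = np.asarray(group_sds, dtype=float)
    p = sds.size
    if p < 2:
        raise ValueError("Mandel's k needs at least 2 groups")
    if (sds < 0).any():
        raise ValueError("standard deviations must be non-negative")
    pooled = math.sqrt(float(np.mean(sds ** 2)))
    if pooled == 0.0:
        raise ValueError("all group standard deviations are zero")
    k = sds / pooled
    assert abs(float(np.sum(k ** 2)) - p) < 1e-9
    return k


def _assert_h_identities(h: np.ndarray) -> None:
    p = h.size
    assert abs(float(h.sum())) < 1e-9
    bound = (p - 1) / math.sqrt(p)
    assert (np.abs(h) <= bound + 1e-9).all()


def h_crit(p: int, alpha: float = 0.05) -> float:
    """Critical value for |h_i| at significance ``alpha``."""
    if p < 3:
        raise ValueError("h_crit requires p >= 3 groups")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    t = stats.t.ppf(1.0 - alpha / 2.0, df=p - 2)
    return (p - 1) * t / math.sqrt(p * (p - 2 + t * t))


def k_crit(p: int, n: int, alpha: float = 0.05) -> float:
    """Critical value for k_i at significance ``alpha`` (balanced design,
    ``n`` replicates per group)."""
    if p < 2:
        raise ValueError("k_crit requires p >= 2 groups")
    if n < 2:
        raise ValueError("k_crit requires n >= 2 replicates per group")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    f = stats.f.ppf(1.0 - alpha, dfn=n - 1, dfd=(p - 1) * (n - 1))
    return math.sqrt(p / (1.0 + (p - 1.0) / f))


@dataclass(frozen=True)
class MandelReport:
    """Per-group consistency statistics with critical values and flags."""

    groups: tuple[str, ...]
    n_per_group: tuple[int, ...]
    means: np.ndarray
    sds: np.ndarray
    h: np.ndarray
    k: np.ndarray
    grand_mean: float
    between_sd: float
    pooled_sd: float
    h_critical: float
    k_critical: float | None
    alpha: float

    @property
    def h_flags(self) -> np.ndarray:
        return np.abs(self.h) > self.h_critical

    @property
    def k_flags(self) -> np.ndarray:
        if self.k_critical is None:
            return np.zeros(len(self.groups), dtype=bool)
        return self.k > self.k_critical

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": list(self.groups),
                "n": list(self.n_per_group),
                "mean": self.means,
                "sd": self.sds,
                "h": self.h,
                "k": self.k,
                "h_flag": self.h_flags,
                "k_flag": self.k_flags,
            }
        )


def mandel_report(
    observations: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> MandelReport:
    """Assemble Mandel h/k statistics from per-group replicate vectors.

    Each group needs >= 2 replicates.  An unbalanced design omits k_crit
    with a warning (its closed form assumes equal replicate counts).
    """
    names = tuple(observations.keys())
    if len(names) < 3:
        raise ValueError("need at least 3 groups")
    data = [np.asarray(observations[g], dtype=float) for g in names]
    for g, v in zip(names, data):
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    counts = tuple(int(v.size) for v in data)
    means = np.array([v.mean() for v in data])
    sds = np.array([v.std(ddof=1) for v in data])

    h = mandel_h(means)
    k = mandel_k(sds)
    hc = h_crit(len(names), alpha)
    if len(set(counts)) == 1:
        kc = k_crit(len(names), counts[0], alpha)
    else:
        warnings.warn(
            "unbalanced design: k critical value omitted", stacklevel=2
        )
        kc = None
    return MandelReport(
        groups=names,
        n_per_group=counts,
        means=means,
        sds=sds,
        h=h,
        k=k,
        grand_mean=float(means.mean()),
        between_sd=float(means.std(ddof=1)),
        pooled_sd=float(np.sqrt(np.mean(sds ** 2))),
        h_critical=hc,
        k_critical=kc,
        alpha=alpha,
    )
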