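"""Exploratory data analysis over the physicochemical descriptor table.

Per-class descriptive statistics, between-class hypothesis tests (Mann-
Whitney U by default, Student's t as an option), and PCA on column-
standardized descriptors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

# at most this many group assignments are enumerated for the exact U test
EXACT_ENUMERATION_LIMIT = 200_000


@dataclass(frozen=True)
class DescriptiveStats:
    """Nine-number summary of one descriptor in one class."""

    min: float
    q1: float
    median: float
    mean: float
    std: float
    q3: float
    max: float
    skewness: float
    kurtosis: float


def describe(values) -> DescriptiveStats:
    """Nine-number summary; quartiles by linear interpolation, sample std
    (n-1), adjusted Fisher-Pearson skewness, excess kurtosis."""
    x = np.sort(np.asarray(values, dtype=float))  # sorted: permutation-invariant sums
    if x.size < 2:
        raise ValueError("describe requires at least 2 values (std undefined for n<2)")
    return DescriptiveStats(
        min=float(x.min()),
        q1=float(np.percentile(x, 25)),
        median=float(np.median(x)),
        mean=float(x.mean()),
        std=float(x.std(ddof=1)),
        q3=float(np.percentile(x, 75)),
        max=float(x.max()),
        skewness=float(stats.skew(x, bias=False)) if x.std() > 0 else 0.0,
        kurtosis=float(stats.kurtosis(x, bias=False)) if x.std() > 0 else 0.0,
    )


def describe_by_class(table: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-class, per-descriptor nine-number summary (long format)."""
    rows = []
    for cls, idx in labels.groupby(labels).groups.items():
        sub = table.loc[idx]
        for col in table.columns:
            d = describe(sub[col].to_numpy())
            rows.append({"bioclass": cls, "descriptor": col, **d.__dict__})
    return pd.DataFrame(rows)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a from midranks of the pooled data."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2)


def mann_whitney_u(a, b, exact: bool | None = None) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Returns ``(U, p)`` where U is the statistic of the first sample. The
    exact p-value is obtained by enumerating all group assignments of the
    pooled data (valid under ties); it is used whenever the number of
    assignments C(n, n_a) is at most ``EXACT_ENUMERATION_LIMIT``, otherwise
    the tie-corrected normal approximation is used. ``exact`` forces the
    choice.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    u_obs = _u_statistic(a, b)
    n_total = a.size + b.size
    if exact is None:
        exact = math.comb(n_total, a.size) <= EXACT_ENUMERATION_LIMIT
    if exact:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        offset = a.size * (a.size + 1) / 2
        u_all = np.array(
            [sum(ranks[list(pick)]) - offset for pick in combinations(range(n_total), a.size)]
        )
        # two-sided: double the smaller tail (point mass included), cap at 1
        p_low = float(np.mean(u_all <= u_obs + 1e-9))
        p_high = float(np.mean(u_all >= u_obs - 1e-9))
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(p)
    return u_obs, p


def students_t(a, b) -> tuple[float, float]:
    """Two-sided two-sample Student's t test (equal-variance)."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(t), float(p)


@dataclass(frozen=True)
class PCAResult:
    """PCA on column-standardized data.

    ``loadings`` is a (n_components x n_features) frame of unit eigenvectors
    of the correlation matrix; ``scores`` projects each compound onto them.
    """

    loadings: pd.DataFrame
    explained_variance_pct: np.ndarray
    cumulative_variance_pct: np.ndarray
    scores: pd.DataFrame
    feature_means: pd.Series
    feature_stds: pd.Series


def pca(table: pd.DataFrame, n_components: int) -> PCAResult:
    """PCA of a descriptor table after z-score standardization.

    Zero-variance columns are dropped with a warning. Components are ordered
    by decreasing explained variance; each loading vector is signed so its
    largest-magnitude entry is positive.
    """
    if table.shape[0] < 2:
        raise ValueError("pca requires at least 2 rows")
    stds = table.std(ddof=1)
    zero_var = stds[stds == 0].index.tolist()
    if zero_var:
        logger.warning("dropping zero-variance columns before PCA: %s", zero_var)
        table = table.drop(columns=zero_var)
        stds = stds.drop(zero_var)
    if n_components > table.shape[1]:
        raise ValueError(
            f"n_components={n_components} exceeds usable feature count {table.shape[1]}"
        )
    means = table.mean()
    z = (table - means) / stds
    corr = np.atleast_2d(np.cov(z.to_numpy(), rowvar=False, ddof=1))
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-magnitude loading entry positive
    for j in range(eigvecs.shape[1]):
        k = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    pct = 100.0 * eigvals / eigvals.sum()
    comps = [f"PC{i + 1}" for i in range(n_components)]
    loadings = pd.DataFrame(
        eigvecs[:, :n_components].T, index=comps, columns=table.columns
    )
    scores = pd.DataFrame(
        z.to_numpy() @ eigvecs[:, :n_components], index=table.index, columns=comps
    )
    return PCAResult(
        loadings=loadings,
        explained_variance_pct=pct[:n_components],
        cumulative_variance_pct=np.cumsum(pct)[:n_components],
        scores=scores,
        feature_means=means,
        feature_stds=stds,
    )
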