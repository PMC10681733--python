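"""Shared statistical primitives.

The central piece is a two-group moderated t-test in the empirical-Bayes
tradition: per-feature residual variances are shrunk toward a prior variance
whose scale and degrees of freedom are estimated across features by moment
matching on the scaled-F distribution of sample variances.  With thousands of
features and only a handful of replicates per group this borrows strength
across features and stabilises the denominator of the t-statistic, which is
what makes 3-vs-3 proteomics comparisons workable.

Also here: Benjamini-Hochberg adjustment, seeded k-means, row z-scoring and
squared Pearson correlation, all used by both the AP-MS and TMT arms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .errors import DesignError, ParameterError, UndefinedResultError
from .io_tables import SampleDesign


@dataclass(frozen=True)
class ShrinkageEstimate:
    """Empirical-Bayes variance prior: ``prior_df`` pseudo-observations of
    variance ``prior_var``, and the resulting per-feature posterior variances
    (a df-weighted convex combination of feature and prior variance)."""

    prior_df: float
    prior_var: float
    posterior_var: np.ndarray


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-10:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled-F distribution to observed sample variances.

    Returns ``(prior_df, prior_var)``; ``prior_df`` may be ``inf`` when the
    spread of log sample variances is no larger than expected from chi-square
    sampling noise alone.
    """
    ok = (df > 0) & np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return math.inf, float(np.nanmedian(s2[ok])) if ok.any() else 0.0
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        prior_df = 2.0 * _trigamma_inverse(evar)
        prior_var = math.exp(emean + special.digamma(prior_df / 2.0) - math.log(prior_df / 2.0))
    else:
        prior_df = math.inf
        prior_var = math.exp(emean)
    return prior_df, prior_var


def moderated_two_group_test(
    matrix: pd.DataFrame,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-feature moderated two-group comparison on a log2 matrix.

    Parameters
    ----------
    matrix
        log2 features x samples DataFrame; ``NaN`` entries are treated as
        missing and excluded per feature.
    design
        Sample annotation supplying group membership.
    group_a, group_b
        Group labels; the reported ``log2_fc`` is mean(A) - mean(B).
    prior_df
        Override for the prior degrees of freedom.  ``None`` estimates it
        from the data; ``0`` reduces to the ordinary pooled two-sample t;
        ``inf`` divides by the prior standard deviation alone.

    Returns
    -------
    DataFrame indexed by feature id with columns ``log2_fc``, ``mean_a``,
    ``mean_b``, ``t``, ``p_value``, ``adj_p``, ``n_valid_a``, ``n_valid_b``.
    Features with fewer than two valid values in either group get ``NaN``
    statistics and are excluded from the BH adjustment.
    """
    a_samples = [s for s in design.samples_in_group(group_a) if s in matrix.columns]
    b_samples = [s for s in design.samples_in_group(group_b) if s in matrix.columns]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise DesignError(
            f"both groups need >= 2 samples (got {len(a_samples)} in {group_a!r}, "
            f"{len(b_samples)} in {group_b!r})"
        )
    A = matrix[a_samples].to_numpy(dtype=float)
    B = matrix[b_samples].to_numpy(dtype=float)
    na = np.sum(np.isfinite(A), axis=1)
    nb = np.sum(np.isfinite(B), axis=1)
    with np.errstate(invalid="ignore"):
        mean_a = np.where(na > 0, np.nansum(A, axis=1) / np.maximum(na, 1), np.nan)
        mean_b = np.where(nb > 0, np.nansum(B, axis=1) / np.maximum(nb, 1), np.nan)
        ssa = np.nansum((A - mean_a[:, None]) ** 2, axis=1)
        ssb = np.nansum((B - mean_b[:, None]) ** 2, axis=1)
    df_resid = (na + nb - 2).astype(float)
    testable = (na >= 2) & (nb >= 2)
    s2 = np.full(len(matrix), np.nan)
    s2[testable] = (ssa + ssb)[testable] / df_resid[testable]

    if prior_df is None:
        d0, s20 = estimate_variance_prior(s2[testable], df_resid[testable])
    elif prior_df == 0:
        d0, s20 = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s20 = estimate_variance_prior(s2[testable], df_resid[testable])

    post_var = np.full(len(matrix), np.nan)
    if math.isinf(d0):
        post_var[testable] = s20
        df_total = np.full(len(matrix), np.inf)
    else:
        post_var[testable] = (d0 * s20 + df_resid[testable] * s2[testable]) / (d0 + df_resid[testable])
        df_total = df_resid + d0

    diff = mean_a - mean_b
    se = np.sqrt(post_var * (1.0 / np.maximum(na, 1) + 1.0 / np.maximum(nb, 1)))
    t = np.full(len(matrix), np.nan)
    p = np.full(len(matrix), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        nonzero_se = testable & (se > 0)
        t[nonzero_se] = diff[nonzero_se] / se[nonzero_se]
        finite_df = nonzero_se & np.isfinite(df_total)
        p[finite_df] = 2.0 * stats.t.sf(np.abs(t[finite_df]), df_total[finite_df])
        inf_df = nonzero_se & ~np.isfinite(df_total)
        p[inf_df] = 2.0 * stats.norm.sf(np.abs(t[inf_df]))
    # degenerate features: zero posterior variance
    zero_se = testable & (se == 0)
    t[zero_se & (diff == 0)] = 0.0
    p[zero_se & (diff == 0)] = 1.0
    t[zero_se & (diff > 0)] = np.inf
    t[zero_se & (diff < 0)] = -np.inf
    p[zero_se & (diff != 0)] = 0.0

    adj = np.full(len(matrix), np.nan)
    have_p = np.isfinite(p)
    if have_p.any():
        adj[have_p] = bh_adjust(p[have_p])

    return pd.DataFrame(
        {
            "log2_fc": diff,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "t": t,
            "p_value": p,
            "adj_p": adj,
            "n_valid_a": na,
            "n_valid_b": nb,
        },
        index=matrix.index.rename("feature_id"),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, original
    order restored)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def kmeans_cluster(matrix, k: int, seed: int = 0) -> np.ndarray:
    """Seeded k-means labels (squared Euclidean, 10 random restarts, 300
    iteration cap); deterministic given the seed."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if k < 1:
        raise ParameterError("k must be positive")
    if k > X.shape[0]:
        raise ParameterError(f"k={k} exceeds number of features ({X.shape[0]})")
    if np.isnan(X).any():
        raise ParameterError("k-means input must not contain missing values")
    km = KMeans(n_clusters=k, n_init=10, max_iter=300, init="random", random_state=seed)
    return km.fit_predict(X)


def zscore_rows(matrix) -> np.ndarray | pd.DataFrame:
    """Center and scale each row to mean 0 / sd 1 (n-1 denominator); constant
    rows map to all zeros."""
    is_df = isinstance(matrix, pd.DataFrame)
    X = np.asarray(matrix, dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (X - mean) / sd, 0.0)
    if is_df:
        return pd.DataFrame(Z, index=matrix.index, columns=matrix.columns)
    return Z


def squared_pearson(x, y) -> float:
    """Square of the Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ParameterError("inputs must share a length of at least 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedResultError("correlation undefined for constant input")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def write_diff_result(result: pd.DataFrame, path) -> None:
    out = result.reset_index()[
        ["feature_id", "log2_fc", "t", "p_value", "adj_p", "n_valid_a", "n_valid_b"]
    ].rename(columns={"p_value": "p"})
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
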