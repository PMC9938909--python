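"""Per-group insulin-response testing and regulation calling.

For each biological group the insulin response of a feature is summarized by
``log2fc = mean(INS) - mean(BAS)`` (a log2 INS/BAS fold change) and tested by
a two-sided unequal-variance (Welch) t-test; the mouse study instead uses an
empirical-Bayes moderated t in which per-feature variances are shrunk toward
a prior fitted by moment matching across features. p-values are adjusted by
Benjamini-Hochberg within an explicitly stated family (a study, or one diet
of the mouse study), and a feature is called insulin-regulated when both the
adjusted significance (p_adj < 0.05) and fold-change magnitude
(|log2fc| > 0.58, i.e. a 1.5-fold linear change) thresholds are met.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_io import IntensityTable

#: log2 fold-change magnitude corresponding to a 1.5-fold linear change.
FC_THRESHOLD = 0.58
ALPHA = 0.05


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Two-sided Welch t-test of ``mean(x) - mean(y)`` (base-R convention).

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of freedom.
    Requires at least two non-missing values per side.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t_test needs >= 2 values per side")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return 0.0, float(nx + ny - 2), 1.0
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    # Satterthwaite df via the bounded ratio r = (vx/nx)/se2 (underflow-safe)
    r = (vx / nx) / se2
    df = 1.0 / (r**2 / (nx - 1) + (1.0 - r) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _welch_matrix(bas: np.ndarray, ins: np.ndarray) -> tuple[np.ndarray, ...]:
    """Row-wise Welch test over matrices with possible NaN (vectorized)."""
    n_b = np.sum(~np.isnan(bas), axis=1)
    n_i = np.sum(~np.isnan(ins), axis=1)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        m_b = np.nanmean(bas, axis=1)
        m_i = np.nanmean(ins, axis=1)
        v_b = np.nanvar(bas, axis=1, ddof=1)
        v_i = np.nanvar(ins, axis=1, ddof=1)
    testable = (n_b >= 2) & (n_i >= 2)
    se2 = np.where(testable, v_b / n_b + v_i / n_i, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m_i - m_b) / np.sqrt(se2)
        r = (v_b / n_b) / se2
        df = 1.0 / (r**2 / (n_b - 1) + (1.0 - r) ** 2 / (n_i - 1))
    zero_se = testable & (se2 == 0)
    t[zero_se] = 0.0
    df[zero_se] = (n_b + n_i - 2)[zero_se]
    p = np.full(len(t), np.nan)
    ok = testable & np.isfinite(t) & np.isfinite(df)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    p[zero_se] = 1.0
    return m_i - m_b, t, df, p, n_b, n_i


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN entries are passed through
    and do not count toward the family size."""
    arr = np.asarray(p, float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    pv = arr[mask]
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t


@dataclass
class ModeratedTestParams:
    """Prior degrees of freedom and prior variance for variance shrinkage."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be > 0 (use np.inf for complete shrinkage)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be > 0")


def _trigamma_inverse(x: float) -> float:
    # Newton iteration on psi'(y) = x; standard closed-form start points.
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> ModeratedTestParams:
    """Fit (d0, s0^2) by moment matching on log sample variances.

    Under the hierarchical model ``s^2 | sigma^2 ~ sigma^2 chi2_d / d`` with
    ``1/sigma^2 ~ chi2_d0 / (d0 s0^2)``, the statistic
    ``e = log s^2 - digamma(d/2) + log(d/2)`` has mean
    ``log s0^2 + digamma(d0/2) - log(d0/2)`` and variance
    ``trigamma(d/2) + trigamma(d0/2)``; matching both moments yields the
    prior. Features with zero or undefined variance are excluded from the fit.
    """
    s2 = np.asarray(s2, float)
    df = np.asarray(df, float)
    ok = np.isfinite(s2) & (s2 > 0) & np.isfinite(df) & (df > 0)
    s2, df = s2[ok], df[ok]
    if len(s2) < 2:
        raise ValueError("need >= 2 positive sample variances to fit the prior")
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) * (len(e) - 1) / len(e)  # population variance, as in moment matching
    excess = e_var - np.mean(special.polygamma(1, df / 2.0))
    if excess <= 0:
        # variances more concentrated than any finite-d0 prior allows
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(float(excess))
        # E[e] = log s0^2 + log(d0/2) - digamma(d0/2); invert for s0^2
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModeratedTestParams(d0=d0, s0_sq=s0_sq)


def moderated_t_test(
    table: IntensityTable,
    group: str,
    treatments: tuple[str, str] = ("BAS", "INS"),
    prior: ModeratedTestParams | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test of treatment response within a group.

    Per-feature pooled variances are shrunk toward the moment-matched prior:
    ``s_tilde^2 = (d0 s0^2 + d s^2) / (d0 + d)``, and the t statistic
    ``log2fc / (s_tilde sqrt(1/n1 + 1/n2))`` is referred to a t distribution
    with ``d0 + d`` degrees of freedom. The constant-prior (no variance
    trend) variant is used.
    """
    t0, t1 = treatments
    bas = table.values[table.samples_of(group, t0)].to_numpy()
    ins = table.values[table.samples_of(group, t1)].to_numpy()
    n1 = np.sum(~np.isnan(bas), axis=1)
    n2 = np.sum(~np.isnan(ins), axis=1)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        m1 = np.nanmean(bas, axis=1)
        m2 = np.nanmean(ins, axis=1)
        ss = (np.nansum((bas - m1[:, None]) ** 2, axis=1)
              + np.nansum((ins - m2[:, None]) ** 2, axis=1))
    df = n1 + n2 - 2.0
    testable = (n1 >= 2) & (n2 >= 2)
    s2 = np.where(testable & (df > 0), ss / np.maximum(df, 1), np.nan)

    if prior is None:
        prior = fit_variance_prior(s2[testable], df[testable])
    d0, s0_sq = prior.d0, prior.s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    log2fc = m2 - m1
    with np.errstate(invalid="ignore", divide="ignore"):
        t = log2fc / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    p = np.full(len(t), np.nan)
    ok = testable & np.isfinite(t)
    if np.isinf(d0):
        p[ok] = 2.0 * stats.norm.sf(np.abs(t[ok]))
    else:
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_total[ok])
    t = np.where(testable, t, np.nan)

    return pd.DataFrame(
        {
            "feature_id": table.feature_ids,
            "group": group,
            "log2fc": np.where(testable, log2fc, np.nan),
            "t": t,
            "df": np.where(testable, df_total, np.nan),
            "p_raw": p,
            "n_bas": n1,
            "n_ins": n2,
        }
    ).set_index("feature_id", drop=False)


def insulin_response_test(
    table: IntensityTable,
    group: str,
    treatments: tuple[str, str] = ("BAS", "INS"),
) -> pd.DataFrame:
    """Welch t-test of the treatment response within one group, per feature.

    Features quantified fewer than twice on either side are reported with
    NaN statistics (untested), never dropped.
    """
    t0, t1 = treatments
    bas = table.values[table.samples_of(group, t0)].to_numpy()
    ins = table.values[table.samples_of(group, t1)].to_numpy()
    log2fc, t, df, p, n_b, n_i = _welch_matrix(bas, ins)
    return pd.DataFrame(
        {
            "feature_id": table.feature_ids,
            "group": group,
            "log2fc": log2fc,
            "t": t,
            "df": df,
            "p_raw": p,
            "n_bas": n_b,
            "n_ins": n_i,
        }
    ).set_index("feature_id", drop=False)


def adjust_within_family(results: pd.DataFrame, family: str | None = None) -> pd.DataFrame:
    """Append BH-adjusted p-values; the adjustment family is the given frame.

    The family is an explicit choice of the caller (one study, or one diet),
    recorded in the ``family`` column.
    """
    out = results.copy()
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["family"] = family if family is not None else str(out["group"].iloc[0])
    return out


def call_regulated(
    results: pd.DataFrame,
    fc_threshold: float = FC_THRESHOLD,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Label each feature up / down / unregulated / untested.

    up: p_adj < alpha and log2fc > fc_threshold; down mirrored; untested
    where no p-value could be computed.
    """
    out = results.copy()
    lfc = out["log2fc"].to_numpy()
    padj = out["p_adj"].to_numpy()
    label = np.where(np.isnan(padj), "untested", "unregulated").astype(object)
    label[(padj < alpha) & (lfc > fc_threshold)] = "up"
    label[(padj < alpha) & (lfc < -fc_threshold)] = "down"
    out["label"] = label
    return out
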