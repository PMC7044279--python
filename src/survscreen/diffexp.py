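"""Quantile normalization and empirical-Bayes moderated differential expression.

The two-group contrast (high minus low expressers) is tested per probe with
a moderated t-statistic: the pooled per-probe variance s^2 (df = nL + nH - 2)
is shrunk toward a prior variance s0^2 carrying d0 prior degrees of freedom,

    s_tilde^2 = (d0 * s0^2 + df * s^2) / (d0 + df)
    t_tilde   = (mean_high - mean_low) / (s_tilde * sqrt(1/nL + 1/nH))

with two-sided p from a t distribution on d0 + df degrees of freedom.  The
hyperparameters (d0, s0^2) are estimated by matching the first two moments
of log sample variances under the scaled-F model, using digamma/trigamma
identities and a Newton inversion of the trigamma function.  d0 = 0 recovers
the ordinary pooled t; d0 = infinity shrinks every variance fully to s0^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

log = logging.getLogger(__name__)

MIN_PROBES_FOR_MODERATION = 30
#: above this many degrees of freedom the t distribution is treated as normal
MAX_T_DF = 1e6


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the common rank-mean distribution.

    Each column's sorted values are replaced by the across-column means of
    order statistics; ties within a column receive the mean of the reference
    values they span.  Missing cells are filled with the column mean for
    ranking and restored to missing afterwards.
    """
    df = matrix.values
    if df.shape[1] < 2:
        log.warning("quantile normalization skipped: single-sample matrix")
        return ExpressionMatrix(df.copy())
    arr = df.to_numpy(dtype=float)
    missing = np.isnan(arr)
    if missing.any():
        col_means = np.nanmean(arr, axis=0)
        arr = np.where(missing, col_means[None, :], arr)
    order = np.argsort(arr, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(arr, order, axis=0)
    ref = sorted_vals.mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")  # mid-ranks for ties
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), ref)
    out[missing] = np.nan
    return ExpressionMatrix(pd.DataFrame(out, index=df.index, columns=df.columns))


@dataclass
class ModerationParams:
    """Scaled-F prior for per-probe variances: d0 prior df, s0_sq prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0 or self.s0_sq <= 0:
            raise ValueError("d0 must be >= 0 and s0_sq > 0")


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/x asymptotics."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y  # start from trigamma(x) ~ 1/x + 1/(2x^2)
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_moderation(residual_variances, residual_df: int) -> ModerationParams:
    """Moment-match (d0, s0^2) from observed log sample variances.

    Under the scaled-F model, log s^2 = log s0^2 + log F(df, d0); the mean
    and variance of e = log s^2 - digamma(df/2) + log(df/2) identify the
    hyperparameters through digamma/trigamma identities.  When the observed
    spread does not exceed the chi-square sampling spread, d0 is infinite
    (all variances shrunk fully).  Fewer than 30 probes → no moderation
    (d0 = 0, s0^2 = mean variance) with a warning.
    """
    s2 = np.asarray(residual_variances, dtype=float)
    if (s2 <= 0).any():
        raise ValueError("residual variances must be positive")
    if residual_df < 1:
        raise ValueError("residual_df must be >= 1")
    if s2.size < MIN_PROBES_FOR_MODERATION:
        log.warning("only %d probes: falling back to d0=0 (no moderation)", s2.size)
        return ModerationParams(0.0, float(np.mean(s2)))
    df = float(residual_df)
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return ModerationParams(np.inf, float(np.exp(e_mean)))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return ModerationParams(d0, s0_sq)


def moderated_t_test(
    matrix: ExpressionMatrix,
    low_ids,
    high_ids,
    params: ModerationParams | None = None,
) -> pd.DataFrame:
    """Per-probe moderated t between high and low expressers.

    Returns a DataFrame indexed by probe id with columns mean_low, mean_high,
    log2fc (= mean_high - mean_low), t_moderated, p_value, p_adjusted (BH),
    posterior_s2 and degenerate.  ``params=None`` estimates the moderation
    hyperparameters from this matrix's pooled variances.
    """
    low_ids, high_ids = list(low_ids), list(high_ids)
    nL, nH = len(low_ids), len(high_ids)
    if nL < 2 or nH < 2:
        raise ValueError("both groups need at least 2 samples")
    lo = matrix.values.loc[:, low_ids].to_numpy(dtype=float)
    hi = matrix.values.loc[:, high_ids].to_numpy(dtype=float)
    mean_low = np.nanmean(lo, axis=1)
    mean_high = np.nanmean(hi, axis=1)
    var_low = np.nanvar(lo, axis=1, ddof=1)
    var_high = np.nanvar(hi, axis=1, ddof=1)
    df_resid = nL + nH - 2
    s2 = ((nL - 1) * var_low + (nH - 1) * var_high) / df_resid
    if params is None:
        positive = s2[s2 > 0]
        params = estimate_moderation(positive, df_resid) if positive.size else ModerationParams(0.0, 1.0)
    d0 = params.d0
    if np.isinf(d0):
        post_s2 = np.full_like(s2, params.s0_sq)
        df_total = np.inf
    else:
        post_s2 = (d0 * params.s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    log2fc = mean_high - mean_low
    se = np.sqrt(post_s2 * (1.0 / nL + 1.0 / nH))
    degenerate = post_s2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, np.sign(log2fc) * np.inf, log2fc / se)
    if np.isinf(df_total) or df_total > MAX_T_DF:
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(degenerate & (log2fc != 0), 0.0, p)
    p = np.where(degenerate & (log2fc == 0), 1.0, p)
    out = pd.DataFrame(
        {
            "mean_low": mean_low,
            "mean_high": mean_high,
            "log2fc": log2fc,
            "t_moderated": t,
            "p_value": p,
            "p_adjusted": bh_adjust(p),
            "posterior_s2": post_s2,
            "degenerate": degenerate,
        },
        index=matrix.values.index,
    )
    out.index.name = "probe_id"
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_de_genes(
    records: pd.DataFrame, fc_cut: float = 1.0, q_cut: float = 0.05
) -> tuple[list[str], list[str]]:
    """(up_in_high, down_in_high) probe lists at |log2fc| > fc_cut, q < q_cut."""
    if records.empty:
        raise ValueError("no differential-expression records")
    sig = records["p_adjusted"] < q_cut
    up = list(records.index[sig & (records["log2fc"] > fc_cut)])
    down = list(records.index[sig & (records["log2fc"] < -fc_cut)])
    return up, down
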