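"""Descriptive and inferential statistics for the participation analysis.

* ``describe`` reports mean/SD or median/IQR, the branch chosen by skewness
  and kurtosis Z scores (|Z| <= 1.96 for both -> treat as normal).
* ``spearman_matrix`` correlates participation measures with influencing
  factors, flagged at alpha 0.01 (the convention adopted for the multiple
  correlations) and 0.05.  P-values use the t approximation
  t = rho * sqrt((n-2)/(1-rho^2)); for n <= 10 an exact permutation
  distribution is enumerated instead.
* ``paired_agreement`` runs a paired t-test on self-report minus GPS
  differences and summarises agreement Bland-Altman style (bias and
  bias +/- 1.96 SD limits).
"""
from __future__ import annotations

import functools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import AgreementResult, Descriptives


# --------------------------------------------------------------------------
# Normality-aware descriptives
# --------------------------------------------------------------------------


def _skew_kurt_z(x: np.ndarray) -> tuple[float, float]:
    """Z scores of sample skewness and excess kurtosis (bias-corrected,
    standard errors from the normal-theory formulas)."""
    n = x.size
    se_skew = math.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))
    skew_z = sps.skew(x, bias=False) / se_skew
    if n > 3:
        se_kurt = 2.0 * se_skew * math.sqrt((n * n - 1) / ((n - 3) * (n + 5)))
        kurt_z = sps.kurtosis(x, bias=False) / se_kurt
    else:
        kurt_z = float("nan")
    return float(skew_z), float(kurt_z)


def describe(values, z_crit: float = 1.96) -> Descriptives:
    """Mean/SD or median/IQR, chosen by a Z-score normality check (n >= 3)."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    mean = float(np.mean(x)) if n else float("nan")
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    median = float(np.median(x)) if n else float("nan")
    q1, q3 = (
        (float(np.percentile(x, 25)), float(np.percentile(x, 75)))
        if n
        else (float("nan"), float("nan"))
    )
    if n < 3:
        return Descriptives(n, mean, sd, median, q1, q3,
                            float("nan"), float("nan"), None, "insufficient")
    if sd == 0.0:
        return Descriptives(n, mean, 0.0, median, q1, q3,
                            float("nan"), float("nan"), None, "degenerate")
    skew_z, kurt_z = _skew_kurt_z(x)
    normal = abs(skew_z) <= z_crit and (math.isnan(kurt_z) or abs(kurt_z) <= z_crit)
    return Descriptives(
        n, mean, sd, median, q1, q3, skew_z, kurt_z, normal,
        "mean_sd" if normal else "median_iqr",
    )


# --------------------------------------------------------------------------
# Spearman correlation
# --------------------------------------------------------------------------


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman_rho(x, y) -> float:
    """Spearman's rho with average ranks for ties (undefined for a
    zero-variance input, reported as NaN)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx, ry = _rank(x), _rank(y)
    if np.std(rx) == 0.0 or np.std(ry) == 0.0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


@functools.lru_cache(maxsize=4)
def _all_perms(n: int) -> np.ndarray:
    """All n! permutations of range(n) as an (n!, n) int8 array (n <= 10)."""
    if n == 1:
        return np.zeros((1, 1), dtype=np.int8)
    p = _all_perms(n - 1)
    m = p.shape[0]
    out = np.empty((n * m, n), dtype=np.int8)
    for i in range(n):
        block = out[i * m: (i + 1) * m]
        block[:, 0] = i
        block[:, 1:] = p + (p >= i)  # remap 0..n-2 onto values != i
    return out


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value, enumerating all n! orderings.

    Under permutation the rank mean and variance of y are fixed, so only the
    cross-product with the centred x ranks varies; the enumeration reduces
    to chunked matrix products.
    """
    rx = _rank(x)
    ry = _rank(y)
    rx_c = rx - rx.mean()
    den = np.sqrt(np.sum(rx_c**2)) * np.sqrt(np.sum((ry - ry.mean()) ** 2))
    n = rx.size
    perms = _all_perms(n)
    stat_obs = abs(rho_obs) - 1e-12
    count = 0
    for i in range(0, perms.shape[0], 1_000_000):
        chunk = perms[i: i + 1_000_000]
        # sum(rx_c) == 0, so centring y contributes nothing to the product
        rho = (ry[chunk] @ rx_c) / den
        count += int(np.sum(np.abs(rho) >= stat_obs))
    return count / perms.shape[0]


def spearman_pvalue(x, y, rho: float | None = None, exact_max_n: int = 10) -> float:
    """Two-sided p for Spearman's rho (exact permutation for n <= 10)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if rho is None:
        rho = spearman_rho(x, y)
    if math.isnan(rho):
        return float("nan")
    n = x.size
    if n <= exact_max_n:
        return _exact_spearman_p(x, y, rho)
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


class SpearmanMatrix:
    """rho / p / significance tables between row and column variables."""

    def __init__(self, rho: pd.DataFrame, p: pd.DataFrame, alpha: float = 0.01):
        self.rho = rho
        self.p = p
        self.alpha = alpha
        self.sig_alpha = p < alpha
        self.sig_05 = p < 0.05

    def annotated(self) -> pd.DataFrame:
        """rho rounded to 3 dp with 'b' (alpha) / 'a' (0.05) markers."""
        out = self.rho.round(3).astype(object)
        for r in out.index:
            for c in out.columns:
                mark = ""
                if self.sig_alpha.loc[r, c]:
                    mark = "b"
                elif self.sig_05.loc[r, c]:
                    mark = "a"
                out.loc[r, c] = f"{self.rho.loc[r, c]:.3f}{mark}"
        return out


def spearman_matrix(
    data: pd.DataFrame,
    row_vars: list[str],
    col_vars: list[str],
    alpha: float = 0.01,
) -> SpearmanMatrix:
    """Spearman correlations of every row variable against every column
    variable (needs >= 5 complete observations)."""
    if len(data) < 5:
        raise ValueError("spearman_matrix needs at least 5 participants")
    rho = pd.DataFrame(index=row_vars, columns=col_vars, dtype=float)
    p = pd.DataFrame(index=row_vars, columns=col_vars, dtype=float)
    for r in row_vars:
        for c in col_vars:
            rv = spearman_rho(data[r], data[c])
            rho.loc[r, c] = rv
            p.loc[r, c] = (
                spearman_pvalue(data[r], data[c], rv)
                if not math.isnan(rv)
                else float("nan")
            )
    return SpearmanMatrix(rho, p, alpha)


# --------------------------------------------------------------------------
# Paired agreement (self-report vs GPS) and Bland-Altman
# --------------------------------------------------------------------------


def paired_agreement(
    self_counts, gps_counts, by: str = "total", alpha: float = 0.05
) -> AgreementResult:
    """Paired t-test and Bland-Altman agreement on self - GPS differences.

    Zero-variance differences use the degenerate convention t = 0, p = 1
    (an all-zero difference vector is perfect agreement; a constant non-zero
    one has no within-pair variability to test against).
    """
    s = np.asarray(self_counts, dtype=float)
    g = np.asarray(gps_counts, dtype=float)
    if s.shape != g.shape:
        raise ValueError("paired vectors must have equal length")
    n = s.size
    if n < 2:
        raise ValueError("paired_agreement needs n >= 2")
    d = s - g
    sd_d = float(np.std(d, ddof=1))
    bias = float(np.mean(d))
    degenerate = sd_d == 0.0
    if degenerate:
        t_stat, p_value = 0.0, 1.0
    else:
        t_stat = bias / (sd_d / math.sqrt(n))
        p_value = float(2.0 * sps.t.sf(abs(t_stat), df=n - 1))
    return AgreementResult(
        by=by,
        n=n,
        self_mean=float(np.mean(s)),
        self_sd=float(np.std(s, ddof=1)),
        gps_mean=float(np.mean(g)),
        gps_sd=float(np.std(g, ddof=1)),
        mean_diff=bias,
        t_stat=float(t_stat),
        p_value=p_value,
        bias=bias,
        loa_low=bias - 1.96 * sd_d,
        loa_high=bias + 1.96 * sd_d,
        degenerate=degenerate,
        pair_means=(s + g) / 2.0,
        pair_diffs=d,
    )


def bland_altman_table(result: AgreementResult) -> pd.DataFrame:
    """(mean of pair, difference) rows for a Bland-Altman plot/export."""
    return pd.DataFrame(
        {"pair_mean": result.pair_means, "difference": result.pair_diffs}
    )


def agreement_table(
    self_df: pd.DataFrame, gps_df: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Per-location agreement table (total first, then each category).

    ``self_df``/``gps_df``: participants x location-type count tables with
    identical indices and columns.
    """
    results: dict[str, AgreementResult] = {}
    rows = []
    cols = ["total"] + [c for c in self_df.columns if c != "total"]
    s_tot = (
        self_df["total"]
        if "total" in self_df
        else self_df.sum(axis=1)
    )
    g_tot = (
        gps_df["total"]
        if "total" in gps_df
        else gps_df.sum(axis=1)
    )
    for c in cols:
        s = s_tot if c == "total" else self_df[c]
        g = g_tot if c == "total" else gps_df[c]
        r = paired_agreement(s, g, by=c, alpha=alpha)
        results[c] = r
        rows.append(
            {
                "location": c,
                "self_mean": r.self_mean,
                "self_sd": r.self_sd,
                "gps_mean": r.gps_mean,
                "gps_sd": r.gps_sd,
                "mean_difference": r.mean_diff,
                "t": r.t_stat,
                "p": r.p_value,
            }
        )
    return pd.DataFrame(rows).set_index("location"), results
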