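"""Design-based estimation for clustered survey samples.

Weighted prevalences use the ratio estimator with Taylor-linearized
variance treating clusters as with-replacement primary sampling units
(single implicit stratum); confidence intervals are logit-transformed
Wald intervals with t(n_psu − 1) reference, which keeps them inside
(0, 100) — a plain Wald interval is available.  Contingency-table
tests use the design-based Pearson statistic with a second-order
Rao–Scott correction referred to an F distribution, the convention of
standard survey software.  ``relative_change`` is the relative-percent
trend statistic used for the telephone-ownership series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .sampling import SurveySample
from .weighting import WeightVector

logger = logging.getLogger(__name__)


class EstimationError(ValueError):
    pass


@dataclass
class PrevalenceEstimate:
    """Weighted prevalence with design-based uncertainty (percent scale)."""

    indicator: str
    percent: float
    se_percent: float
    ci_low: float
    ci_high: float
    n_unweighted: int
    n_weighted: float
    n_psu: int
    ci_method: str = "logit"

    def rounded(self) -> tuple[float, float, float]:
        """Point and CI rounded to one decimal, the reporting convention."""
        return (round(self.percent, 1), round(self.ci_low, 1),
                round(self.ci_high, 1))


@dataclass
class ChiSquareResult:
    """Design-based Pearson test of independence.

    ``statistic`` is the uncorrected design-based Pearson X²;
    ``f_statistic`` with (``df1``, ``df2``) and ``p_value`` carry the
    second-order Rao–Scott correction.
    """

    statistic: float
    df: float
    p_value: float
    f_statistic: float
    df1: float
    df2: float
    deff_mean: float


def _prep(sample, weights):
    df = sample.data if isinstance(sample, SurveySample) else sample
    w = np.asarray(weights.values if isinstance(weights, WeightVector)
                   else weights, dtype=float)
    if len(w) != len(df):
        raise EstimationError("weights not aligned with sample")
    return df, w


def _cluster_totals(z: np.ndarray, psu_codes: np.ndarray,
                    n_psu: int) -> np.ndarray:
    if z.ndim == 1:
        return np.bincount(psu_codes, weights=z, minlength=n_psu)
    return np.stack([np.bincount(psu_codes, weights=z[:, j], minlength=n_psu)
                     for j in range(z.shape[1])], axis=1)


def _linearized_variance(z: np.ndarray, psu_codes: np.ndarray,
                         n_psu: int) -> np.ndarray:
    """With-replacement PSU variance of a total whose linearized scores
    are ``z`` (rows sum to the estimator's deviation; score totals sum
    to zero over clusters)."""
    zc = _cluster_totals(z, psu_codes, n_psu)
    zc = zc - zc.mean(axis=0)
    if z.ndim == 1:
        return n_psu / (n_psu - 1) * float(np.sum(zc ** 2))
    return n_psu / (n_psu - 1) * (zc.T @ zc)


def weighted_prevalence(sample: SurveySample | pd.DataFrame,
                        weights: WeightVector | pd.Series | np.ndarray,
                        indicator: str,
                        psu_col: str = "cluster_id",
                        ci_method: str = "logit",
                        alpha: float = 0.05) -> PrevalenceEstimate:
    """Design-based weighted prevalence of a binary indicator.

    Missing indicator values are excluded from numerator and
    denominator.  Requires at least two primary sampling units.
    """
    df, w = _prep(sample, weights)
    y = pd.to_numeric(df[indicator], errors="coerce").to_numpy(dtype=float)
    keep = ~np.isnan(y)
    if not keep.any():
        raise EstimationError(f"indicator {indicator!r} is entirely missing")
    y, w_k = y[keep], w[keep]
    psu = df.loc[keep, psu_col].to_numpy()
    codes, _ = pd.factorize(psu)
    n_psu = int(codes.max()) + 1
    if n_psu < 2:
        raise EstimationError("variance undefined with fewer than 2 PSUs")

    W = w_k.sum()
    p = float(np.dot(w_k, y) / W)
    z = w_k * (y - p) / W
    var = _linearized_variance(z, codes, n_psu)
    se = float(np.sqrt(var))
    tcrit = stats.t.ppf(1 - alpha / 2, n_psu - 1)

    if p <= 0.0 or p >= 1.0 or ci_method == "wald":
        lo = max(0.0, p - tcrit * se)
        hi = min(1.0, p + tcrit * se)
        method = "wald"
    else:
        se_l = se / (p * (1 - p))
        lo = float(expit(logit(p) - tcrit * se_l))
        hi = float(expit(logit(p) + tcrit * se_l))
        method = "logit"
    return PrevalenceEstimate(indicator=indicator, percent=100 * p,
                              se_percent=100 * se, ci_low=100 * lo,
                              ci_high=100 * hi,
                              n_unweighted=int(keep.sum()),
                              n_weighted=float(W), n_psu=n_psu,
                              ci_method=method)


NO_TELEPHONE_STATUSES = ("neither",)


def exclude_no_telephone(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop records whose household has no telephone service (or whose
    status is missing); returns the kept frame and the excluded count."""
    status = df["telephone_status"]
    bad = status.isna() | status.astype(object).isin(NO_TELEPHONE_STATUSES)
    return df.loc[~bad], int(bad.sum())


def crosstab_proportions(sample: SurveySample | pd.DataFrame,
                         weights: WeightVector | pd.Series | np.ndarray,
                         row_var: str,
                         indicator: str,
                         psu_col: str = "cluster_id",
                         drop_no_telephone: bool = True,
                         ci_method: str = "logit"
                         ) -> dict[object, PrevalenceEstimate]:
    """Weighted prevalence of ``indicator`` within each category of
    ``row_var`` (the layout of a mobile-only-by-demographics table).

    By default records from households with no telephone service (or
    undetermined status) are excluded first, mirroring the analysis
    convention for telephone-status tabulations.  Empty categories are
    omitted with a warning.
    """
    df, w = _prep(sample, weights)
    if drop_no_telephone and "telephone_status" in df.columns:
        kept, n_dropped = exclude_no_telephone(df)
        if n_dropped:
            logger.info("excluded %d record(s) with no telephone service "
                        "or undetermined status", n_dropped)
        w = w[np.asarray(df.index.get_indexer(kept.index))]
        df = kept
    out: dict[object, PrevalenceEstimate] = {}
    for cat, part in df.groupby(row_var, observed=True):
        if len(part) == 0:
            continue
        idx = df.index.get_indexer(part.index)
        try:
            out[cat] = weighted_prevalence(part, w[idx], indicator,
                                           psu_col=psu_col,
                                           ci_method=ci_method)
        except EstimationError as err:
            logger.warning("category %r omitted: %s", cat, err)
    if not out:
        raise EstimationError(f"no estimable categories for {row_var!r}")
    return out


def rao_scott_chi2(sample: SurveySample | pd.DataFrame,
                   weights: WeightVector | pd.Series | np.ndarray,
                   row_var: str, col_var: str,
                   psu_col: str = "cluster_id",
                   correction: str = "rao-scott") -> ChiSquareResult:
    """Test of independence on the weighted contingency table.

    The Pearson statistic is computed on weighted cell proportions with
    the unweighted n.  With ``correction="rao-scott"`` (default) the
    generalized design effects — eigenvalues of the SRS-multinomial
    covariance inverse times the linearized covariance, on the space of
    independence contrasts — give the second-order (Satterthwaite)
    adjustment, and the p-value comes from an F reference with
    (d/(1+a²), ν·d/(1+a²)) degrees of freedom, ν = n_psu − 1.  With
    ``correction="none"`` a classical chi-square reference is used.
    """
    df, w = _prep(sample, weights)
    r_codes, r_cats = pd.factorize(df[row_var].astype(object), sort=True)
    c_codes, c_cats = pd.factorize(df[col_var].astype(object), sort=True)
    keep = (r_codes >= 0) & (c_codes >= 0)
    r_codes, c_codes, w_k = r_codes[keep], c_codes[keep], w[keep]
    R, C = len(r_cats), len(c_cats)
    if R < 2 or C < 2:
        raise EstimationError("both variables need at least 2 levels")
    n = int(keep.sum())

    cell = r_codes * C + c_codes
    W = w_k.sum()
    p = np.bincount(cell, weights=w_k, minlength=R * C) / W
    P = p.reshape(R, C)
    rmarg, cmarg = P.sum(axis=1), P.sum(axis=0)
    if (rmarg <= 0).any() or (cmarg <= 0).any():
        raise EstimationError("degenerate table: a margin is zero")
    expected = np.outer(rmarg, cmarg)
    x2 = float(n * np.sum((P - expected) ** 2 / expected))
    d = (R - 1) * (C - 1)

    psu_codes, _ = pd.factorize(df.loc[keep, psu_col].to_numpy())
    n_psu = int(psu_codes.max()) + 1
    if n_psu < 2:
        raise EstimationError("need at least 2 PSUs")

    if correction == "none":
        pval = float(stats.chi2.sf(x2, d))
        return ChiSquareResult(statistic=x2, df=float(d), p_value=pval,
                               f_statistic=x2 / d, df1=float(d),
                               df2=float("inf"), deff_mean=1.0)

    # linearized covariance of the RC cell-proportion vector
    ind = np.zeros((n, R * C))
    ind[np.arange(n), cell] = 1.0
    z = (w_k[:, None] * (ind - p[None, :])) / W
    vhat = _linearized_variance(z, psu_codes, n_psu)

    # contrasts h_ab = p_ab − r_a c_b, a < R−1? use all (R−1)(C−1)
    G = np.zeros((d, R * C))
    k = 0
    for a in range(R - 1):
        for b in range(C - 1):
            for cc in range(R):
                for dd in range(C):
                    val = 0.0
                    if cc == a and dd == b:
                        val += 1.0
                    if cc == a:
                        val -= cmarg[b]
                    if dd == b:
                        val -= rmarg[a]
                    G[k, cc * C + dd] = val
            k += 1
    v_h = G @ vhat @ G.T
    p_mult = np.diag(p) - np.outer(p, p)
    v0_h = G @ p_mult @ G.T / n
    # pseudo-inverse guards degenerate tables (e.g. perfect association,
    # where the estimated null covariance of the contrasts is singular)
    delta = np.real(np.linalg.eigvals(np.linalg.pinv(v0_h) @ v_h))
    delta = delta[delta > 1e-9]
    if delta.size == 0:
        delta = np.ones(1)
    dbar = float(delta.mean())
    a2 = float(delta.var() / dbar ** 2) if delta.size > 1 else 0.0

    df1 = d / (1 + a2)
    nu = n_psu - 1
    df2 = nu * df1
    f_stat = x2 / (d * dbar)
    pval = float(stats.f.sf(f_stat, df1, df2))
    return ChiSquareResult(statistic=x2, df=df1, p_value=pval,
                           f_statistic=f_stat, df1=df1, df2=df2,
                           deff_mean=dbar)


def relative_change(old_pct: float, new_pct: float) -> float:
    """Relative percent change ((new − old) / old) × 100.

    E.g. a rise from 5.2 % to 27.6 % is a 430.8 % ≈ 431 % increase.
    Undefined for ``old_pct == 0``.
    """
    if old_pct == 0:
        raise EstimationError("relative change undefined for old value 0")
    return (new_pct - old_pct) / old_pct * 100.0


def report_relative_change(old_pct: float, new_pct: float) -> float:
    """``relative_change`` rounded by the reporting convention: whole
    percent when the magnitude is at least 100, one decimal below."""
    rc = relative_change(old_pct, new_pct)
    return float(round(rc)) if abs(rc) >= 100 else round(rc, 1)
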