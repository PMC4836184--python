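"""Hypothetical telephone sampling frames and the relative coverage
bias (RCB) statistic.

Two frames are built from a face-to-face sample's telephone questions:

* ``rdd_landline`` — households with a working landline connection
  (mobile-only and no-telephone households excluded), the population an
  RDD landline survey can reach;
* ``directory_listed`` — households with either a landline or a mobile
  number listed in the public directory (EWP), the population a
  directory-sampled survey can reach.

The bias of a frame-based prevalence estimate is summarised by

    RCB = (N_nc / N) · (p_c − p_nc) / P

where ``f = N_nc/N`` is the non-covered share, ``p_c``/``p_nc`` the
prevalence among covered/non-covered people, and ``P`` the overall
prevalence.  In *consistent* mode one weight vector is used throughout,
so the decomposition P = (1−f)p_c + f·p_nc holds and RCB equals
(p_c − P)/P exactly.  In *reweighted* mode the covered-frame prevalence
is first re-calibrated to the population benchmarks — the workflow used
to produce published frame comparisons — which breaks the exact
identity but answers "what would the telephone survey have published?".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .estimation import EstimationError, weighted_prevalence
from .sampling import SurveySample
from .weighting import WeightVector, reweight_subsample

_SCALES = ("auto", "percent", "proportion")


@dataclass(frozen=True)
class FrameDefinition:
    """A named membership predicate over person records."""

    name: str
    predicate: Callable[[pd.DataFrame], pd.Series]

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        m = np.asarray(self.predicate(df), dtype=bool)
        if len(m) != len(df):
            raise ValueError(f"frame {self.name!r} predicate returned "
                             f"{len(m)} values for {len(df)} records")
        return m


RDD_LANDLINE = FrameDefinition(
    "rdd_landline",
    lambda df: df["telephone_status"].astype(object)
                 .isin(("landline_only", "both")))

DIRECTORY_LISTED = FrameDefinition(
    "directory_listed",
    lambda df: df["listed_landline"].astype(bool)
               | df["listed_mobile"].astype(bool))

FRAMES: dict[str, FrameDefinition] = {f.name: f
                                      for f in (RDD_LANDLINE, DIRECTORY_LISTED)}


@dataclass
class FramePartition:
    """Exhaustive, disjoint covered / not-covered split of a sample."""

    frame: FrameDefinition
    covered: pd.DataFrame
    not_covered: pd.DataFrame
    mask: np.ndarray


@dataclass
class RCBResult:
    """RCB of one indicator for one frame.

    Prevalences are on the percent scale; ``abs_diff`` is the frame
    estimate minus the overall estimate, in percentage points (its
    magnitude is what gets reported); ``rcb`` is dimensionless,
    conventionally printed to three decimals (:meth:`rounded`).
    """

    frame: str
    indicator: str
    n_total: float
    n_not_covered: float
    f: float
    p_c: float
    p_nc: float
    p_overall: float
    rcb: float
    abs_diff: float
    mode: str

    def rounded(self) -> float:
        return round(self.rcb, 3)


def _as_frame(sample) -> pd.DataFrame:
    return sample.data if isinstance(sample, SurveySample) else sample


def _frame_of(frame: FrameDefinition | str) -> FrameDefinition:
    if isinstance(frame, str):
        try:
            return FRAMES[frame]
        except KeyError:
            raise KeyError(f"unknown frame {frame!r}; "
                           f"available: {sorted(FRAMES)}") from None
    return frame


def build_frame(sample: SurveySample | pd.DataFrame,
                frame: FrameDefinition | str) -> FramePartition:
    """Partition a sample into frame members and the non-covered rest."""
    df = _as_frame(sample)
    fd = _frame_of(frame)
    for col in ("telephone_status", "listed_landline", "listed_mobile"):
        if col not in df.columns:
            raise ValueError(f"sample lacks required column {col!r}")
    m = fd.mask(df)
    return FramePartition(frame=fd, covered=df.loc[m],
                          not_covered=df.loc[~m], mask=m)


def coverage_fraction(sample: SurveySample | pd.DataFrame,
                      weights: WeightVector | pd.Series | np.ndarray | None,
                      frame: FrameDefinition | str,
                      weighted: bool = True) -> float:
    """Non-covered share f = N_nc / N (weighted by default)."""
    df = _as_frame(sample)
    if len(df) == 0:
        raise EstimationError("empty sample")
    m = _frame_of(frame).mask(df)
    if weighted and weights is not None:
        w = np.asarray(weights.values if isinstance(weights, WeightVector)
                       else weights, dtype=float)
        return float(w[~m].sum() / w.sum())
    return float((~m).mean())


def _common_scale(p_c: float, p_nc: float, p_overall: float,
                  scale: str) -> None:
    if scale not in _SCALES:
        raise ValueError(f"scale must be one of {_SCALES}")
    vals = (p_c, p_nc, p_overall)
    if scale == "auto":
        scale = "percent" if any(v > 1.0 for v in vals) else "proportion"
    limit = 100.0 if scale == "percent" else 1.0
    if any(v < 0 or v > limit for v in vals):
        raise ValueError(
            f"prevalences {vals} are not all on the {scale} scale; "
            f"mixed percent/proportion inputs are rejected")


def rcb(f: float, p_c: float, p_nc: float, p_overall: float,
        scale: str = "auto") -> float:
    """RCB = f · (p_c − p_nc) / P, dimensionless.

    ``f`` is the non-covered population share in [0, 1]; the three
    prevalences must share a scale (all percent or all proportions).
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"coverage fraction f={f} outside [0, 1]")
    if p_overall <= 0:
        raise ValueError("overall prevalence P must be positive")
    _common_scale(p_c, p_nc, p_overall, scale)
    return f * (p_c - p_nc) / p_overall


def rcb_from_sample(sample: SurveySample | pd.DataFrame,
                    weights: WeightVector | pd.Series | np.ndarray,
                    frame: FrameDefinition | str,
                    indicator: str,
                    mode: str = "consistent",
                    benchmark: pd.DataFrame | None = None,
                    design_weights: WeightVector | pd.Series | np.ndarray | None = None,
                    psu_col: str = "cluster_id") -> RCBResult:
    """Compute the RCB of ``indicator`` under a hypothetical frame.

    mode="consistent"
        One weight vector (``weights``) is used for f, p_c, p_nc and P;
        the result satisfies rcb == (p_c − P)/P exactly.
    mode="reweighted"
        Mirrors the published workflow: the frame subsample is
        re-calibrated to ``benchmark`` starting from ``design_weights``
        (original relative weights) and that estimate is p_c; f, p_nc
        and P come from the full-sample ``weights``.  Requires
        ``benchmark`` and ``design_weights``.
    """
    if mode not in ("consistent", "reweighted"):
        raise ValueError(f"unknown mode {mode!r}")
    df = _as_frame(sample)
    w = np.asarray(weights.values if isinstance(weights, WeightVector)
                   else weights, dtype=float)
    fd = _frame_of(frame)
    part = build_frame(df, fd)
    m = part.mask

    W = w.sum()
    f = float(w[~m].sum() / W)
    p_overall = _prevalence_point(df, w, indicator, psu_col)
    p_nc = (_prevalence_point(part.not_covered, w[~m], indicator, psu_col)
            if (~m).any() else float("nan"))

    if mode == "consistent":
        p_c = (_prevalence_point(part.covered, w[m], indicator, psu_col)
               if m.any() else float("nan"))
    else:
        if benchmark is None or design_weights is None:
            raise ValueError("mode='reweighted' needs benchmark and "
                             "design_weights")
        dw = np.asarray(design_weights.values
                        if isinstance(design_weights, WeightVector)
                        else design_weights, dtype=float)
        rw = reweight_subsample(part.covered, dw[m], benchmark)
        p_c = _prevalence_point(part.covered, rw.to_numpy(), indicator,
                                psu_col)

    if f == 0.0:
        value = 0.0  # full coverage: no room for coverage bias
    else:
        value = rcb(f, p_c, p_nc, p_overall, scale="percent")
    return RCBResult(frame=fd.name, indicator=indicator, n_total=float(W),
                     n_not_covered=float(w[~m].sum()), f=f, p_c=p_c,
                     p_nc=p_nc, p_overall=p_overall, rcb=value,
                     abs_diff=p_c - p_overall, mode=mode)


def _prevalence_point(df: pd.DataFrame, w: np.ndarray, indicator: str,
                      psu_col: str) -> float:
    """Weighted prevalence point estimate (percent); falls back to the
    pointwise ratio when the subsample has too few PSUs for a CI."""
    try:
        return weighted_prevalence(df, w, indicator, psu_col=psu_col).percent
    except EstimationError:
        y = pd.to_numeric(df[indicator], errors="coerce").to_numpy(float)
        keep = ~np.isnan(y)
        if not keep.any():
            raise
        return 100.0 * float(np.dot(w[keep], y[keep]) / w[keep].sum())


def absolute_difference(frame_estimate_pct: float,
                        overall_estimate_pct: float) -> float:
    """Overall minus frame estimate, percentage points (signed; report
    the magnitude to one decimal)."""
    return overall_estimate_pct - frame_estimate_pct


def summarize_range(values: Iterable[float]) -> tuple[float, float]:
    """(min, max) of per-year statistics, e.g. absolute differences
    across survey years."""
    vals = list(values)
    if not vals:
        raise ValueError("summarize_range needs at least one value")
    return (min(vals), max(vals))
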