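"""Design weights, post-stratification, and frame re-weighting.

Design weights are inverse selection probabilities (cluster ×
household × within-household person stages), normalised to sum to the
respondent count so they are *relative* weights.  Post-stratification
scales weights within each age-group × sex × area cell so the weighted
cell totals equal external population benchmarks; empty sample cells
are handled by collapsing adjacent age bands within sex × area.
Re-weighting a frame subsample applies the same calibration starting
from the original relative design weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AGE_BANDS
from .sampling import SurveySample

logger = logging.getLogger(__name__)

DEFAULT_CELLS = ("age_group", "sex", "area")

_POSTSTRAT_RTOL = 1e-6


class WeightingError(ValueError):
    pass


@dataclass
class WeightVector:
    """Per-respondent positive weights with provenance.

    ``values`` is aligned (positionally) with the sample it was computed
    for; ``stage`` is one of ``design``, ``poststratified``,
    ``reweighted``; ``benchmark_total`` is the population total the
    weights sum to after (re-)calibration, ``None`` for design weights.
    """

    values: pd.Series
    stage: str
    benchmark_total: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.isfinite(v).all() or (v <= 0).any():
            raise WeightingError("weights must be positive and finite")

    def to_numpy(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def _as_frame(sample: SurveySample | pd.DataFrame) -> pd.DataFrame:
    return sample.data if isinstance(sample, SurveySample) else sample


def design_weight(sample: SurveySample | pd.DataFrame,
                  normalize: bool = True) -> WeightVector:
    """Inverse-probability design weights, normalised to sum to n.

    The within-household stage contributes a factor
    ``household_size_eligible`` (inverse of the last-birthday selection
    probability).  When the cluster/household stage probabilities are
    present (``prob_cluster``, ``prob_household``) they are inverted
    too, making the unnormalised (``normalize=False``) weight a
    Horvitz–Thompson weight for population totals.
    """
    df = _as_frame(sample)
    if "household_size_eligible" not in df.columns:
        raise WeightingError("sample lacks household_size_eligible; "
                             "selection metadata is required")
    if df["household_size_eligible"].isna().any():
        bad = df.index[df["household_size_eligible"].isna()][0]
        raise WeightingError(f"respondent {bad} has missing selection metadata")
    w = df["household_size_eligible"].astype(float).to_numpy()
    for col in ("prob_cluster", "prob_household"):
        if col in df.columns:
            p = df[col].to_numpy(dtype=float)
            if (p <= 0).any() or np.isnan(p).any():
                raise WeightingError(f"invalid {col} in sample")
            w = w / p
    if normalize:
        w = w * (len(w) / w.sum())
    return WeightVector(pd.Series(w, index=df.index), stage="design")


def _collapse_groups(bands_present: list, weighted: np.ndarray) -> np.ndarray:
    """Group consecutive age bands so every group has positive sample
    weight.  Returns a group id per band; raises if all are empty."""
    if not (weighted > 0).any():
        raise WeightingError("no sample support in stratum; cannot collapse")
    group = np.zeros(len(bands_present), dtype=int)
    gid = -1
    pending = 0  # leading empty bands attach to the first supported one
    for i, w in enumerate(weighted):
        if w > 0:
            gid += 1
            group[i] = gid
            if pending:
                group[:i] = gid
                pending = 0
        elif gid < 0:
            pending += 1
        else:
            group[i] = gid
    return group


def poststratify(sample: SurveySample | pd.DataFrame,
                 weights: WeightVector | pd.Series | np.ndarray,
                 benchmark: pd.DataFrame,
                 cells: tuple[str, ...] = DEFAULT_CELLS,
                 collapse: bool = True,
                 stage: str = "poststratified") -> WeightVector:
    """Scale weights so weighted cell totals match benchmark counts.

    ``benchmark`` has the cell columns plus ``count``.  Within each
    sex × area stratum, age bands whose weighted sample count is zero
    are collapsed with the nearest populated band (toward younger bands
    first) so every benchmark person is represented; a warning is
    logged.  Output weights sum to the benchmark total to 1e-6
    relative; the result is invariant to the scale of the input weights
    and idempotent.
    """
    df = _as_frame(sample)
    w = np.asarray(weights.values if isinstance(weights, WeightVector)
                   else weights, dtype=float)
    if len(w) != len(df):
        raise WeightingError("weights not aligned with sample")
    if "count" not in benchmark.columns:
        raise WeightingError("benchmark lacks a 'count' column")

    age_col, *strata_cols = cells  # first cell variable is collapsible
    bench = benchmark.copy()
    bench_total = float(bench["count"].sum())

    key_cols = list(cells)
    samp = df[key_cols].copy()
    for c in key_cols:
        samp[c] = samp[c].astype(object)
        bench[c] = bench[c].astype(object)
    samp["_w"] = w
    wsum = (samp.groupby(key_cols, observed=True)["_w"].sum()
            .rename("wsum").reset_index())
    bench = bench.merge(wsum, on=key_cols, how="left").fillna({"wsum": 0.0})

    missing = samp.merge(bench[key_cols].assign(_in=1), on=key_cols,
                         how="left")["_in"].isna()
    if missing.any():
        raise WeightingError(
            f"{int(missing.sum())} sample records fall in cells absent "
            f"from the benchmark")

    band_order = {b: i for i, b in enumerate(AGE_BANDS)}
    factors: dict[tuple, float] = {}
    if strata_cols:
        strata_iter = bench.groupby(strata_cols, observed=True, sort=False)
    else:
        strata_iter = [((), bench)]
    for stratum, part in strata_iter:
        if not isinstance(stratum, tuple):
            stratum = (stratum,)
        part = part.sort_values(age_col,
                                key=lambda s: s.map(lambda b: band_order.get(b, -1)))
        bands = part[age_col].tolist()
        wsums = part["wsum"].to_numpy(dtype=float)
        counts = part["count"].to_numpy(dtype=float)
        if collapse and (wsums == 0).any():
            group = _collapse_groups(bands, wsums)
            logger.warning("post-stratification collapsed %d empty age "
                           "band(s) in stratum %s",
                           int((wsums == 0).sum()), stratum)
        elif (wsums == 0).any():
            raise WeightingError(
                f"empty sample cell with positive benchmark in stratum "
                f"{stratum}; enable collapse")
        else:
            group = np.arange(len(bands))
        for g in np.unique(group):
            m = group == g
            factor = counts[m].sum() / wsums[m].sum()
            for b in np.asarray(bands, dtype=object)[m]:
                factors[(b, *stratum)] = factor

    keys = list(zip(*(samp[c] for c in key_cols)))
    factor_arr = np.asarray([factors[k] for k in keys])
    new_w = w * factor_arr

    total = new_w.sum()
    if abs(total - bench_total) > _POSTSTRAT_RTOL * bench_total:
        raise WeightingError(
            f"post-stratified weights sum to {total}, benchmark total "
            f"is {bench_total}")
    return WeightVector(pd.Series(new_w, index=df.index), stage=stage,
                        benchmark_total=bench_total)


def reweight_subsample(subsample: SurveySample | pd.DataFrame,
                       original_weights: WeightVector | pd.Series | np.ndarray,
                       benchmark: pd.DataFrame,
                       cells: tuple[str, ...] = DEFAULT_CELLS,
                       collapse: bool = True) -> WeightVector:
    """Re-calibrate a frame subsample to the full-population benchmark,
    starting from the original relative design weights of the retained
    respondents.  ``original_weights`` must be aligned with
    ``subsample`` (already restricted)."""
    return poststratify(subsample, original_weights, benchmark, cells=cells,
                        collapse=collapse, stage="reweighted")


def rake(sample: SurveySample | pd.DataFrame,
         weights: WeightVector | pd.Series | np.ndarray,
         margins: dict[str, pd.Series],
         max_iter: int = 100, tol: float = 1e-10) -> WeightVector:
    """Iterative proportional fitting to one-way margins.

    ``margins`` maps a column name to a Series of population counts
    indexed by category.  Offered as an alternative to full-cell
    post-stratification when joint benchmarks are unavailable.
    """
    df = _as_frame(sample)
    w = np.asarray(weights.values if isinstance(weights, WeightVector)
                   else weights, dtype=float).copy()
    totals = {var: float(m.sum()) for var, m in margins.items()}
    ref = next(iter(totals.values()))
    for var, t in totals.items():
        if abs(t - ref) > 1e-6 * ref:
            raise WeightingError("margin totals disagree; cannot rake")
    for _ in range(max_iter):
        max_shift = 0.0
        for var, margin in margins.items():
            cur = pd.Series(w).groupby(df[var].astype(object).values).sum()
            factor = (margin / cur.reindex(margin.index)).to_dict()
            f = np.asarray([factor[v] for v in df[var].astype(object)])
            if not np.isfinite(f).all():
                raise WeightingError(f"empty sample category in margin {var!r}")
            w = w * f
            max_shift = max(max_shift, float(np.abs(f - 1.0).max()))
        if max_shift < tol:
            break
    return WeightVector(pd.Series(w, index=df.index), stage="poststratified",
                        benchmark_total=ref)
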