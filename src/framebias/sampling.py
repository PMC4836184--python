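"""Multistage clustered survey simulation.

Mirrors a face-to-face omnibus design: equal-probability draw of area
clusters, a systematic run of 10 households within each cluster (random
start, fixed skip), last-birthday (uniform) selection of one person
aged 15+ per household, and household-level Bernoulli nonresponse with
no replacement.  Every stage records its selection probability so
design weights are computable afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import SampleDesign

logger = logging.getLogger(__name__)


class DesignError(ValueError):
    """Raised when a design is infeasible for the given population."""


@dataclass
class HouseholdIndex:
    """Precomputed household layout of a population frame.

    Built once; lets replicate surveys be drawn cheaply.  Requires the
    population rows to be ordered so each household is contiguous (as
    :func:`framebias.population.generate_population` produces).
    """

    cluster_ids: np.ndarray          # per household
    first_row: np.ndarray            # first person row of each household
    size: np.ndarray                 # eligible members per household
    cluster_labels: np.ndarray       # unique cluster ids
    cluster_start: np.ndarray        # slice starts into the household arrays

    @classmethod
    def from_population(cls, population: pd.DataFrame) -> "HouseholdIndex":
        hh = population["household_id"].to_numpy()
        is_first = np.ones(len(hh), dtype=bool)
        is_first[1:] = hh[1:] != hh[:-1]
        first_row = np.flatnonzero(is_first)
        size = np.diff(np.append(first_row, len(hh)))
        cluster_ids = population["cluster_id"].to_numpy()[first_row]
        if (np.diff(cluster_ids) < 0).any():
            order = np.argsort(cluster_ids, kind="stable")
            first_row, size = first_row[order], size[order]
            cluster_ids = cluster_ids[order]
        labels, start = np.unique(cluster_ids, return_index=True)
        return cls(cluster_ids, first_row, size, labels, start)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_labels)

    def cluster_slice(self, k: int) -> slice:
        end = (self.cluster_start[k + 1] if k + 1 < self.n_clusters
               else len(self.cluster_ids))
        return slice(int(self.cluster_start[k]), int(end))


@dataclass
class SurveySample:
    """Respondent records with design metadata.

    ``data`` has one row per responding household's selected respondent,
    carrying the population columns plus ``prob_cluster``,
    ``prob_household`` and ``prob_person`` (stage selection
    probabilities).
    """

    data: pd.DataFrame
    design: SampleDesign
    provenance: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)


def draw_clusters(population: pd.DataFrame | HouseholdIndex,
                  design: SampleDesign,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw ``design.n_clusters`` cluster labels equal-probability
    without replacement."""
    index = (population if isinstance(population, HouseholdIndex)
             else HouseholdIndex.from_population(population))
    if design.n_clusters > index.n_clusters:
        raise DesignError(
            f"design asks for {design.n_clusters} clusters but the "
            f"population has only {index.n_clusters}")
    chosen = rng.choice(index.n_clusters, size=design.n_clusters,
                        replace=False)
    return index.cluster_labels[np.sort(chosen)]

def systematic_indices(n_households: int, take: int,
                       start: int) -> np.ndarray:
    """Systematic run: ``take`` households from ``start`` with fixed skip
    ``max(1, n // take)``, wrapping around; all of them if ``n <= take``.

    With skip ``floor(n/take)`` the selected indices are always
    distinct, and every household has inclusion probability
    ``take / n`` under a uniform random start.
    """
    if n_households <= take:
        return np.arange(n_households)
    skip = max(1, n_households // take)
    return (start + skip * np.arange(take)) % n_households


def sample_households(cluster_households: np.ndarray, design: SampleDesign,
                      rng: np.random.Generator) -> np.ndarray:
    """Systematic sample of ``min(households_per_cluster, available)``
    households (given as an array of household positions/ids) from one
    cluster: random start, fixed skip."""
    n = len(cluster_households)
    if n == 0:
        raise DesignError("cluster has no households")
    idx = systematic_indices(n, design.households_per_cluster,
                             int(rng.integers(n)))
    return np.asarray(cluster_households)[idx]


def select_respondent(household: pd.DataFrame,
                      rng: np.random.Generator) -> pd.Series:
    """Uniform (last-birthday) draw of one eligible member; the selection
    probability ``1/household_size_eligible`` is attached as
    ``prob_person``."""
    n = len(household)
    if n == 0:
        raise DesignError("household has no eligible member")
    row = household.iloc[int(rng.integers(n))].copy()
    row["prob_person"] = 1.0 / n
    return row


def _nonresponse_probability(data: pd.DataFrame,
                             design: SampleDesign) -> np.ndarray:
    eta = np.full(len(data), logit(design.response_rate))
    for var, table in design.nonresponse_offsets.items():
        eta += np.asarray([float(table.get(v, 0.0)) for v in data[var]])
    return expit(eta)


def apply_nonresponse(sample: SurveySample,
                      rng: np.random.Generator) -> SurveySample:
    """Household-level Bernoulli response; non-respondents are dropped
    and not replaced.  With ``response_rate == 1`` and no offsets the
    sample is returned unchanged."""
    design = sample.design
    if design.response_rate >= 1.0 and not design.nonresponse_offsets:
        return sample
    p = _nonresponse_probability(sample.data, design)
    keep = rng.random(len(sample.data)) < p
    data = sample.data.loc[keep].reset_index(drop=True)
    prov = dict(sample.provenance,
                n_issued=len(sample.data), n_responded=int(keep.sum()))
    return SurveySample(data=data, design=design, provenance=prov)


def draw_survey(population: pd.DataFrame, design: SampleDesign,
                rng: np.random.Generator | int | None = None,
                index: HouseholdIndex | None = None,
                nonresponse: bool = True) -> SurveySample:
    """Run the full multistage draw and return a :class:`SurveySample`.

    Stage probabilities stored per respondent: ``prob_cluster`` =
    n_clusters drawn / clusters available, ``prob_household`` =
    households taken / households in the cluster, ``prob_person`` =
    1 / eligible household members.
    """
    design.validate()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(design.seed if rng is None else rng)
    if index is None:
        index = HouseholdIndex.from_population(population)

    if design.n_clusters > index.n_clusters:
        raise DesignError(
            f"design asks for {design.n_clusters} clusters but the "
            f"population has only {index.n_clusters}")
    chosen = np.sort(rng.choice(index.n_clusters, size=design.n_clusters,
                                replace=False))
    prob_cluster = design.n_clusters / index.n_clusters

    hh_rows, hh_sizes, hh_prob = [], [], []
    for k in chosen:
        sl = index.cluster_slice(int(k))
        n_hh = sl.stop - sl.start
        local = systematic_indices(n_hh, design.households_per_cluster,
                                   int(rng.integers(n_hh)))
        take = len(local)
        hh_rows.append(index.first_row[sl][local])
        hh_sizes.append(index.size[sl][local])
        hh_prob.append(np.full(take, take / n_hh))
    first = np.concatenate(hh_rows)
    sizes = np.concatenate(hh_sizes)
    prob_hh = np.concatenate(hh_prob)

    # last-birthday selection: uniform member within each household
    member = (rng.random(len(first)) * sizes).astype(int)
    rows = first + member

    data = population.iloc[rows].reset_index(drop=True)
    data["prob_cluster"] = prob_cluster
    data["prob_household"] = prob_hh
    data["prob_person"] = 1.0 / sizes
    sample = SurveySample(data=data, design=design,
                          provenance={"n_population_clusters": index.n_clusters,
                                      "n_issued": len(data)})
    if nonresponse:
        sample = apply_nonresponse(sample, rng)
    if len(sample.data) == 0:
        logger.warning("survey draw produced zero respondents")
    return sample
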