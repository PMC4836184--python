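"""Synthetic finite populations with household telephone structure.

Persons aged 15+ are generated in households; telephone status (one of
mobile-only, landline-only, both, neither) is a *household* attribute
drawn from a multinomial-logit model whose baseline is the configured
status mixture and whose mobile-only utility is shifted by demographic
log-odds gradients of the household's reference person.  Directory
listing of landlines/mobiles is Bernoulli per household.  Binary health
indicators are person-level logistic draws that may depend on telephone
status and demographics — the mechanism behind frame coverage bias.
"""

from __future__ import annotations

from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import (AGE_BANDS, AREAS, SEXES, TELEPHONE_STATUSES,
                     ScenarioConfig)

#: Health indicators carried by every generated person (0/1 columns).
DEFAULT_INDICATORS = ("diabetes", "current_asthma", "arthritis",
                      "mental_health", "current_smoker", "obese")

_DEMOGRAPHIC_COLS = ("age_group", "sex", "area")

_HOUSEHOLDS_PER_CLUSTER = 60  # default area-cluster granularity


def _categorical_draw(rng: np.random.Generator, dist: Mapping[Any, float],
                      size: int) -> np.ndarray:
    cats = np.asarray(list(dist.keys()), dtype=object)
    probs = np.asarray(list(dist.values()), dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(cats), size=size, p=probs)
    return cats[idx]


def _offset_lookup(spec: Mapping[str, Mapping[Any, float]], var: str,
                   values: np.ndarray) -> np.ndarray:
    table = spec.get(var)
    if not table:
        return np.zeros(len(values))
    return np.asarray([float(table.get(v, 0.0)) for v in values])


def generate_population(config: ScenarioConfig) -> pd.DataFrame:
    """Generate a person-level population frame.

    Returns a DataFrame with one row per person aged 15+, columns
    ``person_id, household_id, cluster_id, age_group, sex, area,
    household_size_eligible, telephone_status, listed_landline,
    listed_mobile`` plus one 0/1 column per configured health indicator
    (all of :data:`DEFAULT_INDICATORS` are always present).  Rows are
    ordered by household; all members of a household share telephone
    status, listing flags and area.  Fully reproducible given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_target = config.population_size

    # -- households -------------------------------------------------------
    size_dist = config.demographic_spec["household_size"]
    mean_size = float(sum(int(k) * v for k, v in size_dist.items()))
    n_guess = int(np.ceil(n_target / mean_size * 1.15)) + 8
    sizes = _categorical_draw(rng, size_dist, n_guess).astype(int)
    cum = np.cumsum(sizes)
    n_hh = int(np.searchsorted(cum, n_target) + 1)
    sizes = sizes[:n_hh]
    # trim the final household so the person count is exact
    sizes[-1] -= int(cum[n_hh - 1] - n_target)
    if sizes[-1] == 0:
        sizes = sizes[:-1]
        n_hh -= 1
    assert sizes.sum() == n_target and (sizes >= 1).all()

    n_clusters = config.n_clusters or max(1, round(n_hh / _HOUSEHOLDS_PER_CLUSTER))
    n_clusters = min(n_clusters, n_hh)
    # contiguous blocks of households form area clusters
    hh_cluster = np.floor(np.arange(n_hh) * n_clusters / n_hh).astype(int)
    cluster_area = _categorical_draw(rng, config.demographic_spec["area"],
                                     n_clusters)
    hh_area = cluster_area[hh_cluster]

    # -- person demographics ---------------------------------------------
    age = _categorical_draw(rng, config.demographic_spec["age_group"], n_target)
    sex = _categorical_draw(rng, config.demographic_spec["sex"], n_target)
    hh_of_person = np.repeat(np.arange(n_hh), sizes)
    first_member = np.concatenate(([0], np.cumsum(sizes)[:-1]))

    extra_cols: dict[str, np.ndarray] = {}
    for var, dist in config.demographic_spec.items():
        if var in ("age_group", "sex", "area", "household_size"):
            continue
        # optional covariates are household-level grouping labels
        extra_cols[var] = _categorical_draw(rng, dist, n_hh)[hh_of_person]

    # -- telephone status: multinomial logit on the reference person ------
    utilities = np.full((n_hh, len(TELEPHONE_STATUSES)), -np.inf)
    for j, status in enumerate(TELEPHONE_STATUSES):
        p = float(config.telephone_mixture.get(status, 0.0))
        if p > 0:
            utilities[:, j] = np.log(p)
    mo = TELEPHONE_STATUSES.index("mobile_only")
    if np.isfinite(utilities[:, mo]).any():
        offset = (_offset_lookup(config.gradient_spec, "age_group", age[first_member])
                  + _offset_lookup(config.gradient_spec, "sex", sex[first_member])
                  + _offset_lookup(config.gradient_spec, "area", hh_area))
        for var, values in extra_cols.items():
            offset += _offset_lookup(config.gradient_spec, var,
                                     values[first_member])
        utilities[:, mo] += offset
    utilities -= utilities.max(axis=1, keepdims=True)
    probs = np.exp(utilities)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n_hh)
    hh_status_idx = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1)
    hh_status = np.asarray(TELEPHONE_STATUSES, dtype=object)[hh_status_idx]

    # -- directory listing (household-level) ------------------------------
    has_landline = np.isin(hh_status, ("landline_only", "both"))
    has_mobile = np.isin(hh_status, ("mobile_only", "both"))
    listed_landline = has_landline & (
        rng.random(n_hh) < config.listing_rates["landline"])
    listed_mobile = has_mobile & (
        rng.random(n_hh) < config.listing_rates["mobile"])

    data: dict[str, Any] = {
        "person_id": np.arange(n_target),
        "household_id": hh_of_person,
        "cluster_id": hh_cluster[hh_of_person],
        "age_group": pd.Categorical(age, categories=list(AGE_BANDS)),
        "sex": pd.Categorical(sex, categories=list(SEXES)),
        "area": pd.Categorical(hh_area[hh_of_person], categories=list(AREAS)),
        "household_size_eligible": sizes[hh_of_person],
        "telephone_status": pd.Categorical(hh_status[hh_of_person],
                                           categories=list(TELEPHONE_STATUSES)),
        "listed_landline": listed_landline[hh_of_person],
        "listed_mobile": listed_mobile[hh_of_person],
    }
    for var, values in extra_cols.items():
        data[var] = values

    # -- health indicators (person-level logistic) ------------------------
    person_status = hh_status[hh_of_person]
    for name in DEFAULT_INDICATORS:
        spec = config.health_spec.get(name, {"baseline": 0.0})
        base = float(spec.get("baseline", 0.0))
        if base <= 0.0:
            data[name] = np.zeros(n_target, dtype=np.int8)
            continue
        if base >= 1.0:
            data[name] = np.ones(n_target, dtype=np.int8)
            continue
        eta = np.full(n_target, logit(base))
        status_off = spec.get("status_offsets", {})
        if status_off:
            eta += np.asarray([float(status_off.get(s, 0.0))
                               for s in person_status])
        for var, table in spec.get("offsets", {}).items():
            eta += _offset_lookup({var: table}, var, data[var])
        data[name] = (rng.random(n_target) < expit(eta)).astype(np.int8)

    return pd.DataFrame(data)


def benchmark_from_population(population: pd.DataFrame,
                              cells: tuple[str, ...] = _DEMOGRAPHIC_COLS
                              ) -> pd.DataFrame:
    """Population counts per (age_group, sex, area) cell.

    Empty cells are never emitted; the counts sum to the population
    size.  This table is the post-stratification benchmark.
    """
    if len(population) == 0:
        raise ValueError("population is empty")
    counts = (population.groupby(list(cells), observed=True)
              .size().rename("count").reset_index())
    for col in cells:
        if isinstance(counts[col].dtype, pd.CategoricalDtype):
            counts[col] = counts[col].astype(object)
    return counts


# ---------------------------------------------------------------------------
# Calibrated per-year scenarios
# ---------------------------------------------------------------------------

# Household telephone-status mixtures by survey year, derived from the
# published ownership series: mobile-only overall shares, total mobile
# ownership rising 89.7 % (2006) to 96.3 % (2013), landline ownership
# 94.4 % -> 71.7 %, telephone coverage ~97-99 %.
YEAR_MIXTURES: dict[int, dict[str, float]] = {
    2006: {"mobile_only": 0.052, "landline_only": 0.099, "both": 0.845,
           "neither": 0.004},
    2010: {"mobile_only": 0.171, "landline_only": 0.060, "both": 0.764,
           "neither": 0.005},
    2011: {"mobile_only": 0.217, "landline_only": 0.051, "both": 0.727,
           "neither": 0.005},
    2012: {"mobile_only": 0.239, "landline_only": 0.041, "both": 0.715,
           "neither": 0.005},
    2013: {"mobile_only": 0.276, "landline_only": 0.030, "both": 0.687,
           "neither": 0.007},
}

# Probability a landline is directory-listed, by year (mobiles ~4.6 %
# throughout); chosen so the simulated directory-listed population share
# tracks the published 73.8 % (2006) -> 60.4 % (2010) -> 49.6 % (2013)
# decline given each year's status mixture.
YEAR_LANDLINE_LISTING: dict[int, float] = {
    2006: 0.770, 2010: 0.710, 2011: 0.680, 2012: 0.655, 2013: 0.627,
}
MOBILE_LISTING_RATE = 0.046


def default_gradients() -> dict[str, dict[Any, float]]:
    """Mobile-only log-odds gradients echoing the observed demographic
    profile: young adults and renters-alike strongly mobile-only, the
    elderly rarely; small sex and area effects.  Offsets are roughly
    centred so the marginal mixture stays close to the configured one."""
    age = {"15-19": 0.45, "20-24": 0.45, "25-29": 1.20, "30-34": 1.20,
           "35-39": 0.35, "40-44": 0.35, "45-49": -0.30, "50-54": -0.30,
           "55-59": -0.85, "60-64": -0.85, "65-69": -1.55, "70-74": -1.55,
           "75+": -2.20}
    return {
        "age_group": age,
        "sex": {"male": 0.06, "female": -0.06},
        "area": {"metro": -0.10, "regional": 0.27},
    }


def default_health_spec() -> dict[str, dict[str, Any]]:
    """Indicator models with baselines near the published all-household
    prevalences and a smoking (and mental-health) excess in mobile-only
    households — the structure that produces negative coverage bias."""
    return {
        "diabetes": {"baseline": 0.082,
                     "status_offsets": {"mobile_only": -0.15}},
        "current_asthma": {"baseline": 0.13,
                           "status_offsets": {"mobile_only": 0.10}},
        "arthritis": {"baseline": 0.22,
                      "status_offsets": {"mobile_only": -0.10}},
        "mental_health": {"baseline": 0.105,
                          "status_offsets": {"mobile_only": 0.45}},
        "current_smoker": {"baseline": 0.160,
                           "status_offsets": {"mobile_only": 0.65,
                                              "landline_only": 0.10}},
        "obese": {"baseline": 0.228,
                  "status_offsets": {"mobile_only": 0.05}},
    }


def scenario_for_year(year: int, population_size: int = 50_000,
                      seed: int | None = None,
                      with_gradients: bool = True) -> ScenarioConfig:
    """A calibrated :class:`ScenarioConfig` for one of the survey years
    2006/2010–2013."""
    if year not in YEAR_MIXTURES:
        raise KeyError(f"no calibrated scenario for year {year}; "
                       f"available: {sorted(YEAR_MIXTURES)}")
    return ScenarioConfig(
        year=year,
        population_size=population_size,
        telephone_mixture=dict(YEAR_MIXTURES[year]),
        listing_rates={"landline": YEAR_LANDLINE_LISTING[year],
                       "mobile": MOBILE_LISTING_RATE},
        gradient_spec=default_gradients() if with_gradients else {},
        health_spec=default_health_spec(),
        seed=seed,
    ).validate()
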