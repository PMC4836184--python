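"""Scenario and design configuration objects.

A :class:`ScenarioConfig` describes one synthetic population: the
household telephone-status mixture for a given survey year, directory
listing rates, demographic category distributions, log-odds gradients
for mobile-only status, and the health-indicator model.  A
:class:`SampleDesign` describes one multistage clustered survey drawn
from such a population.  Both round-trip through YAML/JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

TELEPHONE_STATUSES = ("mobile_only", "landline_only", "both", "neither")

#: 5-year age bands for persons aged 15 and over.
AGE_BANDS = (
    "15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49",
    "50-54", "55-59", "60-64", "65-69", "70-74", "75+",
)

SEXES = ("male", "female")
AREAS = ("metro", "regional")

SIMPLEX_TOL = 1e-12


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


def _check_probability(name: str, value: float) -> None:
    if not (0.0 <= float(value) <= 1.0):
        raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")


def _check_simplex(name: str, probs: Mapping[str, float], keys=None) -> None:
    if keys is not None:
        extra = set(probs) - set(keys)
        if extra:
            raise ConfigError(f"{name} has unknown categories {sorted(extra)}")
    for k, v in probs.items():
        _check_probability(f"{name}[{k}]", v)
    total = float(sum(probs.values()))
    if abs(total - 1.0) > SIMPLEX_TOL:
        raise ConfigError(f"{name} must sum to 1 (got {total!r})")


def _default_age_distribution() -> dict[str, float]:
    # Approximate 15+ age structure of an Australian state population.
    weights = (0.075, 0.080, 0.085, 0.085, 0.080, 0.085, 0.085,
               0.090, 0.080, 0.075, 0.060, 0.050, 0.070)
    return dict(zip(AGE_BANDS, weights))


def default_demographic_spec() -> dict[str, dict[Any, float]]:
    return {
        "age_group": _default_age_distribution(),
        "sex": {"male": 0.49, "female": 0.51},
        "area": {"metro": 0.73, "regional": 0.27},
        # Eligible (15+) persons per household; "4" means four or more.
        "household_size": {1: 0.27, 2: 0.40, 3: 0.17, 4: 0.16},
    }


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic survey-year population.

    Parameters
    ----------
    year
        Calendar-year label (metadata only).
    population_size
        Number of persons aged 15+ to generate.
    telephone_mixture
        Baseline household probabilities over
        ``{mobile_only, landline_only, both, neither}``; must sum to 1.
    listing_rates
        ``{"landline": p, "mobile": p}`` — probability that a household
        with a landline (mobile) has it listed in the public directory.
    demographic_spec
        Category distributions for ``age_group`` (5-year bands), ``sex``,
        ``area`` and ``household_size``; optional extra categorical
        covariates (e.g. ``seifa_quintile``) may be added.
    gradient_spec
        Per-variable, per-category additive log-odds offsets applied to
        the *mobile_only* utility of the household's reference person in
        a multinomial-logit telephone-status model.
    health_spec
        Per-indicator ``{"baseline": p, "status_offsets": {...},
        "offsets": {var: {cat: log-odds}}}`` logistic model.
    n_clusters
        Number of area clusters the population is partitioned into;
        ``None`` → one cluster per ~60 households.
    seed
        RNG seed for full reproducibility.
    """

    year: int = 2013
    population_size: int = 10_000
    telephone_mixture: dict[str, float] = field(
        default_factory=lambda: {"mobile_only": 0.276, "landline_only": 0.030,
                                 "both": 0.687, "neither": 0.007})
    listing_rates: dict[str, float] = field(
        default_factory=lambda: {"landline": 0.627, "mobile": 0.046})
    demographic_spec: dict[str, dict[Any, float]] = field(
        default_factory=default_demographic_spec)
    gradient_spec: dict[str, dict[Any, float]] = field(default_factory=dict)
    health_spec: dict[str, dict[str, Any]] = field(default_factory=dict)
    n_clusters: int | None = None
    seed: int | None = None

    def validate(self) -> "ScenarioConfig":
        if self.population_size < 1:
            raise ConfigError("population_size must be >= 1")
        _check_simplex("telephone_mixture", self.telephone_mixture,
                       keys=TELEPHONE_STATUSES)
        for key in ("landline", "mobile"):
            if key not in self.listing_rates:
                raise ConfigError(f"listing_rates missing {key!r}")
            _check_probability(f"listing_rates[{key}]",
                               self.listing_rates[key])
        for var in ("age_group", "sex", "area", "household_size"):
            if var not in self.demographic_spec:
                raise ConfigError(f"demographic_spec missing {var!r}")
        for var, dist in self.demographic_spec.items():
            _check_simplex(f"demographic_spec[{var}]", dist)
        for var, offsets in self.gradient_spec.items():
            if var not in self.demographic_spec:
                raise ConfigError(
                    f"gradient_spec refers to unknown variable {var!r}")
            for cat in offsets:
                if cat not in self.demographic_spec[var]:
                    raise ConfigError(
                        f"gradient_spec[{var}] has unknown category {cat!r}")
        for name, spec in self.health_spec.items():
            if "baseline" not in spec:
                raise ConfigError(f"health_spec[{name}] missing baseline")
            _check_probability(f"health_spec[{name}].baseline",
                               spec["baseline"])
            for status in spec.get("status_offsets", {}):
                if status not in TELEPHONE_STATUSES:
                    raise ConfigError(
                        f"health_spec[{name}].status_offsets has unknown "
                        f"telephone status {status!r}")
        if self.n_clusters is not None and self.n_clusters < 1:
            raise ConfigError("n_clusters must be >= 1 when given")
        return self

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown ScenarioConfig fields {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(_load_mapping(path))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class SampleDesign:
    """Multistage clustered survey design.

    ``n_clusters`` first-stage areas drawn equal-probability without
    replacement; within each, a systematic run of
    ``households_per_cluster`` households (random start, fixed skip);
    one respondent per household by last-birthday (uniform) selection;
    household-level Bernoulli nonresponse at ``response_rate``,
    optionally skewed by per-category log-odds ``nonresponse_offsets``.
    """

    n_clusters: int = 300
    households_per_cluster: int = 10
    response_rate: float = 0.593
    nonresponse_offsets: dict[str, dict[Any, float]] = field(
        default_factory=dict)
    seed: int | None = None

    def validate(self) -> "SampleDesign":
        if self.n_clusters < 1:
            raise ConfigError("n_clusters must be >= 1")
        if self.households_per_cluster < 1:
            raise ConfigError("households_per_cluster must be >= 1")
        if not (0.0 < self.response_rate <= 1.0):
            raise ConfigError("response_rate must lie in (0, 1]")
        return self

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SampleDesign":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SampleDesign fields {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "SampleDesign":
        return cls.from_dict(_load_mapping(path))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_mapping(path: str | Path) -> dict[str, Any]:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    return data
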