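"""Scenario orchestration: simulate → sample → weight → estimate → bias.

A :class:`ScenarioSuite` is an ordered set of survey years, each with a
population scenario and a sample design.  :func:`run_scenario` executes
every stage for every year and writes CSV report tables —
telephone-status mixture over time, mobile-only prevalence by
demographics, and prevalence + RCB by frame — plus a trend summary and
a JSON manifest with config hashes and per-stage seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimation, frames
from .config import TELEPHONE_STATUSES, SampleDesign, ScenarioConfig
from .population import (DEFAULT_INDICATORS, benchmark_from_population,
                         generate_population, scenario_for_year)
from .sampling import SurveySample, draw_survey
from .weighting import design_weight, poststratify

logger = logging.getLogger(__name__)


@dataclass
class ScenarioSuite:
    """Ordered (year, population scenario, sample design) runs."""

    scenarios: list[tuple[int, ScenarioConfig, SampleDesign]]
    seed: int = 0
    indicators: tuple[str, ...] = DEFAULT_INDICATORS
    frames_enabled: bool = True
    demographics: tuple[str, ...] = ("sex", "age_group", "area")

    def __post_init__(self) -> None:
        years = [y for y, _, _ in self.scenarios]
        if len(set(years)) != len(years):
            raise ValueError("suite years must be unique")


def default_suite(years=(2006, 2010, 2011, 2012, 2013),
                  population_size: int = 40_000,
                  n_clusters: int = 120,
                  seed: int = 0) -> ScenarioSuite:
    """A scaled-down annual series spanning the telephone transition."""
    scen = [(y, scenario_for_year(y, population_size=population_size),
             SampleDesign(n_clusters=n_clusters))
            for y in years]
    return ScenarioSuite(scenarios=scen, seed=seed)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def run_year(year: int, config: ScenarioConfig, design: SampleDesign,
             seed: int, indicators, frames_enabled: bool,
             demographics) -> dict[str, object]:
    """Run one survey year end-to-end; returns in-memory tables."""
    pop_seed, sample_seed = _spawn_seeds(seed, 2)
    config = dataclasses.replace(config, seed=pop_seed)
    population = generate_population(config)
    benchmark = benchmark_from_population(population)
    sample = draw_survey(population, design,
                         rng=np.random.default_rng(sample_seed))
    dw = design_weight(sample)
    pw = poststratify(sample, dw, benchmark)

    mixture_rows = []
    kept, _ = estimation.exclude_no_telephone(sample.data)
    for status in TELEPHONE_STATUSES:
        flag = (sample.data["telephone_status"].astype(object) == status
                ).astype(int).rename(status)
        est = estimation.weighted_prevalence(
            sample.data.assign(**{status: flag}), pw, status)
        mixture_rows.append({"year": year, "status": status,
                             "percent": round(est.percent, 1),
                             "ci_low": round(est.ci_low, 1),
                             "ci_high": round(est.ci_high, 1),
                             "n": est.n_unweighted})

    demo_rows = []
    mo = (sample.data["telephone_status"].astype(object) == "mobile_only"
          ).astype(int)
    tab_sample = sample.data.assign(mobile_only=mo)
    for var in demographics:
        ests = estimation.crosstab_proportions(tab_sample, pw, var,
                                               "mobile_only")
        chi = estimation.rao_scott_chi2(tab_sample, pw, var, "mobile_only")
        for cat, est in ests.items():
            demo_rows.append({"year": year, "variable": var,
                              "category": cat, "n": est.n_unweighted,
                              "percent": round(est.percent, 1),
                              "ci_low": round(est.ci_low, 1),
                              "ci_high": round(est.ci_high, 1),
                              "p_value": round(chi.p_value, 4)})

    bias_rows = []
    if frames_enabled:
        for ind in indicators:
            overall = estimation.weighted_prevalence(sample.data, pw, ind)
            for fname in frames.FRAMES:
                res = frames.rcb_from_sample(
                    sample.data, pw, fname, ind, mode="reweighted",
                    benchmark=benchmark, design_weights=dw)
                cons = frames.rcb_from_sample(sample.data, pw, fname, ind,
                                              mode="consistent")
                bias_rows.append({
                    "year": year, "indicator": ind, "frame": fname,
                    "all_households_pct": round(overall.percent, 1),
                    "frame_pct": round(res.p_c, 1),
                    "abs_diff": round(
                        frames.absolute_difference(res.p_c, overall.percent), 1),
                    "rcb_reweighted": res.rounded(),
                    "rcb_consistent": cons.rounded(),
                    "f_not_covered": round(res.f, 3),
                })

    return {"population_hash": config.config_hash(),
            "seeds": {"population": pop_seed, "sample": sample_seed},
            "n_respondents": len(sample.data),
            "mixture": mixture_rows, "demographics": demo_rows,
            "bias": bias_rows}


def run_scenario(suite: ScenarioSuite, out_dir: str | Path) -> dict[str, object]:
    """Execute the whole suite and write report CSVs + manifest.

    Files written: ``telephone_status.csv``, ``mobile_only_by_demographics
    .csv``, ``prevalence_rcb.csv`` (when frames are enabled),
    ``trend_summary.csv``, ``manifest.json``.  Deterministic for a
    fixed suite seed.  Any stage failure aborts with the year and
    stage named.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(suite.seed, len(suite.scenarios))

    mixture, demo, bias, manifest_years = [], [], [], {}
    for (year, config, design), seed in zip(suite.scenarios, seeds):
        try:
            res = run_year(year, config, design, seed, suite.indicators,
                           suite.frames_enabled, suite.demographics)
        except Exception as err:
            raise RuntimeError(f"scenario year {year} failed: {err}") from err
        mixture.extend(res["mixture"])
        demo.extend(res["demographics"])
        bias.extend(res["bias"])
        manifest_years[str(year)] = {
            "config_hash": res["population_hash"],
            "design_hash": design.config_hash(),
            "seeds": res["seeds"],
            "n_respondents": res["n_respondents"],
        }

    mixture_df = pd.DataFrame(mixture)
    mixture_df.to_csv(out / "telephone_status.csv", index=False)
    pd.DataFrame(demo).to_csv(out / "mobile_only_by_demographics.csv",
                              index=False)
    if bias:
        pd.DataFrame(bias).to_csv(out / "prevalence_rcb.csv", index=False)

    trend_rows = []
    years_sorted = sorted({r["year"] for r in mixture})
    if len(years_sorted) >= 2:
        first, last = years_sorted[0], years_sorted[-1]
        by = mixture_df.set_index(["year", "status"])["percent"]
        for status in TELEPHONE_STATUSES:
            old, new = float(by[first, status]), float(by[last, status])
            if old > 0:
                trend_rows.append({
                    "status": status, "year_from": first, "year_to": last,
                    "pct_from": old, "pct_to": new,
                    "relative_change_pct":
                        estimation.report_relative_change(old, new)})
    pd.DataFrame(trend_rows).to_csv(out / "trend_summary.csv", index=False)

    manifest = {"suite_seed": suite.seed, "years": manifest_years,
                "indicators": list(suite.indicators),
                "frames_enabled": suite.frames_enabled}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    logger.info("scenario suite written to %s", out)
    return manifest


# ---------------------------------------------------------------------------

_FIXTURE_SEED = 20130415


@dataclass
class FixtureBundle:
    population: pd.DataFrame
    benchmark: pd.DataFrame
    sample: SurveySample
    config: ScenarioConfig
    design: SampleDesign


def fixture_bundle() -> FixtureBundle:
    """Deterministic miniature dataset for tests and documentation:
    a 2013-like population of 2000 persons in 30 clusters and a 12-
    cluster survey drawn from it.  Generated on the fly; no files."""
    config = scenario_for_year(2013, population_size=2000,
                               seed=_FIXTURE_SEED)
    config = dataclasses.replace(config, n_clusters=30)
    design = SampleDesign(n_clusters=12, seed=_FIXTURE_SEED + 1)
    population = generate_population(config)
    benchmark = benchmark_from_population(population)
    sample = draw_survey(population, design)
    return FixtureBundle(population=population, benchmark=benchmark,
                         sample=sample, config=config, design=design)
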