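"""Draw a multistage clustered face-to-face survey and weight it.

300 clusters x 10 households, one respondent per household selected by
last birthday, 59.3% household response.  Design weights invert the
selection probabilities; post-stratification forces the weighted
age x sex x area margins onto the population benchmark.
"""

import numpy as np

import framebias as fb

config = fb.scenario_for_year(2013, population_size=120_000, seed=2)
population = fb.generate_population(config)
benchmark = fb.benchmark_from_population(population)

design = fb.SampleDesign(n_clusters=300, households_per_cluster=10,
                         response_rate=0.593)
sample = fb.draw_survey(population, design, rng=np.random.default_rng(3))
print(f"issued {sample.provenance['n_issued']} households, "
      f"{len(sample)} respondents "
      f"(rate {len(sample) / sample.provenance['n_issued']:.3f})")

dw = fb.design_weight(sample)
pw = fb.poststratify(sample, dw, benchmark)
print(f"post-stratified weights sum to {pw.to_numpy().sum():.1f} "
      f"(benchmark total {benchmark['count'].sum()})")

# weighting corrects the demographic tilt of the respondent pool
est_raw = fb.weighted_prevalence(sample, np.ones(len(sample)),
                                 "current_smoker")
est_w = fb.weighted_prevalence(sample, pw, "current_smoker")
truth = 100 * population["current_smoker"].mean()
print(f"\nsmoking: unweighted {est_raw.percent:.1f}%, "
      f"weighted {est_w.percent:.1f}% "
      f"(95% CI {est_w.ci_low:.1f}-{est_w.ci_high:.1f}), "
      f"population truth {truth:.1f}%")
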