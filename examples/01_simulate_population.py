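"""Generate a synthetic 2013-like population and inspect its telephone
structure.

The scenario encodes the end state of the landline-to-mobile
transition: ~27.6% of households are mobile-only, ~62.7% of landlines
but only ~4.6% of mobiles are directory-listed.
"""

import framebias as fb

config = fb.scenario_for_year(2013, population_size=50_000, seed=1,
                              with_gradients=False)
population = fb.generate_population(config)
households = population.drop_duplicates("household_id")

print(f"{len(population)} persons in {len(households)} households, "
      f"{population['cluster_id'].nunique()} area clusters")
print("\nHousehold telephone status (share):")
print(households["telephone_status"].value_counts(normalize=True)
      .round(3).to_string())

landline = households[households["telephone_status"]
                      .isin(["landline_only", "both"])]
mobile = households[households["telephone_status"]
                    .isin(["mobile_only", "both"])]
print(f"\nlandlines directory-listed: {landline['listed_landline'].mean():.3f}"
      f"  (configured {config.listing_rates['landline']})")
print(f"mobiles directory-listed:   {mobile['listed_mobile'].mean():.3f}"
      f"  (configured {config.listing_rates['mobile']})")

# Mobile-only households are where landline frames lose people; they
# smoke more, which is the seed of the coverage bias downstream.
mo = population["telephone_status"] == "mobile_only"
print(f"\nsmoking prevalence: mobile-only {population[mo]['current_smoker'].mean():.3f}"
      f" vs rest {population[~mo]['current_smoker'].mean():.3f}")
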