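"""A small end-to-end synthetic study: mobility- vs residence-based exposure.

Generates a 12 km world with an LST-like (high spatial, low temporal
resolution) and an air-temperature-like (low spatial, high temporal
resolution) indicator plus an 8-participant GPS cohort, runs the full
assessment, and prints the method comparison.  The qualitative signature
to look for: differences in means near zero for both indicators, but a
much larger difference in maximums for the high-spatial-resolution
indicator — the mobility-based method visits hot spots the home location
never sees.
"""

from heatpath import pipeline, synth

cfg = pipeline.StudyConfig(
    world=synth.WorldConfig(
        domain_km=(12.0, 12.0),
        n_days=7,
        seed=42,
        lst=synth.LstLikeConfig(cell_size_m=60.0, corr_length_m=600.0),
        at=synth.AtLikeConfig(cell_size_m=3000.0, corr_length_m=4000.0),
    ),
    cohort=synth.CohortConfig(
        n_participants=8, followup_days=7, mean_daily_km=12.0,
        home_margin_km=4.0, seed=42,
    ),
)

lst, at = synth.simulate_heat_surface(cfg.world)
pings, truths, covariates = synth.simulate_cohort(cfg.cohort, cfg.world)
print(f"simulated {len(pings):,} pings for {cfg.cohort.n_participants} "
      f"participants over {cfg.cohort.followup_days} days")

assessed = pipeline.run_assess(pings, lst, at, cfg)
d = assessed["descriptives"]
print(f"mean daily distance {d.mean_daily_km.mean():.1f} km, "
      f"time at home {d.pct_time_home.mean():.0f}%")

compared = pipeline.run_compare(assessed["exposures"], d, covariates, cfg)
overall = compared["table"].query("stratum_variable == 'overall'")
print("\nindicator  diff_means (C)  diff_maximums (C)  r(means)")
for _, row in overall.iterrows():
    print(f"{row.indicator:<9}  {row.mean_difference_means:+13.3f}  "
          f"{row.mean_difference_maximums:+16.3f}  {row.pearson_r_means:8.4f}")
print("\nmeans agree (both methods share the temporal weighting); the "
      "spatially detailed indicator's maximum is what the home misses")
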