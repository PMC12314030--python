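"""Evidence for correlation drivers: deviance partitioning and sign tests.

Two questions on one synthetic world: (1) how much fungal-richness deviance
does plant richness explain once environmental covariates are controlled
(symbiosis evidence)?  (2) do ecoregions where plants and fungi respond to
temperature in the same direction have positive richness correlations
(environment evidence)?
"""

import divermap as dm

# zones alternate between same-sign and opposite-sign temperature responses,
# with the correlation target wired to match the response agreement
env_effects, rho = {}, {}
for z in range(1, 61):
    agree = z % 2 == 0
    env_effects[z] = {"temperature": (0.8, 0.8 if agree else -0.8)}
    rho[z] = 0.5 if agree else -0.5
cfg = dm.WorldConfig(nrows=120, ncols=120, n_biomes=6, ecoregions_per_biome=10,
                     rho=rho, autocorr_length=1.0, noise_cv=0.1,
                     env_effects=env_effects, seed=5)
world = dm.make_world(cfg)
pair = dm.harmonize_pair(world.studies["plant"], world.studies["AM"],
                         world.uncertainty["plant"], world.uncertainty["AM"],
                         pair="plant-AM", zones=world.zones)
extras = {"plant-AM": {name: world.covariates[name]
                       for name in dm.COVARIATES}}
scan = dm.scan_all_scales({"plant-AM": pair}, world.zones,
                          quotas={"global": 5000, "biome": 2000,
                                  "ecoregion": 240},
                          min_cells=100, seed=0, extras=extras)

gfit = dm.fit_global_driver_model(scan.sample("plant-AM", "global", -1))
print(f"global smooth model: {gfit.deviance_explained_pct:.1f}% deviance explained")
print(f"partial deviance uniquely from plant richness: "
      f"{gfit.partition.partial_pct:.1f}%")
print("   (near zero here by construction: the +0.5 and -0.5 zones cancel")
print("    when cells are pooled globally, so plant richness carries almost")
print("    no global signal about fungal richness)")

pairs_sp, dropped = dm.collect_sign_pairs(scan, "plant-AM", "temperature",
                                          "am_host_pct")
res = dm.sign_concordance_test(pairs_sp, alpha=0.05)
print(f"\nsign concordance (temperature), {res.n_used} usable ecoregions:")
print(f"  [[agree&rho+, agree&rho-], [disagree&rho+, disagree&rho-]] = "
      f"{res.table.tolist()}")
print(f"  chi-squared = {res.chi2:.1f}, p = {res.p:.2e}")
print("\n-> same-direction environmental responses line up with positive")
print("   correlations, exactly as constructed into this world.")
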