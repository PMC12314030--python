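"""Propagate per-cell prediction uncertainty into the global correlation.

Holding the sampled cells fixed, each iteration jitters every study's
richness values by Uniform(-SD, +SD), redoes the log/standardize/consensus
steps and recomputes Spearman's rho.  The spread of the 1000 recomputed
correlations shows how fragile the baseline estimate is; a sign-stable
distribution means prediction error cannot flip the conclusion.
"""

import numpy as np

import divermap as dm
import divermap.montecarlo as mc

world = dm.make_world(dm.WorldConfig(nrows=100, ncols=100, rho=0.8,
                                     autocorr_length=1.0, noise_cv=0.4,
                                     seed=2))
pair = dm.harmonize_pair(world.studies["plant"], world.studies["AM"],
                         world.uncertainty["plant"], world.uncertainty["AM"],
                         pair="plant-AM", zones=world.zones)
samples, _ = dm.sample_cells(pair.plant_consensus, pair.fungal_consensus,
                             pair.mask, world.zones, "global", quota=5000,
                             seed=0)
sample = samples[0]
baseline = dm.spearman_correlation(sample).rho

rows = sample.table["row"].to_numpy()
cols = sample.table["col"].to_numpy()
inputs = {}
for taxon in ("plant", "AM"):
    inputs[taxon] = tuple(
        mc.make_study_input(world.studies[taxon][i],
                            mc.to_sd(world.uncertainty[taxon][i],
                                     world.studies[taxon][i]).sd,
                            rows, cols)
        for i in (0, 1))

dist = dm.perturb_and_correlate(inputs["plant"], inputs["AM"],
                                n_iterations=1000, seed=1)
summary = dm.mc_summary(dist, baseline)
print(f"baseline rho:            {baseline:+.3f}")
print(f"error-adjusted mean rho: {summary.mean:+.3f} "
      f"(95% interval {summary.q025:+.3f} .. {summary.q975:+.3f})")
print(f"sign stable across 1000 iterations: {summary.sign_stable}")
print("\n-> adding error attenuates the correlation but, at this noise")
print("   level, never flips its sign.")
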