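"""Reconstruct founder haplotypes from low-coverage depths.

Allele depths -> genotype likelihoods -> 36-state diplotype HMM ->
8-founder allele probabilities, then crossover locations from the
maximum-marginal path.
"""

import numpy as np

import dohaplo as dh
from dohaplo.impute import sequencing_emissions

panel = dh.simulate_founder_panel(2000, 50_000_000, seed=1)
mosaics = dh.simulate_do_diplotypes(panel, 41, 2, seed=2)
depths = dh.simulate_read_cohort(mosaics, panel, 1.0, seed=3)

gl = dh.genotype_likelihoods(depths, base_error=0.001)
post = dh.diplotype_posteriors(sequencing_emissions(gl, panel),
                               panel.cm, n_gen=41)
probs = dh.genoprob_to_alleleprob(post)

truth = np.stack([m.dose(panel) for m in mosaics])
stats = dh.impute_cohort(gl, panel, 41)
hard = np.argmax(stats.dose_posteriors, axis=-1)
print(f"hard-call genotype concordance with truth: "
      f"{(hard == truth).mean():.3f}")

for i, m in enumerate(mosaics):
    path = dh.maxmarg_path(post[i])
    xo = dh.locate_crossovers(path, panel.positions)
    print(f"sample {i}: {xo.total} crossovers called "
          f"(truth {m.observable_junction_count()}), "
          f"median block {np.median(xo.block_lengths)/1e6:.2f} Mb")
# At 1x the HMM shares information along the chromosome, so nearly all
# genotypes are recovered even though most markers have 0-2 reads.
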