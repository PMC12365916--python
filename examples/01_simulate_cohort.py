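"""Simulate a small DO cohort with known truth.

Builds an 8-founder reference panel, draws diplotype mosaics at
outbreeding generation 41, and samples 1x sequencing depths.
"""

import numpy as np

import dohaplo as dh

panel = dh.simulate_founder_panel(n_markers=1000, chrom_length_bp=50_000_000,
                                  seed=1)
mosaics = dh.simulate_do_diplotypes(panel, n_gen=41, n_samples=4, seed=2)
depths = dh.simulate_read_cohort(mosaics, panel, coverage=1.0, seed=3)

print(f"panel: {panel.n_markers} segregating markers on "
      f"{panel.chrom_length_bp/1e6:.0f} Mb "
      f"({panel.cm[-1]-panel.cm[0]:.1f} cM)")
for sid, m in zip(depths.sample_ids, mosaics):
    print(f"{sid}: {m.observable_junction_count()} observable junctions, "
      f"{sum(len(h) for h in m.homologs)} founder segments")
print(f"mean depth {depths.total.mean():.3f} reads/marker "
      f"(nominal {depths.nominal_coverage}x)")
print(f"expected genome-wide crossovers at generation 41: "
      f"{dh.expected_crossovers(41):.0f}")
# Junction counts here cover one chromosome, i.e. the genome-wide
# expectation scaled by this chromosome's share of the genetic map.
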