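# dohaplo

Simulation-backed benchmarking of founder haplotype reconstruction from
low-coverage whole-genome sequencing (lcWGS) in Diversity Outbred (DO)
mice.

## The problem

The DO population descends from eight inbred founder strains (labelled
A–H: five "classical" laboratory strains A–E and three wild-derived
strains F–H). Quantitative genetics in the DO models the additive
effect of each founder allele at each locus, which requires
reconstructing every sample's mosaic of founder haplotypes. Genotyping
arrays (GigaMUGA-style) have been the standard input, but as crossovers
accumulate over outbreeding generations, fixed marker panels miss
increasingly small haplotype blocks, and array genotyping dominates
study cost. Low-coverage sequencing plus imputation against the founder
reference is the emerging alternative — provided its reconstructions
match the array's and support the same QTL mapping.

`dohaplo` implements the full evaluation loop for that question as a
tested Python library:

- **synthetic cohorts with exact truth** — founder panels with
  engineered identity-by-descent (IBD) blocks, diplotype mosaics whose
  genome-wide crossover count follows the DO's linear accumulation
  model (≈400 at generation 11 plus 23.9 per generation, ≈1117 at
  generation 41), binomial read sampling at 0.001–2×, sparse array
  calls, and negative-binomial expression with planted local-eQTL
  effects;
- **a 36-state founder diplotype HMM** — forward–backward over
  unordered founder pairs with genetic-map-scaled transitions,
  condensation to 8-founder allele probabilities, maximum-marginal
  calls, and crossover/block accounting;
- **imputation machinery** — binomial genotype likelihoods, expected
  dosages, IMPUTE-style INFO scores, binomial depth thinning, and the
  adaptive marker filter (Hardy-Weinberg screen + INFO cutoff relaxed
  in 0.01 steps until enough markers survive);
- **concordance analysis** — per-locus cosine similarity of allele
  probability vectors,

  cos(G,Q) = Σᵢ GᵢQᵢ / (‖G‖‖Q‖),

  flagging of sub-0.87 runs as discordant regions, founder-pair IBD
  segment detection by log₁₀ likelihood-ratio scoring, and
  classification of discordant regions as IBD-explained;
- **eQTL mapping** — rank-Z traits, the haplotype regression
  yᵢ = sᵢβₛ + gᵢβ_g + Σⱼ fᵢⱼβⱼ + λᵢ + εᵢ scanned as
  LOD = (n/2)·log₁₀(RSS₀/RSS₁) with optional LOCO-kinship LMM,
  peak calling (LOD ≥ 8, peak drop 5, 1.5-LOD intervals), the 2 Mb
  local-eQTL rule, 1-to-1 cross-method matching and allele-effect
  cosine comparison.

## Worked example

```python
import numpy as np
import dohaplo as dh
from dohaplo.impute import sequencing_emissions

panel = dh.simulate_founder_panel(2000, 50_000_000, seed=1)
mosaics = dh.simulate_do_diplotypes(panel, n_gen=41, n_samples=2, seed=2)
depths = dh.simulate_read_cohort(mosaics, panel, coverage=1.0, seed=3)

gl = dh.genotype_likelihoods(depths, base_error=0.001)
stats = dh.impute_cohort(gl, panel, n_gen=41)
truth = np.stack([m.dose(panel) for m in mosaics])
hard = np.argmax(stats.dose_posteriors, axis=-1)
print(f"hard-call genotype concordance with truth: {(hard == truth).mean():.3f}")
```

prints

```
hard-call genotype concordance with truth: 0.987
```

i.e. at 1× coverage — where most markers carry 0–2 reads — the
diplotype HMM recovers 98.7% of genotypes by sharing information along
the founder mosaic. The `examples/` directory walks through each
capability: cohort simulation, reconstruction and crossover calling,
the coverage–concordance ladder, IBD-explained discordance, and the
dual-platform eQTL scan; each script prints its numbers with a note on
what they mean.

A thin CLI mirrors the library for shell-driven runs:

```sh
dobench bench --config config.yaml     # full simulate->compare loop
dobench validate RUN_DIR               # invariant checks on outputs
dobench simulate|impute|filter|reconstruct|concord|ibd|eqtl ...
```

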