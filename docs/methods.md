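# Methods

This note documents the models behind `dohaplo`, the defaults and why
they were chosen, what the synthetic data does and does not emulate,
and the numerical choices a maintainer would want written down.

## The diplotype model

At any locus a DO sample carries an unordered pair of founder
haplotypes: 8 homozygous + 28 heterozygous = 36 diplotype states. The
HMM (`dohaplo.hmm`) assumes each homolog switches founder along the
genetic map independently with an exponential-decay kernel: over a gap
of d cM, P(stay with the same founder) = e^(−r) + (1 − e^(−r))/8 and
P(switch to a specific other founder) = (1 − e^(−r))/8, where
r = n_gen · d/100 and `n_gen` is the outbreeding generation. Diplotype
transitions are the symmetrized product of the two homolog processes.
This kernel has the right limits — identity at d = 0, the stationary
diplotype law (1/64 per ordered pair) as d → ∞ — and a single scale
parameter tied to the generation number, which is what the benchmark
needs; it does not reproduce the bespoke transition expressions of
DO-specific reconstruction software, nor crossover interference.

Numerics: forward–backward runs in the *ordered* 8×8 tensor space,
where the kernel's rank-one structure makes each step O(64) instead of
O(36²); posteriors are lumped back to the 36 unordered states (exact,
because the ordered kernel is lumpable and the initial distribution and
emissions are symmetric). The initial distribution is uniform over the
36 unordered states. Scaling is by per-marker normalization; a dense
engine over the unordered states (any founder count) exists for
cross-checking and is tested to agree to 10⁻¹⁰ with both the factored
engine and brute-force path enumeration. The X chromosome is treated
as autosomal.

Emissions: sequencing observations enter as binomial genotype
likelihood triples L(g) = Binom(alt | depth, p_g) with
p_g ∈ {ε, ½, 1−ε} for dose g ∈ {0,1,2} (base-error ε, default 0.001);
array observations as hard calls with symmetric error (correct call
1−e, each wrong dose e/2; missing = uninformative). A state's emission
is the likelihood of its founder-implied dose.

Derived calls: `maxmarg_path` calls the argmax state where the
posterior reaches `minprob` (default 0.95, ties to the lowest state
index); `locate_crossovers` counts, at each adjacent pair of called
states, the founder-multiset difference (one shared founder → 1
crossover, disjoint pairs → 2), bridges uncertain calls by comparing
the nearest called flanks, places boundaries on the flanking
inter-marker interval, and splits block lengths at boundary-interval
midpoints so blocks tile the marker span. Bridging means a short block
whose markers are all uncertain collapses into a single junction — the
same mechanism by which real reconstructions undercount crossovers in
founder-identical regions.

## Synthetic cohorts

The generator (`dohaplo.simulate`) is the package's definition of the
study conditions; all of its choices are the package's own.

**Founder panel.** Marker positions uniform on the chromosome; each
marker's alternate allele assigned to k ∈ [1,7] founders (k from a
uniform allele-frequency range, default 0.125–0.5), so every site
segregates and is homozygous in all founders. Genetic map: uniform
0.5 cM/Mb (the mouse genome-wide average; configurable). Engineered
IBD blocks copy one founder's column onto its partner over a span;
markers made monomorphic by the copy are repaired by flipping a founder
outside every covering block, so block identity is never broken.

**Mosaics.** Per-homolog breakpoints are a Poisson process on the
genetic map. The genome-wide expected crossover count follows the DO's
empirical linear accumulation — count(g) = 400 + 23.9·(g − 11), i.e.
≈1117 at generation 41 — and a simulated chromosome receives its
genetic-length share of that total (genome size 1400 cM by default).
The affine form (rather than intensity strictly proportional to n_gen)
is what matches both anchor points; the slope in n_gen is still the
configured per-generation rate. Founders are uniform with
self-transitions resampled, so every junction is observable and the
simulator's junction count is the truth that crossover calling is
tested against. Not emulated: crossover interference, recombination
hotspots, sex chromosomes, and crossovers between identical-by-state
haplotypes (invisible in real data by definition).

**Reads and arrays.** Read depth per marker is Poisson(coverage) with
alt counts binomial at the dose-implied rate — no alignment artifacts,
mapping bias, or duplicate structure; "array" calls are the true dose
with symmetric miscall probability (default 0.005) on a marker subset.
The array subset uses an evenly spaced grid at a density chosen so
that, relative to the crossover scale, array reconstructions are
near-exact (as GigaMUGA's are in practice): in the benchmark fixtures
one array marker per ~0.1 cM. ddRADseq-style designs are representable
as "fewer markers, higher per-marker depth" but have no
restriction-site model.

**Expression.** Gene counts are negative-binomial (gene dispersion,
default 0.1) around exp(latent) · size-factor, with latent =
Σⱼ fᵢⱼβⱼ + sex and generation covariate effects + N(0,1) noise, scaled
by 0.4 on the log-mean. Planted local eQTL use sum-to-zero ±effect
bipartitions of the founders (default ±1 latent SD, i.e. a 2-SD
contrast between founder groups) at the marker nearest the gene
midpoint. Cohort generations are drawn over a ±2 window around the
mosaic generation, mirroring multi-generation cohorts (and keeping the
generation covariate non-degenerate). Not emulated: trans effects,
batch structure, count-depth heteroskedasticity beyond NB, or real
variance-stabilization (a log2 transform stands in; rank-Z absorbs
monotone differences).

## Filters and scores

INFO is the IMPUTE-style ratio: info = 1 − Σᵢ Var_i(dose) / (2N·θ(1−θ))
with θ the cohort mean dosage/2, clamped to [0,1], and defined as 1 at
θ ∈ {0,1}. The adaptive filter screens sites at HWE p > 0.05
(chi-square on hard calls; an exact test is available) and relaxes the
INFO cutoff from 0.95 in 0.01 steps until strictly more than
`min_snps` sites pass (10,000 at real scale; scaled to the synthetic
chromosome in fixtures), recording the final cutoff. HWE is known to
be misspecified for a population bred from eight inbreds; the filter
uses it pragmatically as an artifact screen, which is the role it plays
in practice.

IBD segments: for each founder pair, per-marker scores are
log₁₀((1−err)/p_match) for matches and log₁₀(err/(1−p_match)) for
mismatches, with p_match = p₀² + p₁² from the 8-founder allele
frequency at the marker and err the tolerated mismatch rate (default
0.002, exposed because tolerance to internal mismatches is a modelling
choice). Maximal positive-scoring runs come from recursive
maximum-subarray decomposition (ties broken toward longer bp span,
then leftmost); the minimum LOD (default 10) is applied as a
post-filter, so lowering it only adds segments.

## Concordance and IBD classification

Reconstructions are compared by per-locus cosine similarity of the
8-founder probability vectors, interpolated linearly in bp onto the
target map with row renormalization (a step interpolation is available
for sensitivity analysis). Runs below 0.87 — the similarity produced
when one platform splits a haplotype's probability between two founders
that the other assigns to one — are flagged with no minimum run length;
region spans use marker positions.

A flagged region is *IBD-explained* when an IBD segment overlapping it
by ≥ 10 kb involves a founder pair that (a) lies within the union of
founders exceeding a probability floor (default 0.05) in either
reconstruction and (b) has at least one member whose region-mean
probability differs between the reconstructions by more than the floor.
Condition (b) covers both ways IBD manifests: one platform seeing a
founder the other doesn't, and both seeing the pair but splitting
probability differently. The sharing category (classical-only,
classical+WSB, PWK–CAST, other) is taken from the highest-LOD
explaining pair.

## eQTL scan

Genes are kept when their total count exceeds 3000 and they show at
least 100 distinct values ("total across samples" is the reading
adopted for the count rule; both thresholds configurable), then
variance-stabilized, rank-Z transformed (Φ⁻¹((rank−½)/n), average
ranks on ties), and scanned against the 8 allele-probability columns
plus intercept, sex, and generation (numeric coding). One founder
column is dropped against the intercept; LOD = (n/2)·log₁₀(RSS₀/RSS₁)
is invariant to which. With kinship, a one-random-effect LMM is fit by
eigen-rotation with the heritability estimated once per trait under
the null and reused across markers (the standard approximation); the
no-kinship mode is the default for synthetic benchmarks, whose cohorts
are unrelated by construction. Peaks merge unless the valley between
two summits drops ≥ 5 LOD below the smaller; support intervals are the
contiguous run within 1.5 LOD of the peak; local eQTL lie within 2 Mb
(inclusive) of the gene midpoint on the same chromosome, one per gene
(nearest). Allele effects are reported under the sum-to-zero contrast,
the unique estimable representation; cross-method agreement is their
cosine similarity.

## Benchmark fixtures and problem sizes

The acceptance-level tests run the full loop at sizes that keep the
suite in minutes on one CPU while staying in the regime the method
operates in (marker spacing well below the haplotype-block scale):

- imputation accuracy: 10 samples, 5,000 markers / 125 Mb, 1×;
- concordance ladder: 5 replicates × 5 samples, 2,500 markers /
  100 Mb, 500 array markers, coverages 1×→0.001×;
- IBD-discordance: 12 samples, 3,000 markers / 100 Mb, three
  engineered classical-pair blocks (15–20 Mb), discordance engineered
  by the probability-preserving founder-pair relabelling
  (`swap_founder_probs`) inside the blocks;
- eQTL: 183 samples, 5,000 markers / 60 Mb, 50 genes (25 planted),
  full coverage vs 0.1×.

Each acceptance property states a cohort-level rate (≥95% hard-call
accuracy at 1×, monotone concordance ladder, ≥90% of block-overlapping
regions IBD-explained, ≥90% planted-eQTL detection with ≥80% of
matched effects at cosine > 0.9); passing them shows the machinery is
self-consistent under the generator's idealizations, not that real
cohorts will hit the same numbers — real data add alignment error,
reference bias, uneven maps and relatedness that the generator
deliberately omits.

## Known limitations

- The transition kernel is an exponential-switch approximation, not
  the DO-specific kernel of dedicated reconstruction software; n_gen
  is a rate scale, not a pedigree model.
- `min_snps`-style defaults are per-chromosome quantities; multi-
  chromosome orchestration treats chromosomes as independent units.
- The LMM reuses null-model variance components across markers and
  fits h² by bounded scalar ML, not full per-marker REML.
- Crossover counting undercounts when entire blocks fall below the
  maxmarg confidence threshold (by design, mirroring the real
  pipeline's behavior in founder-identical regions).
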