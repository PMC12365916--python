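"""Synthetic Diversity Outbred cohorts with known ground truth.

The DO population descends from eight inbred founder strains (labelled
A-H; A-E are "classical" laboratory strains, F-H wild-derived).  Each DO
genome is a mosaic of founder haplotypes accumulated over ~40 outbreeding
generations.  This module generates every input a genotyping benchmark
needs -- a founder reference panel with engineered identity-by-descent
(IBD) blocks, per-sample diplotype mosaics, low-coverage read depths,
sparse array-style genotype calls, and negative-binomial expression
counts with planted local-eQTL effects -- so every downstream stage can
be tested against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FOUNDER_LABELS = ("A", "B", "C", "D", "E", "F", "G", "H")
CLASSICAL = frozenset("ABCDE")
WILD_DERIVED = frozenset("FGH")

#: Default genetic map density (cM per Mb); the mouse genome averages
#: roughly 1400 cM over ~2.5 Gb.
DEFAULT_CM_PER_MB = 0.5

#: Genome-wide genetic length (cM) used to apportion crossovers to a
#: simulated chromosome.
DEFAULT_GENOME_CM = 1400.0

#: Observed-crossover accumulation in the DO: ~400 crossovers per mouse
#: at outbreeding generation 11, increasing by ~23.9 per generation.
XO_RATE_PER_GEN = 23.9
XO_ANCHOR_GEN = 11
XO_ANCHOR_COUNT = 400.0


def expected_crossovers(gen_target, gen_anchor=XO_ANCHOR_GEN,
                        count_anchor=XO_ANCHOR_COUNT,
                        rate_per_gen=XO_RATE_PER_GEN):
    """Expected genome-wide observed crossovers per DO mouse.

    Linear accumulation model: ``count_anchor + rate_per_gen *
    (gen_target - gen_anchor)``.  With the defaults this extrapolates the
    ~400 crossovers seen at generation 11 to ~1117 at generation 41.
    """
    if rate_per_gen < 0:
        raise ValueError("rate_per_gen must be non-negative")
    if gen_target < gen_anchor:
        raise ValueError("gen_target must be >= gen_anchor")
    return count_anchor + rate_per_gen * (gen_target - gen_anchor)


@dataclass
class FounderHaplotypePanel:
    """Biallelic SNP reference for the 8 DO founders on one chromosome.

    ``alleles`` is a (markers x 8) 0/1 matrix (0 = reference allele).
    ``ibd_truth`` records engineered identical-by-descent blocks as
    ``((label_a, label_b), start_bp, end_bp)`` tuples over which the two
    founder columns are byte-identical.
    """

    chrom: str
    positions: np.ndarray
    cm: np.ndarray
    alleles: np.ndarray
    founder_labels: tuple = FOUNDER_LABELS
    ibd_truth: list = field(default_factory=list)
    chrom_length_bp: int = 0

    @property
    def n_markers(self):
        return len(self.positions)

    @property
    def n_founders(self):
        return self.alleles.shape[1]

    def validate(self):
        if self.n_markers < 1:
            raise ValueError("empty panel")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("cM map must be monotone non-decreasing")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be binary")
        row_sums = self.alleles.sum(axis=1)
        if np.any(row_sums == 0) or np.any(row_sums == self.n_founders):
            raise ValueError("every marker must segregate among founders")
        lab = {l: i for i, l in enumerate(self.founder_labels)}
        for (a, b), start, end in self.ibd_truth:
            sel = (self.positions >= start) & (self.positions <= end)
            if not np.array_equal(self.alleles[sel, lab[a]],
                                  self.alleles[sel, lab[b]]):
                raise ValueError(f"IBD block {(a, b)} not identical")
        return self

    def founder_index(self, label):
        return self.founder_labels.index(label)

    def subset(self, idx):
        """Panel restricted to marker indices ``idx`` (order preserved)."""
        idx = np.asarray(idx)
        return FounderHaplotypePanel(
            chrom=self.chrom, positions=self.positions[idx],
            cm=self.cm[idx], alleles=self.alleles[idx],
            founder_labels=self.founder_labels, ibd_truth=list(self.ibd_truth),
            chrom_length_bp=self.chrom_length_bp)


@dataclass
class DiplotypeMosaic:
    """One DO genome on one chromosome: two homologs, each a list of
    ``(start_bp, end_bp, founder_index)`` segments tiling [1, L]."""

    homologs: list
    generation: int
    chrom: str = "1"
    chrom_length_bp: int = 0

    def validate(self):
        for segs in self.homologs:
            if segs[0][0] != 1 or segs[-1][1] != self.chrom_length_bp:
                raise ValueError("segments must tile the chromosome")
            for (s0, e0, f0), (s1, e1, f1) in zip(segs, segs[1:]):
                if s1 != e0 + 1:
                    raise ValueError("segments must be contiguous")
                if f0 == f1:
                    raise ValueError("adjacent segments share a founder")
        return self

    def founders_at(self, positions):
        """(n_positions, 2) founder index per homolog at each bp."""
        positions = np.asarray(positions)
        out = np.empty((len(positions), 2), dtype=np.int64)
        for h, segs in enumerate(self.homologs):
            ends = np.array([e for _, e, _ in segs])
            founders = np.array([f for _, _, f in segs])
            out[:, h] = founders[np.searchsorted(ends, positions)]
        return out

    def dose(self, panel):
        """True alternate-allele dose (0/1/2) at each panel marker."""
        fnd = self.founders_at(panel.positions)
        a = panel.alleles
        m = np.arange(panel.n_markers)
        return a[m, fnd[:, 0]] + a[m, fnd[:, 1]]

    def junctions(self):
        """Breakpoint positions (bp of new segment start) per homolog."""
        return [[s for s, _, _ in segs[1:]] for segs in self.homologs]

    def observable_junction_count(self):
        """Junctions at which the unordered founder pair changes.

        Crossovers between identical-by-state haplotypes would be
        invisible to any reconstruction; with self-transitions forbidden
        in the generator, every junction changes the diplotype unless
        both homologs switch at the same bp (probability zero under a
        continuous breakpoint process).
        """
        events = {}
        for h, segs in enumerate(self.homologs):
            for s, _, f in segs[1:]:
                events.setdefault(s, [0, 0])[h] += 1
        n = 0
        for pos, (a, b) in events.items():
            n += a + b
        return n


@dataclass
class AlleleDepthMatrix:
    """Per sample x marker reference/alternate read counts."""

    ref: np.ndarray
    alt: np.ndarray
    nominal_coverage: float
    sample_ids: list = None
    marker_ids: list = None

    def __post_init__(self):
        if self.sample_ids is None:
            self.sample_ids = [f"S{i:03d}" for i in range(self.ref.shape[0])]
        if self.marker_ids is None:
            self.marker_ids = [f"m{i}" for i in range(self.ref.shape[1])]

    @property
    def total(self):
        return self.ref + self.alt

    def validate(self):
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("negative read counts")
        return self


@dataclass
class ExpressionTruth:
    """Ground truth for one simulated expression trait."""

    gene_id: str
    midpoint_bp: int
    causal: bool
    effects: np.ndarray  # length 8, latent-SD units; zero if not causal
    dispersion: float = 0.1
    base_mean: float = 500.0

    def validate(self):
        if not self.causal and np.any(self.effects != 0):
            raise ValueError("non-causal gene with non-zero effects")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        return self


def simulate_founder_panel(n_markers, chrom_length_bp, ibd_spec=None,
                           maf_range=(0.125, 0.5), seed=0, chrom="1",
                           cm_per_mb=DEFAULT_CM_PER_MB):
    """Simulate a segregating biallelic founder panel.

    ``ibd_spec`` is a list of ``((label_a, label_b), start_bp, end_bp)``;
    over each block founder b's alleles are copied from founder a so the
    pair is byte-identical there (emulating shared ancestry among the
    classical strains).  Markers made monomorphic by the copy are
    repaired by flipping a founder outside every block covering the
    marker, so the IBD identity is never broken.
    """
    if n_markers < 2:
        raise ValueError("n_markers must be >= 2")
    ibd_spec = list(ibd_spec or [])
    by_pair = {}
    for (a, b), start, end in ibd_spec:
        if start < 1 or end > chrom_length_bp or start > end:
            raise ValueError("ibd_spec interval outside chromosome")
        key = tuple(sorted((a, b)))
        for s0, e0 in by_pair.get(key, []):
            if start <= e0 and s0 <= end:
                raise ValueError(f"overlapping ibd_spec intervals for {key}")
        by_pair.setdefault(key, []).append((start, end))

    rng = np.random.default_rng(seed)
    positions = np.unique(rng.integers(1, chrom_length_bp + 1,
                                       size=n_markers))
    while len(positions) < n_markers:  # top up collisions
        extra = rng.integers(1, chrom_length_bp + 1,
                             size=n_markers - len(positions))
        positions = np.unique(np.concatenate((positions, extra)))
    positions = np.sort(positions)
    cm = positions * (cm_per_mb / 1e6)
    lo, hi = maf_range
    freqs = rng.uniform(lo, hi, size=n_markers)
    n_alt = np.clip(np.round(freqs * 8).astype(int), 1, 7)
    alleles = np.zeros((n_markers, 8), dtype=np.uint8)
    for m in range(n_markers):
        carriers = rng.choice(8, size=n_alt[m], replace=False)
        alleles[m, carriers] = 1

    lab = {l: i for i, l in enumerate(FOUNDER_LABELS)}
    norm_spec = [((a, b), s, e) for (a, b), s, e in ibd_spec]
    for (a, b), start, end in norm_spec:
        sel = (positions >= start) & (positions <= end)
        alleles[sel, lab[b]] = alleles[sel, lab[a]]

    # repair monomorphic markers without breaking engineered identity
    for m in np.flatnonzero(
            (alleles.sum(1) == 0) | (alleles.sum(1) == 8)):
        covered = set()
        pairs_here = []
        for (a, b), start, end in norm_spec:
            if start <= positions[m] <= end:
                covered.update((lab[a], lab[b]))
                pairs_here.append((lab[a], lab[b]))
        free = [i for i in range(8) if i not in covered]
        if free:
            alleles[m, rng.choice(free)] ^= 1
        else:
            ia, ib = pairs_here[0]
            alleles[m, [ia, ib]] ^= 1

    return FounderHaplotypePanel(
        chrom=chrom, positions=positions, cm=cm, alleles=alleles,
        ibd_truth=[(tuple(p), s, e) for p, s, e in norm_spec],
        chrom_length_bp=chrom_length_bp).validate()


def _bp_of_cm(panel, cm_points):
    """Invert the (monotone) marker genetic map by linear interpolation."""
    return np.interp(cm_points, panel.cm, panel.positions)


def simulate_do_diplotypes(panel, n_gen, n_samples, seed=0,
                           xo_rate_per_gen=XO_RATE_PER_GEN,
                           gen_anchor=XO_ANCHOR_GEN,
                           count_anchor=XO_ANCHOR_COUNT,
                           genome_cm=DEFAULT_GENOME_CM):
    """Simulate DO diplotype mosaics at outbreeding generation ``n_gen``.

    Per homolog, breakpoints follow a Poisson process on the genetic map
    whose genome-wide expectation matches the linear accumulation model
    of :func:`expected_crossovers`; the simulated chromosome receives the
    fraction (its cM length / ``genome_cm``) of that total.  Founders are
    drawn uniformly, with self-transitions forbidden so every breakpoint
    is an observable junction.
    """
    if n_gen < 1:
        raise ValueError("n_gen must be >= 1")
    if xo_rate_per_gen < 0:
        raise ValueError("negative crossover rate")
    rng = np.random.default_rng(seed)
    length_cm = float(panel.cm[-1] - panel.cm[0])
    e_total = expected_crossovers(n_gen, gen_anchor, count_anchor,
                                  xo_rate_per_gen)
    mean_per_homolog = e_total * (length_cm / genome_cm) / 2.0
    L = panel.chrom_length_bp or int(panel.positions[-1])
    mosaics = []
    for _ in range(n_samples):
        homologs = []
        for _h in range(2):
            k = rng.poisson(mean_per_homolog)
            if k > 0:
                bp_cm = np.sort(rng.uniform(panel.cm[0], panel.cm[-1], k))
                bps = np.unique(np.clip(
                    np.round(_bp_of_cm(panel, bp_cm)).astype(np.int64), 2, L))
            else:
                bps = np.array([], dtype=np.int64)
            founders = [rng.integers(8)]
            for _j in range(len(bps)):
                nxt = rng.integers(7)
                founders.append(nxt if nxt < founders[-1] else nxt + 1)
            starts = np.concatenate(([1], bps))
            ends = np.concatenate((bps - 1, [L]))
            homologs.append(
                [(int(s), int(e), int(f))
                 for s, e, f in zip(starts, ends, founders)])
        mosaics.append(DiplotypeMosaic(
            homologs=homologs, generation=n_gen, chrom=panel.chrom,
            chrom_length_bp=L).validate())
    return mosaics


def simulate_reads(mosaic, panel, coverage, base_error=0.001, seed=0):
    """Binomial read sampling at a marker grid for one sample.

    Total depth per marker is Poisson(``coverage``); the alternate count
    is Binomial(depth, p) with p = ``base_error``, 0.5 or
    1 - ``base_error`` for true dose 0, 1, 2.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0 <= base_error < 0.5:
        raise ValueError("base_error must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    dose = mosaic.dose(panel)
    depth = rng.poisson(coverage, size=panel.n_markers)
    p = np.array([base_error, 0.5, 1 - base_error])[dose]
    alt = rng.binomial(depth, p)
    return depth - alt, alt


def simulate_read_cohort(mosaics, panel, coverage, base_error=0.001, seed=0):
    """:func:`simulate_reads` over a cohort -> :class:`AlleleDepthMatrix`."""
    rng = np.random.default_rng(seed)
    refs, alts = [], []
    for mos in mosaics:
        r, a = simulate_reads(mos, panel, coverage, base_error,
                              seed=rng.integers(2**31))
        refs.append(r)
        alts.append(a)
    return AlleleDepthMatrix(
        ref=np.array(refs), alt=np.array(alts),
        nominal_coverage=coverage).validate()


def simulate_array_calls(mosaics, panel, array_marker_indices,
                         call_error=0.005, seed=0):
    """Hard genotype calls (0/1/2) on a sparse marker subset.

    Emulates array genotyping: each call equals the true dose with
    probability 1 - ``call_error``, otherwise one of the two other doses
    uniformly.  Returns a (samples x markers) int matrix.
    """
    idx = np.asarray(array_marker_indices)
    if idx.size == 0:
        raise ValueError("array marker index set is empty")
    rng = np.random.default_rng(seed)
    sub = panel.subset(idx)
    calls = np.empty((len(mosaics), len(idx)), dtype=np.int64)
    for i, mos in enumerate(mosaics):
        dose = mos.dose(sub)
        err = rng.random(len(idx)) < call_error
        shift = rng.integers(1, 3, size=len(idx))
        calls[i] = np.where(err, (dose + shift) % 3, dose)
    return calls


def simulate_expression(mosaics, panel, truth, seed=0, sex=None,
                        generation=None, sex_effect=0.1, gen_effect=0.02,
                        latent_sd=1.0, latent_scale=0.4):
    """Negative-binomial expression counts with founder-additive effects.

    Latent trait per gene: sum_j f_ij beta_j + covariate effects +
    Gaussian noise (SD ``latent_sd``), where f_ij is the true founder
    allele fraction (0, 0.5, 1) at the marker nearest the gene midpoint.
    Counts are NB with mean ``base_mean * exp(latent_scale * latent) *
    size_factor``.  Returns (counts, sex, generation, size_factors).
    """
    rng = np.random.default_rng(seed)
    n = len(mosaics)
    if sex is None:
        sex = rng.integers(0, 2, size=n)
    if generation is None:
        # cohorts typically span a few outbreeding generations
        g = mosaics[0].generation
        generation = rng.integers(max(1, g - 2), g + 3, size=n)
    size_factors = np.exp(rng.normal(0, 0.1, size=n))
    counts = np.empty((n, len(truth)), dtype=np.int64)
    fnd = np.stack([m.founders_at(panel.positions) for m in mosaics])
    for g, t in enumerate(truth):
        t.validate()
        mi = int(np.argmin(np.abs(panel.positions - t.midpoint_bp)))
        f = np.zeros((n, 8))
        for h in range(2):
            np.add.at(f, (np.arange(n), fnd[:, mi, h]), 0.5)
        latent = (f @ t.effects + sex_effect * sex
                  + gen_effect * (generation - generation.mean())
                  + rng.normal(0, latent_sd, size=n))
        mu = t.base_mean * np.exp(latent_scale * latent) * size_factors
        r = 1.0 / t.dispersion
        counts[:, g] = rng.negative_binomial(r, r / (r + mu))
    return counts, np.asarray(sex), np.asarray(generation), size_factors


def make_expression_truth(panel, n_genes, n_causal, effect_size=1.0,
                          seed=0, dispersion=0.1):
    """Build an :class:`ExpressionTruth` list with bipartite planted effects.

    Causal genes get a sum-to-zero effect vector of +/- ``effect_size``
    over a random 4/4 split of founders (an allele contrast of
    2x``effect_size`` between groups); the rest are null.
    """
    rng = np.random.default_rng(seed)
    mids = np.sort(rng.choice(
        np.arange(int(panel.positions[0]), int(panel.positions[-1])),
        size=n_genes, replace=False))
    causal = np.zeros(n_genes, dtype=bool)
    causal[rng.choice(n_genes, size=n_causal, replace=False)] = True
    out = []
    for g in range(n_genes):
        eff = np.zeros(8)
        if causal[g]:
            up = rng.choice(8, size=4, replace=False)
            eff -= effect_size
            eff[up] = effect_size
        out.append(ExpressionTruth(
            gene_id=f"gene{g:04d}", midpoint_bp=int(mids[g]),
            causal=bool(causal[g]), effects=eff,
            dispersion=dispersion).validate())
    return out
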