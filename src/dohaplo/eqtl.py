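"""Haplotype-regression expression QTL mapping.

Traits are variance-stabilized counts, filtered, then forced to
standard-normal quantiles (rank-Z).  At each marker the model

    y_i = s_i b_s + g_i b_g + sum_j f_ij b_j + lambda_i + e_i

regresses the trait on sex, outbreeding generation and the eight
founder allele probabilities f_ij; LOD = (n/2) log10(RSS0/RSS1)
compares it to the covariate-only fit.  Relatedness (lambda_i) can be
absorbed with leave-one-chromosome-out (LOCO) kinship via a
one-random-effect LMM eigen-rotation; the fast no-kinship mode is the
default for synthetic benchmarking.  Peaks are called at LOD >= 8 with
a peak drop of 5 and 1.5-LOD support intervals; peaks within 2 Mb of
the gene midpoint are local eQTL, matched 1-to-1 across genotyping
methods by support-interval overlap, and their per-founder additive
effects compared by cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

LOD_THRESHOLD = 8.0
PEAKDROP = 5.0
LOD_DROP = 1.5
LOCAL_MAX_DIST = 2_000_000


def filter_genes(counts, min_total=3000, min_unique=100):
    """Indices of genes passing count filters.

    Keep genes whose total count across samples exceeds ``min_total``
    and that show at least ``min_unique`` distinct count values
    (guarding against degenerate, QTL-hostile trait distributions).
    ``counts`` is (samples x genes).
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty count matrix")
    totals = counts.sum(axis=0)
    uniques = np.array([len(np.unique(counts[:, g]))
                        for g in range(counts.shape[1])])
    return np.flatnonzero((totals > min_total) & (uniques >= min_unique))


def vst(counts, size_factors=None):
    """Simple variance stabilization: log2(count/size_factor + 1)."""
    counts = np.asarray(counts, dtype=float)
    if size_factors is None:
        lib = counts.sum(axis=1)
        size_factors = lib / lib.mean()
    return np.log2(counts / np.asarray(size_factors)[:, None] + 1)


def rankz(values):
    """Inverse-normal transform of ranks: Phi^-1((rank - 0.5)/n).

    Ties share the average rank; a constant vector is rejected.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 values")
    if np.all(values == values[0]):
        raise ValueError("constant trait cannot be rank-Z transformed")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / n)


def loco_kinship(alleleprobs_by_chrom):
    """Leave-one-chromosome-out allele-probability kinship matrices.

    ``alleleprobs_by_chrom`` maps chrom -> (S, M_c, 8).  K excluding
    chromosome c is the mean over all other markers of F_m F_m^T, where
    F_m is the (S, 8) allele-probability row at marker m.
    """
    chroms = list(alleleprobs_by_chrom)
    if len(chroms) < 2:
        raise ValueError(
            "LOCO kinship requires >= 2 chromosomes (nothing to leave out)")
    partial = {}
    counts = {}
    for c, probs in alleleprobs_by_chrom.items():
        P = np.asarray(probs)
        S = P.shape[0]
        flat = P.transpose(1, 0, 2)  # (M, S, 8)
        partial[c] = np.einsum("mif,mjf->ij", flat, flat)
        counts[c] = P.shape[1]
    total = sum(partial.values())
    m_total = sum(counts.values())
    return {c: (total - partial[c]) / (m_total - counts[c])
            for c in chroms}


def _design(covariates, n):
    X0 = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X0 = np.hstack([X0, C])
    if np.linalg.matrix_rank(X0) < X0.shape[1]:
        raise ValueError("rank-deficient covariates")
    return X0


def _rss(X, Y):
    """Residual sum of squares of Y on X, per column of Y."""
    beta, res, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if res.size == Y.shape[1] and rank == X.shape[1]:
        return res
    r = Y - X @ beta
    return np.sum(r * r, axis=0)


def scan1(traits, alleleprobs, covariates=None, kinship=None):
    """Genome scan: LOD per marker (and trait).

    ``traits``: (n,) or (n, T) rank-Z traits; ``alleleprobs``:
    (n, M, 8).  Without kinship, LOD = (n/2) log10(RSS0/RSS1) between
    the covariate-only and covariate+allele-probability regressions
    (one founder column dropped against the intercept).  With a kinship
    matrix, variance components are estimated once per trait under the
    null via the eigen-rotation and GLS is run at each marker.
    Returns an (M,) or (M, T) LOD array.
    """
    Y = np.asarray(traits, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    P = np.asarray(alleleprobs, dtype=float)
    n, M = P.shape[0], P.shape[1]
    if Y.shape[0] != n:
        raise ValueError("traits and alleleprobs misaligned")
    X0 = _design(covariates, n)
    if kinship is not None:
        lods = np.stack([
            _scan1_kinship(Y[:, t], P, X0, kinship)
            for t in range(Y.shape[1])], axis=-1)
        return lods[..., 0] if squeeze else lods
    rss0 = _rss(X0, Y)
    lods = np.empty((M, Y.shape[1]))
    for m in range(M):
        X1 = np.hstack([X0, P[:, m, :-1]])
        lods[m] = (n / 2) * np.log10(rss0 / _rss(X1, Y))
    return lods[:, 0] if squeeze else lods


def _scan1_kinship(y, P, X0, K):
    """LOD scan for one trait under a one-random-effect LMM.

    K is eigendecomposed; the heritability h2 is fit by ML on the null
    model, then every model is fit by weighted least squares in the
    rotated space with weights 1/(h2*lam + 1 - h2).
    """
    n, M = P.shape[0], P.shape[1]
    lam, U = np.linalg.eigh(K)
    y_r = U.T @ y
    X0_r = U.T @ X0

    def negll(h2):
        w = h2 * lam + (1 - h2)
        sw = 1 / np.sqrt(w)
        rss = _rss(X0_r * sw[:, None], (y_r * sw)[:, None])[0]
        return np.sum(np.log(w)) + n * np.log(rss)

    res = optimize.minimize_scalar(negll, bounds=(0.0, 0.999),
                                   method="bounded")
    h2 = res.x
    w = h2 * lam + (1 - h2)
    sw = 1 / np.sqrt(w)
    yw = (y_r * sw)[:, None]
    X0w = X0_r * sw[:, None]
    rss0 = _rss(X0w, yw)[0]
    lods = np.empty(M)
    for m in range(M):
        Xw = np.hstack([X0w, (U.T @ P[:, m, :-1]) * sw[:, None]])
        lods[m] = (n / 2) * np.log10(rss0 / _rss(Xw, yw)[0])
    return lods


@dataclass
class EqtlPeak:
    """A called QTL peak with its 1.5-LOD support interval."""

    gene: str
    chrom: str
    peak_bp: int
    lod: float
    ci_lo: int
    ci_hi: int
    effects: np.ndarray = None  # centered beta_1..beta_8, filled later
    is_local: bool = False
    peak_index: int = -1


def find_peaks(lods, positions, chrom="1", gene="",
               threshold=LOD_THRESHOLD, peakdrop=PEAKDROP, drop=LOD_DROP):
    """Call peaks on one chromosome's LOD curve.

    Local maxima at or above ``threshold`` are kept; two summits merge
    into one peak unless the valley between them falls at least
    ``peakdrop`` below the smaller summit.  The support interval spans
    the contiguous run of markers within ``drop`` of the peak LOD.
    """
    lods = np.asarray(lods, dtype=float)
    positions = np.asarray(positions)
    M = len(lods)
    order = np.argsort(lods)[::-1]
    accepted = []
    for m in order:
        if lods[m] < threshold:
            break
        if not ((m == 0 or lods[m] >= lods[m - 1])
                and (m == M - 1 or lods[m] >= lods[m + 1])):
            continue  # not a local maximum
        merged = False
        for a in accepted:
            lo, hi = min(a, m), max(a, m)
            valley = lods[lo:hi + 1].min()
            if lods[m] - valley < peakdrop:
                merged = True
                break
        if merged:
            continue
        accepted.append(m)
    peaks = []
    for m in sorted(accepted):
        lo = m
        while lo > 0 and lods[lo - 1] >= lods[m] - drop:
            lo -= 1
        hi = m
        while hi < M - 1 and lods[hi + 1] >= lods[m] - drop:
            hi += 1
        peaks.append(EqtlPeak(
            gene=gene, chrom=chrom, peak_bp=int(positions[m]),
            lod=float(lods[m]), ci_lo=int(positions[lo]),
            ci_hi=int(positions[hi]), peak_index=m))
    return peaks


def local_eqtl(peaks, gene_midpoints, gene_chroms=None,
               max_dist=LOCAL_MAX_DIST):
    """Flag local peaks and select one per gene for comparison.

    A peak is local iff it lies on the gene's chromosome within
    ``max_dist`` (inclusive) of the gene midpoint.  Among a gene's
    local peaks the one closest to the midpoint is selected.  Returns
    (all peaks with ``is_local`` set, {gene: selected peak}).
    """
    selected = {}
    flagged = []
    for p in peaks:
        mid = gene_midpoints[p.gene]
        chrom_ok = (gene_chroms is None or gene_chroms[p.gene] == p.chrom)
        dist = abs(p.peak_bp - mid)
        p.is_local = bool(chrom_ok and dist <= max_dist)
        flagged.append(p)
        if p.is_local:
            cur = selected.get(p.gene)
            if cur is None or dist < abs(cur.peak_bp - mid):
                selected[p.gene] = p
    return flagged, selected


def match_eqtl(catalog_a, catalog_b):
    """1-to-1 match of per-gene local eQTL across two methods.

    Catalogs map gene -> selected :class:`EqtlPeak`.  A pair matches iff
    the gene is in both and the support intervals overlap by >= 1 bp.
    Returns (pairs, unmatched_a, unmatched_b); each pair carries the
    LOD, peak-position and interval-width deltas (b - a).
    """
    for cat in (catalog_a, catalog_b):
        genes = list(cat)
        if len(genes) != len(set(genes)):
            raise ValueError("duplicate gene entries in catalog")
    pairs = []
    unmatched_a, unmatched_b = [], []
    for gene, pa in catalog_a.items():
        pb = catalog_b.get(gene)
        if pb is None or pa.chrom != pb.chrom \
                or pa.ci_lo > pb.ci_hi or pb.ci_lo > pa.ci_hi:
            unmatched_a.append(gene)
            continue
        pairs.append({
            "gene": gene, "peak_a": pa, "peak_b": pb,
            "delta_lod": pb.lod - pa.lod,
            "delta_peak_bp": pb.peak_bp - pa.peak_bp,
            "delta_width_bp": ((pb.ci_hi - pb.ci_lo)
                               - (pa.ci_hi - pa.ci_lo)),
        })
    matched = {p["gene"] for p in pairs}
    unmatched_b = [g for g in catalog_b if g not in matched]
    return pairs, unmatched_a, unmatched_b


def allele_effects(trait, alleleprobs_at_peak, covariates=None):
    """Additive effect of each founder allele at a fixed peak marker.

    Regresses the trait on the 8 allele probabilities plus covariates
    and returns the 8 coefficients under a sum-to-zero contrast
    (centered), which is the unique estimable representation given the
    probabilities sum to 1.  Raises if the probabilities are collinear
    beyond that intrinsic constraint.
    """
    y = np.asarray(trait, dtype=float)
    P = np.asarray(alleleprobs_at_peak, dtype=float)
    X0 = _design(covariates, len(y))
    X = np.hstack([X0, P])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1] - 1:
        raise ValueError("collinear allele probabilities at the marker")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    eff = beta[X0.shape[1]:]
    return eff - eff.mean()
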