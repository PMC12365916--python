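"""Marker-retention heuristics ahead of haplotype reconstruction.

Imputation quality depends directly on coverage, so the marker set
entering reconstruction is chosen adaptively: sites must look roughly
Hardy-Weinberg (a pragmatic screen -- a population descended from eight
inbred founders violates HWE by construction) and must exceed an INFO
cutoff that starts at 0.95 and is relaxed in 0.01 steps until more than
a minimum number of markers survive, so that coverage levels remain
comparable.  The final cutoff is recorded per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def hwe_pvalue(n0, n1, n2, exact=False):
    """Hardy-Weinberg goodness-of-fit p-value from genotype counts.

    Chi-square with 1 df against expected counts at the sample allele
    frequency (the default), or the mid-p-free exact test on
    heterozygote counts when ``exact=True``.  Monomorphic samples are
    in HWE by convention (p = 1).
    """
    n0, n1, n2 = int(n0), int(n1), int(n2)
    if min(n0, n1, n2) < 0:
        raise ValueError("negative genotype count")
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("all-zero genotype counts")
    p = (2 * n2 + n1) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    if exact:
        return _hwe_exact(n0, n1, n2)
    expected = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p ** 2])
    stat = np.sum((np.array([n0, n1, n2]) - expected) ** 2 / expected)
    return float(stats.chi2.sf(stat, df=1))


def _hwe_exact(n0, n1, n2):
    """Exact HWE test (sum of probabilities <= observed config)."""
    from scipy.special import logsumexp
    n = n0 + n1 + n2
    n_alt = 2 * n2 + n1
    hets = np.arange(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2)
    logp = np.array([
        _log_hwe_prob(n, n_alt, int(h)) for h in hets])
    logp -= logsumexp(logp)
    p_obs = logp[hets == n1][0]
    return float(np.exp(logsumexp(logp[logp <= p_obs + 1e-12])))


def _log_hwe_prob(n, n_alt, n_het):
    from scipy.special import gammaln
    n_hom_alt = (n_alt - n_het) // 2
    n_hom_ref = n - n_het - n_hom_alt
    return (n_het * np.log(2)
            + gammaln(n + 1)
            - gammaln(n_hom_ref + 1) - gammaln(n_het + 1)
            - gammaln(n_hom_alt + 1))


@dataclass
class FilterReport:
    """Outcome of the adaptive INFO filter on one chromosome."""

    chrom: str
    n_input: int
    n_retained: int
    final_info_cutoff: float
    hwe_alpha: float
    exhausted: bool = False  # cutoff hit 0 without reaching min_snps


def adaptive_info_filter(info, hwe_p, start_cutoff=0.95, step=0.01,
                         min_snps=10_000, hwe_alpha=0.05, chrom="1"):
    """Adaptive marker retention: HWE screen + relaxing INFO cutoff.

    Candidates are sites with HWE p > ``hwe_alpha``.  The INFO cutoff
    starts at ``start_cutoff`` and decreases by ``step`` until strictly
    more than ``min_snps`` candidates exceed it (or the cutoff reaches
    0, in which case all candidates are returned and the report flags
    exhaustion).  Returns (retained indices, :class:`FilterReport`).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    info = np.asarray(info, dtype=float)
    hwe_p = np.asarray(hwe_p, dtype=float)
    if info.shape != hwe_p.shape:
        raise ValueError("info and hwe_p must be aligned")
    candidates = hwe_p > hwe_alpha
    cutoff = start_cutoff
    exhausted = False
    while True:
        retained = candidates & (info > cutoff)
        if retained.sum() > min_snps:
            break
        if cutoff <= 0:
            retained = candidates
            exhausted = True
            import warnings
            warnings.warn(
                f"INFO cutoff exhausted on {chrom}: "
                f"{int(retained.sum())} HWE-passing sites returned")
            break
        cutoff = max(0.0, cutoff - step)
    idx = np.flatnonzero(retained)
    report = FilterReport(
        chrom=chrom, n_input=len(info), n_retained=len(idx),
        final_info_cutoff=round(cutoff, 10), hwe_alpha=hwe_alpha,
        exhausted=exhausted)
    return idx, report


def hwe_pvalues_from_calls(calls):
    """Per-marker HWE p-values from an (S, M) hard-call matrix."""
    calls = np.asarray(calls)
    out = np.empty(calls.shape[1])
    for m in range(calls.shape[1]):
        col = calls[:, m]
        col = col[col >= 0]
        if col.size == 0:
            out[m] = 1.0
            continue
        out[m] = hwe_pvalue(int((col == 0).sum()), int((col == 1).sum()),
                            int((col == 2).sum()))
    return out
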