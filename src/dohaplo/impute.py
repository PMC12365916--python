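"""Genotype likelihoods, diplotype-HMM imputation and INFO scores.

Allele depths are turned into binomial genotype likelihoods, then a
founder diplotype HMM (see :mod:`dohaplo.hmm`) shares information along
the chromosome to produce posterior genotype-dose probabilities and
expected dosages per sample, plus an IMPUTE-style per-site INFO score
summarising how much of the dosage variance the data determined.
Coverage ladders are built by binomial thinning of the read counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from . import hmm
from .simulate import AlleleDepthMatrix


def genotype_likelihoods(depths, base_error=0.001):
    """Log-scale genotype likelihood triples from allele depths.

    L(g) = Binomial(alt | total, p_g) with p_g = ``base_error``, 0.5,
    1 - ``base_error`` for g = 0, 1, 2; renormalized so the maximum of
    each triple is 0.  Zero-depth sites give a flat triple.
    Returns an (S, M, 3) array.
    """
    if not 0 < base_error < 0.5:
        raise ValueError("base_error must be in (0, 0.5)")
    ref = np.asarray(depths.ref)
    alt = np.asarray(depths.alt)
    if (alt < 0).any() or (ref < 0).any():
        raise ValueError("negative counts")
    p = np.array([base_error, 0.5, 1 - base_error])
    # log L(g) up to the depth-only binomial coefficient, which cancels
    ll = (alt[..., None] * np.log(p) + ref[..., None] * np.log1p(-p))
    return ll - ll.max(axis=-1, keepdims=True)


def downsample_depths(depths, target_cov, seed=0):
    """Binomial thinning of read counts to a lower nominal coverage.

    Each read is kept independently with probability target/current,
    where current coverage is estimated as the mean total depth; ref and
    alt counts are thinned separately.  Thinning composes: thinning to c1
    then c2 is distributed as thinning directly to c2.
    """
    if target_cov <= 0:
        raise ValueError("target_cov must be positive")
    current = depths.total.mean()
    if target_cov > current:
        raise ValueError("target coverage exceeds current coverage")
    keep = target_cov / current
    if keep >= 1.0:
        return depths
    rng = np.random.default_rng(seed)
    return AlleleDepthMatrix(
        ref=rng.binomial(depths.ref, keep),
        alt=rng.binomial(depths.alt, keep),
        nominal_coverage=target_cov,
        sample_ids=list(depths.sample_ids),
        marker_ids=list(depths.marker_ids))


@dataclass
class SiteImputationStats:
    """Cohort imputation output at each marker."""

    dose_posteriors: np.ndarray  # (S, M, 3)
    dosages: np.ndarray          # (S, M) expected alt dose
    info: np.ndarray             # (M,) in [0, 1]


def dose_posteriors_from_diplotypes(diplotype_post, panel):
    """Sum 36-state posteriors into dose-0/1/2 posteriors per marker."""
    S, M, K = diplotype_post.shape
    out = np.zeros((S, M, 3))
    pairs = hmm.state_pairs(panel.n_founders)
    doses = np.stack([panel.alleles[:, i] + panel.alleles[:, j]
                      for i, j in pairs], axis=1)  # (M, K)
    for d in range(3):
        out[:, :, d] = np.sum(diplotype_post * (doses == d)[None], axis=-1)
    return out


def impute_cohort(gl, panel, n_gen, return_diplotypes=False):
    """Impute dosages for a cohort via the diplotype HMM.

    ``gl`` is the (S, M, 3) log-likelihood array from
    :func:`genotype_likelihoods`, aligned with ``panel`` markers.
    Posterior dose probabilities are the 36-state posteriors grouped by
    each state's founder-implied dose; the dosage is the expected dose.
    """
    gl = np.asarray(gl)
    if gl.shape[1] != panel.n_markers:
        raise ValueError("gl markers do not match panel markers")
    emissions = sequencing_emissions(gl, panel)
    post = hmm.diplotype_posteriors(emissions, panel.cm, n_gen)
    dose_post = dose_posteriors_from_diplotypes(post, panel)
    dosages = dose_post @ np.array([0.0, 1.0, 2.0])
    stats = SiteImputationStats(
        dose_posteriors=dose_post, dosages=dosages,
        info=info_score(dose_post))
    if return_diplotypes:
        return stats, post
    return stats


def sequencing_emissions(gl, panel):
    """(S, M, 36) emission matrix from GL triples and founder alleles."""
    pairs = hmm.state_pairs(panel.n_founders)
    doses = np.stack([panel.alleles[:, i] + panel.alleles[:, j]
                      for i, j in pairs], axis=1)  # (M, K)
    like = np.exp(gl)  # (S, M, 3)
    return np.take_along_axis(
        like[:, :, None, :].repeat(doses.shape[1], axis=2),
        doses[None, :, :, None], axis=-1)[..., 0]


def reconstruct_alleleprobs(gl_or_calls, panel, n_gen, model="sequencing",
                            error=0.005, batch_size=32):
    """Founder allele probabilities for a cohort, in sample batches.

    Convenience wrapper running emissions -> diplotype HMM -> 8-state
    condensation without holding the full cohort's 36-state posteriors
    in memory at once.  ``model`` selects sequencing GL input or array
    hard calls.  Returns an (S, M, 8) array.
    """
    from . import hmm as _hmm
    data = np.asarray(gl_or_calls)
    S = data.shape[0]
    out = np.empty((S, panel.n_markers, panel.n_founders))
    for lo in range(0, S, batch_size):
        chunk = data[lo:lo + batch_size]
        if model == "sequencing":
            em = sequencing_emissions(chunk, panel)
        elif model == "array":
            em = array_emissions(chunk, panel, error)
        else:
            raise ValueError(f"unknown model {model!r}")
        post = _hmm.diplotype_posteriors(em, panel.cm, n_gen)
        out[lo:lo + batch_size] = _hmm.genoprob_to_alleleprob(post)
    return out


def array_emissions(calls, panel, call_error=0.005):
    """(S, M, 36) emissions from hard calls (-1 = missing)."""
    pairs = hmm.state_pairs(panel.n_founders)
    doses = np.stack([panel.alleles[:, i] + panel.alleles[:, j]
                      for i, j in pairs], axis=1)
    calls = np.asarray(calls)
    like = np.full(calls.shape + (3,), call_error / 2.0)
    for d in range(3):
        like[..., d] = np.where(calls == d, 1 - call_error, like[..., d])
    like[calls < 0] = 1.0
    return np.take_along_axis(
        like[:, :, None, :].repeat(doses.shape[1], axis=2),
        doses[None, :, :, None], axis=-1)[..., 0]


def info_score(dose_posteriors):
    """IMPUTE-style per-marker imputation quality in [0, 1].

    info = 1 - sum_i Var_i(dose) / (N * 2 theta (1-theta)) with theta
    the cohort mean dosage / 2.  Point-mass posteriors give 1; sites
    where every posterior equals the Hardy-Weinberg prior give 0; the
    monomorphic limit (theta in {0, 1}) is defined as 1.
    """
    dp = np.asarray(dose_posteriors)
    if dp.ndim != 3 or dp.shape[0] < 1:
        raise ValueError("need an (S, M, 3) array with >= 1 sample")
    d = np.array([0.0, 1.0, 2.0])
    e = dp @ d
    v = dp @ (d ** 2) - e ** 2
    N = dp.shape[0]
    theta = e.sum(axis=0) / (2 * N)
    denom = 2 * N * theta * (1 - theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        info = 1.0 - v.sum(axis=0) / denom
    info = np.where(denom <= 0, 1.0, info)
    return np.clip(info, 0.0, 1.0)


def hard_calls(dose_posteriors):
    """Most probable dose per sample-marker."""
    return np.argmax(dose_posteriors, axis=-1)


def per_site_baseline_dosages(gl, panel):
    """No-HMM baseline: posterior-mean dose per site in isolation.

    Prior per site is Hardy-Weinberg at the founder-panel allele
    frequency; no linkage information is used.  Serves as the control
    showing what the HMM's haplotype sharing adds.
    """
    p1 = panel.alleles.mean(axis=1)
    prior = np.stack([(1 - p1) ** 2, 2 * p1 * (1 - p1), p1 ** 2], axis=-1)
    logpost = gl + np.log(np.maximum(prior, 1e-300))
    logpost -= logsumexp(logpost, axis=-1, keepdims=True)
    return np.exp(logpost) @ np.array([0.0, 1.0, 2.0])
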