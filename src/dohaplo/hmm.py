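"""36-state founder diplotype hidden Markov model.

At each marker a DO sample carries an unordered pair of founder
haplotypes: 8 homozygous + 28 heterozygous = 36 diplotype states.  Each
homolog switches founder along the genetic map with an exponential-decay
model whose rate scales with the outbreeding generation (nGen): over a
gap of d cM, stay-with-self = exp(-r) + (1-exp(-r))/8 and
switch-to-a-specific-other = (1-exp(-r))/8, with r = n_gen * d/100.
Diplotype transitions are the symmetrized product of two independent
homolog processes.

Two equivalent forward-backward engines are provided: a dense one over
the unordered state space (any founder count; used by the enumeration
oracles) and a factored one that works in the ordered 8x8 tensor space,
where the transition operator costs O(K) per marker instead of O(K^4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def state_pairs(n_founders=8):
    """Unordered founder pairs (i <= j) in lexicographic order."""
    return [(i, j) for i in range(n_founders) for j in range(i, n_founders)]


def n_states(n_founders=8):
    return n_founders * (n_founders + 1) // 2


def state_index(i, j, n_founders=8):
    i, j = min(i, j), max(i, j)
    return i * n_founders - i * (i - 1) // 2 + (j - i)


def state_doses(panel_row, n_founders=8):
    """Alt dose (0/1/2) of each unordered state given founder alleles."""
    a = np.asarray(panel_row)
    return np.array([a[i] + a[j] for i, j in state_pairs(n_founders)])


def _homolog_transition(d_cM, n_gen, n_founders=8):
    if d_cM < 0:
        raise ValueError("d_cM must be non-negative")
    if n_gen < 1:
        raise ValueError("n_gen must be >= 1")
    r = n_gen * d_cM / 100.0
    w = -np.expm1(-r)  # 1 - e^-r
    P = np.full((n_founders, n_founders), w / n_founders)
    P[np.diag_indices(n_founders)] += 1 - w
    return P


def transition_matrix(d_cM, n_gen, n_founders=8):
    """Unordered diplotype transition matrix over a gap of ``d_cM``.

    Rows/columns follow :func:`state_pairs` order; each row sums to 1.
    At d=0 this is the identity; as d grows rows converge to the
    stationary diplotype distribution (1/F^2 per homozygote, 2/F^2 per
    unordered heterozygote).
    """
    P = _homolog_transition(d_cM, n_gen, n_founders)
    pairs = state_pairs(n_founders)
    K = len(pairs)
    T = np.empty((K, K))
    for s, (a, b) in enumerate(pairs):
        for t, (c, d) in enumerate(pairs):
            if c == d:
                T[s, t] = P[a, c] * P[b, c]
            else:
                T[s, t] = P[a, c] * P[b, d] + P[a, d] * P[b, c]
    return T


def emission_probs(observation, panel_row, model, error=0.001,
                   n_founders=8):
    """Likelihood of one observation under each diplotype state.

    ``model="sequencing"``: observation is a log-scale genotype
    likelihood triple (L0, L1, L2); the emission for a state is
    exp(L[dose]).  ``model="array"``: observation is a hard call in
    {0, 1, 2} or -1 for missing; correct call has likelihood 1 - error,
    each wrong call error/2; missing is uninformative.
    """
    doses = state_doses(panel_row, n_founders)
    if model == "sequencing":
        gl = np.asarray(observation, dtype=float)
        if gl.shape != (3,):
            raise ValueError("sequencing observation must be a GL triple")
        return np.exp(gl)[doses]
    if model == "array":
        call = int(observation)
        if call < 0:
            return np.ones(len(doses))
        like = np.full(3, error / 2.0)
        like[call] = 1 - error
        return like[doses]
    raise ValueError(f"unknown emission model: {observation!r}/{model!r}")


def _dense_forward_backward(emissions, d_cM, n_gen, n_founders):
    """Scaled forward-backward over unordered states, one sample.

    emissions: (M, K); d_cM: (M-1,) inter-marker gaps.
    """
    M, K = emissions.shape
    Ts = [transition_matrix(d, n_gen, n_founders) for d in d_cM]
    alpha = np.empty((M, K))
    a = emissions[0] / K
    alpha[0] = a / a.sum()
    for m in range(1, M):
        a = (alpha[m - 1] @ Ts[m - 1]) * emissions[m]
        alpha[m] = a / a.sum()
    beta = np.empty((M, K))
    beta[-1] = 1.0
    for m in range(M - 2, -1, -1):
        b = Ts[m] @ (emissions[m + 1] * beta[m + 1])
        beta[m] = b / b.sum()
    post = alpha * beta
    return post / post.sum(axis=1, keepdims=True)


def _sym_expand(e36, n_founders=8):
    """(S, M, K) unordered emissions -> (S, M, F, F) ordered tensor."""
    S, M, K = e36.shape
    F = n_founders
    out = np.empty((S, M, F, F))
    for s, (i, j) in enumerate(state_pairs(F)):
        out[:, :, i, j] = e36[:, :, s]
        out[:, :, j, i] = e36[:, :, s]
    return out


def _lump(post88):
    """Ordered (S, M, F, F) posterior -> unordered (S, M, K)."""
    S, M, F, _ = post88.shape
    out = np.empty((S, M, n_states(F)))
    for s, (i, j) in enumerate(state_pairs(F)):
        if i == j:
            out[:, :, s] = post88[:, :, i, i]
        else:
            out[:, :, s] = post88[:, :, i, j] + post88[:, :, j, i]
    return out


def _apply_T(A, s, w, F):
    """Transition operator on ordered tensors A (..., F, F), O(F^2)."""
    B = s * A + (w / F) * A.sum(axis=-1, keepdims=True)
    return s * B + (w / F) * B.sum(axis=-2, keepdims=True)


def _factored_forward_backward(e36, d_cM, n_gen, n_founders=8):
    """Batched forward-backward in the ordered tensor space.

    e36: (S, M, K) emissions for all samples; returns (S, M, K)
    posteriors identical (up to fp error) to the dense engine.
    """
    F = n_founders
    E = _sym_expand(e36, F)
    S, M = E.shape[:2]
    r = n_gen * np.asarray(d_cM) / 100.0
    stay = np.exp(-r)
    switch = -np.expm1(-r)
    # uniform prior over the K unordered states, expanded symmetrically
    K = n_states(F)
    prior = np.full((F, F), 1.0 / (2 * K))
    prior[np.diag_indices(F)] = 1.0 / K
    alpha = np.empty_like(E)
    a = E[:, 0] * prior
    alpha[:, 0] = a / a.sum(axis=(1, 2), keepdims=True)
    for m in range(1, M):
        a = _apply_T(alpha[:, m - 1], stay[m - 1], switch[m - 1], F) * E[:, m]
        alpha[:, m] = a / a.sum(axis=(1, 2), keepdims=True)
    beta = np.empty_like(E)
    beta[:, -1] = 1.0
    for m in range(M - 2, -1, -1):
        b = _apply_T(E[:, m + 1] * beta[:, m + 1], stay[m], switch[m], F)
        beta[:, m] = b / b.sum(axis=(1, 2), keepdims=True)
    post = alpha * beta
    post /= post.sum(axis=(2, 3), keepdims=True)
    return _lump(post)


def diplotype_posteriors(emissions, cm_map, n_gen, n_founders=8,
                         engine="auto"):
    """Posterior diplotype probabilities by forward-backward.

    ``emissions``: (S, M, K) or (M, K) per-marker state likelihoods;
    ``cm_map``: genetic positions (cM) of the M markers.  Initial state
    distribution is uniform.  Returns posteriors with the input's
    leading shape; every marker row sums to 1.
    """
    e = np.asarray(emissions, dtype=float)
    squeeze = e.ndim == 2
    if squeeze:
        e = e[None]
    if e.shape[1] < 1:
        raise ValueError("need at least one marker")
    if not np.isfinite(e).all():
        raise ValueError("non-finite emissions")
    d_cM = np.diff(np.asarray(cm_map, dtype=float))
    if engine == "auto":
        engine = "factored"
    if engine == "factored":
        post = _factored_forward_backward(e, d_cM, n_gen, n_founders)
    elif engine == "dense":
        post = np.stack([
            _dense_forward_backward(e[s], d_cM, n_gen, n_founders)
            for s in range(e.shape[0])])
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return post[0] if squeeze else post


def genoprob_to_alleleprob(diplotype_probs, n_founders=8):
    """Condense 36-state diplotype posteriors to 8 founder allele probs.

    allele_i = P(hom ii) + 1/2 * sum_{j != i} P(het ij); rows sum to 1
    exactly when the diplotype rows do.
    """
    probs = np.asarray(diplotype_probs)
    out = np.zeros(probs.shape[:-1] + (n_founders,))
    for s, (i, j) in enumerate(state_pairs(n_founders)):
        if i == j:
            out[..., i] += probs[..., s]
        else:
            out[..., i] += 0.5 * probs[..., s]
            out[..., j] += 0.5 * probs[..., s]
    return out


def maxmarg_path(diplotype_probs, minprob=0.95):
    """Maximum-marginal state call per marker.

    Returns the argmax state index where the maximum posterior reaches
    ``minprob``, else -1 ("uncertain").  Ties break to the lowest state
    index.
    """
    if not 0.5 < minprob <= 1:
        raise ValueError("minprob must be in (0.5, 1]")
    probs = np.asarray(diplotype_probs)
    path = np.argmax(probs, axis=-1)
    return np.where(np.max(probs, axis=-1) >= minprob, path, -1)


@dataclass
class CrossoverSet:
    """Crossovers located on one sample's called diplotype path."""

    chrom: str
    boundaries: list  # (left_bp, right_bp, n_changes in {1, 2})
    block_lengths: list = field(default_factory=list)

    @property
    def total(self):
        return sum(n for _, _, n in self.boundaries)


def _multiset_changes(pair_a, pair_b):
    """Founder haplotypes changed between two unordered pairs (0/1/2)."""
    a = sorted(pair_a)
    b = sorted(pair_b)
    common = 0
    bb = list(b)
    for x in a:
        if x in bb:
            bb.remove(x)
            common += 1
    return 2 - common


def locate_crossovers(path, positions, chrom="1", n_founders=8,
                      chrom_start=None, chrom_end=None):
    """Locate crossovers on a maxmarg path.

    At each pair of successive *called* markers whose states differ, the
    number of crossovers is the founder-multiset difference (one shared
    founder -> 1, disjoint -> 2); uncertain calls are bridged by
    comparing the nearest called flanks.  Boundaries are the flanking
    inter-marker bp intervals; block lengths split the chromosome span
    at boundary-interval midpoints and sum to the span length.
    """
    path = np.asarray(path)
    positions = np.asarray(positions)
    if len(path) < 2:
        raise ValueError("path must cover at least two markers")
    pairs = state_pairs(n_founders)
    called = np.flatnonzero(path >= 0)
    if chrom_start is None:
        chrom_start = int(positions[0])
    if chrom_end is None:
        chrom_end = int(positions[-1])
    if called.size == 0:
        import warnings
        warnings.warn("all-missing path: no crossovers located")
        return CrossoverSet(chrom=chrom, boundaries=[],
                            block_lengths=[chrom_end - chrom_start])
    boundaries = []
    for k0, k1 in zip(called, called[1:]):
        n = _multiset_changes(pairs[path[k0]], pairs[path[k1]])
        if n:
            boundaries.append((int(positions[k0]), int(positions[k1]), n))
    cuts = [chrom_start] + [(l + r) / 2 for l, r, _ in boundaries] + [chrom_end]
    lengths = [b - a for a, b in zip(cuts, cuts[1:])]
    return CrossoverSet(chrom=chrom, boundaries=boundaries,
                        block_lengths=lengths)
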