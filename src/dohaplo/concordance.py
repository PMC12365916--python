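"""Comparing haplotype reconstructions and explaining disagreements.

Two reconstructions of the same sample (e.g. sequencing-based vs
array-based) are compared marker by marker with the cosine similarity
of their 8-founder allele-probability vectors -- a metric insensitive
to the mean probability, so it measures absolute agreement at a locus.
Runs of markers below a similarity threshold (default 0.87, the value
produced when one platform splits a haplotype's probability between two
founders that the other assigns to one) are flagged as discordant
regions, then tested against founder-pair IBD segments: if the founders
that disagree are identical-by-descent over the region, the discordance
reflects genuine ambiguity rather than reconstruction error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import CLASSICAL

#: Default flagging threshold: cos((0,...,0,.5,.5), (0,...,.25,.25,.5)).
DISCORDANCE_THRESHOLD = 0.87


def cosine_similarity(g, q):
    """Cosine similarity of two founder allele-probability vectors.

    cos(G, Q) = sum_i G_i Q_i / (||G|| ||Q||).  Raises on a zero-norm
    vector.  For non-negative probability vectors the value lies in
    [0, 1].
    """
    g = np.asarray(g, dtype=float)
    q = np.asarray(q, dtype=float)
    ng = np.linalg.norm(g)
    nq = np.linalg.norm(q)
    if ng == 0 or nq == 0:
        raise ValueError("zero-norm probability vector")
    return float(g @ q / (ng * nq))


def cosine_track(G, Q):
    """Per-marker cosine similarity between two (M, 8) matrices."""
    G = np.asarray(G, dtype=float)
    Q = np.asarray(Q, dtype=float)
    num = np.sum(G * Q, axis=-1)
    den = np.linalg.norm(G, axis=-1) * np.linalg.norm(Q, axis=-1)
    if np.any(den == 0):
        raise ValueError("zero-norm probability row")
    return num / den


def interpolate_probs(probs, from_bp, to_bp, method="linear"):
    """Interpolate allele probabilities onto a different marker map.

    Linear interpolation in bp per founder column followed by row
    renormalization (targets outside the source span take the nearest
    end row).  ``method="step"`` instead carries the previous source row
    forward, for sensitivity analysis.
    """
    probs = np.asarray(probs, dtype=float)
    from_bp = np.asarray(from_bp, dtype=float)
    to_bp = np.asarray(to_bp, dtype=float)
    if from_bp.size == 0:
        raise ValueError("empty source map")
    if method == "linear":
        out = np.stack([np.interp(to_bp, from_bp, probs[..., j])
                        for j in range(probs.shape[-1])], axis=-1)
    elif method == "step":
        idx = np.clip(np.searchsorted(from_bp, to_bp, side="right") - 1,
                      0, len(from_bp) - 1)
        out = probs[idx]
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    return out / out.sum(axis=-1, keepdims=True)


@dataclass
class DiscordantRegion:
    """A maximal run of markers where two reconstructions disagree."""

    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    n_markers: int
    mean_cosine: float
    marker_slice: tuple = (0, 0)  # [first, last] marker index of the run
    founders_G: frozenset = frozenset()
    founders_Q: frozenset = frozenset()
    ibd_explained: bool = False
    sharing_category: str = "none"


def flag_discordant_regions(cosines, positions, threshold=DISCORDANCE_THRESHOLD,
                            sample="S0", chrom="1"):
    """Maximal runs of consecutive markers with cosine < threshold.

    Single-marker runs are kept (start = end = that marker's bp); the
    region span runs from the first to the last marker of the run.
    """
    cosines = np.asarray(cosines)
    positions = np.asarray(positions)
    below = cosines < threshold
    regions = []
    m = 0
    M = len(cosines)
    while m < M:
        if below[m]:
            e = m
            while e + 1 < M and below[e + 1]:
                e += 1
            regions.append(DiscordantRegion(
                sample=sample, chrom=chrom,
                start_bp=int(positions[m]), end_bp=int(positions[e]),
                n_markers=e - m + 1,
                mean_cosine=float(cosines[m:e + 1].mean()),
                marker_slice=(m, e)))
            m = e + 1
        else:
            m += 1
    return regions


def summarize_regions(regions):
    """Per-sample region count, median bp length and mean discordance."""
    if not regions:
        return {"n_regions": 0, "median_length_bp": 0.0,
                "mean_discordance": float("nan")}
    lengths = [r.end_bp - r.start_bp + 1 for r in regions]
    return {
        "n_regions": len(regions),
        "median_length_bp": float(np.median(lengths)),
        "mean_discordance": float(np.mean([r.mean_cosine for r in regions])),
    }


def swap_founder_probs(probs, positions, pair_indices, start_bp, end_bp):
    """Swap two founders' probability columns over a bp interval.

    Relabelling one member of an IBD pair as the other is a
    probability-preserving transformation wherever the two founders are
    identical-by-descent -- exactly the ambiguity that drives platform
    discordance.  Used to engineer regions of known IBD-driven
    discordance for validation and sensitivity analysis.
    """
    out = np.array(probs, copy=True)
    i, j = pair_indices
    sel = (np.asarray(positions) >= start_bp) & \
          (np.asarray(positions) <= end_bp)
    out[..., sel, i], out[..., sel, j] = \
        probs[..., sel, j], probs[..., sel, i]
    return out


def _sharing_category(pair):
    a, b = pair
    if a in CLASSICAL and b in CLASSICAL:
        return "classical-only"
    if {a, b} == {"F", "G"}:
        return "PWK-CAST"
    if ("H" in (a, b)) and (a in CLASSICAL or b in CLASSICAL):
        return "classical+WSB"
    return "other"


def classify_discordance_ibd(regions, ibd_segments, probs_G, probs_Q,
                             min_overlap_bp=10_000, prob_floor=0.05):
    """Fill ``ibd_explained`` / ``sharing_category`` on each region.

    For each region the founders with region-mean probability above
    ``prob_floor`` in each reconstruction are collected.  The region is
    IBD-explained iff an IBD segment overlapping it by at least
    ``min_overlap_bp`` involves a founder pair lying within the union of
    the two founder sets such that at least one pair member's
    region-mean probability differs between the reconstructions by more
    than ``prob_floor`` (the pair actually participates in the
    disagreement, whether the platforms disagree on a founder's
    presence or only on how probability is split between the two).
    The sharing category is taken from the highest-LOD explaining pair:
    both classical -> "classical-only"; classical with WSB (H) ->
    "classical+WSB"; {CAST, PWK} = {F, G} -> "PWK-CAST"; else "other".
    """
    if prob_floor >= 1:
        raise ValueError("prob_floor must be < 1")
    labels = "ABCDEFGH"
    out = []
    for r in regions:
        lo, hi = r.marker_slice
        mean_G = probs_G[lo:hi + 1].mean(axis=0)
        mean_Q = probs_Q[lo:hi + 1].mean(axis=0)
        diff = np.abs(mean_G - mean_Q)
        fg = frozenset(labels[i] for i in np.flatnonzero(mean_G > prob_floor))
        fq = frozenset(labels[i] for i in np.flatnonzero(mean_Q > prob_floor))
        union = fg | fq
        best = None
        for seg in ibd_segments:
            if seg.chrom != r.chrom:
                continue
            if seg.overlap_bp(r.start_bp, r.end_bp) < min_overlap_bp:
                continue
            pair = set(seg.founder_pair)
            involved = any(diff[labels.index(f)] > prob_floor for f in pair)
            if involved and pair <= union:
                if best is None or seg.lod > best.lod:
                    best = seg
        out.append(DiscordantRegion(
            sample=r.sample, chrom=r.chrom, start_bp=r.start_bp,
            end_bp=r.end_bp, n_markers=r.n_markers,
            mean_cosine=r.mean_cosine, marker_slice=r.marker_slice,
            founders_G=fg, founders_Q=fq,
            ibd_explained=best is not None,
            sharing_category=(_sharing_category(sorted(best.founder_pair))
                              if best is not None else "none")))
    return out
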