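"""Founder reference preparation and founder-pair IBD detection.

The eight DO founder strains include five classical inbred lines that
share long identical-by-descent (IBD) tracts; within such a tract the
founders are indistinguishable to any reconstruction, which is the main
source of disagreement between genotyping platforms.  This module
filters a raw founder call set down to the biallelic, segregating,
all-homozygous sites used as the imputation reference, anchors markers
to an evenly spaced physical grid, and scores founder pairs for IBD
segments with a per-marker log10 likelihood-ratio (LOD) model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import FOUNDER_LABELS, FounderHaplotypePanel
from .simulate import DEFAULT_CM_PER_MB


@dataclass
class IBDSegment:
    """A maximal-scoring run of allele sharing between two founders."""

    founder_pair: tuple  # sorted (label_a, label_b)
    chrom: str
    start_bp: int
    end_bp: int
    lod: float
    n_markers: int

    def overlap_bp(self, start, end):
        """Overlap length (1-based inclusive) with [start, end]."""
        return max(0, min(self.end_bp, end) - max(self.start_bp, start) + 1)


def filter_founder_sites(raw, chrom_length_bp=0,
                         cm_per_mb=DEFAULT_CM_PER_MB):
    """Filter a raw founder call table to the reconstruction reference.

    ``raw`` is a DataFrame with columns ``chrom``, ``pos``, optionally
    ``cm``, and one genotype column per founder label (strings like
    "0/0", "0/1", "1/1", "./.", or "1/2" for multiallelic calls).
    Retained sites are biallelic, homozygous in every founder, and
    segregating (not all-reference, not all-alternate); input order is
    preserved.  Raises if nothing survives.
    """
    geno = raw[list(FOUNDER_LABELS)].to_numpy(dtype=object)
    n = len(raw)
    alleles = np.zeros((n, 8), dtype=np.int16)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        for j in range(8):
            g = str(geno[i, j]).replace("|", "/")
            parts = g.split("/")
            if len(parts) != 2 or parts[0] != parts[1] or parts[0] == ".":
                keep[i] = False  # het or missing in some founder
                break
            a = int(parts[0])
            if a > 1:
                keep[i] = False  # multiallelic
                break
            alleles[i, j] = a
        if keep[i]:
            s = alleles[i].sum()
            if s == 0 or s == 8:
                keep[i] = False  # non-segregating
    if not keep.any():
        raise ValueError(
            f"no sites survive founder filtering (0 of {n} retained)")
    sub = raw.loc[keep]
    pos = sub["pos"].to_numpy(dtype=np.int64)
    cm = (sub["cm"].to_numpy(dtype=float) if "cm" in sub.columns
          else pos * (cm_per_mb / 1e6))
    return FounderHaplotypePanel(
        chrom=str(sub["chrom"].iloc[0]), positions=pos, cm=cm,
        alleles=alleles[keep].astype(np.uint8),
        chrom_length_bp=chrom_length_bp or int(pos[-1])).validate()


def select_grid(panel, n_grid):
    """Indices of markers nearest ``n_grid`` evenly spaced positions.

    Targets are evenly spaced over the chromosome span; for each target
    the nearest panel marker (ties to the left) is chosen and duplicates
    are collapsed, so fewer than ``n_grid`` indices may be returned.
    """
    if n_grid < 1:
        raise ValueError("n_grid must be >= 1")
    if n_grid > panel.n_markers:
        raise ValueError("n_grid exceeds marker count")
    if n_grid == panel.n_markers:
        return np.arange(panel.n_markers)
    lo = panel.positions[0]
    hi = panel.positions[-1]
    if n_grid == 1:
        targets = np.array([(lo + hi) / 2.0])
    else:
        targets = np.linspace(lo, hi, n_grid)
    right = np.searchsorted(panel.positions, targets)
    left = np.clip(right - 1, 0, panel.n_markers - 1)
    right = np.clip(right, 0, panel.n_markers - 1)
    d_left = np.abs(panel.positions[left] - targets)
    d_right = np.abs(panel.positions[right] - targets)
    idx = np.where(d_left <= d_right, left, right)
    return np.unique(idx)


def _max_subarray(scores, positions, lo, hi):
    """Best-scoring subinterval of scores[lo..hi] by Kadane's scan.

    Ties on score prefer the longer bp span, then the leftmost start.
    Returns (start, end, score) or None if every subinterval is <= 0.
    """
    best = None  # (score, span, start, end)
    cur = 0.0
    cur_start = lo
    for k in range(lo, hi + 1):
        if cur <= 0:
            cur = scores[k]
            cur_start = k
        else:
            cur += scores[k]
        if cur > 0:
            span = positions[k] - positions[cur_start]
            cand = (cur, span, cur_start, k)
            if (best is None or cand[0] > best[0] + 1e-12
                    or (abs(cand[0] - best[0]) <= 1e-12
                        and cand[1] > best[1])):
                best = cand
    if best is None:
        return None
    return best[2], best[3], best[0]


def maximal_segments(scores, positions):
    """Disjoint positive-scoring segments by recursive max-then-split.

    The highest-scoring subinterval is taken, then the procedure recurses
    on the flanks; all segments with positive score are returned sorted
    by start.  The decomposition is independent of any LOD threshold, so
    filtering afterwards is monotone in the threshold.
    """
    out = []
    stack = [(0, len(scores) - 1)]
    while stack:
        lo, hi = stack.pop()
        if lo > hi:
            continue
        hit = _max_subarray(scores, positions, lo, hi)
        if hit is None:
            continue
        s, e, score = hit
        out.append((s, e, score))
        stack.append((lo, s - 1))
        stack.append((e + 1, hi))
    return sorted(out)


def ibd_marker_scores(panel, ia, ib, err):
    """Per-marker log10 LR for founders ia, ib being IBD.

    At marker m with founder alternate-allele frequency p1 (over the 8
    founders) the chance two random founders match by state is
    p_match = p0^2 + p1^2; a match scores log10((1-err)/p_match) and a
    mismatch log10(err/(1-p_match)).
    """
    p1 = panel.alleles.mean(axis=1)
    p_match = p1 ** 2 + (1 - p1) ** 2
    match = panel.alleles[:, ia] == panel.alleles[:, ib]
    return np.where(match,
                    np.log10((1 - err) / p_match),
                    np.log10(err / (1 - p_match)))


def find_ibd_segments(panel, min_lod=10.0, err=0.002):
    """Detect IBD segments between every founder pair.

    For each of the 28 founder pairs the per-marker LOD scores are
    decomposed into maximal positive-scoring runs; runs with total LOD
    >= ``min_lod`` are reported with their bp span.  Segments for a pair
    never overlap, and lowering ``min_lod`` only adds segments.
    """
    if min_lod <= 0:
        raise ValueError("min_lod must be positive")
    if not 0 < err < 0.5:
        raise ValueError("err must be in (0, 0.5)")
    segments = []
    labels = panel.founder_labels
    for ia in range(panel.n_founders):
        for ib in range(ia + 1, panel.n_founders):
            scores = ibd_marker_scores(panel, ia, ib, err)
            for s, e, lod in maximal_segments(scores, panel.positions):
                if lod >= min_lod:
                    segments.append(IBDSegment(
                        founder_pair=(labels[ia], labels[ib]),
                        chrom=panel.chrom,
                        start_bp=int(panel.positions[s]),
                        end_bp=int(panel.positions[e]),
                        lod=float(lod), n_markers=e - s + 1))
    segments.sort(key=lambda s: (s.start_bp, s.founder_pair))
    return segments
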