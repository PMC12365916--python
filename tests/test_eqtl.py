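"""Trait preparation, the haplotype-regression scan and peak calling."""

import numpy as np
import pytest
from scipy import stats as sps

import dohaplo as dh
from dohaplo import eqtl


class TestFilterGenes:
    def test_brute_force_fixture(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 60, size=(120, 10))
        counts[:, 3] = 0                      # low total
        counts[:, 7] = 29                     # single unique value
        keep = dh.filter_genes(counts, min_total=3000, min_unique=100)
        want = [g for g in range(10)
                if counts[:, g].sum() > 3000
                and len(np.unique(counts[:, g])) >= 100]
        assert list(keep) == want

    def test_total_boundary_is_strict(self):
        counts = np.zeros((100, 2), dtype=int)
        counts[:, 0] = np.arange(100)         # total 4950, 100 unique
        counts[:30, 1] = 100                  # total 3000 exactly
        keep = dh.filter_genes(counts, min_total=3000, min_unique=2)
        assert list(keep) == [0]

    def test_uniqueness_veto(self):
        counts = np.full((50, 1), 10_000)
        assert len(dh.filter_genes(counts, min_total=3000,
                                   min_unique=100)) == 0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            dh.filter_genes(np.zeros((0, 0)))


class TestRankz:
    def test_three_values_closed_form(self):
        out = dh.rankz([10.0, 3.0, 7.0])
        want = sps.norm.ppf([5 / 6, 1 / 6, 3 / 6])
        assert np.allclose(out, want)
        assert out[1] == pytest.approx(-0.9674216, abs=1e-6)

    def test_symmetry_mean_zero(self):
        rng = np.random.default_rng(1)
        out = dh.rankz(rng.normal(size=101))
        assert abs(out.mean()) < 1e-12

    def test_monotone(self):
        rng = np.random.default_rng(2)
        v = np.sort(rng.normal(size=50))
        assert np.all(np.diff(dh.rankz(v)) > 0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            dh.rankz(np.ones(10))


@pytest.fixture(scope="module")
def probs_by_chrom():
    rng = np.random.default_rng(3)
    return {c: rng.dirichlet(np.ones(8), size=(6, 40))
            for c in ("1", "2", "3")}


class TestLocoKinship:
    def test_duplicate_samples_share_self_kinship(self):
        rng = np.random.default_rng(4)
        base = rng.dirichlet(np.ones(8), size=(1, 30))
        probs = {c: np.concatenate([base, base]) for c in ("1", "2")}
        K = dh.loco_kinship(probs)["1"]
        assert K[0, 1] == pytest.approx(K[0, 0])

    def test_decomposition_identity(self, probs_by_chrom):
        """LOCO matrices recombine to the all-marker kinship."""
        Ks = dh.loco_kinship(probs_by_chrom)
        m = {c: p.shape[1] for c, p in probs_by_chrom.items()}
        M = sum(m.values())
        all_k = sum(
            np.einsum("mif,mjf->ij", p.transpose(1, 0, 2),
                      p.transpose(1, 0, 2))
            for p in probs_by_chrom.values()) / M
        # K_all = (K_loco(c) * (M - m_c) + K_c * m_c) / M for any c
        c = "2"
        Kc = np.einsum(
            "mif,mjf->ij", probs_by_chrom[c].transpose(1, 0, 2),
            probs_by_chrom[c].transpose(1, 0, 2)) / m[c]
        recombined = (Ks[c] * (M - m[c]) + Kc * m[c]) / M
        assert np.allclose(recombined, all_k, atol=1e-12)

    def test_symmetric(self, probs_by_chrom):
        for K in dh.loco_kinship(probs_by_chrom).values():
            assert np.allclose(K, K.T, atol=1e-12)

    def test_single_chromosome_rejected(self):
        with pytest.raises(ValueError, match="LOCO"):
            dh.loco_kinship({"1": np.zeros((2, 5, 8))})


class TestScan1:
    def _toy(self, seed=5, n=120, M=30):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(8), size=(n, M))
        covar = np.stack([rng.integers(0, 2, n),
                          rng.integers(40, 46, n)], axis=1)
        return rng, probs, covar

    def test_closed_form_on_toy_regression(self):
        """LOD equals (n/2) log10(RSS0/RSS1) computed by hand."""
        rng, probs, covar = self._toy()
        n = probs.shape[0]
        y = dh.rankz(rng.normal(size=n))
        lods = dh.scan1(y, probs, covar)
        X0 = np.column_stack([np.ones(n), covar])
        rss0 = np.sum((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0])**2)
        m = 7
        X1 = np.column_stack([X0, probs[:, m, :-1]])
        rss1 = np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0])**2)
        assert lods[m] == pytest.approx((n / 2) * np.log10(rss0 / rss1),
                                        rel=1e-10)

    def test_null_trait_rarely_reaches_threshold(self):
        rng, probs, covar = self._toy(seed=6, n=100, M=60)
        exceed = 0
        for _ in range(100):
            y = dh.rankz(rng.normal(size=100))
            if dh.scan1(y, probs, covar).max() >= 8:
                exceed += 1
        assert exceed <= 5

    def test_perfect_signal_unbounded_lod(self):
        _, probs, covar = self._toy(seed=7)
        y = 3.0 * probs[:, 4, 0]
        lods = dh.scan1(y, probs, covar)
        assert np.argmax(lods) == 4
        assert lods[4] > 50

    def test_trait_location_scale_invariance(self):
        rng, probs, covar = self._toy(seed=8)
        y = rng.normal(size=probs.shape[0])
        a = dh.scan1(y, probs, covar)
        b = dh.scan1(5.0 * y + 11.0, probs, covar)
        assert np.allclose(a, b, atol=1e-8)

    def test_kinship_mode_close_to_ols_for_unrelated(self):
        rng, probs, covar = self._toy(seed=9, n=80, M=20)
        y = 4.0 * probs[:, 3, 2] + rng.normal(0, 0.5, size=80)
        K = np.eye(80)
        a = dh.scan1(y, probs, covar, kinship=K)
        b = dh.scan1(y, probs, covar)
        # with identity kinship the LMM collapses to OLS
        assert np.allclose(a, b, atol=0.05)
        assert np.argmax(a) == np.argmax(b) == 3

    def test_rank_deficient_covariates_rejected(self):
        _, probs, _ = self._toy()
        bad = np.ones((probs.shape[0], 2))
        with pytest.raises(ValueError, match="rank-deficient"):
            dh.scan1(np.zeros(probs.shape[0]), probs, bad)


class TestFindPeaks:
    def test_flat_curve_below_threshold(self):
        assert dh.find_peaks(np.full(10, 3.0), np.arange(10)) == []

    def test_hand_walked_interval(self):
        peaks = dh.find_peaks(np.array([2.0, 9.0, 8.0, 2.0]),
                              np.array([10, 20, 30, 40]))
        assert len(peaks) == 1
        p = peaks[0]
        assert p.peak_bp == 20 and p.lod == 9.0
        assert (p.ci_lo, p.ci_hi) == (20, 30)  # markers within 1.5 of 9

    def test_peakdrop_merging_boundary(self):
        pos = np.arange(5) * 100
        merged = dh.find_peaks(np.array([2, 10, 6, 10, 2.0]), pos)
        assert len(merged) == 1  # valley drop 4 < peakdrop 5
        split = dh.find_peaks(np.array([2, 10, 4, 10, 2.0]), pos)
        assert len(split) == 2   # valley drop 6 >= 5

    def test_interval_contains_peak(self):
        rng = np.random.default_rng(10)
        lods = np.abs(rng.normal(0, 6, size=80))
        pos = np.arange(80) * 1000
        for p in dh.find_peaks(lods, pos):
            assert p.ci_lo <= p.peak_bp <= p.ci_hi


class TestLocalEqtl:
    def _peak(self, gene, bp, lod=9.0, chrom="1"):
        return eqtl.EqtlPeak(gene=gene, chrom=chrom, peak_bp=bp, lod=lod,
                             ci_lo=bp - 1000, ci_hi=bp + 1000)

    def test_two_mb_boundary_inclusive(self):
        peaks = [self._peak("g", 12_000_000)]
        _, sel = dh.local_eqtl(peaks, {"g": 10_000_000})
        assert "g" in sel

    def test_other_chromosome_not_local(self):
        peaks = [self._peak("g", 10_000_000, chrom="2")]
        _, sel = dh.local_eqtl(peaks, {"g": 10_000_000},
                               gene_chroms={"g": "1"})
        assert sel == {}

    def test_nearest_local_peak_selected(self):
        peaks = [self._peak("g", 11_500_000, lod=20.0),
                 self._peak("g", 10_500_000, lod=9.0)]
        _, sel = dh.local_eqtl(peaks, {"g": 10_000_000})
        assert sel["g"].peak_bp == 10_500_000


class TestMatchEqtl:
    def _cat(self, entries):
        return {g: eqtl.EqtlPeak(gene=g, chrom="1", peak_bp=bp, lod=lod,
                                 ci_lo=lo, ci_hi=hi)
                for g, bp, lod, lo, hi in entries}

    def test_identical_catalogs_all_match_with_zero_deltas(self):
        cat = self._cat([("g1", 100, 9.0, 50, 150),
                         ("g2", 500, 12.0, 400, 600)])
        pairs, ua, ub = dh.match_eqtl(cat, dict(cat))
        assert len(pairs) == 2 and not ua and not ub
        assert all(p["delta_lod"] == 0 and p["delta_peak_bp"] == 0
                   for p in pairs)

    def test_disjoint_intervals_unmatched(self):
        a = self._cat([("g", 100, 9.0, 50, 150)])
        b = self._cat([("g", 500, 9.0, 400, 600)])
        pairs, ua, ub = dh.match_eqtl(a, b)
        assert pairs == [] and ua == ["g"] and ub == ["g"]

    def test_overlap_oracle_on_designed_fixture(self):
        a = self._cat([(f"g{i}", 100 * i, 9.0, 100 * i - 30,
                        100 * i + 30) for i in range(1, 6)])
        b = self._cat([("g1", 130, 9.0, 100, 160),
                       ("g2", 300, 9.0, 231, 400),
                       ("g3", 305, 9.0, 270, 340),
                       ("g4", 800, 9.0, 700, 900),
                       ("g5", 505, 9.0, 470, 530)])
        pairs, _, _ = dh.match_eqtl(a, b)
        def overlaps(x, y):
            return x.ci_lo <= y.ci_hi and y.ci_lo <= x.ci_hi
        want = [g for g in a if g in b and overlaps(a[g], b[g])]
        assert [p["gene"] for p in pairs] == want

    def test_duplicate_gene_rejected(self):
        # duplicates cannot occur in a dict; simulate via list-backed map
        class Dup(dict):
            def __iter__(self):
                return iter(["g", "g"])
        with pytest.raises(ValueError, match="duplicate"):
            dh.match_eqtl(Dup(), {})


class TestAlleleEffects:
    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(11)
        probs = rng.dirichlet(np.ones(8), size=200)
        y = 2.0 * probs[:, 0]
        eff = dh.allele_effects(y, probs)
        assert np.argmax(eff) == 0
        want = np.zeros(8)
        want[0] = 2.0
        assert np.allclose(eff, want - want.mean(), atol=1e-8)

    def test_identical_genotypes_cosine_one(self):
        rng = np.random.default_rng(12)
        probs = rng.dirichlet(np.ones(8), size=150)
        y = probs @ np.array([1.0, -1, 0.5, 0, 0, -0.5, 0, 0]) \
            + rng.normal(0, 0.3, 150)
        e1 = dh.allele_effects(y, probs)
        e2 = dh.allele_effects(y, probs.copy())
        assert dh.cosine_similarity(e1 + 2, e2 + 2) == pytest.approx(
            1.0, abs=1e-6)

    def test_recovery_cosine_above_09_in_most_replicates(self):
        """Diplotype-style probability rows (two founders at 1/2 each),
        planted bipartite effects, unit noise: cosine of estimated vs
        true effects exceeds 0.9 in at least 80% of replicates."""
        rng = np.random.default_rng(13)
        beta = np.array([1.0, 1, 1, 1, -1, -1, -1, -1])
        wins = 0
        for _ in range(25):
            probs = np.zeros((200, 8))
            picks = rng.integers(0, 8, size=(200, 2))
            for s in range(200):
                probs[s, picks[s, 0]] += 0.5
                probs[s, picks[s, 1]] += 0.5
            y = probs @ beta + rng.normal(0, 1.0, 200)
            eff = dh.allele_effects(y, probs)
            c = float(np.dot(eff, beta)
                      / np.linalg.norm(eff) / np.linalg.norm(beta))
            wins += c > 0.9
        assert wins >= 20  # >= 80% of replicates

    def test_collinear_probabilities_rejected(self):
        probs = np.zeros((50, 8))
        probs[:, 0] = 0.5
        probs[:, 1] = 0.5
        with pytest.raises(ValueError, match="collinear"):
            dh.allele_effects(np.random.default_rng(14).normal(size=50),
                              probs)
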