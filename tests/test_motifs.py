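"""MI motif discovery, enrichment statistics, regulon correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from greyhound.motifs import (
    MotifModel,
    discover_motifs,
    matched_background,
    motif_hits,
    motif_rbp_enrichment,
    mutual_information,
    permutation_z,
    ranked_list_enrichment,
    regulon_correlation,
)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestMutualInformation:
    def test_perfect_binary_association_is_one_bit(self):
        labels = np.array([0] * 10 + [1] * 10)
        hits = labels.astype(bool)
        assert mutual_information(labels, hits) == pytest.approx(1.0)

    def test_matches_bruteforce_contingency_formula(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, 200)
        hits = rng.random(200) < 0.3
        mi = mutual_information(labels, hits)
        # brute force sum over the table
        brute = 0.0
        n = len(labels)
        for h in (False, True):
            for l in range(3):
                p = np.mean((hits == h) & (labels == l))
                if p > 0:
                    brute += p * np.log2(p / (np.mean(hits == h) * np.mean(labels == l)))
        assert mi == pytest.approx(brute, abs=1e-12)

    def test_symmetry_and_permutation_invariance(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 100)
        hits = rng.random(100) < 0.4
        assert mutual_information(labels, hits) == pytest.approx(
            mutual_information(hits, labels)
        )
        perm = rng.permutation(100)
        assert mutual_information(labels[perm], hits[perm]) == pytest.approx(
            mutual_information(labels, hits)
        )

    def test_nonnegative(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            labels = rng.integers(0, 4, 50)
            hits = rng.random(50) < 0.5
            if len(np.unique(labels)) < 2:
                continue
            assert mutual_information(labels, hits) >= 0

    def test_single_category_errors(self):
        with pytest.raises(ValueError):
            mutual_information(np.zeros(10), np.ones(10, dtype=bool))


class TestPermutationZ:
    def test_null_z_is_small(self):
        rng = np.random.default_rng(3)
        n_large = 0
        n_runs = 40
        for i in range(n_runs):
            labels = rng.integers(0, 2, 100)
            hits = rng.random(100) < 0.3
            z = permutation_z(labels, hits, n_perm=200, seed=i)
            if abs(z) >= 3:
                n_large += 1
        assert n_large / n_runs <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_runs)

    def test_planted_association_gives_large_z(self):
        labels = np.array([0] * 100 + [1] * 100)
        hits = labels.astype(bool)
        assert permutation_z(labels, hits, n_perm=500, seed=0) > 10

    def test_stable_under_more_permutations(self):
        rng = np.random.default_rng(4)
        labels = np.array([0] * 60 + [1] * 60)
        hits = np.concatenate([rng.random(60) < 0.5, rng.random(60) < 0.8])
        z1 = permutation_z(labels, hits, n_perm=500, seed=1)
        z2 = permutation_z(labels, hits, n_perm=1000, seed=2)
        assert abs(z1 - z2) < 1.0

    def test_degenerate_hits_give_inf_sentinel_or_zero(self):
        labels = np.array([0] * 5 + [1] * 5)
        z = permutation_z(labels, np.ones(10, dtype=bool), n_perm=100, seed=0)
        assert z == 0.0 or np.isinf(z)


class TestDiscoverMotifs:
    def test_planted_kmer_recovered_first(self):
        rng = np.random.default_rng(5)
        fg, bg = [], []
        for _ in range(100):
            s = _random_seq(rng, 40)
            if rng.random() < 0.4:
                pos = rng.integers(0, 34)
                s = s[:pos] + "ATAATA" + s[pos + 6 :]
            fg.append(s)
        for _ in range(200):
            s = _random_seq(rng, 40)
            if rng.random() < 0.02:
                pos = rng.integers(0, 34)
                s = s[:pos] + "ATAATA" + s[pos + 6 :]
            bg.append(s)
        motifs = discover_motifs(fg, bg, seed=0)
        assert motifs, "no motif discovered"
        top = motifs[0].pattern
        # top pattern overlaps the planted 6-mer (IUPAC consensus allowed)
        expanded = top.replace("N", ".")
        assert any(
            MotifModel(pattern=top).matches("X" * 4 + "ATAATA" + "X" * 4)
            or top[i : i + 4] in "ATAATA"
            for i in range(max(1, len(top) - 3))
        )

    def test_null_foreground_rarely_yields_motifs(self):
        rng = np.random.default_rng(6)
        n_hits = 0
        n_runs = 12
        for run in range(n_runs):
            fg = [_random_seq(rng, 40) for _ in range(60)]
            bg = [_random_seq(rng, 40) for _ in range(120)]
            if discover_motifs(fg, bg, seed=run, n_perm=300):
                n_hits += 1
        assert n_hits <= 2  # ~binomial(12, 0.05) upper band

    def test_label_reversal_preserves_mi(self):
        rng = np.random.default_rng(7)
        fg = []
        for _ in range(50):
            s = _random_seq(rng, 30)
            if rng.random() < 0.5:
                s = "ATAATA" + s[6:]
            fg.append(s)
        bg = [_random_seq(rng, 30) for _ in range(50)]
        seqs = fg + bg
        labels = np.array([1] * 50 + [0] * 50)
        hits = np.array(["ATAATA" in s for s in seqs])
        assert mutual_information(labels, hits) == pytest.approx(
            mutual_information(1 - labels, hits)
        )

    def test_too_few_foreground_or_empty_background(self):
        rng = np.random.default_rng(8)
        seqs = [_random_seq(rng, 30) for _ in range(10)]
        with pytest.raises(ValueError):
            discover_motifs(seqs, seqs, seed=0)
        with pytest.raises(ValueError):
            discover_motifs([_random_seq(rng, 30) for _ in range(25)], [], seed=0)

    def test_iupac_matching(self):
        m = MotifModel(pattern="ATAAWA")
        assert m.matches("ccATAATAcc")
        assert m.matches("ccATAAAAcc")
        assert not m.matches("ccATAACAcc")
        assert m.matches("uuAUAAUAuu")  # RNA alphabet

    def test_motif_invariants(self):
        with pytest.raises(ValueError):
            MotifModel(pattern="ATA")  # too short
        with pytest.raises(ValueError):
            MotifModel(pattern="ATAAXA")  # not IUPAC


class TestMatchedBackground:
    def test_lengths_match_and_regions_excluded(self):
        rng = np.random.default_rng(9)
        seqs = {f"g{i}": _random_seq(rng, 200) for i in range(20)}
        fg = [seqs["g0"][10:40], seqs["g1"][50:75]]
        exclude = {"g0": [(10, 40)], "g1": [(50, 75)]}
        bg = matched_background(fg, seqs, exclude=exclude, per_sequence=5, seed=0)
        assert len(bg) == 10
        assert sorted({len(b) for b in bg}) == [25, 30]


class TestHypergeometricEnrichment:
    def test_matches_exhaustive_enumeration_small_population(self):
        """p(overlap >= k) against enumeration of all subsets, N <= 20."""
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(12)]
        seqs = {g: _random_seq(rng, 30) for g in genes}
        hit_genes = set(genes[:5])
        for g in hit_genes:
            seqs[g] = "ATAATA" + seqs[g][6:]
        salient = {"rbpA": set(genes[2:8])}
        motif = MotifModel(pattern="ATAATA")
        pmat, edges = motif_rbp_enrichment([motif], salient, seqs, all_genes=genes)
        N, K, n = 12, len(motif_hits(motif, seqs)), 6
        obs = len(motif_hits(motif, seqs) & salient["rbpA"])
        total = 0
        favourable = 0
        from math import comb

        for k in range(0, min(K, n) + 1):
            ways = comb(K, k) * comb(N - K, n - k)
            total += ways
            if k >= obs:
                favourable += ways
        assert pmat.loc["rbpA", "ATAATA"] == pytest.approx(favourable / total, rel=1e-10)

    def test_zero_hit_motif_p_one(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(10)]
        seqs = {g: "ACGC" * 10 for g in genes}
        pmat, edges = motif_rbp_enrichment(
            [MotifModel(pattern="TTTTTT")], {"r": set(genes[:3])}, seqs
        )
        assert pmat.loc["r", "TTTTTT"] == 1.0

    def test_bh_q_values_attached(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(15)]
        seqs = {g: _random_seq(rng, 50) for g in genes}
        pmat, edges = motif_rbp_enrichment(
            [MotifModel(pattern="ATAATA"), MotifModel(pattern="TGCATG")],
            {"r1": set(genes[:5]), "r2": set(genes[5:])},
            seqs,
        )
        assert all(np.isfinite(e.q) and e.q >= e.p - 1e-12 for e in edges)


class TestRegulonCorrelation:
    def test_perfect_anticorrelation(self):
        cells = [f"c{i}" for i in range(5)]
        expr = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=cells)
        reg = pd.DataFrame(
            {c: [-expr[c] + 0.01 * g for g in range(6)] for c in cells},
            index=[f"g{g}" for g in range(6)],
        )
        bg = pd.DataFrame(
            np.random.default_rng(0).standard_normal((20, 5)),
            index=[f"b{g}" for g in range(20)], columns=cells,
        )
        rho, p, rhos = regulon_correlation(expr, reg, bg)
        assert rho == pytest.approx(-1.0)
        assert p < 0.01

    def test_null_calibration(self):
        rng = np.random.default_rng(13)
        cells = [f"c{i}" for i in range(6)]
        n_sig = 0
        n_runs = 40
        for run in range(n_runs):
            expr = pd.Series(rng.standard_normal(6), index=cells)
            reg = pd.DataFrame(rng.standard_normal((10, 6)),
                               index=[f"g{i}" for i in range(10)], columns=cells)
            bg = pd.DataFrame(rng.standard_normal((30, 6)),
                              index=[f"b{i}" for i in range(30)], columns=cells)
            _, p, _ = regulon_correlation(expr, reg, bg)
            if p < 0.05:
                n_sig += 1
        assert n_sig / n_runs <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_runs)

    def test_preconditions(self):
        cells = ["c0", "c1"]
        expr = pd.Series([1.0, 2.0], index=cells)
        df = pd.DataFrame(np.ones((6, 2)), columns=cells)
        with pytest.raises(ValueError):
            regulon_correlation(expr, df, df)


class TestRankedListEnrichment:
    @staticmethod
    def _setup(rng, n=120, planted_low=True):
        genes = [f"g{i:03d}" for i in range(n)]
        seqs = {}
        scores = {}
        for i, g in enumerate(genes):
            s = _random_seq(rng, 60)
            score = i / n + rng.normal(0, 0.01)
            if planted_low and i < n // 4:
                s = "ATAATA" + s[6:]
            seqs[g] = s
            scores[g] = score
        return pd.Series(scores), seqs

    def test_low_bin_enrichment_matches_bruteforce_hypergeometric(self):
        rng = np.random.default_rng(14)
        scores, seqs = self._setup(rng)
        res = ranked_list_enrichment(scores, "ATAATA", seqs, n_bins=6, seed=0)
        assert res.per_bin_log10_p[0] > 0  # leftmost bin enriched
        N = len(scores)
        K = res.n_hits
        n_b = res.bin_counts[0]
        k_b = res.bin_hits[0]
        expected = -np.log10(stats.hypergeom.sf(k_b - 1, N, K, n_b))
        assert res.per_bin_log10_p[0] == pytest.approx(expected, rel=1e-10)
        assert res.z_score > 3

    def test_uniform_assignment_small_z(self):
        rng = np.random.default_rng(15)
        n_large = 0
        n_runs = 25
        for run in range(n_runs):
            scores, seqs = self._setup(rng, planted_low=False)
            res = ranked_list_enrichment(scores, "ATAATA", seqs, n_bins=6,
                                         n_perm=300, seed=run)
            if abs(res.z_score) >= 3:
                n_large += 1
        assert n_large <= 3

    def test_single_bin_mi_zero(self):
        rng = np.random.default_rng(16)
        scores, seqs = self._setup(rng, n=30)
        res = ranked_list_enrichment(scores, "ATAATA", seqs, n_bins=1, seed=0)
        assert res.mi == 0.0

    def test_sign_convention_depletion_negative(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i:03d}" for i in range(120)]
        seqs = {}
        scores = {}
        for i, g in enumerate(genes):
            s = _random_seq(rng, 60)
            if i >= 30:  # motif only outside the lowest quarter
                s = "ATAATA" + s[6:]
            seqs[g] = s
            scores[g] = i / 120
        res = ranked_list_enrichment(pd.Series(scores), "ATAATA", seqs, n_bins=4, seed=0)
        assert res.per_bin_log10_p[0] < 0  # depleted in the lowest bin

    def test_tie_break_deterministic(self):
        rng = np.random.default_rng(18)
        genes = [f"g{i:03d}" for i in range(60)]
        seqs = {g: _random_seq(rng, 40) for g in genes}
        scores = pd.Series(0.0, index=genes)  # all tied
        r1 = ranked_list_enrichment(scores, "ATAATA", seqs, n_bins=4, seed=0)
        r2 = ranked_list_enrichment(scores, "ATAATA", seqs, n_bins=4, seed=0)
        assert np.array_equal(r1.bin_hits, r2.bin_hits)
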