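import numpy as np
import pytest

from gdrep import (
    SimConfig,
    build_network,
    call_expanded,
    clustered_proportion,
    convergence_test,
    simulate_repertoire,
    spectrum_similarity,
)
from gdrep.clustering import top_cdr3s

from _oracles import components_oracle, spectrum_oracle
from conftest import random_cdr3


class TestSpectrumSimilarity:
    def test_identical_strings(self):
        assert spectrum_similarity("CASSLGF", "CASSLGF") == pytest.approx(1.0)

    def test_no_shared_triplet(self):
        assert spectrum_similarity("CAAAF", "WGHKY") == 0.0

    def test_hand_enumerated_value(self):
        # shared triplets {CAS, ASS, SSL}, 4 triplets each: 3/4
        assert spectrum_similarity("CASSLG", "CASSLT") == pytest.approx(0.75, abs=1e-15)

    def test_symmetry(self, rng):
        for _ in range(20):
            x = random_cdr3(rng, int(rng.integers(8, 24)))
            y = random_cdr3(rng, int(rng.integers(8, 24)))
            assert spectrum_similarity(x, y) == pytest.approx(spectrum_similarity(y, x))

    def test_short_string_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert spectrum_similarity("CA", "CASSF") == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            x = random_cdr3(rng, int(rng.integers(8, 24)))
            y = random_cdr3(rng, int(rng.integers(8, 24)))
            assert spectrum_similarity(x, y) == pytest.approx(
                spectrum_oracle(x, y), abs=1e-12
            )

    def test_one_iff_proportional_spectra(self):
        # repeated k-mer structure: "ABCABC" spectrum is proportional to itself
        assert spectrum_similarity("CASCASF", "CASCASF") == pytest.approx(1.0)
        assert spectrum_similarity("CASSLGF", "CASSLTF") < 1.0


class TestBuildNetwork:
    def test_three_string_cluster_vs_oracle(self):
        seqs = ["CASSLGASSLGASSF", "CASSLGASSLGASTF", "CWWWWHHHWWWF"]
        net = build_network(seqs, threshold=0.8)
        oracle = components_oracle(seqs, 0.8)
        expected_clusters = sorted(
            [c for c in oracle if len(c) >= 2], key=lambda c: min(c)
        )
        assert sorted(net.clusters, key=lambda c: min(c)) == expected_clusters

    def test_single_node(self):
        net = build_network(["CASSF"])
        assert net.clusters == []
        assert net.singletons == ["CASSF"]

    def test_threshold_one_gives_no_edges(self, rng):
        seqs = [random_cdr3(rng, 14) for _ in range(10)]
        assert build_network(seqs, threshold=1.0).graph.number_of_edges() == 0

    def test_edges_strictly_exceed_threshold(self, rng):
        seqs = [random_cdr3(rng, 12) for _ in range(30)]
        net = build_network(seqs, threshold=0.5)
        assert all(w > 0.5 for _, _, w in net.edge_list())

    def test_edge_count_monotone_in_threshold(self, rng):
        seqs = [random_cdr3(rng, 10) for _ in range(40)]
        counts = [
            build_network(seqs, threshold=t).graph.number_of_edges()
            for t in (0.2, 0.4, 0.6, 0.8)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_components_match_transitive_closure_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 30))
            seqs = list({random_cdr3(rng, int(rng.integers(8, 16))) for _ in range(n)})
            net = build_network(seqs, threshold=0.8)
            oracle = components_oracle(sorted(seqs), 0.8)
            assert sorted(map(sorted, net.clusters)) == sorted(
                map(sorted, (c for c in oracle if len(c) >= 2))
            )


class TestClusteredProportion:
    def test_planted_single_cluster(self):
        base = "CASSLGQWERTYIPASDFGF"  # length 20: one substitution stays > 0.8
        family = [base] + [base[:i] + "Y" + base[i + 1 :] for i in range(5, 9)]
        assert clustered_proportion(family) == 1.0

    def test_random_sequences_match_oracle(self, rng):
        seqs = list({random_cdr3(rng, 14) for _ in range(50)})
        oracle = components_oracle(sorted(seqs), 0.8)
        expected = sum(len(c) for c in oracle if len(c) >= 2) / len(seqs)
        assert clustered_proportion(seqs) == pytest.approx(expected)

    def test_permutation_invariance(self, rng):
        seqs = [random_cdr3(rng, 10) for _ in range(40)]
        shuffled = list(seqs)
        rng.shuffle(shuffled)
        assert clustered_proportion(seqs) == clustered_proportion(shuffled)

    def test_fewer_than_two_sequences(self):
        assert clustered_proportion(["CASSF"]) == 0.0
        assert clustered_proportion([]) == 0.0

    def test_planted_family_fraction_recovered(self, rng):
        # 40 of 100 sequences in 10 mutated-motif families, 60 random
        seqs = []
        for _ in range(10):
            base = random_cdr3(rng, 18)
            seqs.append(base)
            while len(seqs) % 4:
                i = int(rng.integers(1, 17))
                cand = base[:i] + str(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"))) + base[i + 1 :]
                if cand != base and spectrum_similarity(cand, base) > 0.8:
                    seqs.append(cand)
        randoms = [random_cdr3(rng, 14) for _ in range(60)]
        prop = clustered_proportion(seqs + randoms)
        # audit chance collisions among the random background
        background = clustered_proportion(randoms)
        assert prop == pytest.approx(0.40, abs=background + 0.05)

    def test_top_n_selection_by_count(self):
        cfg = SimConfig(n_clones=300, total_reads=30_000, zipf_exponent=1.5, seed=4)
        rep, _ = simulate_repertoire(cfg)
        exp = call_expanded(rep)
        sel = top_cdr3s(exp, top_n=10)
        assert len(sel) <= 10
        counts = {c.cdr3_aa: c.count for c in exp.clonotypes}
        assert min(counts[s] for s in sel) >= max(
            counts[c.cdr3_aa] for c in exp.clonotypes if c.cdr3_aa not in sel
        ) or len(sel) == len(exp.clonotypes)


class TestConvergence:
    def test_planted_convergent_expansion_is_significant(self):
        cfg = SimConfig(
            n_clones=400, total_reads=100_000, zipf_exponent=1.5,
            n_families=10, family_size=4, seed=21,
        )
        rep, _ = simulate_repertoire(cfg)
        exp = call_expanded(rep)
        res = convergence_test(exp, rep, resamples=200, seed=1, top_n=60)
        assert res.empirical_p <= 0.01

    def test_degenerate_expanded_equals_full(self):
        cfg = SimConfig(n_clones=50, total_reads=5000, zipf_exponent=0.0, seed=9)
        rep, _ = simulate_repertoire(cfg)
        exp = call_expanded(rep)  # all clones expanded under equal-ish counts
        res = convergence_test(exp, rep, resamples=20, seed=2, top_n=1000)
        # null draws are the whole repertoire: all equal the observed value
        assert res.empirical_p == 1.0

    def test_empirical_p_formula(self):
        cfg = SimConfig(n_clones=100, total_reads=10_000, seed=3)
        rep, _ = simulate_repertoire(cfg)
        exp = call_expanded(rep)
        res = convergence_test(exp, rep, resamples=50, seed=4, top_n=30)
        expected = (1 + int((res.null_proportions >=
                             res.observed_clustered_proportion - 1e-12).sum())) / 51
        assert res.empirical_p == pytest.approx(expected)

    def test_resamples_validation(self):
        cfg = SimConfig(n_clones=50, total_reads=5000, seed=6)
        rep, _ = simulate_repertoire(cfg)
        with pytest.raises(ValueError):
            convergence_test(call_expanded(rep), rep, resamples=0)
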