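"""Quartet likelihoods, topology selection and outcome classification."""

import itertools
import math

import numpy as np
import pytest

from longbranch.patterns import CLASS_MULT_4, CLASS_NAMES_4, PatternCounts4, _pattern_class, count_patterns
from longbranch.quartet import (
    TOPOLOGIES,
    QuartetML,
    batched_fit_quartet,
    fit_quartet,
    log_likelihood_4,
    newick_3,
    newick_quartet,
    quartet_class_probs,
)
from longbranch.simulate import QuartetTree, SimConfig, simulate_counts_4, true_class_probs

BASES = "ACGT"
NODE_TIPS = {"WY|XZ": ((0, 2), (1, 3)), "WX|YZ": ((0, 1), (2, 3)), "WZ|XY": ((0, 3), (1, 2))}


def brute_force_class_probs_4(topology, lengths):
    """Oracle: explicit loops over 256 patterns x 16 internal-state pairs."""

    def trans(d, same):
        e = 0.0 if math.isinf(d) else math.exp(-4 * d / 3)
        return 0.25 + 0.75 * e if same else 0.25 - 0.25 * e

    (a1, a2), (b1, b2) = NODE_TIPS[topology]
    agg = {c: 0.0 for c in CLASS_NAMES_4}
    for pat in itertools.product(BASES, repeat=4):
        p = 0.0
        for u in BASES:
            for v in BASES:
                p += (
                    0.25
                    * trans(lengths[a1], u == pat[a1])
                    * trans(lengths[a2], u == pat[a2])
                    * trans(lengths[4], u == v)
                    * trans(lengths[b1], v == pat[b1])
                    * trans(lengths[b2], v == pat[b2])
                )
        agg[_pattern_class(pat)] += p
    return np.array([agg[c] for c in CLASS_NAMES_4])


class TestQuartetProbs:
    @pytest.mark.parametrize("topology", TOPOLOGIES)
    def test_sum_to_one(self, topology):
        e = [np.array([x]) for x in (0.3, 0.8, 1.0, 0.0, 0.5)]
        p = quartet_class_probs(topology, e)[0]
        assert (p * CLASS_MULT_4).sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force(self, rng):
        for i in range(12):
            topology = TOPOLOGIES[i % 3]
            lengths = rng.uniform(0.01, 2.5, 5)
            oracle = brute_force_class_probs_4(topology, lengths)
            e = [np.array([math.exp(-4 * d / 3)]) for d in lengths]
            mine = quartet_class_probs(topology, e)[0] * CLASS_MULT_4
            assert mine == pytest.approx(oracle, abs=1e-12)

    def test_unknown_topology_rejected(self):
        with pytest.raises(ValueError):
            quartet_class_probs("WW|XX", [np.array([0.5])] * 5)


class TestLogLikelihood4:
    def test_constant_data_all_zero_branches(self):
        counts = PatternCounts4((50,) + (0,) * 14)  # 'xxxx' is first class
        assert CLASS_NAMES_4[0] == "xxxx"
        assert log_likelihood_4(counts, "WY|XZ", [0] * 5) == pytest.approx(
            -50 * math.log(4)
        )

    def test_matches_brute_force_on_random_parameters(self, rng):
        for i in range(100):
            topology = TOPOLOGIES[i % 3]
            lengths = rng.uniform(0.01, 3.0, 5)
            counts = PatternCounts4(tuple(rng.integers(0, 20, 15)))
            oracle = brute_force_class_probs_4(topology, lengths) / CLASS_MULT_4
            expected = float(np.sum(counts.as_array() * np.log(oracle)))
            assert log_likelihood_4(counts, topology, lengths) == pytest.approx(
                expected, abs=1e-10
            )

    def test_monte_carlo_frequencies(self):
        # sequence-level simulation oracle against the class probabilities
        from longbranch.simulate import simulate_alignment

        cfg = SimConfig(QuartetTree(0.8), n=100_000, reps=1, seed=11)
        aln = simulate_alignment(cfg)
        counts = count_patterns([aln[t] for t in "WXYZ"]).as_array()
        p = true_class_probs(cfg)
        se = np.sqrt(p * (1 - p) / cfg.n)
        assert (np.abs(counts / cfg.n - p) < 3.5 * se + 1e-9).all()

    def test_bad_inputs(self):
        counts = PatternCounts4((10,) + (0,) * 14)
        with pytest.raises(ValueError):
            log_likelihood_4(counts, "bad", [0.1] * 5)
        with pytest.raises(ValueError):
            log_likelihood_4(counts, "WY|XZ", [0.1] * 4)


class TestQuartetFit:
    def test_consistency_at_expected_counts(self):
        tree = QuartetTree(0.5)
        p = true_class_probs(SimConfig(tree, n=1, reps=1))
        fit = fit_quartet(PatternCounts4(tuple(np.round(p * 2e5).astype(int))), seed=0)
        assert fit.winner.topology == "WY|XZ"
        assert fit.label == "c"
        assert fit.winner.branch_lengths == pytest.approx(
            tree.branch_lengths, abs=2e-3
        )
        assert fit.y_frac == pytest.approx(1 / 3, abs=0.01)
        assert fit.z_frac == pytest.approx(2 / 3, abs=0.01)

    def test_star_data_labelled_f_with_zero_separation(self):
        # counts from a star tree (internal branch zero): y = 0
        tree = QuartetTree(0.4, y_pos=0.5, z_pos=0.5)
        p = true_class_probs(SimConfig(tree, n=1, reps=1))
        fit = fit_quartet(PatternCounts4(tuple(np.round(p * 1e5).astype(int))), seed=0)
        assert fit.label == "f"
        assert fit.y_sep == 0.0

    def test_winner_not_beaten_by_coarse_grid(self, rng):
        cfg = SimConfig(QuartetTree(1.0), n=500, reps=2, seed=21)
        counts = simulate_counts_4(cfg)
        out = batched_fit_quartet(counts, restarts=3, seed=1)
        g = np.linspace(1e-3, 4, 6)
        for r in range(2):
            for ti, topo in enumerate(TOPOLOGIES):
                best = max(
                    log_likelihood_4(PatternCounts4(tuple(counts[r])), topo, bl)
                    for bl in itertools.product(g, repeat=5)
                )
                assert out["loglik"][ti, r] >= best - 1e-6

    def test_determinism(self):
        cfg = SimConfig(QuartetTree(1.5), n=500, reps=3, seed=5)
        counts = simulate_counts_4(cfg)
        a = batched_fit_quartet(counts, seed=9)
        b = batched_fit_quartet(counts, seed=9)
        assert (a["winner"] == b["winner"]).all()
        assert a["loglik"] == pytest.approx(b["loglik"], abs=0)

    def test_model_interface(self):
        cfg = SimConfig(QuartetTree(0.3), n=400, reps=1, seed=2)
        counts = PatternCounts4(tuple(simulate_counts_4(cfg)[0]))
        fit = QuartetML(counts).fit(seed=0)
        assert fit.winner.loglik == max(r.loglik for r in fit.per_topology)
        assert "outcome" in fit.summary()


class TestNewick:
    def test_three_taxon(self):
        s = newick_3((0.1, 0.0, math.inf))
        assert s.startswith("(") and s.endswith(");")
        assert "B:0.0" in s and "infinite=true" in s

    def test_quartet_groups_split_pairs(self):
        s = newick_quartet("WY|XZ", (0.1, 0.2, 0.3, 0.4, 0.05))
        assert "W:" in s and s.index("Y:") < s.index("X:")
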