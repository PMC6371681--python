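"""Three-taxon ML: numeric search, analytic boundary maxima, workflow."""

import math

import numpy as np
import pytest

from longbranch.ml import (
    ThreeTaxonML,
    batched_confirm_infinite,
    batched_numeric_ml_3,
    clock_plane_solution,
    confirm_infinite,
    global_boundary_solution,
    local_boundary_maxima,
    ml_workflow,
    numeric_ml_3,
    position_on_path,
)
from longbranch.patterns import (
    INF,
    PatternCounts3,
    _class_probs_3_from_e,
    log_likelihood_3,
    pattern_class_probs_3,
)


def grid_max_loglik(counts, upper=5.0, k=40):
    """Brute-force likelihood grid oracle over [0, upper]^3."""
    g = np.exp(-4 * np.linspace(1e-4, upper, k) / 3)
    EA, EB, EC = np.meshgrid(g, g, g, indexing="ij")
    logp = np.log(_class_probs_3_from_e(EA, EB, EC))
    return float((logp * np.asarray(counts)).sum(axis=-1).max())


class TestNumericML:
    def test_recovers_truth_at_expected_counts(self):
        p = pattern_class_probs_3((0.1, 0.1, 0.1))
        lengths, _ = batched_numeric_ml_3((p * 1e5)[None, :], seed=0)
        assert lengths[0] == pytest.approx([0.1, 0.1, 0.1], abs=1e-3)

    def test_constant_data_collapses_to_origin(self):
        res = numeric_ml_3(PatternCounts3(100, 0, 0, 0, 0), seed=0)
        assert res.branch_lengths == (0.0, 0.0, 0.0)
        assert res.loglik == pytest.approx(-100 * math.log(4))

    def test_never_beaten_by_grid_oracle(self, random_counts):
        _, ll = batched_numeric_ml_3(random_counts, seed=1)
        for row, l in zip(random_counts, ll):
            assert l >= grid_max_loglik(row) - 1e-9

    def test_exact_zero_boundary_detection(self):
        # data violating the triangle inequality: d_A must sit exactly at 0
        p = pattern_class_probs_3((0.0, 0.15, 1.8))
        counts = np.random.default_rng(3).multinomial(300, p, size=30)
        lengths, _ = batched_numeric_ml_3(counts, seed=0)
        assert (lengths == 0.0).any()
        assert lengths.min() == 0.0  # exact, not merely small

    def test_input_validation(self):
        with pytest.raises(ValueError):
            batched_numeric_ml_3(np.zeros((2, 5)))
        with pytest.raises(ValueError):
            batched_numeric_ml_3(-np.ones((1, 5)))


class TestGlobalBoundary:
    def test_all_constant(self):
        res = global_boundary_solution(PatternCounts3(100, 0, 0, 0, 0))
        assert res.branch_lengths == (0, 0, 0)
        assert res.loglik == pytest.approx(-100 * math.log(4))

    def test_identical_pair_saturated_third(self):
        res = global_boundary_solution(PatternCounts3(20, 80, 0, 0, 0))
        assert res.branch_lengths == (0.0, 0.0, INF)
        assert res.loglik == pytest.approx(-100 * math.log(16))

    def test_identical_pair_estimable_third(self):
        res = global_boundary_solution(PatternCounts3(70, 30, 0, 0, 0))
        assert res.branch_lengths[:2] == (0.0, 0.0)
        assert res.branch_lengths[2] == pytest.approx(0.383119, abs=1e-6)
        # 1-D scan oracle along the free edge
        grid = np.linspace(1e-4, 3, 2000)
        lls = [
            log_likelihood_3(PatternCounts3(70, 30, 0, 0, 0), (0, 0, d))
            for d in grid
        ]
        assert res.loglik >= max(lls) - 1e-9

    def test_other_identical_pairs(self):
        res = global_boundary_solution(PatternCounts3(70, 0, 30, 0, 0))
        assert res.branch_lengths == pytest.approx((0.0, 0.383119, 0.0), abs=1e-6)
        res = global_boundary_solution(PatternCounts3(20, 0, 0, 80, 0))
        assert res.branch_lengths == (INF, 0.0, 0.0)

    def test_none_when_no_global_form_applies(self):
        assert global_boundary_solution(PatternCounts3(50, 20, 20, 5, 5)) is None

    def test_never_beaten_by_numeric_search(self, rng):
        # random count vectors satisfying the identical-pair conditions
        n_xxx = rng.integers(0, 101, size=1000)
        counts = np.zeros((1000, 5), dtype=int)
        counts[:, 0] = n_xxx
        counts[:, 1] = 100 - n_xxx
        _, ll = batched_numeric_ml_3(counts, restarts=3, seed=1)
        for row, l in zip(counts, ll):
            g = global_boundary_solution(PatternCounts3(*row))
            assert g.loglik >= l - 1e-6


class TestLocalBoundary:
    def test_infinite_family_sum(self):
        # n_xxx + n_yxx = 85 > n/4: candidate (inf, a, b) with a+b fixed
        c = PatternCounts3(45, 15, 0, 40, 0)
        cands = [r for r in local_boundary_maxima(c) if r.branch_lengths[0] == INF
                 and not math.isinf(r.branch_lengths[1])]
        assert cands, "expected an (inf, a, b) candidate"
        a, b = cands[0].branch_lengths[1], cands[0].branch_lengths[2]
        assert a + b == pytest.approx(-0.75 * math.log(0.8), abs=1e-12)

    def test_all_infinite_candidate_always_present(self):
        c = PatternCounts3(5, 5, 5, 5, 80)
        cands = local_boundary_maxima(c)
        allinf = [r for r in cands if r.branch_lengths == (INF, INF, INF)]
        assert len(allinf) == 1
        assert allinf[0].loglik == pytest.approx(-100 * math.log(64))

    def test_only_all_infinite_when_conditions_fail(self):
        # every pair's matches <= n/4
        c = PatternCounts3(5, 5, 5, 5, 80)
        assert len(local_boundary_maxima(c)) == 1

    def test_analytic_loglik_consistent_with_likelihood_function(self):
        c = PatternCounts3(60, 20, 10, 8, 2)
        for r in local_boundary_maxima(c):
            assert r.loglik == pytest.approx(
                log_likelihood_3(c, r.branch_lengths), abs=1e-10
            )


class TestConfirmInfinite:
    def test_saturated_third_branch_confirmed(self):
        c = PatternCounts3(20, 80, 0, 0, 0)
        res = confirm_infinite(c, numeric_ml_3(c, seed=0))
        assert INF in res.branch_lengths
        assert res.provenance == "analytic-infinite"

    def test_finite_optimum_retained(self):
        p = pattern_class_probs_3((0.1, 0.1, 0.5))
        c = PatternCounts3(*np.random.default_rng(0).multinomial(300, p))
        numeric = numeric_ml_3(c, seed=0)
        res = confirm_infinite(c, numeric)
        assert res is numeric

    def test_batched_matches_scalar(self, rng):
        p = pattern_class_probs_3((0.1, 0.1, 2.0))
        counts = rng.multinomial(300, p, size=40)
        lengths, ll = batched_numeric_ml_3(counts, seed=5)
        L, LL, conf = batched_confirm_infinite(counts, lengths, ll)
        for i in range(40):
            c = PatternCounts3(*counts[i])
            scalar = confirm_infinite(c, numeric_ml_3(c, seed=5))
            assert conf[i] == (scalar.provenance == "analytic-infinite")
            if conf[i]:
                assert np.isinf(L[i]).any()
                assert LL[i] == pytest.approx(scalar.loglik, abs=1e-9)


class TestClockPlane:
    def test_symmetric_data_center_or_edge(self):
        p = pattern_class_probs_3((0.1, 0.1, 1.0))
        c = PatternCounts3(*(np.round(p * 1000).astype(int)))
        res = clock_plane_solution(c)
        assert res.clock_symmetric == bool(c.n_xyx == c.n_yxx)
        assert res.branch_lengths[0] == res.branch_lengths[1]

    def test_recovers_truth_on_plane(self):
        p = pattern_class_probs_3((0.1, 0.1, 0.5))
        c = PatternCounts3(*np.round(p * 100000).astype(int))
        res = clock_plane_solution(c)
        assert res.branch_lengths[0] == pytest.approx(0.1, abs=2e-3)
        assert res.branch_lengths[2] == pytest.approx(0.5, abs=5e-3)

    def test_beats_2d_grid_oracle(self):
        c = PatternCounts3(150, 50, 40, 40, 20)
        res = clock_plane_solution(c)
        g = np.linspace(1e-4, 3, 80)
        best = max(
            log_likelihood_3(c, (d, d, dc)) for d in g for dc in g
        )
        assert res.loglik >= best - 1e-6


class TestWorkflow:
    def test_global_route(self):
        res = ml_workflow(PatternCounts3(100, 0, 0, 0, 0))
        assert res.provenance == "global-boundary"

    def test_analytic_route_on_predicted_zero(self):
        # triangle-violating data: DM predicts a zero branch
        p = pattern_class_probs_3((0.0, 0.2, 1.5))
        c = PatternCounts3(*np.random.default_rng(1).multinomial(400, p))
        res = ml_workflow(c, seed=0)
        if res.provenance == "local-boundary":
            assert res.zero_branches
        else:  # no anomaly predicted for this draw: numeric is legitimate
            assert res.provenance in ("numeric", "analytic-infinite")

    def test_numeric_route_when_no_anomaly(self):
        p = pattern_class_probs_3((0.1, 0.1, 0.1))
        c = PatternCounts3(*np.random.default_rng(2).multinomial(300, p))
        res = ml_workflow(c, seed=0)
        assert res.provenance == "numeric"

    def test_workflow_at_least_as_good_as_numeric(self, rng):
        p = pattern_class_probs_3((0.1, 0.1, 1.5))
        counts = rng.multinomial(300, p, size=60)
        for row in counts:
            c = PatternCounts3(*row)
            wf = ml_workflow(c, seed=3)
            num = confirm_infinite(c, numeric_ml_3(c, seed=3))
            assert wf.loglik >= num.loglik - 1e-6

    def test_determinism(self):
        c = PatternCounts3(120, 80, 40, 30, 30)
        r1 = ml_workflow(c, seed=7)
        r2 = ml_workflow(c, seed=7)
        assert r1 == r2

    def test_model_interface(self):
        p = pattern_class_probs_3((0.1, 0.1, 0.5))
        c = PatternCounts3(*np.round(p * 300).astype(int))
        model = ThreeTaxonML(c)
        res = model.fit(seed=0)
        assert "log-likelihood" in res.summary()
        assert model.loglike(res.branch_lengths) == pytest.approx(res.loglik, abs=1e-6)


class TestPositionOnPath:
    @pytest.mark.parametrize(
        "dA,dB,expected",
        [(0.0, 0.3, 0.0), (0.3, 0.0, 1.0), (0.05, 0.05, 0.5)],
    )
    def test_fractions(self, dA, dB, expected):
        assert position_on_path(dA, dB) == expected

    @pytest.mark.parametrize("dA,dB", [(0.0, 0.0), (INF, 0.1), (0.1, INF)])
    def test_undefined_cases(self, dA, dB):
        assert math.isnan(position_on_path(dA, dB))
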