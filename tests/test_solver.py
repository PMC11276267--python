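"""The alternating-ascent solver: updates, invariants and fixture limits."""

import math

import numpy as np
import pytest

from rbottleneck import (SolverConfig, ValidationError, build_joint,
                         conditional_mi, evaluate_channel, evaluate_point,
                         solve)
from rbottleneck.gates import random_system
from rbottleneck.solver import (LN2, BottleneckChannel, _pred_comp_nats,
                                _run_once, batch_pred_comp, init_bottleneck,
                                update_bottleneck, update_variational)


def random_joint(seed, n_sources=2, y_card=3, x_cards=(2, 3)):
    return build_joint(random_system(n_sources, y_card, x_cards, seed=seed))


class TestInit:
    def test_degenerate_single_outcome(self, unique_joint, rng):
        r = init_bottleneck(unique_joint, 1, rng)
        np.testing.assert_array_equal(r.rows, 1.0)

    def test_reproducible_from_seed(self, unique_joint):
        a = init_bottleneck(unique_joint, 4, np.random.default_rng(3))
        b = init_bottleneck(unique_joint, 4, np.random.default_rng(3))
        np.testing.assert_array_equal(a.probs, b.probs)

    def test_unique_gate_support_rows(self, unique_joint, rng):
        # two binary sources pooled over a shared alphabet: 4 supported rows
        r = init_bottleneck(unique_joint, 5, rng)
        assert r.rows.shape == (4, 5)
        np.testing.assert_allclose(r.rows.sum(axis=1), 1.0, atol=1e-12)

    def test_rejects_invalid_rows(self, unique_joint):
        bad = np.full((2, 2, 2), 0.4)
        with pytest.raises(ValidationError):
            BottleneckChannel(bad, unique_joint.support)


class TestVariationalStep:
    def test_marginal_over_q_recovers_joint(self, bsc_joint, rng):
        r = init_bottleneck(bsc_joint, 3, rng)
        omega = update_variational(bsc_joint, r)
        np.testing.assert_allclose(omega.sum(axis=3), bsc_joint.p_ysz, atol=1e-15)
        assert omega.sum() == pytest.approx(1.0, abs=1e-12)

    def test_markov_property_of_induced_joint(self, bsc_joint, rng):
        """omega(y | s, z, q) = p(y | s, z): Q adds nothing beyond (S, Z)."""
        r = init_bottleneck(bsc_joint, 3, rng)
        omega = update_variational(bsc_joint, r)
        p_sz = bsc_joint.p_ysz.sum(axis=0)
        p_y_sz = bsc_joint.p_ysz / p_sz[None]
        w_szq = omega.sum(axis=0)
        cond = omega / np.where(w_szq > 0, w_szq, 1.0)[None]
        mask = w_szq > 1e-14
        for q in range(3):
            np.testing.assert_allclose(
                cond[:, mask[..., q], q], p_y_sz[:, mask[..., q]], atol=1e-12)


class TestAscent:
    @pytest.mark.parametrize("objective", ["linear", "exponential"])
    def test_objective_trace_monotone_and_bounded(self, objective):
        """Each alternation increases the objective, which stays below the
        prediction ceiling I(Z;Y|S)."""
        for seed in range(6):
            n_sources = seed % 3 + 1
            joint = random_joint(seed, n_sources=n_sources,
                                 x_cards=[2, 3, 2][:n_sources])
            beta = 10.0 ** ((seed % 5) - 2)
            cfg = SolverConfig(beta=beta, objective=objective, n_q=3,
                               max_iter=400, seed=seed)
            state = _run_once(joint, cfg, init_bottleneck(
                joint, 3, np.random.default_rng(seed)))
            trace = np.array(state.objective_trace)
            assert np.all(np.diff(trace) >= -1e-9)
            ceiling = conditional_mi(joint.p_ysz.transpose(2, 0, 1), 2)
            assert trace[-1] <= ceiling + 1e-9

    def test_single_update_strictly_improves_from_random_start(self, unique_joint):
        rng = np.random.default_rng(5)
        r = init_bottleneck(unique_joint, 3, rng)
        beta = 5.0

        def lagrangian(rr):
            pred, comp = _pred_comp_nats(unique_joint, rr.probs)
            return pred - comp / beta

        before = lagrangian(r)
        r2 = update_bottleneck(unique_joint, update_variational(unique_joint, r), beta)
        assert lagrangian(r2) > before + 1e-6

    def test_fixed_point_is_stationary(self, and_joint):
        cfg = SolverConfig(beta=10.0, objective="linear", n_q=3, seed=0)
        point = solve(and_joint, cfg)
        omega = update_variational(and_joint, point.channel)
        r2 = update_bottleneck(and_joint, omega, cfg.beta)
        np.testing.assert_allclose(r2.rows, point.channel.rows, atol=1e-5)


class TestEvaluation:
    def test_matches_term_by_term_oracle(self):
        """Prediction/compression agree with direct sums over the induced
        joint p(y,s,z,q) for a random channel on a random system."""
        joint = random_joint(42)
        rng = np.random.default_rng(7)
        r = init_bottleneck(joint, 3, rng)
        w = update_variational(joint, r)  # (y,s,z,q)
        j_ysq = w.sum(axis=2)

        def brute(j, pred):
            tot = 0.0
            ny, ns, nq = j.shape
            for y in range(ny):
                for s in range(ns):
                    for q in range(nq):
                        p = j[y, s, q]
                        if p <= 0:
                            continue
                        if pred:  # I(Q;Y|S)
                            ps = j[:, s, :].sum()
                            num = p * ps
                            den = j[:, s, q].sum() * j[y, s, :].sum()
                        else:     # I(Q;S|Y)
                            py = j[y].sum()
                            num = p * py
                            den = j[y, :, q].sum() * j[y, s, :].sum()
                        tot += p * math.log2(num / den)
            return tot

        pred, comp, decomp = evaluate_channel(joint, r)
        assert pred == pytest.approx(brute(j_ysq, True), abs=1e-10)
        assert comp == pytest.approx(brute(j_ysq, False), abs=1e-10)

    def test_copy_of_pooled_outcome_attains_the_bounds(self, unique_joint):
        """Q = Z reaches prediction I(Z;Y|S) and compression I(Z;S|Y)."""
        ns, nz = unique_joint.support.shape
        probs = np.zeros((ns, nz, nz))
        probs[:, np.arange(nz), np.arange(nz)] = 1.0
        r = BottleneckChannel(probs, unique_joint.support)
        pred, comp, _ = evaluate_channel(unique_joint, r)
        assert pred == pytest.approx(
            conditional_mi(unique_joint.p_ysz.transpose(2, 0, 1), 2), abs=1e-12)
        assert comp == pytest.approx(
            conditional_mi(unique_joint.p_ysz.transpose(2, 1, 0), 2), abs=1e-12)

    def test_constant_bottleneck_reveals_nothing(self, bsc_joint, rng):
        r = init_bottleneck(bsc_joint, 1, rng)
        pred, comp, decomp = evaluate_channel(bsc_joint, r)
        assert pred == pytest.approx(0.0, abs=1e-12)
        assert comp == pytest.approx(0.0, abs=1e-12)

    def test_label_permutation_equivariance(self, unique_joint):
        cfg = SolverConfig(beta=50.0, n_q=4, seed=2, n_restarts=2)
        point = solve(unique_joint, cfg)
        permuted = point.channel.permute_labels([2, 0, 3, 1])
        pred, comp, _ = evaluate_channel(unique_joint, permuted)
        assert pred == pytest.approx(point.prediction, abs=1e-12)
        assert comp == pytest.approx(point.compression, abs=1e-12)

    def test_batch_evaluation_matches_single(self, unique_joint):
        rng = np.random.default_rng(0)
        rs = rng.dirichlet(np.ones(2), size=(8, 2, 2)).reshape(8, 2, 2, 2)
        preds, comps = batch_pred_comp(unique_joint, rs)
        for i in range(8):
            r = BottleneckChannel(rs[i], unique_joint.support)
            pred, comp, _ = evaluate_channel(unique_joint, r)
            assert preds[i] == pytest.approx(pred, abs=1e-12)
            assert comps[i] == pytest.approx(comp, abs=1e-12)


class TestSolve:
    def test_and_gate_collapses_to_single_point(self, and_joint):
        for beta in (0.1, 10.0):
            point = solve(and_joint, SolverConfig(beta=beta, seed=0))
            assert point.prediction == pytest.approx(0.311278, abs=1e-3)
            assert point.compression == pytest.approx(0.0, abs=1e-6)

    def test_cardinality_beyond_sufficient_adds_nothing(self, unique_joint,
                                                        and_joint):
        """Doubling the bottleneck cardinality beyond sum|X_s| + 1 leaves the
        best objective unchanged."""
        for joint in (unique_joint, and_joint):
            n_suff = joint.n_support + 1
            obj = {}
            for n_q in (n_suff, 2 * n_suff):
                cfg = SolverConfig(beta=10.0, n_q=n_q, seed=0, n_restarts=5)
                obj[n_q] = solve(joint, cfg).objective
            assert obj[2 * n_suff] == pytest.approx(obj[n_suff], abs=1e-6)

    def test_warm_start_shape_checked(self, unique_joint, bsc_joint, rng):
        wrong = init_bottleneck(bsc_joint, 5, rng)
        with pytest.raises(ValidationError):
            solve(unique_joint, SolverConfig(n_q=5), warm_start=wrong)

    def test_non_convergence_warns_but_returns(self, bsc_joint):
        cfg = SolverConfig(beta=10.0, max_iter=2, n_restarts=1, seed=0)
        with pytest.warns(RuntimeWarning):
            point = solve(bsc_joint, cfg)
        assert not point.converged
        assert point.n_iter == 2

    def test_evaluate_point_wraps_objective(self, unique_joint, rng):
        r = init_bottleneck(unique_joint, 2, rng)
        pt = evaluate_point(unique_joint, r, beta=2.0, objective="linear")
        assert pt.objective == pytest.approx(
            pt.prediction - pt.compression / 2.0, abs=1e-12)

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            SolverConfig(beta=0.0)
        with pytest.raises(ValidationError):
            SolverConfig(objective="quadratic")
        with pytest.raises(ValidationError):
            SolverConfig(n_q=0)
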