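"""Tests of L1 parent selection, DAG repair, scoring, and classification."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ecogdecode import (MtvdbnDirectionClassifier, angular_error,
                        build_acyclic_structure, classify_direction,
                        fit_direction_model, learn_node_coefficients,
                        sample_direction_windows, score_sequence,
                        select_lambda, SimConfig)
from ecogdecode.mtvdbn import _node_objective, empty_model


def cd_lasso_oracle(X, y, lam, n_iter=3000, tol=1e-12):
    """Coordinate descent on (1/N)||y - Xa||^2 + lam ||a||_1."""
    N, p = X.shape
    a = np.zeros(p)
    b = 2.0 * np.sum(X**2, axis=0) / N
    for _ in range(n_iter):
        a_old = a.copy()
        for j in range(p):
            r = y - X @ a + X[:, j] * a[j]
            c = 2.0 * X[:, j] @ r / N
            a[j] = np.sign(c) * max(abs(c) - lam, 0.0) / b[j] if b[j] else 0.0
        if np.max(np.abs(a - a_old)) < tol:
            break
    return a


def penalized_objective(X, y, a, lam):
    return np.mean((y - X @ a) ** 2) + lam * np.sum(np.abs(a))


class TestLearnNodeCoefficients:
    def test_full_shrinkage_above_critical_lambda(self, rng):
        N, M = 40, 4
        W = rng.standard_normal((N, 2, M))
        t, m = 1, 0
        design = np.hstack([W[:, 0, :], W[:, 1, [1, 2, 3]]])
        lam_max = 2.0 * np.max(np.abs(design.T @ W[:, t, m]) / N)
        temporal, spatial = learn_node_coefficients(m, t, W, lam_max * 1.01)
        assert not temporal.any() and not spatial.any()

    def test_exact_relation_recovered_at_zero_penalty(self, rng):
        N = 50
        W = np.zeros((N, 2, 2))
        W[:, 1, 1] = rng.standard_normal(N)
        W[:, 1, 0] = 2.0 * W[:, 1, 1]
        temporal, spatial = learn_node_coefficients(0, 1, W, 0.0)
        assert spatial[1] == pytest.approx(2.0, abs=1e-8)

    def test_orthonormal_design_soft_thresholds_ols(self, rng):
        # build an orthonormal two-column spatial design (t = 0: no temporal)
        N = 64
        q, _ = np.linalg.qr(rng.standard_normal((N, 2)))
        q *= np.sqrt(N)  # columns with (1/N) x.x = 1
        W = np.zeros((N, 1, 3))
        W[:, 0, 1], W[:, 0, 2] = q[:, 0], q[:, 1]
        beta = np.array([1.2, -0.4])
        W[:, 0, 0] = q @ beta + 0.01 * rng.standard_normal(N)
        lam = 0.5
        _, spatial = learn_node_coefficients(0, 0, W, lam)
        ols = np.linalg.lstsq(q, W[:, 0, 0], rcond=None)[0]
        soft = np.sign(ols) * np.maximum(np.abs(ols) - lam / 2.0, 0.0)
        assert np.allclose(spatial[[1, 2]], soft, atol=1e-6)

    def test_negative_penalty_rejected(self, rng):
        W = rng.standard_normal((10, 2, 3))
        with pytest.raises(ValueError):
            learn_node_coefficients(0, 1, W, -0.5)

    def test_matches_coordinate_descent_oracle(self, rng):
        """LARS-path solutions agree with an independent coordinate-descent
        minimizer of the penalized objective on random problems."""
        for _ in range(50):
            N = int(rng.integers(20, 60))
            M = int(rng.integers(3, 6))
            lam = float(rng.uniform(0.05, 1.0))
            W = rng.standard_normal((N, 2, M))
            m = int(rng.integers(0, M))
            temporal, spatial = learn_node_coefficients(m, 1, W, lam)
            sp_idx = [j for j in range(M) if j != m]
            X = np.hstack([W[:, 0, :], W[:, 1, sp_idx]])
            y = W[:, 1, m]
            a_impl = np.concatenate([temporal, spatial[sp_idx]])
            a_oracle = cd_lasso_oracle(X, y, lam)
            gap = (penalized_objective(X, y, a_impl, lam)
                   - penalized_objective(X, y, a_oracle, lam))
            assert abs(gap) <= 1e-6

    def test_nonzero_count_non_increasing_in_lambda(self, rng):
        W = rng.standard_normal((60, 2, 5))
        for m in range(5):
            W[:, 1, m] += 0.6 * W[:, 0, (m + 1) % 5]
        prev = np.inf
        for lam in (0.01, 0.05, 0.2, 0.5, 1.0, 3.0):
            temporal, spatial = learn_node_coefficients(0, 1, W, lam)
            nnz = np.count_nonzero(temporal) + np.count_nonzero(spatial)
            assert nnz <= prev
            prev = nnz


class TestBuildAcyclicStructure:
    def test_empty_candidates_give_empty_graph(self, rng):
        W = rng.standard_normal((20, 1, 3))
        out = build_acyclic_structure(0, {m: [] for m in range(3)}, W, 0.1,
                                      {})
        assert all(not ps for ps in out.values())

    def test_mutual_candidates_keep_exactly_one_edge(self, rng):
        N = 80
        W = np.zeros((N, 1, 2))
        W[:, 0, 0] = rng.standard_normal(N)
        W[:, 0, 1] = 0.9 * W[:, 0, 0] + 0.2 * rng.standard_normal(N)
        out = build_acyclic_structure(0, {0: [1], 1: [0]}, W, 0.1, {})
        n_edges = len(out[0]) + len(out[1])
        assert n_edges == 1

    def test_chain_candidates_fully_retained(self, rng):
        N = 80
        W = np.zeros((N, 1, 3))
        W[:, 0, 0] = rng.standard_normal(N)
        W[:, 0, 1] = 0.9 * W[:, 0, 0] + 0.1 * rng.standard_normal(N)
        W[:, 0, 2] = 0.9 * W[:, 0, 1] + 0.1 * rng.standard_normal(N)
        out = build_acyclic_structure(0, {0: [], 1: [0], 2: [1]}, W, 0.05, {})
        assert out[1] == [0] and out[2] == [1]

    def test_output_always_acyclic(self, rng):
        for _ in range(10):
            M = 5
            W = rng.standard_normal((40, 1, M))
            cand = {m: [int(p) for p in rng.choice(M, size=2, replace=False)
                        if p != m] for m in range(M)}
            out = build_acyclic_structure(0, cand, W, 0.1, {})
            g = nx.DiGraph([(p, m) for m, ps in out.items() for p in ps])
            g.add_nodes_from(range(M))
            assert nx.is_directed_acyclic_graph(g)

    def test_matches_exhaustive_restricted_dag_search(self, rng):
        """On small instances the hill climber attains the optimum of the
        exhaustive search over candidate-restricted DAGs."""
        from ecogdecode.mtvdbn import learn_node_coefficients as lnc
        for _ in range(25):
            M = int(rng.integers(3, 5))
            T = int(rng.integers(1, 4))
            N = 40
            lam = float(rng.choice([0.1, 0.3, 0.5]))
            W = rng.standard_normal((N, T, M))
            for t in range(T):
                for m in range(1, M):
                    if rng.random() < 0.5:
                        W[:, t, m] += 0.8 * W[:, t, int(rng.integers(0, m))]
            t = int(rng.integers(0, T))
            tpar, cand = {}, {}
            for m in range(M):
                temporal, spatial = lnc(m, t, W, lam)
                tpar[m] = np.flatnonzero(np.abs(temporal) > 1e-12)
                cand[m] = list(np.flatnonzero(np.abs(spatial) > 1e-12))

            def design(m, spatial):
                cols = []
                if t > 0 and len(tpar[m]):
                    cols.append(W[:, t - 1, list(tpar[m])])
                if spatial:
                    cols.append(W[:, t, sorted(spatial)])
                return np.hstack(cols) if cols else np.empty((N, 0))

            def total(parent_sets):
                return sum(_node_objective(W[:, t, m],
                                           design(m, parent_sets[m]),
                                           lam)[0] for m in range(M))

            greedy = total(build_acyclic_structure(t, cand, W, lam, tpar))
            edges = [(p, m) for m in cand for p in cand[m]]
            best = np.inf
            for r in range(len(edges) + 1):
                for sub in itertools.combinations(edges, r):
                    g = nx.DiGraph()
                    g.add_nodes_from(range(M))
                    g.add_edges_from(sub)
                    if not nx.is_directed_acyclic_graph(g):
                        continue
                    pa = {m: [p for (p, mm) in sub if mm == m]
                          for m in range(M)}
                    best = min(best, total(pa))
            assert greedy <= best + 1e-8


class TestScoreSequence:
    def _tiny_model(self):
        model = empty_model(0, 2, 2, 0.0)
        # x[1, 1] = 0.7 x[0, 1] + 0.5 x[1, 0]
        model.temporal_parents[1][1] = [1]
        model.temporal_coefs[1][1] = np.array([0.7])
        model.spatial_parents[1][1] = [0]
        model.spatial_coefs[1][1] = np.array([0.5])
        return model

    def test_self_generated_window_scores_zero(self):
        model = self._tiny_model()
        w = np.zeros((2, 2))
        w[0] = [0.0, 2.0]
        w[1, 0] = 1.0
        w[1, 1] = 0.7 * w[0, 1] + 0.5 * w[1, 0]
        residual_free = score_sequence(model, w)
        # the modeled node contributes zero; the parent-free nodes score
        # their own squares
        expected = w[0, 0]**2 + w[0, 1]**2 + w[1, 0]**2
        assert residual_free == pytest.approx(expected)

    def test_empty_model_scores_sum_of_squares(self, rng):
        w = rng.standard_normal((3, 4))
        model = empty_model(0, 3, 4, 0.0)
        assert score_sequence(model, w) == pytest.approx(np.sum(w**2))

    def test_matches_brute_force_double_sum(self, rng):
        cfg = SimConfig(n_channels=2, seed=3)
        W, y = sample_direction_windows(cfg, 10, T=4)
        model = fit_direction_model(W[y == 1], 1, 0.2)
        w = rng.standard_normal((4, 8))
        total = 0.0
        for t in range(4):
            for m in range(8):
                pred = 0.0
                if t > 0:
                    for p, c in zip(model.temporal_parents[t][m],
                                    model.temporal_coefs[t][m]):
                        pred += c * w[t - 1, p]
                for p, c in zip(model.spatial_parents[t][m],
                                model.spatial_coefs[t][m]):
                    pred += c * w[t, p]
                total += (w[t, m] - pred) ** 2
        assert score_sequence(model, w) == pytest.approx(total, rel=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        model = empty_model(0, 3, 4, 0.0)
        with pytest.raises(ValueError):
            score_sequence(model, rng.standard_normal((2, 4)))


class TestClassification:
    def test_all_zero_window_ties_break_to_lowest_index(self):
        models = [empty_model(d, 2, 3, 0.0) for d in range(8)]
        assert classify_direction(models, np.zeros((2, 3))) == 0

    def test_untrained_model_rejected(self):
        models = [empty_model(0, 2, 3, 0.0), None]
        with pytest.raises(ValueError):
            classify_direction(models, np.zeros((2, 3)))

    def test_window_from_known_direction_classified_correctly(self):
        cfg = SimConfig(n_channels=3, seed=2)
        Wtr, ytr = sample_direction_windows(cfg, 25)
        Wte, yte = sample_direction_windows(
            cfg, 10, rng=np.random.default_rng(555))
        clf = MtvdbnDirectionClassifier(lam=0.3).fit(Wtr, ytr)
        acc = np.mean(clf.predict(Wte) == yte)
        assert acc > 0.8

    def test_fitted_slices_are_acyclic(self):
        cfg = SimConfig(n_channels=2, seed=9)
        W, y = sample_direction_windows(cfg, 20)
        clf = MtvdbnDirectionClassifier(lam=0.2).fit(W, y)
        for model in clf.models_:
            for t in range(model.T):
                g = nx.DiGraph([(p, m) for m, ps in
                                model.spatial_parents[t].items()
                                for p in ps])
                g.add_nodes_from(range(model.M))
                assert nx.is_directed_acyclic_graph(g)

    def test_refit_with_permuted_trials_identical(self):
        cfg = SimConfig(n_channels=2, seed=4)
        W, y = sample_direction_windows(cfg, 15)
        perm = np.random.default_rng(0).permutation(len(y))
        a = MtvdbnDirectionClassifier(lam=0.3).fit(W, y)
        b = MtvdbnDirectionClassifier(lam=0.3).fit(W[perm], y[perm])
        for ma, mb in zip(a.models_, b.models_):
            for t in range(ma.T):
                assert ma.temporal_parents[t] == mb.temporal_parents[t]
                assert ma.spatial_parents[t] == mb.spatial_parents[t]
                for m in range(ma.M):
                    assert np.allclose(ma.temporal_coefs[t][m],
                                       mb.temporal_coefs[t][m], atol=1e-8)

    def test_constant_feature_column_gets_no_parents(self):
        cfg = SimConfig(n_channels=2, seed=6)
        W, y = sample_direction_windows(cfg, 15)
        W[:, :, 2] = 1.0  # constant column
        clf = MtvdbnDirectionClassifier(lam=0.3).fit(W, y)
        for model in clf.models_:
            for t in range(model.T):
                assert model.temporal_parents[t][2] == []
                assert model.spatial_parents[t][2] == []

    def test_insufficient_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_direction_model(rng.standard_normal((1, 3, 4)), 0, 0.1)


class TestAngularError:
    @pytest.mark.parametrize("pred,true,expected", [
        (3, 3, 0.0), (0, 4, 180.0), (7, 0, 45.0), (0, 7, 45.0),
        (1, 6, 135.0),
    ])
    def test_known_pairs(self, pred, true, expected):
        assert angular_error(pred, true) == expected

    def test_symmetric_and_bounded(self, rng):
        for _ in range(50):
            a, b = rng.integers(0, 8, size=2)
            err = angular_error(a, b)
            assert err == angular_error(b, a)
            assert 0.0 <= err <= 180.0


class TestSelectLambda:
    def test_degenerate_grid_returned_unchanged(self, rng):
        W = rng.standard_normal((16, 3, 4))
        y = np.repeat([0, 1], 8)
        assert select_lambda(W, y, lambda_grid=(0.7,)) == 0.7

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            select_lambda(rng.standard_normal((8, 2, 2)),
                          np.repeat([0, 1], 4), lambda_grid=())

    def test_pure_noise_selects_sparse_lambda(self, rng):
        W = rng.standard_normal((48, 3, 4))
        y = np.repeat(np.arange(4), 12)
        lam = select_lambda(W, y, lambda_grid=(0.01, 0.3, 3.0), cv=3)
        # one-SE rule drives pure-noise data to the sparsest penalty
        assert lam == 3.0

    def test_structured_data_beats_empty_models(self):
        cfg = SimConfig(n_channels=2, seed=8)
        Wtr, ytr = sample_direction_windows(cfg, 12)
        Wte, yte = sample_direction_windows(
            cfg, 8, rng=np.random.default_rng(321))
        lam = select_lambda(Wtr, ytr, lambda_grid=(0.1, 0.5), cv=3)
        fitted = MtvdbnDirectionClassifier(lam=lam).fit(Wtr, ytr)
        empty = MtvdbnDirectionClassifier(lam=1e6).fit(Wtr, ytr)
        acc_fit = np.mean(fitted.predict(Wte) == yte)
        acc_empty = np.mean(empty.predict(Wte) == yte)
        assert acc_fit > acc_empty
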