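"""Canonical DFA core: scatter algebra, eigenstructure, root tests,
stepwise entry, classification."""

import numpy as np
import pandas as pd
import pytest

from biodfa.dfa import (CanonicalModel, SingularWithinError, canonical_solve,
                        fit_canonical, root_tests, scatter_matrices,
                        standardized_coefficients, stepwise_dfa)


def random_instance(rng, n=24, p=4, g=3):
    X = rng.normal(size=(n, p)) + rng.normal(size=(1, p))
    y = np.array([f"g{i % g}" for i in range(n)], dtype=object)
    X[y == "g0"] += rng.normal(0, 1, size=p)
    return X, y


class TestScatterMatrices:
    def test_total_equals_brute_force_centered_crossproduct(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 3))
        y = np.array(["a", "a", "b", "b", "b"], dtype=object)
        W, B, T = scatter_matrices(X, y)
        xb = X.mean(axis=0)
        T_oracle = np.zeros((3, 3))
        for row in X:
            T_oracle += np.outer(row - xb, row - xb)
        assert np.allclose(T, T_oracle, atol=1e-10)
        assert np.allclose(T, W + B, atol=1e-10)

    def test_symmetry_and_psd(self):
        rng = np.random.default_rng(1)
        X, y = random_instance(rng)
        W, B, T = scatter_matrices(X, y)
        for M in (W, B, T):
            assert np.allclose(M, M.T)
            assert np.linalg.eigvalsh(M).min() > -1e-10

    def test_single_group_has_zero_between(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 3))
        _, B, _ = scatter_matrices(X, np.array(["a"] * 6, dtype=object))
        assert np.allclose(B, 0)

    def test_mirrored_two_group_between_is_rank_one(self):
        X = np.array([[1.0, 0], [2, 1], [3, 2], [-1, 0], [-2, -1], [-3, -2]])
        y = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        _, B, _ = scatter_matrices(X, y)
        assert np.linalg.matrix_rank(B, tol=1e-10) == 1

    def test_singleton_group_rejected(self):
        X = np.ones((3, 2))
        with pytest.raises(ValueError, match="fewer than 2"):
            scatter_matrices(X, np.array(["a", "a", "b"], dtype=object))


class TestCanonicalSolve:
    def test_one_predictor_two_groups_is_ssb_over_ssw(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 10), rng.normal(2, 1, 10)])
        y = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        W, B, _ = scatter_matrices(x[:, None], y)
        lam, _ = canonical_solve(W, B, 20, 2)
        assert lam[0] == pytest.approx(B[0, 0] / W[0, 0], rel=1e-10)

    def test_orthogonal_rotation_leaves_eigenvalues_unchanged(self):
        rng = np.random.default_rng(4)
        X, y = random_instance(rng)
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        lam1, _ = canonical_solve(*scatter_matrices(X, y)[:2], 24, 3)
        lam2, _ = canonical_solve(*scatter_matrices(X @ Q, y)[:2], 24, 3)
        assert np.allclose(lam1, lam2, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_generic_eigensolver_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X, y = random_instance(rng, n=30, p=5, g=4)
        W, B, _ = scatter_matrices(X, y)
        lam, _ = canonical_solve(W, B, 30, 4)
        oracle = np.sort(np.real(np.linalg.eigvals(
            np.linalg.solve(W, B))))[::-1][:3]
        assert np.allclose(lam, np.clip(oracle, 0, None), atol=1e-8)

    def test_scores_have_unit_pooled_within_variance(self):
        rng = np.random.default_rng(6)
        X, y = random_instance(rng, n=30, p=5, g=4)
        W, B, _ = scatter_matrices(X, y)
        lam, A = canonical_solve(W, B, 30, 4)
        Sw_scores = A.T @ (W / (30 - 4)) @ A
        assert np.allclose(np.diag(Sw_scores), 1.0, atol=1e-8)


class TestRootTests:
    def test_null_eigenvalues_give_unit_lambda(self):
        out = root_tests([0.0, 0.0], N=30, p=4, g=4)
        assert np.allclose(out["wilks_lambda"], 1.0)
        assert np.allclose(out["chi_square"], 0.0)
        assert np.allclose(out["p"], 1.0)
        assert out.attrs["n_significant"] == 0

    def test_closed_form_single_root(self):
        # lambda = 1.7, N=30, p=6, g=6: chi2 = (30-1-6) ln 2.7 = 22.8448
        out = root_tests([1.7], N=30, p=6, g=6)
        assert out.loc[0, "chi_square"] == pytest.approx(23 * np.log(2.7),
                                                         rel=1e-12)
        assert out.loc[0, "df"] == 30
        assert out.loc[0, "wilks_lambda"] == pytest.approx(1 / 2.7)

    def test_canonical_correlation_identity(self):
        lam = np.array([3.0, 0.25])
        out = root_tests(lam, N=40, p=5, g=4)
        assert np.allclose(out["canonical_R"] ** 2, lam / (1 + lam))

    def test_extra_root_strictly_increases_leading_chi_square(self):
        a = root_tests([1.5], N=30, p=5, g=4).loc[0, "chi_square"]
        b = root_tests([1.5, 0.4], N=30, p=5, g=4).loc[0, "chi_square"]
        assert b > a


class TestStepwise:
    def test_p_enter_one_fills_the_cap_greedily(self):
        rng = np.random.default_rng(7)
        X, y = random_instance(rng, n=30, p=6, g=3)
        m = stepwise_dfa(X, y, p_enter=1.0, max_predictors=4)
        assert len(m.predictor_labels) == 4
        assert m.trace.table["model_lambda"].is_monotonic_decreasing

    def test_signal_predictor_enters_first(self):
        # one column carries the whole separation among 20 noise columns
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = np.array([f"g{i % 3}" for i in range(30)], dtype=object)
            X = rng.normal(size=(30, 21))
            X[:, 0] += 3.0 * np.array([int(s[1]) for s in y])
            m = stepwise_dfa(X, y, labels=[f"x{j}" for j in range(21)])
            wins += m.predictor_labels[:1] == ["x0"]
        assert wins >= 95

    def test_empty_model_is_flagged_not_raised(self):
        rng = np.random.default_rng(8)
        X, y = random_instance(rng, n=24, p=5, g=3)
        m = stepwise_dfa(X, y, p_enter=1e-12)
        assert m.empty and m.predictor_labels == []
        pred, post = m.predict(X)
        assert np.allclose(post.sum(axis=1), 1.0)

    def test_fixed_input_gives_identical_trace(self, predictor_matrix, grouping):
        m1 = stepwise_dfa(predictor_matrix, grouping)
        m2 = stepwise_dfa(predictor_matrix, grouping)
        assert m1.trace.table.equals(m2.trace.table)
        assert m1.predictor_labels == m2.predictor_labels

    def test_recorded_p_to_enter_below_threshold(self, predictor_matrix,
                                                 grouping):
        m = stepwise_dfa(predictor_matrix, grouping, p_enter=0.05)
        assert (m.trace.table["p_to_enter"] < 0.05).all()
        assert m.trace.table["model_lambda"].is_monotonic_decreasing


@pytest.fixture(scope="module")
def fitted(predictor_matrix, grouping):
    return stepwise_dfa(predictor_matrix, grouping)


class TestModelAlgebra:

    def test_wilks_lambda_equals_det_ratio(self, fitted, predictor_matrix,
                                           grouping):
        pos = [predictor_matrix.labels.index(l)
               for l in fitted.predictor_labels]
        Xs = predictor_matrix.values[:, pos]
        W, _, T = scatter_matrices(Xs, grouping)
        det_ratio = np.exp(np.linalg.slogdet(W)[1] - np.linalg.slogdet(T)[1])
        assert fitted.wilks_lambda == pytest.approx(det_ratio, rel=1e-8)

    def test_number_of_roots(self, fitted):
        assert fitted.n_roots == min(len(fitted.predictor_labels),
                                     len(fitted.groups) - 1)

    def test_priors_are_observed_frequencies(self, fitted, grouping):
        freq = pd.Series(grouping).value_counts(normalize=True)
        assert fitted.priors.sum() == pytest.approx(1.0)
        for g, pr in zip(fitted.groups, fitted.priors):
            assert pr == pytest.approx(freq[g])

    def test_sign_convention_orients_largest_weight_positive(self, fitted):
        for r in range(fitted.n_roots):
            col = fitted.std_coefficients[:, r]
            assert col[np.argmax(np.abs(col))] > 0


class TestStandardizedCoefficients:
    def test_unit_within_sd_makes_standardized_equal_raw(self):
        raw = np.array([[1.0, -2.0], [0.5, 3.0]])
        std = standardized_coefficients(raw, np.ones(2))
        assert np.allclose(std, raw, atol=1e-10)

    def test_rescaling_a_predictor_leaves_standardized_unchanged(self):
        rng = np.random.default_rng(9)
        X, y = random_instance(rng, n=30, p=4, g=3)
        m1 = fit_canonical(X, y, [f"x{j}" for j in range(4)], [0, 1, 2])
        X2 = X.copy()
        X2[:, 1] *= 2.0
        m2 = fit_canonical(X2, y, [f"x{j}" for j in range(4)], [0, 1, 2])
        assert np.allclose(m2.raw_coefficients[1], m1.raw_coefficients[1] / 2,
                           atol=1e-8)
        assert np.allclose(m2.std_coefficients, m1.std_coefficients, atol=1e-8)

    def test_definition_recovered_from_scratch(self, predictor_matrix,
                                               grouping):
        m = stepwise_dfa(predictor_matrix, grouping)
        pos = [predictor_matrix.labels.index(l) for l in m.predictor_labels]
        Xs = predictor_matrix.values[:, pos]
        W, _, _ = scatter_matrices(Xs, grouping)
        sd = np.sqrt(np.diag(W) / (len(grouping) - len(m.groups)))
        assert np.allclose(m.std_coefficients, m.raw_coefficients * sd[:, None],
                           atol=1e-10)


class TestClassification:
    def test_group_centroid_classified_to_its_group(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(24, 3))
        y = np.array([f"g{i % 3}" for i in range(24)], dtype=object)
        X[y == "g1"] += 6.0
        X[y == "g2"] -= 6.0
        m = fit_canonical(X, y, ["a", "b", "c"], [0, 1, 2])
        for g in m.groups:
            centroid = X[y == g].mean(axis=0)
            label, post = m.classify(centroid)
            assert label == g
            assert post[g] > max(v for k, v in post.items() if k != g)

    def test_identical_centroids_tie_broken_by_prior_then_order(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=(4, 2)) * 0.1
        # groups a and b share a centroid exactly; c is far away
        X = np.vstack([base, base, base, rng.normal(8, 0.1, size=(4, 2))])
        y = np.array(["a"] * 4 + ["b"] * 8 + ["c"] * 4, dtype=object)
        m = fit_canonical(X, y, ["p", "q"], [0, 1])
        label, _ = m.classify(X[:4].mean(axis=0))
        assert label == "b"  # higher prior wins the tie
        # equal priors: first group in order wins
        y2 = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4, dtype=object)
        X2 = np.vstack([base, base, rng.normal(8, 0.1, size=(4, 2))])
        m2 = fit_canonical(X2, y2, ["p", "q"], [0, 1])
        label2, _ = m2.classify(base.mean(axis=0))
        assert label2 == "a"

    def test_well_separated_training_data_classified_perfectly(self):
        from biodfa.features import build_predictors
        from biodfa.synthetic import (EffectSpec, StudyDesign,
                                      generate_dataset, pool_controls)
        ds = generate_dataset(StudyDesign(), EffectSpec.separable(1))
        p = pool_controls(ds)
        y = p.groups.to_numpy(object)
        pm = build_predictors(p, max_order=1)
        m = stepwise_dfa(pm, y)
        pred, _ = m.predict(pm.values, labels=pm.labels)
        assert (pred == y).all()

    def test_affine_reparameterization_leaves_labels_unchanged(self):
        rng = np.random.default_rng(12)
        X, y = random_instance(rng, n=30, p=4, g=3)
        sel = [0, 1, 2, 3]
        m1 = fit_canonical(X, y, list("abcd"), sel)
        M = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        X2 = X @ M + rng.normal(size=4)
        m2 = fit_canonical(X2, y, list("abcd"), sel)
        p1, _ = m1.predict(X)
        p2, _ = m2.predict(X2)
        assert (p1 == p2).all()

    def test_two_groups_reproduce_fisher_discriminant(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(30, 4))
        y = np.array(["a"] * 15 + ["b"] * 15, dtype=object)
        X[15:] += [1.5, 0.5, -0.5, 0.0]
        m = fit_canonical(X, y, list("abcd"), [0, 1, 2, 3])
        W, _, _ = scatter_matrices(X, y)
        Sw = W / (30 - 2)
        w = np.linalg.solve(Sw, X[15:].mean(0) - X[:15].mean(0))
        fisher = X @ w
        scores = m.scores(X)[:, 0]
        r = np.corrcoef(fisher, scores)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-8)

    def test_singular_within_raises_informative_error(self):
        X = np.ones((12, 2))
        X[:, 1] = np.arange(12)
        X[:, 0] = X[:, 1] * 2  # perfectly collinear
        y = np.array(["a", "b", "c"] * 4, dtype=object)
        with pytest.raises((SingularWithinError, np.linalg.LinAlgError)):
            fit_canonical(X, y, ["p", "q"], [0, 1])
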