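import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from sleeptransfer import (
    PosteriorMatrix,
    ShiftConfig,
    evaluate_measures,
    fit_subspace_alignment,
    h_score,
    hypothesis_margin,
    leep,
    make_domain_pair,
    make_posteriors,
    mmd2_quadratic,
    mmd_measure,
    median_heuristic,
    project_source,
    project_target,
    silhouette_cross,
    tdas,
)
from sleeptransfer.errors import (
    DegenerateDataError,
    InsufficientDataError,
    ParameterError,
)

from _oracles import (
    h_score_loops,
    hypothesis_margin_loops,
    silhouette_cross_loops,
    tdas_loops,
)
from conftest import make_table


class TestLEEP:
    def test_perfect_one_hot_predictor_scores_zero(self):
        y = np.array([0, 1, 2] * 10)
        theta = np.zeros((30, 3))
        theta[np.arange(30), y] = 1.0
        assert leep(PosteriorMatrix(theta, y)) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_posteriors_balanced_binary_gives_log_half(self):
        theta = np.full((100, 2), 0.5)
        y = np.array([0, 1] * 50)
        assert leep(PosteriorMatrix(theta, y)) == pytest.approx(np.log(0.5))

    def test_never_positive(self, rng):
        for seed in range(5):
            y = rng.integers(0, 5, size=200)
            post = make_posteriors(y, accuracy=0.6, Z=5, seed=seed)
            assert leep(post) <= 0.0

    def test_monotone_in_posterior_quality(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 5, size=2000)
        vals = [
            leep(make_posteriors(y, accuracy=a, Z=5, seed=42))
            for a in (0.2, 0.5, 0.8, 1.0)
        ]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_invalid_rows_rejected(self):
        with pytest.raises(ParameterError):
            PosteriorMatrix(np.array([[0.7, 0.7], [0.5, 0.5]]), np.array([0, 1]))

    def test_invariant_to_sample_order(self, rng):
        y = rng.integers(0, 3, size=150)
        post = make_posteriors(y, accuracy=0.7, Z=4, seed=0)
        perm = rng.permutation(150)
        assert leep(post) == pytest.approx(
            leep(PosteriorMatrix(post.theta[perm], post.target_labels[perm])),
            abs=1e-12,
        )


class TestPosteriorIO:
    def test_round_trip_is_lossless(self, tmp_path, rng):
        from sleeptransfer import load_posterior_matrix, write_posterior_matrix

        y = rng.integers(0, 3, size=25)
        post = make_posteriors(y, accuracy=0.7, Z=4, seed=1)
        path = tmp_path / "post.csv"
        write_posterior_matrix(post, path)
        back = load_posterior_matrix(path)
        np.testing.assert_array_equal(back.theta, post.theta)
        np.testing.assert_array_equal(back.target_labels, post.target_labels)
        assert leep(back) == leep(post)

    def test_missing_label_column_rejected(self, tmp_path):
        from sleeptransfer import load_posterior_matrix

        p = tmp_path / "bad.csv"
        p.write_text("p_0,p_1\n0.5,0.5\n")
        with pytest.raises(ParameterError):
            load_posterior_matrix(p)


class TestHScore:
    def test_class_independent_features_score_zero(self):
        # both classes share the same four points: class means exactly equal
        pts = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 2.0], [0.0, -2.0]])
        phi = np.vstack([pts, pts])
        y = np.array([0] * 4 + [1] * 4)
        assert h_score(phi, y) == 0.0

    def test_two_class_zero_within_variance_scores_one(self):
        phi = np.array([[1.0, 2.0]] * 5 + [[3.0, -1.0]] * 5)
        y = np.array([0] * 5 + [1] * 5)
        assert h_score(phi, y, pseudoinverse=True) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        phi = rng.normal(size=(40, 6))
        y = rng.integers(0, 4, size=40)
        assert h_score(phi, y) == pytest.approx(h_score_loops(phi, y), abs=1e-10)

    def test_invariant_under_invertible_linear_maps(self, rng):
        phi = rng.normal(size=(200, 4))
        y = rng.integers(0, 3, size=200)
        B = rng.normal(size=(4, 4)) + 2 * np.eye(4)
        h0 = h_score(phi, y, pseudoinverse=False)
        h1 = h_score(phi @ B, y, pseudoinverse=False)
        assert h1 == pytest.approx(h0, abs=1e-8)

    def test_single_class_rejected(self, rng):
        with pytest.raises(DegenerateDataError):
            h_score(rng.normal(size=(10, 2)), np.zeros(10))


class TestHypothesisMargin:
    def test_duplicate_sets_have_negative_margin(self, rng):
        X = rng.normal(size=(20, 3))
        assert hypothesis_margin(X, X, downsample=1) < 0.0

    def test_separated_clusters_margin_is_half_the_gap(self, rng):
        Xs = rng.normal(0.0, 0.01, size=(10, 2))
        Xt = rng.normal(0.0, 0.01, size=(10, 2)) + np.array([10.0, 0.0])
        m = hypothesis_margin(Xs, Xt, downsample=1)
        assert m == pytest.approx(
            hypothesis_margin_loops(Xs, Xt), abs=1e-12
        )
        assert m == pytest.approx(5.0, abs=0.1)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_without_downsampling(self, seed):
        rng = np.random.default_rng(seed)
        Xs = rng.normal(size=(17, 3))
        Xt = rng.normal(0.5, 1.2, size=(23, 3))
        assert hypothesis_margin(Xs, Xt, downsample=1) == pytest.approx(
            hypothesis_margin_loops(Xs, Xt), abs=1e-10
        )

    def test_downsampling_is_a_deterministic_stride(self, rng):
        Xs = rng.normal(size=(100, 2))
        Xt = rng.normal(size=(100, 2))
        a = hypothesis_margin(Xs, Xt, downsample=10, seed=5)
        b = hypothesis_margin(Xs, Xt, downsample=10, seed=5)
        assert a == b

    def test_overly_aggressive_downsampling_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            hypothesis_margin(
                rng.normal(size=(5, 2)), rng.normal(size=(5, 2)), downsample=5
            )


class TestSilhouetteCross:
    def test_well_separated_sets_approach_one(self, rng):
        Xs = rng.normal(0, 0.5, size=(50, 3))
        Xt = rng.normal(0, 0.5, size=(50, 3)) + 40.0
        assert silhouette_cross(Xs, Xt) >= 0.95

    def test_same_distribution_is_near_zero(self):
        rng = np.random.default_rng(8)
        Xs = rng.normal(size=(500, 3))
        Xt = rng.normal(size=(500, 3))
        assert abs(silhouette_cross(Xs, Xt)) < 0.05

    @pytest.mark.parametrize("seed", range(3))
    def test_bounded_and_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Xs = rng.normal(size=(12, 2))
        Xt = rng.normal(1, 2, size=(15, 2))
        v = silhouette_cross(Xs, Xt)
        assert -1.0 <= v <= 1.0
        assert v == pytest.approx(silhouette_cross_loops(Xs, Xt), abs=1e-10)

    def test_agrees_with_sklearn_two_cluster_silhouette(self, rng):
        Xs = rng.normal(size=(30, 3))
        Xt = rng.normal(2, 1, size=(40, 3))
        X = np.vstack([Xs, Xt])
        labels = np.array([0] * 30 + [1] * 40)
        assert silhouette_cross(Xs, Xt) == pytest.approx(
            float(silhouette_score(X, labels)), abs=1e-10
        )


class TestTDAS:
    @staticmethod
    def _pair(rng, ns=5, nt=7, d=3):
        Xs = make_table(rng.normal(1.0, 1.0, size=(ns, d)))
        Xt = make_table(rng.normal(1.5, 1.0, size=(nt, d)))
        return Xs, Xt

    def test_saturates_at_target_count_for_tiny_epsilon(self, rng):
        Xs, Xt = self._pair(rng, ns=10, nt=12)
        sa = fit_subspace_alignment(Xs, Xt, k=3)
        sims = project_source(sa, Xs).features @ project_target(sa, Xt).features.T
        from scipy.spatial.distance import pdist

        m = np.median(pdist(Xt.features))
        if sims.min() > 0:
            eps_scale = 0.5 * sims.min() / m
            assert tdas(Xs, Xt, k=3, eps_scale=eps_scale, adapt=sa) == Xt.n
        eps_scale_hi = 2.0 * max(sims.max(), 1e-6) / m
        assert tdas(Xs, Xt, k=3, eps_scale=eps_scale_hi, adapt=sa) == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Xs, Xt = self._pair(rng)
        sa = fit_subspace_alignment(Xs, Xt, k=2)
        S = project_source(sa, Xs).features
        T = project_target(sa, Xt).features
        from scipy.spatial.distance import pdist

        m = np.median(pdist(Xt.features))
        got = tdas(Xs, Xt, k=2, eps_scale=1.0, adapt=sa)
        assert got == pytest.approx(tdas_loops(S, T, m), abs=1e-10)

    def test_degenerate_target_rejected(self):
        Xs = make_table(np.random.default_rng(0).normal(size=(5, 2)))
        Xt = make_table(np.ones((5, 2)))
        with pytest.raises(DegenerateDataError):
            tdas(Xs, Xt, k=2)


class TestMMDMeasure:
    def test_identical_tables_score_zero(self, rng):
        X = make_table(rng.normal(size=(40, 3)))
        assert mmd_measure(X, X) == 0.0

    def test_delegates_to_quadratic_estimator_bit_for_bit(self, rng):
        Xs = make_table(rng.normal(size=(30, 3)))
        Xt = make_table(rng.normal(1, 1, size=(30, 3)))
        spec = median_heuristic(
            np.vstack([Xs.features, Xt.features]), scale=10.0
        )
        assert mmd_measure(Xs, Xt, gamma_scale=10.0) == mmd2_quadratic(
            Xs.features, Xt.features, spec
        ).mmd2

    def test_bandwidth_scale_changes_the_value(self, rng):
        Xs = make_table(rng.normal(size=(50, 3)))
        Xt = make_table(rng.normal(1.0, 1.0, size=(50, 3)))
        v_low = mmd_measure(Xs, Xt, gamma_scale=0.1)
        v_high = mmd_measure(Xs, Xt, gamma_scale=10.0)
        assert v_low >= 0 and v_high >= 0
        assert v_low != v_high


class TestMeasureBattery:
    def test_reports_cover_the_full_battery(self, rng):
        cfg = ShiftConfig(
            n_subjects=4, recordings_per_subject=(1, 1),
            epochs_per_recording=40, shift=1.0, seed=2,
        )
        src, tgt = make_domain_pair(cfg)
        post = make_posteriors(tgt.labels, accuracy=0.7, Z=5, seed=0)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports = evaluate_measures(src, tgt, posteriors=post)
        names = sorted({r.measure for r in reports})
        assert names == [
            "h_score", "hypothesis_margin", "leep", "mmd", "silhouette", "tdas",
        ]
        assert sum(r.measure == "mmd" for r in reports) == 3
        assert sum(r.measure == "tdas" for r in reports) == 3

    def test_measures_invariant_to_sample_order(self, rng):
        Xs = make_table(rng.normal(size=(40, 3)))
        Xt = make_table(rng.normal(0.5, 1, size=(40, 3)))
        ps, pt = rng.permutation(40), rng.permutation(40)
        Xs2, Xt2 = Xs.subset(ps), Xt.subset(pt)
        assert mmd_measure(Xs, Xt) == pytest.approx(mmd_measure(Xs2, Xt2), abs=1e-12)
        assert silhouette_cross(Xs.features, Xt.features) == pytest.approx(
            silhouette_cross(Xs2.features, Xt2.features), abs=1e-12
        )
        assert hypothesis_margin(
            Xs.features, Xt.features, downsample=1
        ) == pytest.approx(
            hypothesis_margin(Xs2.features, Xt2.features, downsample=1), abs=1e-12
        )
        assert tdas(Xs, Xt, k=3) == pytest.approx(tdas(Xs2, Xt2, k=3), abs=1e-10)

    def test_shift_family_orders_the_geometry_measures(self):
        # smaller-n version of the monotone family; full size in acceptance
        mmds, sils, margins, tdass = [], [], [], []
        import warnings

        for s in (0.0, 1.0, 4.0):
            cfg = ShiftConfig(
                n_subjects=5, recordings_per_subject=(1, 1),
                epochs_per_recording=100, shift=s, seed=7,
            )
            src, tgt = make_domain_pair(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mmds.append(mmd_measure(src, tgt))
                tdass.append(tdas(src, tgt, eps_scale=1.0))
            sils.append(silhouette_cross(src.features, tgt.features))
            margins.append(
                hypothesis_margin(src.features, tgt.features, seed=1)
            )
        assert mmds[0] < mmds[1] < mmds[2]
        assert tdass[0] >= tdass[1] >= tdass[2]
        assert sils[0] <= sils[1] <= sils[2]
        assert margins[0] <= margins[1] <= margins[2]
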