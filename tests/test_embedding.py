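import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from genembed.embedding import (
    ConfoundRegressor,
    SampleStandardScaler,
    ScoreSpace,
    build_score_space,
    first_eigenvariate,
    functional_connectivity_features,
    regional_activity_features,
    residualize_confounds,
    standardize,
)
from genembed.invert import PosteriorFit
from genembed.network import BoldRecord


def _space(X, names=None):
    X = np.atleast_2d(X)
    names = names or [f"f{j}" for j in range(X.shape[1])]
    return ScoreSpace(X=X, feature_names=tuple(names),
                      subject_ids=tuple(f"s{i}" for i in range(X.shape[0])))


def _mock_fit(theta, priors):
    theta = np.asarray(theta, float)
    full = np.concatenate([theta, np.zeros(priors.n_model - theta.size)])
    return PosteriorFit(
        posterior_mean=full, posterior_cov=np.eye(full.size),
        free_energy=0.0, noise_log_precision=np.zeros(3),
        free_energy_trace=np.array([0.0]), n_iterations=1, converged=True,
        r2_per_region=np.zeros(3), residual_sd_per_region=np.zeros(3),
        parameter_names=priors.names[: priors.n_model], n_neuronal=12,
    )


class TestFirstEigenvariate:
    def test_rank_one_recovery(self):
        rng = np.random.default_rng(0)
        w = np.abs(rng.standard_normal(20)) + 0.1
        t = rng.standard_normal(100)
        v = first_eigenvariate(np.outer(w, t))
        r = np.corrcoef(v, t - t.mean())[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_single_voxel_returns_centred_course(self):
        ts = np.array([[1.0, 3.0, 5.0, 7.0]])
        v = first_eigenvariate(ts)
        centred = ts[0] - ts[0].mean()
        assert np.allclose(v / np.linalg.norm(v), centred / np.linalg.norm(centred))

    def test_matches_dense_svd_oracle(self):
        rng = np.random.default_rng(1)
        M = rng.standard_normal((50, 200))
        v = first_eigenvariate(M)
        Mc = M - M.mean(axis=1, keepdims=True)
        _, _, Vt = np.linalg.svd(Mc)
        assert abs(np.corrcoef(v, Vt[0])[0, 1]) == pytest.approx(1.0, abs=1e-10)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            first_eigenvariate(np.zeros((5, 10)))


class TestBuildScoreSpace:
    def test_shape_and_ordering(self, priors):
        rng = np.random.default_rng(0)
        thetas = rng.standard_normal((41, 12))
        fits = [_mock_fit(t, priors) for t in thetas]
        space = build_score_space(fits, spec=_wm())
        assert space.X.shape == (41, 12)
        assert np.allclose(space.X, thetas)

    def test_prior_mean_row(self, priors):
        space = build_score_space([_mock_fit(priors.mean[:12], priors)], _wm())
        assert np.allclose(space.X[0], priors.mean[:12])

    def test_reordering_fits_permutes_rows(self, priors):
        rng = np.random.default_rng(2)
        thetas = rng.standard_normal((5, 12))
        fits = [_mock_fit(t, priors) for t in thetas]
        a = build_score_space(fits, _wm()).X
        b = build_score_space(fits[::-1], _wm()).X
        assert np.allclose(b, a[::-1])

    def test_excludes_haemodynamic_and_noise_parameters(self, priors):
        space = build_score_space([_mock_fit(np.zeros(12), priors)], _wm())
        assert all(
            not n.startswith(("hemo[", "noise")) for n in space.feature_names
        )
        assert space.n_features == 12


def _wm():
    from genembed.network import wm_network

    return wm_network()


class TestResidualize:
    def test_intercept_only_centres_columns(self):
        rng = np.random.default_rng(0)
        space = _space(rng.standard_normal((20, 3)))
        out = residualize_confounds(space, pd.DataFrame(index=range(20)))
        assert np.allclose(out.X, space.X - space.X.mean(axis=0), atol=1e-12)

    def test_feature_linear_in_confound_becomes_zero(self):
        age = np.linspace(20, 60, 30)
        space = _space((2.0 * age)[:, None])
        out = residualize_confounds(space, pd.DataFrame({"age": age}))
        assert np.abs(out.X).max() < 1e-10

    def test_residuals_orthogonal_to_confounds(self):
        rng = np.random.default_rng(3)
        conf = pd.DataFrame({"age": rng.normal(40, 10, 200),
                             "sex": rng.binomial(1, 0.5, 200).astype(float)})
        space = _space(rng.standard_normal((200, 4)))
        out = residualize_confounds(space, conf)
        for c in conf.columns:
            assert np.abs(out.X.T @ (conf[c] - conf[c].mean())).max() < 1e-8

    def test_noise_variance_preserved(self):
        rng = np.random.default_rng(4)
        n = 500
        age = rng.normal(40, 10, n)
        noise = rng.standard_normal(n)
        space = _space((0.5 * age + noise)[:, None])
        out = residualize_confounds(space, pd.DataFrame({"age": age}))
        assert out.X[:, 0].var() == pytest.approx(noise.var(), rel=0.05)

    def test_collinear_confounds_named(self):
        rng = np.random.default_rng(5)
        age = rng.normal(40, 10, 30)
        conf = pd.DataFrame({"age": age, "age_copy": 2 * age})
        with pytest.raises(ValueError, match="age_copy"):
            residualize_confounds(_space(rng.standard_normal((30, 2))), conf)


class TestStandardize:
    def test_idempotent(self):
        rng = np.random.default_rng(0)
        z1 = standardize(_space(rng.standard_normal((50, 3))))
        z2 = standardize(z1)
        assert np.abs(z1.X - z2.X).max() < 1e-12

    def test_sample_sd_convention(self):
        out = standardize(_space(np.array([[0.0], [2.0]])))
        # sample SD of (0, 2) is sqrt(2): z = (-1, 1)/sqrt(2) * sqrt(2) ... = +-0.70711
        assert np.allclose(out.X[:, 0], [-0.70711, 0.70711], atol=1e-5)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="f1"):
            standardize(_space(np.column_stack([np.arange(5.0), np.ones(5)])))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_zero_mean_property(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(5, 3, (12, 4))
        out = standardize(_space(X))
        assert np.abs(out.X.mean(axis=0)).max() < 1e-12

    def test_residualize_then_standardize_keeps_zero_mean(self):
        rng = np.random.default_rng(6)
        conf = pd.DataFrame({"age": rng.normal(40, 10, 40)})
        space = _space(rng.standard_normal((40, 3)))
        out = standardize(residualize_confounds(space, conf))
        assert np.abs(out.X.mean(axis=0)).max() < 1e-12
        assert out.log[-1]["step"] == "standardize"


class TestFunctionalConnectivity:
    def _rec(self, y):
        return BoldRecord(y=y, TR=2.0, region_names=("VC", "PC", "DLPFC"))

    def test_duplicated_region_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(100)
        y = np.column_stack([a, a, rng.standard_normal(100)])
        space = functional_connectivity_features([self._rec(y)])
        assert space.X[0, 0] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal((10_000, 3))
        space = functional_connectivity_features([self._rec(y)])
        assert np.abs(space.X).max() < 0.05

    def test_three_regions_three_features(self):
        rng = np.random.default_rng(2)
        space = functional_connectivity_features(
            [self._rec(rng.standard_normal((50, 3)))]
        )
        assert space.n_features == 3
        assert space.provenance == "functional_connectivity"

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal((80, 3))
        y2 = y.copy()
        y2[:, 1] = 5.0 * y2[:, 1] - 3.0
        a = functional_connectivity_features([self._rec(y)]).X
        b = functional_connectivity_features([self._rec(y2)]).X
        assert np.allclose(a, b, atol=1e-12)

    def test_constant_region_rejected(self):
        y = np.column_stack([np.ones(50), np.arange(50.0), np.arange(50.0)])
        with pytest.raises(ValueError, match="VC"):
            functional_connectivity_features([self._rec(y)])


class TestRegionalActivity:
    def test_constant_voxels(self):
        space = regional_activity_features(
            [{"VC": np.full(10, 3.0), "PC": np.full(10, 3.0),
              "DLPFC": np.full(10, 3.0)}]
        )
        assert np.allclose(space.X[0, ::2], 3.0)
        assert np.allclose(space.X[0, 1::2], 0.0)

    def test_hand_computed_mean_sd(self):
        space = regional_activity_features(
            [{"VC": np.array([1.0, 2.0, 3.0]), "PC": np.ones(2), "DLPFC": np.ones(2)}]
        )
        assert space.X[0, 0] == pytest.approx(2.0)
        assert space.X[0, 1] == pytest.approx(1.0)  # sample SD

    def test_three_regions_six_features(self):
        rng = np.random.default_rng(0)
        space = regional_activity_features(
            [{r: rng.standard_normal(20) for r in ("VC", "PC", "DLPFC")}]
        )
        assert space.n_features == 6

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError, match="PC"):
            regional_activity_features([{"PC": np.array([1.0])}])


class TestTransformers:
    def test_confound_regressor_round_trip(self):
        rng = np.random.default_rng(0)
        conf = rng.standard_normal((50, 2))
        X = rng.standard_normal((50, 3)) + conf @ rng.standard_normal((2, 3))
        resid = ConfoundRegressor().fit_transform(X, conf)
        assert np.abs(resid.T @ (conf - conf.mean(axis=0))).max() < 1e-8

    def test_scaler_uses_sample_sd(self):
        X = np.array([[0.0], [2.0]])
        z = SampleStandardScaler().fit_transform(X)
        assert np.allclose(z[:, 0], [-1 / np.sqrt(2), 1 / np.sqrt(2)])
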