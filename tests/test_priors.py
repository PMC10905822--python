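import numpy as np
import pytest
from scipy import stats

from bernexp import (
    GaussianPriorSpec,
    ModelParameters,
    PanelDataset,
    SubjectRecord,
    fisher_information_alpha,
    jeffreys_log_prior_alpha,
    log_prior_gaussian,
    preset_scheme,
)
from conftest import random_params, random_tiny_panel


def _spec(p=2, var=1.0, means=0.0):
    return GaussianPriorSpec(
        alpha_mean=np.full(p, means),
        alpha_cov=var * np.eye(p),
        psi=(means, var), vartheta=(means, var), xi=(means, var), gamma=(means, var),
    )


def _intercept_panel(m, pattern=None):
    """Intercept-only subjects; with alpha = 0 every visit mean is 0.5."""
    visits = pattern or [(1.0, 1)] * m
    return PanelDataset([SubjectRecord("s", x=[1.0], visits=visits)])


class TestGaussianLogPrior:
    def test_standard_normal_blocks_at_mean(self):
        # each scalar at its prior mean with unit variance contributes -ln(2*pi)/2,
        # the alpha block -(p/2) ln(2*pi)
        p = 2
        params = ModelParameters(alpha=np.zeros(p), psi=0, vartheta=0, xi=0, gamma=0)
        expected = -(p + 4) / 2 * np.log(2 * np.pi)
        assert log_prior_gaussian(params, _spec(p)) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_densities_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = 3
            A = rng.normal(size=(p, p))
            cov = A @ A.T + p * np.eye(p)
            spec = GaussianPriorSpec(
                alpha_mean=rng.normal(size=p), alpha_cov=cov,
                psi=(rng.normal(), 0.5 + rng.random()),
                vartheta=(rng.normal(), 0.5 + rng.random()),
                xi=(rng.normal(), 0.5 + rng.random()),
                gamma=(rng.normal(), 0.5 + rng.random()),
            )
            params = random_params(rng, p)
            expected = stats.multivariate_normal.logpdf(params.alpha, spec.alpha_mean, cov)
            for name in ("psi", "vartheta", "xi", "gamma"):
                mean, var = getattr(spec, name)
                expected += stats.norm.logpdf(getattr(params, name), mean, np.sqrt(var))
            assert log_prior_gaussian(params, spec) == pytest.approx(expected, abs=1e-10)

    def test_maximised_at_hyperparameter_means(self):
        rng = np.random.default_rng(8)
        spec = _spec(2, var=2.0, means=0.7)
        at_mean = log_prior_gaussian(
            ModelParameters(alpha=[0.7, 0.7], psi=0.7, vartheta=0.7, xi=0.7, gamma=0.7), spec
        )
        for _ in range(10):
            other = random_params(rng, 2)
            assert log_prior_gaussian(other, spec) <= at_mean

    def test_non_positive_definite_cov_rejected(self):
        spec = GaussianPriorSpec(
            alpha_mean=[0.0, 0.0], alpha_cov=[[1.0, 2.0], [2.0, 1.0]],
            psi=(0, 1), vartheta=(0, 1), xi=(0, 1), gamma=(0, 1),
        )
        params = ModelParameters(alpha=[0.0, 0.0], psi=0, vartheta=0, xi=0, gamma=0)
        with pytest.raises(ValueError, match="positive definite"):
            log_prior_gaussian(params, spec)

    def test_noninformative_scheme_near_flat(self):
        # log-prior differences below 1e-3 for coordinates bounded by 100
        scheme = preset_scheme("noninformative", 3)
        rng = np.random.default_rng(2)
        a = ModelParameters(alpha=rng.uniform(-100, 100, 3), psi=50.0, vartheta=-100.0,
                            xi=100.0, gamma=-7.0)
        b = ModelParameters(alpha=rng.uniform(-100, 100, 3), psi=-100.0, vartheta=3.0,
                            xi=-88.0, gamma=100.0)
        diff = log_prior_gaussian(a, scheme.gaussian) - log_prior_gaussian(b, scheme.gaussian)
        assert abs(diff) < 1e-3


class TestFisherInformation:
    def test_intercept_only_half_means(self):
        info = fisher_information_alpha([0.0], _intercept_panel(4), (0.0, 0.0))
        assert info.shape == (1, 1)
        assert info[0, 0] == pytest.approx(1.0, abs=1e-14)  # 4 rows x 0.25

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        data = random_tiny_panel(rng)
        info = fisher_information_alpha(rng.normal(size=3), data, (0.3, 0.1))
        assert np.max(np.abs(info - info.T)) < 1e-12

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(10)
        data = random_tiny_panel(rng)
        alpha = rng.normal(size=3)
        psi, vt = 0.4, -0.2
        info = fisher_information_alpha(alpha, data, (psi, vt))
        brute = np.zeros((3, 3))
        for s in data.subjects:
            y_prev = None
            for k, (t, y) in enumerate(s.visits, start=1):
                eta = s.x @ alpha + ((vt * t + psi * y_prev) if k > 1 else 0.0)
                mu = 1 / (1 + np.exp(-eta))
                brute += mu * (1 - mu) * np.outer(s.x, s.x)
                y_prev = y
        assert np.allclose(info, brute, atol=1e-12)


class TestJeffreysPrior:
    def test_unit_information_gives_zero(self):
        assert jeffreys_log_prior_alpha([0.0], _intercept_panel(4), (0.0, 0.0)) == pytest.approx(
            0.0, abs=1e-14
        )

    @pytest.mark.parametrize("m", [1, 3, 8, 40])
    def test_intercept_closed_form(self, m):
        lp = jeffreys_log_prior_alpha([0.0], _intercept_panel(m), (0.0, 0.0))
        assert lp == pytest.approx(0.5 * np.log(m / 4), abs=1e-12)

    def test_column_scaling_law(self):
        # scaling all covariate columns by c adds p*ln|c| to the log prior;
        # needs >= p subjects since covariate rows repeat within subject
        rng = np.random.default_rng(12)
        data = PanelDataset(
            [
                SubjectRecord(i, x=np.concatenate([[1.0], rng.normal(size=2)]),
                              visits=[(1.0, 1), (0.5, 0)])
                for i in range(4)
            ]
        )
        alpha = rng.normal(size=3) * 0.2
        c = 2.5
        scaled = PanelDataset(
            [
                SubjectRecord(s.subject_id, x=c * s.x, visits=s.visits)
                for s in data.subjects
            ]
        )
        lp = jeffreys_log_prior_alpha(alpha, data, (0.1, 0.1))
        lp_scaled = jeffreys_log_prior_alpha(np.asarray(alpha) / c, scaled, (0.1, 0.1))
        assert lp_scaled - lp == pytest.approx(3 * np.log(c), abs=1e-9)

    def test_singular_information_warns_minus_inf(self):
        # perfectly collinear covariates
        data = PanelDataset(
            [SubjectRecord("s", x=[1.0, 2.0], visits=[(1.0, 1), (0.5, 0)])]
        )
        with pytest.warns(RuntimeWarning, match="singular"):
            lp = jeffreys_log_prior_alpha([0.0, 0.0], data, (0.0, 0.0))
        assert lp == -np.inf

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(13)
        data = random_tiny_panel(rng)
        alpha = rng.normal(size=3)
        perm = PanelDataset(list(data.subjects)[::-1])
        assert jeffreys_log_prior_alpha(alpha, perm, (0.2, 0.1)) == pytest.approx(
            jeffreys_log_prior_alpha(alpha, data, (0.2, 0.1)), rel=1e-12
        )


class TestPresets:
    def test_noninformative_values(self):
        s = preset_scheme("noninformative", 7)
        g = s.gaussian
        assert s.tag == "gaussian_noninformative"
        assert np.all(g.alpha_mean == 0) and np.allclose(g.alpha_cov, 1e8 * np.eye(7))
        for name in ("psi", "vartheta", "xi", "gamma"):
            assert getattr(g, name) == (0.0, 1e8)

    def test_simulation_informative_values(self):
        g = preset_scheme("informative", 7).gaussian
        assert np.allclose(g.alpha_mean, 0.6) and np.allclose(g.alpha_cov, 5.0 * np.eye(7))
        assert g.vartheta == (0.2, 0.3)
        assert g.psi == (0.3, 0.4)
        assert g.xi == (0.3, 0.2)
        assert g.gamma == (1.0, 1.5)  # the published omega slot, mapped to gamma

    def test_bladder_informative_values(self):
        g = preset_scheme("informative", 4, study="bladder").gaussian
        assert np.allclose(g.alpha_mean, 0.4) and np.allclose(g.alpha_cov, 4.0 * np.eye(4))
        assert g.xi == (2.0, 0.2)
        assert g.gamma == (0.2, 0.1)
        assert g.vartheta == (0.5, 0.5)
        assert g.psi == (0.2, 0.2)

    def test_jeffreys_tag(self):
        assert preset_scheme("jeffreys", 4).is_jeffreys

    def test_unknown_name_lists_valid(self):
        with pytest.raises(ValueError, match="informative.*noninformative.*jeffreys"):
            preset_scheme("flat", 4)
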