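"""MCMC sampling, bridge-sampling evidence and posterior model weights."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from bmdkit.averaging import posterior_model_weights, select_exponential
from bmdkit.evidence import bridge_sampling_evidence
from bmdkit.mcmc import (
    DegenerateLikelihoodError,
    McmcSettings,
    ModelFit,
    _run_single_chain,
    run_mcmc,
)
from bmdkit.models import PriorBox, get_model
from bmdkit.simulate import StudyDesign, generate_study


class TestRunMcmc:
    def test_retained_draw_count(self):
        assert McmcSettings(iterations=30000, warmup_fraction=0.5).n_retained == 15000
        ds = generate_study(
            StudyDesign("s", "e", (0.0, 1.0, 10.0), 10, "linear", (10.0, 1.0),
                        0.2, 1)
        )
        fit = run_mcmc(ds, get_model("linear", dose_scale=10.0),
                       McmcSettings(iterations=3000, seed=5))
        assert fit.draws.shape == (1500, 3)  # a, b, sigma

    def test_same_seed_identical_draws(self, hill_dataset):
        m = get_model("hill", direction=+1, dose_scale=hill_dataset.max_dose)
        settings = McmcSettings(iterations=2000, seed=11)
        f1 = run_mcmc(hill_dataset, m, settings)
        f2 = run_mcmc(hill_dataset, m, settings)
        np.testing.assert_array_equal(f1.draws, f2.draws)

    def test_different_seed_different_draws(self, hill_dataset):
        m = get_model("hill", direction=+1, dose_scale=hill_dataset.max_dose)
        f1 = run_mcmc(hill_dataset, m, McmcSettings(iterations=2000, seed=11))
        f2 = run_mcmc(hill_dataset, m, McmcSettings(iterations=2000, seed=12))
        assert not np.array_equal(f1.draws, f2.draws)

    def test_zero_variance_everywhere_is_degenerate(self):
        from bmdkit.data import DoseResponseDataset

        ds = DoseResponseDataset(
            "s", "e", [0.0, 0.0, 1.0, 1.0, 2.0, 2.0], [5.0, 5.0, 6.0, 6.0, 7.0, 7.0]
        )
        with pytest.raises(DegenerateLikelihoodError):
            run_mcmc(ds, get_model("linear", dose_scale=2.0), McmcSettings(iterations=2000))

    def test_linear_parameter_recovery(self):
        """Posterior means of a and b within 3 posterior SDs of the truth."""
        design = StudyDesign("s", "e", (0.0, 0.02, 0.2, 20.0, 200.0), 50,
                             "linear", (100.0, 1.0), 0.1, 99)
        ds = generate_study(design)
        m = get_model("linear", dose_scale=ds.max_dose)
        fit = run_mcmc(ds, m, McmcSettings(iterations=10000, seed=3))
        mean = fit.draws.mean(axis=0)
        sd = fit.draws.std(axis=0)
        # b is fitted on the scaled dose axis: b_scaled = b_true * dmax
        truth = np.array([100.0, 1.0 * ds.max_dose, 0.1])
        assert np.all(np.abs(mean - truth) < 3.0 * sd)

    def test_multichain_rhat_close_to_one(self, hill_dataset):
        m = get_model("linear", dose_scale=hill_dataset.max_dose)
        fit = run_mcmc(hill_dataset, m, McmcSettings(iterations=4000, chains=2, seed=8))
        rhat = fit.diagnostics["split_rhat"]
        assert rhat.shape == (3,)
        assert np.all(rhat < 1.2)


class _ConjugateToy:
    """y_i ~ N(θ, s²) with θ ~ N(μ0, τ²): closed-form posterior/evidence."""

    def __init__(self, seed=1, n=20, s=1.3, mu0=0.5, tau=2.0):
        rng = np.random.default_rng(seed)
        self.y = rng.normal(1.2, s, n)
        self.s, self.mu0, self.tau, self.n = s, mu0, tau, n
        post_var = 1.0 / (n / s**2 + 1.0 / tau**2)
        self.post_mean = post_var * (n * self.y.mean() / s**2 + mu0 / tau**2)
        self.post_sd = math.sqrt(post_var)

    def log_post(self, theta):
        th = float(theta[0])
        return float(np.sum(stats.norm.logpdf(self.y, th, self.s))) + float(
            stats.norm.logpdf(th, self.mu0, self.tau)
        )

    def analytic_evidence(self):
        cov = self.s**2 * np.eye(self.n) + self.tau**2 * np.ones((self.n, self.n))
        return float(
            stats.multivariate_normal.logpdf(self.y, np.full(self.n, self.mu0), cov)
        )

    def posterior_draws(self, n, seed):
        rng = np.random.default_rng(seed)
        return rng.normal(self.post_mean, self.post_sd, (n, 1))


class TestBridgeSampling:
    def test_conjugate_normal_evidence(self):
        toy = _ConjugateToy()
        fit = ModelFit("toy", ("theta",), toy.posterior_draws(4000, 2))
        est = bridge_sampling_evidence(fit, toy.log_post, seed=5)
        assert est == pytest.approx(toy.analytic_evidence(), abs=0.05)

    def test_one_parameter_bounded_model_vs_quadrature(self):
        rng = np.random.default_rng(1)
        y = rng.lognormal(math.log(7.0), 0.5, 15)
        sig, upper = 0.5, 50.0

        def loglik(a):
            return float(np.sum(stats.norm.logpdf(np.log(y), math.log(a), sig)
                                - np.log(y)))

        def log_post(theta):
            a = float(theta[0])
            if not 0.0 < a <= upper:
                return -math.inf
            return loglik(a) - math.log(upper)

        val, _ = integrate.quad(lambda a: math.exp(loglik(a)) / upper, 1e-6, upper,
                                limit=200)
        box = PriorBox(("a",), np.array([0.0]), np.array([upper]))
        draws, _ = _run_single_chain(log_post, np.array([7.0]), box, 20000, 10000,
                                     np.random.default_rng(3))
        est = bridge_sampling_evidence(ModelFit("toy", ("a",), draws), log_post, seed=9)
        assert est == pytest.approx(math.log(val), abs=0.05)

    def test_invariant_to_moment_matching_split(self):
        toy = _ConjugateToy()
        draws = toy.posterior_draws(4000, 2)
        fit_a = ModelFit("toy", ("theta",), draws)
        perm = np.random.default_rng(7).permutation(4000)
        fit_b = ModelFit("toy", ("theta",), draws[perm])
        est_a = bridge_sampling_evidence(fit_a, toy.log_post, seed=5)
        est_b = bridge_sampling_evidence(fit_b, toy.log_post, seed=6)
        assert abs(est_a - est_b) < 0.1

    def test_duplicated_data_evidence_tracks_oracle(self):
        """Doubling the independent observations doubles the likelihood
        contribution; the bridge estimate must follow the analytic value."""
        toy1 = _ConjugateToy(n=10)
        y2 = np.concatenate([toy1.y, toy1.y])
        toy2 = _ConjugateToy(n=20)
        toy2.y = y2
        post_var = 1.0 / (20 / toy2.s**2 + 1.0 / toy2.tau**2)
        toy2.post_mean = post_var * (20 * y2.mean() / toy2.s**2 + toy2.mu0 / toy2.tau**2)
        toy2.post_sd = math.sqrt(post_var)
        fit = ModelFit("toy", ("theta",), toy2.posterior_draws(4000, 4))
        est = bridge_sampling_evidence(fit, toy2.log_post, seed=8)
        assert est == pytest.approx(toy2.analytic_evidence(), abs=0.05)

    def test_requires_enough_draws(self):
        toy = _ConjugateToy()
        fit = ModelFit("toy", ("theta",), toy.posterior_draws(500, 2))
        with pytest.raises(ValueError, match="1000"):
            bridge_sampling_evidence(fit, toy.log_post)


class TestModelWeights:
    def test_equal_evidence_gives_prior_weights(self):
        ev = {m: -100.0 for m in ("linear", "power", "michaelis_menten", "hill", "exp5")}
        w = posterior_model_weights(ev, {m: 0.2 for m in ev})
        assert all(v == pytest.approx(0.2) for v in w.posterior.values())

    def test_log_ml_gap_of_ln3(self):
        w = posterior_model_weights({"a": 0.0, "b": -math.log(3.0)},
                                    {"a": 0.5, "b": 0.5})
        assert w.posterior["a"] == pytest.approx(0.75)
        assert w.posterior["b"] == pytest.approx(0.25)

    def test_shift_invariance(self):
        ev = {"a": -10.0, "b": -12.0, "c": -11.0}
        w1 = posterior_model_weights(ev)
        w2 = posterior_model_weights({k: v + 1234.5 for k, v in ev.items()})
        for m in ev:
            assert w1.posterior[m] == pytest.approx(w2.posterior[m], rel=1e-12)

    def test_nonfinite_evidence_dropped_and_renormalized(self):
        w = posterior_model_weights({"a": -5.0, "b": math.nan, "c": -5.0},
                                    {"a": 0.2, "b": 0.6, "c": 0.2})
        assert set(w.posterior) == {"a", "c"}
        assert sum(w.posterior.values()) == pytest.approx(1.0)
        assert w.prior["a"] == pytest.approx(0.5)

    def test_weights_sum_to_one_and_nonnegative(self):
        w = posterior_model_weights({"a": -3.0, "b": -400.0, "c": -2.5})
        assert sum(w.posterior.values()) == pytest.approx(1.0)
        assert all(v >= 0 for v in w.posterior.values())


class TestSelectExponential:
    def test_argmax(self):
        assert select_exponential(-10.0, -5.0) == "exp5"
        assert select_exponential(-5.0, -10.0) == "exp3"

    def test_tie_breaks_to_exp5(self):
        assert select_exponential(-7.0, -7.0) == "exp5"
        assert select_exponential(-7.0 + 5e-10, -7.0) == "exp5"

    def test_nonfinite_falls_back(self):
        assert select_exponential(math.nan, -3.0) == "exp5"
        assert select_exponential(-3.0, math.nan) == "exp3"

    def test_exp5_selected_on_exp5_data(self):
        """Strong-curvature exp5 simulations pick exp5 in >= 8/10 replicates."""
        from bmdkit import BenchmarkDose, CesSpec

        picks = []
        for rep in range(10):
            design = StudyDesign("s", "e5", (0.0, 0.02, 0.2, 20.0, 200.0), 50,
                                 "exp5", (100.0, 0.012, 0.4, 2.0), 0.2, 3000 + rep,
                                 direction=-1)
            res = BenchmarkDose(
                generate_study(design), CesSpec.from_signed(-0.10),
                settings=McmcSettings(iterations=4000), models=("exp3", "exp5"),
            ).fit(seed=70 + rep)
            picks.append(res.exponential_choice)
        assert picks.count("exp5") >= 8
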