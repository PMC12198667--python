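"""BMD inversion, model-averaged estimates, QC screening and ranking."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from bmdkit.averaging import ModelWeights
from bmdkit.bmd import (
    CesSpec,
    InsufficientInformationError,
    QcCriteria,
    apply_qc,
    averaged_bmd,
    bmd_from_params,
    rank_endpoints,
)
from bmdkit.data import EndpointResultRow
from bmdkit.mcmc import ModelFit
from bmdkit.models import get_model


def _fit_with_bmds(name, bmds):
    draws = np.zeros((len(bmds), 2))
    fit = ModelFit(name, ("a", "sigma"), draws)
    fit.bmd_draws = np.asarray(bmds, dtype=float)
    return fit


def _weights(**kw):
    total = sum(kw.values())
    return ModelWeights(
        prior={k: 1.0 / len(kw) for k in kw},
        posterior={k: v / total for k, v in kw.items()},
    )


class TestBmdFromParams:
    def test_linear_example(self):
        ces = CesSpec.from_signed(+0.10)
        assert bmd_from_params(get_model("linear"), (100.0, 2.0), ces) == pytest.approx(5.0)

    def test_michaelis_menten_example(self):
        ces = CesSpec.from_signed(-0.10)
        got = bmd_from_params(get_model("michaelis_menten"), (100.0, -50.0, 10.0), ces)
        assert got == pytest.approx(2.5)

    def test_hill_example(self):
        ces = CesSpec.from_signed(+0.10)
        got = bmd_from_params(get_model("hill"), (10.0, 10.0, 50.0, 2.0), ces)
        assert got == pytest.approx(50.0 / 3.0)

    def test_wrong_direction_is_na(self):
        ces = CesSpec.from_signed(-0.10)
        assert math.isnan(bmd_from_params(get_model("linear"), (100.0, 2.0), ces))

    def test_asymptote_short_of_target_is_na(self):
        # MM asymptote at a+b = 95 cannot fall 10% below a = 100
        ces = CesSpec.from_signed(-0.10)
        got = bmd_from_params(get_model("michaelis_menten"), (100.0, -5.0, 10.0), ces)
        assert math.isnan(got)

    def test_extrapolation_cap(self):
        ces = CesSpec.from_signed(+0.10)
        m = get_model("linear")
        assert math.isnan(m.bmd((100.0, 1e-6), ces, max_dose=200.0))

    CASES = [
        ("linear", (100.0, 2.0), +1),
        ("linear", (50.0, -1.5), -1),
        ("power", (100.0, 0.5, 1.7), +1),
        ("michaelis_menten", (100.0, -60.0, 25.0), -1),
        ("michaelis_menten", (20.0, 15.0, 3.0), +1),
        ("hill", (10.0, 10.0, 50.0, 2.0), +1),
        ("hill", (80.0, -40.0, 12.0, 0.8), -1),
        ("exp3", (50.0, 0.01, 1.3), +1),
        ("exp5", (100.0, 0.02, 3.0, 1.4), +1),
        ("exp5", (900.0, 0.01, 0.5, 1.0), -1),
    ]

    @pytest.mark.parametrize("name,params,direction", CASES)
    @pytest.mark.parametrize("magnitude", [0.05, 0.10, 0.25])
    def test_closed_form_matches_root_finder(self, name, params, direction, magnitude):
        """Closed-form inversion against an independent bracketing solver."""
        ces = CesSpec(magnitude, direction)
        m = get_model(name, direction=direction)
        got = bmd_from_params(m, params, ces)
        target = params[0] * (1.0 + ces.direction * ces.magnitude)

        def f(d):
            return float(m.mean(np.asarray(params), d)) - target

        hi = 1e3 if name == "exp3" else 1e8  # exp3 overflows far beyond its root
        oracle = brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-15)
        assert got == pytest.approx(oracle, rel=1e-9)


class TestAveragedBmd:
    def test_degenerate_single_model(self):
        ces = CesSpec.from_signed(+0.10)
        fit = _fit_with_bmds("linear", np.full(2000, 7.0))
        est = averaged_bmd([fit], _weights(linear=1.0), ces, seed=1)
        assert (est.bmdl, est.bmd, est.bmdu) == (7.0, 7.0, 7.0)
        assert not est.clamped

    def test_matches_pooled_quantile_oracle(self):
        ces = CesSpec.from_signed(+0.10)
        a = np.arange(1.0, 1001.0)
        b = np.arange(1001.0, 2001.0)
        fits = [_fit_with_bmds("linear", a), _fit_with_bmds("hill", b)]
        est = averaged_bmd(fits, _weights(linear=0.5, hill=0.5), ces, seed=3,
                           n_resample=200_000)
        pooled = np.concatenate([a, b])
        lo, mid, hi = np.percentile(pooled, [5, 50, 95])
        assert est.bmdl == pytest.approx(lo, rel=0.03)
        assert est.bmd == pytest.approx(mid, rel=0.03)
        assert est.bmdu == pytest.approx(hi, rel=0.03)

    def test_weighted_mixture_shifts_toward_heavy_model(self):
        ces = CesSpec.from_signed(+0.10)
        fits = [_fit_with_bmds("linear", np.full(2000, 10.0)),
                _fit_with_bmds("hill", np.full(2000, 100.0))]
        est = averaged_bmd(fits, _weights(linear=0.9, hill=0.1), ces, seed=5)
        assert est.bmd == 10.0
        assert est.bmdu == 100.0

    def test_negative_lower_bound_clamped_to_zero(self):
        ces = CesSpec.from_signed(+0.10)
        draws = np.concatenate([np.full(500, -3.0), np.linspace(1, 100, 1500)])
        est = averaged_bmd([_fit_with_bmds("linear", draws)], _weights(linear=1.0),
                           ces, seed=2)
        assert est.bmdl == 0.0
        assert est.clamped

    def test_na_draws_excluded_and_flagged(self):
        ces = CesSpec.from_signed(+0.10)
        draws = np.concatenate([np.full(1500, np.nan), np.linspace(5, 15, 500)])
        est = averaged_bmd([_fit_with_bmds("linear", draws)], _weights(linear=1.0),
                           ces, seed=4)
        assert est.direction_inconsistent
        assert est.n_valid_draws < est.n_total_draws
        assert 5.0 <= est.bmd <= 15.0

    def test_too_few_valid_draws_raises(self):
        ces = CesSpec.from_signed(+0.10)
        draws = np.concatenate([np.full(1995, np.nan), np.full(5, 3.0)])
        with pytest.raises(InsufficientInformationError):
            averaged_bmd([_fit_with_bmds("linear", draws)], _weights(linear=1.0),
                         ces, seed=6)

    def test_interval_widens_with_credible_level(self):
        ces = CesSpec.from_signed(+0.10)
        rng = np.random.default_rng(0)
        fit = _fit_with_bmds("linear", rng.lognormal(3.0, 0.8, 4000))
        narrow = averaged_bmd([fit], _weights(linear=1.0), ces, seed=7,
                              credible_level=0.80)
        wide = averaged_bmd([fit], _weights(linear=1.0), ces, seed=7,
                            credible_level=0.95)
        assert wide.bmdl <= narrow.bmdl
        assert wide.bmdu >= narrow.bmdu


class TestQc:
    CRITERIA = QcCriteria.for_design(0.02)

    def test_accepted_row_passes(self):
        row = EndpointResultRow("prog", 0.10, 9.1, 36.6, 204.0, True)
        verdict = apply_qc(row, self.CRITERIA)
        assert verdict.passed and verdict.reasons == ()

    def test_bmd_bmdl_ratio_fails(self):
        row = EndpointResultRow("primordial", -0.10, 2.6, 193.0, 1499.0, False)
        verdict = apply_qc(row, self.CRITERIA)
        assert not verdict.passed
        assert "bmd_bmdl_ratio" in verdict.reasons
        assert "bmdu_bmdl_ratio" in verdict.reasons

    def test_zero_bmdl_fails_with_na_reason(self):
        row = EndpointResultRow("estrus", 0.10, 0.0, 230.0, 1329.0, False)
        verdict = apply_qc(row, self.CRITERIA)
        assert not verdict.passed
        assert "bmdl_zero_or_na" in verdict.reasons

    def test_dose_floor(self):
        row = EndpointResultRow("e", 0.10, 0.0015, 0.003, 0.01, False)
        verdict = apply_qc(row, self.CRITERIA)
        assert "bmdl_below_dose_floor" in verdict.reasons


class TestRanking:
    def _rows(self):
        return [
            EndpointResultRow("c", 0.10, 30.0, 60.0, 90.0, True),
            EndpointResultRow("a", 0.10, 9.1, 36.6, 204.0, True),
            EndpointResultRow("fail", 0.10, 0.0, 50.0, 100.0, False),
            EndpointResultRow("b", 0.10, 9.1, 20.0, 80.0, True),
        ]

    def test_sorted_by_bmdl_then_bmd_with_failures_last(self):
        ranked = rank_endpoints(self._rows())
        assert [r.endpoint_id for r in ranked] == ["b", "a", "c", "fail"]
        assert not ranked[-1].qc_pass

    @given(st.permutations(range(4)))
    def test_invariant_under_permutation(self, perm):
        rows = self._rows()
        ranked = rank_endpoints([rows[i] for i in perm])
        assert [r.endpoint_id for r in ranked] == ["b", "a", "c", "fail"]


class TestCesSpec:
    def test_from_signed(self):
        ces = CesSpec.from_signed(-0.05)
        assert ces.magnitude == 0.05 and ces.direction == -1
        assert ces.signed == -0.05

    @pytest.mark.parametrize("bad", [0.0, 1.0, -1.5])
    def test_invalid_magnitude_rejected(self, bad):
        with pytest.raises(ValueError):
            CesSpec.from_signed(bad)
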