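import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rodcone.core import ParameterError, Trace, UndefinedIndexError
from rodcone.interaction import (DEFAULT_OFFSETS, biphasic_index,
                                 interaction_index, offset_sweep,
                                 predict_flash_response,
                                 predict_paired_response,
                                 scale_filter_to_flash)
from rodcone.ln import LNModel
from rodcone.nonlinearities import Linear, ThresholdLinear
from rodcone.synthetic import make_biphasic_filter


def _bump(onset, amp, n=2000, dt=0.001, width=0.05):
    """A smooth positive flash-response-like bump."""
    t = dt * np.arange(n)
    x = np.maximum(t - onset, 0.0) / width
    return Trace(amp * x * np.exp(1.0 - x), dt)


class TestScaleFilterToFlash:
    def test_identity_nonlinearity_inverts_directly(self, rod):
        model = LNModel(rod, Linear(), rod.dt)
        scaling = scale_filter_to_flash(model, 3.0)
        assert scaling.alpha == pytest.approx(3.0, rel=1e-9)

    def test_threshold_linear_closed_form(self, rod):
        """For N(x) = g*max(x - theta, 0) and a unit-peak filter the scale
        satisfies alpha = theta + peak/g."""
        theta, gain, peak = 0.2, 2.5, 1.7
        model = LNModel(rod, ThresholdLinear(theta, gain), rod.dt)
        scaling = scale_filter_to_flash(model, peak)
        assert scaling.alpha == pytest.approx(theta + peak / gain, rel=1e-9)

    def test_predicted_peak_matches_target(self, rod_model):
        scaling = scale_filter_to_flash(rod_model, 1.0)
        resp = predict_flash_response(rod_model, scaling, onset=0.2,
                                      duration=1.0)
        base = float(np.asarray(rod_model.nonlinearity(0.0)))
        assert resp.values.max() - base == pytest.approx(1.0, rel=1e-6)

    def test_nonpositive_target_rejected(self, rod_model):
        with pytest.raises(ParameterError):
            scale_filter_to_flash(rod_model, 0.0)

    def test_bounded_nonlinearity_rejected(self, rod):
        from rodcone.ln import NonlinearityEstimate
        flat = NonlinearityEstimate(np.array([0.0, 1.0]),
                                    np.array([0.5, 0.5]),
                                    np.array([5.0, 5.0]))
        with pytest.raises(ParameterError):
            scale_filter_to_flash(LNModel(rod, flat, rod.dt), 2.0)


class TestPredictResponses:
    def test_identity_nonlinearity_shifts_scaled_filter(self, rod):
        model = LNModel(rod, Linear(), rod.dt)
        scaling = scale_filter_to_flash(model, 2.0)
        resp = predict_flash_response(model, scaling, onset=0.1, duration=1.0)
        i0 = resp.index_at(0.1)
        assert np.allclose(resp.values[i0:i0 + len(rod)], 2.0 * rod.taps)
        assert np.allclose(resp.values[:i0], 0.0)

    def test_paired_equals_sum_under_identity(self, rod, cone):
        paired = predict_paired_response(rod, 1.5, cone, 2.0, 0.3, Linear(),
                                         adapt_onset=0.2, duration=1.5)
        a = predict_flash_response(LNModel(rod, Linear(), rod.dt),
                                   scale_filter_to_flash(
                                       LNModel(rod, Linear(), rod.dt), 1.5),
                                   onset=0.2, duration=1.5)
        t = predict_flash_response(LNModel(cone, Linear(), cone.dt),
                                   scale_filter_to_flash(
                                       LNModel(cone, Linear(), cone.dt), 2.0),
                                   onset=0.5, duration=1.5)
        assert np.allclose(paired.values, a.values + t.values, atol=1e-9)

    def test_rod_undershoot_suppresses_cone_test(self, rod, cone, shared_nl):
        """At a 0.2 s offset the cone test rides the rod undershoot, so the
        paired response in the test epoch is smaller than the test alone."""
        alpha = 1.0 + shared_nl.threshold
        paired = predict_paired_response(rod, alpha, cone, alpha, 0.2,
                                         shared_nl, adapt_onset=0.5,
                                         duration=2.0)
        model_c = LNModel(cone, shared_nl, cone.dt)
        test = predict_flash_response(model_c,
                                      scale_filter_to_flash(model_c, 1.0),
                                      onset=0.7, duration=2.0)
        adapt_model = LNModel(rod, shared_nl, rod.dt)
        adapt = predict_flash_response(adapt_model,
                                       scale_filter_to_flash(adapt_model, 1.0),
                                       onset=0.5, duration=2.0)
        i0, i1 = test.index_at(0.7), test.index_at(1.3)
        test_epoch_paired = paired.values[i0:i1] - adapt.values[i0:i1]
        assert test_epoch_paired.sum() < test.values[i0:i1].sum()


class TestInteractionIndex:
    def test_linear_sum_gives_zero(self):
        """paired = test + adapt is the linear-summation null: II = 0."""
        adapt, test = _bump(0.5, 2.0), _bump(0.8, 1.5)
        paired = test.with_values(test.values + adapt.values)
        res = interaction_index(test, paired, adapt, test_onset=0.8,
                                adapt_onset=0.5)
        assert res.ii == pytest.approx(0.0, abs=1e-12)

    def test_total_suppression_gives_one(self):
        """paired = adapt alone means the test evoked nothing: II = 1."""
        adapt, test = _bump(0.5, 2.0), _bump(0.8, 1.5)
        paired = adapt.with_values(adapt.values.copy())
        res = interaction_index(test, paired, adapt, test_onset=0.8,
                                adapt_onset=0.5)
        assert res.ii == pytest.approx(1.0, abs=1e-12)

    def test_formula_on_known_integrals(self):
        """R_single = 2, R_pair = 1.5 must give II = 0.25."""
        dt = 0.001
        n = 2000
        test = Trace(np.full(n, 2.0 / 0.6), dt)   # integral 2 over 0.6 s
        adapt = Trace(np.zeros(n), dt)
        paired = Trace(np.full(n, 1.5 / 0.6), dt)
        res = interaction_index(test, paired, adapt, test_onset=0.5,
                                window=0.6, baseline=0.0)
        assert res.r_single == pytest.approx(2.0, rel=1e-3)
        assert res.r_pair == pytest.approx(1.5, rel=1e-3)
        assert res.ii == pytest.approx(0.25, abs=1e-3)

    def test_zero_test_response_is_undefined(self):
        flat = Trace(np.zeros(2000), 0.001)
        bump = _bump(0.5, 1.0)
        with pytest.raises(UndefinedIndexError):
            interaction_index(flat, bump, bump, test_onset=0.8)

    def test_facilitation_flagged_not_clipped(self):
        adapt, test = _bump(0.5, 2.0), _bump(0.8, 1.5)
        paired = test.with_values(test.values * 1.5 + adapt.values)
        res = interaction_index(test, paired, adapt, test_onset=0.8,
                                adapt_onset=0.5)
        assert res.ii == pytest.approx(-0.5, abs=1e-9)
        assert res.facilitation

    @settings(deadline=None, max_examples=20)
    @given(scale=st.floats(0.01, 100.0))
    def test_invariant_to_uniform_rescaling(self, scale):
        adapt, test = _bump(0.5, 2.0), _bump(0.8, 1.5)
        paired = test.with_values(0.7 * test.values + adapt.values)
        a = interaction_index(test, paired, adapt, test_onset=0.8,
                              adapt_onset=0.5).ii
        b = interaction_index(
            test.with_values(scale * test.values),
            paired.with_values(scale * paired.values),
            adapt.with_values(scale * adapt.values),
            test_onset=0.8, adapt_onset=0.5).ii
        assert b == pytest.approx(a, rel=1e-9)


class TestOffsetSweep:
    def test_identity_nonlinearity_null_everywhere(self, rod, cone):
        sweep = offset_sweep((rod, 1.0), (cone, 1.0), Linear(),
                             direction="rod-cone")
        assert np.all(np.abs(sweep.indices) < 1e-9)
        sweep = offset_sweep((rod, 1.0), (cone, 1.0), Linear(),
                             direction="cone-rod")
        assert np.all(np.abs(sweep.indices) < 1e-9)

    def test_peak_offset_in_reported_band(self, rod, cone, shared_nl):
        alpha = 1.0 + shared_nl.threshold
        sweep = offset_sweep((rod, alpha), (cone, alpha), shared_nl,
                             direction="rod-cone")
        assert 0.1 <= sweep.peak_offset <= 0.3

    def test_no_overlap_at_long_offsets(self, rod, cone, shared_nl):
        """With 0.5 s filters, an 0.8 s offset leaves no temporal overlap,
        so the interaction must vanish."""
        alpha = 1.0 + shared_nl.threshold
        sweep = offset_sweep((rod, alpha), (cone, alpha), shared_nl,
                             offsets=[0.8], direction="rod-cone")
        assert abs(sweep.indices[0]) < 0.02

    def test_swap_symmetry_with_identical_filters(self, rod, shared_nl):
        alpha = 1.0 + shared_nl.threshold
        fwd = offset_sweep((rod, alpha), (rod, alpha), shared_nl,
                           direction="rod-cone")
        rev = offset_sweep((rod, alpha), (rod, alpha), shared_nl,
                           direction="cone-rod")
        assert np.allclose(fwd.indices, rev.indices, atol=1e-12)

    def test_asymmetry_with_default_presets(self, rod, cone, shared_nl):
        alpha = 1.0 + shared_nl.threshold
        k = int(np.argmin(np.abs(DEFAULT_OFFSETS - 0.2)))
        fwd = offset_sweep((rod, alpha), (cone, alpha), shared_nl,
                           direction="rod-cone").indices[k]
        rev = offset_sweep((rod, alpha), (cone, alpha), shared_nl,
                           direction="cone-rod").indices[k]
        assert fwd > rev

    def test_suppression_grows_with_rod_undershoot(self, cone, shared_nl):
        """rod->cone II at 0.2 s must be non-decreasing in the rod filter's
        undershoot ratio (deeper overshoot, stronger gating)."""
        alpha = 1.0 + shared_nl.threshold
        k = int(np.argmin(np.abs(DEFAULT_OFFSETS - 0.2)))
        last = -np.inf
        for ratio in [0.0, 0.2, 0.4, 0.6, 0.8]:
            if ratio == 0.0:
                rod_r = make_biphasic_filter(0.10, 0.20, 0.0, pathway="rod")
            else:
                rod_r = make_biphasic_filter(0.10, 0.20, ratio, pathway="rod")
            ii = offset_sweep((rod_r, alpha), (cone, alpha), shared_nl,
                              direction="rod-cone").indices[k]
            assert ii >= last - 1e-9
            last = ii

    def test_invalid_direction_rejected(self, rod, cone, shared_nl):
        with pytest.raises(ParameterError):
            offset_sweep((rod, 1.0), (cone, 1.0), shared_nl,
                         direction="sideways")


class TestBiphasicIndex:
    def test_purely_positive_response(self):
        res = biphasic_index(_bump(0.5, 2.0), flash_onset=0.5)
        assert res.bi == 0.0

    def test_symmetric_biphasic_response(self):
        dt = 0.001
        t = dt * np.arange(1500)
        vals = np.sin(2.0 * np.pi * (t - 0.5) / 0.3)
        vals[t < 0.5] = 0.0
        vals[t > 0.8] = 0.0
        res = biphasic_index(Trace(vals, dt), flash_onset=0.5)
        assert res.bi == pytest.approx(0.5, abs=1e-3)

    def test_rod_preset_closed_form(self, rod):
        """Under an identity nonlinearity the flash response is the filter,
        so BI = r/(1+r) with r the undershoot ratio (0.5 -> 1/3)."""
        model = LNModel(rod, Linear(), rod.dt)
        resp = predict_flash_response(model, scale_filter_to_flash(model, 1.0),
                                      onset=0.1, duration=1.0)
        res = biphasic_index(resp, flash_onset=0.1)
        assert res.bi == pytest.approx(0.5 / 1.5, rel=0.02)

    def test_flat_response_undefined(self):
        with pytest.raises(UndefinedIndexError):
            biphasic_index(Trace(np.zeros(1000), 0.001), flash_onset=0.2)

    @settings(deadline=None, max_examples=25)
    @given(data=st.lists(st.floats(-5.0, 5.0), min_size=45, max_size=80))
    def test_bounded_in_unit_interval(self, data):
        arr = np.array(data)
        if np.ptp(arr) == 0:
            return
        tr = Trace(np.concatenate([np.zeros(10), arr]), dt=0.01)
        try:
            res = biphasic_index(tr, flash_onset=0.1, baseline=0.0)
        except UndefinedIndexError:
            return
        assert 0.0 <= res.bi <= 1.0
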