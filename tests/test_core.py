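"""Unit tests for the activation function and the layer-by-layer dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgbg import (
    ModelParams,
    NetworkWeights,
    decide,
    gpe_activity,
    gpi_activity,
    phi,
    pmc_activity,
    run_phase,
    striatum_activity,
    thalamus_activity,
)
from conftest import make_zero_weights, random_weights


class TestPhi:
    @pytest.mark.parametrize(
        "x, expected",
        [
            (1.0, 1.0),
            (0.5, math.exp(-2.0)),
            (0.0, math.exp(-8.0)),
        ],
    )
    def test_values(self, x, expected):
        assert phi(x, 8.0) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_shape(self):
        with pytest.raises(ValueError):
            phi(0.5, 0.0)

    @pytest.mark.parametrize("bad", [float("nan"), float("inf")])
    def test_rejects_nonfinite_preactivation(self, bad):
        with pytest.raises(ValueError):
            phi(bad, 8.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        x=st.floats(-5, 1),
        y=st.floats(-5, 1),
        a=st.floats(0.5, 20),
    )
    def test_strictly_increasing_below_one(self, x, y, a):
        lo, hi = sorted((x, y))
        if hi - lo > 1e-9:  # below float resolution phi(lo) == phi(hi)
            assert phi(lo, a) < phi(hi, a)

    @settings(derandomize=True, max_examples=200)
    @given(x=st.floats(-5, 5), a=st.floats(0.5, 20))
    def test_symmetric_about_one_with_max_there(self, x, a):
        assert phi(x, a) == pytest.approx(phi(2.0 - x, a), rel=1e-12)
        assert phi(x, a) <= 1.0


class TestPallidalChain:
    def test_gpe_complements_nogo(self):
        np.testing.assert_allclose(
            gpe_activity(np.array([0.0, 1.0, 0.3])), [1.0, 0.0, 0.7]
        )

    @pytest.mark.parametrize(
        "go, gpe, expected",
        [(1.0, 1.0, 0.0), (0.0, 1.0, 0.5), (0.0, 0.0, 1.0)],
    )
    def test_gpi_values(self, go, gpe, expected):
        assert gpi_activity(np.array([go]), np.array([gpe]))[0] == pytest.approx(expected)

    @settings(derandomize=True, max_examples=200)
    @given(go=st.floats(0, 1), gpe=st.floats(0, 1))
    def test_gpi_clamped_at_zero(self, go, gpe):
        out = gpi_activity(np.array([go]), np.array([gpe]))
        assert out[0] >= 0.0

    def test_thalamus_complements_gpi(self):
        np.testing.assert_allclose(
            thalamus_activity(np.array([1.0, 0.0, 0.5])), [0.0, 1.0, 0.5]
        )


class TestStriatum:
    """The printed-equation examples use the absolute dopamine coding."""

    def test_tonic_go_and_nogo_with_zero_weights(self, absolute_params):
        w = make_zero_weights(1)
        snc = np.array([0.5, 0.5])
        act = striatum_activity(w, absolute_params, np.array([1.0]), snc)
        assert act[0] == pytest.approx(math.exp(-2.0), rel=1e-12)  # Go: phi(0.5)
        assert act[1] == pytest.approx(math.exp(-18.0), rel=1e-12)  # NoGo: phi(-0.5)

    def test_burst_saturates_go_unit(self, absolute_params):
        w = make_zero_weights(1)
        act = striatum_activity(w, absolute_params, np.array([1.0]), np.array([1.0, 1.0]))
        assert act[0] == pytest.approx(1.0)

    def test_pfc_drive_hits_only_instructed_go_unit(self, absolute_params):
        w = make_zero_weights(2)
        snc = np.full(4, 0.5)
        y_in = np.array([1.0, 1.0])
        base = striatum_activity(w, absolute_params, y_in, snc)
        biased = striatum_activity(w, absolute_params, y_in, snc, pfc_go_index=1, y_pfc=1)
        assert biased[1] == pytest.approx(phi(0.5 + 0.3, 8.0))
        assert biased[0] == base[0] and (biased[2:] == base[2:]).all()

    def test_dimension_mismatch_raises(self, absolute_params):
        w = make_zero_weights(2)
        with pytest.raises(ValueError):
            striatum_activity(w, absolute_params, np.array([1.0]), np.full(4, 0.5))


class TestPmc:
    def test_thalamic_drive_only(self, default_params):
        w = make_zero_weights(2)
        x, y = pmc_activity(w, default_params, np.array([1.0, 0.0]), np.array([1.0, 1.0]))
        np.testing.assert_allclose(x, [0.5, 0.0])
        assert y[0] == pytest.approx(math.exp(-2.0), rel=1e-12)
        assert y[1] == pytest.approx(math.exp(-8.0), rel=1e-12)

    def test_normalization_divides_by_max(self, default_params):
        # weights chosen so the preactivations come out (1.5, 0.75) before scaling
        w = NetworkWeights(2, np.zeros((2, 4)), np.array([[3.0, 1.5], [0.0, 0.0]]))
        x, _ = pmc_activity(w, default_params, np.zeros(2), np.array([1.0, 0.0]))
        np.testing.assert_allclose(x, [1.0, 0.5])

    def test_no_normalization_below_one(self, default_params):
        w = make_zero_weights(2)
        thal = np.array([0.9, 0.4])
        x, _ = pmc_activity(w, default_params, thal, np.array([1.0, 1.0]))
        np.testing.assert_array_equal(x, 0.5 * thal)  # bit-for-bit untouched

    @settings(derandomize=True, max_examples=100)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 4))
    def test_preactivation_never_exceeds_one(self, seed, n):
        rng = np.random.default_rng(seed)
        w = random_weights(rng, n, scale=3.0)
        thal = rng.uniform(0, 1, n)
        y_in = np.zeros(n)
        y_in[rng.integers(n)] = 1.0
        x, _ = pmc_activity(w, ModelParams(), thal, y_in)
        assert x.max() <= 1.0 + 1e-15


class TestDecide:
    def test_picks_maximum_among_presented(self):
        chosen, y_out = decide(np.array([0.8, 0.3]), {0, 1})
        assert chosen == 0 and y_out.tolist() == [1.0, 0.0]

    def test_masks_absent_stimuli(self):
        chosen, _ = decide(np.array([0.8, 0.3, 0.9]), {0, 1})
        assert chosen == 0

    def test_tie_breaks_to_lowest_index(self):
        chosen, _ = decide(np.array([0.5, 0.5]), {0, 1})
        assert chosen == 0

    def test_empty_presented_set_rejected(self):
        with pytest.raises(ValueError):
            decide(np.array([0.5, 0.5]), set())


class TestRunPhase:
    def test_minus_phase_gpi_baseline(self, absolute_params):
        """Zero weights, tonic dopamine: GPi = 1 - phi(0.5)/2 - (1 - phi(-0.5))/2."""
        w = make_zero_weights(2)
        state = run_phase(w, absolute_params, np.array([1.0, 1.0]))
        expected = max(1 - 0.5 * math.exp(-2.0) - 0.5 * (1 - math.exp(-18.0)), 0.0)
        np.testing.assert_allclose(state.y_gpi, expected, rtol=1e-12)
        assert expected == pytest.approx(0.4323, abs=1e-4)

    def test_plus_phase_routes_phasic_da_to_chosen_units_only(self, absolute_params):
        w = make_zero_weights(3)
        y_in = np.array([1.0, 1.0, 0.0])
        state = run_phase(
            w, absolute_params, y_in, phasic_level=absolute_params.snc_burst, chosen=1
        )
        np.testing.assert_array_equal(state.y_snc_per_unit, [0.5, 1.0, 0.5, 0.5, 1.0, 0.5])

    def test_plus_phase_after_punishment_silences_chosen_go(self, absolute_params):
        w = make_zero_weights(2)
        state = run_phase(
            w,
            absolute_params,
            np.array([1.0, 1.0]),
            phasic_level=absolute_params.snc_dip,
            chosen=0,
        )
        assert state.y_stria[0] == pytest.approx(math.exp(-8.0), rel=1e-12)

    def test_plus_phase_requires_the_choice(self, absolute_params):
        w = make_zero_weights(2)
        with pytest.raises(ValueError):
            run_phase(w, absolute_params, np.array([1.0, 1.0]), phasic_level=1.0)

    def test_opponency_at_tonic_under_absolute_coding(self, absolute_params):
        w = make_zero_weights(1)
        state = run_phase(w, absolute_params, np.array([1.0]))
        assert state.y_stria[0] > state.y_stria[1]

    @pytest.mark.parametrize("s", np.arange(0.0, 0.25, 0.03))
    def test_burst_raises_chosen_go_activity_when_drive_below_quarter(self, s, default_params):
        """phi's symmetry about 1 makes the burst help only for drive < 0.25."""
        n = 1
        w = NetworkWeights(n, np.array([[s, 0.0]]), np.zeros((n, n)))
        y_in = np.array([1.0])
        minus = run_phase(w, default_params, y_in)
        plus = run_phase(
            w, default_params, y_in, phasic_level=default_params.snc_burst, chosen=0
        )
        assert plus.y_stria[0] > minus.y_stria[0]

    @settings(derandomize=True, max_examples=150)
    @given(seed=st.integers(0, 10_000))
    def test_all_activities_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 5))
        w = random_weights(rng, n, scale=2.0)
        y_in = np.zeros(n)
        presented = rng.choice(n, size=int(rng.integers(1, n + 1)), replace=False)
        y_in[presented] = 1.0
        state = run_phase(w, ModelParams(), y_in)
        for layer in (state.y_stria, state.y_gpe, state.y_gpi, state.y_thal, state.y_pmc):
            assert np.all(layer >= 0.0) and np.all(layer <= 1.0)
        assert state.y_out.sum() == 1.0
        assert state.chosen in set(int(i) for i in presented)
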