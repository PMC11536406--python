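import numpy as np
import pytest

from alifp.membrane import MembranePotential
from alifp.params import ModelParams
from alifp.path_engine import mean_spike_rate, prune, simulate, split_paths
from alifp.pulse_response import cancellation_offset, component_response
from alifp.stimulus import PulseTrain, make_train
from alifp.threshold_state import (
    ADAPTATION,
    FAC_ACC,
    REFRACTORY,
    ModifierEvent,
    ThresholdComponent,
    ThresholdMixture,
)

from .conftest import biphasic, closed_form_i50, monophasic


class TestSplitPaths:
    def test_single_path_splits_with_outcome_weights(self):
        mix = ThresholdMixture.resting()
        out = split_paths(mix, [0.3], [55e-6], fac_anchor=100e-6)
        assert sorted(c.weight for c in out.components) == pytest.approx([0.3, 0.7])
        spike = next(c for c in out.components if c.weight == pytest.approx(0.3))
        assert {e.kind for e in spike.events} == {REFRACTORY, ADAPTATION}
        quiet = next(c for c in out.components if c.weight == pytest.approx(0.7))
        assert [e.kind for e in quiet.events] == [FAC_ACC]

    def test_zero_probability_suppresses_spike_child(self):
        mix = ThresholdMixture.resting()
        out = split_paths(mix, [0.0], [None], fac_anchor=100e-6)
        assert len(out.components) == 1
        assert out.components[0].weight == 1.0

    def test_misaligned_lists_rejected(self):
        with pytest.raises(ValueError, match="align"):
            split_paths(ThresholdMixture.resting(), [0.3, 0.4], [None], 0.0)

    def test_two_level_tree_weights_multiply(self):
        mix = ThresholdMixture.resting()
        mix = split_paths(mix, [0.4], [50e-6], fac_anchor=100e-6)
        mix = split_paths(mix, [0.2, 0.6], [1.05e-3, 1.06e-3], fac_anchor=1.1e-3)
        expected = sorted([0.4 * 0.2, 0.4 * 0.8, 0.6 * 0.6, 0.6 * 0.4])
        assert sorted(c.weight for c in mix.components) == pytest.approx(expected)
        assert sum(c.weight for c in mix.components) == pytest.approx(1.0, abs=1e-12)


class TestPrune:
    def test_identical_components_merge(self):
        events = (ModifierEvent(FAC_ACC, 1e-3),)
        mix = ThresholdMixture(
            components=(
                ThresholdComponent(0.4, events),
                ThresholdComponent(0.6, events),
            )
        )
        out = prune(mix)
        assert len(out.components) == 1 and out.components[0].weight == pytest.approx(1.0)

    def test_sub_grid_anchor_difference_merges(self):
        # anchors 0.2 us apart quantize to the same 1 us cell
        mix = ThresholdMixture(
            components=(
                ThresholdComponent(0.5, (ModifierEvent(FAC_ACC, 1.0e-3),)),
                ThresholdComponent(0.5, (ModifierEvent(FAC_ACC, 1.0002e-3),)),
            )
        )
        assert len(prune(mix).components) == 1

    def test_lowest_weight_removed_and_rescaled(self):
        n = 21
        weights = np.arange(1, n + 1, dtype=float)
        weights /= weights.sum()
        comps = tuple(
            ThresholdComponent(w, (ModifierEvent(FAC_ACC, (i + 1) * 1e-3),))
            for i, w in enumerate(weights)
        )
        out = prune(ThresholdMixture(components=comps, k_max=20))
        assert len(out.components) == 20
        kept_anchors = {c.events[0].anchor for c in out.components}
        assert 1e-3 not in kept_anchors  # the lightest one went
        assert sum(c.weight for c in out.components) == pytest.approx(1.0, abs=1e-12)

    def test_equal_weights_tie_removes_newest(self):
        n = 21
        comps = tuple(
            ThresholdComponent(1.0 / n, (ModifierEvent(FAC_ACC, (i + 1) * 1e-3),))
            for i in range(n)
        )
        out = prune(ThresholdMixture(components=comps, k_max=20))
        anchors = {c.events[0].anchor for c in out.components}
        assert n * 1e-3 not in anchors  # newest (last-listed) removed
        assert 1e-3 in anchors


class TestSimulate:
    def test_single_subthreshold_pulse_splits_once(self, params):
        amp = closed_form_i50(params, 100e-6)
        train = PulseTrain(pulses=(monophasic(amp),), duration=2e-4)
        res = simulate(train, params)
        assert res.responses[0].p_s_total == pytest.approx(0.5, abs=1e-6)
        assert len(res.final_state.components) == 2
        assert sorted(c.weight for c in res.final_state.components) == pytest.approx(
            [0.5, 0.5], abs=1e-6
        )

    def test_pulse_inside_absolute_refractory_period_cannot_fire(self, params):
        # probe 0.3 ms after a virtually certain spike: inside t_arp = 0.37 ms
        amp = 2.0 * closed_form_i50(params, 100e-6)
        p1 = monophasic(amp, phase=100e-6)
        p2 = monophasic(amp, phase=50e-6, t_start=0.3e-3)
        res = simulate(PulseTrain(pulses=(p1, p2), duration=1e-3), params)
        assert res.responses[0].p_s_total > 1 - 1e-15
        assert res.responses[1].p_s_total < 1e-50

    def test_zero_amplitude_train_keeps_one_path(self, params):
        zero = biphasic(0.0, phase=40e-6, ipg=30e-6)
        train = make_train(1000.0, 0.02, zero)
        res = simulate(train, params)
        assert max(res.path_counts) == 1
        assert max(r.p_s_total for r in res.responses) < 1e-100

    def test_invariants_near_threshold(self, params):
        amp = closed_form_i50(params, 40e-6)
        train = make_train(1000.0, 0.02, biphasic(amp, phase=40e-6))
        res = simulate(train, params)
        assert all(abs(w - 1.0) < 1e-9 for w in res.weight_sums)
        assert all(0.0 <= r.p_s_total <= 1.0 for r in res.responses)
        assert max(res.path_counts) <= params.k_max
        for r in res.responses:
            mix = r.spike_time_mixture
            if r.p_s_total > 1e-9:
                assert sum(c.weight for c in mix) == pytest.approx(1.0, abs=1e-9)

    def test_two_pulse_simulation_matches_hand_composed_tree(self, params):
        """A 2-pulse run must equal exhaustive enumeration of the 4-outcome
        tree built by composing the per-pulse operations directly."""
        amp = closed_form_i50(params, 100e-6)
        p1 = monophasic(amp)
        p2 = monophasic(amp, t_start=1e-3)
        train = PulseTrain(pulses=(p1, p2), duration=2e-3)
        res = simulate(train, params)

        pot = MembranePotential.from_train(train, params.membrane)
        c1 = cancellation_offset(p1, pot, params.phi)
        root = ThresholdComponent(1.0)
        r1 = component_response(p1, pot, root, params.threshold, params.latency, c1)
        spike = ThresholdComponent(
            1.0,
            (ModifierEvent(REFRACTORY, r1.mu_ct), ModifierEvent(ADAPTATION, r1.mu_ct)),
        )
        quiet = ThresholdComponent(1.0, (ModifierEvent(FAC_ACC, p1.t_lead_end),))
        c2 = cancellation_offset(p2, pot, params.phi)
        r2s = component_response(p2, pot, spike, params.threshold, params.latency, c2)
        r2q = component_response(p2, pot, quiet, params.threshold, params.latency, c2)

        p1_hat = r1.p_cond
        total2 = p1_hat * r2s.p_cond + (1 - p1_hat) * r2q.p_cond
        assert res.responses[0].p_s_total == pytest.approx(p1_hat, rel=1e-12)
        assert res.responses[1].p_s_total == pytest.approx(total2, rel=1e-9)

        expected_leaves = sorted(
            [
                p1_hat * r2s.p_cond,
                p1_hat * (1 - r2s.p_cond),
                (1 - p1_hat) * r2q.p_cond,
                (1 - p1_hat) * (1 - r2q.p_cond),
            ]
        )
        got = sorted(c.weight for c in res.final_state.components)
        # paths with vanishing probability are not branched; compare the
        # surviving leaves against the non-negligible enumerated ones
        expected_kept = [w for w in expected_leaves if w > 1e-12][-len(got):]
        assert got == pytest.approx(expected_kept, rel=1e-9)

    def test_high_rate_depression_and_recovery(self, params):
        # suprathreshold 5,000 pps burst, then a probe after a 15 ms silent
        # gap (> 5 * tau_rrp): per-pulse probability collapses during the
        # burst and mostly recovers at the probe
        from alifp.metrics import find_i50

        amp = 1.3 * find_i50(biphasic(1e-3, phase=40e-6), params)
        burst = make_train(5000.0, 2e-3, biphasic(amp, phase=40e-6))
        probe = biphasic(amp, phase=40e-6, t_start=burst.pulses[-1].t_end + 15e-3)
        train = PulseTrain(pulses=burst.pulses + (probe,), duration=probe.t_end)
        res = simulate(train, params)
        ps = [r.p_s_total for r in res.responses]
        assert ps[0] > 0.999
        assert min(ps[1:-1]) < 0.05
        assert ps[-1] > 0.8 * ps[0]

    def test_probability_trace_integrates_to_total_probability(self, params):
        amp = 1.2 * closed_form_i50(params, 100e-6)
        train = PulseTrain(pulses=(monophasic(amp),), duration=2e-4)
        res = simulate(train, params)
        integral = np.trapezoid(res.trace.density, res.trace.times)
        assert integral == pytest.approx(res.responses[0].p_s_total, rel=1e-5)

    def test_anodic_leading_pulse_rejected(self, params):
        bad = biphasic(1e-3, phase=40e-6).scaled(-1.0)
        with pytest.raises(ValueError, match="cathodic"):
            simulate(PulseTrain(pulses=(bad,), duration=1e-3), params)


class TestMeanSpikeRate:
    def test_certain_spikes_give_pulse_rate(self, params):
        amp = 3.0 * closed_form_i50(params, 100e-6)
        train = make_train(100.0, 0.1, monophasic(amp))
        res = simulate(train, params)
        # 10 near-certain spikes in 0.1 s; window extended past the last latency
        rate = mean_spike_rate(res, (0.0, 0.1))
        assert rate == pytest.approx(100.0, rel=0.02)

    def test_zero_probability_gives_zero_rate(self, params):
        train = make_train(100.0, 0.1, monophasic(0.0))
        res = simulate(train, params)
        assert mean_spike_rate(res, (0.0, 0.1)) == pytest.approx(0.0, abs=1e-50)

    def test_empty_window_rejected(self, params):
        train = make_train(100.0, 0.05, monophasic(0.0))
        res = simulate(train, params)
        with pytest.raises(ValueError, match="window"):
            mean_spike_rate(res, (0.1, 0.1))
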