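"""Medium spiny neuron model: Kir2 closed form, modulation couplings,
excitability, and the population readout."""

import numpy as np
import pytest

from glyqsp.striatum import (
    KirParams,
    MSNParams,
    MSNResult,
    ModulationState,
    dopamine_release_scale,
    kir2_current,
    simulate_msn,
    square_pulse_gate,
    striatal_population_readout,
)

DT = 0.05
N = int(1000 / DT)  # 1 s runs keep these tests cheap
GATE = square_pulse_gate(N, DT, onset_ms=100.0)


class TestKir2:
    def test_half_activation_at_vh(self):
        p = KirParams()
        assert kir2_current(p.v_h, 1.0, p) == pytest.approx(
            0.5 * p.g_bar * (p.v_h - p.e_k)
        )
        assert kir2_current(p.v_h, 1.0, p) == pytest.approx(-12.6)

    def test_zero_at_reversal_and_zero_activation(self):
        p = KirParams()
        assert kir2_current(p.e_k, 0.7, p) == 0.0
        assert kir2_current(-60.0, 0.0, p) == 0.0

    def test_matches_closed_form_at_random_points(self):
        rng = np.random.default_rng(1)
        p = KirParams()
        for _ in range(100):
            v = rng.uniform(-120.0, 0.0)
            u = rng.uniform(0.0, 2.0)
            g = p.g_bar / (1.0 + np.exp(-(v - p.v_h) / p.v_c))
            assert kir2_current(v, u, p) == pytest.approx(u * g * (v - p.e_k), rel=1e-12)

    def test_inward_rectification_sign_convention(self):
        # with v_c = -11 mV the conductance *decreases* with depolarization
        p = KirParams()
        g = lambda v: p.g_bar / (1.0 + np.exp(-(v - p.v_h) / p.v_c))
        assert g(-120.0) > g(-80.0) > g(-40.0)
        assert g(-400.0) == pytest.approx(p.g_bar, abs=1e-9)
        assert g(200.0) == pytest.approx(0.0, abs=1e-9)

    def test_d1_boost_strengthens_stabilizing_current(self):
        # hyperpolarized holding: more D1 -> larger-magnitude Kir2 current
        assert abs(kir2_current(-85.0, 1.2)) > abs(kir2_current(-85.0, 1.0))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            KirParams(g_bar=0.0)
        with pytest.raises(ValueError):
            KirParams(v_c=0.0)
        with pytest.raises(ValueError):
            kir2_current(-60.0, -1.0)


class TestSimulation:
    def test_zero_drive_resting_and_silent(self):
        res = simulate_msn(MSNParams(noise_amp=0.0), np.zeros(N), GATE, seed=0)
        assert res.spike_count == 0
        assert -90.0 < res.voltage.mean() < -70.0
        assert np.ptp(res.voltage[int(0.2 * N):]) < 5.0  # subthreshold

    def test_excitability_monotone_in_cortical_drive(self):
        counts = []
        for amp in (0.2, 0.5, 1.0):
            per_seed = [
                simulate_msn(MSNParams(), np.full(N, amp), GATE, seed=s).spike_count
                for s in range(3)
            ]
            counts.append(np.mean(per_seed))
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[2] > counts[0]

    def test_presynaptic_glutamate_boost_never_silences(self):
        # D2 relative activation below baseline raises presynaptic release
        boost = ModulationState(x_d2=-0.5)
        for seed in range(3):
            base = simulate_msn(
                MSNParams(cell_class="Enk_D2"), np.full(N, 0.5), GATE, seed=seed
            ).spike_count
            up = simulate_msn(
                MSNParams(cell_class="Enk_D2"), np.full(N, 0.5), GATE, boost, seed=seed
            ).spike_count
            assert up >= base

    def test_deterministic_given_seed(self):
        a = simulate_msn(MSNParams(), np.full(N, 0.5), GATE, seed=9)
        b = simulate_msn(MSNParams(), np.full(N, 0.5), GATE, seed=9)
        assert np.array_equal(a.voltage, b.voltage)
        assert a.spike_count == b.spike_count

    def test_mismatched_drives_rejected(self):
        with pytest.raises(ValueError):
            simulate_msn(MSNParams(), np.zeros(10), np.zeros(11))

    def test_class_validation(self):
        with pytest.raises(ValueError):
            MSNParams(cell_class="cholinergic")


class TestModulation:
    def test_dopamine_release_baseline(self):
        assert dopamine_release_scale(ModulationState()) == 1.0

    def test_5ht2c_inhibition_raises_dopamine(self):
        m = ModulationState(x_5ht2c=-0.2, k_2c=0.5)
        assert dopamine_release_scale(m) == pytest.approx(1.10)

    def test_combined_serotonergic_changes_compose_additively(self):
        m = ModulationState(x_5ht2c=-0.2, x_5ht3=-0.3, k_2c=0.5, k_3=0.5)
        assert dopamine_release_scale(m) == pytest.approx(1.0 + 0.1 - 0.15)

    def test_scale_clipped_at_zero(self):
        m = ModulationState(x_5ht3=-0.9, k_3=5.0)
        assert dopamine_release_scale(m) == 0.0

    def test_relative_activation_domain(self):
        with pytest.raises(ValueError):
            ModulationState(x_d1=-1.5)


class TestPopulationReadout:
    @staticmethod
    def _result(cls, excitability):
        return MSNResult(
            voltage=np.array([]), spike_count=int(excitability), excitability=excitability,
            dt=DT, cell_class=cls,
        )

    def test_silent_population_reads_zero(self):
        cells = [self._result("SP_D1", 0.0), self._result("Enk_D2", 0.0)]
        assert striatal_population_readout(cells) == 0.0

    def test_single_cell_identity(self):
        assert striatal_population_readout([self._result("dual", 12.5)]) == 12.5

    def test_linearity_in_spike_counts(self):
        cells = [
            self._result("SP_D1", 4.0),
            self._result("Enk_D2", 8.0),
            self._result("dual", 2.0),
        ]
        doubled = [
            self._result(c.cell_class, 2 * c.excitability) for c in cells
        ]
        assert striatal_population_readout(doubled) == pytest.approx(
            2 * striatal_population_readout(cells)
        )

    def test_class_weights(self):
        cells = [self._result("SP_D1", 10.0), self._result("Enk_D2", 20.0)]
        val = striatal_population_readout(
            cells, class_weights={"SP_D1": 3.0, "Enk_D2": 1.0}
        )
        assert val == pytest.approx((3 * 10 + 1 * 20) / 4)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            striatal_population_readout([])
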