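"""Cortical circuit: pathology algebra, receptor couplings, determinism,
baseline normalization, and E/I balance behavior."""

from dataclasses import replace

import numpy as np
import pytest

from glyqsp.cortical import (
    DEFAULT_PATHOLOGY,
    NetworkConfig,
    PathologyConfig,
    ReceptorCouplingTable,
    apply_pathology,
    apply_receptor_effects,
    simulate_network,
)

# short-duration config for cheap behavioral tests
FAST = NetworkConfig(duration=4000.0)


class TestPathology:
    def test_zero_pathology_is_identity(self):
        cfg = NetworkConfig()
        out, _ = apply_pathology(cfg, PathologyConfig())
        assert out == cfg

    def test_nmda_reduction_scales_every_nmda_weight(self):
        cfg = NetworkConfig()
        out, _ = apply_pathology(cfg, PathologyConfig(nmda_reduction=0.2))
        assert out.w_nmda_ee == pytest.approx(0.8 * cfg.w_nmda_ee)
        assert out.w_nmda_ei == pytest.approx(0.8 * cfg.w_nmda_ei)
        assert out.w_ampa_ee == cfg.w_ampa_ee  # AMPA untouched

    def test_successive_applications_compose_multiplicatively(self):
        cfg = NetworkConfig()
        p = PathologyConfig(nmda_reduction=0.2, gaba_reduction=0.1, noise_increase=0.3)
        once, _ = apply_pathology(cfg, p)
        twice, _ = apply_pathology(once, p)
        assert twice.w_nmda_ee == pytest.approx(cfg.w_nmda_ee * 0.8**2)
        assert twice.w_gaba_ie == pytest.approx(cfg.w_gaba_ie * 0.9**2)
        assert twice.noise_amp == pytest.approx(cfg.noise_amp * 1.3**2)

    def test_da_deficit_scales_dopamine_coupling_gains_only(self):
        _, table = apply_pathology(NetworkConfig(), PathologyConfig(da_deficit=0.5))
        gains = {(r, t): g for r, t, g in table.couplings}
        assert gains[("D1", "g_ks")] == pytest.approx(-0.25)
        assert gains[("D1", "g_hva")] == pytest.approx(0.15)

    def test_out_of_range_fractions_rejected(self):
        with pytest.raises(ValueError):
            PathologyConfig(nmda_reduction=1.0)
        with pytest.raises(ValueError):
            PathologyConfig(noise_increase=-0.1)

    def test_original_config_unmodified(self):
        cfg = NetworkConfig()
        apply_pathology(cfg, DEFAULT_PATHOLOGY)
        assert cfg.w_nmda_ee == NetworkConfig().w_nmda_ee


class TestReceptorEffects:
    def test_zero_effects_identity(self):
        cfg = NetworkConfig()
        assert apply_receptor_effects(cfg, {"D1": 0.0}) == cfg

    def test_d1_slow_k_coupling(self):
        cfg = NetworkConfig()
        out = apply_receptor_effects(cfg, {"D1": 0.1})
        assert out.g_ks == pytest.approx(cfg.g_ks * 0.95)  # gain -0.5
        assert out.g_hva == pytest.approx(cfg.g_hva * 1.03)  # gain +0.3

    def test_stacked_receptors_multiply(self):
        table = ReceptorCouplingTable(
            couplings=(("D1", "g_ks", -0.5), ("M1", "g_ks", 0.2))
        )
        cfg = NetworkConfig()
        out = apply_receptor_effects(cfg, {"D1": 0.2, "M1": 0.5}, table)
        assert out.g_ks == pytest.approx(cfg.g_ks * 0.9 * 1.1)

    def test_unknown_receptor_lists_known_ones(self):
        with pytest.raises(KeyError, match="D1"):
            apply_receptor_effects(NetworkConfig(), {"H3": 0.1})

    def test_unknown_coupling_target_rejected(self):
        with pytest.raises(ValueError):
            ReceptorCouplingTable(couplings=(("D1", "not_a_channel", 1.0),))


class TestSimulation:
    def test_seed_for_seed_reproducibility(self, pd_beneficial):
        a = simulate_network(replace(FAST, seed=3), DEFAULT_PATHOLOGY, 1.0, pd_beneficial)
        b = simulate_network(replace(FAST, seed=3), DEFAULT_PATHOLOGY, 1.0, pd_beneficial)
        assert np.array_equal(a.spike_neurons, b.spike_neurons)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert a.mean_exc_rate == b.mean_exc_rate

    def test_disconnected_silent_network_has_flat_unit_drives(self):
        cfg = replace(
            FAST,
            w_ampa_ee=0.0, w_ampa_ei=0.0, w_nmda_ee=0.0, w_nmda_ei=0.0,
            w_gaba_ie=0.0, w_gaba_ii=0.0, noise_amp=0.0, noise_nmda_amp=0.0,
            noise_nmda_amp_inh=0.0, distractor_amp=0.0,
            stimulus_amplitude=0.0, bias_exc=0.0, bias_inh=0.0, bias_jitter=0.0,
            seed=0,
        )
        out = simulate_network(cfg)
        assert len(out.spike_times) == 0
        assert np.allclose(out.u_e, 1.0) and np.allclose(out.u_i, 1.0)

    def test_prestimulus_baseline_normalized_within_one_percent(self, pd_beneficial):
        out = simulate_network(replace(FAST, seed=5), DEFAULT_PATHOLOGY, 1.0, pd_beneficial)
        n_pre = int(FAST.stimulus_onset / (out.u_dt * 1e3))
        assert abs(np.mean(out.u_e[:n_pre]) - 1.0) < 0.01
        assert abs(np.mean(out.u_i[:n_pre]) - 1.0) < 0.01

    def test_raising_interneuron_nmda_drive_never_raises_pyramidal_rate(
        self, pd_beneficial
    ):
        diffs = []
        for seed in range(6):
            base = simulate_network(
                replace(FAST, seed=seed), DEFAULT_PATHOLOGY, 1.0, pd_beneficial
            ).mean_exc_rate
            boosted_cfg = replace(
                FAST,
                seed=seed,
                w_nmda_ei=FAST.w_nmda_ei * 1.3,
                noise_nmda_amp_inh=FAST.noise_nmda_amp_inh * 1.3,
            )
            boosted = simulate_network(
                boosted_cfg, DEFAULT_PATHOLOGY, 1.0, pd_beneficial
            ).mean_exc_rate
            diffs.append(boosted - base)
        assert all(d <= 0 for d in diffs)

    def test_raising_recurrent_excitation_never_lowers_pyramidal_rate(
        self, pd_beneficial
    ):
        diffs = []
        for seed in range(6):
            base = simulate_network(
                replace(FAST, seed=seed), DEFAULT_PATHOLOGY, 1.0, pd_beneficial
            ).mean_exc_rate
            boosted_cfg = replace(
                FAST,
                seed=seed,
                w_nmda_ee=FAST.w_nmda_ee * 1.2,
                noise_nmda_amp=FAST.noise_nmda_amp * 1.2,
            )
            boosted = simulate_network(
                boosted_cfg, DEFAULT_PATHOLOGY, 1.0, pd_beneficial
            ).mean_exc_rate
            diffs.append(boosted - base)
        assert all(d >= 0 for d in diffs)

    def test_glycine_at_ratio_minimum_beats_saturating_glycine(self, pd_beneficial):
        from glyqsp.pharmacology import find_ratio_extremum

        g_star = find_ratio_extremum(pd_beneficial, window=(0.01, 100.0)).gly_star
        wins = 0
        for seed in range(6):
            at_min = simulate_network(
                replace(FAST, seed=seed), DEFAULT_PATHOLOGY, g_star, pd_beneficial
            ).mean_exc_rate
            saturated = simulate_network(
                replace(FAST, seed=seed), DEFAULT_PATHOLOGY, 100.0, pd_beneficial
            ).mean_exc_rate
            wins += at_min > saturated
        assert wins >= 5

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(dt=0.2)
        with pytest.raises(ValueError):
            NetworkConfig(duration=1000.0)  # before stimulus onset
        with pytest.raises(ValueError):
            NetworkConfig(n_stim_targets=50)
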