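"""Conductance-based cortical microcircuit with subunit-resolved NMDA synapses.

A 20-pyramidal / 10-interneuron network of single-compartment
Hodgkin-Huxley-type neurons (leak, transient Na+, delayed-rectifier K+, plus
a slow K+ current I_ks and a high-voltage-activated Ca2+ current as
neuromodulation targets).  Synapses are exponential-decay AMPA and GABA-A
conductances and NMDA conductances with the standard voltage-dependent Mg2+
block; the NMDA maximal conductance of pyramidal-pyramidal (e-e) synapses is
scaled by the NR2A/B glycine potentiation and that of pyramidal-interneuron
(e-i) synapses by the NR2C/D potentiation, which is how extracellular
glycine shifts the circuit's excitation/inhibition balance.

Schizophrenia pathology enters as fractional reductions of NMDA and GABA
conductances and dopamine-coupled channel gains plus an increase of the
Poisson background noise.  A transient current injected into a target subset
of pyramidal cells at t = 2000 ms triggers a synchronized firing epoch that
degrades under noise and independently driven distractor cells; readouts are
spike trains, the window-averaged pyramidal firing rate, and population
activities u_e(t), u_i(t) normalized to a pre-stimulus baseline of 1 (the
inputs to the BOLD stage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numba import njit

from glyqsp.pharmacology import SynapseClassPD, effective_conductance

__all__ = [
    "NetworkConfig",
    "PathologyConfig",
    "ReceptorCouplingTable",
    "NetworkOutput",
    "simulate_network",
    "apply_pathology",
    "apply_receptor_effects",
]

#: channel/parameter names that receptor couplings may target
COUPLABLE_PARAMETERS = ("g_ks", "g_hva", "noise_amp", "w_ampa_ee", "w_gaba_ie")

#: receptors whose couplings are scaled by the dopamine-deficit pathology
DOPAMINE_RECEPTORS = ("D1", "D2", "D3", "D4")


@dataclass(frozen=True)
class PathologyConfig:
    """Fractional schizophrenia lesions: NMDA and GABA conductance
    reductions, dopamine-coupling deficit, and background-noise increase."""

    nmda_reduction: float = 0.0
    gaba_reduction: float = 0.0
    da_deficit: float = 0.0
    noise_increase: float = 0.0

    def __post_init__(self) -> None:
        for name in ("nmda_reduction", "gaba_reduction", "da_deficit"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.noise_increase < 0:
            raise ValueError("noise_increase must be >= 0")


#: default schizophrenia lesion used by the pipeline — placeholder magnitudes
#: inside the sensitivity sweep ranges, not literature-calibrated values
DEFAULT_PATHOLOGY = PathologyConfig(
    nmda_reduction=0.3, gaba_reduction=0.3, da_deficit=0.3, noise_increase=0.3
)


@dataclass(frozen=True)
class ReceptorCouplingTable:
    """Map receptor -> (target parameter, gain).

    Gains are dimensionless per unit relative activation; a targeted
    parameter is scaled by ``1 + gain * relative_activation`` (clipped at 0).
    Only D1 ships with nonzero default gains (slow K+ down, HVA Ca2+ up, the
    classic cortical dopamine signature); other receptors are accepted but
    their gains are user data.
    """

    couplings: tuple = (
        ("D1", "g_ks", -0.5),
        ("D1", "g_hva", 0.3),
        ("D2", "w_ampa_ee", 0.0),
        ("5HT2A", "g_ks", 0.0),
        ("M1", "g_ks", 0.0),
        ("alpha1A", "noise_amp", 0.0),
    )

    def __post_init__(self) -> None:
        for receptor, target, _gain in self.couplings:
            if target not in COUPLABLE_PARAMETERS:
                raise ValueError(
                    f"coupling for {receptor!r} targets unknown parameter {target!r}; "
                    f"known: {COUPLABLE_PARAMETERS}"
                )

    @property
    def receptors(self) -> tuple:
        return tuple(sorted({r for r, _, _ in self.couplings}))


@dataclass(frozen=True)
class NetworkConfig:
    """Circuit wiring, conductances, drive and integration settings.

    Conductances are in mS/cm2, currents in uA/cm2, times in ms.  Synaptic
    weights are the per-spike conductance increments for each connection
    class; NMDA weights are further multiplied at simulation time by the
    glycine potentiation of the corresponding synapse class.
    """

    n_exc: int = 20
    n_inh: int = 10
    # connection probabilities per directed class
    p_ee: float = 0.5
    p_ei: float = 0.5
    p_ie: float = 0.8
    p_ii: float = 0.4
    # synaptic weights (conductance increment per presynaptic spike)
    w_ampa_ee: float = 0.002
    w_ampa_ei: float = 0.001
    w_nmda_ee: float = 0.005
    w_nmda_ei: float = 0.025
    w_gaba_ie: float = 0.05
    w_gaba_ii: float = 0.005
    # synaptic kinetics and reversals
    tau_ampa: float = 2.0
    tau_nmda: float = 100.0
    tau_gaba: float = 8.0
    e_exc: float = 0.0
    e_gaba: float = -70.0
    mg_mM: float = 1.0
    # modulation-target channels (pyramidal cells)
    g_ks: float = 0.25
    g_hva: float = 0.02
    # background Poisson bombardment (per neuron): AMPA-like events plus an
    # NMDA component carrying the class-appropriate NR2 subunits (NR2A/B on
    # pyramidal targets, NR2C/D on interneurons), hence glycine-scaled
    noise_rate: float = 1000.0  # Hz
    noise_amp: float = 0.005
    noise_nmda_amp: float = 0.004
    noise_nmda_amp_inh: float = 0.0028
    # tonic bias currents (uA/cm2) with per-neuron jitter for heterogeneity
    bias_exc: float = 2.5
    bias_inh: float = 0.9
    bias_jitter: float = 0.25
    # stimulus: transient current to a pyramidal target subset
    stimulus_onset: float = 2000.0
    stimulus_duration: float = 50.0
    stimulus_amplitude: float = 3.0
    n_stim_targets: int = 10
    # distractors: pyramidal subset with independent Poisson drive
    n_distractors: int = 5
    distractor_rate: float = 200.0  # Hz
    distractor_amp: float = 0.015
    # integration
    duration: float = 6000.0
    dt: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exc <= 0 or self.n_inh <= 0:
            raise ValueError("population counts must be positive")
        for name in ("p_ee", "p_ei", "p_ie", "p_ii"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dt <= 0 or self.dt > 0.05:
            raise ValueError("dt must lie in (0, 0.05] ms")
        if self.duration <= self.stimulus_onset:
            raise ValueError("duration must exceed the stimulus onset")
        if self.n_stim_targets > self.n_exc or self.n_distractors > self.n_exc:
            raise ValueError("stimulus/distractor subsets must fit in the pyramidal population")


@dataclass
class NetworkOutput:
    """Spikes, window-averaged pyramidal rate, and normalized drives."""

    spike_neurons: np.ndarray
    spike_times: np.ndarray  # ms
    mean_exc_rate: float  # Hz over the analysis window
    u_e: np.ndarray
    u_i: np.ndarray
    u_dt: float  # s, sampling interval of u_e/u_i
    analysis_window: tuple
    rate_e: np.ndarray = field(default_factory=lambda: np.array([]))  # Hz, absolute


def apply_pathology(cfg: NetworkConfig, path: PathologyConfig,
                    couplings: Optional[ReceptorCouplingTable] = None
                    ) -> tuple[NetworkConfig, ReceptorCouplingTable]:
    """Return a lesioned copy of the config (and coupling table).

    NMDA weights x(1 - nmda_reduction); GABA weights x(1 - gaba_reduction);
    dopamine-receptor coupling gains x(1 - da_deficit); noise amplitude
    x(1 + noise_increase).  Inputs are left unmodified.
    """
    couplings = couplings or ReceptorCouplingTable()
    lesioned = replace(
        cfg,
        w_nmda_ee=cfg.w_nmda_ee * (1.0 - path.nmda_reduction),
        w_nmda_ei=cfg.w_nmda_ei * (1.0 - path.nmda_reduction),
        w_gaba_ie=cfg.w_gaba_ie * (1.0 - path.gaba_reduction),
        w_gaba_ii=cfg.w_gaba_ii * (1.0 - path.gaba_reduction),
        noise_amp=cfg.noise_amp * (1.0 + path.noise_increase),
    )
    new_couplings = ReceptorCouplingTable(
        couplings=tuple(
            (r, t, g * (1.0 - path.da_deficit) if r in DOPAMINE_RECEPTORS else g)
            for r, t, g in couplings.couplings
        )
    )
    return lesioned, new_couplings


def apply_receptor_effects(
    cfg: NetworkConfig,
    effects: dict,
    table: ReceptorCouplingTable = ReceptorCouplingTable(),
) -> NetworkConfig:
    """Scale coupled channel parameters by receptor relative activations.

    ``effects`` maps receptor name -> relative activation (X_eff).  Each
    coupling (receptor, parameter, gain) multiplies the parameter by
    ``max(0, 1 + gain * X_eff)``; multiple receptors on one parameter stack
    multiplicatively.  Unknown receptors raise, listing the known ones.
    """
    known = table.receptors
    unknown = sorted(set(effects) - set(known))
    if unknown:
        raise KeyError(f"unknown receptor(s) {unknown}; known receptors: {list(known)}")
    factors = {p: 1.0 for p in COUPLABLE_PARAMETERS}
    for receptor, target, gain in table.couplings:
        if receptor in effects:
            factors[target] *= max(0.0, 1.0 + gain * effects[receptor])
    return replace(cfg, **{
        p: getattr(cfg, p) * f for p, f in factors.items() if f != 1.0
    })


# ---------------------------------------------------------------------------
# integration kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _integrate(
    n_e, n_i, dt, n_steps,
    w_ampa, w_nmda, w_gaba,          # (n, n) pre -> post conductance increments
    g_ks, g_hva,                     # per-neuron modulation-target conductances
    phi,                             # per-neuron gating temperature factor
    mg,
    tau_ampa, tau_nmda, tau_gaba,
    e_exc, e_gaba,
    noise_p, noise_amp, noise_nmda_amp,  # per-neuron Poisson prob/step and amplitudes
    bias,                            # per-neuron tonic current
    stim_current,                    # per-neuron stimulus amplitude
    stim_start, stim_end,            # step indices
    distract_p, distract_amp,        # per-neuron distractor Poisson drive
    seed,
    max_spikes,
):
    n = n_e + n_i
    np.random.seed(seed)
    # Wang-Buzsaki-type membrane: C = 1, g_na = 35, g_k = 9, g_l = 0.1
    c_m, g_na, g_kdr, g_l = 1.0, 35.0, 9.0, 0.1
    e_na, e_k, e_l = 55.0, -90.0, -65.0

    v = np.full(n, -64.0) + np.random.standard_normal(n) * 2.0
    h = np.full(n, 0.78)
    nn = np.full(n, 0.09)
    z = np.zeros(n)  # slow K+ activation
    s_ampa = np.zeros(n)
    s_nmda = np.zeros(n)
    s_gaba = np.zeros(n)
    s_noise = np.zeros(n)
    s_noise_nmda = np.zeros(n)

    d_ampa = math.exp(-dt / tau_ampa)
    d_nmda = math.exp(-dt / tau_nmda)
    d_gaba = math.exp(-dt / tau_gaba)

    spike_neuron = np.empty(max_spikes, dtype=np.int64)
    spike_step = np.empty(max_spikes, dtype=np.int64)
    n_spikes = 0
    refract = np.zeros(n, dtype=np.int64)
    refract_steps = int(2.0 / dt)

    for step in range(n_steps):
        stim_on = stim_start <= step < stim_end
        # synaptic decay
        s_ampa *= d_ampa
        s_nmda *= d_nmda
        s_gaba *= d_gaba
        s_noise *= d_ampa
        s_noise_nmda *= d_nmda
        # background + distractor Poisson events
        for i in range(n):
            if np.random.random() < noise_p[i]:
                s_noise[i] += noise_amp[i]
                s_noise_nmda[i] += noise_nmda_amp[i]
            if distract_p[i] > 0.0 and np.random.random() < distract_p[i]:
                s_noise[i] += distract_amp[i]

        spiked_now = np.zeros(n, dtype=np.bool_)
        for i in range(n):
            vi = v[i]
            # instantaneous Na+ activation
            am = 0.1 * (vi + 35.0) / (1.0 - math.exp(-0.1 * (vi + 35.0))) if vi != -35.0 else 1.0
            bm = 4.0 * math.exp(-(vi + 60.0) / 18.0)
            m_inf = am / (am + bm)
            ah = 0.07 * math.exp(-(vi + 58.0) / 20.0)
            bh = 1.0 / (1.0 + math.exp(-0.1 * (vi + 28.0)))
            an = 0.01 * (vi + 34.0) / (1.0 - math.exp(-0.1 * (vi + 34.0))) if vi != -34.0 else 0.1
            bn = 0.125 * math.exp(-(vi + 44.0) / 80.0)
            # Rush-Larsen exponential gating update (stable at dt = 0.05 ms)
            rh = phi[i] * (ah + bh)
            h[i] += (1.0 - math.exp(-dt * rh)) * (ah / (ah + bh) - h[i])
            rn = phi[i] * (an + bn)
            nn[i] += (1.0 - math.exp(-dt * rn)) * (an / (an + bn) - nn[i])
            z_inf = 1.0 / (1.0 + math.exp(-(vi + 35.0) / 10.0))
            z[i] += (1.0 - math.exp(-dt / 75.0)) * (z_inf - z[i])

            i_na = g_na * m_inf**3 * h[i] * (vi - e_na)
            i_kdr = g_kdr * nn[i] ** 4 * (vi - e_k)
            i_ks = g_ks[i] * z[i] * (vi - e_k)
            s_hva = 1.0 / (1.0 + math.exp(-(vi + 20.0) / 9.0))
            i_hva = g_hva[i] * s_hva * (vi - 120.0)
            i_leak = g_l * (vi - e_l)
            b_mg = 1.0 / (1.0 + (mg / 3.57) * math.exp(-0.062 * vi))
            i_syn = (
                (s_ampa[i] + s_noise[i]) * (vi - e_exc)
                + (s_nmda[i] + s_noise_nmda[i]) * b_mg * (vi - e_exc)
                + s_gaba[i] * (vi - e_gaba)
            )
            i_app = bias[i] + (stim_current[i] if stim_on else 0.0)
            dv = (-i_na - i_kdr - i_ks - i_hva - i_leak - i_syn + i_app) / c_m
            v_new = vi + dt * dv
            if not math.isfinite(v_new):
                # signal integration failure with the offending step encoded
                return spike_neuron[:0], spike_step[:0], step
            if v_new >= -20.0 and vi < -20.0 and refract[i] <= 0:
                spiked_now[i] = True
                refract[i] = refract_steps
                if n_spikes < max_spikes:
                    spike_neuron[n_spikes] = i
                    spike_step[n_spikes] = step
                    n_spikes += 1
            if refract[i] > 0:
                refract[i] -= 1
            v[i] = v_new

        # propagate spikes
        for j in range(n):
            if spiked_now[j]:
                for i in range(n):
                    if w_ampa[j, i] > 0.0:
                        s_ampa[i] += w_ampa[j, i]
                    if w_nmda[j, i] > 0.0:
                        s_nmda[i] += w_nmda[j, i]
                    if w_gaba[j, i] > 0.0:
                        s_gaba[i] += w_gaba[j, i]

    return spike_neuron[:n_spikes], spike_step[:n_spikes], -1


def _build_weights(cfg: NetworkConfig, g_ee_factor: float, g_ei_factor: float,
                   rng: np.random.Generator):
    n = cfg.n_exc + cfg.n_inh
    w_ampa = np.zeros((n, n))
    w_nmda = np.zeros((n, n))
    w_gaba = np.zeros((n, n))
    e_idx = np.arange(cfg.n_exc)
    i_idx = np.arange(cfg.n_exc, n)
    for j in e_idx:  # excitatory projections
        for i in e_idx:
            if i != j and rng.random() < cfg.p_ee:
                w_ampa[j, i] = cfg.w_ampa_ee
                w_nmda[j, i] = cfg.w_nmda_ee * g_ee_factor
        for i in i_idx:
            if rng.random() < cfg.p_ei:
                w_ampa[j, i] = cfg.w_ampa_ei
                w_nmda[j, i] = cfg.w_nmda_ei * g_ei_factor
    for j in i_idx:  # inhibitory projections
        for i in e_idx:
            if rng.random() < cfg.p_ie:
                w_gaba[j, i] = cfg.w_gaba_ie
        for i in i_idx:
            if i != j and rng.random() < cfg.p_ii:
                w_gaba[j, i] = cfg.w_gaba_ii
    return w_ampa, w_nmda, w_gaba


def _population_activity(spike_steps: np.ndarray, spike_neurons: np.ndarray,
                         members: np.ndarray, cfg: NetworkConfig,
                         bin_ms: float = 10.0, smooth_bins: int = 5,
                         rate_floor: float = 0.5):
    """Binned, smoothed population rate normalized to pre-stimulus mean 1.

    A small rate floor (Hz) regularizes the normalization so silent traces
    map to a flat u = 1 rather than 0/0.
    """
    n_bins = int(round(cfg.duration / bin_ms))
    mask = np.isin(spike_neurons, members)
    times_ms = spike_steps[mask] * cfg.dt
    counts, _ = np.histogram(times_ms, bins=n_bins, range=(0.0, n_bins * bin_ms))
    rate = counts / (len(members) * bin_ms * 1e-3)  # Hz per neuron
    kernel = np.ones(smooth_bins) / smooth_bins
    rate = np.convolve(rate, kernel, mode="same")
    pre = rate[: int(cfg.stimulus_onset / bin_ms)]
    baseline = float(np.mean(pre)) if len(pre) else 0.0
    u = (rate + rate_floor) / (baseline + rate_floor)
    return u, rate, bin_ms * 1e-3


def simulate_network(
    cfg: NetworkConfig,
    path: Optional[PathologyConfig] = None,
    gly: float = 1.0,
    pd_: Optional[SynapseClassPD] = None,
    couplings: Optional[ReceptorCouplingTable] = None,
    receptor_effects: Optional[dict] = None,
) -> NetworkOutput:
    """Simulate the cortical circuit at one glycine concentration.

    The e-e NMDA weight is scaled by the NR2A/B glycine potentiation and the
    e-i NMDA weight by the NR2C/D potentiation (both 1 when ``pd_`` is
    omitted).  Pathology, receptor effects and the stimulus/distractor
    protocol are applied before integration; the run is deterministic given
    ``cfg.seed``.  Returns spikes, the mean pyramidal rate over the
    analysis window (stimulus onset to end), and normalized population
    drives sampled every 10 ms.
    """
    couplings = couplings or ReceptorCouplingTable()
    if path is not None:
        cfg, couplings = apply_pathology(cfg, path, couplings)
    if receptor_effects:
        cfg = apply_receptor_effects(cfg, receptor_effects, couplings)

    if pd_ is None:
        g_ee_factor = g_ei_factor = 1.0
    else:
        g_ee_factor = effective_conductance(gly, "ee", pd_)
        g_ei_factor = effective_conductance(gly, "ei", pd_)

    n = cfg.n_exc + cfg.n_inh
    rng = np.random.default_rng(cfg.seed)
    w_ampa, w_nmda, w_gaba = _build_weights(cfg, g_ee_factor, g_ei_factor, rng)

    phi = np.where(np.arange(n) < cfg.n_exc, 1.0, 5.0)
    g_ks = np.where(np.arange(n) < cfg.n_exc, cfg.g_ks, 0.0)
    g_hva = np.where(np.arange(n) < cfg.n_exc, cfg.g_hva, 0.0)
    noise_p = np.full(n, cfg.noise_rate * cfg.dt * 1e-3)
    noise_amp = np.full(n, cfg.noise_amp)
    noise_nmda_amp = np.where(
        np.arange(n) < cfg.n_exc,
        cfg.noise_nmda_amp * g_ee_factor,
        cfg.noise_nmda_amp_inh * g_ei_factor,
    )
    bias = np.where(np.arange(n) < cfg.n_exc, cfg.bias_exc, cfg.bias_inh)
    bias = bias + rng.standard_normal(n) * cfg.bias_jitter
    stim_current = np.zeros(n)
    stim_current[: cfg.n_stim_targets] = cfg.stimulus_amplitude
    distract_p = np.zeros(n)
    distract_amp = np.zeros(n)
    if cfg.n_distractors > 0:
        d_idx = np.arange(cfg.n_exc - cfg.n_distractors, cfg.n_exc)
        distract_p[d_idx] = cfg.distractor_rate * cfg.dt * 1e-3
        distract_amp[d_idx] = cfg.distractor_amp

    n_steps = int(round(cfg.duration / cfg.dt))
    stim_start = int(round(cfg.stimulus_onset / cfg.dt))
    stim_end = int(round((cfg.stimulus_onset + cfg.stimulus_duration) / cfg.dt))
    max_spikes = int(n * cfg.duration * 0.4)  # 400 Hz/neuron headroom
    kernel_seed = int(rng.integers(0, 2**31 - 1))

    spike_neurons, spike_steps, fail_step = _integrate(
        cfg.n_exc, cfg.n_inh, cfg.dt, n_steps,
        w_ampa, w_nmda, w_gaba,
        g_ks, g_hva, phi, cfg.mg_mM,
        cfg.tau_ampa, cfg.tau_nmda, cfg.tau_gaba,
        cfg.e_exc, cfg.e_gaba,
        noise_p, noise_amp, noise_nmda_amp, bias,
        stim_current, stim_start, stim_end,
        distract_p, distract_amp,
        kernel_seed, max_spikes,
    )
    if fail_step >= 0:
        raise FloatingPointError(
            f"membrane potential became non-finite at step {fail_step} "
            f"(t = {fail_step * cfg.dt:.2f} ms)"
        )

    window = (cfg.stimulus_onset, cfg.duration)
    window_s = (window[1] - window[0]) * 1e-3
    exc_mask = spike_neurons < cfg.n_exc
    in_window = (spike_steps * cfg.dt >= window[0]) & (spike_steps * cfg.dt < window[1])
    mean_rate = float(np.sum(exc_mask & in_window) / (cfg.n_exc * window_s))

    u_e, rate_e, u_dt = _population_activity(
        spike_steps, spike_neurons, np.arange(cfg.n_exc), cfg
    )
    u_i, _, _ = _population_activity(
        spike_steps, spike_neurons, np.arange(cfg.n_exc, n), cfg
    )
    return NetworkOutput(
        spike_neurons=spike_neurons,
        spike_times=spike_steps * cfg.dt,
        mean_exc_rate=mean_rate,
        u_e=u_e,
        u_i=u_i,
        u_dt=u_dt,
        analysis_window=window,
        rate_e=rate_e,
    )
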