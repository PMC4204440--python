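"""Ventral-striatum medium spiny neuron (MSN) model.

The MSN is the principal GABAergic cell of the nucleus accumbens.  Its
membrane potential integrates a dopamine-modulated inward-rectifier K+
current (Kir2), an A-type K+ current, a Cl- current, Ca2+ currents
(including L-type), a slow K+ current, and standard spike currents, driven
by afferent cortical glutamate gated by hippocampal/amygdala projections:

    C dV/dt = -(I_Kir2 + I_KA + I_Cl + I_Ca + I_Ks + ...) + I_syn

The Kir2 conductance follows a Boltzmann form
``g = g_bar / (1 + exp(-(V - V_h)/V_c))`` with g_bar = 1.2 mS/cm2,
V_h = -111 mV, V_c = -11 mV and E_K = -90 mV; with this (negative) V_c the
conductance falls with depolarization — inward rectification — and the
whole current is multiplied by the D1 activation scale u.

Three cell classes are simulated: substance-P/D1 (direct pathway),
enkephalin/D2 (indirect pathway), and a small dual D1/D2 population.
Receptor relative activations modulate class-appropriate targets: D1 scales
Kir2 and L-type Ca2+ in SP cells, D2 scales the A-type K+ current and
presynaptic glutamate release in Enk cells, M1 the Cl- channel, M2 the
afferent drive, alpha-1A the gating signal, and 5HT2C/5HT3 shift striatal
dopamine release linearly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "KirParams",
    "MSNParams",
    "ModulationState",
    "MSNResult",
    "kir2_current",
    "dopamine_release_scale",
    "simulate_msn",
    "striatal_population_readout",
    "square_pulse_gate",
]

CELL_CLASSES = ("SP_D1", "Enk_D2", "dual")


@dataclass(frozen=True)
class KirParams:
    """Kir2 Boltzmann parameters (defaults from striatal recordings)."""

    g_bar: float = 1.2  # mS/cm2
    e_k: float = -90.0  # mV
    v_h: float = -111.0  # mV, half-activation
    v_c: float = -11.0  # mV, sensitivity (negative: g falls with V)

    def __post_init__(self) -> None:
        if not self.g_bar > 0:
            raise ValueError("g_bar must be positive")
        if self.v_c == 0:
            raise ValueError("v_c must be nonzero")


def kir2_current(v, u: float, p: KirParams = KirParams()):
    """Dopamine-scaled inward-rectifier current (uA/cm2).

    ``I = u * g(v) * (v - E_K)`` with the Boltzmann conductance above; at
    v = V_h the conductance is exactly g_bar/2.  ``u`` is the D1 activation
    scale (1 = baseline).
    """
    if u < 0:
        raise ValueError("activation scale u must be >= 0")
    varr = np.asarray(v, dtype=float)
    g = p.g_bar / (1.0 + np.exp(-(varr - p.v_h) / p.v_c))
    out = u * g * (varr - p.e_k)
    return float(out) if np.isscalar(v) else out


@dataclass(frozen=True)
class MSNParams:
    """MSN channel densities (mS/cm2) and synaptic gain for one cell class.

    A-type K+, Cl-, Ca2+ and slow-K+ kinetics are standard textbook
    formulations (the half-activation voltages and time constants below are
    labeled assumptions); Kir2 follows :class:`KirParams`.
    """

    cell_class: str = "SP_D1"
    c_m: float = 1.0  # uF/cm2
    kir: KirParams = field(default_factory=KirParams)
    g_ka: float = 1.5
    g_cl: float = 0.06
    e_cl: float = -60.0
    g_ca_l: float = 0.02
    e_ca: float = 120.0
    g_ks: float = 0.3  # slow K+ (the I_Ksi term)
    g_na: float = 35.0
    g_kdr: float = 9.0
    g_leak: float = 0.05
    e_leak: float = -75.0
    g_syn: float = 0.25  # glutamate conductance per unit drive
    noise_rate: float = 400.0  # Hz background events
    noise_amp: float = 0.004

    def __post_init__(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"cell_class must be one of {CELL_CLASSES}")
        if not self.c_m > 0:
            raise ValueError("membrane capacitance must be positive")


@dataclass(frozen=True)
class ModulationState:
    """Receptor relative activations (X_eff, 0 = no change) plus the linear
    gains coupling them to channel and release parameters.

    The derived dopamine release scale is
    ``1 + k_2c*(-x_5ht2c) + k_3*(x_5ht3)`` clipped at 0: 5HT2C inhibition
    (negative X_eff) raises striatal dopamine, 5HT3 antagonism lowers it.
    Gains default to 0.5; they are the calibration tunables, not measured
    constants.
    """

    x_d1: float = 0.0
    x_d2: float = 0.0
    x_m1: float = 0.0
    x_m2: float = 0.0
    x_5ht2c: float = 0.0
    x_5ht3: float = 0.0
    x_alpha1a: float = 0.0
    k_2c: float = 0.5
    k_3: float = 0.5
    k_d1_ca: float = 0.5
    k_d2_ka: float = 0.5
    k_d2_glu: float = 0.5
    k_m1: float = 0.5
    k_m2: float = 0.5
    k_a1: float = 0.5

    def __post_init__(self) -> None:
        for name in ("x_d1", "x_d2", "x_m1", "x_m2", "x_5ht2c", "x_5ht3", "x_alpha1a"):
            if getattr(self, name) <= -1.0:
                raise ValueError(f"{name} must exceed -1 (relative activation)")


def dopamine_release_scale(m: ModulationState) -> float:
    """Striatal dopamine release scale from serotonergic modulation."""
    return max(0.0, 1.0 + m.k_2c * (-m.x_5ht2c) + m.k_3 * m.x_5ht3)


def _class_factors(p: MSNParams, m: ModulationState) -> dict:
    """Resolve the class-appropriate modulation multipliers."""
    da = dopamine_release_scale(m)
    has_d1 = p.cell_class in ("SP_D1", "dual")
    has_d2 = p.cell_class in ("Enk_D2", "dual")
    d1 = (1.0 + m.x_d1) * da if has_d1 else 1.0
    d2 = (1.0 + m.x_d2) * da if has_d2 else 1.0
    return {
        "u_kir": max(0.0, d1),
        "ca_l": max(0.0, 1.0 + m.k_d1_ca * (d1 - 1.0)) if has_d1 else 1.0,
        "ka": max(0.0, 1.0 + m.k_d2_ka * (d2 - 1.0)) if has_d2 else 1.0,
        # D2 activity inhibits presynaptic glutamate release
        "presyn": max(0.0, 1.0 - m.k_d2_glu * (d2 - 1.0)) if has_d2 else 1.0,
        "cl": max(0.0, 1.0 + m.k_m1 * m.x_m1),
        "afferent": max(0.0, 1.0 - m.k_m2 * m.x_m2),
        "gating": max(0.0, 1.0 + m.k_a1 * m.x_alpha1a),
    }


@njit(cache=True)
def _integrate_msn(
    dt, n_steps, c_m,
    kir_gbar, kir_ek, kir_vh, kir_vc, u_kir,
    g_ka, g_cl, e_cl, g_ca, e_ca, g_ks,
    g_na, g_kdr, g_leak, e_leak,
    drive,                    # pre-multiplied conductance time series
    noise_p, noise_amp, seed,
):
    np.random.seed(seed)
    v = -82.0
    h, nn = 0.9, 0.05
    b_ka = 0.8
    z = 0.0
    s_noise = 0.0
    d_noise = math.exp(-dt / 2.0)
    trace = np.empty(n_steps)
    n_spikes = 0
    was_below = True
    for step in range(n_steps):
        s_noise *= d_noise
        if np.random.random() < noise_p:
            s_noise += noise_amp
        # gating kinetics
        am = 0.1 * (v + 35.0) / (1.0 - math.exp(-0.1 * (v + 35.0))) if v != -35.0 else 1.0
        bm = 4.0 * math.exp(-(v + 60.0) / 18.0)
        m_inf = am / (am + bm)
        ah = 0.07 * math.exp(-(v + 58.0) / 20.0)
        bh = 1.0 / (1.0 + math.exp(-0.1 * (v + 28.0)))
        an = 0.01 * (v + 34.0) / (1.0 - math.exp(-0.1 * (v + 34.0))) if v != -34.0 else 0.1
        bn = 0.125 * math.exp(-(v + 44.0) / 80.0)
        h += (1.0 - math.exp(-dt * (ah + bh))) * (ah / (ah + bh) - h)
        nn += (1.0 - math.exp(-dt * (an + bn))) * (an / (an + bn) - nn)
        b_inf = 1.0 / (1.0 + math.exp((v + 70.0) / 7.0))
        b_ka += (1.0 - math.exp(-dt / 25.0)) * (b_inf - b_ka)
        z_inf = 1.0 / (1.0 + math.exp(-(v + 35.0) / 8.0))
        z += (1.0 - math.exp(-dt / 100.0)) * (z_inf - z)

        g_kir = kir_gbar / (1.0 + math.exp(-(v - kir_vh) / kir_vc))
        i_kir = u_kir * g_kir * (v - kir_ek)
        a_inf = 1.0 / (1.0 + math.exp(-(v + 45.0) / 14.0))
        i_ka = g_ka * a_inf * b_ka * (v - kir_ek)
        i_cl = g_cl * (v - e_cl)
        s_ca = 1.0 / (1.0 + math.exp(-(v + 25.0) / 5.0))
        i_ca = g_ca * s_ca * s_ca * (v - e_ca)
        i_ks = g_ks * z * (v - kir_ek)
        i_na = g_na * m_inf**3 * h * (v - 55.0)
        i_kdr = g_kdr * nn**4 * (v - kir_ek)
        i_leak = g_leak * (v - e_leak)
        i_syn = (drive[step] + s_noise) * (v - 0.0)
        dv = (-(i_kir + i_ka + i_cl + i_ca + i_ks + i_na + i_kdr + i_leak + i_syn)) / c_m
        v_new = v + dt * dv
        if not math.isfinite(v_new):
            return trace[:0], -1, step
        if v_new >= -20.0 and was_below:
            n_spikes += 1
            was_below = False
        elif v_new < -30.0:
            was_below = True
        v = v_new
        trace[step] = v
    return trace, n_spikes, -1


@dataclass
class MSNResult:
    """Voltage trace, spike count, and an excitability index (spike rate
    in Hz over the simulation)."""

    voltage: np.ndarray
    spike_count: int
    excitability: float
    dt: float
    cell_class: str


def square_pulse_gate(n_steps: int, dt: float, onset_ms: float = 500.0,
                      offset_ms: float | None = None, level: float = 1.0) -> np.ndarray:
    """Default hippocampal/amygdala gating: a square pulse opening at
    ``onset_ms`` (closing at ``offset_ms`` if given), 0 elsewhere."""
    t = np.arange(n_steps) * dt
    gate = np.zeros(n_steps)
    hi = offset_ms if offset_ms is not None else t[-1] + dt
    gate[(t >= onset_ms) & (t < hi)] = level
    return gate


def simulate_msn(
    p: MSNParams,
    cortical_drive: np.ndarray,
    gating_drive: np.ndarray,
    m: ModulationState = ModulationState(),
    dt: float = 0.05,
    seed: int = 0,
) -> MSNResult:
    """Integrate one MSN driven by gated cortical glutamate.

    ``cortical_drive`` is a nonnegative series (arbitrary drive units,
    sampled at ``dt`` ms) multiplied by ``gating_drive`` (the
    hippocampal/amygdala gate), the synaptic gain and the modulation
    factors (presynaptic D2, M2 afferent, alpha-1A gating) to form the
    glutamatergic conductance.  Deterministic given ``seed``.
    """
    cortical_drive = np.asarray(cortical_drive, dtype=float)
    gating_drive = np.asarray(gating_drive, dtype=float)
    if cortical_drive.shape != gating_drive.shape:
        raise ValueError("cortical and gating drives must share a time base")
    if np.any(cortical_drive < 0):
        raise ValueError("cortical drive must be nonnegative")
    f = _class_factors(p, m)
    drive = (
        p.g_syn * f["presyn"] * f["afferent"]
        * cortical_drive * (f["gating"] * gating_drive)
    )
    trace, n_spikes, fail = _integrate_msn(
        dt, len(drive), p.c_m,
        p.kir.g_bar, p.kir.e_k, p.kir.v_h, p.kir.v_c, f["u_kir"],
        p.g_ka * f["ka"], p.g_cl * f["cl"], p.e_cl,
        p.g_ca_l * f["ca_l"], p.e_ca, p.g_ks,
        p.g_na, p.g_kdr, p.g_leak, p.e_leak,
        drive, p.noise_rate * dt * 1e-3, p.noise_amp, seed,
    )
    if fail >= 0:
        raise FloatingPointError(
            f"MSN membrane potential became non-finite at step {fail} "
            f"(t = {fail * dt:.2f} ms)"
        )
    duration_s = len(drive) * dt * 1e-3
    return MSNResult(
        voltage=trace,
        spike_count=n_spikes,
        excitability=n_spikes / duration_s,
        dt=dt,
        cell_class=p.cell_class,
    )


def striatal_population_readout(
    cells: Sequence[MSNResult],
    class_weights: dict | None = None,
) -> float:
    """Weighted mean firing measure (Hz) over the MSN population.

    Cells are grouped by class; each class contributes its mean
    excitability, weighted by ``class_weights`` (default equal weights over
    the classes present).  Linear in spike counts; 0 for a silent
    population.
    """
    if len(cells) == 0:
        raise ValueError("empty MSN population")
    by_class: dict[str, list[float]] = {}
    for c in cells:
        by_class.setdefault(c.cell_class, []).append(c.excitability)
    if class_weights is None:
        class_weights = {k: 1.0 for k in by_class}
    missing = set(class_weights) - set(by_class)
    if missing:
        raise ValueError(f"no cells for weighted class(es) {sorted(missing)}")
    total_w = sum(class_weights.values())
    if total_w <= 0:
        raise ValueError("class weights must sum to a positive number")
    return sum(
        w * float(np.mean(by_class[k])) for k, w in class_weights.items()
    ) / total_w
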