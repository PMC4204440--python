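"""Balloon-model BOLD readout driven by excitatory/inhibitory activity.

The metabolic-hemodynamic cascade maps normalized excitatory and inhibitory
population activities u_e(t), u_i(t) (baseline = 1) to a BOLD signal:

* a sigmoid transfer (steepness ``c``, threshold ``d``, rescaled so baseline
  1 maps to 1) shapes the neural drives;
* second-order linear responses turn delayed drives into normalized glucose
  consumption g_e(t), g_i(t);
* oxygen consumption m(t) is a gamma-weighted mix of the excitatory rate
  m_e = g_e*(2-x)/(2-x0) (x = oxygen-glucose index, constant x0 by default)
  and the inhibitory rate m_i = g_i;
* a flow-inducing signal drives cerebral blood flow f(t), and the venous
  balloon integrates volume v(t) and deoxyhemoglobin q(t) with outflow
  f_out = v**(1/alpha) + tau*dv/dt;
* the BOLD signal is y(t) = V0*(a1*(1-q) - a2*(1-v)).

At u_e = u_i = 1 every state sits at its fixed point and y = 0, so the model
reports only departures from baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = ["BalloonParams", "BoldResult", "simulate_bold", "metabolic_rate", "bold_summary"]

# state vector layout
_V, _Q, _F, _S, _GE, _GI, _SE, _SI = range(8)


@dataclass(frozen=True)
class BalloonParams:
    """Hemodynamic and metabolic parameters.

    Printed literature values: a_e = 1.2 (glucose-response efficacy to
    excitation), c = 2.5 and d = 1.6 (sigmoid), tau = 10 s (viscoelastic
    volume adjustment), a1 = 3.4 (deoxyhemoglobin weight).  The remaining
    defaults are standard hemodynamic-review values: Grubb exponent
    alpha = 0.4, transit time t0 = 1 s, flow-response epsilon = 0.5,
    tau_s = 0.8 s, tau_f = 0.4 s.  a2 (volume weight) defaults to 1.0.
    """

    v0: float = 0.02
    a1: float = 3.4
    a2: float = 1.0
    t0: float = 1.0
    tau: float = 10.0
    alpha: float = 0.4
    gamma: float = 1.0
    a_e: float = 1.2
    a_i: float = 0.4
    tau_e: float = 1.0
    tau_i: float = 1.0
    delta_e: float = 0.5
    delta_f: float = 0.5
    # flow-response efficacy: steady CBF change is epsilon*tau_f*(u-1);
    # 3.0 puts the flow response ~2x the oxygen-consumption response,
    # the usual flow-metabolism uncoupling that makes BOLD positive
    epsilon: float = 3.0
    tau_s: float = 0.8
    tau_f: float = 0.4
    c: float = 2.5
    d: float = 1.6
    x0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("v0", "t0", "tau", "alpha", "tau_e", "tau_i", "tau_s", "tau_f"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.delta_e < 0 or self.delta_f < 0:
            raise ValueError("delays must be >= 0")
        if self.x0 == 2.0:
            raise ValueError("x0 = 2 makes the excitatory oxygen rate singular")


def metabolic_rate(g_e, g_i, x, p: BalloonParams):
    """Oxygen consumption m from normalized glucose rates and the
    oxygen-glucose index x: m_i = g_i, m_e = g_e*(2-x)/(2-x0),
    m = (gamma*m_e + m_i)/(gamma + 1)."""
    if p.x0 == 2.0:
        raise ValueError("x0 = 2 is singular")
    m_i = np.asarray(g_i, dtype=float)
    m_e = np.asarray(g_e, dtype=float) * (2.0 - np.asarray(x)) / (2.0 - p.x0)
    m = (p.gamma * m_e + m_i) / (p.gamma + 1.0)
    return float(m) if np.isscalar(g_e) and np.isscalar(g_i) else m


def _sigmoid_drive(u: np.ndarray, p: BalloonParams) -> np.ndarray:
    """Logistic transfer rescaled to map baseline activity 1 to 1."""
    s = 1.0 / (1.0 + np.exp(-p.c * (u - p.d)))
    s1 = 1.0 / (1.0 + np.exp(-p.c * (1.0 - p.d)))
    return s / s1


@dataclass
class BoldResult:
    """BOLD trajectory plus the underlying hemodynamic states."""

    t: np.ndarray
    y: np.ndarray
    states: dict = field(default_factory=dict)


def simulate_bold(
    u_e: np.ndarray,
    u_i: np.ndarray,
    p: BalloonParams = BalloonParams(),
    dt: float = 0.005,
    x_of_t: Optional[Callable[[float], float]] = None,
) -> BoldResult:
    """Integrate the hemodynamic cascade for drives sampled at ``dt`` (s).

    ``u_e`` and ``u_i`` are normalized population activities (baseline 1)
    sampled on a common grid; integration starts from the baseline fixed
    point (v = q = f = g_e = g_i = 1, signals 0) and uses fixed-step RK4.
    ``x_of_t`` optionally supplies a time-varying oxygen-glucose index;
    the default holds x = x0 (uncoupling off).

    Raises on dt > 0.01 s, non-finite states, or v/q leaving the positive
    domain.
    """
    if dt <= 0 or dt > 0.01:
        raise ValueError("dt must be in (0, 0.01] s")
    u_e = np.asarray(u_e, dtype=float)
    u_i = np.asarray(u_i, dtype=float)
    if u_e.shape != u_i.shape or u_e.ndim != 1 or len(u_e) < 2:
        raise ValueError("u_e and u_i must be equal-length 1-D series")
    n = len(u_e)
    t_grid = np.arange(n) * dt
    ue_s = _sigmoid_drive(u_e, p)
    ui_s = _sigmoid_drive(u_i, p)

    def drive(series: np.ndarray, t: float) -> float:
        if t <= 0.0:
            return series[0]
        return float(np.interp(t, t_grid, series))

    x_fun = (lambda t: p.x0) if x_of_t is None else x_of_t

    def rhs(t: float, st: np.ndarray) -> np.ndarray:
        v, q, f, s, g_e, g_i, s_e, s_i = st
        d = np.empty(8)
        ue_de = drive(ue_s, t - p.delta_e)
        ui_de = drive(ui_s, t - p.delta_e)
        ue_df = drive(ue_s, t - p.delta_f)
        # balloon: dv/dt solved algebraically from the implicit f_out coupling
        dv = (f - v ** (1.0 / p.alpha)) / (p.t0 + p.tau)
        f_out = v ** (1.0 / p.alpha) + p.tau * dv
        m = metabolic_rate(g_e, g_i, x_fun(t), p)
        d[_V] = dv
        d[_Q] = (m - f_out * q / v) / p.t0
        d[_F] = s
        d[_S] = p.epsilon * (ue_df - 1.0) - s / p.tau_s - (f - 1.0) / p.tau_f
        d[_GE] = s_e
        d[_GI] = s_i
        d[_SE] = p.a_e * (ue_de - 1.0) / p.tau_e - 2.0 * s_e / p.tau_e - (g_e - 1.0) / p.tau_e**2
        d[_SI] = p.a_i * (ui_de - 1.0) / p.tau_i - 2.0 * s_i / p.tau_i - (g_i - 1.0) / p.tau_i**2
        return d

    st = np.array([1.0, 1.0, 1.0, 0.0, 1.0, 1.0, 0.0, 0.0])
    traj = np.empty((n, 8))
    traj[0] = st
    for k in range(n - 1):
        t = t_grid[k]
        k1 = rhs(t, st)
        k2 = rhs(t + dt / 2, st + dt / 2 * k1)
        k3 = rhs(t + dt / 2, st + dt / 2 * k2)
        k4 = rhs(t + dt, st + dt * k3)
        st = st + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(st)):
            raise FloatingPointError(f"non-finite hemodynamic state at t = {t + dt:.3f} s")
        if st[_V] <= 0 or st[_Q] <= 0:
            raise FloatingPointError(
                f"blood volume or deoxyhemoglobin left the positive domain at t = {t + dt:.3f} s"
            )
        traj[k + 1] = st

    y = p.v0 * (p.a1 * (1.0 - traj[:, _Q]) - p.a2 * (1.0 - traj[:, _V]))
    states = {
        name: traj[:, idx]
        for name, idx in zip(
            ("v", "q", "f", "s", "g_e", "g_i", "s_e", "s_i"),
            range(8),
        )
    }
    return BoldResult(t=t_grid, y=y, states=states)


def bold_summary(y: np.ndarray, window: tuple[float, float], dt: float, method: str = "peak") -> float:
    """Scalar summary of a BOLD trace over a time window (s).

    ``peak`` (default) is the maximum of y in the window; ``integral`` is the
    trapezoidal time-integral.  Both are linear in y.
    """
    y = np.asarray(y, dtype=float)
    t = np.arange(len(y)) * dt
    mask = (t >= window[0]) & (t <= window[1])
    if not np.any(mask):
        raise ValueError(f"window {window} selects no samples")
    if method == "peak":
        return float(np.max(y[mask]))
    if method == "integral":
        return float(np.trapezoid(y[mask], t[mask]))
    raise ValueError(f"unknown summary method {method!r}")
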