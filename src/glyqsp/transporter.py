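"""Thermodynamics and kinetics of the GlyT1 glycine transporter.

GlyT1, mostly astrocytic, cotransports glycine with 2 Na+ and 1 Cl-, moving
one net positive charge inward per cycle.  At thermodynamic equilibrium the
electrochemical free energies balance, which pins the extracellular glycine
concentration:

    Gly_out = Gly_in * (Na_in/Na_out)^2 * (Cl_in/Cl_out) * exp(F*Vm / (R*T))

With physiological ion gradients and an astrocyte resting potential of
-75 to -40 mV this caps free extracellular glycine in the low micromolar
range — well below the glycine-site saturating concentrations — which is
what makes the low-micromolar ratio minimum pharmacologically reachable.
Uptake kinetics follow Michaelis-Menten with a slow turnover (~10/s) and
Km of 10-20 uM.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.constants import R as GAS_CONSTANT  # J/(mol K)
from scipy.constants import physical_constants

FARADAY = physical_constants["Faraday constant"][0]  # C/mol

__all__ = [
    "IonConditions",
    "TransporterKinetics",
    "equilibrium_glycine_out",
    "max_equilibrium_over_ranges",
    "mm_uptake_rate",
]


@dataclass(frozen=True)
class IonConditions:
    """Ion concentrations (mM), membrane potential (mV, inside - outside)
    and temperature (K) constraining the transporter equilibrium.

    Defaults: Na_out 140 mM and Cl_out 120 mM (standard extracellular
    values), astrocytic Na_in 15 mM, Cl_in in the reported 6-12 mM range
    (default 12), intracellular glycine 2 mM, Vm -75 mV, 310 K.
    """

    na_in: float = 15.0
    na_out: float = 140.0
    cl_in: float = 12.0
    cl_out: float = 120.0
    gly_in: float = 2.0
    vm: float = -75.0
    temperature: float = 310.0

    def __post_init__(self) -> None:
        for name in ("na_in", "na_out", "cl_in", "cl_out", "gly_in"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not np.isfinite(self.vm):
            raise ValueError("vm must be finite")
        if not 273.0 <= self.temperature <= 320.0:
            raise ValueError("temperature must lie in [273, 320] K")


@dataclass(frozen=True)
class TransporterKinetics:
    """Michaelis-Menten uptake parameters: Km (uM), turnover (cycles/s per
    transporter) and relative transporter density."""

    km: float = 15.0
    turnover: float = 10.0
    density: float = 1.0

    def __post_init__(self) -> None:
        if not (self.km > 0 and self.turnover > 0):
            raise ValueError("km and turnover must be positive")


def equilibrium_glycine_out(c: IonConditions) -> float:
    """Equilibrium extracellular glycine (uM) for a 2Na+/1Cl-/Gly cycle.

    Zero net free energy per cycle (net charge +1 inward) gives
    ``gly_in * (na_in/na_out)**2 * (cl_in/cl_out) * exp(F*vm/(R*T))``;
    gly_in is in mM, the result in uM.
    """
    rt = GAS_CONSTANT * c.temperature
    factor = (
        (c.na_in / c.na_out) ** 2
        * (c.cl_in / c.cl_out)
        * np.exp(FARADAY * (c.vm * 1e-3) / rt)
    )
    return float(c.gly_in * 1e3 * factor)


def max_equilibrium_over_ranges(
    na_in: Sequence[float] = (10.0, 20.0),
    cl_in: Sequence[float] = (6.0, 12.0),
    gly_in: Sequence[float] = (0.5, 5.0),
    vm: Sequence[float] = (-75.0, -40.0),
    na_out: float = 140.0,
    cl_out: float = 120.0,
    temperature: float = 310.0,
) -> tuple[float, IonConditions]:
    """Maximum equilibrium extracellular glycine (uM) over a physiological box.

    Each factor of the equilibrium relation is monotone in its variable, so
    the maximum sits at a corner; all corners are evaluated and the maximizing
    one returned alongside the value.  Ranges are (lo, hi) pairs in the units
    of :class:`IonConditions`.
    """
    for name, rng in (("na_in", na_in), ("cl_in", cl_in), ("gly_in", gly_in), ("vm", vm)):
        if len(rng) == 0:
            raise ValueError(f"empty range for {name}")
    best: tuple[float, IonConditions] | None = None
    for na, cl, gly, v in itertools.product(na_in, cl_in, gly_in, vm):
        cond = IonConditions(
            na_in=na, na_out=na_out, cl_in=cl, cl_out=cl_out,
            gly_in=gly, vm=v, temperature=temperature,
        )
        val = equilibrium_glycine_out(cond)
        if best is None or val > best[0]:
            best = (val, cond)
    assert best is not None
    return best


def mm_uptake_rate(gly_out, k: TransporterKinetics = TransporterKinetics()):
    """Michaelis-Menten uptake rate: ``density * turnover * s/(s + Km)``
    at extracellular glycine ``s`` (uM).  Scalar or array."""
    arr = np.asarray(gly_out, dtype=float)
    if np.any(arr < 0):
        raise ValueError("gly_out must be >= 0")
    out = k.density * k.turnover * arr / (arr + k.km)
    return float(out) if np.isscalar(gly_out) else out
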