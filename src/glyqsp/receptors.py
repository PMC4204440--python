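"""Steady-state receptor-competition pharmacology.

Mass-action competition between the endogenous neurotransmitter and up to
four exogenous agents (drugs, metabolites, radiotracers) at one receptor:
each ligand occupies a fraction (C/Ki) / (1 + sum_j C_j/Ki_j) of receptors,
and receptor activation is the intrinsic-activity-weighted sum of
occupancies (neurotransmitter intrinsic activity = 1; a neutral antagonist
contributes occupancy but no activation).  An optional presynaptic
autoreceptor feedback rescales neurotransmitter release by
``1 + gain * (baseline_auto_activation - auto_activation)`` and is solved by
fixed-point iteration.

The relative-activation statistic, ``(activated - control)/control``, is the
interface between this pharmacology layer and the circuit models: each
receptor's relative activation scales its coupled ion-channel or release
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Ligand",
    "SynapseContext",
    "steady_state_activation",
    "occupancies",
    "relative_effect",
    "occupancy_to_concentration",
    "read_affinity_table",
]

MAX_AGENTS = 4


@dataclass(frozen=True)
class Ligand:
    """One competing agent: free concentration (nM), Ki (nM) and intrinsic
    activity in [0, 1] (1 = full agonist, 0 = neutral antagonist)."""

    concentration: float
    ki: float
    intrinsic_activity: float = 0.0

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not self.ki > 0:
            raise ValueError("ki must be positive")
        if not 0.0 <= self.intrinsic_activity <= 1.0:
            raise ValueError("intrinsic_activity must lie in [0, 1]")


@dataclass(frozen=True)
class SynapseContext:
    """Endogenous neurotransmitter context at one receptor.

    ``nt_concentration`` is the free transmitter level (nM), ``nt_ki`` its
    affinity at the receptor, and ``autoreceptor_gain`` the fractional
    release change per unit change of autoreceptor activation (0 disables
    feedback; positive gain means autoreceptor inhibition of release).
    """

    nt_concentration: float
    nt_ki: float
    autoreceptor_gain: float = 0.0

    def __post_init__(self) -> None:
        if not (self.nt_concentration > 0 and self.nt_ki > 0):
            raise ValueError("nt concentration and ki must be positive")


def _occ_fractions(nt_c: float, nt_ki: float, drugs: Sequence[Ligand]) -> np.ndarray:
    """Occupancy of NT followed by each drug; free fraction is 1 - sum."""
    ratios = np.array([nt_c / nt_ki] + [d.concentration / d.ki for d in drugs])
    return ratios / (1.0 + ratios.sum())


def _release_scale(ctx: SynapseContext, drugs: Sequence[Ligand], tol: float = 1e-8,
                   max_iter: int = 500) -> float:
    """Fixed point of the autoreceptor feedback loop on release."""
    if ctx.autoreceptor_gain == 0.0:
        return 1.0
    baseline = _occ_fractions(ctx.nt_concentration, ctx.nt_ki, [])[0]
    r = 1.0
    for _ in range(max_iter):
        occ = _occ_fractions(r * ctx.nt_concentration, ctx.nt_ki, drugs)
        act = occ[0] + sum(o * d.intrinsic_activity for o, d in zip(occ[1:], drugs))
        r_new = max(0.0, 1.0 + ctx.autoreceptor_gain * (baseline - act))
        if abs(r_new - r) < tol:
            return r_new
        r = 0.5 * (r + r_new)  # damped to guarantee contraction
    raise RuntimeError("autoreceptor feedback iteration did not converge")


def occupancies(ctx: SynapseContext, drugs: Sequence[Ligand] = ()) -> np.ndarray:
    """Fractional receptor occupancy of [NT, drug_1, ..., drug_k] after
    autoreceptor feedback settles; the free fraction is 1 minus the sum."""
    if len(drugs) > MAX_AGENTS:
        raise ValueError(f"at most {MAX_AGENTS} competing agents supported")
    r = _release_scale(ctx, drugs)
    return _occ_fractions(r * ctx.nt_concentration, ctx.nt_ki, drugs)


def steady_state_activation(ctx: SynapseContext, drugs: Sequence[Ligand] = ()) -> float:
    """Receptor activation under competition: occupancy-weighted intrinsic
    activity, neurotransmitter counted as a full agonist."""
    occ = occupancies(ctx, drugs)
    return float(occ[0] + sum(o * d.intrinsic_activity for o, d in zip(occ[1:], drugs)))


def relative_effect(activated: float, control: float) -> float:
    """Relative activation change (activated - control)/control — the linear
    normalized statistic coupling receptor pharmacology to circuit
    parameters."""
    if control <= 0:
        raise ValueError("control activation must be positive")
    return (activated - control) / control


def occupancy_to_concentration(
    target_occupancy: float,
    ki: float,
    ctx: SynapseContext,
    intrinsic_activity: float = 0.0,
) -> float:
    """Free drug concentration (nM) producing a target receptor occupancy.

    Inverts the competitive-binding relation under NT competition (e.g., to
    turn a PET tracer displacement measurement into a functional intrasynaptic
    concentration).  With autoreceptor feedback active the inversion is
    numerical; otherwise closed-form.
    """
    if not 0.0 < target_occupancy < 1.0:
        raise ValueError("target occupancy must lie strictly in (0, 1)")
    if not ki > 0:
        raise ValueError("ki must be positive")
    n = ctx.nt_concentration / ctx.nt_ki

    def drug_occ(conc: float) -> float:
        return float(occupancies(ctx, [Ligand(conc, ki, intrinsic_activity)])[1])

    # closed form ignoring feedback: occ*(1 + N + x) = x  ->  x = occ*(1+N)/(1-occ)
    x0 = target_occupancy * (1.0 + n) / (1.0 - target_occupancy)
    c0 = x0 * ki
    if ctx.autoreceptor_gain == 0.0:
        return c0
    lo, hi = c0 * 1e-6, c0
    while drug_occ(hi) < target_occupancy:
        hi *= 10.0
        if hi > 1e18:
            raise RuntimeError("occupancy inversion failed to bracket")
    return float(brentq(lambda c: drug_occ(c) - target_occupancy, lo, hi, xtol=1e-12, rtol=1e-12))


def read_affinity_table(path) -> "pd.DataFrame":
    """Read a drug-receptor affinity table (columns: drug, receptor, ki_nM,
    intrinsic_activity) from delimited text."""
    import pandas as pd

    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"drug", "receptor", "ki_nM"}
    if required - set(df.columns):
        raise ValueError(f"affinity table must have columns {sorted(required)}")
    if "intrinsic_activity" not in df.columns:
        df["intrinsic_activity"] = 0.0
    return df
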