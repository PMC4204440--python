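"""Synthetic clinical-trial fixture generator.

The original calibration used a literature database of 34 antipsychotic
drug-dose combinations (D2 occupancy from PET displacement, multi-receptor
affinities, observed change on the PANSS negative subscale, patient counts)
that is not publicly deposited.  This module generates synthetic databases
with the same schema and a known ground truth so that the calibration
machinery can be exercised and its recovery properties tested:

* drug receptor affinities are drawn log-uniformly per receptor;
* the functional synaptic concentration at each dose is computed and the
  D2 occupancy derived through the competitive-binding layer;
* a deterministic surrogate proxy (a fixed linear read of the per-receptor
  relative activations, standing in for a full circuit evaluation) is
  computed per trial;
* observed PANSS-negative changes are the ground-truth linear map of the
  proxy plus Gaussian noise, with the noise amplitude calibrated so the
  realized proxy-outcome correlation matches a target (default 0.65).

Everything is deterministic given the master seed, and the ground truth is
returned separately so recovery tests can compare against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from glyqsp.calibration import TrialRecord
from glyqsp.receptors import Ligand, SynapseContext, steady_state_activation, occupancies, relative_effect

__all__ = ["SyntheticTrialSpec", "SyntheticTrials", "generate_synthetic_trials"]

#: receptors sampled for each synthetic drug, with baseline neurotransmitter
#: context (free NT concentration as a multiple of its Ki at the receptor)
RECEPTORS = ("D1", "D2", "5HT2A", "5HT2C", "5HT3", "M1", "alpha1A")
NT_LEVEL = {  # NT concentration / NT Ki at each receptor (baseline tone)
    "D1": 1.0, "D2": 1.0, "5HT2A": 0.5, "5HT2C": 0.5,
    "5HT3": 0.5, "M1": 1.0, "alpha1A": 1.0,
}

#: fixed surrogate weights mapping per-receptor relative activations to the
#: negative-symptom proxy (a cheap deterministic stand-in for the circuit)
PROXY_WEIGHTS = {
    "D2": 1.0, "D1": -0.4, "5HT2A": -0.5, "5HT2C": 0.4,
    "5HT3": 0.2, "M1": -0.3, "alpha1A": -0.2,
}


@dataclass(frozen=True)
class SyntheticTrialSpec:
    """Generator settings for one synthetic trial database."""

    n_drugs: int = 12
    n_doses: int = 3  # dose levels per drug; trials are truncated to n_trials
    n_trials: int = 34
    ki_range_nM: tuple = (1.0, 3000.0)  # log-uniform per receptor
    dose_range: tuple = (1.0, 20.0)  # arbitrary mg units
    truth_slope: float = 3.0
    truth_intercept: float = -2.0
    target_r: float = 0.65
    noise_sd: float | None = None  # explicit sd overrides target_r calibration
    n_patients_range: tuple = (30, 300)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 1 or self.n_doses < 1 or self.n_trials < 3:
            raise ValueError("need >= 1 drug/dose and >= 3 trials")
        if self.n_drugs * self.n_doses < self.n_trials:
            raise ValueError("n_drugs * n_doses must cover n_trials")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0 < self.target_r <= 1:
            raise ValueError("target_r must lie in (0, 1]")


@dataclass
class SyntheticTrials:
    """Generated database plus the ground truth used to build it."""

    records: list = field(default_factory=list)
    affinities: pd.DataFrame = field(default_factory=pd.DataFrame)
    proxies: np.ndarray = field(default_factory=lambda: np.array([]))
    truth: dict = field(default_factory=dict)


def _drug_proxy(kis: dict, conc: float) -> tuple[float, float]:
    """Surrogate proxy and D2 occupancy for one drug at one concentration.

    The drug is treated as a neutral antagonist at every receptor; the
    proxy is the weighted sum of the relative activation changes it causes.
    """
    proxy = 0.0
    d2_occ = np.nan
    for rec in RECEPTORS:
        ctx = SynapseContext(nt_concentration=NT_LEVEL[rec], nt_ki=1.0)
        control = steady_state_activation(ctx, [])
        drug = Ligand(concentration=conc, ki=kis[rec], intrinsic_activity=0.0)
        treated = steady_state_activation(ctx, [drug])
        proxy += PROXY_WEIGHTS[rec] * relative_effect(treated, control)
        if rec == "D2":
            d2_occ = float(occupancies(ctx, [drug])[1])
    return proxy, d2_occ


def generate_synthetic_trials(spec: SyntheticTrialSpec = SyntheticTrialSpec()) -> SyntheticTrials:
    """Generate a deterministic synthetic trial database.

    Returns trial records (drug, dose, D2 occupancy, observed
    PANSS-negative change, patient count), the affinity table, the
    noise-free proxies, and the ground-truth map.  With ``noise_sd = 0``
    outcomes lie exactly on the truth line; otherwise the noise amplitude
    is rescaled so the realized sample correlation equals ``target_r``.
    """
    rng = np.random.default_rng(spec.master_seed)
    lo, hi = np.log(spec.ki_range_nM[0]), np.log(spec.ki_range_nM[1])

    aff_rows = []
    drug_kis = {}
    for d in range(spec.n_drugs):
        name = f"drug{d:02d}"
        kis = {rec: float(np.exp(rng.uniform(lo, hi))) for rec in RECEPTORS}
        drug_kis[name] = kis
        for rec in RECEPTORS:
            aff_rows.append(
                {"drug": name, "receptor": rec, "ki_nM": kis[rec], "intrinsic_activity": 0.0}
            )
    affinities = pd.DataFrame(aff_rows)

    combos = [
        (name, float(dose))
        for name in drug_kis
        for dose in np.sort(rng.uniform(*spec.dose_range, size=spec.n_doses))
    ]
    combos = combos[: spec.n_trials]

    proxies = np.empty(len(combos))
    d2_occs = np.empty(len(combos))
    for i, (name, dose) in enumerate(combos):
        # dose (mg) to synaptic concentration (nM): fixed unit conversion
        conc = 50.0 * dose
        proxies[i], d2_occs[i] = _drug_proxy(drug_kis[name], conc)

    signal = spec.truth_slope * proxies + spec.truth_intercept
    raw_noise = rng.standard_normal(len(combos))
    if spec.noise_sd is not None:
        noise = spec.noise_sd * raw_noise
    else:
        # orthogonalize the noise against the proxy, then scale it so the
        # sample correlation equals target_r exactly
        p_c = proxies - proxies.mean()
        e_c = raw_noise - raw_noise.mean()
        e_perp = e_c - (e_c @ p_c / (p_c @ p_c)) * p_c
        sp = float(np.std(p_c))
        se = float(np.std(e_perp))
        if se == 0 or sp == 0:
            noise = np.zeros(len(combos))
        else:
            lam = abs(spec.truth_slope) * sp * np.sqrt(1.0 / spec.target_r**2 - 1.0) / se
            noise = lam * e_perp
    outcomes = signal + noise

    records = [
        TrialRecord(
            drug=name,
            dose=dose,
            dpanss_neg=float(outcomes[i]),
            n=int(rng.integers(*spec.n_patients_range)),
            d2_occupancy=float(d2_occs[i]),
        )
        for i, (name, dose) in enumerate(combos)
    ]
    truth = {
        "slope": spec.truth_slope,
        "intercept": spec.truth_intercept,
        "target_r": spec.target_r,
        "noise_sd": spec.noise_sd,
        "master_seed": spec.master_seed,
    }
    return SyntheticTrials(records=records, affinities=affinities, proxies=proxies, truth=truth)
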