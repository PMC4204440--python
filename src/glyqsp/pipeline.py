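"""End-to-end pipeline: glycine level -> cortical network -> BOLD and
striatal readouts -> composite negative-symptom proxy.

For each glycine concentration the cortical circuit is simulated under the
configured schizophrenia pathology, its normalized population activities
drive the Balloon model (cortical readout = BOLD summary) and, through the
corticostriatal projection, a small mixed population of medium spiny
neurons (striatal readout = weighted population firing).  The weighted sum
of the two readouts (default 40% cortical / 60% striatal) is the proxy that
the calibration layer maps to PANSS-negative points.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Optional, Sequence

import numpy as np

from glyqsp import config as _config
from glyqsp.bold import BalloonParams, bold_summary, simulate_bold
from glyqsp.calibration import ReadoutWeights, composite_readout
from glyqsp.cortical import NetworkConfig, PathologyConfig, simulate_network
from glyqsp.pharmacology import DoseResponseCurve, HillParams, SynapseClassPD
from glyqsp.striatum import (
    MSNParams,
    ModulationState,
    simulate_msn,
    square_pulse_gate,
    striatal_population_readout,
)

__all__ = [
    "PipelinePoint",
    "pd_from_config",
    "network_config_from_config",
    "pathology_from_config",
    "run_single_point",
    "run_dose_response",
    "dose_response_outcome",
]


def _hill_or_none(section) -> Optional[HillParams]:
    if section is None:
        return None
    return HillParams(ec50=section["ec50_uM"], slope=section["slope"])


def pd_from_config(cfg: dict) -> SynapseClassPD:
    p = cfg["pharmacodynamics"]
    return SynapseClassPD(
        ee=HillParams(p["ee"]["ec50_uM"], p["ee"]["slope"]),
        ei=HillParams(p["ei"]["ec50_uM"], p["ei"]["slope"]),
        gmax_ee=p["gmax_ee"],
        gmax_ei=p["gmax_ei"],
        internalization_ee=_hill_or_none(p["internalization_ee"]),
        internalization_ei=_hill_or_none(p["internalization_ei"]),
    )


def network_config_from_config(cfg: dict, seed: int) -> NetworkConfig:
    known = {f.name for f in fields(NetworkConfig)}
    overrides = cfg.get("network", {})
    unknown = set(overrides) - known
    if unknown:
        raise KeyError(f"unknown network config key(s): {sorted(unknown)}")
    return replace(NetworkConfig(**overrides), seed=seed)


def pathology_from_config(cfg: dict) -> PathologyConfig:
    return PathologyConfig(**cfg["pathology"])


@dataclass
class PipelinePoint:
    """Readouts of one (glycine, seed) pipeline evaluation."""

    glycine_uM: float
    seed: int
    mean_exc_rate: float
    bold: float
    striatal: float
    composite: float


def _striatal_readout(cfg: dict, rate_e: np.ndarray, u_dt: float, seed: int) -> float:
    """Drive a mixed MSN population with the absolute cortical rate trace
    (normalized by a nominal reference rate) and return the population
    readout."""
    sc = cfg["striatum"]
    dt = 0.05  # ms
    duration = sc["duration_ms"]
    n_steps = int(round(duration / dt))
    drive_series = rate_e / sc["reference_rate_hz"]
    # resample the 10-ms-binned cortical drive onto the MSN time step,
    # tiling if the cortical trace is shorter than the MSN run
    u_src = np.tile(
        drive_series, int(np.ceil(n_steps * dt / (len(drive_series) * u_dt * 1e3))) + 1
    )
    idx = np.minimum((np.arange(n_steps) * dt / (u_dt * 1e3)).astype(int), len(u_src) - 1)
    drive = sc["drive_gain"] * u_src[idx]
    gate = square_pulse_gate(n_steps, dt, onset_ms=sc["gate_onset_ms"])
    mod = ModulationState(**sc["modulation"])
    cells = []
    mix = [("SP_D1", sc["n_sp_d1"]), ("Enk_D2", sc["n_enk_d2"]), ("dual", sc["n_dual"])]
    k = 0
    for cls, count in mix:
        params = MSNParams(cell_class=cls, **sc["params"])
        for _ in range(count):
            cells.append(simulate_msn(params, drive, gate, mod, dt=dt, seed=seed + k))
            k += 1
    return striatal_population_readout(cells)


def run_single_point(cfg: dict, gly: float, seed: int) -> PipelinePoint:
    """Evaluate the full cascade at one glycine level with one seed."""
    pd_ = pd_from_config(cfg)
    path = pathology_from_config(cfg)
    net_cfg = network_config_from_config(
        cfg, _config.stage_seed(cfg["seed"], "network", seed)
    )
    out = simulate_network(net_cfg, path, gly, pd_)

    bp = BalloonParams(**cfg["bold"]["params"])
    bold_res = simulate_bold(out.u_e, out.u_i, bp, dt=out.u_dt)
    # summarize from stimulus onset onward, where the evoked transient lives
    t_on = net_cfg.stimulus_onset * 1e-3
    bold = bold_summary(
        bold_res.y, (t_on, bold_res.t[-1]), out.u_dt, method=cfg["bold"]["summary"]
    )

    striatal = _striatal_readout(
        cfg, out.rate_e, out.u_dt, _config.stage_seed(cfg["seed"], "striatum", seed)
    )
    w = ReadoutWeights(
        w_cortical=cfg["calibration"]["w_cortical"],
        w_striatal=cfg["calibration"]["w_striatal"],
    )
    # scale BOLD (fractional signal ~1e-3) into the same numeric range as
    # the striatal rate before weighting
    composite = composite_readout(1e3 * bold, striatal, w)
    return PipelinePoint(
        glycine_uM=gly,
        seed=seed,
        mean_exc_rate=out.mean_exc_rate,
        bold=bold,
        striatal=striatal,
        composite=composite,
    )


def run_dose_response(
    cfg: dict,
    glycine_grid: Optional[Sequence[float]] = None,
    n_seeds: Optional[int] = None,
) -> DoseResponseCurve:
    """Seed-averaged composite outcome over a glycine grid (uM)."""
    _config.validate_config(cfg)
    grid = np.asarray(
        glycine_grid
        if glycine_grid is not None
        else cfg["dose_response"]["glycine_grid_uM"],
        dtype=float,
    )
    n_seeds = n_seeds if n_seeds is not None else cfg["dose_response"]["n_seeds"]
    values = np.empty(len(grid))
    for i, g in enumerate(grid):
        values[i] = float(
            np.mean([run_single_point(cfg, g, s).composite for s in range(n_seeds)])
        )
    return DoseResponseCurve(
        glycine_uM=grid,
        response=values,
        metadata={
            "response": "network outcome",
            "n_seeds": n_seeds,
            "seed": cfg["seed"],
            "config_hash": _config.config_hash(cfg),
        },
    )


def dose_response_outcome(cfg: dict, seed: int) -> float:
    """Scalar model outcome for sensitivity sweeps: the dose-response
    optimum (maximum composite readout over the configured glycine grid)."""
    cfg = dict(cfg, seed=seed)
    curve = run_dose_response(cfg)
    return float(np.max(curve.response))
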