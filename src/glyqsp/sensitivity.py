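"""Range-based sensitivity analysis of the model outcome.

Each parameter is excursed by fractional amounts around its calibrated
value, the model outcome (by default the dose-response optimum of the
calibrated PANSS proxy) is re-evaluated on a grid, and each evaluation is
expressed as a percent change versus the calibrated setting.  The summary
statistic is the range-based effect size:

    effect_size = ((max_pct - min_pct) / 100) / (hi_frac - lo_frac)

i.e., the spread of relative outcome changes divided by the fractional
parameter range swept.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import numpy as np

__all__ = ["SweepSpec", "SensitivityRow", "effect_size", "run_sweep", "get_path", "set_path"]


@dataclass(frozen=True)
class SweepSpec:
    """One parameter sweep: a dot-addressed config key, fractional excursion
    bounds (e.g., -0.2 to +0.2), grid resolution and evaluation seeds."""

    parameter: str
    lo_frac: float = -0.2
    hi_frac: float = 0.2
    n: int = 5
    seeds: Sequence[int] = (0,)

    def __post_init__(self) -> None:
        if not self.lo_frac < self.hi_frac:
            raise ValueError("lo_frac must be < hi_frac")
        if self.n < 2:
            raise ValueError("need at least 2 grid points")


@dataclass
class SensitivityRow:
    """Sweep result: extreme percent outcome changes and the effect size."""

    parameter: str
    min_effect_pct: float
    max_effect_pct: float
    effect_size: float
    grid_fracs: np.ndarray = field(default_factory=lambda: np.array([]))
    grid_effects_pct: np.ndarray = field(default_factory=lambda: np.array([]))


def effect_size(min_pct: float, max_pct: float, lo_frac: float, hi_frac: float) -> float:
    """Range-based effect size from extreme percent changes and the swept
    fractional range: ((max_pct - min_pct)/100) / (hi_frac - lo_frac)."""
    if not hi_frac > lo_frac:
        raise ValueError("hi_frac must exceed lo_frac")
    if max_pct < min_pct:
        raise ValueError("max_pct must be >= min_pct")
    return ((max_pct - min_pct) / 100.0) / (hi_frac - lo_frac)


def get_path(config: Mapping[str, Any], path: str) -> Any:
    """Resolve a dot-addressed key in a nested mapping."""
    node: Any = config
    for part in path.split("."):
        try:
            node = node[part]
        except (KeyError, TypeError):
            raise KeyError(f"config path {path!r} does not resolve (failed at {part!r})")
    return node


def set_path(config: dict, path: str, value: Any) -> None:
    parts = path.split(".")
    node: Any = config
    for part in parts[:-1]:
        try:
            node = node[part]
        except (KeyError, TypeError):
            raise KeyError(f"config path {path!r} does not resolve (failed at {part!r})")
    if parts[-1] not in node:
        raise KeyError(f"config path {path!r} does not resolve (failed at {parts[-1]!r})")
    node[parts[-1]] = value


def run_sweep(
    outcome_fn: Callable[[dict, int], float],
    config: dict,
    spec: SweepSpec,
) -> SensitivityRow:
    """Sweep one parameter and summarize the outcome sensitivity.

    ``outcome_fn(config, seed)`` evaluates the model outcome for a config;
    it is seed-averaged over ``spec.seeds`` at each of ``spec.n`` evenly
    spaced fractional excursions (the calibrated value scaled by
    ``1 + frac``).  Effects are percent changes versus the calibrated
    (frac = 0) outcome, which is evaluated with the same seeds.
    """
    base_value = get_path(config, spec.parameter)
    if not isinstance(base_value, (int, float)) or isinstance(base_value, bool):
        raise TypeError(f"swept parameter {spec.parameter!r} must be numeric")

    def averaged(cfg: dict) -> float:
        return float(np.mean([outcome_fn(cfg, s) for s in spec.seeds]))

    baseline = averaged(config)
    if baseline == 0:
        raise ZeroDivisionError(
            f"baseline outcome is zero; percent changes for {spec.parameter!r} undefined"
        )
    fracs = np.linspace(spec.lo_frac, spec.hi_frac, spec.n)
    effects = np.empty_like(fracs)
    for i, frac in enumerate(fracs):
        cfg = copy.deepcopy(config)
        set_path(cfg, spec.parameter, base_value * (1.0 + frac))
        effects[i] = 100.0 * (averaged(cfg) - baseline) / abs(baseline)
    return SensitivityRow(
        parameter=spec.parameter,
        min_effect_pct=float(np.min(effects)),
        max_effect_pct=float(np.max(effects)),
        effect_size=effect_size(float(np.min(effects)), float(np.max(effects)),
                               spec.lo_frac, spec.hi_frac),
        grid_fracs=fracs,
        grid_effects_pct=effects,
    )
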