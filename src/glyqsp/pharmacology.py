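"""Glycine-site pharmacodynamics at NMDA receptors.

Glycine is an obligatory co-agonist at the NMDA receptor's NR1 glycine-B
site, but the potency of potentiation differs across NR2 subunits: NR2A/NR2B
(enriched on pyramidal-pyramidal, "e-e", synapses) versus NR2C/NR2D (enriched
on pyramidal-to-interneuron, "e-i", synapses).  Each synapse class is
described by a Hill relation

    g(Gly) = gmax * Gly^n / (Gly^n + EC50^n)

and the ratio of e-i over e-e potentiation — the quantity that shifts
cortical excitation/inhibition balance — can pass through a minimum at low
micromolar glycine, producing an inverse U-shaped network dose-response.
This module provides the Hill machinery, the e-i/e-e ratio, extremum finding
and classification of the dose-response shape, surface-expression loss
(receptor internalization) at high glycine, and per-subunit summary
statistics over published experimental estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "HillParams",
    "SynapseClassPD",
    "DoseResponseCurve",
    "DoseResponseClass",
    "GLYCINE_SUBUNIT_STUDIES",
    "hill_activation",
    "effective_conductance",
    "subunit_averages",
    "ei_over_ee_ratio",
    "find_ratio_extremum",
    "RatioExtremum",
    "classify_dose_response",
    "read_subunit_table",
    "write_subunit_table",
]

SUBUNITS = ("NR2A", "NR2B", "NR2C", "NR2D")

#: Published whole-cell estimates of glycine EC50 (uM) and Hill slope for
#: recombinant NMDA receptors by NR2 subunit.  Sources: Matsui et al. 1995;
#: Kutsuwada et al. 1992; Woodward et al. 1995; Laurie & Seeburg 1994;
#: Chen et al. 2008.  Blanks (None) are conditions the study did not report.
GLYCINE_SUBUNIT_STUDIES = pd.DataFrame(
    [
        ("Matsui1995", "NR2A", 0.97, 1.5),
        ("Matsui1995", "NR2B", 0.84, 2.0),
        ("Matsui1995", "NR2C", 0.75, 2.0),
        ("Matsui1995", "NR2D", 0.56, 1.0),
        ("Kutsuwada1992", "NR2A", 2.1, 1.5),
        ("Kutsuwada1992", "NR2B", 0.3, 1.5),
        ("Kutsuwada1992", "NR2C", 0.2, 1.5),
        ("Kutsuwada1992", "NR2D", None, None),
        ("Woodward1995", "NR2A", 0.84, 1.5),
        ("Woodward1995", "NR2B", 0.19, 2.0),
        ("Woodward1995", "NR2C", 0.15, 1.5),
        ("Woodward1995", "NR2D", 0.096, 1.0),
        ("Laurie1994", "NR2A", 3.7, 1.0),
        ("Laurie1994", "NR2B", 2.1, 1.5),
        ("Laurie1994", "NR2C", 0.36, 1.5),
        ("Laurie1994", "NR2D", 2.3, 1.5),
        ("Chen2008", "NR2A", 1.31, 1.66),
        ("Chen2008", "NR2B", 0.72, 1.84),
        ("Chen2008", "NR2C", 0.34, 1.81),
        ("Chen2008", "NR2D", 0.13, 1.32),
    ],
    columns=["study", "subunit", "ec50_uM", "hill_slope"],
)


@dataclass(frozen=True)
class HillParams:
    """EC50 (uM) and Hill coefficient for glycine potentiation of one
    NMDA synapse class."""

    ec50: float
    slope: float

    def __post_init__(self) -> None:
        if not (self.ec50 > 0 and np.isfinite(self.ec50)):
            raise ValueError(f"ec50 must be positive and finite, got {self.ec50}")
        if not (self.slope > 0 and np.isfinite(self.slope)):
            raise ValueError(f"slope must be positive and finite, got {self.slope}")


@dataclass(frozen=True)
class SynapseClassPD:
    """Pharmacodynamic parameters for the two cortical NMDA synapse classes.

    ``ee`` describes the lumped NR2A/B (pyramidal-pyramidal) class and ``ei``
    the lumped NR2C/D (pyramidal-interneuron) class.  ``gmax_*`` are relative
    maximal-conductance scales.  When ``internalization_*`` is set, the
    corresponding class loses surface receptors with its own Hill dependence
    on glycine (half-loss around 40 uM in slice work), multiplying the
    potentiation by ``1 - hill(gly, internalization)``.
    """

    ee: HillParams
    ei: HillParams
    gmax_ee: float = 1.0
    gmax_ei: float = 1.0
    internalization_ee: Optional[HillParams] = None
    internalization_ei: Optional[HillParams] = None

    def __post_init__(self) -> None:
        if not (self.gmax_ee > 0 and self.gmax_ei > 0):
            raise ValueError("gmax values must be positive")

    def params(self, synapse_class: str) -> tuple[HillParams, float, Optional[HillParams]]:
        if synapse_class == "ee":
            return self.ee, self.gmax_ee, self.internalization_ee
        if synapse_class == "ei":
            return self.ei, self.gmax_ei, self.internalization_ei
        raise ValueError(f"synapse class must be 'ee' or 'ei', got {synapse_class!r}")


class DoseResponseClass(str, Enum):
    """Shape classes of the e-i/e-e ratio dose-response.

    ``beneficial_U``: interior ratio minimum in the physiological
    0.5-10 uM window with ratio < 1 — excitation transiently dominates,
    predicting clinical benefit with an inverse U-shaped dose-response.
    ``subphysiological_minimum``: minimum below 0.5 uM, unreachable given
    transporter-constrained glycine. ``monotonic``: no usable minimum.
    """

    beneficial_U = "beneficial_U"
    monotonic = "monotonic"
    subphysiological_minimum = "subphysiological_minimum"


@dataclass
class DoseResponseCurve:
    """A response sampled on a strictly increasing glycine grid (uM)."""

    glycine_uM: np.ndarray
    response: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.glycine_uM = np.asarray(self.glycine_uM, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.glycine_uM.shape != self.response.shape:
            raise ValueError("glycine grid and response must have equal length")
        if np.any(np.diff(self.glycine_uM) <= 0):
            raise ValueError("glycine grid must be strictly increasing")

    def write(self, path: str | Path) -> None:
        """Write curve as TSV with a JSON metadata sidecar (<path>.meta.json)."""
        path = Path(path)
        pd.DataFrame(
            {"glycine_uM": self.glycine_uM, "response": self.response}
        ).to_csv(path, sep="\t", index=False)
        with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)


def _check_gly(gly) -> np.ndarray:
    arr = np.asarray(gly, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("glycine concentration must be finite and >= 0")
    return arr


def hill_activation(gly, p: HillParams):
    """Fractional glycine-site activation, ``gly^n / (gly^n + ec50^n)``.

    Returns 0 at gly = 0, exactly 0.5 at gly = ec50, and approaches (never
    reaches) 1 at saturating glycine.  Accepts scalars or arrays (uM).
    """
    arr = _check_gly(gly)
    with np.errstate(over="ignore"):
        x = (arr / p.ec50) ** p.slope
    out = np.where(np.isinf(x), 1.0, x / (1.0 + x))
    return float(out) if np.isscalar(gly) else out


def effective_conductance(gly, synapse_class: str, pd_: SynapseClassPD):
    """Relative NMDA conductance of one synapse class at a glycine level.

    ``gmax * hill(gly)`` with an additional ``1 - hill(gly, internalization)``
    surface-expression factor when internalization is configured.
    """
    p, gmax, internalization = pd_.params(synapse_class)
    g = gmax * hill_activation(gly, p)
    if internalization is not None:
        g = g * (1.0 - hill_activation(gly, internalization))
    return g


def subunit_averages(table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic per-subunit means of EC50 and Hill slope over studies.

    Missing cells are excluded from the corresponding mean (not treated as
    zero).  A subunit with no data at all in a requested column raises.

    Parameters
    ----------
    table
        DataFrame with columns ``study, subunit, ec50_uM, hill_slope``;
        blanks encoded as NaN/None.

    Returns
    -------
    DataFrame indexed by subunit with columns ``ec50_uM`` and ``hill_slope``.
    """
    required = {"study", "subunit", "ec50_uM", "hill_slope"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    out = table.groupby("subunit")[["ec50_uM", "hill_slope"]].mean()
    counts = table.groupby("subunit")[["ec50_uM", "hill_slope"]].count()
    empty = counts[(counts == 0).any(axis=1)]
    if len(empty):
        raise ValueError(
            f"no data for subunit(s) {list(empty.index)} in at least one column"
        )
    return out


def read_subunit_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited subunit study table (TSV/CSV; blank cells = missing)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def write_subunit_table(table: pd.DataFrame, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table.to_csv(path, sep=sep, index=False)


def ei_over_ee_ratio(gly, pd_: SynapseClassPD):
    """Ratio of e-i over e-e relative NMDA potentiation at a glycine level.

    Internalization factors are applied when configured.  The ratio tends to
    gmax_ei/gmax_ee as glycine saturates both classes; gly = 0 is rejected
    because both activations vanish there (0/0).
    """
    arr = _check_gly(gly)
    if np.any(arr == 0):
        raise ValueError("e-i/e-e ratio is undefined at glycine = 0 (0/0)")
    num = effective_conductance(gly, "ei", pd_)
    den = effective_conductance(gly, "ee", pd_)
    return num / den


@dataclass(frozen=True)
class RatioExtremum:
    """Location and value of the e-i/e-e ratio minimum on a window."""

    gly_star: float
    ratio_star: float
    is_interior_minimum: bool


def find_ratio_extremum(
    pd_: SynapseClassPD,
    window: tuple[float, float] = (1e-4, 1e4),
    n_grid: int = 1000,
) -> RatioExtremum:
    """Locate the minimum of the e-i/e-e ratio on a glycine window (uM).

    A log-spaced grid scan (``n_grid`` points) brackets the minimum, then a
    bounded scalar minimization in log-glycine refines it.  The minimum is
    flagged interior only when it falls strictly inside the window and the
    curve is not flat; ties break toward the lowest glycine.
    """
    lo, hi = window
    if not (0 < lo < hi):
        raise ValueError(f"window must satisfy 0 < lo < hi, got {window}")
    grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    ratio = ei_over_ee_ratio(grid, pd_)
    if not np.all(np.isfinite(ratio)):
        raise FloatingPointError("non-finite e-i/e-e ratio on the search grid")
    i = int(np.argmin(ratio))  # argmin takes the first (lowest-glycine) tie
    flat = np.ptp(ratio) <= 1e-12 * max(1.0, float(np.max(np.abs(ratio))))
    if flat or i == 0 or i == n_grid - 1:
        return RatioExtremum(float(grid[i]), float(ratio[i]), False)
    res = minimize_scalar(
        lambda lg: float(ei_over_ee_ratio(10.0**lg, pd_)),
        bounds=(np.log10(grid[i - 1]), np.log10(grid[i + 1])),
        method="bounded",
        options={"xatol": 1e-10},
    )
    gly_star = float(10.0**res.x)
    ratio_star = float(res.fun)
    if ratio_star > ratio[i]:  # refinement may not improve on the grid point
        gly_star, ratio_star = float(grid[i]), float(ratio[i])
    return RatioExtremum(gly_star, ratio_star, True)


def classify_dose_response(
    pd_: SynapseClassPD,
    window: tuple[float, float] = (1e-4, 1e4),
    beneficial_band: tuple[float, float] = (0.5, 10.0),
) -> DoseResponseClass:
    """Classify the shape of the e-i/e-e ratio dose-response.

    ``beneficial_U`` requires an interior minimum with ratio < 1 located in
    the physiological glycine band (default 0.5-10 uM); an interior minimum
    below the band is ``subphysiological_minimum``; anything else (including
    a minimum above the band) is ``monotonic``.
    """
    ext = find_ratio_extremum(pd_, window=window)
    if not ext.is_interior_minimum:
        return DoseResponseClass.monotonic
    lo, hi = beneficial_band
    if lo <= ext.gly_star <= hi and ext.ratio_star < 1.0:
        return DoseResponseClass.beneficial_U
    if ext.gly_star < lo:
        return DoseResponseClass.subphysiological_minimum
    return DoseResponseClass.monotonic
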