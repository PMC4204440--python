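"""Clinical calibration of the circuit readout against PANSS-negative.

The negative-symptom proxy is a weighted sum of the cortical change (BOLD
summary) and ventral-striatal change (population activity), by default
40% cortical / 60% striatal.  A linear map fitted over a database of
drug-dose trial records (drug, dose, D2 occupancy, observed change on the
PANSS negative subscale, patient count) converts the proxy into predicted
PANSS-negative points; replicate trials of the same drug-dose are pooled by
patient-count-weighted averaging before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrialRecord",
    "ReadoutWeights",
    "CalibrationMap",
    "composite_readout",
    "pool_replicates",
    "calibrate",
    "predict_panss_change",
    "read_trial_table",
    "write_trial_table",
]

TRIAL_COLUMNS = ["drug", "dose", "d2_occupancy", "dpanss_neg", "n"]


@dataclass(frozen=True)
class TrialRecord:
    """One drug-dose clinical calibration point."""

    drug: str
    dose: float
    dpanss_neg: float
    n: int
    d2_occupancy: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("patient count n must be >= 1")
        if not self.dose > 0:
            raise ValueError("dose must be positive")


@dataclass(frozen=True)
class ReadoutWeights:
    """Cortical/striatal mixing weights for the negative-symptom proxy."""

    w_cortical: float = 0.4
    w_striatal: float = 0.6

    def __post_init__(self) -> None:
        if self.w_cortical < 0 or self.w_striatal < 0:
            raise ValueError("weights must be >= 0")
        if self.w_cortical + self.w_striatal <= 0:
            raise ValueError("weights must not both be zero")


@dataclass
class CalibrationMap:
    """Linear proxy -> PANSS-negative map with fit diagnostics."""

    slope: float = np.nan
    intercept: float = np.nan
    pearson_r: float = np.nan
    n_trials: int = 0
    slope_se: float = np.nan
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def is_calibrated(self) -> bool:
        return np.isfinite(self.slope) and np.isfinite(self.intercept)


def composite_readout(
    cortical_change: float, striatal_change: float, w: ReadoutWeights = ReadoutWeights()
) -> float:
    """Negative-symptom proxy: weighted sum of regional changes."""
    if not (np.isfinite(cortical_change) and np.isfinite(striatal_change)):
        raise ValueError("regional changes must be finite")
    return w.w_cortical * cortical_change + w.w_striatal * striatal_change


def pool_replicates(records: Sequence[TrialRecord]) -> TrialRecord:
    """Pool replicate trials of one drug-dose: patient-count-weighted mean
    outcome, patient counts summed."""
    if len(records) == 0:
        raise ValueError("cannot pool an empty set of trials")
    keys = {(r.drug, r.dose) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span multiple drug-dose combinations: {sorted(keys)}")
    ns = np.array([r.n for r in records], dtype=float)
    outcomes = np.array([r.dpanss_neg for r in records], dtype=float)
    occs = [r.d2_occupancy for r in records if r.d2_occupancy is not None]
    pooled_occ = float(np.mean(occs)) if occs else None
    return TrialRecord(
        drug=records[0].drug,
        dose=records[0].dose,
        dpanss_neg=float(np.sum(ns * outcomes) / np.sum(ns)),
        n=int(np.sum(ns)),
        d2_occupancy=pooled_occ,
    )


def calibrate(
    proxies: Sequence[float],
    outcomes: Sequence[float],
    n: Optional[Sequence[float]] = None,
    weighted: bool = False,
) -> CalibrationMap:
    """Least-squares linear fit of observed PANSS-negative change on the
    model proxy, optionally weighted by patient counts.

    Reports the (unweighted) Pearson correlation between proxy and outcome
    alongside slope, intercept, slope standard error and residuals.
    """
    x = np.asarray(proxies, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("proxies and outcomes must be equal-length 1-D")
    if len(x) < 3:
        raise ValueError("need at least 3 trials to calibrate")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in proxies; cannot fit a slope")
    if weighted:
        if n is None:
            raise ValueError("weighted fit requires patient counts n")
        w = np.asarray(n, dtype=float)
        wls = np.polyfit(x, y, 1, w=np.sqrt(w))
        slope, intercept = float(wls[0]), float(wls[1])
        resid = y - (slope * x + intercept)
        dof = len(x) - 2
        sxx = np.sum(w * (x - np.average(x, weights=w)) ** 2)
        slope_se = float(np.sqrt(np.sum(w * resid**2) / dof / sxx))
    else:
        fit = stats.linregress(x, y)
        slope, intercept, slope_se = float(fit.slope), float(fit.intercept), float(fit.stderr)
        resid = y - (slope * x + intercept)
    r = float(stats.pearsonr(x, y)[0])
    return CalibrationMap(
        slope=slope,
        intercept=intercept,
        pearson_r=r,
        n_trials=len(x),
        slope_se=slope_se,
        residuals=resid,
    )


def predict_panss_change(proxy, cal: CalibrationMap):
    """Predicted PANSS-negative change (points) for a proxy value."""
    if not cal.is_calibrated:
        raise RuntimeError("calibration map has not been fitted")
    out = cal.slope * np.asarray(proxy, dtype=float) + cal.intercept
    return float(out) if np.isscalar(proxy) else out


def read_trial_table(path: str | Path) -> list[TrialRecord]:
    """Read a trial database from delimited text (columns: drug, dose,
    d2_occupancy, dpanss_neg, n; blank occupancy allowed)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    records = []
    for row in df.itertuples(index=False):
        occ = getattr(row, "d2_occupancy", None)
        records.append(
            TrialRecord(
                drug=str(row.drug),
                dose=float(row.dose),
                dpanss_neg=float(row.dpanss_neg),
                n=int(row.n),
                d2_occupancy=None if occ is None or pd.isna(occ) else float(occ),
            )
        )
    return records


def write_trial_table(records: Sequence[TrialRecord], path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame(
        [
            {
                "drug": r.drug,
                "dose": r.dose,
                "d2_occupancy": r.d2_occupancy,
                "dpanss_neg": r.dpanss_neg,
                "n": r.n,
            }
            for r in records
        ]
    ).to_csv(path, sep=sep, index=False)
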