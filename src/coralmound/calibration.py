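"""Fit regional proxy calibrations from modern hydrography.

Two empirical relations underpin the reconstruction chain and are refit here
from hydrographic records (CTD + seawater d18O):

* the d18O_SW-salinity mixing line (OLS of d18O_SW on S), and
* the sigma_theta-d18O_C quadratic, where equilibrium calcite d18O is
  predicted from (T, d18O_SW) with the epibenthic paleotemperature equation
  and sigma_theta is computed from (S, T, p) by EOS-80 where not measured.

Fits are unweighted ordinary least squares; coefficient "2 SD" values are
twice the OLS standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from . import eos80
from .proxies import PaleotempEquation

__all__ = [
    "HydroRecord",
    "FitResult",
    "predicted_d18oc",
    "fit_d18osw_salinity",
    "fit_density_d18oc",
    "records_from_frame",
]


@dataclass(frozen=True)
class HydroRecord:
    """One hydrographic level; d18o_sw and sigma_theta may be missing (NaN)."""

    depth: float
    pressure: float
    temperature: float
    salinity: float
    d18o_sw: float = float("nan")
    sigma_theta: float = float("nan")


@dataclass
class FitResult:
    """Polynomial fit with 2 SD per coefficient (lowest order first)."""

    coefficients: List[float]
    sd2: List[float]
    r_squared: float
    n: int

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n < len(self.coefficients) + 1:
            raise ValueError("need more records than coefficients")


def predicted_d18oc(temperature, d18o_sw,
                    equation: PaleotempEquation = PaleotempEquation()):
    """Equilibrium calcite d18O (VPDB) predicted from (T, seawater d18O).

    Exact forward model of :func:`coralmound.proxies.d18osw_from_calcite`.
    """
    t = np.asarray(temperature, dtype=float)
    dsw = np.asarray(d18o_sw, dtype=float)
    out = (dsw - equation.scale_offset) + equation.k0 + equation.k1 * t + equation.k2 * t**2
    return float(out) if out.ndim == 0 else out


def _polyfit_with_errors(x: np.ndarray, y: np.ndarray, degree: int) -> FitResult:
    n = len(x)
    if n < degree + 2:
        raise ValueError(f"need >= {degree + 2} records for a degree-{degree} fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: predictor is constant")
    X = np.vander(x, degree + 1, increasing=True)
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < degree + 1:
        raise ValueError("degenerate design: collinear predictors")
    yhat = X @ beta
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    dof = n - (degree + 1)
    sigma2 = ss_res / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    sd2 = (2.0 * np.sqrt(np.diag(cov))).tolist()
    return FitResult(list(map(float, beta)), sd2, r2, n)


def fit_d18osw_salinity(records: Sequence[HydroRecord]) -> FitResult:
    """OLS line d18O_SW = slope*S + intercept; coefficients [intercept, slope]."""
    pts = [(r.salinity, r.d18o_sw) for r in records if np.isfinite(r.d18o_sw)]
    if len(pts) < 3:
        raise ValueError("need >= 3 records with d18o_sw")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    return _polyfit_with_errors(x, y, 1)


def fit_density_d18oc(records: Sequence[HydroRecord],
                      equation: PaleotempEquation = PaleotempEquation()) -> FitResult:
    """Quadratic sigma_theta = c0 + c1*d18O_C + c2*d18O_C^2 from hydrography.

    sigma_theta is computed by EOS-80 from (S, T, p) where not supplied;
    d18O_C is the predicted equilibrium calcite value. Coefficients are
    returned lowest order first.
    """
    usable = [r for r in records if np.isfinite(r.d18o_sw)]
    if len(usable) < 4:
        raise ValueError("need >= 4 records with (T, S or sigma_theta, d18o_sw)")
    sig = np.array([
        r.sigma_theta if np.isfinite(r.sigma_theta)
        else eos80.sigma_theta(r.salinity, r.temperature, r.pressure)
        for r in usable
    ])
    d18oc = predicted_d18oc(
        np.array([r.temperature for r in usable]),
        np.array([r.d18o_sw for r in usable]),
        equation,
    )
    return _polyfit_with_errors(np.asarray(d18oc), sig, 2)


def records_from_frame(df: pd.DataFrame) -> List[HydroRecord]:
    """Build HydroRecords from a table with (depth_m, temperature, salinity[, ...])."""
    recs = []
    for _, row in df.iterrows():
        depth = float(row["depth_m"])
        pressure = float(row["pressure_dbar"]) if "pressure_dbar" in row and np.isfinite(row.get("pressure_dbar", np.nan)) \
            else float(eos80.pressure_from_depth(depth))
        recs.append(HydroRecord(
            depth=depth,
            pressure=pressure,
            temperature=float(row["temperature"]),
            salinity=float(row["salinity"]),
            d18o_sw=float(row.get("d18o_sw", np.nan)),
            sigma_theta=float(row.get("sigma_theta", np.nan)),
        ))
    return recs
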