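"""Foraminiferal proxy chain: Mg/Ca -> BWT; d18O -> seawater d18O, density, salinity.

The chain inverts the species-specific exponential Mg/Ca-temperature
calibration for *Lobatula lobatula*,

    Mg/Ca (mmol/mol) = a * exp(b * T),   a = 1.24 +/- 0.04, b = 0.069 +/- 0.005,

removes the temperature effect from foraminiferal calcite d18O with the
epibenthic paleotemperature equation (Marchitto-type quadratic) to obtain
seawater d18O, and converts d18O_C to potential density via empirical
quadratics (a regional Skagerrak/Norwegian-margin calibration and the global
Lynch-Stieglitz relation). Salinity follows two routes:

    A. the regional d18O_SW-salinity mixing line, S = (d18O_SW - intercept)/slope;
    B. inversion of the EOS-80 equation of state from (BWT, sigma_theta, p).

All "+/-" uncertainties are treated as 2 SD and propagated either analytically
(delta method) or by seeded Monte Carlo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import eos80

__all__ = [
    "ForamSample",
    "MgCaCalibration",
    "PaleotempEquation",
    "DensityCalibration",
    "SalinityRegression",
    "ReconstructionRow",
    "REGIONAL_DENSITY",
    "GLOBAL_DENSITY",
    "DEFAULT_SALINITY_REGRESSION",
    "bwt_from_mgca",
    "d18osw_from_calcite",
    "salinity_from_d18osw",
    "density_from_d18oc",
    "salinity_route_eos",
    "screen_contamination",
    "propagate_uncertainty",
    "reconstruct_downcore",
]


@dataclass(frozen=True)
class ForamSample:
    """One downcore *L. lobatula* geochemistry row.

    2 SD defaults are the stated external reproducibilities:
    +/- 0.1 mmol/mol for Mg/Ca and +/- 0.06 permil for d18O.
    """

    depth: float
    mgca: float
    d18o_c: float
    alca: float = float("nan")
    feca: float = float("nan")
    sd2_mgca: float = 0.1
    sd2_d18o: float = 0.06

    def __post_init__(self):
        if self.mgca <= 0:
            raise ValueError("mgca must be > 0 mmol/mol")
        if self.sd2_mgca <= 0 or self.sd2_d18o <= 0:
            raise ValueError("2 SD uncertainties must be > 0")


@dataclass(frozen=True)
class MgCaCalibration:
    """Exponential Mg/Ca = a*exp(b*T); 2 SDs on both coefficients.

    ``t_range`` is the temperature interval the calibration was fit over
    (1.0-2.4 mmol/mol, i.e. about 0-10 degC); values outside are flagged,
    not rejected.
    """

    a: float = 1.24
    b: float = 0.069
    sd2_a: float = 0.04
    sd2_b: float = 0.005
    t_range: tuple = (0.0, 10.0)

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("calibration coefficients must be positive")


@dataclass(frozen=True)
class PaleotempEquation:
    """Quadratic paleotemperature equation for epibenthic foraminifera.

    d18O_C - (d18O_SW - scale_offset) = k0 + k1*T + k2*T^2, with the 0.27
    permil VSMOW->VPDB water adjustment. Coefficients are from the cited
    cosmopolitan epibenthic calibration, overridable.
    """

    k0: float = 3.58
    k1: float = -0.245
    k2: float = 0.0011
    scale_offset: float = 0.27
    t_validity: tuple = (0.0, 26.0)

    def __post_init__(self):
        if self.k1 >= 0:
            raise ValueError("k1 must be negative (calcite d18O decreases with T)")


@dataclass(frozen=True)
class DensityCalibration:
    """sigma_theta = c0 + c1*d18O_C + c2*d18O_C^2 with 2 SDs per coefficient."""

    c0: float
    c1: float
    c2: float
    sd2_c0: float = 0.0
    sd2_c1: float = 0.0
    sd2_c2: float = 0.0
    provenance: str = "regional"


#: Regional (Skagerrak / Norwegian margin) calibration with stated 2 SDs.
REGIONAL_DENSITY = DensityCalibration(25.64, 1.43, 0.21, 0.26, 0.03, 0.02, "regional")
#: Global open-ocean relation (4 permil fresher end member), no stated errors.
GLOBAL_DENSITY = DensityCalibration(25.7, 1.0, 0.12, provenance="global")


@dataclass(frozen=True)
class SalinityRegression:
    """Regional mixing line d18O_SW = slope*S + intercept (full precision)."""

    slope: float = 0.2547
    intercept: float = -8.6493

    def __post_init__(self):
        if self.slope == 0:
            raise ValueError("slope must be nonzero")


DEFAULT_SALINITY_REGRESSION = SalinityRegression()


@dataclass
class ReconstructionRow:
    depth: float
    bwt: float
    sd2_bwt: float
    d18o_sw: float
    sd2_d18o_sw: float
    sigma_theta_regional: float
    sd2_sigma_theta_regional: float
    sigma_theta_global: float
    sd2_sigma_theta_global: float
    sal_route_a: float
    sd2_sal_route_a: float
    sal_route_b: Optional[float]
    sd2_sal_route_b: Optional[float]
    qc_flags: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# Closed-form steps


def bwt_from_mgca(mgca, calibration: MgCaCalibration = MgCaCalibration()):
    """Invert the exponential calibration: T = ln(Mg/Ca / a) / b (degC)."""
    m = np.asarray(mgca, dtype=float)
    if np.any(m <= 0):
        raise ValueError("mgca must be > 0")
    t = np.log(m / calibration.a) / calibration.b
    return float(t) if t.ndim == 0 else t


def d18osw_from_calcite(d18o_c, bwt, equation: PaleotempEquation = PaleotempEquation()):
    """Remove the temperature effect from calcite d18O -> seawater d18O (VSMOW)."""
    d = np.asarray(d18o_c, dtype=float)
    t = np.asarray(bwt, dtype=float)
    out = d - (equation.k0 + equation.k1 * t + equation.k2 * t**2) + equation.scale_offset
    return float(out) if out.ndim == 0 else out


def salinity_from_d18osw(d18o_sw, regression: SalinityRegression = DEFAULT_SALINITY_REGRESSION):
    """Route A: salinity from seawater d18O via the regional mixing line."""
    d = np.asarray(d18o_sw, dtype=float)
    s = (d - regression.intercept) / regression.slope
    return float(s) if s.ndim == 0 else s


def density_from_d18oc(d18o_c, calibration: DensityCalibration = REGIONAL_DENSITY):
    """sigma_theta (kg/m3) from calcite d18O via the empirical quadratic."""
    d = np.asarray(d18o_c, dtype=float)
    out = calibration.c0 + calibration.c1 * d + calibration.c2 * d**2
    return float(out) if out.ndim == 0 else out


def salinity_route_eos(bwt: float, sigma_theta: float, pressure: float) -> float:
    """Route B: salinity by EOS-80 inversion from (BWT, sigma_theta, pressure)."""
    return eos80.salinity_from_sigma_theta(sigma_theta, bwt, pressure)


# ---------------------------------------------------------------------------
# QC


def screen_contamination(samples: Sequence[ForamSample], r2_limit: float = 0.4,
                         feca_limit: Optional[float] = None,
                         alca_limit: Optional[float] = None) -> Dict:
    """Contamination screen: Fe/Ca and Al/Ca must not covary with Mg/Ca.

    Computes OLS R^2 of Fe/Ca on Mg/Ca and Al/Ca on Mg/Ca; the dataset passes
    when both R^2 < ``r2_limit``. High absolute Fe/Ca alone is tolerated (it
    is commonly pyrite, which carries no Mg); optional absolute cutoffs can
    flag individual samples.
    """
    if len(samples) < 3:
        raise ValueError("need >= 3 samples for the contamination regression")
    mg = np.array([s.mgca for s in samples])
    report: Dict = {"n": len(samples), "r2": {}, "pass": True, "flagged_samples": []}
    for name, vals in (("feca", [s.feca for s in samples]),
                       ("alca", [s.alca for s in samples])):
        y = np.array(vals, dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 3:
            report["r2"][name] = None
            continue
        if np.ptp(y[ok]) == 0 or np.ptp(mg[ok]) == 0:
            r2 = 0.0
        else:
            r2 = float(stats.pearsonr(mg[ok], y[ok])[0] ** 2)
        report["r2"][name] = r2
        if r2 >= r2_limit:
            report["pass"] = False
    for i, s in enumerate(samples):
        if feca_limit is not None and s.feca > feca_limit:
            report["flagged_samples"].append((i, "high_feca"))
        if alca_limit is not None and s.alca > alca_limit:
            report["flagged_samples"].append((i, "high_alca"))
    return report


# ---------------------------------------------------------------------------
# Uncertainty propagation

_CHAIN_OUTPUTS = ("bwt", "d18o_sw", "sigma_theta_regional", "sigma_theta_global",
                  "sal_route_a", "sal_route_b")


def _chain(mgca, d18o_c, a, b, k0, k1, k2, off, reg: SalinityRegression,
           cal_r: Sequence[float], cal_g: Sequence[float], pressure):
    """Vectorised full proxy chain on raw inputs; route B left to the caller."""
    t = np.log(mgca / a) / b
    dsw = d18o_c - (k0 + k1 * t + k2 * t**2) + off
    sig_r = cal_r[0] + cal_r[1] * d18o_c + cal_r[2] * d18o_c**2
    sig_g = cal_g[0] + cal_g[1] * d18o_c + cal_g[2] * d18o_c**2
    sal_a = (dsw - reg.intercept) / reg.slope
    return t, dsw, sig_r, sig_g, sal_a


def propagate_uncertainty(sample: ForamSample,
                          calibration: MgCaCalibration = MgCaCalibration(),
                          equation: PaleotempEquation = PaleotempEquation(),
                          density_calibration: DensityCalibration = REGIONAL_DENSITY,
                          regression: SalinityRegression = DEFAULT_SALINITY_REGRESSION,
                          pressure: float = 101.0 * eos80.DBAR_PER_METER,
                          method: str = "delta",
                          n: int = 5000,
                          seed: int = 0) -> Dict[str, float]:
    """2 SD uncertainties of every chain output for one sample.

    ``method='delta'`` uses analytic partial derivatives of the closed forms
    (finite differences only through the EOS inversion of route B);
    ``method='mc'`` perturbs (Mg/Ca, d18O_C, a, b, c0, c1, c2) as independent
    Gaussians with the stated 2 SDs (halved to 1 SD internally) and reports
    2 x SD of each output over ``n`` seeded draws.
    """
    cal, eq, dc = calibration, equation, density_calibration
    m, d = sample.mgca, sample.d18o_c
    s_m, s_d = sample.sd2_mgca / 2.0, sample.sd2_d18o / 2.0
    s_a, s_b = cal.sd2_a / 2.0, cal.sd2_b / 2.0
    s_c = (dc.sd2_c0 / 2.0, dc.sd2_c1 / 2.0, dc.sd2_c2 / 2.0)

    t0 = bwt_from_mgca(m, cal)
    dsw0 = d18osw_from_calcite(d, t0, eq)
    sig0 = density_from_d18oc(d, dc)
    sigg0 = density_from_d18oc(d, GLOBAL_DENSITY)

    def eos_partials(sig, t):
        # dS/dsigma and dS/dT of the inversion, by central differences of the
        # forward sigma_theta around the solution point.
        try:
            s_star = eos80.salinity_from_sigma_theta(sig, t, pressure)
        except (eos80.DensityUnattainableError, eos80.EnvelopeError):
            return None
        h = 1e-3
        dsig_ds = (eos80.sigma_theta(s_star + h, t, pressure)
                   - eos80.sigma_theta(s_star - h, t, pressure)) / (2 * h)
        dsig_dt = (eos80.sigma_theta(s_star, t + h, pressure)
                   - eos80.sigma_theta(s_star, t - h, pressure)) / (2 * h)
        return 1.0 / dsig_ds, -dsig_dt / dsig_ds

    if method == "delta":
        dt_dm = 1.0 / (cal.b * m)
        dt_da = -1.0 / (cal.a * cal.b)
        dt_db = -t0 / cal.b
        var_t = (dt_dm * s_m) ** 2 + (dt_da * s_a) ** 2 + (dt_db * s_b) ** 2
        ddsw_dt = -(eq.k1 + 2 * eq.k2 * t0)
        var_dsw = s_d**2 + (ddsw_dt**2) * var_t
        var_sig = ((dc.c1 + 2 * dc.c2 * d) * s_d) ** 2 + s_c[0] ** 2 \
            + (d * s_c[1]) ** 2 + (d**2 * s_c[2]) ** 2
        var_sigg = ((GLOBAL_DENSITY.c1 + 2 * GLOBAL_DENSITY.c2 * d) * s_d) ** 2
        var_sala = var_dsw / regression.slope**2
        out = {
            "bwt": 2 * math.sqrt(var_t),
            "d18o_sw": 2 * math.sqrt(var_dsw),
            "sigma_theta_regional": 2 * math.sqrt(var_sig),
            "sigma_theta_global": 2 * math.sqrt(var_sigg),
            "sal_route_a": 2 * math.sqrt(var_sala),
        }
        p = eos_partials(sig0, t0)
        if p is None:
            out["sal_route_b"] = None
        else:
            ds_dsig, ds_dt = p
            out["sal_route_b"] = 2 * math.sqrt(
                (ds_dsig**2) * var_sig + (ds_dt**2) * var_t
            )
        return out

    if method != "mc":
        raise ValueError("method must be 'delta' or 'mc'")
    if n < 100:
        raise ValueError("Monte-Carlo n must be >= 100")

    rng = np.random.default_rng(seed)
    m_d = rng.normal(m, s_m, n)
    d_d = rng.normal(d, s_d, n)
    a_d = rng.normal(cal.a, s_a, n)
    b_d = rng.normal(cal.b, s_b, n)
    c_d = [rng.normal(c, s, n) for c, s in zip((dc.c0, dc.c1, dc.c2), s_c)]
    m_d = np.clip(m_d, 1e-6, None)
    a_d = np.clip(a_d, 1e-6, None)
    b_d = np.clip(b_d, 1e-6, None)
    t, dsw, sig, sigg, sala = _chain(
        m_d, d_d, a_d, b_d, eq.k0, eq.k1, eq.k2, eq.scale_offset,
        regression, c_d, (GLOBAL_DENSITY.c0, GLOBAL_DENSITY.c1, GLOBAL_DENSITY.c2),
        pressure,
    )
    out = {
        "bwt": 2 * float(np.std(t)),
        "d18o_sw": 2 * float(np.std(dsw)),
        "sigma_theta_regional": 2 * float(np.std(sig)),
        "sigma_theta_global": 2 * float(np.std(sigg)),
        "sal_route_a": 2 * float(np.std(sala)),
    }
    # Route B via linearised EOS partials at the central point (a full
    # re-inversion per draw is equivalent at these small perturbations).
    p = eos_partials(sig0, t0)
    if p is None:
        out["sal_route_b"] = None
    else:
        ds_dsig, ds_dt = p
        salb = ds_dsig * (sig - sig0) + ds_dt * (t - t0)
        out["sal_route_b"] = 2 * float(np.std(salb))
    return out


# ---------------------------------------------------------------------------
# Downcore driver


def reconstruct_downcore(samples: Sequence[ForamSample],
                         calibration: MgCaCalibration = MgCaCalibration(),
                         equation: PaleotempEquation = PaleotempEquation(),
                         density_calibration: DensityCalibration = REGIONAL_DENSITY,
                         regression: SalinityRegression = DEFAULT_SALINITY_REGRESSION,
                         pressure: float = 101.0 * eos80.DBAR_PER_METER,
                         uncertainty_method: str = "delta",
                         n_monte_carlo: int = 5000,
                         seed: int = 0) -> List[ReconstructionRow]:
    """Apply the full proxy chain to every sample.

    Per-row failures (e.g. a density unattainable by any salinity) are
    flagged and leave that output missing; the batch never aborts.
    ``density_calibration`` drives route B; the regional and global sigma
    estimates are always both reported.
    """
    if len(samples) == 0:
        raise ValueError("no samples to reconstruct")
    rows = []
    for i, s in enumerate(samples):
        flags = set()
        t = bwt_from_mgca(s.mgca, calibration)
        if t < calibration.t_range[0] or s.mgca < calibration.a:
            flags.add("below_calibration_range")
        elif t > calibration.t_range[1]:
            flags.add("above_calibration_range")
        if not (equation.t_validity[0] <= t <= equation.t_validity[1]):
            flags.add("paleotemp_equation_range")
        dsw = d18osw_from_calcite(s.d18o_c, t, equation)
        sig_used = density_from_d18oc(s.d18o_c, density_calibration)
        sig_g = density_from_d18oc(s.d18o_c, GLOBAL_DENSITY)
        sal_a = salinity_from_d18osw(dsw, regression)
        try:
            sal_b = salinity_route_eos(t, sig_used, pressure)
        except (eos80.DensityUnattainableError, eos80.EnvelopeError):
            sal_b = None
            flags.add("density_unattainable")
        sd2 = propagate_uncertainty(
            s, calibration, equation, density_calibration, regression, pressure,
            method=uncertainty_method, n=n_monte_carlo, seed=(seed + i) % (2**31),
        )
        rows.append(ReconstructionRow(
            depth=s.depth,
            bwt=t, sd2_bwt=sd2["bwt"],
            d18o_sw=dsw, sd2_d18o_sw=sd2["d18o_sw"],
            sigma_theta_regional=density_from_d18oc(s.d18o_c, REGIONAL_DENSITY),
            sd2_sigma_theta_regional=sd2["sigma_theta_regional"],
            sigma_theta_global=sig_g,
            sd2_sigma_theta_global=sd2["sigma_theta_global"],
            sal_route_a=sal_a, sd2_sal_route_a=sd2["sal_route_a"],
            sal_route_b=sal_b, sd2_sal_route_b=sd2["sal_route_b"],
            qc_flags=flags,
        ))
    return rows


def rows_to_frame(rows: Iterable[ReconstructionRow]) -> pd.DataFrame:
    """Tabulate reconstruction rows; flags joined with ';'."""
    recs = []
    for r in rows:
        d = {k: v for k, v in r.__dict__.items() if k != "qc_flags"}
        d["qc_flags"] = ";".join(sorted(r.qc_flags))
        recs.append(d)
    return pd.DataFrame(recs)
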