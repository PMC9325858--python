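"""Seeded synthetic-data generators with recorded ground truth.

Every input the analysis stages consume can be generated here, emulating the
study setting: a three-water-mass stratified shelf profile (brackish surface
water over mixed and Atlantic water), smooth downcore bottom-water (T, S)
truth series inside the modern reef envelope, clustered coral U-series dates,
forward-modelled activity ratios, and branching-tube CT phantoms of known
per-slice coral fraction.

All generators consume an integer seed and are byte-deterministic under it.
Stated reproducibilities are 2 SD and are halved to 1 SD for the Gaussian
noise draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from . import eos80, useries
from .calibration import HydroRecord, predicted_d18oc
from .ct import CoreVolume
from .proxies import (
    DEFAULT_SALINITY_REGRESSION,
    ForamSample,
    MgCaCalibration,
    PaleotempEquation,
    SalinityRegression,
)
from .chronology import CoralDate

__all__ = [
    "gen_hydro_profile",
    "gen_downcore",
    "gen_coral_dates",
    "gen_ct_phantom",
    "gen_useries",
    "smooth_series",
]

#: Depth anchors (m) of the synthetic CTD profile and the water-mass
#: structure they encode: warm fresh surface layer, a slight temperature
#: inversion near the base of the surface layer, then gradual transition
#: through mixed water into saline Atlantic water at ~100 m.
_HYDRO_ANCHORS = {
    "depth": np.array([0.0, 18.0, 25.0, 32.0, 40.0, 60.0, 80.0, 100.0, 115.0]),
    "temperature": np.array([15.3, 15.3, 15.6, 16.3, 15.0, 12.2, 9.9, 8.3, 8.2]),
    "salinity": np.array([27.2, 27.6, 29.5, 31.0, 31.6, 33.1, 34.3, 35.0, 35.05]),
}


def gen_hydro_profile(seed: int, n_levels: int = 60, max_depth: float = 115.0,
                      noise_sd_t: float = 0.05, noise_sd_s: float = 0.02,
                      ) -> List[HydroRecord]:
    """Synthetic CTD + seawater-d18O profile of the stratified NE-shelf setting.

    Monotone-cubic interpolation through the water-mass anchors plus small
    seeded noise; seawater d18O follows the regional mixing line; sigma-theta
    is computed by EOS-80 and stable stratification (non-decreasing
    sigma-theta with depth) is enforced by minimally increasing salinity
    where noise would invert it.
    """
    if n_levels < 10:
        raise ValueError("n_levels must be >= 10")
    rng = np.random.default_rng(seed)
    depth = np.linspace(0.0, max_depth, n_levels)
    t = PchipInterpolator(_HYDRO_ANCHORS["depth"], _HYDRO_ANCHORS["temperature"])(depth)
    s = PchipInterpolator(_HYDRO_ANCHORS["depth"], _HYDRO_ANCHORS["salinity"])(depth)
    t = t + rng.normal(0.0, noise_sd_t, n_levels)
    s = s + rng.normal(0.0, noise_sd_s, n_levels)
    p = eos80.pressure_from_depth(depth)
    sig = np.array([eos80.sigma_theta(si, ti, pi) for si, ti, pi in zip(s, t, p)])
    # Stable stratification: carry the running maximum and re-solve S there.
    run = np.maximum.accumulate(sig)
    for i in np.flatnonzero(run > sig + 1e-12):
        s[i] = eos80.salinity_from_sigma_theta(run[i], t[i], p[i])
        sig[i] = run[i]
    reg = DEFAULT_SALINITY_REGRESSION
    d18o_sw = reg.slope * s + reg.intercept
    return [
        HydroRecord(depth=float(d), pressure=float(pi), temperature=float(ti),
                    salinity=float(si), d18o_sw=float(dw), sigma_theta=float(sg))
        for d, pi, ti, si, dw, sg in zip(depth, p, t, s, d18o_sw, sig)
    ]


def smooth_series(rng: np.random.Generator, n: int, lo: float, hi: float,
                  window: int = 9) -> np.ndarray:
    """Moving-average-smoothed white noise rescaled to span [lo, hi]."""
    if n == 1:
        return np.array([(lo + hi) / 2.0])
    x = rng.normal(0.0, 1.0, n + window - 1)
    x = np.convolve(x, np.ones(window) / window, mode="valid")
    span = np.ptp(x)
    if span == 0:
        return np.full(n, (lo + hi) / 2.0)
    return lo + (x - x.min()) / span * (hi - lo)


@dataclass(frozen=True)
class DowncoreTruth:
    """Per-depth forward-model truth for one synthetic downcore series."""

    frame: pd.DataFrame  # depth, bwt, salinity, d18o_sw, sigma_theta, d18o_c, mgca


def gen_downcore(seed: int, n: int,
                 bwt_range: Tuple[float, float] = (6.4, 12.4),
                 sal_range: Tuple[float, float] = (33.6, 35.1),
                 depth_range: Tuple[float, float] = (0.0, 212.0),
                 noise_mgca_2sd: float = 0.1,
                 noise_d18o_2sd: float = 0.06,
                 t_jitter_sd: float = 0.25,
                 window: int = 9,
                 water_depth_m: float = 101.0,
                 calibration: MgCaCalibration = MgCaCalibration(),
                 equation: PaleotempEquation = PaleotempEquation(),
                 regression: SalinityRegression = DEFAULT_SALINITY_REGRESSION,
                 ) -> Tuple[List[ForamSample], pd.DataFrame]:
    """Synthetic downcore foraminiferal series with recorded truth.

    The true salinity is a smooth series inside ``sal_range``; true BWT
    follows the water-mass mixing relation (fresher = warmer) with small
    smooth jitter, clipped to ``bwt_range``. Forward models:
    Mg/Ca = a*exp(b*T) + noise, d18O_C = predicted calcite + noise, seawater
    d18O on the regional mixing line; sigma-theta truth by EOS-80 at the site
    water depth. Fe/Ca and Al/Ca are independent noise columns (pyrite-like
    high Fe/Ca, uncorrelated with Mg/Ca).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    depth = np.linspace(depth_range[0], depth_range[1], n)
    sal = smooth_series(rng, n, sal_range[0], sal_range[1], window)
    # Mixing relation: linear in S from (S_min -> T_max) to (S_max -> T_min).
    frac = (sal - sal_range[0]) / max(sal_range[1] - sal_range[0], 1e-12)
    t_mix = bwt_range[1] + frac * (bwt_range[0] - bwt_range[1])
    jitter = smooth_series(rng, n, -t_jitter_sd, t_jitter_sd, window) if n > 1 else np.zeros(1)
    bwt = np.clip(t_mix + jitter, bwt_range[0], bwt_range[1])

    pressure = float(eos80.pressure_from_depth(water_depth_m))
    d18o_sw = regression.slope * sal + regression.intercept
    d18o_c = predicted_d18oc(bwt, d18o_sw, equation)
    mgca_true = calibration.a * np.exp(calibration.b * bwt)
    sigma = np.array([eos80.sigma_theta(s, t, pressure) for s, t in zip(sal, bwt)])

    mgca = mgca_true + rng.normal(0.0, noise_mgca_2sd / 2.0, n)
    d18o_obs = d18o_c + rng.normal(0.0, noise_d18o_2sd / 2.0, n)
    alca = np.abs(rng.normal(0.3, 0.05, n))
    feca = np.abs(rng.normal(4.0, 0.5, n))

    samples = [
        ForamSample(depth=float(z), mgca=float(m), d18o_c=float(dc),
                    alca=float(al), feca=float(fe),
                    sd2_mgca=max(noise_mgca_2sd, 1e-9),
                    sd2_d18o=max(noise_d18o_2sd, 1e-9))
        for z, m, dc, al, fe in zip(depth, mgca, d18o_obs, alca, feca)
    ]
    truth = pd.DataFrame({
        "depth": depth, "bwt": bwt, "salinity": sal, "d18o_sw": d18o_sw,
        "sigma_theta": sigma, "d18o_c": d18o_c, "mgca": mgca_true,
    })
    return samples, truth


def gen_coral_dates(seed: int, cluster_specs: Sequence[Dict],
                    sd2_age_default: float = 0.04,
                    ) -> Tuple[List[CoralDate], List[float]]:
    """Clustered coral dates with linear age-depth inside each cluster.

    Each spec is a dict with keys (depth_min, depth_max, age_min, age_max, n).
    Dates take uniform depths in the cluster's depth range; the age at a
    depth follows the cluster's linear age-depth trend plus Gaussian dating
    noise at the stated 2 SD, so the cluster's true average aggradation rate,
    (depth span)/(age span), is recoverable. Specs must not overlap in depth.

    Returns the dates and the true AR (cm/kyr) per spec (None when the age
    span is zero).
    """
    specs = sorted(cluster_specs, key=lambda c: c["depth_min"])
    for a, b in zip(specs, specs[1:]):
        if b["depth_min"] <= a["depth_max"]:
            raise ValueError("cluster specs overlap in depth")
    rng = np.random.default_rng(seed)
    dates: List[CoralDate] = []
    true_ars: List[float] = []
    for ci, c in enumerate(specs):
        d0, d1 = float(c["depth_min"]), float(c["depth_max"])
        a0, a1 = float(c["age_min"]), float(c["age_max"])
        n = int(c["n"])
        sd2 = float(c.get("sd2_age", sd2_age_default))
        true_ars.append((d1 - d0) / (a1 - a0) if a1 > a0 else None)
        if n == 1:
            depths = np.array([(d0 + d1) / 2.0])
        else:
            inner = np.sort(rng.uniform(d0, d1, max(n - 2, 0)))
            depths = np.concatenate([[d0], inner, [d1]])
        frac = (depths - d0) / max(d1 - d0, 1e-12)
        ages = a0 + frac * (a1 - a0) + rng.normal(0.0, sd2 / 2.0, n)
        ages = np.clip(ages, 1e-6, None)
        for j, (z, age) in enumerate(zip(depths, ages)):
            dates.append(CoralDate(depth=float(z), age=float(age), sd2=sd2,
                                   sample_id=f"C{ci + 1}-{j + 1}"))
    return dates, true_ars


def gen_ct_phantom(seed: int, shape: Tuple[int, int, int] = (60, 64, 64),
                   target_fraction: float = 0.07,
                   n_branches: Optional[int] = None,
                   matrix_intensity: float = 100.0,
                   coral_intensity: float = 200.0,
                   noise_sd: float = 10.0,
                   voxel_size: Tuple[float, float, float] = (0.9, 0.6, 0.6),
                   ) -> Tuple[CoreVolume, np.ndarray]:
    """Branching-tube coral phantom inside a cylindrical VOI.

    Random capsules (line segments with radius) of high intensity are placed
    on a low-intensity matrix until the coral volume fraction of the VOI
    reaches ``target_fraction`` (or ``n_branches`` capsules when given);
    Gaussian noise is added afterwards. Returns the noisy volume and the true
    per-slice coral percentage (computed from the clean mask, before noise).
    """
    if not (0.0 <= target_fraction <= 0.4):
        raise ValueError("target_fraction must lie in [0, 0.4]")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r_voi = 0.45 * min(ny, nx)
    voi = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_voi**2

    mask = np.zeros(shape, dtype=bool)
    voi_count = int(voi.sum())

    def add_capsule():
        start = np.array([rng.uniform(0, nz - 1),
                          rng.uniform(cy - r_voi * 0.7, cy + r_voi * 0.7),
                          rng.uniform(cx - r_voi * 0.7, cx + r_voi * 0.7)])
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = rng.uniform(12.0, 35.0)
        radius = rng.uniform(1.6, 3.0)
        end = start + direction * length
        pts = np.stack([zz, yy, xx], axis=-1).astype(float)
        seg = end - start
        tproj = np.clip(((pts - start) @ seg) / (seg @ seg), 0.0, 1.0)
        closest = start + tproj[..., None] * seg
        dist2 = np.sum((pts - closest) ** 2, axis=-1)
        mask[dist2 <= radius**2] = True

    if n_branches is not None:
        for _ in range(n_branches):
            add_capsule()
    else:
        guard = 0
        while (mask & voi).sum() / voi_count < target_fraction and guard < 500:
            add_capsule()
            guard += 1

    clean = np.where(mask, coral_intensity, matrix_intensity)
    noisy = clean + rng.normal(0.0, noise_sd, shape)
    truth = mask & voi
    voi_per_slice = voi.reshape(nz, -1).sum(axis=1)
    truth_percent = 100.0 * truth.reshape(nz, -1).sum(axis=1) / np.maximum(voi_per_slice, 1)
    return CoreVolume(noisy, voxel_size, voi), truth_percent


def gen_useries(seed: int, true_ages_ka: Sequence[float],
                d234U_initial: float = useries.SEAWATER_D234U,
                rel_noise: float = 0.003,
                depths_cm: Optional[Sequence[float]] = None,
                constants: useries.DecayConstants = useries.CHENG_2013,
                ) -> List[useries.UraniumSeriesMeasurement]:
    """Forward-modelled U-series measurements with multiplicative noise.

    232Th concentrations are drawn below the 6 ppb screening limit, so the
    default regime emulates clean coral aragonite.
    """
    ages = np.asarray(true_ages_ka, dtype=float)
    if np.any(ages < 0):
        raise ValueError("true ages must be >= 0")
    rng = np.random.default_rng(seed)
    if depths_cm is None:
        depths_cm = np.arange(len(ages)) * 10.0
    out = []
    for i, (age, depth) in enumerate(zip(ages, depths_cm)):
        ar, d234 = useries.forward_ratios(age, d234U_initial, constants)
        ar_obs = ar * (1.0 + rng.normal(0.0, rel_noise)) if rel_noise > 0 else ar
        d_obs = d234 * (1.0 + rng.normal(0.0, rel_noise)) if rel_noise > 0 else d234
        sd2_ar = max(2.0 * rel_noise * max(ar, 1e-6), 1e-8)
        sd2_d = max(2.0 * rel_noise * abs(d234), 1e-3)
        th232 = rng.uniform(0.3, 4.5)
        out.append(useries.UraniumSeriesMeasurement(
            sample_id=f"U{i + 1}", depth_cm=float(depth),
            ar230_238=float(max(ar_obs, 0.0)), sd2_ar230=float(sd2_ar),
            d234U_measured=float(d_obs), sd2_d234U=float(sd2_d),
            th232_ppb=float(th232),
        ))
    return out
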