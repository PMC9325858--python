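"""Coral-mound chronology: age clusters, aggradation and sedimentation rates.

Dated coral fragments from mound cores group into age clusters that mark
periods of active mound formation. Clusters are found with a gap rule on the
depth-sorted dates: a new cluster starts whenever the step to the previous
date exceeds the age-gap threshold or the depth-gap threshold. The
aggradation rate (AR, cm/kyr) of a cluster is its depth span over its age
span; matrix sediment is assumed coeval with the coral framework, so linear
interpolation between dated horizons also yields sedimentation rates.

The default gaps (0.6 kyr, 110 cm) recover a three-cluster structure from
the main-text dates of the study core; cluster boundaries from sparse dates
are inherently ambiguous, so both gaps are exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CoralDate",
    "CoralCluster",
    "DEFAULT_MAX_AGE_GAP_KA",
    "DEFAULT_MAX_DEPTH_GAP_CM",
    "identify_clusters",
    "aggradation_rate",
    "sedimentation_rate",
    "detect_reversals",
    "paleo_depth_correction",
]

DEFAULT_MAX_AGE_GAP_KA = 0.6
DEFAULT_MAX_DEPTH_GAP_CM = 110.0


@dataclass(frozen=True)
class CoralDate:
    """One dated coral fragment: depth in cm below core top, age in ka."""

    depth: float
    age: float
    sd2: float = 0.0
    reliable: bool = True
    sample_id: str = ""

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("depth must be >= 0 (cm below core top)")
        if self.age <= 0:
            raise ValueError("age must be > 0 ka")


@dataclass
class CoralCluster:
    member_ids: List[int]
    depth_min: float
    depth_max: float
    age_min: float
    age_max: float
    ar: Optional[float] = field(default=None)

    def __post_init__(self):
        if self.depth_max < self.depth_min:
            raise ValueError("depth_max must be >= depth_min")


def identify_clusters(dates: Sequence[CoralDate],
                      max_age_gap_ka: float = DEFAULT_MAX_AGE_GAP_KA,
                      max_depth_gap_cm: float = DEFAULT_MAX_DEPTH_GAP_CM,
                      include_unreliable: bool = False) -> List[CoralCluster]:
    """Partition dates into clusters by depth-consecutive gap thresholds.

    Dates are sorted by depth; a new cluster starts when the gap to the
    previous date exceeds ``max_age_gap_ka`` (absolute age difference) OR
    ``max_depth_gap_cm``. Unreliable (screened-out) dates are excluded unless
    ``include_unreliable``. Singleton clusters are allowed; their AR is None.
    """
    usable = [
        (i, d) for i, d in enumerate(dates) if d.reliable or include_unreliable
    ]
    if not usable:
        raise ValueError("no usable dates (empty input or all flagged unreliable)")
    usable.sort(key=lambda t: (t[1].depth, t[1].age))

    groups: List[List[Tuple[int, CoralDate]]] = [[usable[0]]]
    for prev, cur in zip(usable, usable[1:]):
        age_gap = abs(cur[1].age - prev[1].age)
        depth_gap = cur[1].depth - prev[1].depth
        if age_gap > max_age_gap_ka or depth_gap > max_depth_gap_cm:
            groups.append([cur])
        else:
            groups[-1].append(cur)

    clusters = []
    for g in groups:
        ages = [d.age for _, d in g]
        cluster = CoralCluster(
            member_ids=[i for i, _ in g],
            depth_min=min(d.depth for _, d in g),
            depth_max=max(d.depth for _, d in g),
            age_min=min(ages),
            age_max=max(ages),
        )
        cluster.ar = aggradation_rate(cluster)
        clusters.append(cluster)
    return clusters


def aggradation_rate(cluster: CoralCluster) -> Optional[float]:
    """Average AR of a cluster in cm/kyr, None when the age span is zero."""
    age_span = cluster.age_max - cluster.age_min
    if age_span <= 0:
        return None
    return (cluster.depth_max - cluster.depth_min) / age_span


def sedimentation_rate(dates: Sequence[CoralDate], depth_top: float,
                       depth_bottom: float) -> float:
    """Mean sedimentation rate (cm/kyr) over [depth_top, depth_bottom].

    Ages at the interval ends are linearly interpolated between the nearest
    reliable dated horizons; the interval must lie inside the dated range.
    """
    pts = sorted(((d.depth, d.age) for d in dates if d.reliable))
    if len(pts) < 2:
        raise ValueError("need at least two reliable dates")
    depths = np.array([p[0] for p in pts])
    ages = np.array([p[1] for p in pts])
    if depth_top < depths[0] or depth_bottom > depths[-1]:
        raise ValueError(
            f"interval [{depth_top}, {depth_bottom}] extends beyond the dated "
            f"range [{depths[0]}, {depths[-1]}] cm; refusing to extrapolate"
        )
    if depth_bottom <= depth_top:
        raise ValueError("depth_bottom must exceed depth_top")
    age_top = float(np.interp(depth_top, depths, ages))
    age_bottom = float(np.interp(depth_bottom, depths, ages))
    if age_bottom <= age_top:
        raise ValueError("interpolated ages do not increase over the interval")
    return (depth_bottom - depth_top) / (age_bottom - age_top)


def detect_reversals(dates: Sequence[CoralDate], k_sd: float = 2.0
                     ) -> List[Tuple[CoralDate, CoralDate]]:
    """Flag depth-consecutive pairs whose age DECREASES downcore.

    A pair is flagged when the age drop exceeds ``k_sd`` times the combined
    2 SD of the two dates (quadrature), i.e. the reversal is resolvable
    against dating uncertainty.
    """
    if len(dates) < 2:
        raise ValueError("need at least two dates")
    ordered = sorted(dates, key=lambda d: d.depth)
    flagged = []
    for a, b in zip(ordered, ordered[1:]):
        combined = float(np.hypot(a.sd2, b.sd2))
        if a.age - b.age > k_sd * combined:
            flagged.append((a, b))
    return flagged


def paleo_depth_correction(age_ka: float, uplift_rate_mm_per_yr: float) -> float:
    """Additional water depth (m) at ``age_ka`` under linear isostatic uplift.

    mm/yr times kyr gives metres, e.g. 5 mm/yr over 3.5 kyr -> 17.5 m.
    """
    if age_ka < 0:
        raise ValueError("age_ka must be >= 0")
    return age_ka * uplift_rate_mm_per_yr
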