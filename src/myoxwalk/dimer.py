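"""Mechanics of the myosin X dimer: lever arms, coiled-coil, reach and stroke.

The two heads are joined head-to-tail by an anti-parallel coiled-coil (CC)
formed after each lever arm's single α-helix (SAH).  Each arm is modelled as a
planar two-segment linkage: the stiff converter+3IQ segment from the head to
the pliant point, then the SAH down to the SAH/CC junction.  Bending is
allowed at the two joints only, up to per-joint limits, which is the minimal
mechanical picture that reproduces both the ~66 nm flattened head-head span
and the penalty for short (~19 nm) steps that require strong folding.

Axial separations throughout are along-track distances, matching how
single-molecule step sizes are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .actin import TargetZone

__all__ = [
    "LeverSpec",
    "DimerGeometry",
    "StrokeSpec",
    "ReachEnvelope",
    "FLAT_BIAS_DEFAULT",
    "MYOSIN5_STROKE",
    "MYOSIN10_STROKE",
    "reach_envelope",
    "stroke_distance",
    "min_bend_for_separation",
    "preferred_step_weights",
    "crystal_preset",
    "relaxed_preset",
]

#: Quadratic bending stiffness (deg^-2) calibrated so that on the fascin
#: hot-spot set the 52 nm separation is weighted ~3x the 19 nm separation.
FLAT_BIAS_DEFAULT = 2.54e-5


@dataclass(frozen=True)
class LeverSpec:
    """Lever-arm segment lengths and joint bend limits.

    ``iq_segment_nm`` is the stiff converter+3IQ segment (head to pliant
    point); ``sah_nm`` the single α-helix (pliant point to CC junction),
    10.5 nm in the dimer.  Joint limits are the maximum bend at the pliant
    point and at the SAH/CC junction respectively, in degrees.
    """

    iq_segment_nm: float = 9.7
    sah_nm: float = 10.5
    pliant_bend_max_deg: float = 120.0
    sah_bend_max_deg: float = 90.0

    def __post_init__(self) -> None:
        if self.iq_segment_nm <= 0 or self.sah_nm <= 0:
            raise ValueError("segment lengths must be positive")
        for b in (self.pliant_bend_max_deg, self.sah_bend_max_deg):
            if not 0 <= b <= 180:
                raise ValueError("bend limits must be in [0, 180] degrees")

    @property
    def extent_nm(self) -> float:
        """Head-to-CC extent of one straight arm."""
        return self.iq_segment_nm + self.sah_nm


@dataclass(frozen=True)
class DimerGeometry:
    """Two lever arms joined by the anti-parallel coiled-coil."""

    lever: LeverSpec = field(default_factory=LeverSpec)
    cc_length_nm: float = 25.7
    flat_bias: float = FLAT_BIAS_DEFAULT

    def __post_init__(self) -> None:
        if self.cc_length_nm <= 0:
            raise ValueError("cc_length_nm must be positive")
        if self.flat_bias < 0:
            raise ValueError("flat_bias must be >= 0")


def crystal_preset() -> DimerGeometry:
    """SAH-CC-SAH length as seen in the crystal structure (24 nm)."""
    return DimerGeometry(cc_length_nm=24.0)


def relaxed_preset() -> DimerGeometry:
    """SAH-CC-SAH length averaged over MD of the dimerization region (25.7 nm)."""
    return DimerGeometry(cc_length_nm=25.7)


@dataclass(frozen=True)
class StrokeSpec:
    """Rigid-lever swing between pre-powerstroke and rigor orientations."""

    lever_length_nm: float
    pre_angle_deg: float
    post_angle_deg: float

    def __post_init__(self) -> None:
        if self.lever_length_nm <= 0:
            raise ValueError("lever_length_nm must be positive")


#: Myosin V: ~70° swing at the end of 6 IQ; lever length inverted from the
#: 25 nm stroke via the chord formula.
MYOSIN5_STROKE = StrokeSpec(25.0 / (2 * math.sin(math.radians(35.0))), 0.0, 70.0)

#: Myosin X: ~120° swing at the end of converter+3IQ+SAH; lever length
#: inverted from the ~48 nm stroke.
MYOSIN10_STROKE = StrokeSpec(48.0 / (2 * math.sin(math.radians(60.0))), 0.0, 120.0)


@dataclass(frozen=True)
class ReachEnvelope:
    """Attainable head-head axial separations of the dimer."""

    min_sep_nm: float
    max_sep_nm: float
    flattened_span_nm: float


def stroke_distance(s: StrokeSpec) -> float:
    """Chord displacement of the lever tip, ``2 L sin(Δθ/2)``."""
    dtheta = abs(s.pre_angle_deg - s.post_angle_deg)
    return 2.0 * s.lever_length_nm * math.sin(math.radians(dtheta) / 2.0)


def _arm_extent_range(lever: LeverSpec, n_grid: int = 721) -> tuple[float, float]:
    """Axial extent range of one arm over its allowed joint bends."""
    b1 = np.radians(np.linspace(0.0, lever.sah_bend_max_deg, n_grid))
    b2 = np.radians(np.linspace(0.0, lever.pliant_bend_max_deg, n_grid))
    ext = lever.sah_nm * np.cos(b1)[:, None] + lever.iq_segment_nm * np.cos(
        b1[:, None] + b2[None, :]
    )
    return float(ext.min()), lever.extent_nm


def reach_envelope(dimer: DimerGeometry) -> ReachEnvelope:
    """Head-head separation envelope from the planar two-segment arm model.

    The flattened span — both arms collinear with the CC — is the maximum
    separation; the minimum comes from folding both arms as far as the joint
    limits allow (clamped at zero: heads cannot pass through each other in
    this planar picture).
    """
    e_min, e_max = _arm_extent_range(dimer.lever)
    flattened = dimer.cc_length_nm + 2.0 * e_max
    return ReachEnvelope(
        min_sep_nm=max(dimer.cc_length_nm + 2.0 * e_min, 0.0),
        max_sep_nm=flattened,
        flattened_span_nm=flattened,
    )


def _min_arm_bend(lever: LeverSpec, extents: np.ndarray, n_grid: int = 1801) -> np.ndarray:
    """Minimal total joint bend (deg) for one arm to reach each axial extent.

    For proximal bend b1 the distal segment's direction is b1 + b2, so the
    total bend equals the distal direction angle; minimising it means
    maximising ``cos(b1 + b2) = (e - sah cos b1) / iq`` over feasible b1.
    Solved on a b1 grid; infeasible extents map to +inf.
    """
    extents = np.atleast_1d(np.asarray(extents, dtype=float))
    b1_deg = np.linspace(0.0, lever.sah_bend_max_deg, n_grid)
    b1 = np.radians(b1_deg)
    # ratio[i, j] = cos(b1_i + b2) required for extent_j
    ratio = (extents[None, :] - lever.sah_nm * np.cos(b1)[:, None]) / lever.iq_segment_nm
    with np.errstate(invalid="ignore"):
        total = np.degrees(np.arccos(np.clip(ratio, -1.0, 1.0)))
    feasible = (np.abs(ratio) <= 1.0 + 1e-12) & (
        (total - b1_deg[:, None] >= -1e-9)
        & (total - b1_deg[:, None] <= lever.pliant_bend_max_deg + 1e-9)
    )
    total = np.where(feasible, total, np.inf)
    return total.min(axis=0)


def min_bend_for_separation(
    dimer: DimerGeometry, separation_nm: float, n_split: int = 201
) -> float:
    """Minimal total joint bending (deg, both arms) to put the heads at a
    given axial separation, or +inf if outside the reach envelope."""
    lever = dimer.lever
    need = separation_nm - dimer.cc_length_nm
    e_min, e_max = _arm_extent_range(lever)
    lo = max(e_min, need - e_max)
    hi = min(e_max, need - e_min)
    if lo > hi:
        return float("inf")
    e_front = np.linspace(lo, hi, n_split)
    bends = _min_arm_bend(lever, e_front) + _min_arm_bend(lever, need - e_front)
    return float(bends.min())


def preferred_step_weights(
    dimer: DimerGeometry,
    zones: Sequence[TargetZone] | Iterable[float] | np.ndarray,
) -> np.ndarray:
    """Relative preference of the dimer for each target zone.

    weight_i ∝ exp(-flat_bias * bend_i**2) with bend_i the minimal total
    joint bending (degrees) needed to reach the zone's axial separation.
    Zones outside the reach envelope get weight 0.  Returns a probability
    vector; raises if every zone is unreachable.
    """
    zones = list(zones)
    if not zones:
        raise ValueError("zones must be non-empty")
    seps = np.array(
        [z.axial_nm if isinstance(z, TargetZone) else float(z) for z in zones]
    )
    bends = np.array([min_bend_for_separation(dimer, s) for s in seps])
    with np.errstate(over="ignore"):
        w = np.where(
            np.isfinite(bends), np.exp(-dimer.flat_bias * bends**2), 0.0
        )
    total = w.sum()
    if total <= 0:
        raise ValueError("all zones lie outside the reach envelope")
    return w / total
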