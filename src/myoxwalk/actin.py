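"""Helical lattice of F-actin and fascin bundles, and motor target zones.

F-actin is modelled as a single-start left-handed helix: subunit ``n`` sits at
axial position ``n * rise_nm`` and azimuth ``n * twist_deg`` (degrees, wrapped
to ``(-180, 180]``).  With the default 13/6 lattice the twist is exactly
``-2160/13`` degrees per subunit, so subunit 13 returns to azimuth zero and the
familiar ~36 nm pseudo-repeat is crisp.

A dimeric motor whose rear head is bound at subunit 0 can only place its lead
head on subunits whose binding face points roughly toward the motor — an
azimuthal cone — and that lie within the axial reach band of the dimer.  Such
subunits are the "target zones" (hot spots).  On a fascin bundle the lead head
may also reach subunits of neighbouring filaments; there the motor-facing
direction is the inter-filament direction and each neighbour carries its own
azimuthal registry (phase) and axial registry shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "TWIST_13_6",
    "TWIST_ALTERNATIVE",
    "HelixParams",
    "FilamentPlacement",
    "BundleLattice",
    "AccessibilityParams",
    "TargetZone",
    "wrap_deg",
    "subunit_azimuth",
    "accessible_sites_same_filament",
    "accessible_sites_neighbor",
    "bundle_target_map",
    "fascin_bundle",
]

#: Exact 13-subunit pseudo-repeat: 6 left-handed turns per 13 subunits.
TWIST_13_6 = -2160.0 / 13.0

#: Commonly quoted average F-actin twist (not an exact repeat).
TWIST_ALTERNATIVE = -166.6


def wrap_deg(angle: float) -> float:
    """Wrap an angle in degrees to the half-open interval (-180, 180]."""
    wrapped = -((-angle + 180.0) % 360.0 - 180.0)
    return wrapped


@dataclass(frozen=True)
class HelixParams:
    """Geometry of one actin filament's helical lattice.

    Parameters
    ----------
    rise_nm : float
        Axial rise per subunit (nm).
    twist_deg : float
        Signed rotation per subunit (degrees); negative = left-handed.
        Default is the exact 13/6 helix, -2160/13 ≈ -166.154°.
    radius_nm : float
        Radial distance of the myosin binding site from the filament axis.
        Bookkeeping only — accessibility below is decided from azimuth and
        axial separation, not 3-D distance.
    n_subunits : int
        Lattice extent used when enumerating candidate subunits.
    """

    rise_nm: float = 2.75
    twist_deg: float = TWIST_13_6
    radius_nm: float = 3.5
    n_subunits: int = 30

    def __post_init__(self) -> None:
        if self.rise_nm <= 0:
            raise ValueError("rise_nm must be positive")
        if not 0 < abs(self.twist_deg) < 360:
            raise ValueError("twist_deg must have magnitude in (0, 360)")
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")


@dataclass(frozen=True)
class FilamentPlacement:
    """Placement and registry of one filament inside a bundle.

    ``phase_deg`` is the azimuthal registry: the rotation that would align
    subunit 0's binding face with the motor-facing (inter-filament) direction.
    A subunit ``n`` therefore faces the motor when ``n * twist - phase``
    wraps to zero.  ``axial_offset_nm`` shifts the whole subunit ladder along
    the bundle axis relative to the reference filament.
    """

    filament_id: str
    lateral_offset_nm: tuple[float, float] = (0.0, 0.0)
    axial_offset_nm: float = 0.0
    phase_deg: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase_deg", wrap_deg(self.phase_deg))


@dataclass(frozen=True)
class BundleLattice:
    """A set of parallel filaments crosslinked at a fixed axis spacing."""

    filaments: tuple[FilamentPlacement, ...]
    spacing_nm: float = 12.0

    def __post_init__(self) -> None:
        if self.spacing_nm <= 0:
            raise ValueError("spacing_nm must be positive")
        ids = [f.filament_id for f in self.filaments]
        if len(ids) != len(set(ids)):
            raise ValueError("filament_ids must be unique")

    def __getitem__(self, filament_id: str) -> FilamentPlacement:
        for f in self.filaments:
            if f.filament_id == filament_id:
                return f
        raise KeyError(f"no filament {filament_id!r} in bundle")


@dataclass(frozen=True)
class AccessibilityParams:
    """Operational definition of an accessible subunit.

    A subunit is accessible when its binding-face azimuth is within
    ``azim_tol_deg`` of the motor-facing direction and its axial separation
    from the rear head lies in ``[band_min_nm, band_max_nm]`` (the reach band
    of the dimer, see :mod:`myoxwalk.dimer`).
    """

    azim_tol_deg: float = 60.0
    band_min_nm: float = 33.0
    band_max_nm: float = 57.0

    def __post_init__(self) -> None:
        if not 0 <= self.azim_tol_deg <= 180:
            raise ValueError("azim_tol_deg must be in [0, 180]")
        if not 0 <= self.band_min_nm < self.band_max_nm:
            raise ValueError("require 0 <= band_min_nm < band_max_nm")


@dataclass(frozen=True)
class TargetZone:
    """One candidate binding site for the lead head."""

    filament_id: str
    subunit_index: int
    axial_nm: float
    azimuth_deg: float
    accessible: bool

    def as_dict(self) -> dict:
        return {
            "filament_id": self.filament_id,
            "subunit": self.subunit_index,
            "axial_nm": self.axial_nm,
            "azimuth_deg": self.azimuth_deg,
            "accessible": self.accessible,
        }


def subunit_azimuth(helix: HelixParams, n: int) -> float:
    """Azimuth of subunit ``n`` (degrees in (-180, 180]); subunit 0 is at 0."""
    if n < 0:
        raise ValueError("subunit index must be non-negative")
    return wrap_deg(n * helix.twist_deg)


def _enumerate(
    helix: HelixParams,
    acc: AccessibilityParams,
    *,
    filament_id: str,
    phase_deg: float,
    axial_offset_nm: float,
) -> list[TargetZone]:
    # Enumerate every subunit whose axial position can fall in the band; the
    # cone test is exact so no candidate beyond n_max can qualify.
    n_max = max(
        helix.n_subunits,
        int(math.ceil((acc.band_max_nm - axial_offset_nm) / helix.rise_nm)) + 1,
    )
    zones = []
    for n in range(1, n_max + 1):
        axial = n * helix.rise_nm + axial_offset_nm
        if not acc.band_min_nm <= axial <= acc.band_max_nm:
            continue
        azim = wrap_deg(n * helix.twist_deg - phase_deg)
        if abs(azim) <= acc.azim_tol_deg:
            zones.append(TargetZone(filament_id, n, axial, azim, True))
    zones.sort(key=lambda z: z.axial_nm)
    return zones


def accessible_sites_same_filament(
    helix: HelixParams, acc: AccessibilityParams, *, filament_id: str = "f0"
) -> list[TargetZone]:
    """Target zones on the rear head's own filament, ordered by axial distance.

    The motor-facing direction is the rear head's own azimuth, so only the
    relative twist ``n * twist_deg`` matters.
    """
    return _enumerate(
        helix, acc, filament_id=filament_id, phase_deg=0.0, axial_offset_nm=0.0
    )


def accessible_sites_neighbor(
    helix: HelixParams, placement: FilamentPlacement, acc: AccessibilityParams
) -> list[TargetZone]:
    """Target zones on a neighbouring bundle filament.

    The motor-facing direction is the inter-filament direction; subunit
    azimuths are shifted by the neighbour's registry ``phase_deg`` and axial
    positions by its ``axial_offset_nm``.
    """
    if placement.lateral_offset_nm == (0.0, 0.0):
        raise ValueError("neighbour placement must have a nonzero lateral offset")
    return _enumerate(
        helix,
        acc,
        filament_id=placement.filament_id,
        phase_deg=placement.phase_deg,
        axial_offset_nm=placement.axial_offset_nm,
    )


def bundle_target_map(
    bundle: BundleLattice,
    rear_site: tuple[str, int],
    acc: AccessibilityParams,
    helix: HelixParams | None = None,
) -> list[TargetZone]:
    """All target zones in a bundle for a rear head bound at ``rear_site``.

    Unions the same-filament sites with each neighbour filament's sites,
    deduplicated on (filament, subunit) and ordered by (axial, filament_id).
    Axial separations are measured from the rear head's subunit.
    """
    helix = helix or HelixParams()
    rear_fid, rear_idx = rear_site
    rear_fil = bundle[rear_fid]  # raises KeyError for unknown filament
    rear_axial = rear_idx * helix.rise_nm + rear_fil.axial_offset_nm

    seen: dict[tuple[str, int], TargetZone] = {}
    for z in accessible_sites_same_filament(helix, acc, filament_id=rear_fid):
        seen[(rear_fid, rear_idx + z.subunit_index)] = replace(
            z, subunit_index=rear_idx + z.subunit_index
        )
    for fil in bundle.filaments:
        if fil.filament_id == rear_fid:
            continue
        shifted = replace(
            fil, axial_offset_nm=fil.axial_offset_nm - rear_axial
        )
        for z in accessible_sites_neighbor(helix, shifted, acc):
            seen.setdefault((fil.filament_id, z.subunit_index), z)
    return sorted(seen.values(), key=lambda z: (z.axial_nm, z.filament_id))


def fascin_bundle(spacing_nm: float = 12.0) -> BundleLattice:
    """Hexagonal fascin-bundle preset.

    Neighbour registry classes (phases 90°, 190° and 277°, zero axial offset)
    are calibrated so that, with a 30° cone and a 15–60 nm reach band, the
    bundle target map reproduces the hot spots observed on fascin bundles at
    roughly 19, 38, 52 and 57 nm from the rear head.  The true inter-filament
    registry of fascin bundles is irregular; this preset is a representative
    unit cell, not a transcription of any one bundle.
    """
    s = spacing_nm
    h = s * math.sqrt(3) / 2
    return BundleLattice(
        filaments=(
            FilamentPlacement("f0", (0.0, 0.0), 0.0, 0.0),
            FilamentPlacement("n1", (s, 0.0), 0.0, 90.0),
            FilamentPlacement("n2", (-s / 2, h), 0.0, 190.0),
            FilamentPlacement("n3", (s / 2, h), 0.0, 277.0),
        ),
        spacing_nm=s,
    )
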