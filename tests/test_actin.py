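"""Helical-lattice target-zone geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myoxwalk.actin import (
    AccessibilityParams,
    BundleLattice,
    FilamentPlacement,
    HelixParams,
    accessible_sites_neighbor,
    accessible_sites_same_filament,
    bundle_target_map,
    fascin_bundle,
    subunit_azimuth,
    wrap_deg,
)

DEFAULT = HelixParams()


def brute_force_sites(helix, acc, phase=0.0, axial_offset=0.0):
    """Independent enumeration oracle: plain loop, naive angle wrapping."""
    out = []
    n = 1
    while n * helix.rise_nm + axial_offset <= acc.band_max_nm + helix.rise_nm:
        axial = n * helix.rise_nm + axial_offset
        az = n * helix.twist_deg - phase
        while az <= -180.0:
            az += 360.0
        while az > 180.0:
            az -= 360.0
        if acc.band_min_nm <= axial <= acc.band_max_nm and abs(az) <= acc.azim_tol_deg:
            out.append(round(axial, 9))
        n += 1
    return out


class TestAzimuth:
    @pytest.mark.parametrize(
        "n, expected",
        [(0, 0.0), (13, 0.0), (26, 0.0), (15, 360.0 - 2 * 2160.0 / 13)],
    )
    def test_known_subunits(self, n, expected):
        assert subunit_azimuth(DEFAULT, n) == pytest.approx(expected, abs=1e-6)

    def test_pseudo_repeat_is_exact(self):
        # 13-subunit pseudo-repeat returns to azimuth 0 within 1e-6 degrees
        assert abs(subunit_azimuth(DEFAULT, 13)) < 1e-6

    def test_negative_subunit_rejected(self):
        with pytest.raises(ValueError):
            subunit_azimuth(DEFAULT, -1)

    @given(st.floats(-1e4, 1e4))
    @settings(max_examples=100, derandomize=True)
    def test_wrap_range(self, angle):
        w = wrap_deg(angle)
        assert -180.0 < w <= 180.0
        assert abs((angle - w) % 360.0) < 1e-6 or abs((angle - w) % 360.0 - 360) < 1e-6


class TestSameFilament:
    @pytest.mark.parametrize(
        "tol, band, expected",
        [
            (60.0, (33.0, 57.0), [35.75, 41.25, 46.75]),
            (1e-6, (0.1, 80.0), [35.75, 71.5]),
            # the filament twist forbids lead-head attachment at 47-57 nm
            (60.0, (47.0, 57.0), []),
        ],
    )
    def test_accessible_axial_sets(self, tol, band, expected):
        acc = AccessibilityParams(tol, *band)
        zones = accessible_sites_same_filament(DEFAULT, acc)
        assert [z.axial_nm for z in zones] == pytest.approx(expected)

    def test_sorted_and_unique(self):
        acc = AccessibilityParams(120.0, 5.0, 80.0)
        zones = accessible_sites_same_filament(DEFAULT, acc)
        ax = [z.axial_nm for z in zones]
        assert ax == sorted(ax)
        assert len({(z.filament_id, z.subunit_index) for z in zones}) == len(zones)


class TestNeighborFilament:
    def placement(self, phase, axial=0.0):
        return FilamentPlacement("n1", (12.0, 0.0), axial, phase)

    @pytest.mark.parametrize(
        "phase, tol, band, expected",
        [
            (90.0, 30.0, (45.0, 60.0), [52.25, 57.75]),
            (90.0, 30.0, (15.0, 60.0), [16.5, 22.0, 52.25, 57.75]),
        ],
    )
    def test_registry_shifted_sites(self, phase, tol, band, expected):
        acc = AccessibilityParams(tol, *band)
        zones = accessible_sites_neighbor(DEFAULT, self.placement(phase), acc)
        assert [z.axial_nm for z in zones] == pytest.approx(expected)

    def test_zero_registry_equals_same_filament(self):
        acc = AccessibilityParams(60.0, 33.0, 57.0)
        nb = accessible_sites_neighbor(DEFAULT, self.placement(0.0), acc)
        same = accessible_sites_same_filament(DEFAULT, acc)
        assert [(z.subunit_index, z.axial_nm) for z in nb] == [
            (z.subunit_index, z.axial_nm) for z in same
        ]

    def test_axial_offset_shifts_positions(self):
        acc = AccessibilityParams(30.0, 45.0, 60.0)
        shifted = accessible_sites_neighbor(
            DEFAULT, self.placement(90.0, axial=1.0), acc
        )
        assert [z.axial_nm for z in shifted] == pytest.approx([53.25, 58.75])

    def test_rear_filament_placement_rejected(self):
        with pytest.raises(ValueError):
            accessible_sites_neighbor(
                DEFAULT,
                FilamentPlacement("f0", (0.0, 0.0), 0.0, 90.0),
                AccessibilityParams(),
            )


class TestBundleMap:
    def test_single_filament_bundle_reduces_to_same_filament(self):
        bundle = BundleLattice((FilamentPlacement("f0"),))
        acc = AccessibilityParams(60.0, 33.0, 57.0)
        zones = bundle_target_map(bundle, ("f0", 0), acc)
        same = accessible_sites_same_filament(DEFAULT, acc)
        assert [z.axial_nm for z in zones] == [z.axial_nm for z in same]

    def test_fascin_preset_covers_observed_hot_spots(self):
        acc = AccessibilityParams(30.0, 15.0, 60.0)
        zones = bundle_target_map(fascin_bundle(), ("f0", 0), acc)
        axial = np.array([z.axial_nm for z in zones])
        for hot in (19.0, 38.0, 52.0, 57.0):
            assert np.min(np.abs(axial - hot)) <= 2.0

    def test_identical_neighbors_not_duplicated(self):
        bundle = BundleLattice(
            (
                FilamentPlacement("f0"),
                FilamentPlacement("a", (12.0, 0.0), 0.0, 90.0),
                FilamentPlacement("b", (-12.0, 0.0), 0.0, 90.0),
            )
        )
        acc = AccessibilityParams(30.0, 45.0, 60.0)
        zones = bundle_target_map(bundle, ("f0", 0), acc)
        keys = [(z.filament_id, z.subunit_index) for z in zones]
        assert len(keys) == len(set(keys))
        # both neighbours contribute their own (distinct-filament) records
        assert sorted({z.filament_id for z in zones} - {"f0"}) == ["a", "b"]

    def test_unknown_rear_filament_raises(self):
        with pytest.raises(KeyError):
            bundle_target_map(fascin_bundle(), ("nope", 0), AccessibilityParams())

    def test_deterministic_ordering(self):
        acc = AccessibilityParams(30.0, 15.0, 60.0)
        zones = bundle_target_map(fascin_bundle(), ("f0", 0), acc)
        keys = [(z.axial_nm, z.filament_id) for z in zones]
        assert keys == sorted(keys)


class TestProperties:
    @given(
        tol1=st.floats(0, 180),
        tol2=st.floats(0, 180),
        band_min=st.floats(0, 40),
        width=st.floats(1, 60),
        extra=st.floats(0, 20),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotonic_in_tolerance_and_band(self, tol1, tol2, band_min, width, extra):
        """Enlarging the cone or the band never removes an accessible site."""
        lo, hi = sorted((tol1, tol2))
        small = AccessibilityParams(lo, band_min, band_min + width)
        big = AccessibilityParams(hi, max(band_min - extra, 0.0), band_min + width + extra)
        zs = {z.subunit_index for z in accessible_sites_same_filament(DEFAULT, small)}
        zb = {z.subunit_index for z in accessible_sites_same_filament(DEFAULT, big)}
        assert zs <= zb

    def test_pseudo_repeat_translation(self):
        """Shifting the band by 13 subunits translates the accessible set."""
        acc = AccessibilityParams(60.0, 10.0, 40.0)
        shift = 13 * DEFAULT.rise_nm
        shifted = AccessibilityParams(60.0, 10.0 + shift, 40.0 + shift)
        a = accessible_sites_same_filament(DEFAULT, acc)
        b = accessible_sites_same_filament(DEFAULT, shifted)
        assert [z.subunit_index + 13 for z in a] == [z.subunit_index for z in b]
        assert [z.axial_nm + shift for z in a] == pytest.approx(
            [z.axial_nm for z in b]
        )

    @given(
        rise=st.floats(1.0, 6.0),
        twist=st.floats(-179.0, -30.0),
        tol=st.floats(0.0, 180.0),
        band_min=st.floats(0.0, 50.0),
        width=st.floats(1.0, 50.0),
        phase=st.floats(-180.0, 180.0),
    )
    @settings(max_examples=150, derandomize=True)
    def test_matches_brute_force_oracle(self, rise, twist, tol, band_min, width, phase):
        helix = HelixParams(rise_nm=rise, twist_deg=twist)
        acc = AccessibilityParams(tol, band_min, band_min + width)
        placement = FilamentPlacement("n", (12.0, 0.0), 0.0, phase)
        got = [
            round(z.axial_nm, 9)
            for z in accessible_sites_neighbor(helix, placement, acc)
        ]
        assert got == brute_force_sites(helix, acc, phase=placement.phase_deg)
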