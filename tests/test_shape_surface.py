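"""Pore-shape metrics, SASA point counting and surface decomposition.

SASA is checked against the closed-form sphere area, an analytic
spherical-cap occlusion oracle, and biotite's independent implementation.
"""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from poremap.model import Frame, PolarityClass, Topology
from poremap.shape import (
    PairingError,
    RadiusError,
    atom_sasa,
    buried_fraction,
    cavity_diameter,
    golden_spiral_points,
    pore_ellipticity,
    sasa,
    surface_decomposition,
)
from poremap.synth import make_pore_assembly


class TestEllipticity:
    def test_regular_hexagon_is_zero(self):
        top, frame = make_pore_assembly(6, ring_radius=24.0, stretch=1.0, seed=0)
        assert pore_ellipticity(frame, top.dimer_assignments) == pytest.approx(
            0.0, abs=1e-9)

    def test_stretched_hexagon_matches_chord_difference(self):
        r, s = 24.0, 1.2
        top, frame = make_pore_assembly(6, ring_radius=r, stretch=s, seed=0)
        angles = 2 * np.pi * np.arange(3) / 6
        chords = [2 * math.hypot(s * r * math.cos(a), r * math.sin(a))
                  for a in angles]
        expected = max(chords) - min(chords)
        assert pore_ellipticity(frame, top.dimer_assignments) == pytest.approx(
            expected, abs=1e-9)

    def test_positive_for_any_stretch_above_one(self):
        top, frame = make_pore_assembly(6, ring_radius=24.0, stretch=1.2, seed=0)
        assert pore_ellipticity(frame, top.dimer_assignments) > 0

    def test_invariant_under_rigid_rotation(self):
        top, frame = make_pore_assembly(6, ring_radius=20.0, stretch=1.15, seed=1)
        before = pore_ellipticity(frame, top.dimer_assignments)
        rot = Rotation.from_euler("xyz", [0.4, 1.1, -0.7]).as_matrix()
        moved = Frame(frame.coordinates @ rot.T + [3.0, -8.0, 2.0], frame.box)
        assert pore_ellipticity(moved, top.dimer_assignments) == pytest.approx(
            before, abs=1e-9)

    def test_odd_dimer_count_rejected(self):
        frame = Frame(np.zeros((3, 3)))
        with pytest.raises(PairingError):
            pore_ellipticity(frame, {1: [0], 2: [1], 3: [2]})


class TestCavityDiameter:
    def _ring_frame(self, radius, n=36):
        t = 2 * np.pi * np.arange(n) / n
        coords = np.column_stack([radius * np.cos(t), radius * np.sin(t),
                                  np.zeros(n)])
        return Frame(coords)

    def test_ring_of_radius_24_gives_48(self):
        frame = self._ring_frame(24.0)
        d = cavity_diameter(frame, np.arange(36))
        assert d == pytest.approx(48.0, abs=0.5)

    def test_bead_on_axis_gives_zero(self):
        frame = Frame(np.array([[0.0, 0.0, 0.0]]))
        assert cavity_diameter(frame, [0]) == 0.0

    def test_monotone_non_increasing_as_beads_added(self, rng):
        coords = self._ring_frame(20.0).coordinates
        d_prev = cavity_diameter(Frame(coords), np.arange(len(coords)))
        for _ in range(5):
            extra = rng.uniform(-15, 15, size=(1, 3))
            coords = np.vstack([coords, extra])
            d = cavity_diameter(Frame(coords), np.arange(len(coords)))
            assert d <= d_prev + 1e-9
            d_prev = d


def _uniform_topology(n, resname="ALA", name="CA"):
    return Topology([name] * n, np.arange(1, n + 1), [resname] * n)


class TestSasa:
    def test_isolated_sphere_matches_closed_form(self):
        # 4 pi (r + probe)^2 for r=1.9, probe=1.4 -> 136.85 A^2
        areas = atom_sasa(np.zeros((1, 3)), np.array([1.9]), 1.4, 960)
        assert areas[0] == pytest.approx(4 * np.pi * 3.3**2, rel=0.02)

    def test_separated_spheres_are_additive(self):
        coords = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
        areas = atom_sasa(coords, np.array([1.9, 1.5]), 1.4, 480)
        assert areas[0] == pytest.approx(4 * np.pi * 3.3**2, rel=0.02)
        assert areas[1] == pytest.approx(4 * np.pi * 2.9**2, rel=0.02)

    def test_buried_interior_particle_has_zero_area(self):
        # a central bead fully enclosed by a tight shell
        shell = 2.5 * golden_spiral_points(60)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        radii = np.full(len(coords), 1.9)
        areas = atom_sasa(coords, radii, 1.4, 480)
        assert areas[0] == 0.0

    def test_point_count_convergence_below_one_percent(self, rng):
        coords = rng.uniform(0, 10, size=(20, 3))
        radii = np.full(20, 1.9)
        a1 = atom_sasa(coords, radii, 1.4, 480).sum()
        a2 = atom_sasa(coords, radii, 1.4, 960).sum()
        assert abs(a2 - a1) / a2 < 0.01

    def test_matches_biotite_on_random_cluster(self, rng):
        import biotite.structure as struc

        n = 30
        coords = rng.uniform(0, 12, size=(n, 3))
        radii = np.full(n, 1.7)
        mine = atom_sasa(coords, radii, 1.4, 1000).sum()
        arr = struc.AtomArray(n)
        arr.coord = coords.astype(np.float32)
        arr.atom_name = np.array(["CA"] * n)
        arr.res_name = np.array(["ALA"] * n)
        arr.res_id = np.arange(1, n + 1)
        arr.chain_id = np.array(["A"] * n)
        arr.element = np.array(["C"] * n)
        theirs = struc.sasa(arr, probe_radius=1.4, vdw_radii=radii,
                            point_number=1000).sum()
        assert mine == pytest.approx(theirs, rel=0.02)

    def test_missing_radius_names_particle_type(self):
        top = Topology(["XX1"], [1], ["UNK"])
        # element guess 'X' has no tabulated radius
        with pytest.raises(RadiusError, match="X"):
            sasa(top, Frame(np.zeros((1, 3))), mode="aa")

    def test_per_residue_aggregation(self):
        top = Topology(["CA", "CB", "CA"], [1, 1, 2], ["ALA", "ALA", "GLY"])
        coords = np.array([[0, 0, 0], [3, 0, 0], [50, 0, 0]], dtype=float)
        df = sasa(top, Frame(coords), mode="aa", n_points=480)
        assert len(df) == 2
        assert set(df["resname"]) == {"ALA", "GLY"}
        assert (df["area"] > 0).all()


class TestSurfaceDecomposition:
    def _decomp(self, resnames, coords=None):
        n = len(resnames)
        top = Topology(["BB"] * n, np.arange(1, n + 1), resnames,
                       group_tags="protein")
        if coords is None:
            coords = 10.0 * golden_spiral_points(n)
        frame = Frame(np.asarray(coords))
        df = sasa(top, frame, mode="cg", n_points=240)
        return surface_decomposition(df, top)

    def test_polylysine_fully_hydrophilic(self):
        d = self._decomp(["LYS"] * 12)
        assert d.hydrophilic_fraction == pytest.approx(1.0)
        assert d.fractions["positive"] == pytest.approx(1.0)

    def test_polyleucine_fully_hydrophobic(self):
        d = self._decomp(["LEU"] * 12)
        assert d.fractions["hydrophobic"] == pytest.approx(1.0)
        assert d.hydrophilic_fraction == pytest.approx(0.0)

    def test_fractions_sum_to_one_and_areas_to_total(self):
        d = self._decomp(["LYS", "GLU", "SER", "LEU"] * 4)
        assert sum(d.fractions.values()) == pytest.approx(1.0)
        assert sum(d.areas.values()) == pytest.approx(d.total, abs=1e-6)

    def test_permutation_invariance_of_fractions(self, rng):
        resnames = ["LYS", "GLU", "SER", "LEU", "ALA", "ARG"] * 3
        coords = 10.0 * golden_spiral_points(len(resnames))
        d1 = self._decomp(resnames, coords)
        perm = rng.permutation(len(resnames))
        d2 = self._decomp([resnames[i] for i in perm], coords[perm])
        for k in d1.fractions:
            assert d1.fractions[k] == pytest.approx(d2.fractions[k], abs=1e-9)


class TestBuriedFraction:
    def test_far_separated_components_bury_nothing(self):
        top = _uniform_topology(2)
        coords = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
        pct = buried_fraction(top, Frame(coords), [0], mode="aa", n_points=480)
        assert pct == pytest.approx(0.0, abs=1e-9)

    def test_identical_overlapping_copy_buries_everything(self):
        top = _uniform_topology(2)
        coords = np.zeros((2, 3))
        pct = buried_fraction(top, Frame(coords), [0], mode="aa", n_points=480)
        assert pct == pytest.approx(100.0)

    def test_partial_occlusion_matches_spherical_cap_oracle(self):
        # two C spheres (R = 1.7 + 1.4 = 3.1) at d = 4.0: the buried share
        # of sphere A is its spherical cap inside the extended sphere B
        top = _uniform_topology(2)
        d = 4.0
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        r_ext = 1.7 + 1.4
        cos_t = (d * d + r_ext**2 - r_ext**2) / (2 * d * r_ext)
        cap_fraction = (1.0 - cos_t) / 2.0
        pct = buried_fraction(top, Frame(coords), [0], mode="aa",
                              n_points=4000)
        assert pct == pytest.approx(100.0 * cap_fraction, rel=0.02)

    def test_zero_isolated_sasa_rejected(self):
        top = _uniform_topology(0)
        with pytest.raises(ValueError):
            buried_fraction(top, Frame(np.zeros((0, 3))), [], mode="aa")
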