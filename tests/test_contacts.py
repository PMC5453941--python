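"""Contact matrices, contact-number profiles, polarity pairing and
interface counts, each checked against brute-force enumeration oracles."""

import numpy as np
import pandas as pd
import pytest

from poremap.contacts import (
    contact_matrix,
    contact_number_profiles,
    interface_counts,
    polarity_contact_fractions,
)
from poremap.model import Frame, SelectionError, Topology, Trajectory


def _beads(positions, resnames=None, group="protein", chain="A", names=None):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    resnames = resnames or ["GLY"] * n
    names = names or ["BB"] * n
    top = Topology(names, np.arange(1, n + 1), resnames, [chain] * n,
                   group_tags=group)
    return top, positions


def _two_group_traj(posA, posB, resA=None, resB=None, box=1000.0,
                    namesA=None, namesB=None):
    topA, ca = _beads(posA, resA, names=namesA)
    topB, cb = _beads(posB, resB, chain="B", names=namesB)
    top = Topology(
        names=np.concatenate([topA.names, topB.names]),
        residue_indices=np.concatenate([topA.residue_indices,
                                        topB.residue_indices]),
        residue_names=np.concatenate([topA.residue_names, topB.residue_names]),
        chain_ids=["A"] * len(ca) + ["B"] * len(cb),
    )
    coords = np.vstack([ca, cb])[None]
    traj = Trajectory(top, coords, np.array([box] * 3))
    return traj, np.arange(len(ca)), np.arange(len(ca), len(ca) + len(cb))


def naive_contact_matrix(traj, selA, selB, cutoff):
    """O(N^2) reference: per-frame double loop over residue bead pairs."""
    top = traj.topology
    keyA = top.residue_keys(selA)
    keyB = top.residue_keys(selB)
    posA = {k: [] for k in keyA}
    posB = {k: [] for k in keyB}
    for i in selA:
        posA[(str(top.chain_ids[i]), int(top.residue_indices[i]),
              str(top.residue_names[i]))].append(i)
    for i in selB:
        posB[(str(top.chain_ids[i]), int(top.residue_indices[i]),
              str(top.residue_names[i]))].append(i)
    out = np.zeros((len(keyA), len(keyB)))
    for f in range(len(traj)):
        coords = traj.coordinates[f]
        box = traj.boxes[f]
        for a, ka in enumerate(keyA):
            for b, kb in enumerate(keyB):
                hit = False
                for i in posA[ka]:
                    for j in posB[kb]:
                        d = coords[i] - coords[j]
                        d -= box * np.round(d / box)
                        if np.sqrt((d * d).sum()) < cutoff:
                            hit = True
                            break
                    if hit:
                        break
                out[a, b] += hit
    return out / len(traj)


class TestContactMatrix:
    def test_pair_within_cutoff_scores_one(self):
        traj, a, b = _two_group_traj([[0, 0, 0]], [[5, 0, 0]])
        cm = contact_matrix(traj, a, b)
        assert cm.values[0, 0] == 1.0

    def test_pair_beyond_cutoff_scores_zero(self):
        traj, a, b = _two_group_traj([[0, 0, 0]], [[7, 0, 0]])
        cm = contact_matrix(traj, a, b)
        assert cm.values[0, 0] == 0.0

    def test_matches_naive_double_loop_exactly(self, rng):
        posA = rng.uniform(0, 40, size=(30, 3))
        posB = rng.uniform(0, 40, size=(25, 3))
        traj, a, b = _two_group_traj(posA, posB, box=40.0)
        cm = contact_matrix(traj, a, b, cutoff=6.5)
        np.testing.assert_array_equal(
            cm.values, naive_contact_matrix(traj, a, b, 6.5))

    def test_transpose_symmetry(self, rng):
        posA = rng.uniform(0, 30, size=(10, 3))
        posB = rng.uniform(0, 30, size=(12, 3))
        traj, a, b = _two_group_traj(posA, posB, box=30.0)
        ab = contact_matrix(traj, a, b)
        ba = contact_matrix(traj, b, a)
        np.testing.assert_array_equal(ab.values, ba.values.T)

    def test_cutoff_monotonicity(self, rng):
        posA = rng.uniform(0, 30, size=(10, 3))
        posB = rng.uniform(0, 30, size=(12, 3))
        traj, a, b = _two_group_traj(posA, posB, box=30.0)
        small = contact_matrix(traj, a, b, cutoff=4.0).values
        large = contact_matrix(traj, a, b, cutoff=8.0).values
        assert np.all(large >= small)

    def test_minimum_image_counts_cross_boundary_contact(self):
        traj, a, b = _two_group_traj([[1.0, 5, 5]], [[29.0, 5, 5]], box=30.0)
        cm = contact_matrix(traj, a, b, cutoff=3.0)
        assert cm.values[0, 0] == 1.0

    def test_overlapping_selections_rejected(self):
        traj, a, b = _two_group_traj([[0, 0, 0]], [[5, 0, 0]])
        with pytest.raises(SelectionError):
            contact_matrix(traj, a, np.concatenate([a, b]))


class TestContactProfiles:
    def test_zero_matrix_gives_zero_profiles(self):
        traj, a, b = _two_group_traj([[0, 0, 0]], [[50, 0, 0]])
        cm = contact_matrix(traj, a, b)
        pa, pb = contact_number_profiles(cm)
        assert (pa == 0).all() and (pb == 0).all()

    def test_persistent_pair_counts_once_each_side(self):
        traj, a, b = _two_group_traj([[0, 0, 0], [100, 0, 0]], [[5, 0, 0]])
        cm = contact_matrix(traj, a, b)
        pa, pb = contact_number_profiles(cm)
        assert list(pa) == [1, 0]
        assert list(pb) == [1]

    def test_row_sums_match_recount(self, rng):
        posA = rng.uniform(0, 30, size=(15, 3))
        posB = rng.uniform(0, 30, size=(15, 3))
        traj, a, b = _two_group_traj(posA, posB, box=30.0)
        cm = contact_matrix(traj, a, b)
        pa, pb = contact_number_profiles(cm)
        np.testing.assert_array_equal(pa.values, (cm.values > 0).sum(axis=1))
        np.testing.assert_array_equal(pb.values, (cm.values > 0).sum(axis=0))


class TestPolarityFractions:
    def test_all_polar_interface_is_fully_hydrophilic(self):
        traj, a, b = _two_group_traj(
            [[0, 0, 0], [4, 0, 0]], [[2, 2, 0], [6, 2, 0]],
            resA=["LYS", "LYS"], resB=["ASP", "ASP"])
        cm = contact_matrix(traj, a, b)
        frac = polarity_contact_fractions(cm, traj.topology)
        assert frac["hydrophilic_hydrophilic"] == pytest.approx(100.0)

    def test_all_apolar_interface_is_fully_hydrophobic(self):
        traj, a, b = _two_group_traj(
            [[0, 0, 0]], [[3, 0, 0]], resA=["LEU"], resB=["VAL"])
        cm = contact_matrix(traj, a, b)
        frac = polarity_contact_fractions(cm, traj.topology)
        assert frac["hydrophobic_hydrophobic"] == pytest.approx(100.0)

    def test_mixed_fixture_matches_hand_enumeration(self, rng):
        resA = ["LYS", "LEU", "SER", "VAL", "GLU"]
        resB = ["ASP", "ILE", "THR", "ARG"]
        posA = rng.uniform(0, 20, size=(5, 3))
        posB = rng.uniform(0, 20, size=(4, 3))
        traj, a, b = _two_group_traj(posA, posB, resA=resA, resB=resB)
        cm = contact_matrix(traj, a, b, cutoff=8.0)
        frac = polarity_contact_fractions(cm, traj.topology)
        philic = {"LYS", "SER", "GLU", "ASP", "THR", "ARG"}
        tallies = {"hh": 0, "pp": 0, "mixed": 0}
        for i, ra in enumerate(resA):
            for j, rb in enumerate(resB):
                if cm.values[i, j] > 0:
                    if ra in philic and rb in philic:
                        tallies["hh"] += 1
                    elif ra not in philic and rb not in philic:
                        tallies["pp"] += 1
                    else:
                        tallies["mixed"] += 1
        total = sum(tallies.values())
        assert frac["hydrophilic_hydrophilic"] == pytest.approx(
            100.0 * tallies["hh"] / total)
        assert frac["mixed"] == pytest.approx(100.0 * tallies["mixed"] / total)
        assert sum(frac.values()) == pytest.approx(100.0)


class TestInterfaceCounts:
    def test_ideal_nh_o_geometry_counts_one_hbond(self):
        # N-H...O=C at 2.9 A donor-acceptor, ~165 degrees at H
        top = Topology(["N", "H", "O"], [1, 1, 2], ["GLY", "GLY", "GLY"],
                       ["A", "A", "B"])
        coords = np.array([[0.0, 0.0, 0.0],
                           [1.0, 0.0, 0.0],
                           [2.85, 0.25, 0.0]])
        counts = interface_counts(top, Frame(coords), [0, 1], [2])
        assert counts.h_bonds == 1

    def test_bent_geometry_rejected(self):
        top = Topology(["N", "H", "O"], [1, 1, 2], ["GLY", "GLY", "GLY"],
                       ["A", "A", "B"])
        coords = np.array([[0.0, 0.0, 0.0],
                           [1.0, 0.0, 0.0],
                           [0.0, 3.0, 0.0]])  # ~45 deg at H
        counts = interface_counts(top, Frame(coords), [0, 1], [2])
        assert counts.h_bonds == 0

    def test_salt_bridge_between_lys_and_glu(self):
        top = Topology(["NZ", "OE1"], [1, 2], ["LYS", "GLU"], ["A", "B"])
        coords = np.array([[0.0, 0.0, 0.0], [3.5, 0.0, 0.0]])
        counts = interface_counts(top, Frame(coords), [0], [1])
        assert counts.salt_bridges == 1

    def test_hydrophobic_contact_between_leu_sidechains(self):
        top = Topology(["CD1", "CD1"], [1, 2], ["LEU", "LEU"], ["A", "B"])
        coords = np.array([[0.0, 0.0, 0.0], [4.5, 0.0, 0.0]])
        counts = interface_counts(top, Frame(coords), [0], [1])
        assert counts.hydrophobic_contacts == 1

    def test_coulomb_energy_of_two_unit_charges(self):
        # 332.06 / 10 = 33.2 kcal/mol attraction for opposite unit charges
        top = Topology(["Q1", "Q2"], [1, 2], ["GLY", "GLY"], ["A", "B"])
        coords = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        params = {"Q1": (1.0, 0.0, 0.0), "Q2": (-1.0, 0.0, 0.0)}
        counts = interface_counts(top, Frame(coords), [0], [1], params)
        assert counts.elec_energy == pytest.approx(-33.2, abs=0.01)
        assert counts.vdw_energy == 0.0

    def test_missing_hydrogens_falls_back_with_warning(self, caplog):
        top = Topology(["N", "O"], [1, 2], ["GLY", "GLY"], ["A", "B"])
        coords = np.array([[0.0, 0.0, 0.0], [2.8, 0.0, 0.0]])
        with caplog.at_level("WARNING"):
            counts = interface_counts(top, Frame(coords), [0], [1])
        assert counts.h_bonds == 1
        assert any("hydrogen" in r.message.lower() for r in caplog.records)

    def test_parameter_table_accepts_dataframe(self):
        top = Topology(["Q1", "Q2"], [1, 2], ["GLY", "GLY"], ["A", "B"])
        coords = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        table = pd.DataFrame(
            [["Q1", 0.5, 3.0, 0.1], ["Q2", -0.5, 3.0, 0.1]],
            columns=["atom_name", "charge", "sigma", "epsilon"])
        counts = interface_counts(top, Frame(coords), [0], [1], table)
        assert counts.elec_energy < 0
        assert counts.vdw_energy != 0.0
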