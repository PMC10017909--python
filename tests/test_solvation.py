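import math

import numpy as np
import pytest

from dhpmd.io_formats import Frame
from dhpmd.solvation import (
    count_solvent_near,
    detect_hbonds,
    minimum_image_distance,
    sasa,
    sphere_points,
)

from conftest import make_atoms


def _protein_with_solvent(water_pos, ethanol_pos, box=(20.0, 20.0, 20.0)):
    """One protein CA plus single-atom-anchored 3-atom solvent molecules."""
    positions = [[10.0, 10.0, 10.0]]
    elements = ["C"]
    names = ["CA"]
    res_idx = [1]
    res_names = ["ALA"]
    classes = ["protein"]
    res = 2
    for p in water_pos:
        for off, nm, el in (((0, 0, 0), "OW", "O"), ((0.5, 0, 0), "HW1", "H"),
                            ((0, 0.5, 0), "HW2", "H")):
            positions.append(list(np.add(p, off)))
            names.append(nm)
            elements.append(el)
            res_idx.append(res)
            res_names.append("HOH")
            classes.append("water")
        res += 1
    for p in ethanol_pos:
        for off, nm in (((0, 0, 0), "C1"), ((1.0, 0, 0), "C2"), ((1.5, 0.5, 0), "OH")):
            positions.append(list(np.add(p, off)))
            names.append(nm)
            elements.append("C" if nm.startswith("C") else "O")
            res_idx.append(res)
            res_names.append("ETH")
            classes.append("ethanol")
        res += 1
    return make_atoms(positions, elements=elements, atom_names=names,
                      residue_indices=res_idx, residue_names=res_names,
                      molecule_classes=classes, box=box)


class TestSolventCounting:
    def test_no_solvent(self):
        topology, frame = _protein_with_solvent([], [])
        c = count_solvent_near(frame, topology, [0], cutoff=5.0)
        assert (c.n_water, c.n_ethanol) == (0, 0)

    def test_distance_thresholding(self):
        topology, frame = _protein_with_solvent(
            water_pos=[[13.0, 10.0, 10.0]],      # 3 Å away
            ethanol_pos=[[16.0, 10.0, 10.0]],    # 6 Å away
        )
        c = count_solvent_near(frame, topology, [0], cutoff=5.0)
        assert (c.n_water, c.n_ethanol) == (1, 0)
        c8 = count_solvent_near(frame, topology, [0], cutoff=8.0)
        assert (c8.n_water, c8.n_ethanol) == (1, 1)

    def test_minimum_image_counting_across_boundary(self):
        # site at x=0.2, water O at x=9.7 in a 10 Å box: distance 0.5 Å
        topology, frame = _protein_with_solvent([], [], box=(10.0, 10.0, 10.0))
        topology2, frame2 = _protein_with_solvent(
            water_pos=[[9.7, 5.0, 5.0]], ethanol_pos=[], box=(10.0, 10.0, 10.0)
        )
        coords = frame2.coordinates.copy()
        coords[0] = [0.2, 5.0, 5.0]
        frame2 = Frame(0.0, coords, frame2.box)
        c = count_solvent_near(frame2, topology2, [0], cutoff=5.0)
        assert c.n_water == 1

    def test_molecule_counted_once_even_with_many_close_atoms(self):
        topology, frame = _protein_with_solvent([[12.0, 10.0, 10.0]], [])
        c = count_solvent_near(frame, topology, [0], cutoff=4.0)
        assert c.n_water == 1

    def test_counts_invariant_under_box_translation(self):
        topology, frame = _protein_with_solvent(
            [[13.0, 10.0, 10.0], [2.0, 2.0, 2.0]], [[16.0, 10.0, 10.0]]
        )
        base = count_solvent_near(frame, topology, [0], cutoff=5.0)
        moved = Frame(0.0, frame.coordinates + [7.3, 15.9, -4.2], frame.box)
        shifted = count_solvent_near(moved, topology, [0], cutoff=5.0)
        assert (base.n_water, base.n_ethanol) == (shifted.n_water, shifted.n_ethanol)

    def test_minimum_image_distance_matrix(self):
        box = np.array([10.0, 10.0, 10.0])
        d = minimum_image_distance(
            np.array([[9.5, 0.0, 0.0]]), np.array([[0.5, 0.0, 0.0]]), box
        )
        assert d[0, 0] == pytest.approx(1.0)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        topology, frame = make_atoms([[10.0, 10.0, 10.0]], elements=["O"],
                                     residue_names=["ALA"])
        area = sasa(frame, topology, probe_radius=1.4, n_sphere_points=960)
        expected = 4.0 * math.pi * (1.52 + 1.4) ** 2
        assert area.total == pytest.approx(expected, rel=1e-6)
        assert area.hydrophilic == pytest.approx(expected, rel=1e-6)
        assert area.hydrophobic == 0.0

    def test_tangent_spheres_unoccluded(self):
        r = 1.70 + 1.4
        topology, frame = make_atoms(
            [[10.0, 10.0, 10.0], [10.0 + 2 * r, 10.0, 10.0]],
            elements=["C", "C"], residue_names=["ALA", "ALA"], box=(40, 40, 40),
        )
        area = sasa(frame, topology, probe_radius=1.4, n_sphere_points=960)
        assert area.total == pytest.approx(2 * 4 * math.pi * r**2, rel=1e-6)

    @pytest.mark.parametrize("d_over_2r", [0.3, 0.6, 0.9])
    def test_overlapping_spheres_match_cap_formula(self, d_over_2r):
        # two equal expanded spheres of radius R at distance d < 2R:
        # exposed area per sphere = 4πR² − 2πR·h with cap height h = R − d/2
        R = 1.70 + 1.4
        d = 2 * R * d_over_2r
        topology, frame = make_atoms(
            [[10.0, 10.0, 10.0], [10.0 + d, 10.0, 10.0]],
            elements=["C", "C"], residue_names=["ALA", "ALA"], box=(40, 40, 40),
        )
        area = sasa(frame, topology, probe_radius=1.4, n_sphere_points=960)
        h = R - d / 2
        expected = 2 * (4 * math.pi * R**2 - 2 * math.pi * R * h)
        assert area.total == pytest.approx(expected, rel=0.01)

    def test_buried_atom_has_zero_area(self):
        # central atom enclosed by an octahedral shell of overlapping neighbours
        shell = 2.0
        positions = [[10.0, 10.0, 10.0]]
        for axis in range(3):
            for sign in (-1, 1):
                p = [10.0, 10.0, 10.0]
                p[axis] += sign * shell
                positions.append(p)
        topology, frame = make_atoms(positions, elements=["N"] + ["C"] * 6,
                                     residue_names=["ALA"] * 7, box=(40, 40, 40))
        full = sasa(frame, topology, probe_radius=1.4, n_sphere_points=960)
        buried = full.hydrophilic  # only atom 0 is polar
        assert buried == pytest.approx(0.0, abs=1e-9)

    def test_removing_neighbour_never_decreases_area(self):
        rng = np.random.default_rng(6)
        positions = 10.0 + rng.uniform(-2.0, 2.0, (6, 3))
        topology, frame = make_atoms(positions, elements=["C"] * 6,
                                     residue_names=["ALA"] * 6, box=(40, 40, 40))
        with_all = sasa(frame, topology, n_sphere_points=480)
        topology5, frame5 = make_atoms(positions[:5], elements=["C"] * 5,
                                       residue_names=["ALA"] * 5, box=(40, 40, 40))
        without = sasa(frame5, topology5, n_sphere_points=480)
        assert without.total / 5 >= with_all.total / 6 - 1e-9

    def test_sphere_points_unit_norm(self):
        pts = sphere_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)


def _hbond_system(da_distance, angle_deg):
    """Donor N with H pointing at acceptor O placed to give the requested
    D–H…A angle (180° = linear)."""
    donor = np.array([10.0, 10.0, 10.0])
    hydrogen = donor + [1.0, 0.0, 0.0]
    theta = math.radians(180.0 - angle_deg)
    direction = np.array([math.cos(theta), math.sin(theta), 0.0])
    acceptor = hydrogen + (da_distance - 1.0) * direction
    return make_atoms(
        [donor, hydrogen, acceptor],
        elements=["N", "H", "O"],
        atom_names=["N", "H", "O"],
        residue_indices=[1, 1, 2],
        residue_names=["ALA", "ALA", "ALA"],
        box=(30, 30, 30),
    )


class TestHbonds:
    def test_linear_bond_detected(self):
        topology, frame = _hbond_system(2.9, 180.0)
        bonds = detect_hbonds(frame, topology, donors=[0], acceptors=[2])
        assert len(bonds) == 1
        assert (bonds[0].donor, bonds[0].acceptor) == (0, 2)

    def test_long_distance_rejected(self):
        topology, frame = _hbond_system(4.0, 180.0)
        assert detect_hbonds(frame, topology, donors=[0], acceptors=[2]) == []

    def test_bent_geometry_rejected(self):
        topology, frame = _hbond_system(2.9, 140.0)
        assert detect_hbonds(frame, topology, donors=[0], acceptors=[2]) == []

    def test_donor_without_hydrogen_skipped_with_warning(self):
        topology, frame = make_atoms(
            [[10, 10, 10], [12.9, 10, 10]],
            elements=["N", "O"], atom_names=["N", "O"],
            residue_indices=[1, 2], residue_names=["ALA", "ALA"], box=(30, 30, 30),
        )
        with pytest.warns(UserWarning, match="no attached hydrogen"):
            bonds = detect_hbonds(frame, topology, donors=[0], acceptors=[1])
        assert bonds == []

    def test_matches_brute_force_on_random_geometry(self):
        rng = np.random.default_rng(17)
        n_donors = 25
        positions = []
        donors = []
        acceptors = []
        for i in range(n_donors):
            d = rng.uniform(5.0, 25.0, 3)
            h = d + _unit(rng)
            positions.extend([d, h])
            donors.append(2 * i)
        for _ in range(25):
            acceptors.append(len(positions))
            positions.append(rng.uniform(5.0, 25.0, 3))
        elements = ["N", "H"] * n_donors + ["O"] * 25
        names = list(elements)
        topology, frame = make_atoms(
            positions, elements=elements, atom_names=names,
            residue_indices=list(range(1, len(positions) + 1)),
            residue_names=["ALA"] * len(positions), box=(60, 60, 60),
        )
        bonds = detect_hbonds(frame, topology, donors, acceptors,
                              max_da_distance=3.5, max_dha_angle=30.0)
        got = {(b.donor, b.acceptor) for b in bonds}

        expected = set()
        coords = frame.coordinates
        for d_i in donors:
            h_i = d_i + 1
            for a_i in acceptors:
                if np.linalg.norm(coords[a_i] - coords[d_i]) > 3.5:
                    continue
                v1 = coords[d_i] - coords[h_i]
                v2 = coords[a_i] - coords[h_i]
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if 180.0 - angle <= 30.0:
                    expected.add((d_i, a_i))
        assert got == expected


def _unit(rng):
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)
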