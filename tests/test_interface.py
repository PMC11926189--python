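import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import gemmi

from ribotrace.interface import (
    DEFAULT_PROBE,
    VDW_RADII,
    Structure,
    buried_area,
    classify_binders,
    contact_residues,
    dual_site_report,
    golden_spiral_points,
    load_structure,
    sasa,
    superpose_rmsd,
)


def build_gemmi(chains: dict, altlocs=()):
    """chains: chain_id -> list of (resnum, resname, atom, element, xyz)."""
    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model("1")
    for cid, atoms in chains.items():
        ch = gemmi.Chain(cid)
        residues = {}
        for resnum, resname, aname, element, xyz in atoms:
            if resnum not in residues:
                r = gemmi.Residue()
                r.name = resname
                r.seqid = gemmi.SeqId(resnum, " ")
                residues[resnum] = r
            a = gemmi.Atom()
            a.name = aname
            a.element = gemmi.Element(element)
            a.pos = gemmi.Position(*xyz)
            a.occ = 1.0
            residues[resnum].add_atom(a)
        for r in residues.values():
            ch.add_residue(r)
        model.add_chain(ch)
    for cid, resnum, aname, element, xyz, occ, alt in altlocs:
        a = gemmi.Atom()
        a.name = aname
        a.element = gemmi.Element(element)
        a.pos = gemmi.Position(*xyz)
        a.occ = occ
        a.altloc = alt
        for ch in model:
            if ch.name == cid:
                ch[0].add_atom(a)
    st.add_model(model)
    st.setup_entities()
    return st


class TestLoadStructure:
    def test_hand_written_three_atom_pdb(self, tmp_path):
        st = build_gemmi({"A": [
            (1, "GLY", "N", "N", (1.0, 2.0, 3.0)),
            (1, "GLY", "CA", "C", (2.5, 2.0, 3.0)),
            (1, "GLY", "O", "O", (3.5, 1.0, 3.0)),
        ]})
        p = tmp_path / "toy.pdb"
        st.write_pdb(str(p))
        loaded = load_structure(p)
        assert len(loaded) == 3
        np.testing.assert_allclose(
            loaded.atoms[["x", "y", "z"]].to_numpy(),
            [[1, 2, 3], [2.5, 2, 3], [3.5, 1, 3]], atol=1e-3)
        assert list(loaded.atoms["element"]) == ["N", "C", "O"]

    def test_mmcif_and_pdb_load_identically(self, tmp_path):
        st = build_gemmi({"A": [
            (1, "ALA", "CA", "C", (0.0, 0.0, 0.0)),
            (2, "ALA", "CA", "C", (3.8, 0.0, 0.0)),
        ], "B": [(5, "GLY", "CA", "C", (10.0, 0.0, 0.0))]})
        p_pdb = tmp_path / "toy.pdb"
        p_cif = tmp_path / "toy.cif"
        st.write_pdb(str(p_pdb))
        st.make_mmcif_document().write_file(str(p_cif))
        a = load_structure(p_pdb).atoms
        b = load_structure(p_cif).atoms
        np.testing.assert_allclose(a[["x", "y", "z"]], b[["x", "y", "z"]], atol=1e-3)
        assert list(a["chain"]) == list(b["chain"])
        assert list(a["resnum"]) == list(b["resnum"])

    def test_altloc_resolves_to_highest_occupancy(self, tmp_path):
        st = build_gemmi(
            {"A": [(1, "SER", "N", "N", (0.0, 0.0, 0.0))]},
            altlocs=[("A", 1, "OG", "O", (1.0, 0.0, 0.0), 0.6, "A"),
                     ("A", 1, "OG", "O", (9.0, 0.0, 0.0), 0.4, "B")],
        )
        p = tmp_path / "alt.pdb"
        st.write_pdb(str(p))
        loaded = load_structure(p)
        og = loaded.atoms[loaded.atoms["atom"] == "OG"]
        assert len(og) == 1
        assert og.iloc[0]["x"] == pytest.approx(1.0, abs=1e-3)

    def test_waters_excluded_by_default(self, tmp_path):
        st = build_gemmi({"A": [(1, "ALA", "CA", "C", (0.0, 0.0, 0.0))],
                          "W": [(1, "HOH", "O", "O", (5.0, 0.0, 0.0))]})
        p = tmp_path / "wat.pdb"
        st.write_pdb(str(p))
        assert load_structure(p).chains == ["A"]

    def test_unknown_element_warns_and_defaults(self, tmp_path):
        st = build_gemmi({"A": [(1, "UNK", "X1", "X", (0.0, 0.0, 0.0))]})
        p = tmp_path / "unk.pdb"
        st.write_pdb(str(p))
        with pytest.warns(UserWarning, match="unknown element"):
            loaded = load_structure(p)
        assert loaded.atoms.iloc[0]["radius"] == 1.70


class TestSasa:
    def test_isolated_carbon_matches_sphere_area(self):
        r = VDW_RADII["C"] + DEFAULT_PROBE
        area = sasa(np.zeros((1, 3)), np.array([VDW_RADII["C"]]))
        assert area[0] == pytest.approx(4 * np.pi * r**2, rel=0.01)  # ~120.76

    def test_fully_engulfed_atom_has_zero_area(self):
        # O (inflated 2.92) centred inside C (inflated 3.10)
        areas = sasa(np.zeros((2, 3)), np.array([VDW_RADII["C"], VDW_RADII["O"]]))
        assert areas[1] == 0.0

    def test_two_sphere_overlap_matches_spherical_cap(self):
        d = 3.0
        R = VDW_RADII["C"] + DEFAULT_PROBE
        areas = sasa(np.array([[0.0, 0, 0], [d, 0, 0]]),
                     np.full(2, VDW_RADII["C"]))
        cap = 2 * np.pi * R * (R - d / 2)  # area each sphere loses
        expected = 4 * np.pi * R**2 - cap
        assert areas[0] == pytest.approx(expected, rel=0.02)
        assert areas[1] == pytest.approx(expected, rel=0.02)

    def test_spiral_points_are_unit_and_well_spread(self):
        pts = golden_spiral_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert np.abs(pts.mean(axis=0)).max() < 0.01


def helix_coords(n=80, noise=None, rng=None):
    t = np.linspace(0, 4 * np.pi, n)
    X = np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * t])
    if noise is not None:
        X = X + rng.normal(0, noise, X.shape)
    return X


class TestSuperpose:
    def test_identical_sets_have_zero_rmsd(self):
        A = helix_coords()
        _, _, rmsd = superpose_rmsd(A, A)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rigidly_moved_copy_has_zero_rmsd(self):
        A = helix_coords()
        R0 = Rotation.from_euler("zyx", [90, 30, -40], degrees=True).as_matrix()
        B = A @ R0.T + np.array([10.0, -5.0, 3.0])
        R, t, rmsd = superpose_rmsd(A, B)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(R, R0, atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_noisy_copy_matches_library_oracle(self):
        rng = np.random.default_rng(17)
        A = helix_coords()
        R0 = Rotation.from_rotvec([0.4, -0.2, 0.9]).as_matrix()
        B = A @ R0.T + np.array([3.0, 1.0, -2.0]) + rng.normal(0, 0.5, A.shape)
        _, _, rmsd = superpose_rmsd(A, B)
        # independent solver for the same least-squares problem
        rot, rssd = Rotation.align_vectors(B - B.mean(0), A - A.mean(0))
        assert rmsd == pytest.approx(rssd / np.sqrt(len(A)), abs=1e-9)
        # and the fit cannot be beaten by nearby rigid motions
        base = ((A @ rot.as_matrix().T + (B.mean(0) - rot.apply(A.mean(0)))) - B)
        assert rmsd <= np.sqrt((base**2).sum() / len(A)) + 1e-9

    def test_rmsd_invariant_to_global_motion_of_either_input(self):
        rng = np.random.default_rng(18)
        A = helix_coords(noise=0.3, rng=rng)
        B = helix_coords()
        _, _, r0 = superpose_rmsd(A, B)
        G = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        _, _, r1 = superpose_rmsd(A @ G.T + 5.0, B)
        _, _, r2 = superpose_rmsd(A, B @ G.T - 2.0)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert r2 == pytest.approx(r0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            superpose_rmsd(line, line)
        with pytest.raises(ValueError, match="at least 3"):
            superpose_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


def two_chain_structure(gap: float) -> Structure:
    """Two 4-atom carbon chains separated along x by ``gap``."""
    import pandas as pd

    rows = []
    for i, cid in enumerate(("A", "B")):
        for j in range(4):
            rows.append((cid, j + 1, "", "ALA", "CA", "C",
                         i * gap + 0.0, j * 1.8, 0.0, 1.0, VDW_RADII["C"]))
    atoms = pd.DataFrame(rows, columns=[
        "chain", "resnum", "icode", "resname", "atom", "element",
        "x", "y", "z", "occupancy", "radius"])
    return Structure(atoms, provenance="synthetic toy")


class TestBuriedArea:
    def test_distant_chains_bury_nothing(self):
        rep = buried_area(two_chain_structure(gap=50.0), "A")
        assert rep.buried_area_total == pytest.approx(0.0, abs=1e-9)
        assert rep.contact_residues == set()

    def test_two_overlapping_atoms_match_cap_closed_form(self):
        import pandas as pd

        d = 3.0
        R = VDW_RADII["C"] + DEFAULT_PROBE
        atoms = pd.DataFrame({
            "chain": ["A", "B"], "resnum": [1, 1], "icode": ["", ""],
            "resname": ["ALA", "ALA"], "atom": ["CA", "CA"],
            "element": ["C", "C"], "x": [0.0, d], "y": [0.0, 0.0],
            "z": [0.0, 0.0], "occupancy": [1.0, 1.0],
            "radius": [VDW_RADII["C"]] * 2})
        rep = buried_area(Structure(atoms), "A")
        expected = 2 * (2 * np.pi * R * (R - d / 2))  # both caps
        assert rep.buried_area_total == pytest.approx(expected, rel=0.02)

    def test_point_density_refinement_oracle(self):
        st = two_chain_structure(gap=4.5)
        coarse = buried_area(st, "A", n_points=960).buried_area_total
        fine = buried_area(st, "A", n_points=10_000).buried_area_total
        assert coarse == pytest.approx(fine, rel=0.02)

    def test_sasa_subadditive_and_buried_nonnegative(self):
        st = two_chain_structure(gap=5.0)
        rep = buried_area(st, "A")
        assert rep.buried_area_total >= 0
        assert rep.sasa_query_in_complex <= rep.sasa_query_alone + 1e-9
        assert sum(rep.buried_area_by_partner_chain.values()) <= rep.buried_area_total + 1e-6


def test_neighborhood_shell_preserves_buried_area():
    import pandas as pd

    from ribotrace.interface import neighborhood

    rng = np.random.default_rng(29)
    rows = []
    for j in range(4):  # small query chain
        rows.append(("A", j + 1, "", "ALA", "CA", "C", 4.0, j * 1.8, 0.0, 1.0, 1.7))
    for j in range(60):  # long partner chain, mostly far from A
        rows.append(("B", j + 1, "", "GLY", "CA", "C",
                     0.0, j * 1.8 - 20.0, 0.0, 1.0, 1.7))
    atoms = pd.DataFrame(rows, columns=[
        "chain", "resnum", "icode", "resname", "atom", "element",
        "x", "y", "z", "occupancy", "radius"])
    st = Structure(atoms)
    full = buried_area(st, "A")
    shell = buried_area(neighborhood(st, ["A"], margin=15.0), "A")
    assert len(shell.buried_area_by_partner_chain) == 1
    assert shell.buried_area_total == pytest.approx(full.buried_area_total, abs=1e-9)
    assert shell.contact_residues == full.contact_residues


class TestContacts:
    @pytest.mark.parametrize("offset,expected", [(3.9, True), (4.1, False)])
    def test_cutoff_boundary(self, offset, expected):
        import pandas as pd

        atoms = pd.DataFrame({
            "chain": ["A", "B"], "resnum": [1, 9], "icode": ["", ""],
            "resname": ["ALA", "GLY"], "atom": ["CA", "CA"],
            "element": ["C", "C"], "x": [0.0, offset], "y": [0.0] * 2,
            "z": [0.0] * 2, "occupancy": [1.0] * 2, "radius": [1.7] * 2})
        got = contact_residues(Structure(atoms), "A", cutoff=4.0)
        assert ((1, "ALA") in got) == expected

    def test_matches_brute_force_all_pairs_scan(self):
        rng = np.random.default_rng(23)
        import pandas as pd

        n = 60
        atoms = pd.DataFrame({
            "chain": rng.choice(["A", "B", "C"], n),
            "resnum": rng.integers(1, 12, n), "icode": [""] * n,
            "resname": ["ALA"] * n, "atom": ["CA"] * n, "element": ["C"] * n,
            "x": rng.uniform(0, 25, n), "y": rng.uniform(0, 25, n),
            "z": rng.uniform(0, 25, n), "occupancy": np.ones(n),
            "radius": np.full(n, 1.7)})
        st = Structure(atoms)
        got = {r for r, _ in contact_residues(st, "A", cutoff=4.0)}
        q = atoms[atoms["chain"] == "A"]
        other = atoms[atoms["chain"] != "A"]
        want = set()
        for _, qa in q.iterrows():
            for _, oa in other.iterrows():
                d = np.linalg.norm([qa.x - oa.x, qa.y - oa.y, qa.z - oa.z])
                if d <= 4.0:
                    want.add(int(qa.resnum))
        assert got == want

    def test_contact_sets_grow_with_cutoff(self):
        st = two_chain_structure(gap=4.5)
        small = contact_residues(st, "A", cutoff=3.0)
        large = contact_residues(st, "A", cutoff=6.0)
        assert small <= large

    def test_classify_binders_partition(self):
        classes = classify_binders({(1, "ALA"), (2, "GLY"), (3, "LYS")},
                                   {(2, "GLY"), (4, "ARG")})
        assert classes == {"a_only": {1, 3}, "b_only": {4}, "shared": {2}}


class TestDualSiteReport:
    @pytest.fixture()
    def assembly(self, tmp_path):
        """Synthetic dual-binding-site assembly: one 3-residue protein
        present as chains Q (bound to S at all 3 residues) and R (a rigid
        copy bound to L at residue 1 and U at residue 2)."""
        protein = [
            (1, "LYS", "CA", "C", (0.0, 0.0, 0.0)),
            (2, "ARG", "CA", "C", (3.8, 0.0, 0.0)),
            (3, "HIS", "CA", "C", (5.0, 3.0, 0.0)),
        ]
        shift = np.array([60.0, 0.0, 0.0])
        copy = [(n, rn, an, el, tuple(np.add(x, shift))) for n, rn, an, el, x in protein]
        near = lambda xyz, dy: (xyz[0], xyz[1] + dy, xyz[2])
        st = build_gemmi({
            "Q": protein,
            "S": [(i, "U", "P", "P", near(protein[i - 1][4], 3.5)) for i in (1, 2, 3)],
            "R": copy,
            "L": [(1, "U", "P", "P", near(copy[0][4], 3.5))],
            "U": [(7, "GLU", "CA", "C", near(copy[1][4], -3.5))],
        })
        p = tmp_path / "assembly.pdb"
        st.write_pdb(str(p))
        return load_structure(p)

    def test_rigid_copy_gives_zero_rmsd_and_site_classification(self, assembly):
        rep = dual_site_report(assembly, "Q", "R")
        assert rep["n_paired_ca"] == 3
        assert rep["ca_rmsd_A"] == pytest.approx(0.0, abs=1e-6)
        assert {r for r, _ in rep["site_a"].contact_residues} == {1, 2, 3}
        assert {r for r, _ in rep["site_b"].contact_residues} == {1, 2}
        assert rep["binder_classes"] == {"a_only": {3}, "b_only": set(), "shared": {1, 2}}
        # site A buries more than site B (three partner contacts vs two)
        assert rep["site_a"].buried_area_total > rep["site_b"].buried_area_total
        assert set(rep["site_b"].buried_area_by_partner_chain) == {"S", "L", "U"}
        assert rep["site_b"].buried_area_by_partner_chain["S"] == pytest.approx(0.0, abs=1e-9)
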