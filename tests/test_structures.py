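"""Structure parsing, superposition, RMSD matrices, and ensemble clustering."""

import itertools

import numpy as np
import pytest

from ensemblevs.structures import (
    AtomRecord,
    DistanceMatrix,
    PDBParseError,
    StructureModel,
    extract_binding_site,
    kabsch_superpose,
    pairwise_rmsd_matrix,
    parse_pdb,
    select_representatives,
    upgma_cluster,
    write_pdb,
)
from conftest import random_rotation

MINI_PDB = """\
REMARK   2 RESOLUTION.    2.30 ANGSTROMS.
ATOM      1  CA  ALA A   1      11.000  12.000  13.000  1.00  0.00           C
HETATM    2  O1  LIG A 900      11.500  12.500  13.500  1.00  0.00           O
HETATM    3  O   HOH A 901       0.000   0.000   0.000  1.00  0.00           O
END
"""


def _atom(serial, name, resnum, xyz, resname="ALA", element=None, chain="A"):
    return AtomRecord(
        serial=serial, name=name, residue_name=resname, chain=chain,
        residue_number=resnum, element=element or name[0], xyz=tuple(xyz),
    )


def _model(mid, coords, resolution=2.0, ligand=None):
    atoms = [_atom(i + 1, "CA", i + 1, c) for i, c in enumerate(coords)]
    het = [_atom(1000 + i, "O1", 900, c, resname="LIG", element="O")
           for i, c in enumerate(ligand or [])]
    return StructureModel(id=mid, resolution=resolution, atoms=atoms, het_ligand=het)


class TestParsePDB:
    def test_minimal_file(self):
        m = parse_pdb(MINI_PDB, model_id="4WWO")
        assert len(m.atoms) == 1
        assert len(m.het_ligand) == 1  # water dropped
        assert m.resolution == 2.30
        assert m.atoms[0].xyz == (11.0, 12.0, 13.0)

    def test_roundtrip_preserves_coordinates(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(-50, 50, size=(20, 3))
        m = _model("RT01", coords, ligand=[(1.0, 2.0, 3.0)])
        m2 = parse_pdb(write_pdb(m), model_id="RT01")
        np.testing.assert_allclose(m2.coords(), m.coords(), atol=1e-3)
        np.testing.assert_allclose(
            [a.xyz for a in m2.het_ligand], [a.xyz for a in m.het_ligand], atol=1e-3
        )

    def test_malformed_coordinate_names_line(self):
        bad = MINI_PDB.replace("11.000", "12.3A4")
        with pytest.raises(PDBParseError, match="line 2"):
            parse_pdb(bad)

    def test_no_atoms_is_error(self):
        with pytest.raises(PDBParseError):
            parse_pdb("REMARK hello\nEND\n")

    def test_missing_resolution_requires_override(self):
        text = "\n".join(MINI_PDB.splitlines()[1:])
        with pytest.raises(PDBParseError, match="resolution"):
            parse_pdb(text)
        assert parse_pdb(text, resolution=1.9).resolution == 1.9

    def test_ligand_code_filter(self):
        m = parse_pdb(MINI_PDB, ligand_code="XYZ")
        assert m.het_ligand == []


class TestBindingSite:
    def test_inclusive_boundary(self):
        m = _model("BND1", [(0.0, 0.0, 9.99), (0.0, 0.0, 10.01)], ligand=[(0.0, 0.0, 0.0)])
        site = extract_binding_site(m, cutoff=10.0)
        assert ("A", 1) in site
        assert ("A", 2) not in site

    def test_zero_cutoff_needs_exact_overlap(self):
        m = _model("BND2", [(0.0, 0.0, 1.0)], ligand=[(0.0, 0.0, 0.0)])
        assert extract_binding_site(m, cutoff=0.0) == set()
        m2 = _model("BND3", [(0.0, 0.0, 0.0)], ligand=[(0.0, 0.0, 0.0)])
        assert extract_binding_site(m2, cutoff=0.0) == {("A", 1)}

    def test_empty_ligand_is_error(self):
        m = _model("BND4", [(0.0, 0.0, 0.0)])
        with pytest.raises(ValueError):
            extract_binding_site(m)


def quaternion_rmsd(P, Q):
    """Independent minimum-RMSD oracle via the quaternion characteristic
    polynomial (largest eigenvalue of the Davenport K matrix)."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K).max()
    n = len(P)
    msd = max(((P**2).sum() + (Q**2).sum() - 2.0 * lam) / n, 0.0)
    return float(np.sqrt(msd))


class TestKabsch:
    def test_identity(self):
        rng = np.random.default_rng(1)
        P = rng.standard_normal((8, 3))
        _, _, rmsd = kabsch_superpose(P, P)
        assert rmsd <= 1e-10

    def test_rigid_invariance(self):
        rng = np.random.default_rng(2)
        P = rng.standard_normal((10, 3))
        R = random_rotation(rng)
        Q = P @ R.T + np.array([3.0, -2.0, 7.0])
        rot, _, rmsd = kabsch_superpose(P, Q)
        assert rmsd <= 1e-8
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            P = rng.standard_normal((10, 3))
            Q = P + rng.normal(0.0, 0.5, size=(10, 3))
            _, _, rmsd = kabsch_superpose(P, Q)
            assert rmsd == pytest.approx(quaternion_rmsd(P, Q), abs=1e-6)

    def test_rotation_always_proper(self):
        # reflection-like target must still give det +1
        rng = np.random.default_rng(4)
        P = rng.standard_normal((6, 3))
        Q = P.copy()
        Q[:, 0] = -Q[:, 0]
        rot, _, _ = kabsch_superpose(P, Q)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_or_collinear_points(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestPairwiseRMSD:
    def _models(self, rng, n=5, n_atoms=8):
        base = rng.standard_normal((n_atoms, 3)) * 5
        out = []
        for i in range(n):
            coords = base + rng.normal(0, 0.3, size=base.shape)
            out.append(_model(f"M{i:03d}", coords))
        return out

    def test_identical_models_zero_offdiagonal(self):
        rng = np.random.default_rng(5)
        coords = rng.standard_normal((6, 3))
        models = [_model("A001", coords), _model("B001", coords)]
        site = {("A", i + 1) for i in range(6)}
        d = pairwise_rmsd_matrix(models, site)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_symmetry_and_duplicate_consistency(self):
        rng = np.random.default_rng(6)
        models = self._models(rng, n=4)
        # model 3 duplicates model 1
        models.append(_model("M900", models[1].coords()))
        site = {("A", i + 1) for i in range(8)}
        d = pairwise_rmsd_matrix(models, site)
        assert np.allclose(d.values, d.values.T)
        np.testing.assert_allclose(d.values[0, 1], d.values[0, 4], atol=1e-10)

    def test_missing_residue_reported(self):
        rng = np.random.default_rng(7)
        models = self._models(rng, n=2, n_atoms=5)
        site = {("A", i + 1) for i in range(5)} | {("A", 99)}
        with pytest.raises(ValueError, match="99"):
            pairwise_rmsd_matrix(models, site)


def brute_force_upgma(ids, D, k):
    """Average-linkage by explicit recomputation over all merge steps."""
    clusters = {i: frozenset([ids[i]]) for i in range(len(ids))}
    index = {cid: i for i, cid in enumerate(ids)}
    sets = [frozenset([i]) for i in ids]
    while len(sets) > k:
        best = None
        for a, b in itertools.combinations(sorted(sets, key=lambda s: min(s)), 2):
            dist = np.mean([D[index[x], index[y]] for x in a for y in b])
            key = (dist, min(a), min(b)) if min(a) < min(b) else (dist, min(b), min(a))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        sets.remove(a)
        sets.remove(b)
        sets.append(a | b)
    return {frozenset(s) for s in sets}


class TestUPGMA:
    def test_k_equals_n_all_singletons(self):
        ids = ["A", "B", "C"]
        D = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        a = upgma_cluster(DistanceMatrix(ids, D), k=3)
        assert a.k == 3
        assert len(set(a.labels.values())) == 3

    def test_two_blocks_recovered(self):
        ids = ["A", "B", "C", "D"]
        D = np.zeros((4, 4))
        for i in (0, 1):
            for j in (2, 3):
                D[i, j] = D[j, i] = 10.0
        a = upgma_cluster(DistanceMatrix(ids, D), k=2)
        assert a.labels["A"] == a.labels["B"]
        assert a.labels["C"] == a.labels["D"]
        assert a.labels["A"] != a.labels["C"]

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_agrees_with_brute_force(self, k):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = 4
            ids = [f"S{i}" for i in range(n)]
            D = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            D[iu] = rng.uniform(1, 10, size=len(iu[0]))
            D = D + D.T
            a = upgma_cluster(DistanceMatrix(ids, D), k=k)
            got = {frozenset(a.members(c)) for c in range(1, k + 1)}
            assert got == brute_force_upgma(ids, D, k)

    def test_matches_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(9)
        n = 12
        pts = rng.standard_normal((n, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"S{i:02d}" for i in range(n)]
        for k in (2, 4, 6):
            ours = upgma_cluster(DistanceMatrix(ids, D), k=k)
            ref = fcluster(linkage(squareform(D), method="average"), k, criterion="maxclust")
            got = {frozenset(ours.members(c)) for c in range(1, k + 1)}
            want = {frozenset(ids[i] for i in np.flatnonzero(ref == c)) for c in set(ref)}
            assert got == want

    def test_determinism_and_k1(self):
        ids = ["A", "B", "C", "D", "E"]
        rng = np.random.default_rng(10)
        D = np.zeros((5, 5))
        iu = np.triu_indices(5, 1)
        D[iu] = rng.uniform(1, 5, size=len(iu[0]))
        D = D + D.T
        dm = DistanceMatrix(ids, D)
        assert upgma_cluster(dm, 1).labels == {i: 1 for i in ids}
        assert upgma_cluster(dm, 3).labels == upgma_cluster(dm, 3).labels

    def test_k_out_of_range(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            upgma_cluster(dm, 3)


class TestRepresentatives:
    def test_highest_resolution_wins(self):
        from ensemblevs.structures import ClusterAssignment

        a = ClusterAssignment(labels={"2A5U": 1, "4WWO": 1}, k=1)
        assert select_representatives(a, {"2A5U": 2.70, "4WWO": 2.30}) == ["4WWO"]

    def test_singleton_and_tie(self):
        from ensemblevs.structures import ClusterAssignment

        a = ClusterAssignment(labels={"AAAA": 1, "CCCC": 1, "SOLO": 2}, k=2)
        reps = select_representatives(a, {"AAAA": 2.5, "CCCC": 2.5, "SOLO": 3.1})
        assert reps == ["AAAA", "SOLO"]

    def test_output_size_equals_k(self):
        from ensemblevs.structures import ClusterAssignment

        labels = {f"S{i:02d}": (i % 3) + 1 for i in range(9)}
        a = ClusterAssignment(labels=labels, k=3)
        assert len(select_representatives(a, {i: 2.0 + int(i[1:]) * 0.01 for i in labels})) == 3

    def test_missing_resolution_is_error(self):
        from ensemblevs.structures import ClusterAssignment

        a = ClusterAssignment(labels={"AAAA": 1}, k=1)
        with pytest.raises(ValueError):
            select_representatives(a, {})


def test_biopython_agrees_on_parsed_coordinates(tmp_path):
    """Independent cross-check of the fixed-column reader against Bio.PDB."""
    Bio = pytest.importorskip("Bio.PDB")
    rng = np.random.default_rng(11)
    m = _model("XCHK", rng.uniform(-20, 20, size=(10, 3)), ligand=[(1.0, 2.0, 3.0)])
    path = tmp_path / "xchk.pdb"
    path.write_text(write_pdb(m))
    ours = parse_pdb(path.read_text(), model_id="XCHK")
    parser = Bio.PDBParser(QUIET=True)
    st = parser.get_structure("XCHK", str(path))
    ref = np.array([a.get_coord() for a in st.get_atoms()])
    mine = np.vstack([ours.coords(), [a.xyz for a in ours.het_ligand]])
    np.testing.assert_allclose(mine, ref, atol=1e-3)
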