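"""Protein conformational ensembles: parsing, superposition, and clustering.

An ensemble-docking campaign starts from a set of crystal structures of one
target.  This module reads those structures from PDB text, extracts the
binding site around a co-crystallized ligand, superposes site atoms between
conformations (Kabsch least squares), builds the pairwise RMSD matrix, cuts
an average-linkage (UPGMA) tree into a requested number of conformational
families, and picks the highest-resolution member of each family as the
representative used for docking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "AtomRecord",
    "StructureModel",
    "DistanceMatrix",
    "ClusterAssignment",
    "PDBParseError",
    "parse_pdb",
    "write_pdb",
    "extract_binding_site",
    "kabsch_superpose",
    "pairwise_rmsd_matrix",
    "upgma_cluster",
    "select_representatives",
]

logger = logging.getLogger(__name__)

WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}


class PDBParseError(ValueError):
    """Raised when PDB text cannot be interpreted."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure (coordinates in Å, author residue numbering)."""

    serial: int
    name: str
    residue_name: str
    chain: str
    residue_number: int
    element: str
    xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element must be non-empty")
        if not all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")


@dataclass
class StructureModel:
    """A single protein conformation plus its co-crystallized ligand.

    ``resolution`` is the crystallographic resolution in Å; smaller is
    better.  ``het_ligand`` holds the bound small molecule's atoms when one
    was present in the file.
    """

    id: str
    resolution: float
    atoms: list[AtomRecord]
    het_ligand: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"model {self.id!r} has no atoms")
        serials = [a.serial for a in self.atoms] + [a.serial for a in self.het_ligand]
        if len(serials) != len(set(serials)):
            raise ValueError(f"model {self.id!r} has duplicate atom serials")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive (Å)")

    def coords(self, selection=None) -> np.ndarray:
        """Protein coordinates as an (n, 3) array, optionally filtered."""
        atoms = self.atoms if selection is None else [a for a in self.atoms if selection(a)]
        return np.array([a.xyz for a in atoms], dtype=float).reshape(-1, 3)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of inter-conformation RMSD values (Å)."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(ids=list(df.index), values=df.to_numpy(dtype=float))


@dataclass
class ClusterAssignment:
    """Partition of structure ids into ``k`` clusters labelled 1..k."""

    labels: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        used = set(self.labels.values())
        if used != set(range(1, self.k + 1)):
            raise ValueError(f"expected exactly clusters 1..{self.k}, got {sorted(used)}")

    def members(self, cluster: int) -> list[str]:
        return sorted(i for i, c in self.labels.items() if c == cluster)

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = sorted(self.labels.items())
        pd.DataFrame(rows, columns=["id", "cluster"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PDB I/O (fixed-column ATOM/HETATM dialect)
# ---------------------------------------------------------------------------

def _parse_float(text: str, lineno: int, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(f"line {lineno}: unparseable {what} field {text.strip()!r}") from None


def parse_pdb(
    text: str,
    model_id: str = "XXXX",
    resolution: float | None = None,
    ligand_code: str | None = None,
) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    ATOM records become protein atoms; HETATM records of ``ligand_code``
    (or, when ``ligand_code`` is None, all non-water HETATM records) become
    the co-crystallized ligand.  Crystallographic waters are always dropped.
    Resolution is taken from the ``REMARK   2 RESOLUTION.`` header unless
    overridden via ``resolution``.
    """
    atoms: list[AtomRecord] = []
    het: list[AtomRecord] = []
    parsed_resolution = resolution

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "REMARK" and parsed_resolution is None and "RESOLUTION." in line:
            tail = line.split("RESOLUTION.", 1)[1]
            for tok in tail.split():
                try:
                    parsed_resolution = float(tok)
                    break
                except ValueError:
                    continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: ATOM/HETATM record too short")
        resname = line[17:20].strip()
        if resname in WATER_RESNAMES:
            continue
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            # fall back on the atom-name column, stripping leading digits
            element = line[12:16].strip().lstrip("0123456789")[:1]
        atom = AtomRecord(
            serial=int(line[6:11]),
            name=line[12:16].strip(),
            residue_name=resname,
            chain=line[21],
            residue_number=int(line[22:26]),
            element=element,
            xyz=(
                _parse_float(line[30:38], lineno, "x"),
                _parse_float(line[38:46], lineno, "y"),
                _parse_float(line[46:54], lineno, "z"),
            ),
        )
        if rec == "ATOM  ":
            atoms.append(atom)
        elif ligand_code is None or resname == ligand_code:
            het.append(atom)

    if not atoms and not het:
        raise PDBParseError("no ATOM/HETATM records found")
    if not atoms:
        # ligand-only file: keep het atoms but a model needs >= 1 atom
        raise PDBParseError("no ATOM records found (protein is empty)")
    if parsed_resolution is None:
        raise PDBParseError(
            "resolution not found in REMARK 2 and no override supplied"
        )
    return StructureModel(id=model_id, resolution=parsed_resolution, atoms=atoms, het_ligand=het)


def write_pdb(model: StructureModel) -> str:
    """Serialize a model back to fixed-column PDB text (coordinates %8.3f)."""
    lines = [f"REMARK   2 RESOLUTION.    {model.resolution:.2f} ANGSTROMS."]

    def fmt(rec: str, a: AtomRecord) -> str:
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        return (
            f"{rec:<6s}{a.serial:>5d} {name}{'':1s}{a.residue_name:>3s} {a.chain}"
            f"{a.residue_number:>4d}{'':4s}{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}{'':10s}{a.element:>2s}"
        )

    lines += [fmt("ATOM", a) for a in model.atoms]
    lines += [fmt("HETATM", a) for a in model.het_ligand]
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Binding site and superposition
# ---------------------------------------------------------------------------

def extract_binding_site(model: StructureModel, cutoff: float = 10.0) -> set[tuple[str, int]]:
    """Residues with any atom within ``cutoff`` Å of any ligand atom.

    Returns ``(chain, residue_number)`` pairs.  The boundary is inclusive:
    a residue exactly at the cutoff distance is kept.
    """
    if not model.het_ligand:
        raise ValueError(f"model {model.id!r} has no co-crystallized ligand")
    lig = np.array([a.xyz for a in model.het_ligand], dtype=float)
    prot = model.coords()
    d = cdist(prot, lig).min(axis=1)
    site: set[tuple[str, int]] = set()
    for atom, dist in zip(model.atoms, d):
        if dist <= cutoff:
            site.add((atom.chain, atom.residue_number))
    return site


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``P`` onto ``Q`` (Kabsch, SVD form).

    Returns ``(rotation, translation, rmsd)`` such that ``P @ rotation.T +
    translation`` best matches ``Q`` in the least-squares sense; the rotation
    is always proper (det = +1).  Point correspondence is positional.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must both be (n, 3) with matching n")
    n = P.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2 or np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set: rotation underdetermined")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - P.mean(axis=0) @ R.T
    diff = Pc @ R.T - Qc
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return R, t, rmsd


def _site_coords(
    model: StructureModel,
    site: set[tuple[str, int]],
    atom_subset: set[str] | None,
) -> np.ndarray:
    keys = []
    coords = {}
    for a in model.atoms:
        if (a.chain, a.residue_number) not in site:
            continue
        if atom_subset is not None and a.name not in atom_subset:
            continue
        key = (a.chain, a.residue_number, a.name)
        if key not in coords:  # first altloc wins
            coords[key] = a.xyz
            keys.append(key)
    missing_res = {
        (c, r) for (c, r) in site if not any(k[0] == c and k[1] == r for k in coords)
    }
    if missing_res:
        raise ValueError(
            f"model {model.id!r} is missing selected residues: {sorted(missing_res)}"
        )
    return np.array([coords[k] for k in sorted(coords)], dtype=float), sorted(coords)


def pairwise_rmsd_matrix(
    models: list[StructureModel],
    site: set[tuple[str, int]],
    atom_subset: set[str] | None = frozenset({"CA"}),
) -> DistanceMatrix:
    """All-against-all Kabsch RMSD over a shared residue selection.

    ``atom_subset`` defaults to CA only; pass ``None`` to use every atom of
    the selected residues (atom names must then match across models).
    """
    if atom_subset is not None:
        atom_subset = set(atom_subset)
    ids = [m.id for m in models]
    mats = []
    ref_keys = None
    for m in models:
        xyz, keys = _site_coords(m, site, atom_subset)
        if ref_keys is None:
            ref_keys = keys
        elif keys != ref_keys:
            gap = set(ref_keys) ^ set(keys)
            raise ValueError(f"model {m.id!r} atom selection mismatch: {sorted(gap)}")
        mats.append(xyz)
    n = len(models)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = kabsch_superpose(mats[i], mats[j])
            D[i, j] = D[j, i] = r
    return DistanceMatrix(ids=ids, values=D)


# ---------------------------------------------------------------------------
# UPGMA clustering and representative selection
# ---------------------------------------------------------------------------

def upgma_cluster(d: DistanceMatrix, k: int) -> ClusterAssignment:
    """Cut an average-linkage (UPGMA) agglomeration at ``k`` clusters.

    Merging is deterministic: among equidistant pairs the pair whose
    (lexicographically smallest member, next member) id pair sorts first is
    merged.  Cluster labels 1..k are assigned in order of each cluster's
    smallest member id.
    """
    n = len(d.ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    # clusters keyed by their lexicographically smallest member id
    clusters: dict[str, list[int]] = {cid: [i] for i, cid in enumerate(d.ids)}
    D = d.values
    while len(clusters) > k:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                # average linkage: mean pairwise distance between members
                dist = float(np.mean([D[i, j] for i in clusters[a] for j in clusters[b]]))
                key = (dist, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels: dict[str, int] = {}
    for label, cid in enumerate(sorted(clusters), start=1):
        for i in clusters[cid]:
            labels[d.ids[i]] = label
    return ClusterAssignment(labels=labels, k=k)


def select_representatives(
    assignment: ClusterAssignment, resolutions: dict[str, float]
) -> list[str]:
    """Highest-resolution (smallest Å) member of each cluster.

    Resolution ties break to the lexicographically smallest id.  Output is
    ordered by cluster label.
    """
    missing = [i for i in assignment.labels if i not in resolutions]
    if missing:
        raise ValueError(f"no resolution for ids: {sorted(missing)}")
    reps = []
    for c in range(1, assignment.k + 1):
        members = assignment.members(c)
        reps.append(min(members, key=lambda i: (resolutions[i], i)))
    return reps
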