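"""Drug-likeness filters and fingerprint diversity clustering.

The hit-triage cascade thins a ranked compound list with three property
screens and one diversity step:

* Lipinski rule of five (MW <= 500, logP <= 5, HBD <= 5, HBA <= 10), with a
  configurable number of tolerated violations;
* Veber oral-bioavailability rules (rotatable bonds <= 10, TPSA <= 140 Å²),
  never waivable;
* REOS ("rapid elimination of swill") property windows plus reactive-group
  exclusions;
* Butina sphere-exclusion clustering on fingerprint Tanimoto similarity,
  followed by a round-robin diversity pick so no scaffold family dominates.

Descriptors are consumed, not computed: the module operates on descriptor
tables so the rule logic stays exact and dependency-light.  A chemistry
backend (e.g. RDKit) can populate :class:`DescriptorRecord` from structures
via :func:`descriptors_from_rdkit`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import ClusterAssignment

__all__ = [
    "DescriptorRecord",
    "Fingerprint",
    "lipinski_veber_pass",
    "reos_pass",
    "tanimoto",
    "butina_cluster",
    "diversity_pick",
    "read_descriptor_csv",
    "write_descriptor_csv",
    "read_fingerprint_csv",
    "write_fingerprint_csv",
]

logger = logging.getLogger(__name__)

DESCRIPTOR_FIELDS = (
    "mw", "logp", "hbd", "hba", "rotb", "tpsa", "formal_charge", "heavy_atoms",
)

#: reactive/toxic functional groups screened by REOS; config-editable
DEFAULT_REACTIVE_GROUPS = (
    "acyl_halide", "aldehyde", "michael_acceptor", "alkyl_halide", "epoxide",
)


@dataclass(frozen=True)
class DescriptorRecord:
    """Per-compound physicochemical descriptors driving the filters."""

    compound_id: str
    mw: float          # molecular weight, Da
    logp: float        # octanol/water partition coefficient
    hbd: int           # hydrogen-bond donors
    hba: int           # hydrogen-bond acceptors
    rotb: int          # rotatable bonds
    tpsa: float        # topological polar surface area, Å²
    formal_charge: int
    heavy_atoms: int
    reactive_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"{self.compound_id}: MW must be positive")
        for f in ("hbd", "hba", "rotb", "heavy_atoms"):
            if getattr(self, f) < 0:
                raise ValueError(f"{self.compound_id}: {f} must be >= 0")

    def require(self, *fields: str) -> None:
        for f in fields:
            v = getattr(self, f, None)
            if v is None or (isinstance(v, float) and not np.isfinite(v)):
                raise ValueError(f"{self.compound_id}: missing descriptor {f!r}")


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary fingerprint (default 2048 bits)."""

    compound_id: str
    bits: np.ndarray  # bool array

    @classmethod
    def from_hex(cls, compound_id: str, hexstring: str, n_bits: int | None = None) -> "Fingerprint":
        raw = np.frombuffer(bytes.fromhex(hexstring), dtype=np.uint8)
        bits = np.unpackbits(raw).astype(bool)
        if n_bits is not None:
            bits = bits[:n_bits]
        return cls(compound_id, bits)

    def to_hex(self) -> str:
        return np.packbits(self.bits.astype(np.uint8)).tobytes().hex()

    @classmethod
    def from_bitstring(cls, compound_id: str, s: str) -> "Fingerprint":
        return cls(compound_id, np.array([c == "1" for c in s], dtype=bool))


# ---------------------------------------------------------------------------
# Rule filters
# ---------------------------------------------------------------------------

def lipinski_veber_pass(
    rec: DescriptorRecord, max_lipinski_violations: int = 0
) -> tuple[bool, list[str]]:
    """Lipinski rule-of-five plus Veber rules; boundaries inclusive.

    Up to ``max_lipinski_violations`` Lipinski failures are tolerated (the
    rule of five is classically quoted as "no more than one violation");
    the two Veber rules are hard requirements.
    """
    rec.require("mw", "logp", "hbd", "hba", "rotb", "tpsa")
    lipinski = []
    if rec.mw > 500:
        lipinski.append("MW>500")
    if rec.logp > 5:
        lipinski.append("logP>5")
    if rec.hbd > 5:
        lipinski.append("HBD>5")
    if rec.hba > 10:
        lipinski.append("HBA>10")
    veber = []
    if rec.rotb > 10:
        veber.append("RotB>10")
    if rec.tpsa > 140:
        veber.append("TPSA>140")
    ok = len(lipinski) <= max_lipinski_violations and not veber
    reasons = (lipinski if len(lipinski) > max_lipinski_violations else []) + veber
    return ok, reasons


#: REOS property windows (inclusive)
REOS_RANGES = {
    "mw": (200.0, 500.0),
    "logp": (-5.0, 5.0),
    "hbd": (0, 5),
    "hba": (0, 10),
    "formal_charge": (-2, 2),
    "rotb": (0, 8),
    "heavy_atoms": (15, 50),
}

_REOS_LABEL = {
    "mw": "MW", "logp": "logP", "hbd": "HBD", "hba": "HBA",
    "formal_charge": "charge", "rotb": "RotB", "heavy_atoms": "heavy",
}


def reos_pass(rec: DescriptorRecord) -> tuple[bool, list[str]]:
    """REOS screen: property windows plus reactive-group exclusion.

    All boundaries inclusive; any true reactive flag fails with the flag
    named in the violation list.
    """
    rec.require(*REOS_RANGES)
    reasons = []
    for f, (lo, hi) in REOS_RANGES.items():
        v = getattr(rec, f)
        label = _REOS_LABEL[f]
        if v < lo:
            reasons.append(f"{label}<{lo:g}")
        elif v > hi:
            reasons.append(f"{label}>{hi:g}")
    for name, flagged in sorted((rec.reactive_flags or {}).items()):
        if flagged:
            reasons.append(f"reactive:{name}")
    return not reasons, reasons


# ---------------------------------------------------------------------------
# Similarity / diversity
# ---------------------------------------------------------------------------

def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b|; two empty sets -> 1.0."""
    if len(a.bits) != len(b.bits):
        raise ValueError(f"fingerprint length mismatch: {len(a.bits)} vs {len(b.bits)}")
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        logger.warning("tanimoto of two empty fingerprints: 1.0 by convention")
        return 1.0
    return float(np.logical_and(a.bits, b.bits).sum() / union)


def _similarity_matrix(fps: list[Fingerprint]) -> np.ndarray:
    X = np.stack([fp.bits for fp in fps]).astype(np.float64)
    inter = X @ X.T
    popcnt = X.sum(axis=1)
    union = popcnt[:, None] + popcnt[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return sim


def butina_cluster(
    fps: list[Fingerprint], cutoff: float = 0.8, strict: bool = False
) -> ClusterAssignment:
    """Sphere-exclusion (Butina) clustering at a Tanimoto cutoff.

    Candidates are visited in order of descending neighbour count (ties to
    the lexicographically smaller id); each unassigned candidate becomes a
    centroid and absorbs its still-unassigned neighbours.  Membership uses
    similarity >= cutoff by default; ``strict=True`` switches to a strict
    inequality.  Every compound lands in exactly one cluster; singletons
    form their own.
    """
    if not fps:
        raise ValueError("need at least one fingerprint")
    ids = [fp.compound_id for fp in fps]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids")
    sim = _similarity_matrix(fps)
    hit = sim > cutoff if strict else sim >= cutoff
    np.fill_diagonal(hit, False)
    n_nb = hit.sum(axis=1)
    order = sorted(range(len(fps)), key=lambda i: (-n_nb[i], ids[i]))
    labels_idx = np.full(len(fps), -1, dtype=int)
    next_cluster = 0
    for i in order:
        if labels_idx[i] >= 0:
            continue
        labels_idx[i] = next_cluster
        for j in np.flatnonzero(hit[i]):
            if labels_idx[j] < 0:
                labels_idx[j] = next_cluster
        next_cluster += 1
    labels = {ids[i]: int(labels_idx[i]) + 1 for i in range(len(fps))}
    return ClusterAssignment(labels=labels, k=next_cluster)


def diversity_pick(
    assignment: ClusterAssignment, ranking_scores: dict[str, float], n: int
) -> list[str]:
    """Pick ``n`` compounds round-robin across clusters, best-scored first.

    Clusters are visited in descending order of their best member's score
    (higher = better; ties by cluster's smallest id); each visit takes the
    cluster's best unused member.  Diversity beats depth: a second member of
    any cluster is only taken once every cluster has contributed one.
    """
    population = list(assignment.labels)
    if n > len(population):
        raise ValueError(f"cannot pick {n} from {len(population)} compounds")
    missing = [c for c in population if c not in ranking_scores]
    if missing:
        raise ValueError(f"no ranking score for: {sorted(missing)[:5]}")
    queues = []
    for c in range(1, assignment.k + 1):
        members = sorted(assignment.members(c), key=lambda i: (-ranking_scores[i], i))
        queues.append(members)
    queues.sort(key=lambda q: (-ranking_scores[q[0]], q[0]))
    picked: list[str] = []
    while len(picked) < n:
        took = False
        for q in queues:
            if q and len(picked) < n:
                picked.append(q.pop(0))
                took = True
        if not took:
            break
    return picked


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_descriptor_csv(records: list[DescriptorRecord], path) -> None:
    flag_names = sorted({k for r in records for k in (r.reactive_flags or {})})
    rows = []
    for r in records:
        row = {"compound_id": r.compound_id}
        row.update({f: getattr(r, f) for f in DESCRIPTOR_FIELDS})
        for k in flag_names:
            row[f"reactive_{k}"] = int(bool((r.reactive_flags or {}).get(k, False)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_descriptor_csv(path) -> list[DescriptorRecord]:
    df = pd.read_csv(path)
    missing = set(DESCRIPTOR_FIELDS) - set(df.columns)
    if missing:
        raise ValueError(f"descriptor CSV missing columns: {sorted(missing)}")
    flag_cols = [c for c in df.columns if c.startswith("reactive_")]
    records = []
    for _, row in df.iterrows():
        records.append(
            DescriptorRecord(
                compound_id=str(row["compound_id"]),
                mw=float(row["mw"]),
                logp=float(row["logp"]),
                hbd=int(row["hbd"]),
                hba=int(row["hba"]),
                rotb=int(row["rotb"]),
                tpsa=float(row["tpsa"]),
                formal_charge=int(row["formal_charge"]),
                heavy_atoms=int(row["heavy_atoms"]),
                reactive_flags={c[len("reactive_"):]: bool(row[c]) for c in flag_cols},
            )
        )
    return records


def write_fingerprint_csv(fps: list[Fingerprint], path) -> None:
    pd.DataFrame(
        {"compound_id": [f.compound_id for f in fps],
         "n_bits": [len(f.bits) for f in fps],
         "fingerprint_hex": [f.to_hex() for f in fps]}
    ).to_csv(path, index=False)


def read_fingerprint_csv(path) -> list[Fingerprint]:
    df = pd.read_csv(path, dtype={"fingerprint_hex": str})
    return [
        Fingerprint.from_hex(str(r["compound_id"]), r["fingerprint_hex"], int(r["n_bits"]))
        for _, r in df.iterrows()
    ]


def filter_report(records: list[DescriptorRecord], max_lipinski_violations: int = 0) -> pd.DataFrame:
    """Batch verdicts for both filters; reasons semicolon-joined."""
    rows = []
    for r in records:
        lv_ok, lv_why = lipinski_veber_pass(r, max_lipinski_violations)
        re_ok, re_why = reos_pass(r)
        rows.append({
            "compound_id": r.compound_id,
            "lipinski_veber_pass": lv_ok,
            "lipinski_veber_reasons": ";".join(lv_why),
            "reos_pass": re_ok,
            "reos_reasons": ";".join(re_why),
        })
    return pd.DataFrame(rows)


def descriptors_from_rdkit(mols_with_ids) -> list[DescriptorRecord]:
    """Optional adapter: fill descriptor records from RDKit molecules.

    ``mols_with_ids`` yields ``(compound_id, rdkit.Chem.Mol)`` pairs.  Only
    imported on call, so the core never needs a chemistry stack.
    """
    from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

    records = []
    for cid, mol in mols_with_ids:
        records.append(
            DescriptorRecord(
                compound_id=cid,
                mw=Descriptors.MolWt(mol),
                logp=Crippen.MolLogP(mol),
                hbd=Lipinski.NumHDonors(mol),
                hba=Lipinski.NumHAcceptors(mol),
                rotb=Lipinski.NumRotatableBonds(mol),
                tpsa=rdMolDescriptors.CalcTPSA(mol),
                formal_charge=sum(a.GetFormalCharge() for a in mol.GetAtoms()),
                heavy_atoms=mol.GetNumHeavyAtoms(),
            )
        )
    return records
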