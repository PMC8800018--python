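"""Geometric protein–ligand interaction analysis on poses and snapshots.

Detectors work on static coordinates only — no force field, no trajectory
engine.  A pose is screened against a receptor for hydrogen bonds
(donor–acceptor heavy-atom distance <= 3.5 Å, D–H...A angle >= 120° when a
hydrogen position is available), hydrophobic carbon–carbon contacts
(<= 4.5 Å, side-chain carbons only, one aggregated record per residue) and
ionic contacts between oppositely charged group centres (<= 4.0 Å).  All
cutoffs are conventional values and are exposed as arguments.

Snapshot series (multi-frame pose lists) feed two trajectory-style
summaries: per-(residue, interaction-type) occupancy — the fraction of
frames in which the contact is present — and per-atom ligand RMSF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structures import StructureModel, kabsch_superpose

__all__ = [
    "LigandAtom",
    "LigandPose",
    "InteractionRecord",
    "TrajectorySeries",
    "detect_hbonds",
    "detect_hydrophobic",
    "detect_ionic",
    "detect_water_bridges",
    "detect_all",
    "hot_residue_filter",
    "ligand_rmsf",
    "interaction_occupancy",
    "DEFAULT_HOT_RESIDUES",
]

logger = logging.getLogger(__name__)

ITYPES = ("hbond", "hydrophobic", "ionic", "water_bridge")

#: Binding-pocket residues whose contact is demanded of acceptable poses in
#: the shipped PI3Kγ profile: the hinge valine plus the catalytic-lysine /
#: specificity-pocket residues recurrently contacted by potent inhibitors.
#: Fully user-overridable; any target gets its own hot set.
DEFAULT_HOT_RESIDUES = (
    "VAL882", "LYS833", "TYR867", "ASP964", "ASP836",
    "THR886", "THR887", "MET953", "ILE963",
)

_POSITIVE_RES = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE"), "HIS": ("ND1", "NE2")}
_NEGATIVE_RES = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class LigandAtom:
    """One ligand atom; ``h_positions`` are attached-hydrogen coordinates
    (used for H-bond angle checks), ``formal_charge`` drives ionic detection."""

    element: str
    xyz: tuple[float, float, float]
    h_positions: tuple = ()
    formal_charge: int = 0

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.xyz)):
            raise ValueError("non-finite ligand coordinates")


@dataclass
class LigandPose:
    """A docked/simulated ligand conformation in the receptor frame."""

    compound_id: str
    atoms: list[LigandAtom]
    frame_index: int = 0

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("pose must have at least one atom")

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "LigandPose":
        atoms = [
            LigandAtom(
                a.element,
                tuple(np.asarray(a.xyz) @ R.T + t),
                tuple(tuple(np.asarray(h) @ R.T + t) for h in a.h_positions),
                a.formal_charge,
            )
            for a in self.atoms
        ]
        return LigandPose(self.compound_id, atoms, self.frame_index)


@dataclass(frozen=True)
class InteractionRecord:
    """A detected residue contact: who, what kind, and how close."""

    residue: tuple[str, int, str]  # (chain, residue_number, residue_name)
    itype: str
    distance: float
    angle: float | None = None
    ligand_atom_index: int = -1

    def __post_init__(self) -> None:
        if self.itype not in ITYPES:
            raise ValueError(f"unknown interaction type {self.itype!r}")
        if self.distance <= 0:
            raise ValueError("distance must be positive")


@dataclass
class TrajectorySeries:
    """Ordered ligand snapshots, optionally with a per-frame receptor."""

    poses: list[LigandPose]
    receptor: StructureModel | list[StructureModel] | None = None

    def __post_init__(self) -> None:
        counts = {len(p.atoms) for p in self.poses}
        if len(counts) > 1:
            raise ValueError("all frames must have the same atom count")

    def __len__(self) -> int:
        return len(self.poses)

    def receptor_for(self, i: int) -> StructureModel | None:
        if isinstance(self.receptor, list):
            return self.receptor[i]
        return self.receptor


def _sorted(records: list[InteractionRecord]) -> list[InteractionRecord]:
    return sorted(records, key=lambda r: (r.residue, r.itype, r.distance))


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------

def detect_hbonds(
    pose: LigandPose,
    receptor: StructureModel,
    d_max: float = 3.5,
    angle_min: float = 120.0,
) -> list[InteractionRecord]:
    """Hydrogen bonds between ligand N/O and receptor N/O heavy atoms.

    A pair qualifies when the heavy-atom distance is <= ``d_max`` and, for
    every available donor hydrogen, the best D–H...A angle is >=
    ``angle_min``.  When neither partner carries a usable hydrogen position
    the angle gate is skipped with a warning (distance-only criterion).
    One record per qualifying (residue, ligand atom) pair, then aggregated
    to the closest contact per residue.
    """
    if not receptor.atoms:
        raise ValueError("empty receptor")
    rec_polar = [a for a in receptor.atoms if a.element in ("N", "O")]
    if not rec_polar:
        return []
    rxyz = np.array([a.xyz for a in rec_polar])
    out: dict[tuple, InteractionRecord] = {}
    for li, la in enumerate(pose.atoms):
        if la.element.upper() not in ("N", "O"):
            continue
        d = np.linalg.norm(rxyz - np.asarray(la.xyz), axis=1)
        for ra, dist in zip(rec_polar, d):
            if dist > d_max:
                continue
            angle = None
            if la.h_positions:
                angle = max(
                    _angle(np.asarray(la.xyz), np.asarray(h), np.asarray(ra.xyz))
                    for h in la.h_positions
                )
                if angle < angle_min:
                    continue
            else:
                logger.warning(
                    "hbond check without hydrogen positions: angle gate skipped"
                )
            key = (ra.chain, ra.residue_number, ra.residue_name)
            rec = InteractionRecord(
                residue=key, itype="hbond", distance=float(dist),
                angle=angle, ligand_atom_index=li,
            )
            if key not in out or dist < out[key].distance:
                out[key] = rec
    return _sorted(list(out.values()))


def _angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    """D–H...A angle in degrees (180 = perfectly linear)."""
    v1 = d - h
    v2 = a - h
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def detect_hydrophobic(
    pose: LigandPose, receptor: StructureModel, d_max: float = 4.5
) -> list[InteractionRecord]:
    """Carbon–carbon contacts to side-chain carbons, one record per residue
    at the minimum distance."""
    lig_c = [(i, np.asarray(a.xyz)) for i, a in enumerate(pose.atoms) if a.element.upper() == "C"]
    if not lig_c:
        return []
    rec_c = [a for a in receptor.atoms if a.element == "C" and a.name not in _BACKBONE]
    if not rec_c:
        return []
    rxyz = np.array([a.xyz for a in rec_c])
    lxyz = np.array([x for _, x in lig_c])
    d = cdist(lxyz, rxyz)
    out: dict[tuple, InteractionRecord] = {}
    for (li, _), drow in zip(lig_c, d):
        for ra, dist in zip(rec_c, drow):
            if dist > d_max:
                continue
            key = (ra.chain, ra.residue_number, ra.residue_name)
            if key not in out or dist < out[key].distance:
                out[key] = InteractionRecord(
                    residue=key, itype="hydrophobic", distance=float(dist),
                    ligand_atom_index=li,
                )
    return _sorted(list(out.values()))


def detect_ionic(
    pose: LigandPose, receptor: StructureModel, d_max: float = 4.0
) -> list[InteractionRecord]:
    """Salt bridges: oppositely charged group centres within ``d_max`` Å.

    Receptor charged groups are the carboxylates of Asp/Glu (negative) and
    the Lys/Arg/His nitrogen clusters (positive); the group centre is the
    mean of the named atoms.  Each charged ligand atom is its own centre.
    """
    groups: list[tuple[tuple, int, np.ndarray]] = []
    by_res: dict[tuple, list] = {}
    for a in receptor.atoms:
        by_res.setdefault((a.chain, a.residue_number, a.residue_name), []).append(a)
    for key, atoms in by_res.items():
        resname = key[2]
        for table, sign in ((_POSITIVE_RES, +1), (_NEGATIVE_RES, -1)):
            if resname in table:
                sel = [a for a in atoms if a.name in table[resname]]
                if sel:
                    centre = np.mean([a.xyz for a in sel], axis=0)
                    groups.append((key, sign, centre))
    out: dict[tuple, InteractionRecord] = {}
    for li, la in enumerate(pose.atoms):
        if la.formal_charge == 0:
            continue
        for key, sign, centre in groups:
            if sign * la.formal_charge >= 0:
                continue
            dist = float(np.linalg.norm(np.asarray(la.xyz) - centre))
            if dist <= d_max and (key not in out or dist < out[key].distance):
                out[key] = InteractionRecord(
                    residue=key, itype="ionic", distance=dist, ligand_atom_index=li
                )
    return _sorted(list(out.values()))


def detect_water_bridges(
    pose: LigandPose,
    receptor: StructureModel,
    waters: np.ndarray,
    d_max: float = 3.5,
) -> list[InteractionRecord]:
    """Optional detector: ligand–water and water–residue both <= ``d_max``.

    ``waters`` is an (n, 3) array of water oxygen positions.  Excluded from
    the default detector set because it needs explicit solvent coordinates.
    """
    waters = np.asarray(waters, dtype=float).reshape(-1, 3)
    if len(waters) == 0:
        return []
    lig_polar = [(i, np.asarray(a.xyz)) for i, a in enumerate(pose.atoms)
                 if a.element.upper() in ("N", "O")]
    rec_polar = [a for a in receptor.atoms if a.element in ("N", "O")]
    if not lig_polar or not rec_polar:
        return []
    lxyz = np.array([x for _, x in lig_polar])
    rxyz = np.array([a.xyz for a in rec_polar])
    lw = cdist(lxyz, waters) <= d_max
    rw = cdist(rxyz, waters) <= d_max
    out: dict[tuple, InteractionRecord] = {}
    for wi in range(len(waters)):
        lig_hits = np.flatnonzero(lw[:, wi])
        rec_hits = np.flatnonzero(rw[:, wi])
        for lh in lig_hits:
            for rh in rec_hits:
                ra = rec_polar[rh]
                key = (ra.chain, ra.residue_number, ra.residue_name)
                dist = float(cdist(lxyz[lh][None], waters[wi][None])[0, 0])
                if key not in out or dist < out[key].distance:
                    out[key] = InteractionRecord(
                        residue=key, itype="water_bridge", distance=dist,
                        ligand_atom_index=int(lig_polar[lh][0]),
                    )
    return _sorted(list(out.values()))


def detect_all(
    pose: LigandPose,
    receptor: StructureModel,
    hbond_d_max: float = 3.5,
    hbond_angle_min: float = 120.0,
    hydrophobic_d_max: float = 4.5,
    ionic_d_max: float = 4.0,
) -> list[InteractionRecord]:
    """Run the default detector set (H-bond, hydrophobic, ionic)."""
    return _sorted(
        detect_hbonds(pose, receptor, hbond_d_max, hbond_angle_min)
        + detect_hydrophobic(pose, receptor, hydrophobic_d_max)
        + detect_ionic(pose, receptor, ionic_d_max)
    )


# ---------------------------------------------------------------------------
# Hot-residue filter, occupancy, RMSF
# ---------------------------------------------------------------------------

def _residue_key(residue: tuple[str, int, str]) -> str:
    return f"{residue[2].upper()}{residue[1]}"


def hot_residue_filter(
    records: list[InteractionRecord],
    hot_set,
    require: str = "any",
    itypes: frozenset = frozenset({"hbond"}),
) -> bool:
    """Keep a pose iff it contacts the hot residues via the requested types.

    ``hot_set`` entries are residue labels like ``"VAL882"`` (case
    insensitive).  ``require="any"`` keeps a pose touching at least one hot
    residue; ``"all"`` demands the full set.
    """
    hot = {str(h).upper() for h in hot_set}
    if not hot:
        raise ValueError("hot_set must be non-empty")
    if require not in ("any", "all"):
        raise ValueError(f"require must be 'any' or 'all', got {require!r}")
    touched = {_residue_key(r.residue) for r in records if r.itype in itypes}
    matched = touched & hot
    return bool(matched) if require == "any" else matched == hot


def ligand_rmsf(traj: TrajectorySeries) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean position.

    RMSF_i = sqrt(mean_t ||x_i(t) - mean_t x_i||^2).  When a per-frame
    receptor is supplied, each frame is first aligned onto the first frame's
    receptor CA atoms and the same transform applied to the ligand (removes
    global tumbling, the standard pre-step for fluctuation analysis).
    """
    if len(traj) < 2:
        raise ValueError("RMSF needs at least 2 frames")
    coords = np.stack([p.coords() for p in traj.poses])  # (T, n, 3)
    if isinstance(traj.receptor, list):
        ref = traj.receptor[0].coords(lambda a: a.name == "CA")
        for t in range(len(traj)):
            mob = traj.receptor[t].coords(lambda a: a.name == "CA")
            R, shift, _ = kabsch_superpose(mob, ref)
            coords[t] = coords[t] @ R.T + shift
    mean = coords.mean(axis=0)
    return np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))


def interaction_occupancy(
    traj: TrajectorySeries,
    receptor: StructureModel | None = None,
    detectors: dict | None = None,
) -> dict[tuple[str, str], float]:
    """Fraction of frames in which each (residue, type) contact is present.

    Multiple simultaneous contacts with one residue count once per frame, so
    every occupancy lies in [0, 1].  ``detectors`` passes cutoff overrides
    straight to :func:`detect_all`.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    detectors = detectors or {}
    counts: dict[tuple[str, str], int] = {}
    for i, pose in enumerate(traj.poses):
        rec = receptor if receptor is not None else traj.receptor_for(i)
        if rec is None:
            raise ValueError("no receptor available for occupancy detection")
        seen = {( _residue_key(r.residue), r.itype) for r in detect_all(pose, rec, **detectors)}
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    return {k: v / len(traj) for k, v in counts.items()}


def records_to_frame(records: list[InteractionRecord], frame: int | None = None) -> pd.DataFrame:
    rows = [
        {
            "chain": r.residue[0],
            "residue_number": r.residue[1],
            "residue_name": r.residue[2],
            "itype": r.itype,
            "distance": r.distance,
            "angle": r.angle,
            "ligand_atom_index": r.ligand_atom_index,
            **({"frame": frame} if frame is not None else {}),
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def occupancy_to_frame(occ: dict[tuple[str, str], float]) -> pd.DataFrame:
    rows = [
        {"residue": res, "itype": it, "occupancy": f}
        for (res, it), f in sorted(occ.items())
    ]
    return pd.DataFrame(rows)
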