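"""Synthetic inputs with controlled statistical structure.

Docking engines, compound libraries, and MD trajectories are external to
this package; every downstream stage, however, can be exercised on
synthetic stand-ins whose statistics are dialled explicitly:

* score tables — Gaussian class-conditional docking scores with an
  equicorrelation factor model across conformations, so single-conformation
  AUC and the consensus gain can be tuned independently;
* descriptor tables — two-component mixtures giving each filter rule an
  exact marginal pass probability;
* fingerprints — planted cluster templates with a bit-flip rate calibrated
  to a target within-cluster Tanimoto similarity;
* toy receptor/ligand complexes with hydrogen-bond geometries placed on (or
  away from) designated hot residues;
* snapshot series with isotropic Gaussian jitter for RMSF/occupancy tests.

The default screen configuration mirrors a 1:20 active:decoy validation
set of 800 inhibitors and 16,000 decoys docked into 10 conformations.
All outputs are deterministic functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chemfilters import DEFAULT_REACTIVE_GROUPS, DescriptorRecord, Fingerprint
from .interactions import LigandAtom, LigandPose, TrajectorySeries
from .structures import AtomRecord, StructureModel
from .validation import ScoreTable

__all__ = [
    "ScreenSimConfig",
    "gen_score_table",
    "gen_descriptor_table",
    "gen_fingerprints",
    "gen_toy_complex",
    "gen_snapshot_series",
]


@dataclass(frozen=True)
class ScreenSimConfig:
    """Parameters of the synthetic docking-score generator.

    Defaults encode the standard validation-set design: 800 actives vs
    16,000 decoys (1:20) over 10 conformations, with the class separation
    ``mu_decoy - mu_active`` setting the per-conformation AUC via
    Phi(delta / (sigma * sqrt(2))).
    """

    n_active: int = 800
    n_decoy: int = 16_000
    n_conformations: int = 10
    mu_active: float | tuple = -9.0
    mu_decoy: float | tuple = -7.0
    sigma: float = 1.0
    rho: float = 0.0
    missing_rate: float = 0.0
    mode: str = "SP"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_active, self.n_decoy, self.n_conformations) < 1:
            raise ValueError("counts must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for mu in (self.mu_active, self.mu_decoy):
            vals = np.atleast_1d(np.asarray(mu, dtype=float))
            if not np.isfinite(vals).all():
                raise ValueError("means must be finite")

    def small(self) -> "ScreenSimConfig":
        """The fast test profile: same design at a tenth the size."""
        return replace(self, n_active=80, n_decoy=1_600)


def _per_conf(mu, k: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(mu, dtype=float))
    if len(arr) == 1:
        return np.full(k, arr[0])
    if len(arr) != k:
        raise ValueError(f"need 1 or {k} means, got {len(arr)}")
    return arr


def gen_score_table(cfg: ScreenSimConfig) -> ScoreTable:
    """Simulate a labelled compounds x conformations docking-score table.

    Per compound a latent factor z ~ N(0,1) is shared across conformations:
    score_j = mu_class_j + sigma * (sqrt(rho) z + sqrt(1-rho) eps_j).  With
    rho = 0 the conformations are conditionally independent given the class
    — the regime in which consensus scoring gains the most.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_active + cfg.n_decoy
    k = cfg.n_conformations
    mu_a = _per_conf(cfg.mu_active, k)
    mu_d = _per_conf(cfg.mu_decoy, k)
    y = np.concatenate([np.ones(cfg.n_active, dtype=int), np.zeros(cfg.n_decoy, dtype=int)])
    z = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, k))
    noise = math.sqrt(cfg.rho) * z + math.sqrt(1.0 - cfg.rho) * eps
    mu = np.where(y[:, None] == 1, mu_a[None, :], mu_d[None, :])
    scores = mu + cfg.sigma * noise
    if cfg.missing_rate > 0:
        mask = rng.random((n, k)) < cfg.missing_rate
        scores = np.where(mask, np.nan, scores)
    width = len(str(n))
    ids = [f"CPD{i:0{width}d}" for i in range(n)]
    confs = [f"CONF{j:02d}" for j in range(k)]
    df = pd.DataFrame(scores, index=ids, columns=pd.MultiIndex.from_tuples(
        [(c, cfg.mode) for c in confs], names=["conformation_id", "mode"]
    ))
    return ScoreTable(scores=df, labels=pd.Series(y, index=ids))


# in-range windows satisfying Lipinski, Veber, and REOS simultaneously
_PROPERTY_WINDOWS = {
    "mw": (200.0, 500.0, (500.0, 900.0)),
    "logp": (-5.0, 5.0, (5.0, 10.0)),
    "hbd": (0, 5, (6, 12)),
    "hba": (0, 10, (11, 20)),
    "rotb": (0, 8, (9, 20)),
    "tpsa": (0.0, 140.0, (140.0, 280.0)),
    "formal_charge": (-2, 2, (3, 6)),
    "heavy_atoms": (15, 50, (51, 90)),
}


def gen_descriptor_table(
    n: int,
    pass_probability: float | dict = 1.0,
    seed: int = 0,
    reactive_groups: tuple = DEFAULT_REACTIVE_GROUPS,
) -> list[DescriptorRecord]:
    """Descriptor records whose per-rule marginal pass rate is controlled.

    ``pass_probability`` is either one probability shared by every rule or a
    map (property name or ``"reactive"``) -> probability; each property is
    drawn uniformly from its in-range window with that probability and from
    an out-of-range window otherwise, so rules fail independently.
    """
    rng = np.random.default_rng(seed)
    if not isinstance(pass_probability, dict):
        probs = {k: float(pass_probability) for k in _PROPERTY_WINDOWS}
        probs["reactive"] = float(pass_probability)
    else:
        probs = {k: float(pass_probability.get(k, 1.0)) for k in _PROPERTY_WINDOWS}
        probs["reactive"] = float(pass_probability.get("reactive", 1.0))
    for k, p in probs.items():
        if not 0 <= p <= 1:
            raise ValueError(f"pass probability for {k!r} out of [0,1]")
    records = []
    width = len(str(max(n - 1, 1)))
    for i in range(n):
        vals = {}
        for prop, (lo, hi, (blo, bhi)) in _PROPERTY_WINDOWS.items():
            ok = rng.random() < probs[prop]
            if isinstance(lo, int):
                v = int(rng.integers(lo, hi + 1)) if ok else int(rng.integers(blo, bhi + 1))
            else:
                v = float(rng.uniform(lo, hi)) if ok else float(rng.uniform(blo, bhi))
            vals[prop] = v
        clean = rng.random() < probs["reactive"]
        flags = {g: False for g in reactive_groups}
        if not clean:
            flags[reactive_groups[int(rng.integers(len(reactive_groups)))]] = True
        records.append(DescriptorRecord(compound_id=f"CPD{i:0{width}d}", reactive_flags=flags, **vals))
    return records


def gen_fingerprints(
    n_clusters: int,
    members_per_cluster: int,
    within_sim_target: float = 0.85,
    n_bits: int = 2048,
    bits_on: int = 160,
    seed: int = 0,
    id_prefix: str = "CPD",
) -> list[Fingerprint]:
    """Planted fingerprint clusters with a calibrated within-cluster Tanimoto.

    Each cluster has a random ``bits_on``-bit template; a member keeps each
    template bit with probability q and turns on the same expected number of
    member-specific random bits otherwise.  Between two members the expected
    Tanimoto is q^2 / (2 - q^2), so q = sqrt(2 T / (1 + T)) hits the target.
    Templates are sampled independently over 2048 bits, so cross-cluster
    similarity stays near bits_on/n_bits (≈ 0.08 at the defaults).
    """
    if not 0 < within_sim_target <= 1:
        raise ValueError("within_sim_target must be in (0, 1]")
    rng = np.random.default_rng(seed)
    q = math.sqrt(2 * within_sim_target / (1 + within_sim_target))
    q = min(q, 1.0)
    fps = []
    idx = 0
    for c in range(n_clusters):
        template = rng.choice(n_bits, size=bits_on, replace=False)
        for _ in range(members_per_cluster):
            keep = template[rng.random(bits_on) < q]
            n_extra = bits_on - len(keep)
            pool = np.setdiff1d(np.arange(n_bits), template, assume_unique=False)
            extra = rng.choice(pool, size=n_extra, replace=False) if n_extra else np.array([], int)
            bits = np.zeros(n_bits, dtype=bool)
            bits[keep] = True
            bits[extra] = True
            fps.append(Fingerprint(f"{id_prefix}{idx:05d}", bits))
            idx += 1
    return fps


_RES_ATOMS = ("N", "CA", "C", "O", "CB")
_RES_OFFSETS = {
    "N": (0.0, 0.0, 0.0),
    "CA": (1.45, 0.0, 0.0),
    "C": (2.2, 1.2, 0.0),
    "O": (3.4, 1.2, 0.3),
    "CB": (1.9, -1.0, 1.0),
}


def gen_toy_complex(
    n_residues: int = 12,
    hot_positions: tuple = (5,),
    ligand_near: bool = True,
    hot_resname: str = "VAL",
    seed: int = 0,
) -> tuple[StructureModel, LigandPose]:
    """A synthetic miniature receptor and a ligand pose near or far from it.

    Residues (N, CA, C, O, CB) are laid out along a 6 Å-spaced line; the
    designated hot positions get ``hot_resname``.  With ``ligand_near`` the
    ligand places a carbonyl oxygen 2.9 Å from each hot residue's backbone
    nitrogen with a near-linear donor geometry, so the default H-bond
    detector fires; otherwise every ligand atom stays >= 6 Å away.
    """
    rng = np.random.default_rng(seed)
    if any(h < 1 or h > n_residues for h in hot_positions):
        raise ValueError("hot_positions must lie in 1..n_residues")
    atoms = []
    serial = 1
    spacing = 6.0
    for ri in range(1, n_residues + 1):
        # zig-zag keeps the chain CA set non-collinear so it can anchor
        # rigid-body superposition
        base = np.array([ri * spacing, -1.5 * (ri % 2), 0.8 * (ri % 3)])
        resname = hot_resname if ri in hot_positions else "ALA"
        for name in _RES_ATOMS:
            xyz = base + np.asarray(_RES_OFFSETS[name])
            atoms.append(
                AtomRecord(
                    serial=serial, name=name, residue_name=resname, chain="A",
                    residue_number=ri, element=name[0], xyz=tuple(xyz),
                )
            )
            serial += 1
    receptor = StructureModel(id="TOY1", resolution=2.0, atoms=atoms)

    lig_atoms = []
    for hp in hot_positions:
        n_xyz = np.array([hp * spacing, -1.5 * (hp % 2), 0.8 * (hp % 3)])
        if ligand_near:
            o_xyz = n_xyz + np.array([0.0, 2.9, 0.0])
            c_xyz = o_xyz + np.array([0.0, 1.3, 0.0])
        else:
            o_xyz = n_xyz + np.array([0.0, 8.0 + rng.random(), 0.0])
            c_xyz = o_xyz + np.array([0.0, 1.3, 0.0])
        # hydroxyl-like O donor: its H points toward the backbone N so the
        # D-H...A angle clears the detector gate when the ligand is near
        lig_atoms.append(
            LigandAtom("O", tuple(o_xyz), h_positions=((tuple(o_xyz + np.array([0.0, -1.0, 0.3])),) if ligand_near else ()))
        )
        lig_atoms.append(LigandAtom("C", tuple(c_xyz)))
    # a couple of inert carbons away from everything
    far = np.array([(n_residues + 4) * spacing, 12.0, 5.0])
    for i in range(2):
        lig_atoms.append(LigandAtom("C", tuple(far + i)))
    return receptor, LigandPose("LIG", lig_atoms)


def gen_snapshot_series(
    base: LigandPose, n_frames: int, jitter_sigma: float, seed: int = 0
) -> TrajectorySeries:
    """Gaussian-jittered snapshots of a pose; frame 0 is the base pose.

    Per-axis jitter sigma gives an expected RMSF of sigma * sqrt(3) per atom
    for large frame counts.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    poses = [LigandPose(base.compound_id, base.atoms, frame_index=0)]
    xyz0 = base.coords()
    for t in range(1, n_frames):
        jitter = rng.normal(0.0, jitter_sigma, size=xyz0.shape) if jitter_sigma > 0 else 0.0
        xyz = xyz0 + jitter
        atoms = [
            LigandAtom(a.element, tuple(x), a.h_positions, a.formal_charge)
            for a, x in zip(base.atoms, xyz)
        ]
        poses.append(LigandPose(base.compound_id, atoms, frame_index=t))
    return TrajectorySeries(poses=poses)
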