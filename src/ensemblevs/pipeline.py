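"""The sequential hit-selection cascade and whole-ensemble validation.

The cascade thins a docked library in five deterministic stages, each a
strict subset of the previous survivors:

1. **dock** — rank by the best (or mean) docking score across the ensemble,
   keep the configured number of top compounds;
2. **bayes** — re-score survivors with the fitted naive Bayes consensus
   model, keep the top block;
3. **druglike** — Lipinski/Veber then REOS property screens, capped at the
   configured size by consensus score;
4. **diversity** — Butina clustering on fingerprints, then a round-robin
   pick so every scaffold family is represented;
5. **interactions** — keep only poses contacting the hot residues, final
   cap by consensus score.

All thresholds, stage sizes and the hot-residue set live in one config
object (YAML-serializable).  Ties at any keep-boundary break by compound id
so a rerun is byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import nbc as nbc_mod
from .chemfilters import (
    DescriptorRecord,
    Fingerprint,
    butina_cluster,
    diversity_pick,
    lipinski_veber_pass,
    reos_pass,
)
from .interactions import (
    DEFAULT_HOT_RESIDUES,
    InteractionRecord,
    LigandPose,
    detect_all,
    hot_residue_filter,
)
from .structures import StructureModel
from .validation import (
    LOWER_IS_ACTIVE,
    ScoreTable,
    ValidationReport,
    choose_mode,
    docking_power,
    log10_p_from_t,
    roc_auc,
    two_sample_ttest,
)

__all__ = ["CascadeConfig", "StageReport", "run_cascade", "validate_ensemble"]

logger = logging.getLogger(__name__)


@dataclass
class CascadeConfig:
    """All knobs of the screening cascade in one place.

    The default stage sizes encode the full-scale profile of a
    2,000,000-compound campaign (10,000 docking survivors, 2,000 after
    consensus re-scoring, 200 drug-like, 100 diverse scaffolds, 49 final
    hits); tests and the bundled examples scale them down uniformly.
    """

    dock_keep: int = 10_000
    bayes_keep: int = 2_000
    druglike_keep: int = 200
    diversity_keep: int = 100
    final_keep: int = 49
    rank_rule: str = "best_across_conformations"
    nbc_bins: int = 10
    similarity_cutoff: float = 0.8
    max_lipinski_violations: int = 0
    hot_set: tuple = DEFAULT_HOT_RESIDUES
    hot_require: str = "any"
    hot_itypes: tuple = ("hbond",)
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = [self.dock_keep, self.bayes_keep, self.druglike_keep,
                 self.diversity_keep, self.final_keep]
        if any(s <= 0 for s in sizes):
            raise ValueError("stage sizes must be positive")
        if any(a <= b for a, b in zip(sizes, sizes[1:])):
            raise ValueError(f"stage sizes must be strictly decreasing, got {sizes}")
        if not 0 < self.similarity_cutoff <= 1:
            raise ValueError("similarity_cutoff must be in (0, 1]")
        if self.rank_rule not in ("best_across_conformations", "mean_across_conformations"):
            raise ValueError(f"unknown rank_rule {self.rank_rule!r}")

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CascadeConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        for key in ("hot_set", "hot_itypes"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return cls(**doc)


@dataclass
class StageReport:
    """Audit record of one cascade stage."""

    stage: str
    n_in: int
    n_out: int
    survivors: list[str]
    dropped: dict[str, str] = field(default_factory=dict)
    elapsed: float = 0.0

    def __post_init__(self) -> None:
        if self.n_out > self.n_in:
            raise ValueError("a stage cannot create compounds")


def _rank_scores(scores: pd.DataFrame, rule: str) -> pd.Series:
    """Aggregate per-conformation scores to one ranking value per compound.

    Missing scores are imputed with the worst observed score in their
    conformation + 1.0 before aggregation, so a compound that failed to dock
    somewhere is penalised but not excluded.
    """
    filled = scores.copy()
    n_missing = int(filled.isna().to_numpy().sum())
    if n_missing:
        logger.info("stage 1: imputing %d missing scores with worst+1.0", n_missing)
        filled = filled.fillna(filled.max(axis=0) + 1.0)
    if rule == "best_across_conformations":
        return filled.min(axis=1)
    return filled.mean(axis=1)


def _keep_top(series: pd.Series, n: int, ascending: bool) -> list[str]:
    """Top-n ids with boundary ties broken lexicographically by id."""
    df = series.rename("v").to_frame()
    df["id"] = df.index.astype(str)
    df = df.sort_values(["v", "id"], ascending=[ascending, True])
    return list(df.index[:n])


def run_cascade(
    cfg: CascadeConfig,
    score_table: ScoreTable | pd.DataFrame,
    nbc_model: nbc_mod.NBCModel,
    descriptors: dict[str, DescriptorRecord] | list[DescriptorRecord],
    fingerprints: dict[str, Fingerprint] | list[Fingerprint],
    poses: dict[str, LigandPose] | None = None,
    receptor: StructureModel | None = None,
    interactions: dict[str, list[InteractionRecord]] | None = None,
) -> tuple[list[StageReport], list[str]]:
    """Run the five-stage cascade; returns (stage reports, final hit list).

    Interactions for stage 5 come either from ``poses`` + ``receptor``
    (geometric detection, preferred) or from precomputed ``interactions``
    records.  A stage with zero survivors completes the run with a warning
    and empty downstream stages.
    """
    scores = score_table.scores if isinstance(score_table, ScoreTable) else score_table
    if isinstance(scores.columns, pd.MultiIndex):
        scores = scores.droplevel("mode", axis=1)
    if isinstance(descriptors, list):
        descriptors = {d.compound_id: d for d in descriptors}
    if isinstance(fingerprints, list):
        fingerprints = {f.compound_id: f for f in fingerprints}

    reports: list[StageReport] = []

    # -- stage 1: ensemble docking rank ----------------------------------
    t0 = time.perf_counter()
    agg = _rank_scores(scores, cfg.rank_rule)
    s1 = _keep_top(agg, min(cfg.dock_keep, len(agg)), ascending=True)
    reports.append(StageReport("dock", len(agg), len(s1), s1, elapsed=time.perf_counter() - t0))
    logger.info("stage dock: %d -> %d", len(agg), len(s1))

    # -- stage 2: naive Bayes consensus re-score -------------------------
    t0 = time.perf_counter()
    if s1:
        sub = scores.loc[s1]
        sub.columns = [str(c) for c in sub.columns]
        bayes = nbc_mod.score_frame(nbc_model, sub)
        s2 = _keep_top(bayes, min(cfg.bayes_keep, len(s1)), ascending=False)
    else:
        bayes = pd.Series(dtype=float)
        s2 = []
    reports.append(StageReport("bayes", len(s1), len(s2), s2, elapsed=time.perf_counter() - t0))
    logger.info("stage bayes: %d -> %d", len(s1), len(s2))

    # -- stage 3: drug-likeness ------------------------------------------
    t0 = time.perf_counter()
    dropped3: dict[str, str] = {}
    passed = []
    for cid in s2:
        rec = descriptors.get(cid)
        if rec is None:
            dropped3[cid] = "no descriptors"
            logger.debug("druglike drop %s: no descriptors", cid)
            continue
        ok_lv, why_lv = lipinski_veber_pass(rec, cfg.max_lipinski_violations)
        if not ok_lv:
            dropped3[cid] = "lipinski_veber:" + ";".join(why_lv)
            continue
        ok_re, why_re = reos_pass(rec)
        if not ok_re:
            dropped3[cid] = "reos:" + ";".join(why_re)
            continue
        passed.append(cid)
    if len(passed) > cfg.druglike_keep:
        s3 = _keep_top(bayes.loc[passed], cfg.druglike_keep, ascending=False)
    else:
        s3 = passed
    reports.append(
        StageReport("druglike", len(s2), len(s3), s3, dropped=dropped3,
                    elapsed=time.perf_counter() - t0)
    )
    logger.info("stage druglike: %d -> %d", len(s2), len(s3))

    # -- stage 4: scaffold diversity -------------------------------------
    t0 = time.perf_counter()
    if s3:
        missing_fp = [c for c in s3 if c not in fingerprints]
        if missing_fp:
            raise ValueError(f"no fingerprints for: {missing_fp[:5]}")
        fps = [fingerprints[c] for c in s3]
        assignment = butina_cluster(fps, cutoff=cfg.similarity_cutoff)
        n_pick = min(cfg.diversity_keep, len(s3))
        s4 = diversity_pick(assignment, {c: float(bayes[c]) for c in s3}, n_pick)
    else:
        s4 = []
    reports.append(StageReport("diversity", len(s3), len(s4), s4,
                               elapsed=time.perf_counter() - t0))
    logger.info("stage diversity: %d -> %d", len(s3), len(s4))

    # -- stage 5: hot-residue interactions -------------------------------
    t0 = time.perf_counter()
    dropped5: dict[str, str] = {}
    kept5 = []
    for cid in s4:
        if poses is not None and receptor is not None and cid in poses:
            records = detect_all(poses[cid], receptor)
        elif interactions is not None and cid in interactions:
            records = interactions[cid]
        else:
            dropped5[cid] = "no pose or interaction records"
            logger.debug("interaction drop %s: no data", cid)
            continue
        if hot_residue_filter(records, cfg.hot_set, require=cfg.hot_require,
                              itypes=frozenset(cfg.hot_itypes)):
            kept5.append(cid)
        else:
            dropped5[cid] = "missing hot-residue contact"
    if len(kept5) > cfg.final_keep:
        s5 = _keep_top(bayes.loc[kept5], cfg.final_keep, ascending=False)
    else:
        s5 = kept5
    reports.append(
        StageReport("interactions", len(s4), len(s5), s5, dropped=dropped5,
                    elapsed=time.perf_counter() - t0)
    )
    logger.info("stage interactions: %d -> %d", len(s4), len(s5))
    if any(r.n_out == 0 for r in reports):
        first = next(r.stage for r in reports if r.n_out == 0)
        logger.warning("stage %r produced 0 survivors; downstream stages empty", first)

    # cascade invariant: monotone nesting
    prev = None
    for r in reports:
        if prev is not None:
            assert set(r.survivors) <= prev, f"stage {r.stage} is not nested"
        prev = set(r.survivors)
    return reports, s5


def validate_ensemble(
    table: ScoreTable,
    redock_rmsds: dict[tuple[str, str], float] | None = None,
    n_bins: int = 10,
    ttest_variant: str = "student",
    auc_satisfactory: float = 0.7,
) -> tuple[ValidationReport, nbc_mod.NBCModel]:
    """Validate every (conformation, mode) and fit the consensus model.

    For each column: two-sample t-test between inhibitor and decoy score
    distributions, ROC AUC (lower score = more active), and — when supplied
    — the re-dock RMSD with its <= 2 Å success flag.  The preferred mode per
    conformation is the one with the smaller t-test p-value.  The combined
    naive Bayes model is then fitted on the chosen-mode columns; its single-
    feature AUCs and the combined AUC land in the report attributes.
    """
    if table.labels is None:
        raise ValueError("validation requires labels")
    if len(table.conformation_ids) < 2:
        raise ValueError("ensemble validation needs >= 2 conformations")
    y = table.labels.to_numpy(dtype=int)
    rows = []
    for conf, mode in table.scores.columns:
        x = table.scores[(conf, mode)].to_numpy(dtype=float)
        mask = np.isfinite(x)
        a = x[mask][y[mask] == 1]
        d = x[mask][y[mask] == 0]
        t, p = two_sample_ttest(a, d, variant=ttest_variant)
        df_ = (len(a) + len(d) - 2) if ttest_variant == "student" else _welch_df(a, d)
        auc = roc_auc(x, y, orientation=LOWER_IS_ACTIVE)
        rmsd = (redock_rmsds or {}).get((conf, mode), float("nan"))
        rows.append({
            "conformation_id": conf,
            "mode": mode,
            "redock_rmsd": rmsd,
            "docking_success": docking_power(rmsd) if np.isfinite(rmsd) else None,
            "t_stat": t,
            "p_value": p,
            "log10_p": log10_p_from_t(t, df_) if p > 0 else float("-inf"),
            "auc": auc,
            "satisfactory": auc > auc_satisfactory,
        })
    rep_table = pd.DataFrame(rows).set_index(["conformation_id", "mode"])
    report = ValidationReport(table=rep_table)
    report.chosen_mode = choose_mode(report)
    chosen_df = table.select_mode(report.chosen_mode)
    model = nbc_mod.fit_nbc(chosen_df, table.labels, n_bins=n_bins)
    report.single_feature_auc = {
        c: nbc_mod.model_auc(
            nbc_mod.fit_nbc(chosen_df[[c]], table.labels, n_bins=n_bins),
            chosen_df[[c]], table.labels,
        )
        for c in chosen_df.columns
    }
    report.combined_auc = nbc_mod.model_auc(model, chosen_df, table.labels)
    return report, model


def _welch_df(a: np.ndarray, d: np.ndarray) -> float:
    va, vd = a.var(ddof=1) / len(a), d.var(ddof=1) / len(d)
    return (va + vd) ** 2 / (va**2 / (len(a) - 1) + vd**2 / (len(d) - 1))
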