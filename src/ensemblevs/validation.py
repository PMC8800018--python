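"""Docking-power and screening-power validation of an ensemble.

Two questions are asked of every conformation before it earns a place in
the screening ensemble: can the docking protocol reproduce the known
crystallographic ligand pose (re-dock RMSD, success at <= 2 Å), and do the
docking scores of known inhibitors separate from those of decoys (two-sample
t-test on the score distributions, ROC AUC)?  Both are computed per docking
mode (e.g. standard vs extra precision) and the better-separating mode is
chosen per conformation.

Convention used package-wide: docking scores are kcal/mol-like, lower
(more negative) = better.  Every ranking call states its orientation
explicitly so the convention can never silently invert.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.stats import rankdata

__all__ = [
    "ScoreTable",
    "ValidationReport",
    "pose_rmsd",
    "docking_power",
    "two_sample_ttest",
    "roc_auc",
    "choose_mode",
    "enrichment_factor",
]

logger = logging.getLogger(__name__)

LOWER_IS_ACTIVE = "lower_is_active"
HIGHER_IS_ACTIVE = "higher_is_active"


@dataclass
class ScoreTable:
    """Compounds x (conformation, mode) matrix of docking scores.

    ``scores`` is a DataFrame indexed by compound id with MultiIndex columns
    ``(conformation_id, mode)``; NaN marks a compound that failed to dock in
    that conformation.  ``labels`` maps compound id -> 1 (inhibitor) /
    0 (decoy) when the table is a validation set.
    """

    scores: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.scores.columns, pd.MultiIndex):
            raise ValueError("scores columns must be a (conformation, mode) MultiIndex")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.scores.index)
            if self.labels.isna().any():
                missing = list(self.scores.index[self.labels.isna()])[:5]
                raise ValueError(f"labels missing for compounds: {missing} ...")
            bad = set(self.labels.unique()) - {0, 1}
            if bad:
                raise ValueError(f"labels must be 0/1, found {sorted(bad)}")
            self.labels = self.labels.astype(int)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def conformation_ids(self) -> list[str]:
        seen = dict.fromkeys(c for c, _ in self.scores.columns)
        return list(seen)

    @property
    def modes(self) -> list[str]:
        seen = dict.fromkeys(m for _, m in self.scores.columns)
        return list(seen)

    def column(self, conformation: str, mode: str) -> pd.Series:
        return self.scores[(conformation, mode)]

    def select_mode(self, chosen: dict[str, str]) -> pd.DataFrame:
        """One column per conformation using the chosen mode for each."""
        cols = {c: self.scores[(c, m)] for c, m in chosen.items()}
        return pd.DataFrame(cols)

    # -- long-format CSV round trip --------------------------------------
    def to_csv(self, path) -> None:
        long = self.scores.stack(level=[0, 1], future_stack=True).rename("score").reset_index()
        long.columns = ["compound_id", "conformation_id", "mode", "score"]
        long = long.dropna(subset=["score"])
        if self.labels is not None:
            long["label"] = long["compound_id"].map(self.labels)
        long.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScoreTable":
        long = pd.read_csv(path)
        required = {"compound_id", "conformation_id", "mode", "score"}
        if not required <= set(long.columns):
            raise ValueError(f"score CSV needs columns {sorted(required)}")
        wide = long.pivot_table(
            index="compound_id", columns=["conformation_id", "mode"], values="score",
            aggfunc="first",
        )
        labels = None
        if "label" in long.columns:
            labels = long.groupby("compound_id")["label"].first()
        return cls(scores=wide, labels=labels)


@dataclass
class ValidationReport:
    """Per-(conformation, mode) docking/screening power summary.

    ``table`` columns: ``redock_rmsd`` (Å, NaN when no reference pose was
    supplied), ``docking_success``, ``t_stat``, ``p_value``, ``log10_p``
    (p reported in log10 space as well because magnitudes reach 1e-250),
    ``auc``.  ``chosen_mode`` maps each conformation to its preferred mode.
    """

    table: pd.DataFrame
    chosen_mode: dict[str, str] = field(default_factory=dict)
    single_feature_auc: dict[str, float] = field(default_factory=dict)
    combined_auc: float | None = None

    def to_csv(self, path) -> None:
        out = self.table.reset_index()
        out["chosen"] = [
            self.chosen_mode.get(c) == m for c, m in zip(out["conformation_id"], out["mode"])
        ]
        out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pose RMSD / docking power
# ---------------------------------------------------------------------------

def pose_rmsd(a, b, matching: str = "ordered") -> float:
    """In-place RMSD between two poses of the same molecule (no superposition).

    Both poses are assumed to sit in the same receptor frame, as after
    re-docking into the crystal structure.  Hydrogens are excluded.  With
    ``matching="element_hungarian"`` the atom assignment within each element
    class is optimized (Hungarian algorithm on squared distances), which
    forgives symmetric-group relabelling; ``"ordered"`` trusts input order.
    """
    ea, xa = _heavy(a)
    eb, xb = _heavy(b)
    if len(ea) != len(eb):
        raise ValueError(f"atom-count mismatch: {len(ea)} vs {len(eb)}")
    if matching == "ordered":
        if ea != eb:
            raise ValueError("element sequences differ; use element_hungarian matching")
        return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))
    if matching != "element_hungarian":
        raise ValueError(f"unknown matching {matching!r}")
    if sorted(ea) != sorted(eb):
        raise ValueError("element compositions differ")
    sq_total = 0.0
    for elem in set(ea):
        ia = [i for i, e in enumerate(ea) if e == elem]
        ib = [i for i, e in enumerate(eb) if e == elem]
        cost = ((xa[ia, None, :] - xb[None, ib, :]) ** 2).sum(axis=2)
        r, c = linear_sum_assignment(cost)
        sq_total += float(cost[r, c].sum())
    return float(np.sqrt(sq_total / len(ea)))


def _heavy(pose):
    """Extract (elements, coords) for heavy atoms from a pose-like object."""
    if hasattr(pose, "atoms"):
        items = [(at.element, at.xyz) for at in pose.atoms]
    else:
        items = [(e, x) for e, x in pose]
    items = [(e.upper(), x) for e, x in items if e.upper() != "H"]
    if not items:
        raise ValueError("pose has no heavy atoms")
    elems = [e for e, _ in items]
    xyz = np.array([x for _, x in items], dtype=float)
    return elems, xyz


def docking_power(redock_rmsd: float, threshold: float = 2.0) -> bool:
    """Success flag for pose reproduction: RMSD <= threshold (inclusive)."""
    if redock_rmsd < 0:
        raise ValueError("RMSD cannot be negative")
    return redock_rmsd <= threshold


# ---------------------------------------------------------------------------
# Score separation statistics
# ---------------------------------------------------------------------------

def two_sample_ttest(a, b, variant: str = "student") -> tuple[float, float]:
    """Two-sided two-sample t-test on score distributions.

    ``student`` pools the variance (df = n1 + n2 - 2); ``welch`` uses the
    Satterthwaite approximation — the latter is worth checking when group
    sizes are as lopsided as 1:20.  Degenerate zero-variance inputs follow
    the convention p = 1 for equal means, p = 0 (flagged in the log) for
    unequal means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        logger.warning("zero-variance samples with unequal means: degenerate p=0")
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def log10_p_from_t(t: float, df: float) -> float:
    """log10 of the two-sided p-value; safe far below float underflow."""
    return float((stats.t.logsf(abs(t), df) + np.log(2.0)) / np.log(10.0))


def roc_auc(scores, labels, orientation: str) -> float:
    """Area under the ROC curve by the rank (Mann–Whitney) method.

    Equals the probability that a random active outranks a random decoy,
    with ties counted half.  ``orientation`` must be ``"lower_is_active"``
    (docking scores) or ``"higher_is_active"`` (posterior-like scores).
    NaN scores are dropped pairwise with their labels.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels length mismatch")
    keep = np.isfinite(scores)
    if not keep.all():
        logger.info("roc_auc: dropping %d missing scores", (~keep).sum())
        scores, labels = scores[keep], labels[keep]
    n_act = int((labels == 1).sum())
    n_dec = int((labels == 0).sum())
    if n_act == 0 or n_dec == 0:
        raise ValueError("both classes must be present")
    if orientation == LOWER_IS_ACTIVE:
        scores = -scores
    elif orientation != HIGHER_IS_ACTIVE:
        raise ValueError(f"unknown orientation {orientation!r}")
    ranks = rankdata(scores)  # average ranks handle ties -> half credit
    u = ranks[labels == 1].sum() - n_act * (n_act + 1) / 2.0
    return float(u / (n_act * n_dec))


def enrichment_factor(scores, labels, top_fraction: float, orientation: str = LOWER_IS_ACTIVE) -> float:
    """Actives concentration in the top-ranked fraction relative to random.

    EF = (actives in top f / compounds in top f) / (actives / total).
    The top slice holds ``ceil(f * n)`` compounds; boundary ties are broken
    by rank order after a stable sort.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    keep = np.isfinite(scores)
    scores, labels = scores[keep], labels[keep]
    n = len(scores)
    n_top = int(np.ceil(top_fraction * n))
    if n == 0 or n_top == 0:
        raise ValueError("empty top slice")
    order = np.argsort(scores if orientation == LOWER_IS_ACTIVE else -scores, kind="stable")
    top = labels[order[:n_top]]
    total_rate = labels.mean()
    if total_rate == 0:
        raise ValueError("no actives present")
    return float((top.mean()) / total_rate)


def choose_mode(report: ValidationReport) -> dict[str, str]:
    """Preferred docking mode per conformation: best score separation wins.

    Smaller t-test p-value (compared in log10 space) wins; ties break to the
    higher AUC, then to the first-listed mode.
    """
    chosen: dict[str, str] = {}
    t = report.table
    for conf in t.index.get_level_values("conformation_id").unique():
        sub = t.loc[conf]
        if len(sub) < 2:
            logger.info("conformation %r evaluated in a single mode; choosing it", conf)
        best = None
        for order, (mode, row) in enumerate(sub.iterrows()):
            key = (row["log10_p"], -row["auc"], order)
            if best is None or key < best[0]:
                best = (key, mode)
        chosen[conf] = best[1]
    return chosen
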