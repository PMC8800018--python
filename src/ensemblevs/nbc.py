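"""Naive Bayesian consensus scoring over per-conformation docking scores.

Each conformation of the ensemble contributes one continuous feature — the
compound's docking score against that structure.  Features are discretized
by equal-frequency binning, and each bin b of each conformation gets a
Laplacian-corrected log-likelihood-ratio weight

    w_b = ln[ (A_b + 1) / ((N_b + 1) * prior) ],     prior = A_total / N_total,

where A_b / N_b are the active / total training counts in the bin.  A
compound's consensus score is the sum of bin weights over the conformations
where it has a score; higher = more inhibitor-like.  The Laplace (+1)
correction shrinks sparse-bin estimates toward the class prior, which is
what keeps a 1:20 active:decoy imbalance from destabilising rare bins.

The naive conditional-independence assumption is exactly what makes the
ensemble pay off: conformations that rank compounds differently contribute
complementary evidence, and the additive combination outperforms any single
conformation's ranking.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .validation import HIGHER_IS_ACTIVE, ScoreTable, roc_auc

__all__ = [
    "NBCModel",
    "equal_frequency_edges",
    "fit_nbc",
    "nbc_score",
    "model_auc",
]

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1


@dataclass
class NBCModel:
    """Fitted naive Bayes consensus model.

    ``bin_edges[j]`` holds the interior edges (ascending) for conformation
    j; ``bin_weights[j]`` the per-bin log-likelihood-ratio weights (one more
    entry than edges).  ``training_counts[j]`` keeps the raw (A_b, N_b)
    pairs for audit.  Scores outside the training range clamp into the first
    or last bin.
    """

    conformation_ids: list[str]
    bin_edges: dict[str, np.ndarray]
    bin_weights: dict[str, np.ndarray]
    prior_active: float
    n_bins: int
    training_counts: dict[str, list[tuple[int, int]]]
    gaussian: bool = False
    gaussian_params: dict[str, tuple[float, float, float, float]] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.prior_active < 1:
            raise ValueError("prior_active must be in (0, 1)")
        for j in self.conformation_ids:
            edges = np.asarray(self.bin_edges[j], dtype=float)
            if len(edges) and (np.diff(edges) <= 0).any():
                raise ValueError(f"bin edges for {j!r} not strictly ascending")
            if not np.isfinite(self.bin_weights[j]).all():
                raise ValueError(f"non-finite weight for {j!r}")

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "format_version": FORMAT_VERSION,
            "model": "laplacian-corrected naive Bayes (equal-frequency bins)",
            "n_bins": self.n_bins,
            "prior_active": self.prior_active,
            "gaussian": self.gaussian,
            "conformations": [
                {
                    "id": j,
                    "edges": list(map(float, self.bin_edges[j])),
                    "weights": list(map(float, self.bin_weights[j])),
                    "counts": [[int(a), int(n)] for a, n in self.training_counts[j]],
                }
                for j in self.conformation_ids
            ],
        }
        if self.gaussian and self.gaussian_params:
            doc["gaussian_params"] = {
                j: list(map(float, p)) for j, p in self.gaussian_params.items()
            }
        text = json.dumps(doc, indent=2, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "NBCModel":
        if hasattr(source, "read"):
            doc = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        if doc.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported model format {doc.get('format_version')!r}")
        confs = doc["conformations"]
        gp = doc.get("gaussian_params")
        return cls(
            conformation_ids=[c["id"] for c in confs],
            bin_edges={c["id"]: np.array(c["edges"], dtype=float) for c in confs},
            bin_weights={c["id"]: np.array(c["weights"], dtype=float) for c in confs},
            prior_active=doc["prior_active"],
            n_bins=doc["n_bins"],
            training_counts={c["id"]: [tuple(x) for x in c["counts"]] for c in confs},
            gaussian=doc.get("gaussian", False),
            gaussian_params={j: tuple(p) for j, p in gp.items()} if gp else None,
        )


def equal_frequency_edges(values, n_bins: int) -> np.ndarray:
    """Interior bin edges at empirical quantiles i/n_bins (midpoint rule).

    Duplicate edges (possible when many values tie) are collapsed with a
    warning, so the effective number of bins can shrink.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        raise ValueError("no finite values to bin")
    qs = np.arange(1, n_bins) / n_bins
    edges = np.quantile(values, qs, method="midpoint")
    uniq = np.unique(edges)
    if len(uniq) < len(edges):
        logger.warning(
            "equal_frequency_edges: %d duplicate quantiles collapsed (%d -> %d bins)",
            len(edges) - len(uniq), n_bins, len(uniq) + 1,
        )
    return uniq


def _bin_index(edges: np.ndarray, x) -> np.ndarray:
    """Bin assignment with clamping; values on an edge go to the left bin."""
    return np.searchsorted(edges, np.asarray(x, dtype=float), side="left")


def fit_nbc(
    table: ScoreTable | pd.DataFrame,
    labels: pd.Series | None = None,
    n_bins: int = 10,
    gaussian: bool = False,
) -> NBCModel:
    """Fit the consensus model on a labelled score table.

    ``table`` may be a :class:`ScoreTable` (one mode per conformation, see
    ``select_mode``) or a plain DataFrame with one column per conformation.
    Bin edges are placed on the pooled training scores of each conformation
    (both classes together); the Laplacian-corrected weights then encode how
    the active fraction in each bin deviates from the prior.

    With ``gaussian=True`` a class-conditional Gaussian likelihood ratio
    replaces the binned weights at scoring time (sensitivity-analysis
    variant); bins and weights are still fitted and stored.
    """
    if isinstance(table, ScoreTable):
        if labels is None:
            labels = table.labels
        df = table.select_mode({c: table.scores[c].columns[0] for c in table.conformation_ids}) \
            if isinstance(table.scores.columns, pd.MultiIndex) else table.scores
    else:
        df = table
    if labels is None:
        raise ValueError("labels are required to fit")
    labels = pd.Series(labels).reindex(df.index)
    if labels.isna().any():
        raise ValueError("labels missing for some compounds")
    y = labels.to_numpy(dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("training labels must contain both classes")

    n_total = len(y)
    a_total = int(y.sum())
    prior = a_total / n_total

    edges: dict[str, np.ndarray] = {}
    weights: dict[str, np.ndarray] = {}
    counts: dict[str, list[tuple[int, int]]] = {}
    gauss: dict[str, tuple[float, float, float, float]] = {}
    for j in df.columns:
        x = df[j].to_numpy(dtype=float)
        mask = np.isfinite(x)
        if not mask.any():
            raise ValueError(f"conformation {j!r} has no scores")
        e = equal_frequency_edges(x[mask], n_bins)
        idx = _bin_index(e, x[mask])
        yj = y[mask]
        nb = len(e) + 1
        A = np.bincount(idx[yj == 1], minlength=nb).astype(int)
        N = np.bincount(idx, minlength=nb).astype(int)
        w = np.log((A + 1) / ((N + 1) * prior))
        edges[str(j)] = e
        weights[str(j)] = w
        counts[str(j)] = list(zip(A.tolist(), N.tolist()))
        if gaussian:
            xa, xd = x[mask][yj == 1], x[mask][yj == 0]
            gauss[str(j)] = (
                float(xa.mean()), float(xa.std(ddof=1) or 1e-9),
                float(xd.mean()), float(xd.std(ddof=1) or 1e-9),
            )
    return NBCModel(
        conformation_ids=[str(j) for j in df.columns],
        bin_edges=edges,
        bin_weights=weights,
        prior_active=prior,
        n_bins=n_bins,
        training_counts=counts,
        gaussian=gaussian,
        gaussian_params=gauss if gaussian else None,
    )


def nbc_score(model: NBCModel, score_vector) -> float:
    """Consensus score of one compound: sum of bin weights over present features.

    ``score_vector`` is a mapping conformation id -> docking score (NaN or
    absent = missing).  All-missing input is an error.  Higher output =
    more inhibitor-like.
    """
    total = 0.0
    n_used = 0
    for j in model.conformation_ids:
        x = score_vector.get(j) if hasattr(score_vector, "get") else score_vector[j]
        if x is None or not np.isfinite(x):
            continue
        if model.gaussian and model.gaussian_params:
            ma, sa, md, sd = model.gaussian_params[j]
            from scipy.stats import norm

            total += float(norm.logpdf(x, ma, sa) - norm.logpdf(x, md, sd))
        else:
            b = int(_bin_index(model.bin_edges[j], [x])[0])
            total += float(model.bin_weights[j][b])
        n_used += 1
    if n_used == 0:
        raise ValueError("all features missing: cannot score compound")
    return total


def score_frame(model: NBCModel, df: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`nbc_score` over a compounds x conformations frame."""
    missing_cols = [j for j in model.conformation_ids if j not in map(str, df.columns)]
    if missing_cols:
        raise ValueError(f"frame lacks conformations: {missing_cols}")
    out = np.zeros(len(df))
    n_used = np.zeros(len(df), dtype=int)
    cols = {str(c): c for c in df.columns}
    for j in model.conformation_ids:
        x = df[cols[j]].to_numpy(dtype=float)
        mask = np.isfinite(x)
        if model.gaussian and model.gaussian_params:
            from scipy.stats import norm

            ma, sa, md, sd = model.gaussian_params[j]
            contrib = norm.logpdf(x, ma, sa) - norm.logpdf(x, md, sd)
        else:
            b = _bin_index(model.bin_edges[j], x)
            b = np.clip(b, 0, len(model.bin_weights[j]) - 1)
            contrib = model.bin_weights[j][b]
        out[mask] += contrib[mask]
        n_used += mask
    if (n_used == 0).any():
        bad = list(df.index[n_used == 0])[:5]
        raise ValueError(f"compounds with all scores missing: {bad} ...")
    return pd.Series(out, index=df.index, name="nbc_score")


def model_auc(model: NBCModel, table: ScoreTable | pd.DataFrame, labels=None) -> float:
    """Resubstitution AUC of the consensus score against the 0/1 labels."""
    if isinstance(table, ScoreTable):
        if labels is None:
            labels = table.labels
        df = table.select_mode({c: table.scores[c].columns[0] for c in table.conformation_ids}) \
            if isinstance(table.scores.columns, pd.MultiIndex) else table.scores
    else:
        df = table
    if labels is None:
        raise ValueError("labels required")
    s = score_frame(model, df)
    y = pd.Series(labels).reindex(df.index).to_numpy(dtype=int)
    return roc_auc(s.to_numpy(), y, orientation=HIGHER_IS_ACTIVE)


def stratified_kfold_auc(
    df: pd.DataFrame, labels: pd.Series, n_bins: int = 10, k: int = 5, seed: int = 0
) -> float:
    """Optional held-out check: mean AUC over stratified k folds."""
    rng = np.random.default_rng(seed)
    y = pd.Series(labels).reindex(df.index).to_numpy(dtype=int)
    folds = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    aucs = []
    for f in range(k):
        tr, te = folds != f, folds == f
        m = fit_nbc(df.iloc[tr], pd.Series(y[tr], index=df.index[tr]), n_bins=n_bins)
        s = score_frame(m, df.iloc[te])
        aucs.append(roc_auc(s.to_numpy(), y[te], orientation=HIGHER_IS_ACTIVE))
    return float(np.mean(aucs))
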