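# ensemblevs

Multi-conformation ("ensemble") structure-based virtual screening in Python:
conformer-ensemble construction, per-conformation docking validation, naive
Bayes consensus scoring of docking-score profiles, and a sequential
hit-selection cascade with drug-likeness, diversity and interaction filters.

## Who this is for

Docking a compound library against a single rigid crystal structure ignores
receptor flexibility; kinases such as PI3Kγ crystallize in many binding-site
conformations and different inhibitor chemotypes prefer different ones.
Ensemble docking screens the library against a panel of representative
conformations and combines the per-conformation scores into one consensus
ranking. `ensemblevs` implements the statistical machinery around that idea
for people who already have a docking engine (Glide, Vina, ...) and need
everything before and after it:

- **before docking** — pick the panel: parse the crystal structures, extract
  the binding site (residues within 10 Å of the co-crystallized ligand),
  superpose site atoms between structures (Kabsch), cluster the pairwise-RMSD
  matrix (UPGMA) into *k* conformational families, and take the
  highest-resolution member of each family;
- **validating the panel** — docking power (re-dock RMSD ≤ 2.0 Å) and
  screening power (inhibitor/decoy score separation by two-sample *t*-test
  and ROC AUC) per conformation and docking mode, with automatic choice of
  the better mode;
- **consensus scoring** — a Laplacian-corrected naive Bayesian classifier
  over the per-conformation docking scores: scores are discretized into
  equal-frequency bins and each bin *b* carries the weight
  `w_b = ln[(A_b + 1) / ((N_b + 1)·p)]`, where `A_b`/`N_b` are the active and
  total training counts in the bin and `p = A/N` is the active prior; a
  compound's consensus score is the sum of its bin weights across
  conformations, higher = more inhibitor-like;
- **after scoring** — the sequential triage: rank by ensemble docking score,
  re-rank by consensus score, Lipinski/Veber and REOS drug-likeness screens,
  Butina diversity clustering on fingerprints (Tanimoto ≥ 0.8) with a
  round-robin scaffold pick, and a geometric hot-residue interaction filter
  (hydrogen-bond/hydrophobic/ionic detectors) on the docked poses;
- **pose analytics** — per-atom ligand RMSF and per-residue interaction
  occupancy over snapshot series.

Docking itself is out of scope: score tables, descriptor tables,
fingerprints and poses are inputs (CSV / PDB), and a seeded synthetic
generator (`ensemblevs.fixtures`) stands in for them so the whole pipeline
runs and is testable without any external engine or download.

## Worked example

Why does the ensemble beat its best member?  Each conformation ranks the
library with its own errors; if those errors are only weakly correlated, the
additive consensus cancels them.  Simulate a 1:20 validation set (800
inhibitors, 16,000 decoys) docked into 10 conformations, each conformation
calibrated to a single-feature AUC of about 0.75:

```python
import numpy as np
from scipy.stats import norm
from ensemblevs import ScreenSimConfig, gen_score_table, validate_ensemble

delta = norm.ppf(0.75) * np.sqrt(2)   # class separation for AUC 0.75
cfg = ScreenSimConfig(n_active=800, n_decoy=16_000, n_conformations=10,
                      mu_active=-7.0 - delta, mu_decoy=-7.0, seed=7)
table = gen_score_table(cfg)
report, model = validate_ensemble(table)
for conf, auc in report.single_feature_auc.items():
    print(f"{conf}: single-conformation AUC = {auc:.3f}")
print(f"combined consensus AUC = {report.combined_auc:.3f}")
```

```
CONF00: single-conformation AUC = 0.759
CONF01: single-conformation AUC = 0.755
CONF02: single-conformation AUC = 0.747
CONF03: single-conformation AUC = 0.738
CONF04: single-conformation AUC = 0.737
CONF05: single-conformation AUC = 0.751
CONF06: single-conformation AUC = 0.751
CONF07: single-conformation AUC = 0.758
CONF08: single-conformation AUC = 0.740
CONF09: single-conformation AUC = 0.742
combined consensus AUC = 0.984
```

Every conformation alone is a mediocre classifier (AUC ≈ 0.74–0.76); the
ten-feature naive Bayes consensus separates inhibitors from decoys almost
perfectly because the conformations' errors are conditionally independent
here.  Real docking scores are correlated across conformations, so real
gains are smaller — the generator's `rho` parameter dials exactly that.

The same operations are available from the shell:

```bash
ensemble-vs fixtures make --what scores --n 16800 --n-active 800 --out scores.csv
ensemble-vs validate scores.csv --model-out nbc.json
ensemble-vs cascade run scores.csv nbc.json descriptors.csv fingerprints.csv \
    --config cascade.yaml --hits-out hits.csv
```

## Layout

- `ensemblevs.structures` — PDB parsing, binding sites, Kabsch, RMSD
  matrices, UPGMA clustering, representative selection
- `ensemblevs.validation` — pose RMSD, docking power, *t*-test, ROC AUC,
  enrichment factor, mode choice, score-table I/O
- `ensemblevs.nbc` — the naive Bayes consensus model (fit / score / AUC,
  JSON serialization)
- `ensemblevs.chemfilters` — Lipinski/Veber, REOS, Tanimoto, Butina,
  diversity pick, descriptor/fingerprint I/O
- `ensemblevs.interactions` — geometric contact detectors, hot-residue
  filter, interaction occupancy, ligand RMSF
- `ensemblevs.fixtures` — seeded synthetic generators for every input type
- `ensemblevs.pipeline` — cascade orchestration and ensemble validation
- `ensemblevs.cli` — the `ensemble-vs` command

See `docs/methods.md` for the statistical model, parameter defaults, and
known limitations.
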