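# Methods

This note documents the models and procedures implemented in `ensemblevs`,
the defaults they ship with, and what the synthetic-data tests do and do not
demonstrate about real screening data.

## Ensemble construction

Crystal structures of one target are reduced to a docking panel in four
steps.

**Binding-site definition.** A residue belongs to the binding site iff any
of its atoms lies within a cutoff (default 10 Å, inclusive) of any atom of
the co-crystallized ligand.  The site is defined on one reference structure
and applied as a `(chain, residue_number)` selection to all ensemble
members, which assumes a shared sequence and numbering — true for an
ensemble of one protein, not for homologs.

**Superposition.** Inter-conformation RMSD uses Kabsch least-squares
superposition (SVD form, determinant-corrected so the rotation is always
proper) on the CA atoms of the site selection by default; all heavy atoms
are available behind a flag.  CA-only is the conservative choice when side
chains were refined differently between entries.  Correspondence is by
residue identity, so no sequence alignment is needed or performed.
Collinear point sets are rejected rather than silently returning one of the
infinitely many optimal rotations.

**Clustering.** The pairwise-RMSD matrix is clustered by average-linkage
(UPGMA) agglomeration cut at *k* clusters (default *k* = 10).  Merging is
deterministic: among equidistant cluster pairs, the pair whose smallest
member ids sort first merges first.  The implementation is a direct O(n³)
agglomeration — ensembles are tens of structures, not thousands — and is
cross-checked against `scipy.cluster.hierarchy.linkage` on matrices with
distinct distances.  RMSD after independent pairwise fits is not a metric
(the triangle inequality can fail), which UPGMA tolerates.

**Representative selection.** Each cluster contributes its
highest-resolution member (smallest Å; ties to the lexicographically
smallest id).  Resolution comes from the `REMARK 2` header or an override
table.

## Validation statistics

**Docking power** is the re-dock RMSD between a docked pose and the crystal
pose in the shared receptor frame (no superposition), success at ≤ 2.0 Å
inclusive.  Pose RMSD supports ordered matching or an optimal per-element
assignment (Hungarian algorithm) that forgives symmetric-group relabelling;
hydrogens are excluded.

**Screening power** per (conformation, mode):

- a two-sided two-sample *t*-test between inhibitor and decoy score
  distributions.  The default is the pooled-variance (Student) variant;
  Welch is available because the 1:20 class design makes the equal-variance
  assumption worth probing.  P-values are also reported in log10 space
  (computed via the log-survival function) because realistic separations
  drive them far below double-precision underflow.
- ROC AUC by the rank (Mann–Whitney) method with ties counted ½, computed
  with an explicit orientation argument (`lower_is_active` for docking
  scores) so the sign convention can never silently flip.  The satisfaction
  threshold for a usable conformation is AUC > 0.7.

The preferred mode per conformation is the one with the smaller t-test
p-value (compared in log space), ties broken by higher AUC, then first
listed.  Missing scores are dropped pairwise from the statistics; in the
cascade ranking they are instead imputed with the conformation's worst
observed score + 1.0, penalising but not excluding a compound that failed
to dock somewhere.  Both behaviours are logged.

## Naive Bayes consensus model

Continuous docking scores are discretized per conformation into
equal-frequency bins (default 10) with interior edges at the empirical
quantiles i/n_bins (midpoint convention).  Edges are fitted on the pooled
training scores of both classes; duplicate quantiles collapse with a
warning, shrinking the effective bin count.  Bin *b* of conformation *j*
carries the Laplacian-corrected log-likelihood-ratio weight

    w_jb = ln[(A_jb + 1) / ((N_jb + 1) · p)],    p = A_total / N_total,

and a compound's score is Σ_j w_j,bin(x_j) over its non-missing features;
out-of-range values clamp into the terminal bins.  The +1 correction
shrinks empty or sparse bins toward the class prior, which is what keeps
the model stable at the 1:20 operating imbalance with no resampling.  An
algebraic audit invariant follows directly from the formula:
Σ_b (N_b + 1)·p·e^{w_b} = A_total + n_bins.

Design choices that were genuinely open:

- bin edges on the pooled sample rather than per class: per-class edges
  would make the bin supports class-dependent and the weights
  incomparable;
- the headline AUC is resubstitution (fit and evaluate on the same
  validation set); an optional stratified k-fold AUC quantifies the
  optimism, which for a single uninformative feature at n = 2000 is a
  systematic +0.03–0.04 — visible in the test suite;
- a class-conditional Gaussian likelihood variant is available behind a
  flag as a sensitivity check on the binning.

Models serialize to a versioned JSON document carrying edges, weights, raw
training counts, and the prior, so any score can be audited by hand.

## Hit-selection cascade

Five deterministic stages, each a strict subset of its predecessor
(asserted on every run): ensemble docking rank (best-across-conformations
by default, mean as alternative) → consensus re-score → Lipinski/Veber then
REOS → Butina diversity clustering + round-robin scaffold pick → hot-residue
interaction filter, with final capping by consensus score.  The shipped
default stage profile is 10,000 / 2,000 / 200 / 100 / 49, the conventional
shape for a ~2 M-compound campaign; all sizes live in one YAML config.
Boundary ties anywhere break lexicographically by compound id, making
reruns byte-identical and the output invariant to input row order.

Filter windows (all boundaries inclusive): Lipinski MW ≤ 500, logP ≤ 5,
HBD ≤ 5, HBA ≤ 10 with a configurable number of tolerated violations;
Veber RotB ≤ 10, TPSA ≤ 140 Å² (never waivable); REOS MW 200–500, logP
−5…5, HBD ≤ 5, HBA ≤ 10, formal charge −2…+2, RotB ≤ 8, heavy atoms 15–50,
plus named reactive-group exclusion flags.  Descriptors are consumed from
tables, not computed — the rules are the contribution here, and computing
logP/TPSA would drag in a chemistry stack; an optional RDKit adapter fills
descriptor records from molecules when one is available.

Diversity uses Butina sphere-exclusion clustering on Tanimoto similarity
(membership ≥ cutoff, default 0.8; a strict-inequality flag exists because
"higher than 0.8" is ambiguous at the boundary), with centroids taken in
descending neighbour-count order, ties to the smaller id.

## Interaction detection

Geometric detectors on static coordinates, all cutoffs config-exposed since
there is no universal convention:

- hydrogen bond: ligand N/O to receptor N/O heavy-atom distance ≤ 3.5 Å and
  D–H...A angle ≥ 120° when a donor hydrogen position is available; without
  hydrogens the angle gate is skipped with a warning (distance-only);
- hydrophobic: ligand carbon to side-chain carbon ≤ 4.5 Å, aggregated to
  one record per residue at the minimum distance;
- ionic: oppositely charged group centres ≤ 4.0 Å (Asp/Glu carboxylates
  negative; Lys/Arg/His nitrogen clusters positive; each charged ligand
  atom its own centre);
- water bridge (optional, off by default): ligand–water and water–residue
  both ≤ 3.5 Å; requires explicit water oxygens.

All detectors are invariant under joint rigid motion of pose and receptor
(tested to 1e-8 Å) and independent of atom order (records sorted by
residue, type, distance).  The shipped hot-residue profile for PI3Kγ —
Val882, Lys833, Tyr867, Asp964, Asp836, Thr886, Thr887, Met953, Ile963 —
is the hinge valine plus the recurrently contacted pocket residues for that
target and is fully user-overridable; any other target needs its own list.

Ligand RMSF is √(mean_t ‖x_i(t) − x̄_i‖²) per atom, after aligning each
frame's receptor CA set onto the first frame when per-frame receptors are
given.  Interaction occupancy is the fraction of frames in which a
(residue, type) contact exists, capped at one count per frame, so it always
lies in [0, 1].

## Synthetic data: what it emulates and what it does not

The generator module produces every input the pipeline consumes, from seed
alone:

- **score tables** — Gaussian class-conditional scores with an
  equicorrelation factor: score_j = μ_class,j + σ(√ρ·z + √(1−ρ)·ε_j).  This
  matches the unimodal, shifted inhibitor/decoy score histograms seen in
  practice and gives closed-form handles: single-conformation AUC =
  Φ(Δ/(σ√2)), and ρ dials the consensus gain continuously from maximal
  (ρ = 0) to nil (ρ → 1).  The default design is 800 actives vs 16,000
  decoys (1:20) over 10 conformations; tests also run a 1/10-scale profile
  (80/1,600) for speed, and the acceptance script's cascade run uses a
  20,000-compound screen with stage sizes 1,000/200/20/10/5 — the same
  shape as the full campaign at a tenth the width.
- **descriptor tables** — each property drawn from its in-range window with
  a stated probability, else from an out-of-range window, so rule pass
  rates are exact and independent.
- **fingerprints** — planted cluster templates; members keep each template
  bit with probability q = √(2T/(1+T)), which makes the expected
  member–member Tanimoto equal the target T.
- **toy complexes** — a zig-zag chain of 5-atom residues with a ligand
  placed to satisfy (or miss) the hydrogen-bond geometry at designated hot
  residues.
- **snapshot series** — isotropic Gaussian jitter, so per-atom RMSF → σ√3.

What passing on these fixtures does **not** show: real docking scores are
non-Gaussian in the tails, correlated across conformations in
structure-dependent ways, and their missingness is not random; real
fingerprints have power-law bit statistics; real poses have chemistry the
toy complexes lack.  The fixtures validate the statistical machinery and
the pipeline contracts, not any claim about a particular target's
screening enrichment.

## Numerical notes and limitations

- Equal-frequency edges use the midpoint quantile rule, so exact-tie values
  sit on a bin boundary deterministically (left bin, `side="left"`).
- AUC ties get ½ credit; the complement identity
  AUC(y) + AUC(1−y) = 1 holds exactly, not approximately.
- Degenerate t-tests (zero variance both groups) return p = 1 for equal
  means and a flagged p = 0 otherwise.
- Tanimoto of two all-zero fingerprints is 1.0 by convention, logged.
- PDB support covers the fixed-column ATOM/HETATM dialect with author
  residue numbering; altlocs beyond the first are ignored; insertion codes
  are not supported.
- Protein preparation (protonation, missing loops, minimization) is out of
  scope; structures are taken as given.
- MM/GBSA energies, ADMET prediction, promiscuity services and any docking
  engine invocation are deliberately outside the package.
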