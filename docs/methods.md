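# Methods

## The model

`ramfeat` treats cysteine oxidation-susceptibility prediction as binary
classification of labelled sites (protein, 1-based position, label), with
a feature vector assembled per site from up to six blocks. The premise is
that redox behaviour is conserved across homologous proteins, and that a
cheap, alignment-free summary of a residue's neighbourhood — the residue
adjacency matrix — captures enough of that conservation to classify on.

### Residue adjacency matrices

For alphabet Σ (default: the 20 standard amino acids, rows ordered
alphabetically by full residue name, alanine → valine) and depth *n*, the
matrix cell (*i*, *j*) is the distance from the target site to the *j*-th
nearest residue of type *i*:

- **RAMseq**: absolute 1-based position difference. The distance is
  unsigned — a residue three positions before the target scores the same
  as one three after.
- **RAMmod**: Euclidean distance in ångströms from the target cysteine's
  SG atom to each residue's alpha carbon, from PDB coordinates.

Conventions, all of which the tests pin down:

- **Self-exclusion.** The target residue never contributes to its own
  type's row (in sequence space it would contribute a meaningless 0; in
  structure space, the trivial intra-residue SG–CA distance). For RAMmod
  this is configurable (`exclude_self`).
- **Row imputation.** If a type has *m* < *n* residues, cells *m*+1…*n*
  take the arithmetic mean of the *m* observed distances. Observed
  prefixes are sorted ascending; imputed suffixes are constant, so rows
  need not increase monotonically end to end.
- **Matrix fallback.** A type absent from the protein entirely takes the
  mean over **all observed cells of that site's matrix** (computed per
  data point, before any imputation). A matrix with no observations at
  all (e.g. a single-residue sequence) is filled with 0 under a warning;
  this never arises in practice.
- **Ties.** Equidistant residues are ordered by ascending position; only
  the distance enters the matrix, so this affects nothing but the
  determinism of the imputation mask.
- **Non-standard residues** (X, B, Z, U, O, J) are excluded from all rows
  and counted in a per-protein warning. Selenocysteine is *not* folded
  into cysteine.
- **Missing target SG.** Comparative models sometimes omit side chains;
  the default falls back to the target's alpha carbon with a warning
  (`require_sulfur=True` makes it a hard error). A protein with no
  usable structure at all receives the per-cell mean of the available
  structure matrices, fully masked as imputed.
- **Vectorization** is row-major over (type, rank): type-1 ranks 1…n,
  then type-2, frozen in the CSV column names (`RAMseq_W_3` = third-
  nearest tryptophan).
- Mean imputation only. Forecast-based (ARIMA-style) row extension is
  deliberately not implemented; means are the demonstrated, effective
  convention.

Restricting Σ to {C} with n = 6 reproduces the older "nearest six
cysteines" feature as a special case, which the tests verify.

### Auxiliary blocks

- **PSSM**: the 20 log-odds columns of a PSI-BLAST ASCII profile, windowed
  2k+1 positions around the target (k = 6 → 260 features), position-major,
  zero-filled past the termini (zero is the neutral log-odds score).
- **PSS**: PSIPRED helix/strand/coil confidences, same windowing
  (k = 6 → 39 features). On-disk `.ss2` column order (coil, helix,
  strand) is mapped to canonical (H, E, C) at parse time.
- **pKa**: one scalar; 99.99 is the sentinel for a suspected disulfide.
  Three encodings are supported — pass the sentinel through (default),
  replace with the dataset mean of non-sentinel values, or replace with
  0. Measured AUC differences between these variants are ~0.001, so the
  choice is low-stakes but kept configurable.
- **SASA**: one scalar, the sulfur's solvent-accessible surface area (Å²).

Computing PSSM/PSS/pKa/SASA values themselves (psiblast, PSIPRED, PROPKA,
FreeSASA) and comparative modelling are external; this package defines the
data contracts and parses their outputs.

### Normalization

Two distinct operations, matching how they are consumed:

1. **Per-site, per-block** z-score (default) or min-max: statistics are
   computed within one site's one block, so feature types are normalized
   independently of each other and of other data points. One-dimensional
   blocks (pKa, SASA) are exempt. Degenerate blocks (zero spread) map to
   0 — the conventional neutral value. Whether the published procedure
   normalized every multi-dimensional block or only the RAM blocks is
   ambiguous; the default normalizes all of them, with per-block opt-out
   (`skip_blocks`).
2. **Per-column train/test** z-score with statistics from the training
   set only — required for the SVM backend, applied automatically there;
   tree ensembles do not need it.

### Classification and evaluation

Random forest is the default backend (500 trees, unlimited depth, seeded;
the published work found it strongest and gives no hyperparameters — 500
trees makes the out-of-fold scores stable at these sample sizes). The
confidence score is the fraction of tree votes. SVM (RBF, Platt-scaled),
KNN and a linear least-squares baseline share the same interface.

- **MCC threshold.** Candidate thresholds are the midpoints between
  consecutive distinct sorted scores plus sentinels outside the range;
  between candidates the confusion matrix cannot change, so the sweep is
  exhaustive. Ties resolve to the lowest threshold; a zero factor in the
  MCC denominator yields 0. Reported MCC/ACC/SN/SP are at the optimal
  threshold.
- **AUC** is the tie-aware rank statistic (scikit-learn), equal to
  trapezoidal area under the empirical ROC.
- **Cross-validation** is stratified 10-fold from a seeded shuffle;
  out-of-fold confidences are pooled into a single report per dataset
  (per-fold AUC mean ± sd is attached for transparency). Cross-dataset
  evaluation fits on one table and scores another.
- **Depth grid search** re-assembles the table for every (n_seq, n_mod)
  pair — changing n changes the features themselves — and reports the CV
  AUC grid and its argmax. Published optima vary by dataset (12/18, 6/7,
  5/6); 6 is the recommended default for unseen data, and optimising n
  risks overfitting.
- **Correlation profile**: Pearson correlation of every feature column
  with the label, against a matched matrix of seeded standard-normal
  columns, compared by two-sample Kolmogorov–Smirnov test, with kernel
  density summaries for plotting.

## The synthetic generator

Real inputs require external tools (PSI-BLAST, PSIPRED, MODELLER, PROPKA,
FreeSASA) and curated datasets. The generator emulates every input format
so the full pipeline runs hermetically, and — more importantly — plants a
*known* signal to test recovery end to end:

- `trp_proximity` (default): positive sites get a tryptophan planted
  within `d_near` = 3 positions; negative sites keep all tryptophans at
  least `d_far` = 15 away. The label is then a deterministic function of
  the tryptophan distance profile — the feature family the method is
  built on (tryptophan/cysteine distances dominate feature-importance
  rankings on the real datasets) — but it lives in the sequence, not in
  any feature column, so recovery genuinely exercises the extraction
  code. Target cysteines are spaced ≥ d_far + d_near + 1 apart so the
  construction is always satisfiable.
- `cys_cluster` plants an extra cysteine the same way; `none` leaves
  labels independent of sequence (the negative control: CV AUC must stay
  near 0.5).
- Defaults: 200 proteins of length 80–200, two target cysteines each
  (400 sites, exactly balanced classes — the scale of the published
  balanced benchmark), background residues uniform over the 18 non-C,
  non-W amino acids, `signal_strength` = 1.0 (the probability a site
  obeys its class rule).
- Structures are 3.8 Å-step self-avoiding random walks (the trans
  peptide CA–CA distance) with the SG placed 1.8 Å off the target CA;
  coordinates are rounded to the PDB format's 3 decimals so file
  round-trips are exact. PSSM fixtures are integer log-odds favouring
  the observed residue; `.ss2` fixtures are Dirichlet confidences; pKa
  fixtures are N(9.0, 1.5) clipped to [0, 14] with a configurable
  sentinel fraction (default 0.15); SASA fixtures are |N(10, 8)|.

**What passing tests do and do not show.** Recovery of the planted signal
(CV AUC ≥ 0.9 at 400 sites) demonstrates that the extraction, assembly
and evaluation machinery is correct and leak-free, and the `none` control
(AUC ∈ [0.4, 0.6]) that it does not hallucinate separation. It does *not*
validate the biological claim that adjacency matrices predict real
oxidation susceptibility — synthetic sequences have no evolutionary
homology, no realistic composition, and a single-cause label. One
concrete consequence: on real data the per-feature label-correlation
distribution separates overwhelmingly from random (many features inherit
weak correlation through homology), whereas the planted signal is sparse
(~6–20 of 120 columns), leaving the 120-vs-120 KS comparison underpowered
— its p-value varies from 1e-10 to 0.6 across generator seeds. The tests
therefore assert the robust signature (the strongest correlations are the
tryptophan-row columns, negative in sign) and verify the KS machinery on
a dense-signal construction instead.

## Numerical and scale choices

- Problem sizes in the test suite: 1,000 random sequences and 200
  random-walk structures for brute-force oracle equivalence; 400 sites
  for the recovery/control experiments; 5–10 folds elsewhere as noted in
  the tests. These keep the default suite under a couple of minutes while
  leaving the assertions statistically comfortable.
- Distances are float64 throughout; rigid-motion invariance of RAMmod
  holds to 1e-9 Å (limited only by floating-point rotation arithmetic).
- Positions are 1-based everywhere user-facing (biological convention).
- PDB parsing keeps the first altloc and the first model; residues with
  insertion codes that collide with an existing residue number are
  skipped with a warning (the composite-key alternative would complicate
  every downstream position map for a case absent from both the benchmark
  data and comparative-model output).
- Feature CSVs are written with `%.10g`, round-tripping doubles to 1e-12
  relative; re-running extraction on identical inputs is byte-identical.

## Known limitations

- The original benchmark datasets' label-file dialect is undocumented;
  the canonical interchange here is a TSV site table, and converting the
  original files is left as a documented extension point.
- Cross-dataset significance testing of MCC improvements is out of scope
  (the published comparison does not name its test procedure).
- No mmCIF input, no NMR multi-model handling beyond the first model, no
  feature selection, and no computation of pKa/SASA/PSSM/PSS values
  themselves.
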