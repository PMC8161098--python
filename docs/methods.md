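# Methods

## Overview

`cgbscreen` implements chemogenomic virtual screening in three layers:

1. a **compound–protein interaction (CPI) classifier**: a kernel SVM over
   concatenated compound and protein descriptor vectors, calibrated to
   emit a binding probability score in [0, 1] for any (compound, target)
   pair;
2. a **bioactivity-profile fingerprint**: for each compound, the vector of
   predicted binding probabilities across an eligible target panel — a
   computational analogue of a high-throughput-screening fingerprint,
   with no missing assay entries because every component is predicted;
3. a **similarity-profile screen**: each library compound is scored by its
   maximum cosine similarity to any one reference active's profile
   (1-nearest-neighbour search) and the library is ranked by that score.

A hashed Morgan bit fingerprint (radius 2, 2048 bits) with the Tanimoto
coefficient serves as the purely structural baseline. A hit whose profile
similarity to a reference is high while its structural similarity to every
reference is low has been retrieved across a scaffold boundary — the
scaffold-hopping behaviour that profile-based screening is valued for.

## Descriptors

**Compound block** (default length 1030): a hashed Morgan *count*
fingerprint (radius 2, 1024 dimensions) concatenated with six bounded
physicochemical features — molecular weight / 1000, heavy-atom count /
100, ring count / 10, H-bond donors / 10, H-bond acceptors / 20, fraction
of aromatic atoms — each clipped to [0, 1]. The scaling constants are
frozen in the schema so the SVM sees bounded inputs under any chemistry.

**Protein block** (default length 567): the classical sequence-descriptor
triple.

- *AAC* (20): amino-acid composition, count(a)/N.
- *DPC* (400): overlapping dipeptide composition, count(ab)/(N−1).
- *CTD* (147): for each of seven physicochemical properties
  (hydrophobicity, van der Waals volume, polarity, polarizability, charge,
  secondary-structure propensity, solvent accessibility) the 20 letters
  are partitioned into 3 classes, and the descriptor reports class
  composition (3), adjacent-pair transition frequencies (3), and the
  relative sequence positions of the first/25%/50%/75%/last occurrence of
  each class (15). The q-quantile is the ceil(q·n_g)-th occurrence
  (1-based) divided by N; an absent class reports five zeros. The class
  tables ship as a TSV (`cgbscreen/data/ctd_groups.tsv`) and can be
  swapped.

Sequences are restricted to the 20 standard letters; ambiguous letters
(B, J, O, U, X, Z) are dropped on ingest with a logged count, which keeps
the composition algebra exact. A 30-residue minimum guarantees the CTD
quantiles are meaningful. Every descriptor carries a `schema_id`; models
refuse vectors computed under a different schema.

These descriptor sets are open, exactly specified re-implementations of
the *kind* of features commercial engines produce; no numeric equality
with any proprietary descriptor stack is claimed or needed — the method's
behaviour depends on the pipeline structure, not the specific catalogue.

## CPI model

Interaction vectors are the exact concatenation (compound block first).
Features are **max-abs scaled** per dimension on the training data. This
choice was made after direct comparison: z-score standardization gives
near-zero-variance Morgan-count bits large weights in the RBF distance,
and planted-signal recovery degraded markedly (held-out AUC ≈ 0.74–0.81
versus ≈ 0.94 with max-abs scaling at identical data and budgets).
Max-abs scaling bounds every dimension without recentring sparse counts.

The classifier is an RBF-kernel SVC (defaults C = 10, γ = 0.01 on the
scaled space, balanced class weights) wrapped in Platt sigmoid
calibration fitted on 3 seeded stratified cross-validation folds
(`CalibratedClassifierCV(..., method="sigmoid", ensemble=False)`), which
turns the margin into the binding probability score. A score ≥ 0.5 is
read as predicted binding (boundary inclusive). Negative training pairs
are sampled uniformly without replacement from the complement of the
positive pair set, one negative per positive by default; this ratio is
the main lever affecting calibration and is recorded in the model
manifest together with class counts, per-target positive counts,
hyperparameters and the seed.

## Target panel and fingerprints

Only targets with ≥ `min_count` **positive** training pairs (default 100)
enter the panel: scores for sparsely trained targets are unreliable, and
negatives are excluded from the count because they are synthesized at a
configurable ratio. Panel order is lexicographic by target id and is
serialized with every artifact so cosine comparisons are always aligned.

Batch fingerprinting exploits a factorization of the RBF kernel: for a
pair vector z = (c, p) and support vector sv = (sv_c, sv_p),
‖z − sv‖² = ‖c − sv_c‖² + ‖p − sv_p‖², so
K(z, sv) = exp(−γ‖c − sv_c‖²) · exp(−γ‖p − sv_p‖²) and the entire
compound × target decision-value grid is a single matrix product over
support vectors. This is algebraically identical to per-pair evaluation
(tests pin agreement to 1e-9) and makes profiling a 5,000-compound
library over a 20-target panel take under a second; non-RBF kernels fall
back to per-pair scoring.

## Screening

Cosine similarity on the nonnegative profiles lies in [0, 1]; an all-zero
profile scores 0 with a logged warning rather than aborting a screen.
1-NN ties go to the lexicographically smallest reference id; the ranking
sorts by score descending then compound id ascending, so top-k lists are
reproducible byte for byte. The default hit list is the top 40.

## Synthetic universe

The generator emulates a curated bioactivity corpus without any external
database:

- **Compounds** are assembled from a grammar of 8 ring-system scaffolds ×
  16 substituent fragments (1–3 substituents per molecule, weights
  0.20/0.45/0.35); every molecule is real, parseable SMILES, so the whole
  descriptor pipeline is exercised, not mocked.
- **Targets** are 300-residue sequences mutated at rate 0.2 from
  family archetypes (4 families by default), giving within-family
  relatedness like a real kinome-style panel.
- **Binding rule**: each target prefers 5 of the 16 substituents; a
  compound truly binds iff it carries ≥ 2 distinct preferred substituents.
  Preferred sets are redrawn until every target has ≥ 160 true binders
  (≈ 11% binding rate, about 200–260 binders per target among 2,000
  compounds). Because the rule lives on substituents and not scaffolds,
  actives on unseen scaffolds exist by construction — the premise of any
  scaffold-hopping claim.
- **Label noise**: observed labels flip with probability 0.05. Training
  uses observed labels; evaluation of signal recovery uses the noiseless
  truth table, because with an ≈ 11% positive rate a 5% symmetric flip
  makes roughly a quarter of observed positives false, capping AUC against
  observed labels near 0.88 regardless of model quality — evaluating
  against truth separates model error from injected label noise.

Default study conditions: 20 targets, 2,000 compounds, noise 0.05,
compound-disjoint 25% holdout. Training positives are capped at 120 per
target (≈ 4,800 training pairs with 1:1 negatives), a budget chosen so a
train-plus-calibrate cycle takes tens of seconds on one CPU; at that
budget held-out AUC against truth is ≈ 0.94.

What the generator does **not** emulate: real activity-value
distributions and thresholding, assay heterogeneity, chemotype clustering
beyond the scaffold grammar, target families with correlated
pharmacology, or promiscuity patterns. Passing tests therefore
demonstrate that the machinery recovers planted structure under honest
noise — not that any particular real-world screen would reach the same
enrichment.

## Scaffold-hop benchmark

References are 20 true binders of the most ligand-rich target, all on its
modal scaffold. The 5,000-compound library plants 50 "hops" (rule-binders
on other scaffolds), 150 "lookalikes" (reference-scaffold non-binders),
and random grammar compounds (any that satisfy the rule count as true
binders too — same-scaffold actives analogous to trivial hits). Screening
performance is summarized by the number of true binders in the top 40,
the one-sided hypergeometric p-value against chance retrieval, and the
number of retrieved binders whose maximum Morgan/Tanimoto to every
reference falls below the median of the reference-scaffold library
compounds (the operational definition of a retrieved scaffold hop).
Individual hops can exceed that median when shared substituents dominate
a small molecule's fingerprint; the population of hops sits below it.

## Numerical and degenerate-input conventions

- Canonical SMILES via RDKit; canonicalization is idempotent and checked.
- Duplicate compound ids, duplicate CPI pairs, out-of-{0,1} labels and
  dangling ids are hard errors (training-set hygiene); unparsable
  molecules in bulk inputs are skipped with logged counts.
- The matrix container is CSV with id headers and a `#shape=` marker line
  so truncation is detected; floats are written in shortest round-trip
  form, making save/load value-identical.
- Two empty bit fingerprints have Tanimoto 0 by convention.
- All randomness flows from explicit integer seeds (NumPy `default_rng`);
  rerunning any stage with the same config and seed reproduces artifacts
  byte for byte.

## Known limitations

- One global model serves all targets. Per-family models (an optional
  partition in some deployed systems) are not implemented; with few
  hundred training pairs per target a shared model pools strength, but it
  can blur targets whose descriptors are similar while their ligand
  preferences differ.
- Probability calibration is global, not per-target; per-target score
  distributions can be offset, which cosine similarity on profiles
  partially absorbs but does not remove.
- The screen holds the library fingerprint matrix in memory; at the
  multi-million-compound scale the intended usage is chunked
  fingerprinting to per-chunk matrices, which the batch API supports but
  the CLI does not orchestrate.
- Panel eligibility counts positives in the supplied training table; it
  cannot see curation depth beyond that table.
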