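# cgbscreen

Chemogenomic virtual screening with bioactivity-profile fingerprints.

## The problem

Structural similarity search (Morgan/ECFP fingerprints + Tanimoto) finds
compounds that *look like* known actives, so it struggles to leave the
chemotypes it started from. Experimental HTS fingerprints — profiles of a
compound's behaviour across hundreds of assays — retrieve structurally
diverse actives, but exist only for compounds that have actually been
screened. `cgbscreen` implements the computational middle road: train a
compound–protein interaction (CPI) classifier, then describe *every*
compound by its vector of **predicted** binding probabilities across a
protein target panel, and screen libraries by profile similarity. Because
the profile is predicted, it has no missing entries and can be generated
for any molecule with a structure.

The package is for computational chemists who want a self-contained,
fully reproducible implementation of this pipeline — including a
synthetic chemogenomic universe with planted structure–activity rules, so
every stage can be validated end to end without any external database.

## Method

1. **CPI model.** A pair (compound *c*, target *t*) is represented by the
   concatenation of a Morgan count fingerprint (r = 2, 1024 bits) plus a
   physicochemical tail, and a protein sequence descriptor
   AAC ⊕ DPC ⊕ CTD (20 + 400 + 147 = 567 values). An RBF-kernel SVM with
   Platt sigmoid calibration, trained on binding and (sampled)
   non-binding pairs, yields a binding probability score
   s(c, t) ∈ [0, 1]; s ≥ 0.5 is read as predicted binding.
2. **Profile fingerprint.** For a panel T₁ < … < T_p of targets with at
   least 100 positive training pairs each, a compound's fingerprint is
   FP(c) = (s(c, T₁), …, s(c, T_p)).
3. **1-NN profile screen.** Each library compound x is scored against
   reference actives R by max_{r∈R} cos(FP(x), FP(r)); the library is
   ranked by this score and the top 40 are reported. Morgan/Tanimoto
   similarity to the references is computed alongside as the structural
   baseline, which is what exposes scaffold hops: profile-similar,
   structure-dissimilar hits.

See `docs/methods.md` for descriptor definitions, model and calibration
details, the synthetic-universe design, and known limitations.

## Worked example

Run the whole pipeline on the synthetic universe (2,000 compounds,
20 targets, 5% label noise) and screen a 5,000-compound benchmark library
containing planted scaffold-hopped actives:

```bash
cgbscreen run-all --seed 1 --out runs/demo
head -6 runs/demo/hits.tsv
```

```
rank	compound_id	cgbsp_score	nearest_reference
1	L0785	1.000000	C1916
2	L0813	1.000000	C1543
3	L3883	1.000000	C1731
4	L3920	1.000000	C1222
5	L2096	0.987163	C0638
```

Each row is a library compound, its best profile cosine to any single
reference active, and that nearest reference. A score near 1 means the
model predicts the compound to share the reference's whole target-panel
activity profile — not merely its substructure. The accompanying
`top_hit_comparison.tsv` pairs each top hit's profile score with its
Morgan/Tanimoto structural similarity, and the two together tell the
story: ranks 1–4 are chance rediscoveries of reference structures
(profile 1.00, Tanimoto 1.00), rank 5 is a same-scaffold analogue
(profile 0.987, Tanimoto 0.42), and further down the list sit genuine
scaffold hops — at seed 1, the rank-13 hit scores profile 0.984 against
its nearest reference while its best structural similarity to *any*
reference is 0.32 (a pyrrole active retrieved from benzene references).
The run directory also contains the trained model, the target panel with
its positive-pair counts, the library fingerprint matrix, and a
`manifest.json` with config hash and artifact checksums; rerunning with
the same seed reproduces every artifact byte for byte.

Library functions mirror the CLI: `synthetic_data.generate_universe`,
`cpi_model.train`, `cgbfp.build_panel` / `fingerprint_batch`,
`cgbsp_screen.rank_library` / `compare_profiles`.

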