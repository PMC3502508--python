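# bhlhkit

Identification and Kingdom classification of basic Helix-Loop-Helix (bHLH)
protein domains.

The bHLH domain is a ~60-residue DNA-binding and dimerization module found
in transcription factors across eukaryotes: a 13-residue basic region that
contacts the E-box (CANNTG), two ~15-residue helices that mediate
dimerization, and a variable-length loop between them.  Although the domain
is highly conserved, a handful of sites drifted in Kingdom-specific ways
after the Plant/Animal/Fungal split.  This package provides the statistical
machinery to find those sites, to classify a bHLH domain as Plant, Animal
or Fungal, and to locate bHLH domains inside arbitrary protein sequences —
for anyone mining genomes or environmental samples for transcription
factors of unknown origin.

## What it computes

Sequences are placed on a fixed site numbering (basic 1–13, Helix 1 14–28,
loop 29–49 excluded from models, Helix 2 50–64) and each residue is mapped
to five published physicochemical factor scores (**pah**, **pss**, **ms**,
**cc**, **ec**: polarity/accessibility/hydrophobicity, secondary-structure
propensity, molecular size, codon composition, electrostatic charge), giving
43-variable single-factor datasets or the 215-variable combined set
(**all**).  On these:

- **Canonical Variate Analysis (CVA)** solves the generalized eigenproblem
  `B a = λ W a` (between- vs within-group SSCP), yielding G−1 canonical
  variates with unit pooled within-group variance, squared canonical
  correlations `ρ_i² = λ_i/(1+λ_i)`, group centroids, and Mahalanobis
  distances `d_g² = (x−m_g)ᵀ S_W⁻¹ (x−m_g)` under the pooled covariance
  `S_W`.  A sequence is assigned to the Kingdom maximizing
  `prior_g · exp(−d_g²/2)`; any gap at a model site leaves it UNCLASSIFIED.
- **StepWise Discriminant Analysis (SWDA)** enters variables greedily by
  minimizing Wilks' lambda `Λ = det(W)/det(T)`, tracking partial `r²`,
  F-to-enter, and the Average Squared Canonical Correlation
  (ASCC = Pillai's trace / (G−1)); selection stops at an ASCC target
  (0.70 single factors, 0.80 combined), a step limit, or the entry
  threshold.  Sites entering with partial `r² > 0.20` are called
  highly discerning.
- **A chi-square decision tree** bifurcates sequences on raw residue
  identities (significance 0.20, depth ≤ 4, ≥10 to split, ≥4 per leaf),
  rendered as a dichotomous taxonomic key.
- **Per-Kingdom profile HMMs** are trained separately on each helix; a
  protein is identified as bHLH if and only if a Helix 1 hit completely
  precedes a Helix 2 hit and both bit scores exceed 0.1 (strict).
  Identified domains are mapped back onto the fixed site numbering for
  classification.
- **Conservation analytics**: normalized Boltzmann-Shannon entropy over
  eight physicochemical residue groups (DE, HKR, FWY, AGILMV, NQ, ST, C,
  P), sequence-logo bit scores, and 50–10 consensus motifs (primary
  residue >50%, secondaries >10%).

A seeded synthetic-data generator emulates Kingdom-structured alignments —
shared conserved sites (L at 27, P-dominant 28), discerning sites planted
at 2, 5, 8, 12, 13 and 56, the Animal/Fungal K-dominance vs Plant
variability at site 50 — so the entire pipeline runs and is testable with
no downloads.

## Worked example

```python
import bhlhkit as bk

spec = bk.default_spec(0)
config = bk.GeneratorConfig(n_per_kingdom=200, seed=42, gap_rate=0.0)
alignment, labels = bk.sample_alignment(spec, config)

profile = bk.conservation_profile(alignment)
print(profile.loc[[27, 28, 50]].round(3))

X = bk.transform_alignment(alignment, "all")
swda = bk.fit_swda(X, labels, ascc_target=0.80, max_steps=20)
print(swda.steps_[["step", "site", "factor", "wilks_lambda", "partial_r2", "ascc"]].round(3))

cva = bk.fit_cva(X, labels)
print("CV variance proportions:", cva.proportions_.round(3))
print("sqrt Mahalanobis Plant-Animal:", round(cva.mahalanobis_between("Plant", "Animal"), 2))

pairs = bk.build_kingdom_hmms(alignment)
seqs, truth = bk.embed_in_proteins(alignment, spec, config)
calls, summary = bk.scan_proteome(seqs, pairs)
print("identified:", summary["n_identified_total"], "of", len(seqs))
```

prints

```
      n_observed  group_entropy  information_bits consensus
site
27           600          0.109             3.812         L
28           600          0.295             3.263         P
50           600          0.640             1.773         K
   step  site factor  wilks_lambda  partial_r2   ascc
0     1     5     ec         0.126       0.874  0.437
1     2     2    pah         0.019       0.847  0.860
CV variance proportions: [0.541 0.459]
sqrt Mahalanobis Plant-Animal: 18.48
identified: 600 of 600
```

Reading it: site 27 is near-invariant L in all Kingdoms (group entropy
0.109, consensus L) while site 50 is variable across the pooled alignment
(0.640) because Plants drift where Animals and Fungi keep K.  Stepwise
selection reaches the 80% ASCC target in two steps, entering planted
discerning sites (5 via the **ec** transform, then 2 via **pah**), each
with partial r² well above the 0.20 diagnostic threshold.  The two
canonical variates split the among-group variance 54/46, Kingdom centroids
sit ~18 pooled-covariance standard deviations apart, and the two-helix HMM
rule recovers every embedded domain.

The same operations are available from the shell via the `bhlhkit` console
script (`simulate`, `conserve`, `transform`, `fit-cva`, `fit-swda`,
`fit-tree`, `classify`, `hmm-build`, `scan`, `evaluate`); run
`bhlhkit --help`.

## Layout

- `src/bhlhkit/coordinates.py`, `alignment.py`, `factors.py` — site
  numbering, enumerated alignments (FASTA/TSV), factor-score transform
- `src/bhlhkit/conservation.py` — entropy, logos, 50–10 consensus
- `src/bhlhkit/discriminant.py` — Wilks' lambda, ASCC, CVA, SWDA
- `src/bhlhkit/tree.py` — chi-square decision tree
- `src/bhlhkit/hmm.py` — profile HMMs, two-helix identification, scanning
- `src/bhlhkit/simulate.py` — synthetic generator and analytic baselines
- `src/bhlhkit/evaluation.py`, `cli.py` — one-vs-all metrics, CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
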