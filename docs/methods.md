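# Methods

## Coordinate system and numeric representation

bHLH domains are represented on a fixed site numbering: basic region sites
1–13, Helix 1 sites 14–28, Helix 2 sites 50–64; the loop (29–49) varies in
length between sequences and never enters a numeric dataset, though loop
residues are carried through parsing and extraction.  Every enumerated
record covers all 43 fixed sites, with GAP marking absent residues.
Ambiguity codes (B, Z, X, U, O) are mapped to GAP with a logged warning:
factor scores are defined only for the 20 canonical residues, and a
made-up average would silently distort the discriminant geometry.

Residues are transformed with the bundled 20×5 table of published
physicochemical factor scores (pah, pss, ms, cc, ec), derived from factor
analysis of 495 amino acid property scales and standardized (each column
sums to ~0, a property the test suite checks).  The table is shipped as a
versioned package resource, treated exactly like a substitution matrix.
Single-factor datasets have 43 variables; the combined set has 215,
ordered site-major with factors pah, pss, ms, cc, ec within each site.
(The ordering affects only reporting: CVA and SWDA are invariant to
variable order, up to deterministic tie-breaking.)  A cell is missing iff
the residue is a gap.

## Conservation analytics

Per-site residue frequencies exclude gaps from the denominator, so
consensus percentages are residue concentrations among observed residues.
Group entropy is computed over eight physicochemical groups (DE, HKR, FWY,
AGILMV, NQ, ST, C, P) partitioning the 20 residues, as
H = −Σ p_g ln p_g, normalized by ln 8 to [0, 1]; the log base cancels.
Logo heights use information R = log2 20 − H20 in bits, apportioned as
p_a·R.  The 50–10 consensus includes a site iff its top residue exceeds
0.50 strictly, then lists every residue above 0.10 strictly, primary
first.  A site with no observed residues yields NaN, never 0 — an
all-gap column is "no information", not "perfectly conserved".  No
small-sample entropy correction is applied by default; frequencies at the
intended sample sizes (hundreds per Kingdom) make the bias negligible
relative to the effects of interest.

## Canonical variate analysis

With G groups, within-group (W), between-group (B) and total (T) SSCP
matrices are accumulated about group and grand means of the complete-case
rows.  The generalized eigenproblem B·a = λ·W·a is solved through the
symmetric form (`scipy.linalg.eigh(B, W)`), keeping the top G−1
eigenvalues; eigenvectors are rescaled so each variate has unit pooled
within-group variance (aᵀ S_W a = 1 with S_W = W/(n−G)) and signed so the
largest-magnitude coefficient is positive, making runs deterministic.
Reported per-variate quantities: eigenvalues, squared canonical
correlations λ/(1+λ), and variance proportions λ_i/Σλ.

Classification uses Mahalanobis distances to group means under S_W
(Cholesky solves, no explicit inverse) and posteriors
prior_g·exp(−d_g²/2), normalized after subtracting the max exponent.
Priors are uniform by default (configurable to proportional or explicit):
posteriors should express evidence in the sequence, not the census of the
training set.  A row missing any model variable is UNCLASSIFIED — the
model's distance geometry is undefined on incomplete vectors, and
imputation would manufacture confidence.  Pairwise centroid divergence is
reported as √d²; because group-mean differences lie in the canonical
span, this equals the Euclidean distance between centroids in full
canonical space (asserted in tests).

Fitting requires at least G + p complete cases.  A singular W raises an
error naming the variables loading on the near-null space, with an
optional diagonal ridge ε·diag(W)/n (default off — failing loudly beats
silent regularization).

## Stepwise discriminant analysis

Entry-only (step-up) selection: at each step the candidate minimizing
Wilks' lambda Λ = det(W)/det(T) of the enlarged set enters.  Partial
r² = 1 − Λ_new/Λ_old; F-to-enter = ((n−G−m)/(G−1))·r²/(1−r²) with m
variables already entered, tested against F(G−1, n−G−m) at
significance-to-enter 0.15 (the classical stepwise default).  Primary
stopping rules: cumulative ASCC ≥ target (0.70 for single-factor sets,
0.80 for the combined set) or 20 steps; the recorded stopping reason
distinguishes target, step limit, and entry-threshold exhaustion.  Ties
resolve to the earliest column (lowest site, then factor order).  Λ is
strictly decreasing and ASCC non-decreasing across steps, both asserted as
invariants.  Removal steps (full stepwise) are deliberately not
implemented; entry-only matches the step-up procedure this mirrors and
keeps the step table monotone.  Sites entering with partial r² > 0.20 are
reported as highly discerning.  `swda_to_classifier` refits CVA on the
selected variables only, so classification then tolerates gaps at
unselected sites — the practical advantage of the smaller model.

## Chi-square decision tree

The tree works on raw residue identities.  At a node, each site's observed
residues are ordered by their proportion of the node's majority class and
all contiguous cut points of that ordering are scanned — a standard
deterministic heuristic, since exhausting 2^(k−1) binary partitions of up
to 20 residues is infeasible.  The (site, partition) maximizing the
Pearson chi-square of the branch×Kingdom table (no continuity correction)
is adopted if p ≤ 0.20 and both branches hold ≥ 4 sequences; ties go to
the lowest site.  Growth stops at depth 4, below 10 sequences, or when a
node is ≥ 95% one Kingdom ("almost completely comprised"; configurable).
At prediction, a gap or a residue unseen at that node during training
routes to UNCLASSIFIED rather than a majority branch — a tree built on
observed residue sets has no evidence for unseen symbols, and this is what
produces the small unclassified counts characteristic of the method.
During training, records with a gap at a chosen split site are not routed
to either child; the child-counts-sum-to-parent invariant is exact on
gap-free data.

## Profile HMMs and the two-helix rule

For each Kingdom, separate profile HMMs are built on the Helix 1 and
Helix 2 columns.  Match emissions at column j are
(count_a + κ·bg_a)/(n_j + κ) with pseudocount weight κ = 1 by default;
insert states emit the background; the match→delete probability into a
column blends that column's gap fraction with the prior at weight κ.
Default transition priors m→m 0.95, m→i 0.025, m→d 0.025, i→i 0.3,
d→d 0.3 reflect short, nearly gap-free helices.  The background is the
pooled training frequency (Laplace-smoothed so log-odds stay finite), with
uniform 1/20 available by flag.

Scoring is Viterbi in log2-odds (bits) against the background: local in
the query (alignment may begin and end at any query position, free) but
global in the model — every helix column is traversed, and columns skipped
at either end are charged as delete transitions.  Model-global scoring is
the specificity mechanism: with free entry and exit, a single residue
matching one conserved column can exceed a 0.1-bit threshold, and shuffled
sequences would be "identified" constantly; charging skipped columns means
only near-complete helix matches score positive.  A query is identified as
bHLH by a Kingdom pair iff a Helix 1 hit completely precedes a Helix 2 hit
and both scores strictly exceed the threshold (default 0.1 bits, kept as
the conventional cutoff and validated on synthetic data; scores of this
engine are not bit-identical to any external implementation).  When the
unconstrained best Helix 2 hit overlaps or precedes Helix 1, Helix 2 is
re-searched downstream of the Helix 1 hit before giving up.  No maximum
inter-helix loop length is imposed.

Identified hits are mapped back to fixed sites via the Viterbi traceback
(match column → query position); the 13 residues preceding the Helix 1 hit
fill the basic region, gap-padded on the left, and inter-helix residues
fill loop sites 29–49, truncated beyond 21.  Extraction is exact whenever
the traceback recovers the planted alignment, which the round-trip tests
measure (≥90% of identified domains reproduce the generating record
exactly under the default preset).

## Synthetic generator

The generator defines the study conditions for all self-contained tests.
Its default preset plants: L at 0.95 at site 27 in all Kingdoms; P
dominant at site 28 at 0.92/0.88/0.73 (Fungal/Plant/Animal); K at 0.9 at
site 50 in Animal and Fungal with a near-uniform Plant distribution;
Kingdom-discerning sites 2, 5, 8, 12, 13, 56 with distinct dominant
residues at 0.9 (residue triples chosen well-separated in factor-score
space); all other sites share one moderate-entropy distribution across
Kingdoms (dominant residue at 0.5 plus Dirichlet spread), so they carry no
signal and site discovery has exact ground truth.  Defaults: 300 sequences
per Kingdom, 1% per-cell gap rate, loop lengths uniform on 5–15, flanks
15–60 background residues, all randomness from one seed end-to-end.

Sites are sampled independently: no phylogenetic correlation, no indel
evolution within helices, no compositional bias in flanks.  Passing tests
therefore demonstrate the statistical machinery on Kingdom-structured
categorical signal of realistic strength — not performance on real
proteins, where sites covary along lineages and helix boundaries blur.
The categorical profiles give two analytic baselines used in tests: the
closed-form group entropy of any preset distribution, and a Monte-Carlo
Bayes rate from exact per-site log-likelihoods, against which CVA's
held-out accuracy is compared (within 2 percentage points at n = 5,000
under the default preset).

## Evaluation

Confusion matrices are 3 true × 4 predicted (the fourth column is
UNCLASSIFIED).  One-vs-all sensitivity and specificity count UNCLASSIFIED
as a negative prediction for every class.  Two accuracy conventions are
reported side by side — unclassified-as-error and among-classified —
because collapsing them hides exactly the CVA/SWDA trade-off this toolkit
exists to expose: the full CVA model is the most accurate on complete
sequences but refuses anything gapped, while the smaller stepwise model
classifies more sequences at somewhat lower accuracy.  Zero-denominator
rates are NaN, never 0.

## Problem sizes and numerical notes

Default analysis sizes (300/Kingdom model sets, 900-protein scans,
5,000-sequence test sets) were chosen to mirror the scale of real bHLH
model datasets while keeping any single analysis in the tens of seconds.
Determinants use `slogdet`; covariance solves use Cholesky factors;
eigen-solves use the symmetric generalized form; canonical signs, stepwise
ties, tree ties (lowest site, earliest cut, alphabetical residue order)
are all fixed deterministically.  Degenerate inputs fail with specific
errors: empty alignments, single-group fits, singular SSCP matrices
(naming the collinear variables), extraction from unidentified calls.

## Known limitations

- Discriminant models assume a shared within-group covariance; no
  quadratic discriminant option.
- The stepwise procedure is entry-only; a variable can enter through a
  correlation that later entries would explain.
- HMM scores are engine-specific; the 0.1-bit threshold is a convention
  validated on synthetic data, not a calibrated error rate, and no
  E-values or null2-style corrections are computed.
- The tree's partition heuristic can miss the globally optimal binary
  split at a site, though it is exact for two-class nodes.
- Posteriors are conditional on the three Kingdoms: sequences from other
  lineages will be forced into one of them, and only the Mahalanobis
  distances reveal that the fit is poor.
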