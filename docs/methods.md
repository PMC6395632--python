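# Methods

This note documents the statistical machinery implemented in
`snopred`, the conventions and tunable parameters that matter, what
the synthetic-data generator does and does not emulate, and the design
choices made where the design was genuinely open.

## Peptide windows

A candidate site is represented by the `2t + 1` residues centered on a
cysteine, indexed by offsets `−t … +t` with 0 the site itself.
Default `t = 10` (21-mers), the standard window size in SNO-site
prediction. Flank positions beyond either protein end are filled with
the dummy residue `X`, giving a fixed 21-letter alphabet (20 standard
amino acids + `X`). Non-standard FASTA letters (B, Z, J, U, O, `*`)
are remapped to `X` with a warning rather than rejected, since real
proteomes contain them and `X` already exists in the model. Every
cysteine yields a window, including cysteines within `t` of each
other; no sequence-redundancy filtering is performed (curated SNO
datasets are typically already reduced to ≤ 40 % pairwise identity
upstream).

## Composition encoders

**PC-PseAAC.** The vector `[x₁ … x₂₀, x₂₁ … x₂₀₊λ]` combines the 20
normalized amino-acid frequencies `fᵢ` with λ tier-correlation factors
`Θⱼ`, all divided by the common denominator `Σf + w·ΣΘ`, so the vector
sums to 1. `Θⱼ` is the mean, over residue pairs j positions apart, of
the mean squared difference of standardized physicochemical indices —
hydrophobicity, hydrophilicity and side-chain mass in the classic
three-index mode, any user-supplied index set in the general mode
(with the packaged three tables, the two modes coincide exactly).
Each index is standardized over the 20 amino acids to zero mean and
unit mean square (population ÷20 normalization); a constant index is
rejected as degenerate.

Defaults `λ = 5`, `w = 0.5` — the values found optimal for this task
in the SNO literature. Constraint: λ must be smaller than the
effective (non-`X`) sequence length.

Dummy-residue convention: `X` has no physicochemical values and is not
part of the composition alphabet. `X` occurrences are dropped from the
frequency normalization, and correlation pairs containing `X` are
skipped, with each tier's denominator replaced by the number of pairs
actually evaluated (a tier with no evaluable pair contributes 0).
Whether padded windows should instead be de-gapped before encoding is
unknowable from the upstream literature; this convention keeps every
tier a proper mean and is applied uniformly.

**kmer.** Occurrence frequencies of the `20^k` X-free k-mers among the
X-free k-mers of the window (k = 1: 20 features; k = 2: 400). Entries
sum to 1 by construction.

## Positional-profile encoders

All five profile encoders score a window against per-position
empirical frequency tables estimated separately from positive and
negative training windows — they are *supervised transformers* and are
refit on the training fold of every cross-validation split by default
(see *Evaluation*). Pairs and triplets are indexed over the full
21-letter alphabet, so `X`-containing events in padded flanks are
ordinary outcomes. Frequencies are raw proportions without smoothing
(an optional Laplace `+1` flag exists for downstream classifiers that
dislike exact zeros).

Center-inclusion conventions, fixed to give the canonical dimensions
at `t = 10`: BPB, ANBPB, DBPB and PSTAAP operate on the de-centered
20-residue window (the center is constitutively `C` and carries no
information); IAAPair keeps the full 21-residue window, as its
formulation requires. Resulting lengths: BPB `2·2t = 40`, ANBPB 40,
DBPB `2·(2t−1) = 38`, IAAPair `2t + (2t−1) = 39`, PSTAAP `2t−2 = 18`.

**ANBPB** replaces each positional frequency `f` by `Φ(z)` with
`z = (f − mean)/sd`, where mean and sd are taken over the 21
letter-frequencies at that position within the class (population sd).
A position whose letter distribution is exactly uniform has `sd = 0`
and maps to `Φ(0) = 0.5`; the degeneracy test uses a `1e−12` tolerance
because a uniform empirical table stored in floating point can carry a
~`1e−17` residual sd that would otherwise explode the z-score.

**IAAPair / PSTAAP** encode the *difference* of positive and negative
posteriors (adjacent + gap-1 pairs over the full window; adjacent
triplets over the de-centered window), so their entries lie in
`[−1, 1]`, are antisymmetric under label swap, and vanish when the two
classes are identical.

## Feature selection

**Information gain.** `IG(X|Y) = H(X) − H(X|Y)` in bits (log base 2,
`0·log 0 := 0`), with plug-in probabilities from the 2×2 contingency
table of the binary class against a binarized feature (presence
threshold `> 0`). The implementation is verified exhaustively against
a brute-force mutual-information oracle over every contingency pattern
with `n ≤ 12`. Residue-level ranking uses presence of each of the 20
residues anywhere in the window excluding the center; dipeptide
ranking uses the 400 X-free adjacent pairs not involving the center
position; a positional variant ranks the `2t` offsets by the
21-category conditional entropy of the class given the residue
identity there. Ties preserve original feature order (stable sort).

**MRMD.** Each feature's score is `w_r·MRᵢ + w_d·MDᵢ`: relevance is
the absolute Pearson correlation with the label (0, with a warning,
for a zero-variance column), distance is the mean Euclidean distance,
cosine dissimilarity (1 − similarity), Tanimoto dissimilarity, or the
arithmetic mean of the three, from the feature's column to every other
column. The literature leaves the weights and the commensurability of
the two terms open; here distances are min-max scaled to `[0, 1]` and
`w_r = w_d = 1` by default. Zero-norm columns are handled explicitly
(two zero columns are identical; zero against non-zero is maximally
dissimilar).

For residue-level MRMD ranking (`rank_residue_mrmd`) the feature
matrix is the off-center residue *count* matrix with columns mean-
centered before the distance step. Raw compositional columns are all
non-negative and nearly collinear, so raw cosine/Tanimoto
dissimilarities are almost constant and min-max scaling amplifies pure
sampling noise; after centering, cosine similarity between columns is
exactly their inter-feature Pearson correlation — the standard
redundancy measure — and all four distance variants respond to real
structure. The generic `mrmd_distance` keeps the raw formulas
(`center=False`) as its default.

**Incremental selection** evaluates the top-d ranked features for each
dimension d in a grid, records Sn/Sp/Acc/MCC, and returns the
dimension maximizing accuracy, preferring the smaller dimension on
ties.

## Evaluation

Metrics are the four standard confusion-count measures; any 0/0 ratio
(e.g. specificity of an all-positive rule, MCC with a zero
denominator) is defined as 0 with a warning. Protocols: jackknife
(leave-one-out, deterministic), repeated stratified k-fold (seeded;
pooled confusion counts per repeat, mean and best-repeat summaries),
and independent-test evaluation.

Because the profile encoders and feature rankings are supervised, they
leak label information if fitted on data that later appears in a test
fold. The default is therefore to refit profiles, selection and
classifier inside each training fold. A `prefit_profiles` flag instead fits
the supervised encoders once on the full dataset before splitting —
the protocol many profile-encoded predictors appear to have used — and
is provided for comparability only. On signal-free data the honest
protocol never beats chance (it can fall below it: each training
window contributes mass to its own class profile, and a classifier fit
to that memorized structure anti-generalizes), while `prefit_profiles`
reaches near-perfect pseudo-accuracy; the test suite demonstrates both.

The classifier slot is pluggable (anything with `fit`/`predict`); the
default is an RBF-kernel SVM on per-fold standardized features with
`C = 10`, `γ = 'scale'`, which needs no tuning at these problem sizes.
A small grid search (`C ∈ {1, 10, 100}`, `γ ∈ {1/d, 0.01, 0.001}`) is
available via `default_classifier(param_grid=...)` or the `grid`
config key; on the synthetic benchmark it changes accuracy by well
under one point, so the single fit is the default.

## Synthetic data

The generator emulates the *structure* that positional encoders and IG
assume in real SNO data: fixed-length windows, center always `C`,
non-center positions drawn from a background distribution (uniform by
default) and then overwritten by motif signals with class-specific
probabilities. All draws come from one seeded stream per call; a given
seed reproduces the dataset byte for byte.

Default motif: lysine at offset −1 with probability 0.80 in positives
vs 0.05 in negatives — the dominant signal — plus K at +2, −3, +4, −5,
+6 with probabilities decaying 0.65, 0.60, 0.50, 0.45, 0.40 (0.05 in
negatives throughout). This mirrors, in caricature, the charged
acid-base flanks reported around S-nitrosylated cysteines.
Concentrating the enrichment in one residue keeps a single unambiguous
planted residue for ranking checks, and places the task's Bayes
accuracy at ≈ 0.93 (computable in closed form from the independent
signal positions), so the end-to-end pipeline lands at ≈ 0.88–0.89
under honest 10-fold CV — clearly separable, far from saturated.
The default motif spans offsets ±6 and therefore requires `t ≥ 6`;
narrower windows need an explicit `MotifSpec`.

What the generator does *not* emulate: the amino-acid background of
the real SNO proteome, inter-position dependence, homology structure
between windows, and class imbalance. Passing tests on synthetic data
therefore demonstrate the correctness and leakage behavior of the
machinery, not expected field performance on curated SNO datasets —
published headline accuracies additionally depend on unpublished
classifier choices and on evaluation protocol, and are deliberately
not targets here.

## Problem sizes and determinism

The test suite and the acceptance script use 500 + 500 windows at
`t = 10` for end-to-end checks (a size at which every quantity of
interest is stable across seeds, with the whole suite running in
seconds), 5 000 + 5 000 for distributional goodness-of-fit, and
exhaustive enumeration (`n ≤ 12`) for the IG oracle. Single-seed
determinism is asserted for the generator, cross-validation and the
CLI `run` command (byte-identical metrics on re-run; stage caching
never changes results).

## Known limitations

- Profile encoders memorize training windows by construction (each
  window contributes to its own class tables); resubstitution
  performance is therefore meaningless, and only the fold-wise honest
  protocol should be quoted.
- `X`-handling conventions in PC-PseAAC (skip-and-renormalize) are one
  defensible reading among several; heavily padded windows (sites very
  near protein ends) get their composition estimated from few
  residues.
- MRMD's combined score depends on the distance scaling convention;
  rankings from differently scaled implementations are not directly
  comparable.
- The IAAPair/PSTAAP probability tables are sparse at realistic sample
  sizes (441 and 9 261 cells per position); unseen events score
  exactly 0, which is intended but makes these encoders sensitive to
  training-set size.
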