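# Methods

## Overview

`semspace` computes semantic and syntactic measures from
picture-description transcripts and runs the group-comparison and
cognition-regression analyses used in speech-biomarker studies of
probable Alzheimer's disease (pAD) versus normal controls (NC), in
English (`en`) and Greek (`el`). Because the relevant clinical corpora
are access-restricted, the package pairs every real-model integration
point with a deterministic fixture and ships a synthetic-cohort
generator with known ground truth; the scientific claims the test suite
verifies are therefore claims about the *methods* (correctness,
calibration, power under controlled conditions), not about any
particular clinical dataset.

## Measures

**Tokenization tracks.** Transcripts are lowercased and split into
maximal alphabetic runs (apostrophes word-internal, so punctuation-only
tokens never arise). The *conceptual* track removes stopwords from a
frozen per-language list shipped as package data (seeded from the
standard English and Greek function-word lists) so that results do not
drift with external package versions. The *referential* track keeps
every word and segments it into subwords by greedy longest-match
against a frozen fixture vocabulary; a real wordpiece tokenizer can
replace it behind the same `segment` contract. Sentences split at
`. ! ? ;` followed by whitespace; fragments with no word character are
dropped.

**Similarity.** LSim is the mean cosine over the n−1 consecutive
embedding pairs; GSim the mean over all n(n−1)/2 unordered pairs
(self-pairs excluded, each pair counted once, matching the
2/(n(n−1)) normalizer). Cosines are clipped to [−1, 1] against rounding
overshoot, and the cosine of two bitwise-identical vectors
short-circuits to exactly 1. Zero vectors are rejected. Transcripts
with fewer than two tokens on a track yield NaN (a missing feature, not
an error), because the statistical stage must tolerate incomplete rows.

**Perplexity.** Cross-entropy is accumulated in nats and converted once
to bits, H = −(1/n)Σlog₂p(tᵢ|t₁..ᵢ₋₁); PPL = 2^H. Base invariance
(e^{H nats} = 2^{H bits}) is asserted to 1e−10 relative at every call.
The first token of a sequence has no left context and is never scored;
n counts predicted tokens only. Sequence-start or other special tokens
live entirely inside providers and never enter any measure. Any
positive log-probability is a hard error.

**Bimodal alignment.** Mean cosine between each sentence vector and the
stimulus-image vector in a shared space.

**Dependency distance.** An arc's distance is the absolute difference
of the 1-based linear positions of the dependent and its head. The
alternative "words strictly in between" convention (one less per arc)
is exposed as `convention="gap"` but is not the default: the worked
example sentence (*ate*→*apple* = 5) fixes the position-difference
reading. Arcs with a punctuation token at either end are skipped, but
surviving tokens keep their original positions. ADD pools arcs across
all sentences of a transcript; zero arcs yield NaN. Parses are
exchanged in CoNLL-U layout with punctuation flagged by `UPOS ==
"PUNCT"`; the reader/writer handles only the columns this package uses.

## Fixture providers

All four provider contracts (static embedder, contextual embedder,
autoregressive scorer, bimodal encoder) have deterministic fixtures
that are pure functions of `(inputs, seed)`, built from SHA-256 hashes
of token strings so no vocabulary is stored:

- static: each word hashes to a unit vector (position-invariant by
  construction);
- contextual: a token's vector blends its own hash vector with its
  immediate neighbours' (weight 0.5), so identical tokens in different
  contexts get different vectors. Sequences beyond the provider's
  context limit are encoded in overlapping windows (50% overlap); each
  token keeps the vector from the window where it sits most centrally,
  preserving one vector per token;
- autoregressive: per-token surprisal drawn from Gamma(shape 2, mean =
  target entropy in bits), guaranteeing non-positive log-probabilities
  and an exactly controlled expected cross-entropy; uniform and
  certain-outcome scorers cover the analytic cases;
- bimodal: sentence vector = normalize(a·image + (1−a)·noise) with the
  alignment level a ∈ [0, 1]; a = 1 reproduces the image vector, a = 0
  gives independent vectors.

## Statistical pipeline

**Covariate screening.** Candidates are age, sex, education, word-level
TTR, and word count. Each (measure, candidate) pair gets a Spearman
partial correlation on the pooled two-language table, controlling for
language and group: all variables are rank-transformed, covariate ranks
(plus intercept) are projected out, and the residual Pearson
correlation is tested with the t approximation on n − k − 2 degrees of
freedom. p-values are Benjamini–Hochberg corrected jointly across all
pairs; candidates with q < 0.05 enter that measure's models. Constant
columns are dropped from the controls (e.g., language in a
single-language table).

**GLMs.** Each model is `measure ~ group + covariates` (or `~ MMSE +
covariates` within pAD). Coding: pAD = 1/NC = 0, female = 1/male = 0,
Greek = 1/English = 0, MMSE raw; reported coefficient signs are
documented against this coding. Every model is first fit as
Gaussian/identity; the deviance goodness-of-fit test compares the raw
deviance to χ²(residual df), and only when it rejects at α = 0.05 *and*
the response is strictly positive is the model refit as Gamma/log. On
cosine-scaled measures the Gaussian deviance is far below the residual
df, so the gate keeps them Gaussian; the right-skewed, large-scale PPL
fails it and is routed to Gamma/log — the intended behaviour of the
gate. α = 0.05 matches the pipeline's general significance convention.
The PPL model always additionally adjusts for subword TTR, since
perplexity is strongly confounded with subword lexical diversity.
Inference is Wald (z, normal 95% CI). Focal-term p-values are
FDR-corrected across measures within each dataset. Missing rows are
deleted per model (each model uses its own complete cases); a singular
design is an error naming the collinear terms, and per-measure failures
are collected without aborting the batch.

**Replication.** An English effect is replicated in Greek iff the
coefficients share a sign and the English coefficient lies inside the
Greek 95% CI. A zero coefficient matches either sign (non-strict;
unreachable with continuous data, but the truth table is total).
BH-FDR is delegated to `statsmodels` behind the `fdr_adjust` surface
and checked in the tests against a hand-written step-up oracle.

## Synthetic cohorts

`default_spec("en")` and `default_spec("el")` encode the cohort
conditions the pipeline is designed for: group sizes 143/148 (English)
and 28/26 (Greek); age, education, MMSE means/SDs and female
proportions at the published descriptive magnitudes (NC MMSE ≈ 29,
patients ≈ 18–21, truncated to [0, 30] and rounded to integers);
transcripts of ≈ 58/52 (English) or ≈ 29/30 (Greek) words drawn from a
synthetic pronounceable lexicon with per-subject active vocabularies of
120 (NC) vs 85 (pAD) types, which reproduces word-TTRs near 0.80 vs
0.75 at those lengths.

Effect knobs and their defaults:

- **kappa** (embedding concentration): clouds are
  normalize(centroid + g/(kappa·√d)), g standard normal, around a
  per-subject unit centroid — a pragmatic isotropic stand-in for a
  von Mises–Fisher draw; only the monotone link kappa → expected
  pairwise cosine is relied on. NC 1.0, pAD 1.05.
- **entropy_bits**: mean per-token surprisal; NC 6.0, pAD 6.25 (the
  direction seen once lexical diversity is adjusted for).
- **alignment**: NC 0.60, pAD 0.56.
- **arc_mean**: target mean dependency-arc length; trees are built by
  attaching tokens (in random order) to the already-attached token
  whose distance best matches a shifted-geometric draw, which
  guarantees a single root and no cycles; sentence length (8 words)
  truncates long arcs, so realized means sit slightly below target.
  NC 2.4, pAD 2.1.
- heterogeneity: per-subject kappa is lognormal (σ = 0.10) around the
  group value, entropy normal (σ = 0.30 bits), alignment normal
  (σ = 0.05, clipped). Without between-subject heterogeneity the
  within-transcript averages are nearly noise-free and any group gap
  would be trivially detectable; with it, the default gaps produce
  standardized group effects of ≈ 0.5–0.8 on the measures, the
  magnitude implied by the study-scale z statistics (|z| ≈ 4.5–6 at
  n ≈ 291) this pipeline targets.

A single seed expands into per-subject `SeedSequence` substreams, so
cohorts are bitwise reproducible and independent of generation order.
The truth record stores every generating parameter.

What the generator does **not** emulate: real lexical content and
topical structure (the lexicon is synthetic, so content-word and
all-word tracks coincide), correlations between measures within
subject beyond those induced by shared centroids and lengths, any
MMSE–measure coupling within group, floor/ceiling effects in
demographics, and annotator/ASR noise. Passing tests therefore
demonstrate correctness and calibration of the measures and inference
under controlled conditions, not clinical validity on real speech.

## Problem sizes used by the test suite

Oracle-equivalence checks run 1000 random fixtures at n ≤ 12 (1e−10
tolerance), BH vectors up to m = 50, and 50–100 random GLM/partial
correlation fixtures. Ground-truth recovery runs 100 cohorts at
n = 300/300 (full pipeline per cohort) and requires the injected GSim
effect with q < 0.05 in ≥ 95; the null-calibration check runs 60
cohorts at n = 150/150 with all effect knobs equalized and bounds the
any-discovery rate by the nominal 5% plus three binomial standard
errors. Monotonicity grids use 5 points × 40 subjects per point.

## Known limitations

- The fixture subword vocabulary is small; its segmentations are stable
  but not linguistically meaningful. Real tokenizers change subword
  counts and hence subword TTR.
- The contextual fixture looks only one token left/right, so its
  windowed encoding is exact; real transformers have longer-range
  context, and windowing is then an approximation at window borders.
- The Gamma surprisal model has a fixed shape (4 in the generator, 2 in
  the standalone scorer); real language-model surprisal distributions
  are heavier-tailed.
- `describe_groups` requires complete demographics (run imputation
  first) and reports the Pearson χ² without continuity correction for
  the 2×2 sex table.
- Greek support is limited to the frozen stopword list and a fixture
  vocabulary with the Greek alphabet; no morphological handling.
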