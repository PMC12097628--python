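# semspace

Semantic-space analysis of picture-description speech for Alzheimer's
disease research.

Spontaneous speech elicited by a picture (e.g., the Cookie Theft scene)
carries rich signal about semantic and syntactic degradation in probable
Alzheimer's disease (pAD). `semspace` turns per-subject transcripts into
a panel of language measures and runs the full inferential pipeline that
compares patients (pAD) with normal controls (NC) and relates the
measures to global cognition (MMSE), including a crosslingual
(English/Greek) replication check. It is written for clinical-NLP and
digital-biomarker researchers who need a tested, deterministic,
offline-runnable implementation of this analysis.

## Measures

For a transcript embedded as vectors $U = (e_1, \dots, e_n)$:

- **Local semantic similarity**
  $\mathrm{LSim} = \frac{1}{n-1}\sum_{i=1}^{n-1}\cos(e_i, e_{i+1})$ —
  coherence between consecutive tokens.
- **Global semantic similarity**
  $\mathrm{GSim} = \frac{2}{n(n-1)}\sum_{i<j}\cos(e_i, e_j)$ — how
  tightly the transcript's semantic cloud is concentrated; a
  *contracting* semantic space raises it. Computed on two tracks:
  content words with static (fastText-style) embeddings (conceptual
  meaning) and full subword sequences with contextual (BERT-style)
  embeddings (referential, grammar-sensitive meaning).
- **Perplexity**
  $H = -\frac{1}{n}\sum_i \log_2 p(t_i \mid t_{1:i-1})$, $\mathrm{PPL} =
  2^H$ — the effective number of equally likely continuations under an
  autoregressive language model (a fair six-sided die has $H \approx
  2.585$ bits, $\mathrm{PPL} = 6$).
- **Bimodal alignment** — mean cosine between each sentence's embedding
  and the stimulus picture's embedding in a shared vision-language
  (CLIP-style) space.
- **Averaged dependency distance (ADD)** — mean absolute distance
  between linear positions of syntactically linked words, pooled over
  all dependency arcs (punctuation excluded); in *"Mary ate the juicy
  red sweet apple"* the arc from *ate* (2) to *apple* (7) has distance 5.

The statistical stage screens covariates (age, sex, education, TTR,
word count) by Spearman partial correlation with joint
Benjamini–Hochberg FDR, fits per-measure GLMs
(`measure ~ group + covariates`, Gaussian/identity with a deviance
goodness-of-fit gate that switches skewed responses such as PPL to
Gamma/log), regresses measures on MMSE within the patient group, and
declares an English effect replicated in Greek when the coefficients
share a sign and the English coefficient falls inside the Greek 95% CI.

Real model backends (fastText, BERT, Mistral, CLIP) plug in behind
small provider protocols; the package ships deterministic hash-based
fixture providers and a synthetic-cohort generator with controllable
group effects, so everything runs and tests offline.

## Worked example

```python
import semspace as s

ex = s.generate_worked_examples()
h, ppl = s.perplexity(ex["die_logprobs"])
print(f"cross-entropy = {h:.3f} bits, perplexity = {ppl:.1f}")
print("arc distances:", s.arc_distances(ex["mary_parse"]))

feats = s.features_from_cohort(s.generate_cohort(s.default_spec("en", seed=1)))
results, _ = s.run_group_analysis(feats)
for r in results:
    t = r.focal
    print(f"{r.measure:<12} {r.family:<17} beta={t.coef:+.4f} z={t.z:+.2f} q={t.q:.2e}")
```

prints

```
cross-entropy = 2.585 bits, perplexity = 6.0
arc distances: [1, 4, 3, 2, 1, 5]
ft_lsim      gaussian_identity beta=+0.0376 z=+5.68 q=2.58e-08
ft_gsim      gaussian_identity beta=+0.0365 z=+5.66 q=2.58e-08
bert_lsim    gaussian_identity beta=+0.0349 z=+5.57 q=3.01e-08
bert_gsim    gaussian_identity beta=+0.0346 z=+5.57 q=3.01e-08
ppl          gamma_log         beta=+0.1581 z=+5.08 q=3.83e-07
bimodal_sim  gaussian_identity beta=-0.0455 z=-6.61 q=2.66e-10
add          gaussian_identity beta=-0.1474 z=-6.11 q=3.46e-09
```

The die fixture lands on the textbook entropy of a fair six-sided die.
The arc list enumerates the example sentence's dependency distances,
including the distance-5 verb–object arc. The regression block analyses
a synthetic English-sized cohort (143 NC / 148 pAD) whose generator
injects the expected clinical pattern: similarity measures rise in pAD
(positive group coefficients — semantic space contracts), picture
alignment and dependency distance fall, and the right-skewed PPL is
automatically routed to a Gamma/log model by the goodness-of-fit gate.

A CLI wraps the same pipeline: `semspace all --config config.yaml`
writes feature tables, cohort descriptives, regression tables, and the
replication verdicts; `semspace simulate` writes a synthetic cohort in
the package's input formats (metadata CSV, transcript text files,
CoNLL-U parses).

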