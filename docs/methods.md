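# Methods

This note documents the statistical procedures implemented in `medconf`,
the modeling assumptions behind the synthetic answer-log generator, the
numerical conventions, and the known limitations.

## Setting

A model answers multiple-choice questions (2–5 options lettered A–E, one
gold letter) through a templated prompt that asks it to name a letter and
rate its confidence 0–100. The evaluation asks two questions per
confidence signal: *discrimination* — can the signal separate correct
from incorrect answers? — and *calibration* — does a stated confidence of
c correspond to accuracy c?

## Parsing

The template branch matches
`The correct answer is: [letter]. My confidence level is: [number].`
case-insensitively with flexible whitespace, optional brackets around the
letter and an optional `%`. Off-template responses go through a
deterministic fallback: the first standalone *uppercase* A–E (lowercase
is excluded so the article "a" never parses as an answer) and the first
number within the confidence scale. Responses defeating both branches
get `parse_status=failed` and are excluded from every metric denominator;
the exclusion count is reported, never silently dropped. A response with
a letter but no usable confidence number stays in accuracy and
token-based analyses and is excluded from expressed-confidence analyses
only. The answer token is the first emitted token whose text, after
stripping leading whitespace/brackets and trailing punctuation
(tokenizer dialects emit `B`, ` B`, `B.`, `(B`), equals the parsed
letter; records where it is never found are excluded from
token-probability analyses and tallied.

## Confidence signals

Log-probabilities are stored in natural log exactly as APIs emit them
and exponentiated only inside metric code (this avoids silent
double-exponentiation). The option-token distribution at the answer
position assigns each option letter the probability of its best-matching
top-k entry; mass not matching any letter becomes a single residual
outcome, keeping the distribution proper without fabricating per-letter
mass. Token probability is the chosen letter's raw probability —
renormalizing over options would hide exactly the dispersion the signal
is meant to expose. Entropy is base 2 (bits) over letters + residual;
the base is irrelevant to rank-based analyses. Perplexity multiplies
1/p over *all* emitted tokens of the templated answer, computed in log
space; a length-normalized variant is available behind a flag. Entropy
and perplexity are doubt scores and enter ROC analyses negated, so every
reported AUROC is oriented higher-confidence-is-better.

## Discrimination

The positive class is the correct answer. AUROC is computed from
midranks (exactly the pairwise Mann–Whitney count with ties ½; the sum
of midranks is an exact half-integer, so the fast path agrees with the
O(n²) oracle to the last bit). Variance, CIs and paired tests use
DeLong's structural components: with V₁₀ per positive and V₀₁ per
negative, `var(AUC) = S₁₀/m + S₀₁/n`, and for two signals scored on the
same items the 2×2 component covariance gives the variance of the AUC
difference; z is referred to a standard normal, two-sided. The DeLong CI
is used rather than a bootstrap because it is deterministic.

Operating thresholds maximize Youden's J = TPR − FPR over the observed
score values (no midpoints, matching the integer-percent thresholds
real logs produce); ties break toward the highest threshold, the most
conservative rule (fewest answers flagged confident). "Above threshold"
means score ≥ t, so a threshold of 100 keeps probability-1 answers
above; a strict-`>` variant is exposed. Stratum proportions (TPR, FPR,
accuracy above/below) carry Wilson score intervals; empty strata are
flagged, not errors. Accuracy comparisons across models use Fisher's
exact test; paired above-threshold indicator comparisons between two
signals use McNemar (exact binomial for < 25 discordant pairs,
continuity-corrected χ² otherwise). In the end-to-end report the single
`p_vs_expressed` column is the paired DeLong p; McNemar p-values for the
TPR/FPR contrasts are reported alongside.

## Calibration

Only the two probability-scale signals are calibrated: expressed
confidence (divided by its scale max, 100 or 1 for the 0–1 prompting
variant) and token probability. Entropy and perplexity are not
probabilities and appear only in discrimination.

ACE sorts by confidence (stable; ties may span bins — no tie merging)
and splits into `n_bins` contiguous equal-mass bins (sizes differing by
at most one, larger bins first; default 10, configurable), then averages
|accuracy − mean confidence| over bins. With one bin it reduces exactly
to the overall confidence–accuracy gap. Equal-mass binning is used
because these confidence distributions pile up near 100, where
fixed-width bins would be nearly empty. ACE > 0.25 is flagged as poor
calibration. Brier is the mean squared confidence–outcome difference.

Interval estimates use the seeded percentile bootstrap (default 2000
replicates; 200 minimum). BCa was not used: at the sample sizes involved
(hundreds to thousands) the simplicity and exact reproducibility of the
percentile interval outweigh its small coverage penalty, and the
coverage is property-tested (≥ 90% observed for a nominal 95% Brier
interval). A resample is redrawn only when the original data had both
outcome classes and the resample lost one, with a retry cap. Paired
signal comparisons resample items jointly and report
`p = 2·min(#{diff* ≤ 0}+1, #{diff* ≥ 0}+1)/(reps+1)`, capped at 1, so
the smallest attainable p is 2/(reps+1).

## Synthetic generator

The generator exists so every pipeline stage is testable with known
ground truth, without API access. Per item, correctness is drawn first
(Bernoulli at the target accuracy) and the latent confidence conditioned
on it — correctness-first rather than difficulty-first because it yields
a closed-form true AUC for recovery tests, a deliberate trade of
mechanistic realism for testability. In binormal mode the latent score
is N(μ, 1) for correct and N(0, 1) for incorrect answers, pushed through
the logistic function; since the map is strictly monotone the true AUC
is Φ(μ/√2). The chosen letter (gold if correct, uniform otherwise) gets
the latent score as its token probability and the remainder is split
evenly over the other letters; Dirichlet mode instead draws the whole
option vector from a Dirichlet concentrated on the answered letter,
giving the ragged dispersed-when-wrong distributions seen in real logs.
All non-answer tokens of the templated response have probability 1, with
top-k padded by negligible-mass fillers so the top-k depth (default 5,
the common API limit) is constant within a record.

Verbalized confidence has two profiles: `constant_high` (default, base
95) reproduces the nearly-uninformative clustered-high ratings real chat
models give; `quantized_informative` emits
`clip(round5(100·(s + δ)), 0, 100)` — informative but quantized to
multiples of 5, with δ an overconfidence offset for
calibration-recovery tests. Defaults (2500 items, 5 options, accuracy
0.75, μ = 1.4652 ⇒ true AUC 0.85) emulate a strong commercial model on a
USMLE-style bank; 2500 items matches the size of such question sets and
keeps every analysis comfortably fast.

`expected_expressed_ace` is the analytic oracle for the quantized
profile: it integrates the binormal model exactly (normal CDFs over the
logit intervals that quantize to each confidence atom), applies the same
equal-mass binning to the resulting population — splitting atoms that
straddle bin boundaries proportionally — and returns the infinite-n ACE.
Sampled ACE at n = 5000 is verified to land within ±0.02 of it.

What the generator does **not** emulate: per-item difficulty structure,
language effects (language tags are labels only), off-template or
refused answers, correlated errors across items, and any dependence of
verbalized confidence on question content. Passing tests therefore
demonstrate the correctness of the *measurement machinery*, not claims
about any particular model's behavior on real questions.

## Numerical conventions and degenerate inputs

Reports are CSV with fixed column order and six significant digits;
identical inputs + config + seed give byte-identical files. AUROC on
single-class inputs is an error; identical score vectors in the DeLong
test return p = 1 (zero variance with unequal AUCs is an error);
McNemar with no discordant pairs returns p = 1; ACE requires
n ≥ n_bins; bootstrap p-values are floored by add-one smoothing.
Scores are computed from the response record alone — gold letters enter
only the correctness column (leakage-guard tested). Duplicate records
for the same (item, model, prompt variant) are kept on read with a
warning and only the first is graded, so re-runs never silently
overwrite an earlier answer.

## Limitations

Single-token multiple-choice answers only: no aggregation of token
probabilities over free-text answers, no semantic-entropy clustering
over repeated samples, no self-consistency ensembles, and no
recalibration fitting (temperature scaling etc.). Significance is
two-sided 5% throughout with no multiplicity correction. The live-API
adapter is an interface only; nothing in the test suite performs network
calls.
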