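# medconf

**Do language models know when they don't know?** When chat models answer
multiple-choice medical questions (USMLE-style licensing-exam items), they
verbalize confidence ratings clustered between 80 and 100 regardless of
whether the answer is right. The probability the model assigned to its own
answer token, however, is available from every major API and carries real
information about correctness. `medconf` is a statistical toolkit for
quantifying that contrast: it measures how well each per-answer confidence
signal *discriminates* correct from incorrect answers and how well it is
*calibrated*, for anyone evaluating LLMs on multiple-choice QA —
benchmark builders, clinical-NLP researchers, and model evaluators.

## Confidence signals

For each answer the package computes four signals from the raw response
text and the per-token top-k log-probabilities:

- **Expressed confidence** — the number the model prints when asked to
  rate its confidence from 0 to 100 (parsed from the response template,
  with a deterministic rule-based fallback for off-template replies).
- **Response token probability** — the raw probability `p(letter)` of the
  chosen option-letter token at its generation position, deliberately
  *not* renormalized over the options.
- **Shannon entropy** of the option-token distribution,
  `H = −Σ_k p_k log₂ p_k` over the option letters plus one residual
  outcome for top-k mass not on any letter (a doubt measure).
- **Answer perplexity** `PPL = Π_t 1/p_t = exp(−Σ_t ln p_t)` over all
  emitted tokens (a doubt measure).

## Statistical analyses

- **Discrimination** — AUROC (Mann–Whitney, ties = ½) with DeLong CIs;
  paired DeLong tests between signals; Youden-*J* optimal thresholds;
  TPR/FPR and above/below-threshold accuracy with Wilson CIs; McNemar
  and Fisher exact tests. Doubt-oriented signals are negated before ROC
  entry so every AUROC reads higher-is-better.
- **Calibration** — adaptive calibration error (ACE; mean |accuracy −
  mean confidence| over equal-mass confidence bins, robust to the skewed
  confidence distributions these models produce; ACE > 0.25 is flagged
  as poor calibration), Brier score, seeded percentile-bootstrap CIs and
  bootstrapped paired p-values, plot-ready calibration curves.
- **Synthetic generator** — answer logs with known ground truth:
  configurable accuracy, a binormal latent-confidence mode with
  closed-form true AUC Φ(μ/√2), a Dirichlet mode for ragged option
  distributions, and verbalized-confidence profiles (constant-high, or
  quantized-to-multiples-of-5 with an overconfidence offset) for
  calibration-recovery experiments.

## Worked example

```bash
cat > sim.toml <<'EOF'
n_items = 1000
seed = 7
EOF
medconf simulate --config sim.toml --out simout

cat > run.toml <<'EOF'
dataset_path = "simout/dataset.jsonl"
response_log_path = "simout/responses.jsonl"
output_dir = "evalout"
seed = 11
EOF
medconf evaluate --config run.toml
```

prints

```
n=1000 accuracy=0.768 (0.741-0.793)
expressed: AUROC=0.500 (0.500-0.500) threshold=95
token_prob: AUROC=0.843 (0.814-0.872) threshold=0.666403 p_vs_expressed=1.1e-118
entropy: AUROC=0.843 (0.814-0.872) threshold=1.58575 p_vs_expressed=1.1e-118
perplexity: AUROC=0.843 (0.814-0.872) threshold=1.50059 p_vs_expressed=1.1e-118
expressed: ACE=0.182 Brier=0.211
token_prob: ACE=0.069 Brier=0.126
reports written to evalout
```

Reading: the simulated model answers 76.8% of items correctly. Its
verbalized confidence is a constant 95, so it cannot separate right from
wrong answers at all (AUROC exactly 0.5) and is badly overconfident
(ACE 0.182). The token probability discriminates well (AUROC 0.843; the
paired DeLong test against expressed confidence is decisive) and is much
better calibrated (ACE 0.069, Brier 0.126 vs 0.211). Answers whose token
probability clears the Youden threshold of 0.666 are the ones to trust;
full per-signal tables land in `evalout/*.csv`.

The same analyses run on real logs: write your items and API responses
in the documented JSONL formats (see `medconf.io`) and point
`medconf evaluate` at them. `medconf compare --configs a.toml b.toml …`
DeLong-tests token-probability AUROC across prompt variants against the
first (baseline) config.

All comparisons use a two-sided 5% significance level with no
multiplicity correction — interpret large report tables accordingly.

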