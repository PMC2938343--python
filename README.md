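# signature-ifs

Unified gene-signature discovery for cancer-subtype classification **and**
survival prediction from a single expression matrix.

Subtype calling and survival prediction are usually modelled separately,
even though they are entangled — in diffuse large B-cell lymphoma (DLBCL),
for example, the germinal-center B-cell-like (GCB) subtype carries a better
prognosis than the activated B-cell-like (ABC) subtype. This package treats
the two problems jointly: every patient is assigned to one of **four
groups** (ABC-dead, ABC-alive, GCB-dead, GCB-alive), a single ranked gene
list is learned against that four-group label, and one signature is chosen
that performs well on *both* binary tasks obtained by merging the groups
two ways (ABC vs GCB; dead-labelled "high-risk" vs alive-labelled
"low-risk").

## Method

1. **Preprocessing** — duplicate probes are averaged to genes, low-intensity
   genes (across-sample mean below a threshold) are dropped, and samples are
   quantile-normalized.
2. **mRMR ranking** — expression is discretized per gene into three bins at
   mean ± t·σ and genes are greedily ranked by
   *maximum relevance, minimum redundancy*: the first pick maximizes the
   mutual information `I(g; c)` with the four-group label `c`; each later
   pick maximizes `D − R`, where `D = I(g; c)` and
   `R = (1/|S|) Σ_{s∈S} I(g; s)` over the already-selected set `S`
   (difference form; the quotient form `D/R` is a switch).
3. **Nearest-neighbor LOOCV** — with the top-`k` genes, each sample is
   predicted into one of the four groups by its single nearest neighbor
   under the cosine-derived distance `D(x, y) = 1 − ⟨x,y⟩ / (‖x‖‖y‖)`,
   leaving that sample out of the training set.
4. **Incremental feature selection (IFS)** — for every `k` the four-group
   predictions are merged into the subtype task (overall accuracy) and the
   risk task (log-rank test comparing the observed survival of predicted
   high- vs low-risk samples, with Kaplan–Meier curves per arm). This gives
   two curves over `k`.
5. **Balanced selection** — within `k ∈ [1, k_max)` (default `k_max` 100)
   both metrics (accuracy, −log₁₀ p) are min–max normalized and summed;
   the `k` with the highest combined score is the unified signature
   (smallest `k` on ties).

A first-class synthetic-data generator produces four-group cohorts with
planted subtype- and survival-informative genes and censored exponential
survival times, so the whole pipeline is testable end-to-end without any
external download.

## Worked example

Run the full pipeline on the default synthetic cohort (500 genes, 88
patients in the four groups, 10 subtype-informative and 10
survival-informative genes at effect size 2):

```bash
signature-ifs run --seed 1 --out-dir demo_run
```

prints

```
{"chosen_k": 25, "subtype_accuracy": 0.9545454545454546, "logrank_statistic": 42.2448635939266, "logrank_p": 8.053124193692966e-11}
```

and `demo_run/run.log` records each stage:

```
simulate: 500 genes x 88 samples
preprocess: 500 -> 375 genes
rank: 100 genes ranked
ifs: curve over k=1..100
select: chosen_k=25
survival: high=32 low=56
```

Reading: the balanced choice is a **25-gene signature**; its leave-one-out
subtype accuracy is **95.5%**, and the predicted high-risk patients (n=32)
have markedly worse observed survival than the predicted low-risk ones
(log-rank χ² = 42.2, p ≈ 8×10⁻¹¹). All intermediates (preprocessed matrix,
mRMR table, IFS curve, prediction table, KM step tables, JSON report) are
written to `demo_run/`, and every stage can be replayed individually with
the `simulate`, `preprocess`, `rank`, `loocv`, `ifs`, `select` and
`survival` subcommands.

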