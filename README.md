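# crowdner

Aggregation and evaluation of **crowdsourced disease named-entity
annotations**, with a built-in citizen-science study simulator and an
engagement-metrics report.

## The problem

Named entity recognition (NER) — finding the character spans in an abstract
that mention a disease — is a bottleneck step of biocuration. One scalable
strategy is to show each abstract to many non-expert volunteers and combine
their markings. Individually the volunteers are noisy: they miss mentions,
split multi-word terms ("colorectal cancer" marked as "colorectal" and
"cancer"), include or drop modifier tokens ("premenopausal ovarian cancer"
vs "ovarian cancer"), and mark spurious text. In aggregate, however, simple
agreement voting recovers near-expert annotations.

`crowdner` is for researchers running or analyzing such projects. It
implements:

* **Data model + I/O** — documents and gold annotations in PubTator format
  (`PMID|t|…`, `PMID|a|…`, tab-separated offset rows); multi-annotator
  submission logs as JSONL or long-form CSV with a configurable column
  mapping; spans are 0-based half-open character intervals over
  `title + " " + abstract`.
* **Scoring** — exact-span (and overlap) matching, micro-pooled
  precision/recall/F per user and corpus-wide, and the gamified per-document
  feedback score (F against a partner × 1000).
* **Agreement aggregation** — the central statistic. For each span marked in
  a document, its *minimum percent agreement* is `a = m/n`: the number of
  distinct annotators marking that exact span over the number who processed
  the document. Keeping spans with `a ≥ t` interpolates between the union of
  all markings (`t = 0`) and their intersection (`t = 100`); sweeping `t`
  against gold traces the precision/recall/F trade-off
  `P(t), R(t), F(t) = 2PR/(P+R)` and its F-maximizing threshold.
* **Subsampling** — how many annotators per document are enough? Draw `k`
  annotators per document without replacement, re-run the sweep, repeat over
  replicates, and report mean ± sd of F as a function of `k`.
* **Success metrics** — the twelve-proxy citizen-science success matrix
  (communication, interaction, sustained engagement, distribution of effort
  `1 − Gini`, effective training, completeness, …) from an event log.
* **Simulation** — a generator of synthetic corpora and full studies with
  per-annotator detection probability, boundary/split error rates, spurious
  marks, heavy-tailed workloads and burst-like activity calendars, plus the
  closed-form oracle `R(t) = P(Binomial(n, p) ≥ ⌈nt/100⌉)` for aggregate
  recall under the pure detection model.

## Worked example

Simulate a small study (12 documents, 25 annotators with detection
probability 0.8, 15 annotators per document), then sweep the agreement
threshold:

```bash
crowdner simulate --out demo --seed 7 --n-docs 12 --n-annotators 25
crowdner curve --corpus demo/corpus.txt --submissions demo/submissions.jsonl
```

```
threshold  tp  fp   fn  precision  recall  f1
0.0        29  199  0   0.127      1.000   0.226
10.0       29  38   0   0.433      1.000   0.604
20.0       29  5    0   0.853      1.000   0.921
30.0       29  0    0   1.000      1.000   1.000
50.0       28  0    1   1.000      0.966   0.982
70.0       21  0    8   1.000      0.724   0.840
100.0      0   0    29  0.000      0.000   0.000
```

Reading the table: at 0% agreement (the union of everyone's marks) every
one of the 29 gold spans is recovered (recall 1.0) but spurious marks give
precision 0.127; at 100% (the intersection) nothing survives; in between,
voting suppresses the idiosyncratic errors and F peaks at 1.0 around the
30–40% threshold. Per-user quality and the annotators-per-document curve:

```bash
crowdner score --corpus demo/corpus.txt --submissions demo/submissions.jsonl --out scores.tsv
# mean per-user F = 0.651 (sd 0.107)
crowdner subsample --corpus demo/corpus.txt --submissions demo/submissions.jsonl \
    --ks 2,3,5 --replicates 5 --seed 7
```

```
k  mean_f  sd_f   threshold_policy
2  0.675   0.058  sweep_max
3  0.902   0.020  sweep_max
5  0.961   0.019  sweep_max
```

Individual annotators average F ≈ 0.65 against gold, yet the
agreement-voted aggregate of only 5 of them reaches F ≈ 0.96 — the gain
from two to three annotators is the steepest. The same operations are
available as library functions (`crowdner.agreement_curve`,
`crowdner.f_vs_k`, `crowdner.success_report`, …), and `crowdner run
--config config.yaml` executes the whole pipeline into a TSV report bundle
with a reproducibility manifest.

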