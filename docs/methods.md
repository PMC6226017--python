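# Methods

## Coordinate frame and span identity

All annotations address the concatenation `title + " " + abstract` with
0-based, half-open character offsets (the PubTator convention; the joining
space belongs to the frame). A span's identity is the triple
`(start, end, entity_type)`; its surface string is metadata used for
validation (the document slice must equal it on read; a `--lenient` mode
downgrades mismatches to warnings because real exports can drift in
whitespace). Duplicate identical spans within one annotator's set are
collapsed on ingest: agreement counts *users*, not marks, and a user cannot
vote twice for the same span.

## Scoring

Exact matching is the default: a predicted span is a true positive iff the
identical triple exists in the reference. The `overlap` mode pairs spans of
equal type sharing at least one character, greedily, one-to-one, preferring
larger character overlap and then smaller start offset; it exists because
the two characteristic crowd errors — conjunction splitting and modifier
inclusion — produce overlapping-but-not-exact spans, and quantifying how
much of the disagreement they explain requires a laxer criterion.

Conventions, chosen so that pooled statistics are total functions:

* P = tp/(tp+fp), R = tp/(tp+fn), F = 2PR/(P+R), each defined as 0 when its
  denominator vanishes.
* Per-user scores are micro-pooled: a user's tp/fp/fn are summed over all
  their documents before one P/R/F is computed ("F across all of a user's
  annotations" rather than a mean of per-document F values, which would
  overweight short documents).
* Corpus-level scores in the threshold sweep are likewise micro-pooled
  across documents; a macro (mean per-document F) variant is available via
  `agreement_curve(..., average="macro")`.
* The summary sd of per-user F is the population standard deviation.
* Feedback points are `round_half_up(F × 1000)`; a user with no partner
  receives the full 1000.

## Agreement aggregation

For one document with n distinct annotators, a span marked by m of them has
agreement a = m/n. `aggregate_at_threshold` keeps spans with a ≥ t/100 for
t > 0, and all marked spans (m ≥ 1, the union) at t = 0; t = 100 is exactly
the intersection across annotators. n is the *actual* number of distinct
annotators of that document, never a nominal target — real quest mechanics
can overshoot the planned replication. An annotator who somehow submitted a
document twice is unioned into a single voter. The default threshold grid
is 0, 10, …, 100; the F-maximizing threshold breaks ties toward the lower
threshold (preferring recall at equal F).

Two consequences used as test invariants: the kept set is monotonically
shrinking in t (so corpus recall is non-increasing and fn non-decreasing),
and the endpoints coincide with direct set union/intersection.

## Subsampling experiment

`f_vs_k` draws k annotators per document uniformly without replacement,
re-runs the threshold sweep on the subsample, and records F; repeated over
replicates (default 25) it gives mean ± sd of achievable F as a function of
k. The default threshold policy re-optimizes the threshold at each
subsample (`sweep_max`), since the operating threshold would in practice be
re-chosen for a differently replicated study; a `fixed` policy scores at
one threshold instead, and the policy used is recorded in the output.
Documents with fewer than k annotators are skipped with a warning, not
up-sampled. Seeds are derived per (k, replicate, document) from the root
seed via `SeedSequence` spawn keys, making results independent of iteration
order; at k = n the subsample is the full data, so F equals the full-data
value exactly and the replicate sd is 0.

## Success metrics

The twelve-proxy matrix splits into a Contribution-to-Science panel
(publication rate, completeness of analysis, academic impact, resource
savings, distribution of effort, effective training) and a
Public-Engagement panel (collaboration, communication, interaction, project
appeal, sustained engagement, public contribution). Numerators are event
counts; denominators follow the proxy definitions: publication-linked
metrics divide by the squared *project age* in days, engagement metrics by
the squared *active period* in days (both squared, per the matrix's
definition of these proxies as second-order rates). Specifics:

* **Gini / distribution of effort**: population relative mean absolute
  difference, G = Σᵢⱼ|xᵢ−xⱼ| / (2 n² x̄), computed via the sorted-rank
  identity; distribution of effort is 1 − G. No small-sample correction is
  applied — the variant is not standardized across projects, and the
  uncorrected population form is the most common baseline.
* **Medians** (volunteer active period, classifications per volunteer) use
  the lower median on even counts, keeping the statistic an attained data
  value. A user's active period is `(last submission date − account
  creation date) + 1` whole days, so same-day activity counts as one day.
* **Effective training** = 1 − tutorial-only completions / contributors;
  **completeness** = classifications done / target (may exceed 1 when
  overshoot is allowed).
* **Resource savings** is a configurable cost model, tasks × unit cost ×
  (1 + platform fee); there is no canonical derivation, so the value is
  reported but never asserted against anything.
* Missing optional counts yield an *absent* metric, never a zero.
* Values are carried at full precision; printing rounds half-up to 3
  decimals (2 for completeness).

Funnel helpers: training retention is a plain percentage; survey response
rate is truncated (not rounded) to one decimal, matching the reporting
convention for that figure.

## Synthetic studies

The generator is the package's test bed: it produces a gold corpus, a
submission log and an engagement log with the qualitative features the
analysis must cope with, under full seed control (`SeedSequence` spawn
keys; no global random state).

* **Corpus**: documents of 40–80 random pseudo-words from a 500-word
  vocabulary, 1–4 planted disease entities per document with token lengths
  distributed {1: 0.5, 2: 0.3, 3: 0.15, 4: 0.05}, entities separated by at
  least one token; 10% of documents flagged for gold feedback. Packing
  infeasibility (maximum entities × maximum length exceeding the shortest
  document) is rejected at validation.
* **Annotator error model**: each gold span is detected with `p_detect`
  (default 0.8, in the range of observed individual volunteer quality); a
  detected multi-token span is split into its word pieces with `p_split`
  (0.05), else boundary-shifted by one adjacent token — extend or truncate,
  equally likely among feasible edits — with `p_boundary` (0.1); spurious
  single-token marks are Poisson(`spurious_rate`, default 1.0) on non-gold
  token positions. The split/boundary/spurious defaults are calibration
  choices for plausible-looking studies, not estimates of any real cohort.
  Because spurious marks are placed independently per annotator at random
  positions, high-agreement spurious spans are rare — which is precisely
  the mechanism by which thresholding raises precision.
* **Study assembly**: each document gets exactly `annotators_per_doc`
  (default 15) distinct annotators, drawn with probability proportional to
  Pareto(α = 1.1) workload weights, giving the heavy-tailed
  contributions-per-user distribution seen in volunteer projects. Each
  annotator works in one contiguous burst (mostly a single day), so the
  median account-to-last-submission period is about one day — volunteers
  who participate once dominate. The engagement log is derived from the
  submission log, so its counts are consistent by construction.
* **Closed-form oracle**: under the pure detection model (no
  boundary/split errors, spurious marks that cannot collide with gold), a
  gold span survives threshold t iff at least k = ⌈nt/100⌉ of n annotators
  mark it (k = 1 at t = 0), so aggregate recall is the binomial tail
  P(Binomial(n, p) ≥ k). The parameter-recovery test simulates 400
  documents × 15 annotators at p = 0.8 and requires the observed recall at
  each t ∈ {0, 20, …, 100} to sit within 3 Monte-Carlo standard errors
  √(r(1−r)/G) of the closed form, G being the number of gold spans
  (~1000 at these sizes — chosen so the granularity of a single missed
  span stays inside the band).

What the simulator does *not* model: real language (tokens are random
strings, so no lexical ambiguity or annotation-rule subtleties),
inter-annotator error correlation (all errors are independent given the
profile), learning over time, and partner-pairing dynamics. Passing tests
on synthetic studies therefore demonstrate the correctness of the
aggregation/scoring machinery and the qualitative threshold behavior, not
the real-data accuracy levels; those are checked by an optional
integration test against the original corpus and submission export when
those files are provided locally.

## Pipeline

`run_experiment` chains read → per-user scores → agreement sweep →
subsampling → success metrics → points ledger, writing one TSV per stage
plus a JSON manifest (config echo, seed, library versions, wall time).
Stage failures abort with the stage name. Outputs are byte-identical across
reruns of the same config and inputs (the manifest's wall time excepted).
The points ledger mirrors the gamification rules — per-document feedback
points (partner = expert gold on feedback-flagged documents, else the
previous annotator, else the full allotment) and a 5000-point bonus per
completed quest of five documents — and is reported for completeness; no
analysis depends on it.

Problem sizes in the shipped tests (hundreds of documents, ≤ 40 simulated
annotators, 25 subsampling replicates) were chosen as the smallest at which
the Monte-Carlo bands above are informative; all defaults scale up
unchanged.
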