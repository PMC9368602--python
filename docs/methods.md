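# Methods

## Model

`knrank` treats multi-disease prediction as ranking on an explicit evidence
graph rather than as supervised classification. The core object is a
bipartite **knowledge network** G(D, F): disease nodes D, finding nodes F
(clinical manifestations and auxiliary examination results), and weighted
edges f → d meaning "finding f supports the diagnosis of d". The category of
the relation — occasional manifestation, common manifestation, auxiliary
result — lives on the **edge**, not the finding node: the same symptom can be
a common manifestation of one disease and an incidental one of another, and
that asymmetry is what lets graded weights discriminate. (If the category
were a node property, every edge of a finding would share one weight and the
ratio w(f,d)/out-weight(f) would collapse to 1/degree for *any* scheme — the
weight setting could never change a prediction.) When all edges of a finding
agree, `KnowledgeNetwork.finding_category` still reports a node-level
category.

A **weight scheme** maps categories to positive weights. The named schemes
are `<113>`, `<123>`, `<135>`, `<137>` (default), `<139>`, written
⟨occasional, common, auxiliary⟩, plus the uniform baseline `<111>` used as a
control in the scheme-comparison experiment. An explicit per-edge weight in
the TSV overrides the scheme, for the occasional clinical exception.

### Per-patient subnetwork and calibration

For one record, the affirmed, matched findings plus all diseases they support
(with their KN edge weights) form a directed bipartite DAG. Into every
subnetwork we inject a reserved calibration pair: `__GOLD_STANDARD__` →
`__STANDARD_DISEASE__`, weighted like an auxiliary result. The pair encodes
the decision rule "predict a disease when its pooled evidence reaches the
level of a single defining gold-standard test".

### NodeRank

Scores come from the damped, edge-weighted PageRank recursion

    NR(v) = (1 − d) + d · Σ_{u→v} NR(u) · w(u, v) / outweight(u)

with damping d = 0.85, all ranks initialized at 1, and the (1 − d) term *not*
normalized by node count (the non-stochastic PageRank variant; scores are
per-node quantities, not a probability distribution). Source nodes converge
to exactly 1 − d. The standard disease therefore lands at
(1 − d) + d(1 − d) = (1 − d)(1 + d), independent of the subnetwork — a closed
form the tests check on every generated subnetwork. Prediction outputs every
non-reserved disease with NR ≥ that threshold, sorted by descending rank then
id.

On the bipartite DAGs actually used, every finding is a source, so

    NR(D) = (1 − d) + d(1 − d) · support_ratio(D),
    support_ratio(D) = Σ_f w(f, D) / outweight(f)

and the threshold rule is exactly `support_ratio ≥ 1`, independent of d.
`support_ratio` is exposed as the interpretability handle: each supporting
finding contributes the fraction of its diagnostic weight pointed at D.

Whether one applies the recursion once or iterates to a fixed point is
immaterial on these DAGs (the fixed point is reached after two Jacobi
sweeps); the implementation iterates, so it is also correct on general
weighted digraphs, where it matches a dense linear solve of
(I − d·Mᵀ)x = (1 − d)·1 to below 1e−9 (tested on 100 random graphs).
Convergence is geometric at rate d because each node's outgoing contribution
fractions sum to at most 1.

### Extraction and negation

Tokenization is character-level when the text contains CJK characters
(clinical Chinese has no word boundaries), whitespace otherwise, overridable.
The default tagger is greedy forward maximum matching against a lexicon
(longest term first, left to right, non-overlapping), emitting B/I/O tags.
This is intentionally a transparent baseline: the CRF layer
(`CrfScores`, `crf_score`, `crf_log_likelihood`, `crf_decode`) accepts
emission/transition matrices from any external sequence model and provides
exact Viterbi decoding (ties broken toward the lowest tag index, so decoding
is deterministic) and a log-space forward algorithm. Training neural taggers
is explicitly out of scope.

A mention's polarity is negated iff a cue span ends at most `window` tokens
(default 2) before the mention starts, or lies inside the mention span.
The in-span clause is our reading of mixed phrasings like "mass not
palpable"; the two-token window mirrors how cues in Chinese clinical text sit
immediately before the finding. Both are configurable. The operation is
idempotent and never alters spans or counts. The bundled negation-cue list is
a small demo default (无, 未, 否认, 没有, no, denies, without, …); real
deployments must supply their institution's cue dictionary.

### Matching

Exact surface matches (against finding display names, lexicon surfaces, or a
pre-resolved finding id) win outright. Otherwise the KN finding with the
highest string similarity at or above 0.5 is chosen; ties break to the
shorter display name, then the smaller id. The default similarity is the
character-bigram Dice coefficient (single-character Dice for length-1
strings) — symmetric, 1 only on near-identical surfaces, and cheap. It is a
*surface* measure: true synonym pairs with no shared bigrams (e.g. 腹部疼痛 vs
腹痛 after the shared-character bigrams separate) score 0, which is exactly
why the similarity function is a pluggable callable — a semantic dictionary
or embedding model can be substituted without touching the matcher. Repeated
mentions of one finding collapse to a single subnetwork node.

### Metrics

Hamming loss, one-error, ranking loss, average precision and micro-P/R/F1,
with deterministic conventions where the standard definitions leave slack:
scores absent from a record's map are 0 (the disease never entered the
subnetwork); one-error ties resolve to the lexicographically smallest label;
ranking loss counts ties as loss; ranks are the total order (score
descending, id ascending); average precision normalizes per record by the
gold-set size — the definition whose perfect value is 1 — with the
label-space-normalized variant available behind
`per_label_normalization=False`; empty predictions give precision 0 with a
warning; a record whose gold set covers the whole label space is skipped by
the two ranking metrics (empty complement) with a warning. Every metric is
tested against an independent naive re-implementation on hundreds of random
corpora.

K-fold splitting shuffles by seed and cuts folds whose sizes differ by at
most one. Because the knowledge network is curated evidence rather than a
model fitted to training folds, cross-validation here only partitions records
for evaluation variance estimates (mean ± SD per metric); nothing is learned
from the held-in folds.

## Synthetic data

The simulator emulates the *structure* of a multi-diagnosis gastroenterology
corpus whose published summary statistics it adopts as defaults: a KN of 182
diseases, 1,146 manifestations, 513 auxiliary results; 5,040 records drawn
from a 76-disease case mix; 3.62 diagnoses per record on average. The
generative model itself is ours and deliberately simple:

- gold-set size ~ zero-truncated Poisson with rate solved so the truncated
  mean equals `diseases_per_patient`; diseases uniform without replacement
  from the corpus subset;
- each KN edge of a gold disease emits its finding independently with a
  per-category probability (defaults 0.85 common / 0.30 occasional / 0.70
  auxiliary);
- distractor findings not adjacent to any gold disease are added at rate
  `p_noise_finding` (default 0.05 per true mention), and mentions flip to
  negated with probability `p_negated_mention` (default 0.08);
- `render_text` embeds surfaces in filler tokens, placing a negation cue
  immediately before negated surfaces and more than `window` filler tokens
  after every mention so cues cannot leak forward.

Surfaces are unique ASCII tokens by default; `cjk_surfaces=True` generates
CJK surfaces to exercise character tokenization. Everything is deterministic
given the config seed.

Two designed regimes support the package's verifiable claims:

- **`SimulationConfig.separable`** — each disease has one dedicated auxiliary
  finding, always emitted (support 1), and manifestations are laid out in a
  regular pattern: each common to exactly 4 diseases while each disease
  carries only 3, capping any non-gold disease's support at 3/4. With no
  noise and no negation the pipeline must recover the gold set exactly
  (micro-F1 = 1, Hamming loss = 0) for *every* seed — a structural guarantee,
  not a tuned outcome.
- **`SimulationConfig.weight_contrast`** — manifestations come from a small
  shared pool (typically common for a couple of diseases, occasional for
  several others) while auxiliary findings stay disease-specific but are
  emitted only half the time. Graded weights concentrate a shared finding's
  vote on the diseases it is common for (3/(3+k) per occasional co-holder
  versus the uniform 1/(1+k) split), which both recovers more gold diseases
  and suppresses spurious ones; the acceptance suite checks that `<137>`
  reaches micro-F1 at least that of `<111>` in ≥ 80% of 50 replicates.

What the simulator does **not** emulate: real clinical prose (filler tokens
are not grammar), reporting correlation between findings, comorbidity
structure beyond shared findings, label imbalance of real departments
(diseases are uniform, whereas real corpora range from 76 to ~3,000
occurrences per disease), misspellings, or cross-sentence negation scope.
Passing the end-to-end tests therefore demonstrates the correctness of the
machinery under its stated assumptions, not clinical-grade accuracy on real
EHR text.

## Numerical choices

- NodeRank: Jacobi updates, init 1.0, tol 1e−10 on the max absolute change,
  max 100 iterations, error with residual on non-convergence. On the
  pipeline's DAGs the fixed point is exact after two sweeps, so the schedule
  only matters for user-supplied cyclic graphs.
- The threshold identity: the iterated value equals `(1 − d) + d·(1 − d)`
  bit-for-bit; the algebraically equal product `(1 − d)(1 + d)` can differ by
  one ulp (it does at d = 0.85), so tests assert the sum form exactly and the
  product form at 1e−14 relative.
- CRF log-partition uses `scipy.special.logsumexp` per step; degenerate K = 1
  gives log-likelihood 0 exactly.
- Dangling I tags (an I after O or at sequence start) are repaired as B with
  a logged warning rather than rejected — external taggers are imperfect.
- All tie-breaks (Viterbi backtracking, matching candidates, one-error,
  ranking order, predicted-list order) are fixed and documented so every
  output is deterministic.
- Seeds: generators derive independent streams from the config seed via
  `numpy` seed sequences; text rendering without an explicit generator hashes
  the record id with CRC-32 so per-record text is stable across processes.

## Scale of the shipped checks

Test and acceptance problem sizes are chosen to make the oracles exact and
the suite quick: CRF instances stay at n ≤ 6, K ≤ 4 where full path
enumeration (≤ 4,096 paths) is the oracle; NodeRank uses ≤ 30-node graphs
where a dense solve is exact; the separable regime runs 50 patients; the
scheme comparison 50 replicates of a 30-disease corpus; the reference-scale
evaluation in `scripts/acceptance.py` runs 500 records against the
full-size 182-disease KN. Larger corpora change none of the properties
being checked, only runtime.

## Known limitations

- The dictionary tagger cannot find surface forms absent from the lexicon;
  recall on real text is bounded by lexicon coverage (mitigated by the CRF
  plug-in interface).
- Bigram Dice is a weak proxy for clinical synonymy; the 0.5 threshold is a
  pragmatic default, not a validated operating point.
- Negation scoping is window-based; it has no notion of scope-terminating
  conjunctions, so a cue can reach over a short intervening phrase.
- The KN is assumed correct and complete; there is no mechanism for
  uncertain or time-qualified findings.
- Ranking-based metrics are computed from subnetwork NR scores in which
  absent diseases share score 0; rank ties among them are resolved
  lexicographically, which slightly flatters or penalizes no particular
  disease but is a convention, not information.
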