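# Methods

This note documents the models, procedures, parameter choices, and known
limitations behind `fourms`. It is written for a maintainer or reviewer who
wants to know *why* the pipeline behaves the way it does, not just what the
API returns.

## Corpus model

A corpus is a list of messages `(message_id, resident_id, facility_id,
sender_role, receiver_role, timestamp, text)` with timezone-naive,
minute-precision timestamps, plus a table of nursing-home-to-hospital
transfer events. Messages are linked to every event of the same resident
whose **pre-transfer window** contains them. The window is the half-open
interval `(t − 14 days, t]`: a message sent at the transfer instant belongs
to the transfer's run-up, while the identical instant fourteen days earlier
does not. Fourteen days is the conventional window for transfer-centred
communication analyses and is configurable (`window_days`).

Deduplication defaults to the strictest possible key — every field
byte-identical after whitespace normalization of the text — because any
looser key risks merging distinct clinical events. A
`resident_time_text` key is available for feeds that re-issue message ids.
The first occurrence in input order is retained, which makes the operation
deterministic and idempotent.

## Extraction contract and hallucination screening

Extractors return structured output `{class: [phrases]}` as text. Parsing is
deliberately forgiving: missing classes default to empty lists, unexpected
keys are flagged but tolerated, and syntactically invalid output becomes an
*error result* that carries the raw blob for audit — a pipeline evaluating
generative models must survive malformed output without losing the message.

Validation screens each phrase against its source message using a fuzzy
substring score: the best infix alignment of the normalized phrase against
the normalized message, `1 − edit_distance / len(phrase)`. The default floor
of **0.85** retains clinically meaningful typo variants (e.g.
"disfunction" for "dysfunction") while rejecting fabricated spans; a floor
of 1.0 demands an exact normalized substring. All text comparisons share one
normalization — case-fold, strip punctuation, collapse whitespace — because
informal clinical messages vary freely in all three. Counts count phrases
(not tokens), duplicates included, and are always derived from the validated
span lists; pre-validation counts are kept alongside for audit.

The deterministic lexicon extractor is the reference implementation of the
plug-in contract. It matches lexicon phrases token-aligned on normalized
text, longest-match-first and non-overlapping within a class, and emits the
same JSON schema an LLM adapter would, so it exercises the full parse path.
Decoding parameters (temperature 0.0, top_p 0.9, top_k 40, seed 418) are
carried opaquely for generative adapters and are inert for deterministic
extractors.

## Gold standard and agreement metrics

Two annotators' span sets are diffed per message and class under normalized
fuzzy phrase matching (pairs at similarity ≥ 0.85 are the same phrase —
near-identical wordings should not be adjudicated as disagreements). Every
residual difference must be adjudicated accept/reject; the gold record is
the matched intersection (annotator A's wording is canonical) plus accepted
differences, with per-phrase provenance (`both`, `A_only_accepted`,
`B_only_accepted`). Zero counts are recorded, not dropped: a message without
4M content is a real observation.

The metric battery is computed per class over the gold message set:

- **Cohen's κ** is implemented directly from `(p_o − p_e)/(1 − p_e)` with
  marginal-product chance agreement. The degenerate case `p_e = 1` (both
  raters constant) is undefined in the formula; the package returns 1.0 for
  perfect agreement and 0.0 otherwise, with a warning, so downstream gates
  behave sensibly on single-class slices.
- **ROC AUC** ranks messages by the validated count (more expressions =
  stronger evidence of presence), since a binary extractor emits no scores.
  The score source is configurable. AUC is reported as missing when gold is
  single-class.
- **Binned κ** applies categorical κ to counts mapped into ordinal bins,
  default `{0}, {1}, {2}, {3+}` — fine enough to separate none/one/several,
  coarse enough that sparse high counts do not fragment the table. The bin
  spec is configurable and recorded in the report.
- **Spearman ρ** uses midrank ties and is reported as missing for constant
  vectors. MAE is the plain mean absolute count error.
- The **overall κ** is micro-pooled: one binary decision per message × class,
  flattened across the four classes; the macro average of per-class κ is
  reported alongside. The acceptance gate is κ ≥ 0.60 ("moderate"
  agreement); the report exposes the gate per class and pooled.
- Accuracy and precision are computed and included as supplementary values.

Messages where the validated extraction differs from gold (normalized span
multisets) emit one preference pair: chosen = gold rendered through the same
structured schema, rejected = the extractor's output (or its raw malformed
blob). The train/validation split is grouped by message id so no message
leaks across sets, and is reproducible under a fixed seed.

## Taxonomy induction

Within each class, embedded expressions are deduplicated by a greedy
first-kept scan in input order: an expression merges into the *earliest*
kept expression with cosine similarity ≥ 0.95, unioning provenance. The scan
order is documented (input order) because the choice of survivor is
otherwise arbitrary; the result is idempotent. Deduplication runs within
class rather than across the whole pool — a cross-class merge would delete
class-specific provenance — and the threshold is configurable.

Clustering is agglomerative **Ward linkage on Euclidean distance**, computed
via `scipy.cluster.hierarchy.linkage`. Heights follow the
Euclidean-commensurate convention (the square root of twice the
within-cluster variance increase), so thresholds are comparable to pairwise
distances; this scale is recorded here because more than one convention
exists. Merge ties are resolved by scipy's nearest-neighbor chain order; on
continuous embeddings, exact ties have probability zero, and the test suite
verifies merge-by-merge equality with an exhaustive Ward implementation on
random fixtures.

A cut at threshold `t` applies every merge with height strictly below `t`
(so `t = 0` yields singletons), with cluster ids ordered by smallest member
leaf. Four strictly decreasing thresholds produce four nested levels under a
level-0 class root; nesting is structural (all levels cut one tree), and is
property-tested anyway. Threshold selection is programmatic:
`suggest_thresholds` scans the `n − 1` candidate cut points and returns, per
level, the threshold whose cluster count is closest to a target (ties toward
the larger threshold). This replaces manual visual dendrogram review with a
reproducible procedure; the targets are the operator's knob.

Labeling walks the hierarchy breadth-first. A proposed label is embedded
with the same embedder as the expressions and compared to already accepted
labels at the same class and level; cosine ≥ **0.9999** — near-verbatim
duplication — triggers a re-label with the colliding labels passed to the
labeler as an avoid-list. After `max_rounds` unresolved rounds a
deterministic numeric suffix is appended and the node flagged, so the loop
always terminates with unique labels per class and level. Labeler failures
produce flagged `Unlabeled-<node_id>` placeholders. Member lists passed to
the labeler are capped at the 50 most central members (distance to cluster
mean) to bound prompt size.

## Concept queries and summaries

A query term matches an expression by direct quotation (normalized
substring) or by embedding relatedness (cosine ≥ 0.6 by default;
"relatedness" has no canonical definition, so the threshold is exposed).
Lowering the threshold never removes a match. The concept graph contains
each match with its complete ancestor chain; class roots are always present
and components are connected only through shared clusters — no artificial
super-root is added. GraphML and node-link JSON exports round-trip
losslessly. Corpus summaries tally validated extractions by class and
sender/receiver role; percentages are kept at full precision in files and
rounded only for display.

## Synthetic data: what it emulates, and what it does not

The generator emulates the statistical structure the pipeline assumes:
10–60-word messages of clinical filler plus planted expressions; four
classes with medication-skewed rates (defaults 0.25 / 0.70 / 0.20 / 0.15
expected expressions per content-bearing message); 30 % of messages with no
4M content; a planted four-level phrase hierarchy whose level-1 cluster
counts default to 8/9/4/4; transfer events spaced > 6 weeks apart per
resident with ~70 % of messages placed inside a 14-day pre-transfer window;
a sender-role mix of 45/30/10/15 % (nursing staff / APRN / physician /
other); and two annotators with a controlled disagreement rate. The default
scale, 500 messages, is a desk-scale stand-in for a corpus three orders
larger. Every planted fact is recorded (spans, hierarchy paths, intended
links, role tallies), so downstream measurements are checked against ground
truth rather than against themselves.

Annotator disagreements are span drops (optionally typo perturbations). The
pair of drop indicators is resampled on the both-drop event so that at
least one annotator always retains every planted span; truth-derived
adjudications then restore the planted gold exactly, which is the
conservation property the end-to-end tests rely on. Under this model the
per-span difference probability is `2r/(1+r)` for disagreement rate `r`
(0.182 at r = 0.1). Two distinct-but-fuzzily-identical phrases of one class
are never planted in the same message, since reconciliation could not tell
them apart even in principle (exact repeats are allowed and handled).

The synthetic embedder maps each planted phrase to its leaf centroid plus
isotropic Gaussian noise with total standard deviation `noise_sigma`
(default 1.0), keyed by phrase hash and seed so identical texts embed
identically. Centroids are laid out recursively from the origin with
sibling offsets of magnitude `centroid_separation · 1.4^(4−ℓ)` at level ℓ
along mutually orthogonal directions (QR of a seeded Gaussian matrix). The
gentle 1.4 decay is deliberate: Euclidean distances still grow with how
high two expressions split (Ward recovers all four planted levels at
ARI = 1.0 under the default separation of five noise sigmas), while cosine
similarity tracks shared ancestry — same-leaf phrases sit above the 0.95
dedup threshold and anything splitting at level 3 or higher sits well
below it, so semantic deduplication collapses near-duplicates without
destroying the hierarchy. A steeper decay would make Euclidean recovery
trivial but cosine-collapse entire classes.

What the generator does **not** emulate: real clinical language (filler
sentences are a fixed vetted bank), annotator biases that correlate between
experts, extraction errors that depend on message content, or embedding
anisotropy of real sentence-embedding models. Passing tests therefore
demonstrate the *correctness of the machinery* — metrics, reconciliation,
clustering, bookkeeping — not the performance of any particular extractor or
embedder on real messages.

## Numerical and design choices

- Fuzzy scores come from edlib alignments: infix mode for
  span-in-message screening, global mode for phrase-to-phrase similarity,
  both normalized to [0, 1].
- κ uses exact confusion-table arithmetic in float64; the oracle tests pin
  all metrics to 1e-9 against loop-based reference implementations.
- `split_pairs` shuffles message ids with `numpy.random.default_rng(seed)`
  and fails rather than split a message's pairs across train/validation.
- Problem sizes in the acceptance checks — 500 messages for identity runs,
  5000 for planted-error κ recovery, ~1400 expressions for hierarchy
  recovery — were chosen so that sampling error is comfortably inside each
  check's tolerance while the whole suite stays desk-scale.
- The end-to-end CLI defaults derive everything (corpus, annotators,
  embedder) from one seed; manifests record the seed, config hash, and
  per-stage counts, and any stage failure aborts naming the stage.

## Known limitations

- No generative extractor or labeler adapter is bundled; the lexicon
  extractor and trivial labelers stand in. The plug-in contracts (callable
  signatures) are the integration surface.
- The κ gate applies to binary presence; it says nothing about span
  boundaries, which the evaluation deliberately does not score.
- Preference pairs are emitted at message granularity; span-level credit
  assignment is left to the fine-tuning consumer.
- The taxonomy is a labeled hierarchy, not an ontology: no axioms, no
  cross-class relations beyond co-occurrence in query results.
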