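# Methods

`priobench` is an evaluation harness for phenotype-driven gene
prioritization performed by large language models. Given a cohort of
diagnosed rare-disease cases — each an HPO term list and/or a free-text
phenotype narrative plus one diagnosed gene — it renders prompts, collects
raw model responses (from a pluggable backend; a simulated responder is
built in), and scores them on three outcomes with uncertainty, bias and
stability statistics. This note records the model of the task, the
numerical and design choices, and what the synthetic studies do and do not
demonstrate.

## The task and its outcomes

A prompt asks a model for the top k (10 = challenging, 50 = easy) candidate
genes for one patient, in a fixed output dialect (a comma-separated list of
gene symbols, or the literal "not applicable"). Per case m, experiment e
(one model x template x input-type x k cell) and iteration t we score three
binary indicators I_t(m, e):

* **Task completeness** — the response is not a refusal and names at least
  `ceil(k/2)` valid, deduplicated gene symbols (25 of a top-50 list; 5 of a
  top-10 list). Fabricated symbols are excluded and duplicates are counted
  once before the threshold is applied. The top-10 threshold of 5 is the
  `ceil(k/2)` rule applied at k=10; only the k=50 boundary (<25 incomplete,
  25 complete) is externally fixed, and the harness treats the rule as the
  definition.
* **Prediction accuracy (precision@k)** — the diagnosed gene, after
  canonicalization, appears among the first k parsed genes. Two rates are
  reported: *completed accuracy* over completed tasks only, and *overall
  accuracy* over all tasks, counting incomplete tasks as incorrect. When a
  response over-generates, only the first k canonical symbols count: rank
  order in text is the only ranking a chat response provides.
* **Structure compliance** — the response matches the output dialect:
  either a contiguous comma-separated run of at least k symbol-shaped
  tokens (markup and surrounding prose tolerated, prose inside the run
  not), or a refusal. Compliance is structural only and is evaluated
  independently of completeness; `>= k` rather than `= k` tolerates
  over-generation. A response mixing a clean comma run with extra prose
  counts as compliant — the run itself is what a downstream pipeline would
  consume. The pattern set is configurable so stricter dialects can be
  tested.

The per-iteration rate is `p_e(t) = sum_m I_t(m, e) / M`; the summary rate
averages over the T iterations (default 3). Completed accuracy with zero
completed tasks is reported as missing (NaN), never as 0.

## Gene-symbol canonicalization

Model output names genes as approved symbols, previous (retired) symbols,
aliases, or inventions. The lexicon (HGNC complete-set TSV dialect)
resolves all three known forms to the approved symbol, upper-casing before
lookup since model output varies in case. Two deliberate rules:

* **Precedence approved > previous > alias**, and a previous/alias token
  claimed by more than one approved symbol resolves to nothing. The
  conservative choice never credits an ambiguous match; this also covers
  the open case of a token that is simultaneously an approved symbol and
  another gene's alias (the approved reading wins). We apply the ambiguity
  rule to previous symbols as well as aliases, for symmetry.
* **A blocklist dominates resolution.** Date-like error symbols (SEPT1,
  MARCH1, MARC1, MAR1, DEC1 families) are never credited even where an
  alias of that shape exists, mirroring gene-name-error screening practice.
  The shipped list is a starting point, not ground truth, and is
  user-overridable.

Unresolvable symbol-shaped tokens (>= 3 characters, containing a digit or
fully upper-case) are recorded as *fabricated* — the family-extension
hallucination mode (OPA1 -> OPA50) produces exactly such tokens. The shape
requirement keeps prose words out of the fabrication tally.

## Uncertainty

95% confidence intervals use a percentile bootstrap with B = 100 replicates
(configurable). The resampling unit is the **case with its full iteration
triplet**, not the individual record: iterations of one case share the
case's difficulty and are correlated, so resampling records would
understate variance. Percentile rather than BCa intervals: the statistic is
a mean of proportions, B is small, and the percentile interval is what the
rate's consumers expect. Measured coverage on Bernoulli(0.6) data at
M = 200 is 92-95% over 500 replicates — the familiar slight undercoverage
of the percentile method at B = 100.

## Gene-dependent bias

For each gene, the observed count is the number of experiments (case x
config x iteration) whose top-k prediction contains it, counted once per
experiment. The expected count requires a null model that the task itself
does not define; the default pictures an unbiased predictor filling each of
the k slots by drawing from the diagnosed-gene pool proportionally to pool
frequency: `expected_g = N x k x pool_freq_g`. Alternative nulls (uniform
over pool, uniform over lexicon) are a strategy parameter because the
definition is genuinely open; reports can be produced per model or pooled.
The odds ratio is observed/expected, 0 for never-predicted genes, missing
when expected is 0. Observed counts are bounded by one per experiment while
the slot-filling expectation is not; for `k x pool_freq << 1` the two
scales agree, which holds for the pool sizes used here.

Citation bias is summarized as the Pearson correlation between log10
publication count and OR (publication counts are a user-supplied table, not
scraped), plus mean ORs over four equal-width log10 bins; Spearman is
offered since the relationship is monotone rather than linear. Fewer than
three usable genes flags low-n; constant inputs yield an explicit
undefined-correlation signal instead of a coefficient.

Stability: an experiment (config x case) is discordant on a metric iff its
T iteration indicators are not all equal. Cross-session mode pairs two
record sets by experiment and tallies, per metric, whether the number of
successful iterations changed.

## Simulated responder

The responder turns the observed failure modes into explicit probabilities:
refusal (`p_refuse`, emitting "not applicable", its bracketed variant, or
an ethical declination), truncation (`1 - p_complete`, fewer than k/2 valid
symbols), diagnosed-gene hits (`p_hit`, rank geometric(`hit_rank_q`)
truncated at k), citation-weighted filler sampling without replacement
(weights^`gamma`), per-slot fabrication (`p_fabricate`) and duplication
(`p_duplicate`), and format drift (`p_comply` comma list vs numbered prose
list). Three implementation rules keep the parameters recoverable:

* the diagnosed gene is excluded from filler sampling, so its appearance
  probability is exactly `p_hit` rather than `p_hit` plus a chance filler
  hit;
* the hit slot is never fabricated or duplicated;
* truncated responses contain fillers only.

Closed forms then follow: completeness = `(1-p_refuse) x p_complete`
(minus a negligible duplication term), completed accuracy = `p_hit`,
overall accuracy = their product, and compliance = `p_refuse +
(1-p_refuse) x p_complete x p_comply`, because a truncated comma list has
fewer than k tokens and cannot match the compliance run. The test suite and
the acceptance script verify these recoveries at N = 1000-2000.

Default parameters (`p_complete` 0.8, `p_refuse` 0.05, `p_hit` 0.17,
`hit_rank_q` 0.3, `gamma` 1.0, `p_fabricate` 0.02, `p_duplicate` 0.02,
`p_comply` 0.8) sit in the range reported for large hosted chat models on
this task — mid-70s% effective completion, ~17% top-50 accuracy, ~65%
effective compliance — so the default pipeline exercises all code paths at
realistic rates.

The per-response random stream is derived from the backend seed plus a CRC
of (experiment id, case id, iteration), so a resumed or reordered run
reproduces byte-identical responses.

## Synthetic inputs

The generators emulate the study conditions: a 276-case cohort, a diagnosed
pool of 165 distinct genes with Zipf-like occurrence skew (exponent 0.8: a
few recurrent genes, a long singleton tail), and per-case HPO term counts
from a rounded normal(12, 6) clipped to >= 1 — the 9-35 mean-term range
seen across real case collections. Term sets are the diagnosed gene's
annotated phenotypes plus a `noise_rate` fraction (default 0.1) from other
genes; free-text narratives are template-rendered from the same terms so
HPO-vs-narrative comparisons share ground truth. The synthetic lexicon
(default 300 genes, `GENE001`-style symbols) gives a quarter of genes an
alias and a fifth a previous symbol.

What passing these studies shows: the parsing, scoring, uncertainty, bias
and stability machinery measures what it claims to measure, with known
inputs recovered at Monte-Carlo tolerance. What it does not show: anything
about a real model's clinical accuracy, the linguistic variety of real
responses (the simulator has two formats and three refusal phrasings), or
real HPO semantics (labels are synthetic tokens; no ontology structure is
modelled).

## Retrieval augmentation

G2P documents render "The phenotypes associated with gene g include
p1, p2, ...."; P2G documents list the genes of one phenotype. Lists keep
annotation-file order (a literal template fill). The default embedder is a
hashed (md5) bag-of-words — deterministic, offline, and sufficient for
lexical retrieval; service embedders plug in behind the same contract
(string -> fixed-dimension vector plus an `embedder_id` stamp, checked at
query time). Cosine ranking breaks ties lexicographically by document id
for determinism. Retrieved context *prefixes* the base prompt in a
delimited block; zero retrieved documents leave the prompt unchanged with a
warning.

## Orchestration

The grid is the full Cartesian product of factor levels; execution order is
a seeded uniform permutation of (config, case) pairs, with each pair's
iteration triplet contiguous. Response logs are append-only JSONL keyed by
(experiment, case, iteration), giving resumability and post-hoc re-scoring;
scoring is a pure function of log + cohort + lexicon. Backend failures are
retried (default 3 attempts, exponential backoff) and then recorded as
error records that score as incomplete, inaccurate and non-compliant. Live
API adapters are out-of-tree plugins implementing the backend protocol
(`respond(prompt, context)`); nothing in the repository requires network
access. The context argument exists because the built-in simulated backend
needs the case's ground truth, which a prompt string alone cannot carry;
live adapters simply ignore it.

## Problem sizes

The shipped verification studies use: N = 1000 cases x 3 iterations for
parameter recovery (tolerance ±0.04); 500 replicates at M = 200 for
bootstrap coverage; N = 2000 experiments over a 60-gene mildly skewed pool
for the null-OR and citation-bias studies; N = 400 experiments for the
discordance closed form (truth 0.75 at per-call completion 0.5); and the
full 32-config x 276-case x 3-iteration factorial (26,496 responses) for
the end-to-end pipeline rates. These sizes put Monte-Carlo error well
inside each stated tolerance while keeping the whole suite in the tens of
seconds.

## Known limitations

* The compliance regex is one operationalization of the requested output
  dialect; real evaluation scripts differ in how they treat prose around
  the list, and the pattern set is configurable for that reason.
* The expected-count null model is a modelling choice; odds ratios are only
  comparable under a fixed null.
* The hashed bag-of-words embedder captures lexical overlap only; RAG
  accuracy effects that depend on semantic embeddings are out of reach
  offline.
* The blocklist approach cannot distinguish a genuine reference to a
  blocked alias from an error token; it trades a small false-negative rate
  for never crediting spreadsheet-style artifacts.
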