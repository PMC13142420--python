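# Methods

## Data model and execution

Pipeline nodes exchange relational tables restricted to four nullable
logical dtypes (string, integer, float, boolean), backed by pandas
nullable arrays.  Missing is a first-class cell value distinct from the
empty string: joins and pivots necessarily create absent cells, and the
expression language propagates missingness (Kleene three-valued logic
for `and`/`or`).  Tables are materialised eagerly per node — at the
scale this package targets (≲ millions of count rows) this is simpler
and easier to reason about than block streaming, and it makes replayed
iteration trivially consistent.

Every plugin is a pure function of its input tables and parameters, so
execution order beyond the topological constraints is unobservable:
running with one worker or a thread pool over independent branches
yields byte-identical outputs.  Determinism is enforced everywhere it
could leak: group-by and pivot outputs are sorted by key, joins preserve
left-table order, topological ordering breaks ties lexicographically,
INI serialisation emits sections in topological order with sorted keys,
and gzip writers fix the header timestamp to zero.  Writers write to a
temporary file and rename on success, so a failed run leaves no partial
output.

One run-level seed is the single source of randomness; only the
synthetic-data generators consume it.  The INI round-trip identity
(`parse ∘ serialize = id`) holds for parameter values that survive the
INI format itself — no newlines or leading/trailing whitespace — which
all generated configurations respect.

## Scoring statistics

**Pseudocount.** δ = 0.5 is added to every count (wild type included)
before any log or ratio.  Half-integer pseudocounts are the standard
stabiliser for log-ratio statistics; δ is a parameter on every scoring
plugin.

**Log-ratio score.** For conditions {0, T}, the wt-normalised log count
ratio; its variance is the Poisson first-order approximation
Σ 1/(c+δ) over the four counts involved.  With normalisation the wt row
scores exactly 0 and its sampling error is shared by every variant in
that replicate — visible as a small common offset per replicate that
replicate combination and seed averaging attenuate.

**Regression score.** With T+1 ≥ 3 time points, y_{v,t} =
ln(c_{v,t}+δ) − ln(c_{wt,t}+δ) is regressed on x_t = (t−t_0)/(t_T−t_0)
by weighted least squares with known weights V_{v,t}^{-1} =
1/(c_{v,t}+δ) + 1/(c_{wt,t}+δ).  Normalising time to [0, 1] makes the
slope the total log-enrichment over the experiment, directly comparable
with the two-condition ratio score (with exactly two points they
coincide algebraically).  The slope variance comes from the weighted
normal equations, S_w/(S_w S_wxx − S_wx²), with **no residual
rescaling**: the weights are count-derived variances taken as known, not
estimated from two or three residuals.  (statsmodels' WLS rescales by
the residual mean square, which is why the implementation solves the
2×2 system directly; statsmodels is used in the tests as an independent
check of the slope point estimate.)  The intercept is reported as an
auxiliary column.

**Replicate combination.** DerSimonian–Laird one-pass method of moments:
with w_i = 1/SE_i², Q = Σ w_i (β_i − ȳ_w)², σ²_s = max(0, (Q − (n−1)) /
(Σw_i − Σw_i²/Σw_i)), then inverse-variance averaging with w*_i =
1/(SE_i² + σ²_s).  The combined score always lies within the replicate
range; with homogeneous replicates (Q ≤ n−1) it reduces to fixed-effect
pooling.  Rows with a missing score or SE are dropped before
combination; a variant observed in a single replicate keeps that
replicate's values with n = 1 and missing Q/σ²_s rather than being
discarded.

**FACS bin score.** Counts are normalised within each bin (so sequencing
depth per bin cancels), optionally multiplied by per-bin sorted-cell
fractions (default 1 — the common protocol where bins are sorted to
equal cell numbers), renormalised across bins per variant, and averaged
with the bin weights.  Default weights are equally spaced b/B; any
strictly increasing (or other) weight vector can be supplied.  No
analytic SE is attached to a single sort — replicate combination is the
intended source of uncertainty.  Variants under a total-count threshold
are flagged and left unscored rather than silently zeroed
(min_total_count defaults to 0, i.e. no filtering: filtering is an
explicit user decision).

## Variant calling

Calling is substitution-only by positional comparison against an
equal-length reference; indels/complex variants are the province of
alignment-based callers and are deliberately out of scope.  Reads of the
wrong length, or containing N, are *uncallable values* (with a reason
code), never exceptions and never N-tolerant — ambiguity must not
silently create reference-matching positions.  Coordinates are 1-based
per HGVS with an additive offset for tile designs; protein changes use
three-letter codes with `Ter` for stop, and translation uses the
standard genetic code with stop codons rendered `*` without truncation
(positional comparison requires full length).  The inverse operation
(`apply_variant`) reconstructs the observed sequence from a descriptor
and validates reference bases, which gives the call/apply round-trip
identity exercised over thousands of random mutants.

## Read handling

FASTQ input is Phred+33 only (qualities below `!` are rejected);
gzip is detected from magic bytes, never the file extension.  Filters
run in a fixed order — trim, exact length, N-count, mean quality — and
per-filter drop tallies are kept so count conservation (Σ counts =
reads kept) is checkable exactly.  Mean quality is the arithmetic mean
of Phred scores, the simplest deterministic definition.  Filename
tokenisation matches the base name against a `{field}` template with
shortest-non-empty captures; a non-matching file emits missing metadata
columns and a warning rather than aborting, since mixed file sets are
common.  CSV type inference scans whole columns and takes the narrowest
of integer ⊂ float ⊂ string.

## Synthetic data generator

The generators define the study conditions under which the statistics
are validated:

* **Library**: reference of 40 codons (ATG + random non-stop codons),
  200 variants of one substitution each plus the wild type, 3 unique
  12-nt barcodes per variant.  Variant sequences are kept distinct
  (collisions resampled) so DNA-level HGVS strings identify variants
  uniquely; the truth HGVS is built positionally, independently of the
  variant-calling module, so it can serve as that module's oracle.
* **Selection**: frequencies follow f_v(t) ∝ f_v(0)·exp(s_v·x_t) with
  true scores s_v ~ U(−2, 2), wt fixed at 0, times (0, 1, 2), mildly
  dispersed initial frequencies (lognormal, σ = 0.25), and one
  multinomial draw of exactly 50,000 reads per (replicate, time) file —
  fixed totals keep conservation checks sharp, versus independent
  Poisson sampling.  2 replicates.
* **FACS**: a variant's cells land in bin ⌈θ_v·B⌉ (clamped to [1, B])
  with probability 1−2ε and in each adjacent bin with ε; spillover that
  would leave [1, B] stays in the boundary bin ("folds inward").
  Sequencing is multinomial per bin at fixed depth.
* Reads are written clean (no base errors) so FASTQ → counting recovery
  is exact; an optional uniform per-base error rate exists to exercise
  the unmapped-barcode path.

What the generator does **not** emulate: PCR jackpotting and chimeras,
index hopping, sequencing error structure, paired-end overlap, library
composition bias beyond the lognormal start.  Passing recovery tests
therefore demonstrates correctness of the statistical machinery under
the stated sampling model, not robustness to real-data artefacts.

## Problem sizes

The end-to-end suite and the acceptance script run the full demo —
200 variants × 3 time points × 2 replicates × 50,000 reads per file
(300,000 reads per run) — once per seed over five seeds, which completes
in a few seconds per run on a single core; these sizes were chosen to
make the multinomial sampling error small relative to the U(−2, 2)
score range while keeping the demo instant to rerun.

## Known limitations

* Substitution-only variant calling; no indel/delins nomenclature.
* Single-end, pre-merged reads only; no paired-end merging.
* The expression language is a restricted functional subset by design —
  no host-language escape hatches.
* The random-effects variance estimator is the one-pass DL form; no
  iterative (REML/Paule–Mandel) refinement.
* Thread-based parallelism targets multi-branch pipelines; a single
  heavy node does not parallelise internally.
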