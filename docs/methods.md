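# Methods

## Annotation model

Units are paragraph-sized fragments of clinical-trial-announcement-like
text. An entity is identified by `(unit_id, label, span set)` with 0-based,
end-exclusive character offsets; discontinuous entities carry several
disjoint spans, stored sorted so segment order never affects identity. A
link is identified by its two endpoint entities. Matching is strictly
exact: any boundary or label difference is a full mismatch. This mirrors
the campaign design, where worker trust is scored by whole-unit exact
agreement with hidden gold answers, and it keeps evaluation, trust
accounting and deduplication mutually consistent.

Micro P/R/F pools TP/FP/FN over all entities in all units. Zero-denominator
cases (empty predicted and/or empty gold) are defined as 0; empty-vs-empty
agreement is instead credited at the unit level by `unit_exact_match`,
which is what the trust machinery uses.

## Corpus preparation

The tokenizer splits on whitespace and peels leading/trailing punctuation
into separate tokens; internal punctuation (`250/50`, `2.5`) stays
attached. The rule is deliberately simple — its only job is deterministic
counting of basic units. Documents are cut at blank lines and consecutive
paragraphs are merged greedily until each unit reaches the 50-token floor,
with the document's final remainder kept short if necessary; the merge rule
is our design choice, as only the floor itself is fixed by the campaign
design. Gold annotations are re-offset into unit-local coordinates and an
annotation straddling a unit boundary is a hard preparation error, never a
silent truncation.

Gold-unit selection draws ⌊0.20·N⌉ units (round half to even) by seeded
sampling without replacement. Empty-unit balancing keeps all non-empty
units and trims the empty pool to `round(r/(1−r)·n_nonempty)` by seeded
sampling, hitting the 30% target within one unit.

## Quality control

Trust is always the running fraction of exactly-matched gold units. The
threshold is trust ≥ 0.5 ("at least 2 of 4"). A trusted worker falling
below 0.5 is warned and given a two-gold-test probation; recovery to ≥ 0.5
at any point restores trusted, and exhausting probation still below 0.5
blocks the worker permanently. Of the two defensible readings of "did not
improve during the next two gold tests", we implement overall trust
re-crossing 0.5 (rather than passing both probes individually); it is the
simpler machine and the recovery example traces cleanly. A blocked worker's
entire output is excluded, including pre-warning judgments.

## Voting

All methods divide by J, the number of judgments actually collected for the
unit, which normalizes scores to [0, 1] and lets under-subscribed units
aggregate. The weighted forms — trust score (Σ tᵢ)/J and experience weight
log(1+uᵢ)/log(1+m) — satisfy every stated constraint of the campaign
design (per-vote weighting, [0, 1] normalization, weight 1 for the most
prolific worker, logarithmic compression of the heavy-tailed activity
distribution) and reduce exactly to simple voting when all weights are 1;
the precise published formulas live in an appendix we could not consult, so
the forms here are documented as our reconstruction. Ties at the threshold
select — forced by "2 or more of 5" being score 0.40 at threshold 0.40.
Default production thresholds: simple 0.40, trust 0.24, experience 0.24.

Raising the threshold can only remove candidates, so recall is
anti-monotone by construction. Micro *precision* increasing with the
threshold is not a theorem — discarding a low-score true positive can
lower it — but holds in the simulated noisy-crowd regime because low-vote
candidates are overwhelmingly spurious; the test suite checks it on seeded
campaigns, and that is the regime the claim is scoped to.

## Correction round

Deduplication uses payload identity (offsets + labels). Each unique
judgment fans out to k = 5 correction tasks. The corrected *corpus* pools
all corrections per unit regardless of source judgment (J = pooled count);
the per-source comparison exists only in the improvement analysis, where
each unique judgment's F is compared with the simple-vote (0.40) merge of
its own five corrections. "Unchanged" means F-equality to machine
precision. The corrected corpus is built from corrections only, without
re-mixing first-round judgments. Note a boundary case the exact-threshold
rule produces: if 3 of 5 corrections delete a true entity, the survivors
still score 2/5 = 0.40 and the entity is retained; four deletions are
needed to lose it.

## Pooling chi-square

The table rows are the crowd's correct/incorrect unique-entity counts and
the pooled crowd + expert counts; Pearson chi-square with 1 df, no
continuity correction by default (switchable). The pooled row re-contains
the crowd counts by construction — that is the literal "pool, then test
against the original" design and it makes the test conservative; a plain
crowd-vs-expert homogeneity table is available with `pooled=False`.
Degenerate column margins (e.g. nobody incorrect) return χ² = 0, p = 1,
since the row proportions are then identical by construction. The α
default is 0.05 and configurable. Computation delegates to
`scipy.stats.chi2_contingency`; the tests verify it against a from-scratch
expected-counts implementation to 1e-9.

## Synthetic data generator

The generator emulates the campaign's study conditions: documents of
Normal(212, 30) tokens assembled from paragraphs of 50–64 tokens (each
paragraph ≥ the unit floor, so paragraphs map 1:1 to units); each paragraph
empty with probability 0.30; medication mentions drawn name-vs-type with
probability 9968 : 11789 (the gold-standard inventory ratio); attribute
categories sampled with weights equal to the inventory's category counts,
each attribute linked to exactly one medication in its sentence. The
bundled lexicon is synthetic — plausible drug names, classes and attribute
surfaces — not a real drug vocabulary. Spurious entities are placed on
free token slots, never overlapping gold spans, so simulated precision
errors are genuinely wrong.

Worker error behaviour is parameterized per profile: `p_miss` (per-entity
omission), `p_spurious` (Poisson rate of fabrications per unit),
`p_boundary` (±1-token edge shift), `p_confuse` (name↔type swap),
`p_link_error` (attribute rewired to another medication), and `activity`
(task-taking propensity; the Zipf-like default reproduces the observed
concentration where the top 5 workers take > 40% of jobs). All randomness
derives from one seed via named substreams (corpus / assignment /
per-worker), so campaigns are bit-reproducible.

If the unit stream contains gold units, campaign simulation runs the full
QC machinery inline — training gate on gold units, continuous scoring,
re-assignment of slots lost to blocked workers. With no gold units, QC is
inert and every worker is admitted; this is what makes the closed-form
check meaningful: under miss-only noise s with 5 judgments per unit, an
entity survives the simple vote at 0.40 iff at least 2 of 5 independent
keep-trials succeed, so corpus recall concentrates on P(Bin(5, 1−s) ≥ 2)
(≈ 0.913 at s = 0.4) and precision is exactly 1.

What the generator does **not** emulate: real lexical ambiguity (mentions
are unambiguous lexicon tokens), worker learning or fatigue over time,
correlated errors between workers, section structure within trial
announcements, and payment/latency dynamics. Passing tests therefore
validate the pipeline's mechanics and its statistical behaviour under the
stated error models, not performance on real clinical text.

## Problem sizes and numerical choices

Test and acceptance campaigns are sized so sampling noise sits inside the
stated tolerances: the binomial closed-form check uses ≈ 2,300 gold
entities (3 s.e. ≈ 0.018); the name:type density calibration is checked on
a 400-document corpus (≈ 1,800 medication mentions, where the 10% ratio
band is > 2 s.e. wide); reduction identities run on 1,000 units; the
correction experiment mirrors the 200-unit / 1,000-judgment design. Floats
in report tables print to 3 decimals. Score comparisons use exact floating
arithmetic plus the tie-selects rule; monotonicity checks allow 1e-12
slack for summation order.

## Known limitations

* The weighted-vote formulas are a constrained reconstruction, not a
  transcription (see Voting above).
* The warn/block rule implements one of two defensible readings of the
  probation clause.
* Precision monotonicity across thresholds is an empirical property of the
  noisy-crowd regime, not a theorem.
* The generator's paragraphs are independent; it cannot produce entities
  that span unit boundaries, so the splitter's boundary-error path is
  exercised only by hand-built documents in the tests.
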