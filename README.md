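# crowdgold

Crowdsourced annotation aggregation, quality control and evaluation for
building clinical-text gold standards.

Supervised clinical NLP needs expert-annotated corpora, and expert
annotation is slow and expensive. An alternative is to split the text into
paragraph-sized *units*, farm each unit out to several anonymous crowd
workers ("turkers"), gate the workers with hidden expert-annotated *gold
units*, and merge the redundant judgments by voting. `crowdgold` implements
that whole methodology as a reusable library and CLI — for researchers who
want to run, simulate or stress-test such a campaign for medication
named-entity annotation (specific drug names vs. drug classes), the nine
medication attribute categories (strength, dosage, form, frequency,
duration, route, date, status change, modifier), and medication–attribute
linking. A seeded synthetic-campaign generator means everything runs and is
validated without any external data.

## The model

A **judgment** is one worker's complete entity set (or link set) for one
unit; every entity is a labelled character-offset span set, and all
comparison is span-exact. Quality control works on two levels:

* **Admission** — a worker must annotate 4 training examples exactly
  correctly to enter production.
* **Continuous trust** — 20% of units are hidden gold units. A worker's
  trust *t* is the fraction of gold units answered with a unit-level exact
  match (no partial credit). Trust below 50% triggers a warning; failing to
  recover within the next two gold tests blocks the worker and discards
  their entire output.

With *e* votes for a candidate entity out of *J* judgments on its unit,
three voting rules select candidates whose score reaches a threshold θ:

| method | score |
|---|---|
| simple | e / J |
| trust | (Σᵢ tᵢ) / J over voters i |
| experience | (Σᵢ wᵢ) / J, wᵢ = log(1 + uᵢ) / log(1 + m) |

where uᵢ is worker i's total judgment count and m the maximum over workers,
so the most prolific worker votes with weight 1. At J = 5 and θ = 0.40 the
simple rule is exactly "selected iff 2 or more of 5 votes"; scores at the
threshold select. Adjudicated corpora are scored against gold with
micro-averaged exact-match precision/recall/F.

A **correction round** resubmits the unique judgments of a finished job as
pre-annotated tasks (5 corrections per unique judgment), merges the pooled
corrections per unit by the same voting, and labels each source judgment
improved / worse / unchanged against its corrections' simple-vote merge.
Crowd-vs-expert equivalence is tested with a **pooling chi-square**: the 2×2
table contrasts the crowd's correct/incorrect entity counts with the pooled
crowd + expert counts (Pearson, 1 df; p ≥ α ⇒ no evidence of a quality
difference).

## Worked example

Simulate a 50-document campaign (≈200 units, 5 judgments per unit from 12
workers who miss 25% of entities, fabricate ~0.3 spurious entities per
unit, and occasionally shift boundaries or confuse labels), then sweep the
simple-vote threshold:

```python
from crowdgold.simulate import SimConfig, generate_units, make_profiles, simulate_crowd
from crowdgold.voting import aggregate_corpus, threshold_sweep

_, units = generate_units(SimConfig(n_docs=50, seed=7))
profiles = make_profiles(12, p_miss=0.25, p_spurious=0.3, p_boundary=0.1,
                         p_confuse=0.05, heavy_tailed_activity=False)
judgments, states = simulate_crowd(units, profiles, judgments_per_unit=5, seed=7)
gold = {u.unit_id: u.gold_entities for u in units}

print(threshold_sweep(judgments, "simple", [0.2, 0.4, 0.6, 0.8], gold)
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
_, best = aggregate_corpus(judgments, "simple", 0.40, gold)
print(f"P={best.precision:.3f} R={best.recall:.3f} F={best.f_measure:.3f}")
```

prints

```
 threshold  precision  recall  f_measure
     0.200      0.487   0.992      0.653
     0.400      0.977   0.950      0.963
     0.600      0.995   0.771      0.869
     0.800      1.000   0.454      0.624
P=0.977 R=0.950 F=0.963
```

Low thresholds admit nearly every spurious entity (high recall, poor
precision); high thresholds keep only unanimous entities (the reverse). The
interior threshold 0.40 — two of five votes — maximizes F here, which is
why it is the production default. The same pipeline is available from the
shell: `crowdgold simulate`, `crowdgold qc`, `crowdgold aggregate
[--sweep]`, `crowdgold correct`, `crowdgold evaluate`, `crowdgold stats`.

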