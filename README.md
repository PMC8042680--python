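# gcross

Generalizability (G) and decision (D) studies for **fully crossed
person × task × rater rating designs**, with a matching synthetic-data
simulator for parameter-recovery work.

The motivating setting is simulation-based assessment of practicing
physicians: each examinee (*person*) manages standardised clinical crisis
scenarios (*tasks*) and is scored on a 1–9 scale by trained observers
(*raters*), separately for behavioural (non-technical, BARS-based) and
technical performance. The question such studies ask is psychometric: **how
much of the score variance reflects true differences between examinees, and
how many scenarios and raters would a defensible assessment need?**

## The model

A score is decomposed under the two-facet crossed random-effects model

```
y_ptr = μ + a_p + b_t + c_r + (ab)_pt + (ac)_pr + (bc)_tr + e_ptr
```

with all effects independent and zero-mean. The **G study** estimates the
seven variance components σ²_p, σ²_t, σ²_r, σ²_pt, σ²_pr, σ²_tr, σ²_e from
a balanced crossed design by the ANOVA / expected-mean-squares method
(negative solutions truncated to zero for reporting). The **D study**
projects them onto a hypothetical design with n′_t tasks and n′_r raters:

```
σ²_δ   = σ²_pt/n′_t + σ²_pr/n′_r + σ²_e/(n′_t·n′_r)     relative error
Eρ²    = σ²_p / (σ²_p + σ²_δ)                            generalizability (G)
Φ      = σ²_p / (σ²_p + σ²_Δ)                            dependability
```

where σ²_Δ additionally charges the facet main effects. The package also
searches for the smallest number of tasks reaching a target reliability,
reporting *unattainable* when the person × rater error puts the asymptote
below the target.

Because raw ratings from such studies are rarely deposited, the package
ships a seeded simulator for the same additive model (presets carry the
published component tables of two scenario pairings, LAST/MH and
LAST/Hemorrhage), so every stage — ingest, descriptives, G study, D study —
is testable end to end, and estimator bias/RMSE can be quantified at any
design size.

## Worked example

```python
from gcross import g_table, min_tasks_for_target, get_preset

vc = get_preset("last_mh_behavioural")   # published G-study column
for d in g_table(vc):                    # designs (2,2), (10,1), (20,2)
    print(d.n_t_prime, d.n_r_prime, round(d.g_coefficient, 2))
print(min_tasks_for_target(vc, n_r_prime=2, target=0.70))
```

prints

```
2 2 0.43
10 1 0.61
20 2 0.77
10
```

Read: with the observed 2-scenario, 2-rater design only 43 % of observed
score variance reflects stable examinee differences; one rater on ten
scenarios (0.61) beats two raters on two, because the dominant error source
is person × task, which only more scenarios average away; ten scenarios with
two raters are the minimum to reach the conventional 0.70 threshold. See
`examples/` for runnable scripts covering CSV ingest, descriptives,
parameter recovery and the full pipeline, and `docs/methods.md` for the
statistical details.

A thin CLI mirrors the library:

```
gcross simulate --preset last_mh_behavioural --discretize --out ratings.csv
gcross gstudy ratings.csv --measure behavioural
gcross dstudy --preset last_mh_behavioural --target 0.70 --raters 2
gcross run --config cfg.yaml
```

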