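# nodalscore

Staging a papillary thyroid carcinoma (PTC) as node-negative is only as
trustworthy as the number of lymph nodes the pathologist examined.  If a
patient with occult nodal metastasis has just one or two nodes sampled,
there is a substantial chance every sampled node is negative and the
patient is under-staged.  `nodalscore` implements the **nodal staging
score (NSS)** analysis that quantifies this risk and inverts it into a
concrete surgical recommendation: how many nodes must be examined before a
negative result actually means node-negative.

It is written for biostatisticians and surgical-oncology researchers who
want the full pipeline — model fitting, prevalence correction, score
tables, survival comparison — as a tested, scriptable library rather than
a one-off analysis.

## The model

The number of positive nodes *k* among *n* examined in a truly
node-positive patient is beta-binomial: binomial with per-patient
metastasis probability *p* drawn from Beta(α, β), which captures the
strong between-patient heterogeneity of nodal involvement.  Three
quantities follow:

* **False-negative staging probability.**
  p₀(n) = B(α, β + n)/B(α, β) = ∏ᵢ₌₀ⁿ⁻¹ (β + i)/(α + β + i)
  is the chance a truly node-positive patient shows *no* positive node
  among *n* examined.  With the published shapes (α = 1.51, β = 1.15) a single examined node
  misses metastasis 43% of the time.

* **Corrected prevalence.**  Observed metastasis prevalence understates
  the truth because of those false negatives.  The moment estimator
  π̂ = (# observed positive) / Σᵢ (1 − p₀(nᵢ)) revises it upward per
  clinicopathological stratum (gender, age group, extrathyroidal
  invasion, multifocality, tumor size, T stage).

* **The score.**  NSS(n) = (1 − π) / ((1 − π) + π·p₀(n)) is the posterior
  probability that a patient with *n* examined, all-negative nodes is
  truly node-negative.  Inverting NSS ≥ t gives the smallest dissection
  size reaching a target negative predictive value.

The shapes are fitted by maximum likelihood on node-positive patients
only, so the likelihood is zero-truncated (conditioned on k ≥ 1).  A
synthetic SEER-like cohort generator (with ground-truth occult labels) and
a directly implemented Kaplan–Meier / log-rank comparison of overall
survival across NSS quartiles complete the pipeline.

## Worked example

Reproduce the published gender tables from the printed inputs (no cohort
needed — the shapes and adjusted incidences are injected):

```bash
cat > inject.yaml <<'YAML'
alpha: 1.51
beta: 1.15
prevalences:
  gender:
    male: 0.776
    female: 0.538
YAML
nodalscore nss-table --inject-params inject.yaml --out-dir out/
```

prints

```
== NSS (%) by examined-node count: gender ==
           1     5     10    15    20    25
stratum
male     40.0  74.8  87.6  92.5  94.8  96.2
female   66.5  89.8  95.5  97.3  98.2  98.7

== nodes needed by NSS threshold: gender ==
         80%  85%  90%  95%
stratum
male       7    9   12   21
female     3    4    6   10
```

Reading: a man whose single examined node is negative still has only a
40.0% chance of being truly node-negative (his prior metastasis risk is
77.6%); after 20 negative nodes that rises to 94.8%.  To claim a 90%
negative predictive value, 12 nodes must be examined in men but only 6 in
women.

The full pipeline on a synthetic cohort — generate, fit the zero-truncated
beta-binomial on the node-positive patients, correct prevalences, build
all six factor tables, compare survival across NSS quartiles:

```bash
nodalscore run-all --synthetic-n 12431 --seed 1 --out-dir out/
```

```
alpha=1.4175 beta=1.1116 n_patients=12431
log-rank (t_stage): chi2=17.523 p=0.000551
outputs in out/
```

The fitted shapes recover the generating values (1.51, 1.15) to sampling
error, and overall survival differs significantly across score quartiles
because low-NSS (pathologically node-negative but probably under-staged)
patients carry the hazard of their occult metastases.

In Python the same steps are `generate_cohort`, `fit_truncated`,
`corrected_prevalence`, `nss_value`, `nodes_needed`, `build_nss_table`,
`assign_nss_groups`, `logrank_test` — see the docstrings in
`src/nodalscore/`.

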