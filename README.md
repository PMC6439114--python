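# mitolineage

Extinction analysis for matrilineal mtDNA lineages.

Mitochondrial DNA is inherited only from mothers, so a new mtDNA line —
for example, donor mitochondria introduced into a single female
recipient by mitochondrial replacement therapy (MRT) — persists only as
long as an unbroken chain of daughters does.  `mitolineage` models that
chain as a Galton–Watson branching process and answers the heritability
question quantitatively: *how long does a newly introduced mtDNA line
last?*  It is aimed at reproductive-medicine researchers, population
geneticists, and anyone assessing the "heritable forever" concern about
MRT.

## The model

Let `{p_k}` be the probability a woman has k daughters over her
completed reproductive life, with mean m and PGF
`f(s) = Σ p_k s^k`.  Starting from one founder female, the probability
`q_n` that the lineage is extinct at or before generation n satisfies

```
q_0 = 0,   q_{n+1} = f(q_n)  ↑  q* = smallest fixed point of f on [0,1]
```

If m ≤ 1 (and the law is not "exactly one daughter, always") then
`q* = 1`: extinction is certain, and the extinction generation T
(smallest n ≥ 1 with no females alive) is finite with
`E[T] = Σ (1 − q_n)`.  If m > 1 the line can, but need not, survive
forever (`q* < 1`).  Current US completed fertility gives roughly
m ≈ 0.95 daughters per woman — subcritical — so a transplanted mtDNA
line typically dies out within a handful of generations.

The package provides:

* **offspring laws** — empirical PMFs, parametric families (Poisson,
  negative binomial, geometric), binomial thinning of children counts
  to daughter counts (sex ratio ≈ 100 girls : 105 boys), and a seeded
  synthetic census-like completed-fertility law with a target daughter
  mean;
* **exact analytics** — criticality classification, extinction
  probability via PGF fixed-point iteration, the extinction curve
  `q_n`, mean time to extinction (with geometric tail correction, and
  conditioning on extinction for supercritical laws), quantiles;
* **Monte-Carlo simulation** — seeded, reproducible lineage cohorts
  with censoring at a generation cap, histogram tables, and a built-in
  cross-check of the empirical CDF against the analytic curve;
* **carrier-burden arithmetic** — the companion population estimate of
  pathogenic-mtDNA carriers (total → healthy → carriers → female →
  reproductive age).

## Worked example

Carrier burden with the 2012 US inputs (314 M people, 10.3 % in
fair-to-poor health, 1-in-200 carrier rate):

```
$ mitolineage burden
...
"reported": {
  "healthy_population": 282000000.0,
  "carrier_count": 1400000.0,
  "female_carriers": 700000.0,
  "reproductive_age_female_carriers": 200000.0
}
```

i.e. 282 million healthy people, 1.4 million unknowing carriers of a
pathogenic mtDNA mutation, 700,000 of them female, roughly 200,000 of
reproductive age.

Full extinction pipeline on the synthetic census-like daughter law
(mean 0.95 daughters per woman), 100,000 replicates:

```python
from mitolineage import RunConfig, run_pipeline

report = run_pipeline(RunConfig(synth=True, n_reps=100_000, seed=1))
report["analytic"]["criticality"]                  # 'subcritical'
report["analytic"]["q_star"]                       # 1.0  (extinction certain)
report["analytic"]["mean_extinction_generations"]  # 4.235
report["analytic"]["quantiles"]                    # {'p50': 2, 'p90': 9, 'p95': 16}
report["simulated"]["mean"]                        # 4.22918
report["simulated"]["p90"]                         # 9
report["max_cdf_discrepancy"]                      # 0.00189
```

Read: a new mtDNA line under this fertility law goes extinct with
certainty; on average it lasts about 4.2 generations, half of all lines
are gone within 2, and 90 % within 9.  The exact PGF iteration and the
simulation agree to a few parts in a thousand across the entire
distribution.  The same run is available from the shell:

```
mitolineage run --synth --reps 100000 --seed 1 --out report.json --hist hist.tsv
```

`hist.tsv` is the per-generation extinction histogram
(`generation  count  frequency`).  Real fertility tables can be used
instead of the synthetic law: `mitolineage run --pmf table.tsv`, where
the TSV has header `daughters<TAB>probability`, or
`children<TAB>probability` together with `--p-daughter` to thin.

## Layout

```
src/mitolineage/
  offspring.py    offspring-law construction, thinning, synthetic census law
  branching.py    PGF analytics: q*, extinction curve, E[T], quantiles
  simulation.py   seeded Monte-Carlo lineage cohorts
  burden.py       carrier-population arithmetic
  io.py           PMF TSV and JSON report I/O
  pipeline.py     RunConfig and the end-to-end pipeline
  cli.py          `mitolineage` command (synth/analyze/simulate/burden/run)
docs/methods.md   model conventions, numerical choices, limitations
```
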