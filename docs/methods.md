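# Methods

## Model

A donor mtDNA haplotype introduced into a single female recipient (as by
mitochondrial replacement therapy) is transmitted only through daughters.
Its persistence is therefore a single-type Galton-Watson branching
process: one founder female at generation 0, and every female in
generation n independently contributes a number of daughters drawn from
a fixed offspring law `{p_k}` with mean m (daughters per woman) and PGF

    f(s) = sum_k p_k s^k .

Writing `q_n` for the probability that the lineage is extinct at or
before generation n,

    q_0 = 0 ,   q_{n+1} = f(q_n) ,

and `q_n` increases monotonically to `q*`, the smallest fixed point of
f on [0, 1].  `q* = 1` exactly when m <= 1 (excluding the degenerate law
P(X=1) = 1, which persists forever with probability 1); for m > 1 the
lineage survives forever with probability `1 - q* > 0`.

**Generation convention.** The founder counts as one individual at
generation 0; the extinction generation T is the smallest n >= 1 with
zero females alive.  A founder with no daughters has T = 1, and

    E[T] = sum_{n >= 0} (1 - q_n) .

Published accounts of this kind of calculation rarely state whether the
founder's own generation is counted; this convention is used
consistently by the analytic and simulation paths, and quantiles are
reported as integers so either reading of "under N generations" can be
checked explicitly.

Modelling assumptions inherited from the classical process: daughters
counts are i.i.d. across women and generations; no age structure,
secular fertility trends, population regulation, or correlation between
relatives.  These are the standard simplifications of the surname /
matriline extinction literature.

## Analytics

* **Extinction probability.**  Fixed-point iteration `s <- f(s)` from
  `s = 0`, which provably converges monotonically to the *smallest*
  root (a generic root-finder could land on the fixed point at 1).
  Tolerance 1e-12, iteration cap 1e6.  Subcritical/critical laws return
  exactly 1.0 and the degenerate unit law exactly 0.0 without iterating.
* **Mean time to extinction.**  `sum (1 - q_n)` truncated when the term
  falls below 1e-14, or earlier when the empirical decay ratio
  `(1 - q_{n+1})/(1 - q_n)` (which tends to m) has been stable to 1e-9
  for 50 consecutive steps, at which point a geometric tail `r/(1-r)`
  correction is added.  Plain summation becomes uselessly slow as
  m -> 1; the ratio rule keeps near-critical laws tractable.  Critical
  and degenerate-unit laws report divergence (`inf`).
* **Supercritical laws** report the mean conditioned on extinction,
  computed on the subcritical dual process with PGF `f(q* s)/q*`
  (offspring probabilities reweighted by `q*^{k-1}`); the dual's
  extinction curve is `q_n / q*` of the original, which is tested.
* **Quantiles** are the smallest n with `q_n >= p`, with 1e-12 slack so
  closed-form ties (the critical geometric `q_4 = 0.8` computed in
  floating point as 0.7999999999999999) resolve to the mathematically
  correct generation.

## Synthetic census-like offspring law

The completed-fertility extract behind the published 0.95
daughters-per-woman figure is not publicly printed, so the generator
emulates its qualitative features rather than its exact cell values:

* children counts on {0..12} (completed family sizes above 12 are
  negligible in modern US data);
* over-dispersion relative to Poisson with excess childlessness —
  a zero-inflated negative binomial (size `shape = 3`, extra zero mass
  `zero_inflation = 0.10`);
* a small seeded lognormal jitter (sd 0.05) on the cell weights, so
  different seeds give distinct but similar irregular tables, as a real
  census extract would be irregular;
* exponential tilting (weights scaled by `t^k`, t solved by Brent's
  method) so the binomially thinned daughter mean equals the target
  0.95 to 1e-6;
* binomial thinning with `p_daughter = 0.4878` (≈100 girls per 105
  boys), the standard human secondary sex ratio, since public fertility
  tables count children, not daughters.  Tables that already count
  daughters can be loaded directly; both paths are supported.

What this does **not** emulate: the true 2016 cell values, age
structure, cohort trends, or sampling error of the census extract.
Consequently the pipeline's headline outputs on the stand-in — analytic
mean extinction ≈ 4.2 generations, 90th percentile 9–10 (seed
dependent) — are a consistency band around the published analysis
(mean 4.7, 90% under 12), not a reproduction of it; passing tests show
the machinery is correct, not that the stand-in equals the real
distribution.  Anyone holding the real extract can feed it in as a TSV
and obtain the exact published pathway.

## Simulation

Each replicate starts at population 1; a generation replaces every
female by an independent draw from the offspring law.  The cohort
driver advances all replicates in lockstep: while the whole-cohort
population is below 2e6 it draws one flat array of per-individual
daughter counts and reduces it per replicate; above that (growing
supercritical cohorts) it switches to a vectorized per-replicate
multinomial drawn as a chain of conditional binomials.  Both are exact
laws of the sum of i.i.d. draws and are tested against a brute-force
convolution oracle.  The single-replicate operation uses per-individual
draws up to population 1e4 and a multinomial above.

Defaults: 1e5 replicates, generation cap 1e4, per-replicate population
overflow bound 1e9 (reachable only for supercritical laws, which raise
rather than silently saturate).  Replicates alive at the cap are
censored: counted, reported, excluded from extinction-time summaries,
and the mean is flagged unreliable when the censored fraction exceeds
0.1%.  All randomness flows through one `numpy` generator seeded from a
single integer; identical configuration gives bit-identical results.

Empirical quantiles use the same convention as the analytic ones:
smallest recorded generation g with `fraction(T <= g) >= p`, the
fraction taken over all replicates.

## Numerical choices and tolerances

* PMFs must sum to 1 within 1e-9 after construction; parametric laws
  are truncated at tail mass < 1e-9 (configurable down to 1e-6) and
  renormalized.
* TSV tables off by <= 1e-6 from total mass 1 load silently; <= 1e-3
  renormalize with a warning; beyond that they are rejected.
* Statistical agreement tests use pointwise 3-standard-error bands with
  an additive 3/N guard (N = replicates): where `q_n(1-q_n) -> 0` the
  normal-approximation SE vanishes while single surviving stragglers
  still move the empirical CDF by 1/N, so a pure 3·SE band would be
  wrong in the far tail.
* Problem sizes in the test-suite and acceptance script — 1e5
  replicates, horizon/cap 1e4 — were chosen so Monte-Carlo bands are a
  few times 1e-3 wide while a full run completes in seconds.

## Carrier-burden estimator

A deterministic proportion chain: total population × (1 − fair-to-poor
fraction) → healthy; × carrier rate (default 1/200) → carriers;
× female fraction (default 1/2) → female carriers; × reproductive-age
fraction (default 1/3).  Exact values are always retained; reporting
rounds healthy to the nearest million, carriers to 2 significant
figures, female and reproductive-age carriers to 1 — the conventional
headline precision for such estimates (282 million healthy, 1.4 million
carriers, 700,000 female from the 2012 US defaults).  The female
fraction is a package default, not an input with a published source,
and is overridable.

## Known limitations

* Single-type, time-homogeneous process: no age structure, fertility
  trends, or two-sex dynamics.
* The stand-in offspring law is synthetic; see above for exactly what
  that does and does not validate.
* No confidence intervals on census-estimated PMFs; the burden
  estimator propagates no uncertainty.
* Near-critical laws (|m − 1| ≲ 1e-6) converge slowly; the extinction
  curve reports `converged=False` rather than iterating past its
  horizon, and E[T] may raise a convergence error if the ratio cannot
  stabilize within the horizon.
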