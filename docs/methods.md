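# Methods

## Model

The package implements a chronic cumulative dietary risk assessment
under **dose addition**: all chemicals in an assessment group are assumed
to act on the same endpoint, differing only in potency. No interaction
(synergy/antagonism) is modelled, and no response addition — dose
addition is the package's fixed mixture model.

For an assessment group with per-chemical daily exposures Eᵢ
(µg/kg bw/d) and health-based guidance values HBGVᵢ:

* cumulative exposure  C = Σᵢ RPFᵢ·Eᵢ, with RPFᵢ = HBGV_index/HBGVᵢ,
  expressed in index-chemical (lead) equivalents;
* hazard index  HI = Σᵢ Eᵢ/HBGVᵢ.

These are algebraically linked: HI = C / HBGV_index whenever the RPFs
derive from the same HBGV set. The implementation keeps both routes and
the identity is property-tested to 1e-12, because reporting uses the
cumulative-exposure route (group means divide by the index HBGV) while
the definition is the per-chemical sum.

## HBGV derivation

A `ToxRecord` carries a point of departure (NOAEL, LOAEL, BMDL01,
BMDL05, TWI, or a pre-derived tolerable dose DTD) with a factor chain.
Derivation order: route conversion → TWI/7 → division by assessment
factors.

* **Route conversion.** An intraperitoneal dose is treated as fully
  absorbed; the equivalent oral dose is pod / oral bioavailability
  (nickel: 5%, so 500 → 10 000 µg/kg bw/d).
* **Assessment factors** are ≥ 1 and only shrink the dose (100 for
  interspecies toxicokinetics/toxicodynamics, 3 for short study
  duration, 3 for LOAEL→NOAEL, 10 as a margin of exposure on a BMDL01);
  every step is recorded as provenance.
* **TWI** points of departure are weekly and divided by 7. The methyl
  mercury record is stored as the TWI of 1.3 µg/kg bw/week, so the
  working TDI is 0.185714… µg/kg bw/d; this unrounded value is what
  makes the displayed RPF 0.27 (0.05/0.185714) consistent, while the
  DTD track stores 0.19 directly (RPF 0.26). The two reference tracks
  are deliberately kept distinct.
* **Multiple candidate PODs** for one chemical × endpoint (nickel's
  NOAEL and LOAEL tracks) are derived separately and arithmetically
  averaged; the average is taken on the unrounded chain
  ((33.33 + 22.22)/2 = 27.78, displayed 27.8). Averaging is generic, not
  nickel-specific.
* **NOAEL ≡ BMDL10** is recorded as an assumption only; no numerical
  adjustment is applied.
* **DTD** records pass through unchanged, unifying both tracks under one
  derivation path.

All arithmetic is full precision; RPFs are rounded (2 significant
figures) only at report time.

## Speciation

Monitoring data report total As and total Hg. Fixed fractions by food
category convert to toxic species: iAs = 2% of total As in fish, 3.5%
in crustaceans/mollusks, 100% in water, 70% in other foods, with rice a
pass-through (speciated measurements exist); MeHg = 100% of total Hg in
fish, 80% in crustaceans/mollusks, 0 elsewhere. The inorganic-mercury
rule (complement: 20% in crustaceans/mollusks, 100% in non-seafood
foods, 0 in fish) is a package assumption, flagged as such and
overridable via the rule file. Unmatched categories fall to "other".

## Exposure

Lower-bound (LB) convention: results below the LOQ count as zero, and a
food × chemical pair with no detects at all is excluded (logged). This
yields the minimum exposure consistent with the data; it is
deliberately conservative downward and under-estimates exposure to
ubiquitous contaminants. Per-food concentrations are unweighted
arithmetic means of the LB-substituted samples — a deterministic
pathway; the `ExposureMatrix` also ingests externally modelled
individual exposures directly (`from_entries`), so output of
probabilistic exposure models can be substituted (then without
food-level breakdown). Units are fixed: g/day × µg/kg ÷ 1000 ÷ kg body
weight → µg/kg bw/d, applied once.

Individual averages over the (two) survey days feed the hazard
summaries and exceedance fractions; exceedance is strict (HI > 1).
Group mean HI is the mean of individual HIs, which by linearity equals
the HI of the mean exposure. Chemical shares are
100·RPFᵢ·Ēᵢ / Σⱼ RPFⱼ·Ēⱼ; chemicals not in an endpoint's group are
reported as not applicable, not 0%. Food-group attribution aggregates
the RPF-weighted mean per-food exposures to reporting groups (cereal
products, non-alcoholic drinks, vegetables, fruit and berries, dairy,
fish, meat, others); refining a grouping never changes the total
(order-of-summation invariance, tested).

## Statistical contrasts

Welch two-sided t-tests (unequal variances, Welch–Satterthwaite df) via
`scipy.stats.ttest_ind(equal_var=False)`, validated in the tests against
a hand-rolled 10⁵-draw permutation oracle. The default observation unit
is the study day, mirroring the survey convention "each study day is one
data point"; this violates independence (two days per person) and
overstates the effective n, so the report flags it and
`observation_unit="individual"` switches to individual means. Weight
quartiles use linear-interpolation percentiles, boundary values assigned
to the lower quartile (Q1 is "up to" its boundary); a fully degenerate
weight distribution collapses to Q1 with a warning. No multiplicity
correction is applied.

Disease-burden scaling is the linear point estimate
DALY_mixture = DALY_index / share_index; any published range wider than
the share interval reflects unquantified uncertainty the package does
not model.

## Synthetic survey generator

Defaults encode the emulated study conditions: n = 1708 adults (the
survey's 1295 aged 25–64 plus 413 aged 65–74), ages uniform on 25–74,
55% women, body weight truncated-normal (women 68.9 ± 12 kg, men
84.5 ± 13.5 kg, truncated at 35 kg — truncated normal rather than
lognormal for simplicity; at these parameters the truncation shifts the
mean by < 0.01 kg), two recall days. Fourteen foods span the reporting
groups with Bernoulli(consumer probability) × lognormal amounts;
occurrence is lognormal with per-pair non-detect probability and LOQ
(30 samples per pair by default). Concentration scales follow European
monitoring orders of magnitude and were fixed, before any tuning
against outputs, so that the neuro/kidney hazard-index landscape sits
around 2–4 and fertility around 0.4–0.6 — i.e. individual HIs straddle
1 and the exceedance logic is exercised from both sides. No
between-food correlation, age trends, or heavy occurrence tails are
modelled, so passing recovery tests demonstrate correctness of the
pipeline arithmetic, not realism of any particular national estimate.

`ground_truth_cumulative` gives the closed-form expectation
Σ_f p_consumer·E[amount]/1000 · Σ_specs (1−p_nd)·E[conc] ·
Σᵢ RPFᵢ·fracᵢ · E[1/bw], with lognormal moments in closed form and
E[1/bw] by quadrature over the truncated normal mixed over genders.
Effect injections multiply a demographic group's consumption; the
population expectation adds the injected excess weighted by group
probability (injections assumed disjoint). Recovery tests run n = 2000
individuals and enlarged occurrence samples, comparing the pipeline
mean to the expectation within 3 combined standard errors (day-level
sampling SE plus the analytic occurrence-sampling SE), across three
seeds. Determinism: one integer seed spawns separate child streams for
population, consumption and occurrence; identical config + seed gives
byte-identical CSV output (hash-tested).

## Numerical and design choices

* Full-precision chains everywhere; display rounding only in reports
  (RPF 2 s.f.; HI 2 decimals; shares whole percent, one decimal
  below 1%).
* Self-comparison of a group is allowed as a degenerate identity check
  (t = 0, p = 1); partially overlapping groups are rejected.
* Report CSVs are written with a fixed float format and sorted orders so
  repeated runs are byte-identical.
* Problem sizes in the shipped tests (250–2000 individuals, 10⁵
  permutation draws) were chosen to give stable statistical checks at
  interactive runtimes.

## Limitations

* The deterministic mean-concentration pathway replaces probabilistic
  occurrence/exposure modelling (no Monte Carlo, no bootstrap
  uncertainty); externally modelled exposures can be ingested instead.
* LB substitution biases exposure downward by construction.
* RPFs inherit the heterogeneity of their sources (different species,
  endpoints, study designs); cross-species factor chains are crude.
* Aluminum from food-additive use, usual-intake modelling, clustered
  standard errors and risk–benefit trade-offs are out of scope.
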