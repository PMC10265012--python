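# Methods

This note documents the statistical models implemented in `paradiv`, the
choices made where several reasonable designs exist, and what the
synthetic-data generator does and does not emulate.

## Data model and harmonization

The unit of observation is a dissected host individual; a parasite
observation is a (host individual, morphogroup) pair with a positive
count. Morphogroups — operationally distinct morphotypes treated as
species-level units — carry a higher taxon, a life-cycle category (DLC:
direct, single-host; ILC: indirect, multi-host), a life stage, and an
optional redundancy group marking stages that may belong to one
biological species. A DLC morphogroup is by definition an adult (there is
no intermediate host to harbour a larval stage); the validator enforces
this.

Inclusion filters run in a fixed order — host groups, parasite taxa, then
the minimum-sample-size rule — and each appends a line to the dataset's
provenance log. The sample-size floor (default 10 dissected individuals
per host species, infected or not) is the conventional threshold below
which within-species incidence-based estimates are too unstable to
compare. The order is recorded although it is not consequential: taxon
filtering removes observations, never host records, so it cannot change
which species clear the floor.

Redundant-stage collapsing is deliberately asymmetric across analyses.
Counting species *across* hosts (accumulation curves, life-cycle tables)
would double-count a species represented by both an adult and a larval
morphogroup, so within each host partition all but one member of a
redundancy group are dropped — the adult if present, else the
lexicographically first morphogroup id, a deterministic stand-in for
expert judgement. Life-*stage* composition keeps every intermediate
morphotype, because there the stages themselves are the signal: which
trophic pathways parasites use, not how many species there are. Fish and
invertebrate hosts are always analysed as separate partitions so that an
ILC species passing from invertebrate prey to fish predator cannot appear
twice in one analysis.

## Richness estimation

**Chao2.** From the incidence frequencies within a host species (number
of individuals in which each parasite was detected), with S_obs observed
parasites, Q₁ singletons and Q₂ doubletons:

* bias-corrected (default): `Ŝ = S_obs + Q₁(Q₁−1) / (2(Q₂+1))`
* classic: `Ŝ = S_obs + Q₁² / (2Q₂)`, falling back to the bias-corrected
  term when Q₂ = 0 (the standard convention).

The default follows the behaviour of the widely used R implementations of
the estimator. The small-sample factor (m−1)/m is available
(`small_sample_correction=True`) but off by default for the same reason.
An uninfected dissected individual is an all-zero incidence row: it
carries information (it counts toward m) and is never dropped. An
uninfected host species has estimate 0, not a missing value.

**Sample-based rarefaction.** With H host species and parasite i
occupying hᵢ of them, the expected richness in a random k-subset is
`E[S(k)] = Σᵢ [1 − C(H−hᵢ,k)/C(H,k)]` — exact, not asymptotic. Binomial
ratios are computed as differences of log-gamma functions, stable to
double precision for H well beyond 10³. A brute-force enumeration oracle
(`accumulation_oracle`, guarded at 10⁵ subsets) exists solely to verify
the closed form; the test suite also cross-checks against vegan's exact
rarefaction through Rscript. The curve's pointwise variance is reported
as a seeded Monte-Carlo quantity (over resampled k-subsets) and flagged
as such in output; the analytic mean is always the closed form.

## The ordered ecosystem test

The response is the per-host-species Chao2 estimate, one value per
(ecosystem, host species). Because the estimates are heavy-tailed and the
design unbalanced, everything is rank-based: the model is

```
midrank(chao2) ~ 1 + host_group + midrank(mean_length) + score(ecosystem)
```

with reference-cell coding for host group (alphabetically first level as
reference; the ordered-score coefficient is invariant to this choice,
asserted in tests) and equally spaced integer scores encoding the ordered
alternative (hypothesized poorest ecosystem = 1, next = 2, ...). Mean
host length enters as a midrank covariate because larger-bodied host
species accumulate more parasite species. Host species lacking a length
are excluded with a warning rather than imputed; imputation would inject
an untestable assumption into a rank model.

The test statistic t_obs is the least-squares coefficient on the ordered
score — the simplest statistic that is large exactly when richness ranks
increase along the hypothesized ordering. Significance comes from
randomization: ecosystem labels are permuted among host species *within
each host group*, preserving every group's ecosystem sample sizes, the
model is refitted, and the one-sided p-value is the add-one estimator
`(1 + #{t* ≥ t_obs}) / (B + 1)` with ties counted as exceedances
(conservative; p can never be exactly 0). Default B = 9999; the CLI
requires an explicit seed. A full cross-group shuffle is available behind
a flag for sensitivity analysis. Both the full-model R² and the R² of the
model without the ordered score are reported, since either may be the
quantity of interest when summarizing fit.

Degenerate designs raise rather than guess: a single ecosystem, or a
design where every host group sits inside one ecosystem (making the score
collinear with the group factor and leaving nothing to permute), is an
estimation error.

## Composition tests

Life-cycle (2 × E) and life-stage (C × E) tables count *distinct
morphogroups* per ecosystem; a morphogroup observed in an ecosystem
counts once in that column no matter how many hosts carry it. The test is
the plain Pearson χ² with df = (r−1)(c−1) and no continuity correction or
exact-test fallback; expected cells below 5 raise a warning flag, not a
method switch. All-zero categories make the statistic undefined and are
refused at the API level; the pipeline runner collapses them (with a log
line) before testing, which is what a practitioner would do by hand.

Life-stage categories are configuration, not code. Defaults: fish hosts
{adult, cystacanth, larval_nematode, metacestode, metacercaria};
invertebrate hosts the same but with metacercariae and sporocysts pooled
into one trematode-intermediate category, keeping the table at five rows.
The pooling convention is an assumption and is trivially replaceable via
the `stage_categories` argument.

## Synthetic data

`simulate_dataset` draws, per ecosystem: host species in each taxonomic
group with uniformly drawn per-species sample sizes; per-species mean
lengths from a lognormal (default log-mean 4.0 ≈ 55 mm, log-sd 0.6, a
realistic span from small gastropods to fish) with 10% individual
jitter; and a parasite pool whose morphogroups carry taxon / life cycle /
life stage annotations. Each eligible host species is compatible with a
morphogroup independently with probability breadth / n_eligible, and each
compatible morphogroup is detected independently in each host individual
with its detection probability; detected infections get a count of
1 + Poisson(1), which no downstream statistic consumes beyond presence.

Independence of compatibility across host species is a deliberate design
constraint, not a convenience: sampling compatibility as a fixed-size
subset of species makes the total number of compatible pairs per
ecosystem a constant, inducing negative correlation among species within
an ecosystem. Species-level label permutation is then not
distribution-preserving and the ordered test measures conservative. With
independent Bernoulli compatibility, per-species summaries are i.i.d.
within and across ecosystems under the null scenario, and the stratified
permutation test is exact — which the calibration suite verifies.

Scenario helpers:

* `null_scenario` gives every ecosystem a copy of the first ecosystem's
  pool, making ecosystems exchangeable up to labels (ground truth for
  calibration);
* `ordered_effect_scenario(base, effect, ordering)` multiplies detection
  probabilities (capped at 0.95) and pool sizes by `1 + effect · rank`
  along the ordering — a true monotone richness gradient of tunable
  strength; effect → 0 recovers the null.

Three configurations are provided. `study_scale_config` mirrors a
three-ecosystem comparison at realistic scale: 28 / 44 / 28 host species
split over the four host groups as in the motivating comparison
(vent-like: many invertebrates, only two fish species), 10–30 individuals
per species, and a pool mixing direct-life-cycle ectoparasites on fish
with indirect-life-cycle helminths whose adult stages sit in fish and
whose encysted stages sit in fish and invertebrate prey.
`calibration_config` is a smaller, fully balanced layout (12 species per
ecosystem, detection 0.10) chosen so Chao2 responses take many distinct
values — a near-continuous response keeps the randomization p-value
grid-free. `composition_calibration_config` serves χ² calibration: counts
of observed morphogroups are sums of independent Bernoulli indicators,
which match the Pearson statistic's assumed (product-Poisson)
fluctuation only when each indicator has small probability, so it uses a
large candidate pool (600 morphogroups per ecosystem) with tiny detection
probabilities, putting expected cells near 10 while staying in the
Poisson regime.

What the generator does **not** emulate: aggregation of infections within
hosts beyond independence, spatial or temporal structure in collections,
phylogenetic signal in host specificity, and taxonomy-specific prevalence
differences. Passing calibration and power checks on these synthetic data
therefore demonstrates the correctness and operating characteristics of
the estimators and tests under their stated assumptions — not that any
particular field dataset satisfies those assumptions.

## Problem sizes and numerical conventions

The test suite and `scripts/acceptance.py` use 1000 (suite) or 500
(script) null replicates at B = 199 for calibration, 60/50 replicates per
effect level for power, and 20 random matrices for oracle equivalence —
sizes at which the binomial/KS acceptance bands are informative while a
full run stays in the low minutes on one CPU. Monte-Carlo p-values use
the add-one estimator throughout; comparisons of refitted statistics use
an absolute guard of 1e-9 so bit-identical refits never compare unequal;
rarefaction and Chao2 values are exact to double precision (the
enumeration oracle agrees to < 1e-12 in practice). Seeds are mandatory at
every stochastic entry point; derived seeds are generated with numpy's
`SeedSequence`.

## Known limitations

* The ordered statistic is the score coefficient in the rank model; other
  ordered-alternative statistics (e.g. isotonic contrasts) are not
  implemented, though the score mapping is configurable.
* No interaction terms in the rank model, and no abundance-based
  estimators (Chao1/ACE) — the pipeline is incidence-only by design.
* Accumulation-curve variance is Monte-Carlo, not analytic.
* Redundancy resolution is data-driven (the redundancy-group annotation);
  the package does not attempt taxonomic synonymy resolution.
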