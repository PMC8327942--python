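# Methods

`conflictsim` models the computational core of a 2×2 experimental-evolution
design in the seed beetle *Callosobruchus maculatus*: mating system
(enforced monogamy vs. polygamy) crossed with metapopulation structure
(one panmictic population vs. five demes with migration). It has three
layers — a forward Monte Carlo simulator of the line-propagation husbandry,
effective-population-size (Ne) estimation on the simulator's output, and a
synthetic fitness-data generator paired with the random-slope linear
mixed-model (LMM) analysis design used on such data.

## The propagation protocol and its simulator

Each selection line holds a constant census of 50 breeders (25 females,
25 males). A generation consists of:

1. **Migration** (subdivided lines only). One virgin female and one virgin
   male per deme are relocated along a uniformly sampled derangement of
   demes, so every deme sends and receives exactly one pair and no pair
   stays home. With demes of 5+5 this is a fixed 20% migration rate. The
   derangement is resampled every generation; only the in/out degree of
   each deme is fixed by the design, not the cycle structure.
2. **Mating.** Monogamy: a uniformly random perfect matching of females to
   males within each deme. Polygamy: each female mates `m ~ Uniform{2, 3}`
   distinct males from her deme (males may mate several females). The 2–3
   range is sampled uniformly per female per generation. Paternity over a
   female's fertile mates defaults to equal shares; a last-male-precedence
   share is available but not default because no sperm-precedence value is
   fixed by the design.
3. **Infertility** (scenario knob, default 0). Every female-male pairing is
   independently infertile with the configured probability; shares are
   renormalized over fertile mates, and a female with no fertile mate
   leaves no offspring. The documented scenario preset is 3%, the upper
   bound of observed infertility rates in such lines.
4. **Oviposition and bean sampling.** Each female with a fertile mate lays
   a Poisson(40) number of eggs, one egg per bean (ad libitum substrate;
   no larval competition). 150 beans per line are then sampled uniformly
   without replacement and isolated, each yielding one emerging adult.
   Because every deme is a physically separate container, subdivided lines
   split the quota evenly — 30 beans per deme sampled from that deme's own
   eggs. Only the *relative* variance of fecundity matters after the bean
   downsampling, so the Poisson mean of 40 is not a sensitive parameter.
5. **Breeder selection.** The next generation's 25+25 (or 5+5 per deme)
   virgin breeders are a uniform random sample of the emerged adults.
   Emergence-day structure is collapsed into uniform sampling: collection
   was random precisely to avoid selection on development time, so no
   fitness-relevant information is lost at the modeled level.

The simulator tracks an exact pedigree kinship matrix over the current
breeders (an offspring's inbreeding coefficient F is the kinship of its
parents, propagated by the standard recursive rules) and `L = 100` unlinked
selectively neutral biallelic loci initialized at frequency 0.5, inherited
by Mendelian segregation. Each line's run is a pure function of
`(config, line_id, seed)`: one named RNG stream per line, drawn in a fixed
documented order (migration → mating → infertility → fecundity → bean
sampling → paternity → segregation → sex → selection).

Rare sampling accidents are possible under subdivision: a deme's 30 beans
can fail to contain 5 emerged adults of each sex (~0.1–0.2% of replicates).
Monte Carlo drivers count such replicates and summarize over the rest;
single-line runs raise a shortfall error naming the line and generation.

## Effective population size

Four estimators, all reported per regime at the whole-line
(metapopulation) level with allele frequencies and pedigree F pooled
across demes:

* **Sex ratio** (closed form): `4·Nm·Nf/(Nm+Nf)`; equals the census 50 for
  equal sexes.
* **Family-size variance** (closed form on realized family sizes):
  per sex `Ne = (n·k̄ − 1)/(k̄ − 1 + Vk/k̄)`, sexes combined as
  `4·NeF·NeM/(NeF+NeM)`. Family size is the number of *selected*
  next-generation breeders per candidate parent, zeros included.
* **Pedigree inbreeding**: `Ne = 1/(2ΔF)` where ΔF satisfies geometric
  decay of `1 − F` from a burn-in baseline,
  `ΔF = 1 − ((1−F_T)/(1−F_b))^(1/(T−b))`.
* **Temporal (drift variance)**: `Fc = (p0 − pt)²/(p̄(1−p̄))` averaged over
  segregating loci, `Ne = t/(2·F̄c)`. No sampling-correction terms are
  applied because the simulator observes true census frequencies.

**Burn-in.** Founders are artificially non-inbred, so the inbreeding-rate
baseline starts at generation 1 for undivided lines. Subdivided lines show
an additional transient: mean pedigree F first rises quickly while
within-deme coancestry approaches its migration–drift quasi-equilibrium,
and only afterwards grows at the metapopulation rate that defines the
regime's Ne. The baseline is therefore placed one migrant residence time
into the run, `ceil(1/m)` generations (5 at the imposed 20% rate). The
temporal estimator needs no such treatment (drift has no founder
transient) and uses the founder frequencies as its baseline. Regime
*orderings* are read from the drift-based estimators (temporal and
family-size); at a 10-generation horizon the pedigree estimator's medians
for the two monogamy regimes sit within Monte Carlo noise of each other.

Monte Carlo summaries are medians with 2.5–97.5 percentile intervals
across replicates — not means — because replicate Ne estimates are heavily
right-tailed (a replicate with almost no observed drift yields a huge or
infinite estimate). Percentiles are order statistics
(`numpy method="inverted_cdf"`), since interpolating between infinite
order statistics is undefined.

Default problem sizes: 500 replicates × 10 generations per regime, chosen
to pin regime medians to roughly ±1.5 individuals while keeping a full
four-regime evaluation around one minute on one CPU.

## Synthetic fitness records

The generator emulates the assay-level structure the LMMs assume, using
the published per-assay coefficient vectors as generative truth
(reference coding: monogamy and no-structure are reference levels;
covariates act population-centered so the intercept keeps its printed
meaning). Per line, a random intercept (and optionally a body-size random
slope) is drawn from its SD; per female, body size (elytron length,
`N(2.00, 0.08)` mm; tester males `N(1.85, 0.08)` mm), age at entry
(uniform on 1–3 days) and realized matings (binomial over the assay's
daily opportunities) are drawn raw and stored raw — centering is the
analysis's job, which guards against double-centering bugs.

Where an assay records both longevity and lifetime reproductive success
(LRS), the two residuals are drawn jointly with correlation
`trade_off_rho = −0.3` (cost of reproduction). The cross-trait regression
coefficients printed in the tables are *not* used generatively — the
association is induced through the residual correlation instead, which
avoids a circular two-equation definition. LRS is a rounded, floored
Gaussian on the scale the analyses used (an optional squared-count
transform is exposed, default off, because back-transforming printed
coefficients is ambiguous); consequently LRS values are calibrated to the
published coefficient scale, not to raw offspring counts.

Variance components are not printed in the coefficient tables and are
free parameters with documented defaults: line intercept SD ≈ 10% of the
intercept magnitude (2.4 days for the medium assay; 300 for the
extreme-assay LRS model), residual SDs chosen to give plausible response
spreads (4 days; 800), random-slope SDs default to 0. Default sample
sizes follow the assays: 262 females over 16 lines for the medium
(variable-mating-rate) assay, split 7 (generation 12) + 10 (generation
30) per line; 10 females per line for the single-mating and
continuous-exposure assays.

The generator makes no attempt to model harassment mechanics, mating
behavior, or count overdispersion; a passing recovery study shows the
analysis design recovers the coefficients of *this* linear structure, not
that the published values are correct for real beetles.

## Mixed-model analysis design

`fit_model` fits, via `statsmodels.MixedLM`, the by-line random-intercept
+ random-slope model with grand-mean-centered covariates. The protocol's
conventions are enforced structurally:

* coefficient tables always come from the REML fit; Wald chi-square
  statistics always from the ML fit;
* the full random-effects covariance (intercept–slope correlations
  included) is attempted first; on optimizer failure the fit falls back to
  uncorrelated random effects and flags it. Singular (zero-variance)
  boundary fits are reported, not errors. Optimizers are tried in the
  order lbfgs, bfgs, powell;
* control covariates (age, matings, generation) never receive random
  slopes;
* Type II Wald tests respect marginality (each term is tested in the
  model with all terms containing it removed); Type III tests every term
  in the full model after internally recoding the treatment indicators to
  −1/2, +1/2 contrasts. The `auto` rule computes the interactions' Type
  III tests first and uses Type III throughout if any is significant at
  0.05, else Type II. The regime interaction itself is tested in the full
  model under both types, so its statistic is identical — checked
  numerically in the tests. The Type III full-model test is obtained by an
  exact linear reparametrization of the fitted ML model (no refit), since
  both codings span the same column space;
* p-values are asymptotic chi-square on 1 df; no small-sample
  (Kenward–Roger-style) correction is applied, matching the reported
  tests.

Degenerate noiseless data (an exact linear interpolation) cannot support
a variance-component fit and short-circuits to the exact least-squares
solution with zero SEs.

**Known calibration limitation.** With 16 lines the between-line
information for the regime interaction carries about 12 degrees of
freedom, so even with perfect variance estimation an asymptotic
chi-square Wald test rejects a true null at ≈ P(F₁,₁₂ > 3.84) ≈ 0.073
rather than 0.05; the ML fit used for testing additionally biases the
line variance downward (roughly by 12/16 here), and the calibration study
accordingly measures an empirical size near 0.10 for the regime
interaction at this design. The implementation reproduces the reference
analysis stack (lme4 + car Type III Wald) on identical data, so this is a
property of the stated protocol, not of the fitting code. Random slopes
protect the *covariate* tests from pseudo-replication but cannot buy back
between-line degrees of freedom; an exact-size interaction test would
need a small-sample correction the protocol deliberately omits.

`recovery_study` wraps generate → fit → test over seeded replicates and
aggregates per-coefficient bias, RMSE, 95% CI coverage and rejection
rates, counting (never hiding) fit failures. Recovery studies default to
200 replicates — Monte Carlo SE of the mean interaction estimate ≈ 0.4
days (medium assay) — and the type-I-error study to 1000 replicates
(binomial SE ≈ 0.007 at a 0.05 rate).

## Numerical and design choices

* Configs are frozen after validation; every simulation or study is a
  pure function of (config, seed). Seeds are combined through
  `numpy.random.SeedSequence`; a line's stream is derived from
  (master seed, CRC-32 of the line id).
* Infinite Ne estimates (no drift observed at the numerical floor of
  1e−12) are legal values and survive median/percentile summaries.
* Ties in breeder selection, mate sampling and migration are resolved by
  the RNG, never by index order.
* The temporal estimator drops loci fixed at both time points; an
  all-fixed panel is a degenerate-input error.
* Rank-deficient fixed-effect matrices raise an error naming the aliased
  columns (pivoted QR).

## Limitations

* The simulator is neutral: no fitness variation among genotypes, no
  selection on development time, no deme extinction/recolonization, no
  sex-biased migration, no overlapping generations.
* The generator's Gaussian machinery does not emulate count
  overdispersion, zero-inflation, or the bounded support of real LRS.
* Ne estimates characterize the breeding design, not any particular
  genetic dataset; plan-sampling corrections would be needed before
  applying the temporal estimator to finite marker samples.
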