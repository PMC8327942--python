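# conflictsim

Simulation and inference toolkit for a sexual-conflict experimental-
evolution design in the seed beetle *Callosobruchus maculatus*. The
design crosses two mating systems — enforced monogamy (relaxed sexual
selection and conflict) vs. polygamy — with two levels of spatial
structure — a single panmictic population vs. a metapopulation of five
demes exchanging one male–female migrant pair per deme per generation
(a 20% migration rate) — giving four selection regimes, four replicate
lines each, every line propagated with 50 breeders (25 ♀, 25 ♂) from 150
one-egg beans per generation.

The package is aimed at experimental evolutionists who need to

* quantify the **effective population size (Ne)** implied by such a
  breeding design, via forward Monte Carlo simulation of the exact
  husbandry protocol (migration, mating system, optional infertile
  matings, bean sampling, virgin-breeder selection) with exact pedigree
  inbreeding and neutral-locus drift tracking;
* **generate synthetic fitness-assay data** (female longevity and
  lifetime reproductive success, LRS) with the structure the study's
  mixed models assume — regime fixed effects with a reversal interaction,
  by-line random intercepts and slopes, a residual longevity–LRS
  trade-off; and
* **fit the study's random-slope linear mixed models** — mean-centered
  covariates, REML estimates / ML Wald chi-square tests, Type II tests
  switching to Type III under significant interactions, and a documented
  fallback that drops intercept–slope correlations on non-convergence —
  plus run parameter-recovery and type-I-error studies against the
  generator.

## The quantities at the core

Effective sizes come from four standard estimators, evaluated on
replicate simulations of the propagation protocol:

* sex ratio: `Ne = 4·Nm·Nf / (Nm + Nf)`
* family-size variance, per sex: `Ne = (n·k̄ − 1) / (k̄ − 1 + Vk/k̄)`,
  combined as `4·NeF·NeM / (NeF + NeM)`
* pedigree inbreeding: `Ne = 1 / (2ΔF)`, ΔF the per-generation rate of
  increase of mean pedigree F past a burn-in baseline
* temporal (drift variance): `Fc = (p0 − pt)² / (p̄(1 − p̄))` averaged over
  loci, `Ne = t / (2·F̄c)`

The analysis layer mirrors the published model structure: for example the
medium-conflict assay models female longevity on mating system,
structure, their interaction, centered body size (with treatment × size
terms and a by-line random slope), and age / mating-count / generation
controls.

## Worked example

```python
from conflictsim import (build_regime, monte_carlo_ne, default_models,
                         generate_assay, spec_for, fit_model, wald_tests)

# 1. Ne of the subdivided-polygamy regime, 500 protocol replicates
cfg = build_regime("polygamy", structured=True)
ne = monte_carlo_ne(cfg, replicates=500, generations=10, seed=1,
                    on_shortfall="summarize")
est = ne["pedigree_inbreeding"]
print(f"SPoly inbreeding Ne: {est.value:.1f} "
      f"(95% CI {est.ci[0]:.1f}-{est.ci[1]:.1f})")

# 2. synthetic medium-conflict assay and its mixed-model analysis
model = default_models()["medium"]
data = generate_assay(model, n_per_line=17, seed=5)
fit = fit_model(spec_for(model), data)
print(fit.params.set_index("term").loc["interaction"].round(2).to_dict())
print(wald_tests(fit, "auto").table.round(3).to_string(index=False))
```

prints (abridged):

```
SPoly inbreeding Ne: 45.9 (95% CI 23.3-716.3)
{'estimate': -0.77, 'se': 2.68}
          term  chisq  df     p
 mating_system  0.009   1 0.923
     structure  0.778   1 0.378
     body_size 78.804   1 0.000
           age  0.015   1 0.901
     n_matings  2.049   1 0.152
    generation  7.289   1 0.007
   interaction  0.124   1 0.724
ms_x_body_size  7.228   1 0.007
st_x_body_size  0.008   1 0.930
```

The Ne line says the subdivided-polygamy protocol drifts like an ideal
population of ~46 individuals — slightly below the census of 50, with a
right tail reaching "no measurable drift" replicates. The single synthetic
dataset's interaction estimate (−0.77 ± 2.68) scatters around the
generating value −3.90; `recovery_study` shows the estimator is unbiased
across replicates while a single assay of 272 females carries sizeable
uncertainty. The per-term table reports Wald chi-square tests, here Type
III because a body-size × treatment interaction reached significance.

A command-line interface wraps the same operations:

```bash
conflictsim simulate    --generations 10 --replicates 5 --seed 1 --out runs/sim
conflictsim estimate-ne --replicates 500 --seed 1 --infertility 0,0.03 --out runs/ne.csv
conflictsim generate    --assay medium --seed 2 --out runs/medium.csv
conflictsim fit         --data runs/medium.csv --assay medium --out runs/fit
conflictsim recover     --assay medium --replicates 200 --seed 3 --out runs/recovery.csv
```

Every command writes a JSON manifest (command, config fingerprint, seed,
version, outputs) so runs are reproducible from their outputs alone.

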