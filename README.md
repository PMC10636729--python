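# matrep

Maternal variance partitioning of early-life behavior and survival with
multivariate Bayesian mixed models.

## The problem

In wild mammal populations, offspring of the same mother tend to resemble
each other — through the genes they share and through the environment their
mother provides. For behavioral traits this sibling similarity contributes
to what the animal-personality literature calls *repeatability*. `matrep`
implements the variance-partitioning analysis used to quantify these
effects in a wild eastern gray kangaroo system, where behavior can be
measured extraordinarily early: as a movement score of pouch young (PY)
during handling, as flight initiation distance (FID, the distance at which
an animal flees an approaching human) of subadults and of adult females,
and as survival of subadults to weaning.

The package is written for quantitative ecologists who want to fit this
family of models, or to study their behaviour on simulated data, without a
download of the original field data: a synthetic-data generator reproduces
the study's hierarchical structure (mothers with 1–3 offspring, repeated
FID trials, a binary survival outcome) under known variance components.

## The model

Two multivariate generalized linear mixed models are fitted by Gibbs
sampling, mirroring an MCMCglmm-style analysis:

* **Model I** — a four-trait model of PY movement, trial-averaged subadult
  FID, subadult survival (binary, logit link, latent residual variance
  fixed at 1) and adult female FID, with a mother-level random effect
  carrying an unstructured 4×4 covariance matrix **G**. Residual
  covariances are free among the three offspring traits and fixed to zero
  against the adult trait (disjoint observational units).
* **Model II** — a bivariate repeated-measures model of subadult and adult
  female FID with mother-level effects on both traits (unstructured 2×2
  covariance) and an offspring-level effect on subadult FID.

From the posterior samples the package computes, per retained sample and
only then summarised (posterior mode of a kernel density estimate, 95%
highest posterior density interval, pMCMC for fixed effects):

* maternal repeatability `var_M / (var_M + var_R)` (latent scale for the
  binary trait),
* the data-scale analogue for survival, where the binomial sampling
  variance `E[p(1-p)]` enters the total,
* individual and total repeatability of subadult FID,
  `(var_M + var_O) / (var_M + var_O + var_R)`, and the maternal share
  `var_M / (var_M + var_O)`,
* the upper-limit heritability `upper_h2 = 2 cov(M, O) / var_M` from the
  mother-level covariance between subadult and adult female FID,
* an OLS adoption (cross-fostering) regression contrasting biological and
  rearing mothers when the table contains adopted offspring.

## Worked example

```python
from matrep import SimulationConfig, simulate_dataset, run_full_analysis, MCMCConfig

table, truth = simulate_dataset(SimulationConfig(seed=9))
report = run_full_analysis(table, MCMCConfig(n_iterations=4000, burn_in=1000,
                                             thinning_interval=5, seed=3))
dec = report.models["II"]["decompositions"]["subadult_fid"][0]["ratios"]
for name in ["maternal_repeatability", "individual_repeatability",
             "total_repeatability", "maternal_proportion_of_total"]:
    r = dec[name]
    print(f"{name}: {100*r['posterior_mode']:.1f}% "
          f"({100*r['hpd_low']:.1f}%, {100*r['hpd_high']:.1f}%)")
h = report.heritability["upper_h2"]
print(f"upper-limit h2: {h['posterior_mode']:.2f} ({h['hpd_low']:.2f}, {h['hpd_high']:.2f})")
```

prints

```
maternal_repeatability: 32.2% (20.6%, 45.1%)
individual_repeatability: 18.8% (8.8%, 29.6%)
total_repeatability: 51.5% (43.1%, 60.3%)
maternal_proportion_of_total: 66.5% (42.7%, 81.3%)
upper-limit h2: 2.00 (1.43, 2.63)
```

Half of the phenotypic variance in subadult FID is repeatable, and roughly
two thirds of that repeatable variance traces to differences between
mothers rather than between individual offspring — the synthetic truth
behind this table was generated with exactly such a partition, so the fit
is recovering what was put in. The upper-limit heritability above 1 shows
the mother–offspring covariance inflated by shared-environment effects, as
expected when mothers rear their own young. For the binary survival trait
the same report shows the characteristic scale collapse: a large maternal
repeatability on the latent liability scale shrinks severalfold on the
observed 0/1 scale once binomial sampling variance enters the denominator.

A command-line interface wraps the same pipeline:

```sh
matrep simulate --seed 7 --out sim/
matrep fit --model both --data sim/observations.csv --seed 7 --out run/
matrep summarize --posterior run/posterior_model_II.csv --out run/summary.json
matrep report --run run/
```

## Layout

* `src/matrep/synthetic.py` — synthetic observation tables with known truth
* `src/matrep/model.py` — the multi-trait Gibbs sampler
* `src/matrep/scale.py` — latent-to-data scale conversion for binary traits
* `src/matrep/summaries.py` — posterior modes, HPD intervals, pMCMC, ratios
* `src/matrep/pipeline.py` — Model I / Model II builders and the full analysis
* `src/matrep/io.py`, `src/matrep/cli.py` — CSV formats, validation, CLI
* `docs/methods.md` — modelling assumptions, priors, numerical choices
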