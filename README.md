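# prepost-ma

Meta-analysis of continuous outcomes measured at baseline and follow-up
(pretest–posttest designs), as a Python library and CLI.

Five routes to the summary mean difference (treatment − control):

1. **Follow-up scores** — pooled mean differences of final scores.
2. **Change scores** — pooled mean differences of follow-up − baseline.
3. **ANCOVA recovered estimates** — per-trial single-slope ANCOVA treatment
   effects reconstructed algebraically from the summary statistics alone.
4. **Two-stage pseudo-IPD ANCOVA** — exact-moment pseudo participant data per
   arm, per-trial OLS ANCOVA, coefficients pooled in a second stage.
5. **One-stage pseudo-IPD ANCOVA** — linear mixed model with study-stratified
   intercepts and baseline slopes, optional random treatment effects (REML
   τ²), four within-trial residual-variance structures (`single`, `arm`,
   `study`, `arm_study`), and an optional treatment-by-baseline interaction
   split into within- and between-trial components.

Pooling uses inverse variance with a common-effect (CE) or random-effects
(RE) model; RE heterogeneity is estimated by REML, with optional
Hartung–Knapp standard errors and t(k−1) intervals. A sequential fill-in
engine completes incomplete summary data (SD from SE; sd_F ← sd_B;
r from the three SDs via `r = (sd_B² + sd_F² − sd_CS²)/(2·sd_B·sd_F)`;
mean identities; weighted-mean or fixed correlation imputation), recording
per-cell provenance (observed / calculated / imputed). Forest and funnel
plots export their coordinates as sidecar CSVs.

## Data format

Long format, one row per trial arm, exactly two arms (`control`,
`treatment`; `0`/`1` accepted) per trial. Canonical columns, in order:

```
trial_id, arm, n, mean_B, sd_B, se_B, mean_F, sd_F, se_F, mean_CS, sd_CS, se_CS, r
```

`B` = baseline, `F` = follow-up, `CS` = change score. Blank cells are
missing. CSV (UTF-8) is primary; `.xlsx` is also supported. All SDs use the
n−1 denominator. Change scores follow the convention
`mean_CS = mean_F − mean_B`; use `--negate-change` if your file records
baseline − follow-up. `prepost-ma template --out template.csv` writes an
empty template.

## CLI

```bash
prepost-ma simulate --k 9 --n 50 --theta -0.5 --tau2 0.25 --seed 1 --out sim.csv
prepost-ma fill --in sim.csv --out complete.csv --corr-strategy weighted_mean --report fill_report.csv
prepost-ma effects --in complete.csv --method ancova --out effects.csv
prepost-ma pool --in effects.csv --model re --hk --out result.json
prepost-ma pseudo --in complete.csv --seed 1 --out pseudo.csv
prepost-ma onestage --in complete.csv --resid study --model re --interaction --out fit.json
prepost-ma twostage --in complete.csv --model re --hk --out two.json
prepost-ma plot --effects effects.csv --kind forest --out forest.png
prepost-ma report --in sim.csv --outdir results/ --model re --seed 1
```

`report` runs the whole pipeline and writes `results.json` (full-precision
estimates, CIs, τ², Q, I², H², convergence info), per-method effects CSVs,
the completed dataset, the fill-in provenance report, pseudo-IPD, plots
with `.data.csv` sidecars, and a reproducibility log.

## Library

```python
from prepost_ma import (
    read_dataset, run_fillin, compute_effects, pool_re,
    generate_dataset, twostage, fit_onestage, OneStageSpec,
)

ds = read_dataset("data.csv")
complete, provenance = run_fillin(ds)
pooled = pool_re(compute_effects(complete, "ancova_recovered"), hk=True)
ipd = generate_dataset(complete, seed=1)
fit = fit_onestage(ipd, OneStageSpec(resid_structure="study", model="RE",
                                     interaction=True))
```

Pseudo-IPD matches each arm's five sample moments (means, SDs, correlation)
to 1e−10 by construction, so every downstream model depends on the data
only through those sufficient statistics: different seeds give identical
estimates.

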