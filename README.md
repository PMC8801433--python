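# relapsetrack

A relapse-tracking analysis pipeline for detoxification aftercare cohorts.

Cohorts released from compulsory isolated detoxification are followed at
fixed visits (1 week, 1 month, 3 months, then quarterly), so the time to
first drug reuse is only ever known up to the window between two visits:
relapse times are **interval censored**, and subjects still abstinent at
study end are **right censored**.  `relapsetrack` implements the full
analysis chain for such a design, for epidemiologists and social-work
researchers evaluating aftercare interventions:

1. **Synthetic cohort simulation** — a 1:2 experimental/control split via
   the seat-number rule (multiples of 3 → experimental), baseline
   covariates from configurable marginals, SOCRATES motivation and HADS
   anxiety/depression scale items, and a relapse-time process with an
   early first-week spike plus a long Weibull tail.
2. **Follow-up censoring** — true event days mapped to `(L, R]` visit
   windows or right-censor times.
3. **Descriptives** — relapse-rate and timing tables with uncorrected
   Pearson χ², pooled-variance t from printed group summaries, scale
   scoring, Cronbach's α.
4. **Bayesian survival estimation** — event times
   `T_i ~ Weibull(k, λ_i)` with scale linear in motivation,
   `λ_i = α_g + r_s·M_i`, fitted by Metropolis-within-Gibbs with data
   augmentation (latent event times drawn from truncated Weibulls).  The
   reported quantities are the mean survival `(1/n)Σ λ_i Γ(1+1/k)` in days
   and the motivation effect `r = r_s·Γ(1+1/k)` in days per SOCRATES
   point, summarized in posterior tables with Monte-Carlo SE, posterior
   SD, a Gelman–Rubin convergence statistic (convergence declared at
   C.S. ≤ 1.002) and 95% bounds.
5. **Multiple imputation** — each subject's survival time imputed m=10
   times from the retained latent draws and combined by averaging.
6. **Risk-factor screening** — the combined times discretized by the
   upper-and-lower-27% rule (low survival = 1, high = 0, middle 46%
   excluded) and fed to four nested logistic models (sociodemographic →
   + drug-abuse history → + clinical situation → + group), reporting OR
   (SE), model χ², Nagelkerke R², −2LogLik and predicted %.

## Worked example

The descriptive layer reproduces a published relapse-rate table exactly
from its printed counts:

```python
import relapsetrack as rt
from relapsetrack import datasets

outcomes, groups = datasets.published_outcomes()
table = rt.relapse_rate_table(outcomes, groups)
print(table)
print("chi2 = %.3f, df = %d" % (table.attrs["chi2"], table.attrs["df"]))
```

```
              compliance_n  compliance_pct  relapse_n  relapse_pct
arm
overall                267            52.4        243         47.6
experimental           112            73.2         41         26.8
control                155            43.4        202         56.6
chi2 = 38.090, df = 1
```

An overall relapse rate of 47.6% with 26.8% in the aftercare arm versus
56.6% in the control arm, and a Pearson χ² of 38.090 (df 1): the aftercare
intervention is strongly associated with compliance.

The full simulation → estimation chain runs from the command line:

```sh
relapsetrack all --seed 42 --out run1        # every stage + manifest.json
relapsetrack simulate --seed 42 --out run2   # or stage by stage
```

which writes `cohort.csv`, `outcomes.csv`, descriptive tables, the
posterior summary table, `imputations.csv`, the nested logistic model
table and a `manifest.json` whose artifact hashes are reproducible under a
fixed seed.

## Layout

| Module | Role |
| --- | --- |
| `relapsetrack.cohort` | synthetic cohorts and relapse-time processes |
| `relapsetrack.censoring` | follow-up schedule, interval/right censoring, timing tables |
| `relapsetrack.descriptives` | χ², rates, pooled t, scale scoring, Cronbach's α |
| `relapsetrack.survival` | data-augmented Weibull MCMC and posterior summaries |
| `relapsetrack.diagnostics` | Gelman–Rubin statistic, effective sample size |
| `relapsetrack.imputation` | posterior imputation of survival times |
| `relapsetrack.riskmodel` | 27% rule and batched logistic regression |
| `relapsetrack.pipeline` / `cli` | stage orchestration, CSV artifacts, CLI verbs |

See `docs/methods.md` for the model, priors, numerical choices and known
limitations.
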