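# trialcea

Within-trial cost-effectiveness analysis for two-arm clinical trials, built
around the economic evaluation of wound-edge protection devices (WEPDs)
versus standard care after laparotomy: patient-level costing under a
unit-cost table, EQ-5D-3L utility scoring with the UK time-trade-off value
set, 30-day QALYs with baseline-utility adjustment, multiple imputation by
chained equations, bias-corrected and accelerated (BCa) bootstrap intervals
for incremental costs and effects, cost-effectiveness acceptability curves
(CEACs), and identity-link GLM sensitivity analyses. A calibrated synthetic
trial generator makes every stage testable without access to patient data.

It is aimed at health economists and trial statisticians who want a
reproducible, scriptable pipeline for trial-based economic evaluations, and
at methodologists who want the individual pieces (BCa, CEAC, Rubin pooling,
gamma-identity GLMs) as tested library functions.

## The analysis in brief

For arms *T* (intervention) and *C* (comparator), with per-patient total
costs and QALYs over a 30-day horizon,

- **increments**: ΔC = C̄_T − C̄_C, ΔE = Ē_T − Ē_C;
- **ICER** = ΔC/ΔE (£/QALY), reported only in the trade-off quadrants of
  the cost-effectiveness plane — a strategy that is more costly and less
  effective is *dominated*, the converse *dominant*;
- **QALYs**: EQ-5D-3L profiles scored with the UK tariff
  (index ∈ [−0.594, 1]); QALY = trapezoidal area under the utility line
  between baseline and day 30, in years; deaths decline linearly to zero
  at the day of death; adjusted for baseline utility by regression;
- **uncertainty**: patients resampled with replacement within arm,
  B = 1,000; BCa 95% intervals with bias constant z₀ and jackknife
  acceleration a;
- **CEAC**: at willingness-to-pay λ, the probability of cost-effectiveness
  is the fraction of bootstrap replicates with λ·ΔE_b − ΔC_b > 0;
- **missing data**: chained equations (predictive mean matching, logistic
  for binaries), m = 20 imputations, Rubin's rules for pooling;
- **sensitivity**: the 2×2 scenario matrix {multiply imputed, complete
  case} × {unadjusted, GLM-adjusted}, with gamma-identity models for
  costs and normal-identity for QALYs.

## Worked example

```sh
trialcea simulate --seed 7 --out trial.csv
# wrote 735 patients to trial.csv   (369 device, 366 standard care)
trialcea analyze trial.csv --out-dir results -B 1000 -m 20 --seed 7
```

prints (stderr report, rounded; full precision goes to `results/`):

```
base_case_unadjusted: ΔC £715 (-482 to 2,008), ΔE 0.0007 QALY (-0.0026 to 0.0039) -> £1,005,511/QALY
base_case_adjusted: ΔC £407 (-746 to 1,560), ΔE 0.0019 QALY (-0.0001 to 0.0040) -> £212,871/QALY
complete_case_unadjusted: ΔC £742 (-708 to 2,260), ΔE 0.0012 QALY (-0.0023 to 0.0048) -> £608,707/QALY
complete_case_adjusted: ΔC £376 (-1,039 to 1,791), ΔE 0.0023 QALY (0.0000 to 0.0045) -> £165,734/QALY
```

Each line is one scenario cell: the incremental cost with its 95% BCa
interval, the incremental QALY likewise, and the ICER or dominance label.
In this simulated replicate the device costs several hundred pounds more
per patient for a QALY gain indistinguishable from zero, so any ICER is
far above conventional willingness-to-pay thresholds — the device is not
cost-effective, matching the data-generating truth (a £15 device, equal
effectiveness). `results/` also receives the per-component cost summary,
the CE-plane replicate cloud, per-scenario CEAC curves and a JSON run
manifest; the same seeds reproduce every file byte-for-byte.

The same operations are available as a library:

```python
from trialcea import (rossini_default, generate_calibrated_summary,
                      bootstrap_increments, ceac_from_replicates)

trial = generate_calibrated_summary(rossini_default(), seed=1)
res = bootstrap_increments(trial, B=1000, seed=2)
res.delta_cost, res.delta_effect      # (290.0, -2e-05)
res.icer_or_label                     # 'dominated'
curve = ceac_from_replicates(res.replicates)
curve.max_over(20_000, 30_000)        # ~0.19
```

## Layout

| module | contents |
|---|---|
| `synthetic_trial` | calibrated trial generator, config, CSV round-trip |
| `costing` | unit-cost table, per-patient breakdowns, arm summaries |
| `utility_qaly` | EQ-5D-3L scoring, 30-day QALYs, baseline adjustment |
| `imputation` | chained equations (PMM/logistic), Rubin pooling |
| `incremental` | increments, dominance, BCa bootstrap, CE plane |
| `ceac` | acceptability curves over a willingness-to-pay grid |
| `adjustment` | identity-link gamma/normal GLMs, pooled fits |
| `scenarios` | the 2×2 scenario matrix orchestration |
| `cli` | `trialcea simulate / analyze / ceac / scenarios` |

See `docs/methods.md` for the statistical details and design choices.
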