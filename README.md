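# gslond

Online control of the false discovery rate (FDR) for group-sequential
platform trials: the LOND procedure, its group-sequential scheduling variants,
exact two-stage alpha-spending boundaries, and a Monte-Carlo platform-trial
simulator with a shared control arm.

## Background

In a platform trial, treatment arms enter over time and are each compared
against a shared control arm. Testing every arm at a fixed level inflates the
rate of false positive claims as the platform grows. LOND ("significance
Levels based On Number of Discoveries") controls the *online* FDR: hypothesis
H_i is tested at level

```
alpha_i = beta_i * (1 + R_{i-1})
```

where `beta_i` is a pre-specified budget with `sum_i beta_i <= alpha` and
`R_{i-1}` counts rejections among the first i−1 hypotheses. The FDR is then
at most `alpha` after every decision, for independent or positively dependent
p-values.

Platform trials additionally analyse each arm group-sequentially (an interim
and a final look), and the analyses of different arms interleave in calendar
time, so the rejection count feeding `alpha_i` can change *between* H_i's
interim and final analysis. This package implements four scheduling rules for
that situation:

| rule | rejection count | boundary update at the final look |
|---|---|---|
| `gsLOND` | earlier-entering hypotheses (j < i) decided so far | re-derive both boundaries from the spending function at the new level |
| `gsLOND.II` | as gsLOND | spend the level increment entirely at the final look (exhausts the updated level exactly) |
| `gsLOND.III` | all decided hypotheses (j ≠ i), including later entries | as gsLOND |
| `gsLOND.II.III` | as gsLOND.III | increment-exhausting, triggered by new j < i rejections |

`gsLOND` and `gsLOND.II` preserve the online FDR guarantee; the `.III`
variants use information from later-entering hypotheses and are assessed
empirically.

## Quick tour

```python
from gslond import (
    BetaSequence, two_stage_boundaries, run_fixed_sample,
    run_schedule, AnalysisEvent, SimScenario, run_replicates,
)

# budgets: descending series rescaled to a bound of N = 100 hypotheses
seq = BetaSequence.descending_truncated(0.025, N=100)
float(seq.values(1))                      # 0.006443...

# exact one-sided two-stage boundaries, O'Brien-Fleming spending, t1 = 0.5
plan = two_stage_boundaries(0.025, t1=0.5, spending="OBF")
(plan.a1, plan.a2)                        # (0.001525..., 0.024500...)

# fixed-sample LOND over an ordered p-value stream
rec = run_fixed_sample([0.001, 0.5, 0.5], BetaSequence.equal(0.05, 3))
rec.rejections                            # [True, False, False]

# group-sequential LOND over interleaved analysis events
events = [
    AnalysisEvent(1.0, 1, "interim", 0.004),
    AnalysisEvent(2.0, 2, "interim", 0.30),
    AnalysisEvent(3.0, 2, "final", 0.015),
]
res = run_schedule(events, seq=BetaSequence.equal(0.05, 3),
                   spending="PO", variant="gsLOND.II", futility=None, t1=0.5)
res.rejected                              # {1, 2}

# operating characteristics of a 10-arm platform trial
sc = SimScenario(K=10, pi0=1.0, controls="NCC_CC", spending="OBF",
                 variant="gsLOND", N=100, n_reps=5000)
r = run_replicates(sc)
(r.fdr, r.saved_pct)                      # (~0.012, ~25.1)
```

Under the global null with a non-binding futility stop at interim p ≥ 0.5,
about 25% of the planned treatment observations are saved by interim
stopping, while the empirical FDR stays well below the 0.025 level.

## Command line

```
gslond boundaries --alpha-list 0.0167 0.0334 0.05 --spending po obf --t1 0.5 --round 4
gslond toy --table 2                  # worked three-hypothesis example
gslond run --events events.csv --variant gsLOND.II --alpha 0.05 \
           --beta-kind equal --N 3 --spending PO --futility none
gslond simulate --scenario scenario.yaml --reps 5000 --seed 1 --out results/
```

`gslond toy --table {1,2,3}` prints the deterministic worked example: the
nominal levels and Pocock/O'Brien-Fleming boundaries after 0–2 rejections,
and the per-rule boundary updates of a second and third hypothesis under
every outcome combination of the other two (including the
increment-exhausting values 0.0279 and 0.0389). `gslond simulate` accepts a
YAML file with any `SimScenario` field, including the fixed-budget modes
(`budget_mode: 1..4`, `K0`), and writes `metrics.json` / `metrics.csv`;
outputs are byte-identical across repeated invocations at the same seed.

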