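# crowdmix

Mixture-model analysis of crowding errors in peripheral orientation
estimation.

## The problem

When a peripheral Gabor target is flanked radially by other Gabors,
observers asked to reproduce the target's orientation on a continuous
wheel make characteristic errors: some reports are noisy estimates of
the target, some are random guesses, and some are *misreports* — the
observer reproduces a flanker's orientation instead of the target's. A
central question is whether the flankers contribute symmetrically, or
whether the more eccentric (outer) flanker dominates — the classic
inner–outer asymmetry of crowding.

`crowdmix` is for researchers analysing trial-level continuous-report
data from such displays (or validating analysis pipelines on synthetic
data). It fits probabilistic mixture models that decompose the error
distribution into target, guess and per-flanker components, compares
them with AICc, and derives the summaries group-level statistics
consume: precision, target-report rate, per-flanker report rates, and
outward bias.

## The models

Orientation is 180°-periodic; all circular computation uses angle
doubling, and signed errors θ = response − target live in (−90°, +90°].
With f(·)_σ a zero-mean von Mises density (per degree, width σ expressed
as the circular SD in orientation degrees) and θ\*ᵢ the i-th flanker's
offset from the target, the candidate models are:

- **S — standard mixture** (γ, σ):
  p(θ) = (1 − γ)·f(θ)_σ + γ/180
- **M — misreport** (γ, σ, β): adds a pooled misreport component split
  equally over the m flankers:
  p(θ) = (1 − γ − β)·f(θ)_σ + γ/180 + (β/m)·Σᵢ f(θ − θ\*ᵢ)_σ
- **2M / 4M — independent misreport** (γ, σ, β per flanker): one free
  weight per flanker, e.g.
  p(θ) = (1 − γ − β₁I − β₁O)·f(θ)_σ + γ/180 + β₁I·f(θ − θ\*₁I)_σ + β₁O·f(θ − θ\*₁O)_σ
- **2B / 4B — with bias** (+ μ): the target component's mean is shifted
  by μ on outward-realigned errors, testing whether an averaging pull
  toward the outer flanker is needed beyond misreport weighting.

All von Mises components share one σ. The target-report rate is
P_T = 1 − γ − Σβᵢ. Models are fitted per observer × condition by
multi-start maximum likelihood (softmax reparameterization keeps the
mixture weights on the simplex exactly) and ranked by
AICc = −2 log L + 2k + 2k(k+1)/(n − k − 1).

## Worked example

Simulate 3 observers from a realistic crowding regime (misreport mass
loaded on the first outer flanker) and run the full pipeline:

```python
import crowdmix as cm

df = cm.generate_dataset(cm.DesignConfig(n_observers=3, seed=91))
result = cm.run_pipeline(df, cm.PipelineConfig(fit=cm.FitConfig(n_starts=6, seed=0)))
print(result.summary[["observer_id", "condition", "best_model", "P_T", "gamma", "sigma"]])
```

prints

```
   observer_id     condition           best_model       P_T         gamma      sigma
0            1  four_flanker       four_misreport  0.509434  9.592449e-02  12.895473
1            1   two_flanker        two_misreport  0.550719  4.387023e-02  14.558912
2            1     uncrowded             standard  0.986112  1.388773e-02  12.475822
3            2  four_flanker  four_misreport_bias  0.556979  1.469875e-06  16.353971
...
```

Read: in the uncrowded condition almost all reports are target reports
(P_T ≈ 0.94–0.99) with σ ≈ 12°, matching the generating scenario
(γ = 0.03, σ = 12°); with flankers present P_T drops toward the
generating 0.65/0.57 because misreport components absorb the flanker
reports, and an independent-misreport model wins the AICc comparison
in every crowded cell.
`result.rates` holds the per-item report rates (the fitted β per
flanker role plus a `T` row with P_T); `result.comparison` the full
AICc table including the across-observer mean ΔAICc.

The same analysis from a shell:

```bash
crowdmix simulate --seed 5 --out trials.csv
crowdmix pipeline --trials trials.csv --seed 0 --out results/
crowdmix recover --seed 1 --replicates 10   # quick parameter-recovery check
```

(Exact fitted values above depend on the seeds shown; rerunning with the
same seeds reproduces them bit for bit.)

## Acceptance script

`scripts/acceptance.py` regenerates a large stimulus set with the
package's own design generator and measures the enforced minimum
target–flanker orientation separation:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It writes one JSON object per target quantity, each recomputed from
scratch at run time.
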