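# megcoh

Monte-Carlo assessment of how much Tikhonov regularization a minimum-norm
MEG inverse should use, depending on whether you map **oscillatory power**
or **seed-based corticocortical coherence**.

## The problem

MEG source estimation is ill-posed: thousands of cortical sources, a few
hundred sensors. The Minimum Norm Estimate (MNE) stabilizes it with a
quadratic penalty on the source currents,

```
Ŝ = argmin_S ‖Q^{-1/2}(M − L·S)‖² + λ²‖R^{-1/2}S‖²
W = R·Lᵀ·(L·R·Lᵀ + λ²·Q)⁻¹ ,      Ŝ = W·M
```

with `L` the lead field, `Q` the noise covariance, `R` the source covariance
(identity for classical MNE) and `λ²` the Tikhonov regularization weight.
Practitioners usually pick one `λ` per study and reuse it for every analysis.
But regularization smooths the solution, and smoothing hurts different
analyses differently: a power map keeps its peaks under heavy smoothing,
while a seed-based coherence map accumulates false positives, because
cross-talk makes every source look coupled to the seed. This package
quantifies that trade-off by simulation and reproduces, at desk scale, the
finding that **coherence mapping wants about two orders of magnitude less
regularization than power mapping**, and that the classic L-curve selection
under-regularizes both.

## What it does

- **geometry** — triangulated source spaces (icosphere, a "wrinkled" sphere
  emulating cortical folding, or any OBJ / FreeSurfer-ASCII mesh), Fibonacci
  sensor caps, and the Sarvas single-sphere lead field with the
  normal-orientation constraint.
- **simulate** — pairs of alpha-band (9–14 Hz) oscillators with jittered
  instantaneous frequency, calibrated in a loop to a target band coherence
  (0.1 / 0.2 / 0.4); patch or point sources; white sensor noise at an exact
  Frobenius-amplitude SNR (0 / −20 / −40 dB).
- **inverse** — the regularized operator above, a decade-spaced weight grid,
  and L-curve corner selection (maximum discrete curvature).
- **spectral** — Welch cross-spectra, band power maps and seed-based
  magnitude-squared coherence maps.
- **evaluation** — exact ROC/AUC detection scoring with reference-patch
  exclusion, paired two-tailed t-tests, optimal-weight aggregation.
- **pipeline** — the factorial study (location pairs × source size ×
  coupling × SNR), fully deterministic given one master seed, with CSV
  reports; also exposed as a `megcoh` command-line tool.

## Worked example

```python
from megcoh import OscillatorSpec, StudyConfig, generate_coupled_pair
from megcoh.pipeline import run_study

pair = generate_coupled_pair(OscillatorSpec(), target_coherence=0.4, rng_seed=7)
print("achieved coherence:", round(pair.achieved_coherence, 3),
      "after", pair.iterations_used, "draws")

cfg = StudyConfig(n_location_pairs=10, patch_areas=(0.0, 4.0), couplings=(0.4,),
                  snr_levels=(0.0, -20.0), master_seed=7)
result = run_study(cfg)
print("optimal weight (power):    ", result.optimal_weight_power)
print("optimal weight (coherence):", result.optimal_weight_coherence)
print("mean L-curve log10 weight: ", round(result.lcurve_mean_log10_weight, 2))
print(result.mean_auc_by_weight
      .pivot(index="reg_weight", columns="analysis", values="mean_auc").round(3))
```

prints

```
achieved coherence: 0.405 after 23 draws
optimal weight (power):     10.0
optimal weight (coherence): 0.1
mean L-curve log10 weight:  -1.18
analysis    coherence  power
reg_weight
0.001           0.754  0.636
0.010           0.816  0.670
0.100           0.878  0.737
1.000           0.847  0.810
10.000          0.729  0.841
100.000         0.579  0.826
1000.000        0.495  0.801
```

Reading the table: each row is one regularization weight; the columns are the
mean ROC area (AUC, 1 = perfect detection, 0.5 = chance) for detecting the
simulated patches in the power map and the coupled patch in the seed-based
coherence map. Coherence detection peaks at weight `1e-1`, power at `1e+1` —
two decades apart — and the average L-curve choice (`10^-1.18`) is more than
two decades below the power optimum. Larger studies sharpen these averages.

The same study runs from the shell:

```sh
megcoh run-study --config study.toml --out results/study
```

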