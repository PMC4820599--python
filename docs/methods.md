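# Methods

This note documents the models, numerical choices and limitations behind
`megcoh`. It covers what the code computes and why the defaults are what
they are; every number quoted here is produced by the package's own tests,
reports or the acceptance script, not asserted independently.

## Forward model

Sources are current dipoles at the vertices of a triangulated surface,
constrained to the outward vertex normal, so each source is a scalar
amplitude (orientation-constrained model). Sensor fields come from the
closed-form solution for a current dipole in a spherically symmetric
conductor (Sarvas solution). Two properties of that solution shape the
design:

- it depends only on the sphere **center**, not its radius or conductivity
  profile; and
- a **radially oriented dipole produces no external field at all**.

The second property makes the obvious synthetic source space — an icosphere
concentric with the conductor — exactly degenerate: every normal is radial
and the whole lead field vanishes to rounding error. Real cortex is folded,
so its normals point in all directions. The study surface therefore applies
smooth deterministic radial corrugations to the icosphere (default relative
amplitude 0.1, a fixed low-order angular pattern): vertex radii range over
7.2–8.8 cm and mesh normals tilt away from radial by up to ~28°
(median ~14°), giving every region a mixture of well-seen and poorly-seen
sources, as in real MEG. The pure icosphere builder is retained for
geometric tests and as a neutral mesh primitive; arbitrary triangle meshes
load from Wavefront OBJ or FreeSurfer ASCII.

Geometry defaults (head-centered Cartesian meters, z toward the sensor cap):
source shell 8 cm nominal radius, conductor sphere 9 cm, 150 radial
magnetometers on a 12 cm shell arranged as a Fibonacci lattice over the
upper 75% of the sphere. The 0.75 coverage emulates a whole-head helmet;
with only hemispheric coverage, sources below the equator are essentially
invisible and detection scores saturate near chance for a large fraction of
location pairs. An axial-gradiometer mode (5 cm baseline, field difference
between the two coils) is available but not the default: detection metrics,
not absolute field values, are the quantity of interest.

Vertex areas use barycentric lumping (one third of each incident triangle's
area); at subdivision level 2 the lumped areas sum to the analytic sphere
area within 3%. Patch growth is breadth-first over mesh edges from a seed
vertex, ring by ring, vertices within a ring ordered by Euclidean distance
to the seed, stopping as soon as the accumulated area reaches the target
(with 1e-9 relative slack for float accumulation). This edge-hop
approximation to geodesic growth is insensitive to the difference on
near-uniform meshes at the 2–8 cm² areas used here. A target of 0 cm²
yields a point-like source (one vertex).

The lead field is globally rescaled by its median column norm (one scalar,
no per-column depth weighting), removing the arbitrary physical amplitude
unit so that regularization weights are comparable across geometries.

## Synthetic coupled sources

Each source pair carries two alpha-band oscillators built by phase
integration: the instantaneous frequency is a 12 Hz base plus Gaussian
noise smoothed with a 50-sample moving average and rescaled to a 0.5 Hz
standard deviation; the signal is the cosine of the integrated phase,
normalized to zero mean and unit RMS. With these defaults ≥95% of spectral
power stays inside the 9–14 Hz band. Sample count and rate are 7000 at
600 Hz (≈11.7 s).

Band-limited magnitude-squared coherence between the two oscillators is
controlled by how much jitter they share. The second oscillator's frequency
perturbation is `ρ·pert₁ + √(1−ρ²)·pert_fresh`, with a fresh independent
realization drawn each iteration of a calibration loop; the loop accepts a
draw when the Welch band coherence (computed with the *same* estimator
settings as the analysis, so generator and analysis agree by construction)
lands within ±0.02 of the target, and otherwise nudges ρ toward the target
every 10 draws. A fully independent second jitter cannot reach high
coherence targets — the ceiling is set by the first oscillator's own phase
drift across Welch segments and varies between ~0.03 and ~0.4 per
realization — which is why the shared component exists. The loop typically
converges in under 25 draws at all three study targets (0.1 / 0.2 / 0.4);
target 1.0 short-circuits to an identical copy. Iteration budget: 2000,
after which a convergence error reports the best value reached.

Patch activity places the identical time series at every member vertex with
unit dipole amplitude. Sensor noise is i.i.d. Gaussian, rescaled so the
amplitude SNR `20·log10(‖L·S‖_F/‖N‖_F)` equals the requested level
*exactly*; the noise covariance `Q` is the empirical channel covariance of
the realized noise (ridge-stabilized by 1e-12·trace(Q)/n before use). The
20-log convention follows from the SNR being defined on amplitude norms.

## Inverse solution and weight grid

Classical MNE: `W = R·Lᵀ(L·R·Lᵀ + γQ)⁻¹` with `R = I`, solved by Cholesky
factorization (never an explicit inverse); `γ` is the composite Tikhonov
weight (the λ² multiplying Q). No depth weighting and no noise
normalization (dSPM/sLORETA) — deliberately the plain minimum-norm
solution. The Monte-Carlo loop evaluates all weights from one SVD of the
prewhitened gain `Q^{-1/2}L = U·diag(s)·Vᵀ`, whose filter factors are
`s/(s²+γ)`; a test verifies this path agrees with the direct solve to
1e-9.

The weight grid is decade-spaced with 7 values, default `1e-3 … 1e+3`. The
window was chosen by inspecting a pilot subset of simulations so that the
power and coherence detection optima and the typical L-curve corner all lie
well inside it — the same inspection procedure used to pick classic
`1e-11 … 1e-5` windows for physical-unit lead fields. Absolute weights are
tied to the unit-median-column normalization and unit source amplitudes;
only decade *ratios* between optima are meaningful quantities.

The L-curve records, per weight, the whitened residual norm
`‖Q^{-1/2}(M−LŜ)‖_F` and the solution norm `‖Ŝ‖_F`, both computed from the
SVD coefficients; the corner is the interior grid point with maximum
three-point circumscribed-circle (Menger) curvature of the log-log
polyline. A collinear curve raises a corner-undefined error suggesting a
wider grid.

## Spectral maps and scoring

Welch settings: 600-sample (1 s) Hann segments, 50% overlap, constant
detrend — 22 segments of a 7000-sample series, 1 Hz resolution. Band
statistics average over the bins whose centers lie in 9–14 Hz inclusive
(arithmetic mean, not peak — a stabler detection statistic). The scalar
estimators delegate to `scipy.signal`; the vectorized band-limited
cross-spectral matrices used by the study implement the identical estimator
and are tested for agreement with scipy to 1e-10.

Because the inverse is linear and Welch windowing acts along time, the
source cross-spectral matrix equals `W·C(f)·Wᵀ` with `C(f)` the sensor
cross-spectral matrix; the pipeline computes maps in that domain (one
`C(f)` per cell instead of one Welch pass per source and weight). A
dedicated test confirms the resulting AUCs equal the literal route —
apply inverse, Welch every source, map, score — at every grid weight.

Power maps are the band-averaged autospectrum per vertex. Coherence maps
are seed-based: band-averaged magnitude-squared coherence of every vertex's
reconstructed series against the reconstructed series at the first patch's
seed vertex. Ground truth for power is the union of both patches; for
coherence it is the second patch only, with the entire reference (first)
patch excluded from scoring — the seed's trivial self-coherence must not
count as a detection. Silent vertices (zero autospectrum) take coherence 0
by convention; an all-silent seed is an error.

ROC curves sweep the threshold over every distinct map value (exact ROC, no
resolution parameter); TPF divides by the number of truth vertices, FPF by
the remaining evaluable vertices, and the AUC is the trapezoidal area —
provably equal to the normalized Mann–Whitney U statistic, which the tests
check to 1e-12 including ties. Comparisons between weights use paired
two-tailed t-tests across configurations (paired, because each
configuration is scored under both weights).

## The factorial study

A study is `n_location_pairs` random seed-vertex pairs (uniform over
vertices, ≥3 cm apart, redrawn if their patches at the largest requested
area would overlap) crossed with source size (default point, 2, 4, 8 cm²),
coupling (0.1, 0.2, 0.4) and SNR (0, −20, −40 dB). At the original scale —
600 pairs × 4 × 3 × 3 — this is 21,600 configurations; the desk-scale
default uses 50 pairs, and the bundled scaled-down study drops the hardest
factor levels (8 cm², coupling 0.1, −40 dB) for 600 cells, which runs in a
few minutes on one CPU.

Seeding is counter-based: every cell's noise seed and every
(pair, coupling)'s time-series seed derive from the master seed via
`numpy.random.SeedSequence` spawn keys, so cells are independently
reproducible and order-free; one coupled pair draw is shared across the
area and SNR levels of a (pair, coupling) combination, so those factors
vary around identical source dynamics. Two runs with the same master seed
are bit-identical (tested). Individual cell failures are recorded and
skipped; more than 10% failed cells aborts the study.

Reports comprise the full study table (CSV, one row per cell × weight ×
analysis), mean-AUC-by-weight tables overall and per factor, the optimal
weights with grid-edge flags, paired t-tests between the two optima applied
to both analyses and against the per-cell L-curve choice, and a JSON
provenance record.

## What the desk-scale study shows (and does not)

At the scaled-down study conditions the coherence-optimal weight lands two
decades below the power-optimal weight with both optima interior to the
grid; the mean L-curve selection sits another ~0.3–1 decade below the
coherence optimum (i.e. ~2.3–3 decades below the power optimum) and is
significantly worse than either data-derived optimum; and using the
power-optimal weight for coherence mapping (or vice versa) costs detection
performance at p < 0.001. These reproduce the direction and decade
structure of the full-scale finding. What passing these checks does *not*
show: absolute weight values transfer to physical-unit lead fields (they do
not — only ratios are portable), or that the synthetic surface reproduces
cortical geometry. The noise is white and the two sources are the only
active ones; colored brain noise, third non-interacting sources and epoched
data are out of scope.

## Known limitations

- The wrinkled sphere is a stand-in for cortical folding: its
  orientation statistics are smoother than real sulci/gyri, and the
  642-vertex mesh makes "point-like" sources ~1.2 cm² of implicit support.
- The synthetic lead field is far better conditioned than a real
  275-channel × 15k-source gain matrix, so detection degrades more
  gracefully at the low-regularization end than it would with real
  anatomy (the coherence AUC curve plateaus rather than collapsing below
  its optimum).
- The L-curve corner is grid-quantized (decade resolution); the mean
  log-weight across cells is the meaningful summary.
- Patch growth uses edge-hop rings, not exact geodesics; achieved areas
  overshoot targets by up to one vertex area.
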