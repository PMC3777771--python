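# Methods

## Signal model and what the simulator emulates

The cohort generator stands in for beamformer-reconstructed source activity
in atlas regions. Each resting-state network (RSN) is modelled as a set of
regions sharing one narrowband stochastic carrier: with `z(t)` the analytic
signal of band-limited Gaussian noise, member *i* receives

    x_i(t) = c · Re[z(t) · e^{−iθ_i}] + (1 − c) · ξ_i(t) + σ · w_i(t),

where `c ∈ [0, 1]` is the coupling strength (shared amplitude fraction),
`θ_i` a fixed per-member phase offset, `ξ_i` an independent narrowband
process and `w_i` white noise (σ = 1 by default). Pairwise phase differences
concentrate at `θ_i − θ_j`; at `c = 1`, σ = 0 the lag is exactly constant and
the PLI is exactly 1. Member offsets are spread deterministically over
[π/6, 5π/6] so every within-network pair has a nonzero lag. Volume
conduction is emulated separately as instantaneous (zero-lag) linear mixing.

This is deliberately *not* a biophysical neural-mass model: phase-coupled
band-filtered noise is the simplest structure exposing exactly what the PLI
measures. The simulator omits 1/f spectral backgrounds, sensor-level
physics, head geometry, artifacts, and non-stationarity. Passing tests
therefore demonstrate the correctness and calibration of the *analysis*
under the stated coupling model, not robustness to every property of real
MEG. An optional voxel expansion (k = 3 jittered copies per region with
power scales 1, 1/2, 1/4) exercises representative-voxel selection.

## Coupling calibration

The map from coupling strength to PLI has no closed form; it is calibrated
once per recording configuration by Monte-Carlo simulation (fixed internal
seed, cached). Because the pair PLI also depends on the lag's distance to
the sign-flip boundaries {0, π}, the calibration is a 2-D grid — 11 coupling
levels × 5 boundary distances, 25 replicates per cell — and the generator
averages the grid over a network's actual pair lags before inverting it with
a monotone (PCHIP) spline. Injected effects are specified in PLI units
(`effect_size` = target per-pair PLI increase at T2); across replicate
cohorts the realized network-mean change lands within roughly 20% of the
target, which is adequate because every validation compares the pipeline to
replicate simulations under the *same* calibration, never to the nominal
target alone.

## Finite-sample PLI floor and epoch handling

PLI per epoch is |mean of sign(sin Δφ)|; the absolute value makes the
independent-pair expectation strictly positive at finite length (≈ 0.15 for
five 13.1 s epochs of a 2 Hz band, ≈ 0.19–0.21 for the reduced two-epoch
configurations used in replicate tests, since narrowband autocorrelation
leaves few effective samples). Baseline network PLI defaults to 0.25 —
above the floor and in the range observed for alpha-band within-network
coupling. Matrices are computed per epoch and averaged arithmetically
(avoiding phase discontinuities at epoch boundaries); a pooled
"concatenate" mode is available. 5% of samples per epoch edge are trimmed
before the sign-sine mean to discard Hilbert edge effects (configurable in
[0, 0.25]). sign(0) = 0 by convention, so a channel paired with its own
zero-lag copy scores exactly 0 and the diagonal is 0.

## Preprocessing choices

- Order of operations: decimate → band-filter → epoch, with bands defined
  relative to the post-decimation rate; this matches the 4096-sample /
  13.1072 s epoch arithmetic at 312.5 Hz.
- Filters: order-4 Butterworth band-pass applied forward-backward
  (`sosfiltfilt`), i.e. zero net group delay — the analysis is phase-based,
  so phase fidelity dominates the choice. The design was verified to keep
  ≥ 95% of white-noise output power in-band for all six bands and to
  attenuate ≥ 40 dB one octave outside the edges; a compensated linear-phase
  FIR family is available as an alternative. Decimation uses a zero-phase
  FIR anti-alias filter.
- Epochs are the first n non-overlapping blocks from the recording start
  (synthetic data has no artifacts to skip); an explicit start-index list
  reproduces a manual artifact-free selection.
- Pseudo-Z reduces to band-limited variance because the noise covariance is
  the identity; representative-voxel selection maximizes it per band but
  retains the winner's broad-band series, with ties broken toward the
  lowest voxel index.

## Statistics

- Wilcoxon signed ranks on subject-aligned T1/T2 values; zero differences
  dropped (Pratt's variant available), average ranks for ties,
  tie-corrected variance Σr²/4, no continuity correction; z is reported
  negative when T2 exceeds T1 (the convention of the classic statistical
  packages, under which an all-increase n = 10 sample gives z = −2.803).
  p-values are exact (full sign-flip distribution via dynamic programming,
  equivalent to 2^n enumeration) for n ≤ 15, else the normal approximation.
  The approximation tracks the exact p to within 0.01 wherever the exact p
  is ≤ 0.05 for 5 ≤ n ≤ 12; for mid-range p at very small n the
  discrepancy can reach ~0.1, which is why the exact method is the default
  at study sizes.
- FDR: Benjamini–Hochberg step-up at q = 0.05 within each band's family of
  network tests, never pooled across bands; the six global tests form their
  own family. BH rather than BY because the network statistics are
  positively dependent at worst. Note that one family {0.003, 0.027, 0.027,
  0.8} rejects *three* tests (step-up threshold 3q/4 = 0.0375); a 0.027
  only fails when it is the smallest p within its own band family.
- Kendall tau-b (tie-corrected) for the post-hoc stage; exact p for n ≤ 10
  on tie-free data, asymptotic otherwise; no multiplicity correction on the
  post-hoc correlations, matching uncorrected post-hoc reporting practice.
- Stage gating: only (band, network) cells surviving FDR are correlated
  with the six cognitive domains, using per-subject ΔPLI = mean_pli(T2) −
  mean_pli(T1); subjects missing cognition drop out of this stage only.

## Cognitive scoring

Subtests are polarity-corrected (timed tests flipped so higher = better),
standardized against the T1 group mean/SD (frozen and reused at T2), and
averaged into each domain they measure. The "overall" score is the mean of
all standardized subtests — a convention, since no aggregation rule for
published overall scores can be recovered; the bundled ten-subject
reference delta table is therefore exact per domain but its overall column
may follow a different convention than ours. Missing timepoints yield
missing deltas, never imputed.

## Study-condition defaults and validation problem sizes

Cohorts default to 10 subjects × 2 timepoints, five 4096-sample epochs at
312.5 Hz (generated directly at the analysis rate; a 1250 Hz/decimate-4
configuration exercises the decimation path), baseline network PLI 0.25
with per-subject coupling jitter SD 0.02, injected effect 0.05 PLI,
cognitive noise SD 0.5 z-units. The connectivity–cognition link slope used
in validation is 25 z-units per PLI unit, fixed by the replicate-simulation
oracle so that the planted correlation's sign is recovered in ≥ 95% of
detecting replicates. Replicate suites run at reduced sizes chosen as a
balance between Monte-Carlo resolution and runtime: null calibration uses
200 cohorts of 12 regions with two 2048-sample epochs; effect recovery uses
100 cohorts of four 4-region networks at full epoch count. RSN membership
in the shipped 78-region atlas configuration is a literature-based
approximation (data, not code — the YAML file is authoritative); the
anterior cingulate is assigned to the executive-control network so that the
default-mode network shares no within-network *pair* with the ECN or left
frontoparietal network, keeping injected-effect specificity exact.

## Known limitations

- The coupling→PLI calibration is Monte-Carlo: targets are met to ~10–20%,
  not exactly; effect sizes should be read as nominal.
- Networks sharing a region (not a pair) experience second-order leakage of
  an injected effect through amplitude renormalization; with the default
  memberships this is below measurement noise.
- The generator's exchangeability under the null holds by construction only
  when effect size and cognition links are zero.
- Exact Wilcoxon p-values are limited to n ≤ 15 (dynamic programming is
  exact but the distribution is discrete; at n = 10 the attainable
  two-sided test size at α = 0.05 is 0.0488, visible in null-calibration
  rates).
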