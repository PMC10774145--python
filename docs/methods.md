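# Methods

This note documents the models and procedures implemented in `holostim`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not establish.

## Neural-field model

### Dynamics and linearization

The circuit is described by excitatory (E) and inhibitory (I) rate fields on
a periodic square domain of side 1,400 µm crossed with an orientation axis
θ ∈ [0°, 180°).  Around the uniform spontaneous state (gray screen, low
gain), the steady-state response to a small added input factorizes per
Fourier mode; writing `W̃(k)` for the 2×2 population block of transformed
connectivity kernels, the E-rate perturbation is

    Δr̃_e(k) = [(I − W̃)⁻¹ W̃ r̃_stim]_e = (a + b·c)·s̃ / ((1 − a) − b·c),

with `a = W̃_ee`, `b = W̃_ei`, `c = W̃_ie`, `s̃` the transformed stimulation
field, and `W_ii = 0` (a single generic inhibitory population, no I→I
recurrence in the reduced model).  Because only the product `b·c` enters the
E response, the disynaptic inhibitory weight is carried as one effective
parameter `w_eie`, internally split as `w_ei = −w_eie`, `w_ie = 1`.

In the weak-coupling regime the inverse expands into synaptic pathways; the
package truncates at second order,

    Δr_e ≈ W_ee∗r_stim + W_ee∗W_ee∗r_stim + W_ei∗W_ie∗r_stim,

exposing the monosynaptic E→E, disynaptic E→E→E and disynaptic E→I→E terms
individually (`decompose_pathways`).  The exact per-mode inversion is kept
as a cross-check and refuses to run when any mode's spectral radius reaches
one, reporting the offending mode.  Both solvers are exactly linear in the
stimulus.

### Connectivity kernels

Connection strength is separable into space and orientation,

    W_αβ(x₁,θ₁; x₂,θ₂) = w_αβ · g(r; σ_β, κ_β) · h_β(θ₁−θ₂) / z ,

where `g` is a normalized mixture of a broad and a narrow 2-D Gaussian and
`h(Δθ) = r₀ + r_p e^{−Δθ²/(2σ_θ²)}` on the folded axis Δθ ∈ [0°, 90°].
Spatial profiles attach to the *presynaptic* population (projections out of
E use the E profile, out of I the I profile), and the normalization `z` is
fixed by requiring the discretized kernel — summed over space (weighted by
the grid-cell area) and orientation — to equal `w_αβ`, so the effective
weight is the total operator gain.

Defaults (all configurable in `ModelConfig`):

| parameter | default | meaning |
|---|---|---|
| `sigma_e_broad` | 110 µm | broad scale of E-outgoing projections (anatomical-tracing range) |
| `sigma_i_broad` | 90 µm | broad scale of I-outgoing projections |
| `sigma_e_narrow` | 15 µm | narrow (<50 µm) E wiring scale |
| `kappa_e` / `kappa_i` | 0.3 / 0 | narrow-scale weight; attached to recurrent excitation only |
| `w_ee` | 0.3 | effective E→E gain (swept in the regime experiment) |
| `w_eie` | 0.6 | effective disynaptic inhibitory gain (w_ei·w_ie) |
| `feature_ee` | (0, 1, 20°) | like-to-like E→E profile (r₀, r_p, σ_θ) |
| `feature_ei`, `feature_ie` | (0, 1, 25°) | like-to-like wiring through inhibition |
| `stim_amplitude` | 10 | added-rate mass per target |
| `grid_spacing` | 4 µm | 350×350 nodes; must be ≤ σ_e_narrow so the narrow scale is resolved |
| `n_orientations` | 4 | levels {0°, 45°, 90°, 135°}, matching 8-direction tuning granularity |

The broad scales are anatomically constrained; the narrow-scale and
feature-kernel parameters are not available as printed values anywhere, so
they were calibrated **once** against the qualitative regime the method is
about — (i) a w_ee-swept locus that passes through a ~33 µm zero crossing at
an activation/suppression ratio near 10 only when κ > 0, (ii) surround
suppression (50–150 µm) growing monotonically as a ten-target ensemble is
compacted, with the inhibitory pathway magnitude changing faster with spread
than the excitatory ones, and (iii) like-to-like E→E wiring alone producing
iso-oriented activation at all analyzed distances while adding like-to-like
E→I/I→E wiring flips iso-oriented cells beyond ~50 µm to suppression — and
then frozen.  Sharper inhibitory feature tuning than one might naively pick
(σ_θ = 25°, no untuned floor) is what lets disynaptic inhibition converge
onto co-tuned cells strongly enough for property (iii).

### Discretization choices

* δ-function stimulation: each target's mass lands on the nearest grid node
  and orientation level with density `amplitude / cell_area`, conserving the
  integrated input exactly; coincident targets accumulate.
* The orientation axis is a circulant lattice (circular convolution by FFT
  over all three axes); Δθ values are folded to [0°, 90°] before `h` is
  evaluated, so adding 180° to any preference is a no-op.
* Model-predicted per-cell responses (`predict_cell_responses`) embed the
  800 µm field of view centrally in the 1,400 µm domain, collapse imaging
  planes (the model is 2-D), and sample the solved field by bilinear
  interpolation at each cell's position and nearest orientation level.

### In-silico experiments

* **Regime locus** (`sweep_regime_locus`): single point stimulus, untuned
  kernels, orientation-averaged radial profile in 2 µm bins; the zero
  crossing is sign-change interpolated and the ratio is max activation over
  |max suppression| (zero when nothing is activated).  The default sweep is
  16 `w_ee` values × 4 κ values — denser in `w_ee` than a square grid
  because the locus moves quickly near its knee.  The "experimentally
  observed" rectangle is centered on the reference center–surround fit's
  (crossing, ratio) with half-width 7.5 µm in crossing and a factor 1.5 in
  ratio; the box construction from data at multiple bin widths
  (`data_regime_box`) is also provided.
* **Spread experiment** (`spread_pathway_experiment`): ten targets placed on
  a deterministic golden-angle spiral rescaled to the requested mean
  pairwise spread (spreads 60–400 µm by default), so geometry is identical
  across spreads up to scale.  Pathway "magnitude" is the L2 norm of the
  pathway field — the signed total mass of each pathway is
  spread-invariant by construction, so an L1-type measure would be blind to
  concentration.
* **Tuning modes** (`tuning_mode_experiment`): a cotuned ensemble (all
  targets at 0°) solved under three wiring modes (no feature dependence;
  tuned E→E only; all kernels tuned), reported as iso/45°/ortho distance
  curves in 15 µm bins to 300 µm (the range over which distance-resolved
  responses are analyzed).

## Analysis pipeline

* **ΔF/F**: `F = F_cell − c·F_neuropil` (c = 0.7 default), baseline `F0` a
  moving average of the rolling 10th percentile over a 1,000-frame (~3 min)
  window, `ΔF/F = (F − F0)/F0`.  Two numerical choices: the trace is
  low-passed (30-frame rolling mean) before the percentile — a low
  percentile of an unsmoothed noisy trace sits ~1.3 noise-SD below the true
  baseline and would inflate every amplitude — and the rolling percentile is
  evaluated at strided anchor frames (default every 50) with linear
  interpolation, since the exact rolling percentile is O(n·window) per cell;
  both degrees of freedom are exposed (`stride=1`, `presmooth=1` recover the
  exact estimator).  Cells whose baseline touches zero are flagged invalid,
  not clipped.
* **Trial responses**: mean ΔF/F over the stimulus frames plus one frame,
  minus the mean of the three frames before onset.  The window is a config
  value; the default reflects that at ~6 Hz the indicator integrates the
  1 s stimulation period with roughly one frame of decay lag.
* **Tuning**: responses to eight drift directions are folded by averaging
  opposite directions; OSI = (PO − OO)/(PO + OO) on the folded, rectified
  (≥0) curve, so OSI ∈ [0, 1] even with negative ΔF/F; flat or all-zero
  curves get OSI 0.  Visual responsiveness is a one-way ANOVA across the
  direction conditions plus the blank (p < 0.05).
* **Exclusions** (`apply_exclusions`), in the order FOV → ensemble → trial →
  cell, each rule audited: FOVs need ≥5% visually responsive cells, ≤50%
  running trials and ≥250 cells; ensembles are dropped when >33% of targets
  are undetected, >50% of their stimulation trials fail, or fewer than ten
  good repetitions remain; trials are dropped for running (>6 cm/s), ≥50%
  target failures (targets must reach 0.25 z-scored fluorescence), or
  registration shift >4.7 µm; cells are dropped per trial when inside an
  off-target zone (<15 µm radially on the same plane, <30 µm one plane
  away — targets themselves always), stimulated in the immediately
  preceding trial, occluded by the stimulation artifact (a boolean supplied
  by the data layer), or unmatched.  Cell rules are counted at
  (cell, trial) granularity with fixed precedence (off-target first), which
  makes the audit exactly enumerable on fixtures.  The filter is idempotent.
* **Distance curves**: per-(cell, ensemble) mean responses binned by the
  minimal 3-D distance to any attempted target (planes 30 µm apart; a 2-D
  option exists), bin edges {0, 15, 30, …}; empty bins are missing, not
  zero; sem uses the n−1 denominator and is missing for single-observation
  bins.
* **Center–surround fits**: `f(d) = A₁e^{−(d/σ₁)²} + A₂e^{−(d/σ₂)²}`,
  least squares with a 3×3 multi-start grid over the length scales.  Note
  the fit convention has no ½ factor in the exponent, unlike the wiring
  kernels — both conventions are kept as is.  The zero crossing has the
  closed form `d* = sqrt(ln(A₁/|A₂|) / (1/σ₁² − 1/σ₂²))` (checked against a
  bracketing root finder at 1e-9 µm), and the activation/suppression ratio
  is max f / |min f| over d ≥ 0.  End-to-end parameter recovery fits the
  raw (distance, response) pairs rather than binned means: with a 20 µm
  center and 15 µm bins, assigning a bin average to the bin center biases
  the extrapolated A₁.
* **Significance**: per cell, a seeded bootstrap (2,000 resamples) of the
  mean trial response; activated/suppressed requires the 99% percentile CI
  to exclude zero *and* survival of Benjamini–Hochberg FDR control at 1%
  across cells on the bootstrap sign-crossing p-values (+1-corrected).
  Cells with fewer than ten trials are flagged insufficient, not tested.
* **PPSF**: per-axis Gaussian fit (amplitude, center, width, baseline) of
  response versus hologram offset; FWHM = 2√(2 ln 2)·σ.

## Ensemble design optimizer

Targets are selected from the eligible (opsin-positive, matched) pool to
minimize a weighted cost with one hard constraint — no two members of an
ensemble within 30 µm.  Soft terms: squared deviation of spread, ensemble
OSI and mean member OSI from their requested window centers; a soft
within-ensemble crowding penalty (pairs closer than twice the hard minimum);
mean stimmable power (lower preferred); fraction of visually responsive
members (bonus); pairwise Jaccard overlap between ensembles; and a squared
per-cell reuse count across ensembles.  The functional forms and relative
weights are package choices (the criteria themselves name goals, not
formulas) and are exposed in `EnsembleSpec`.  Search is random-restart
greedy improvement over single-member swaps (20 restarts, 5,000-iteration
cap, 500-iteration stall) — accepted moves are strictly cost-decreasing, so
the cost trajectory is monotone; all randomness flows from
`EnsembleSpec.random_seed` and ties resolve by candidate order.

## Synthetic-data generator

The generator emulates the structure the analysis assumes: three 800 ×
800 µm planes 30 µm apart at 6 Hz; uniform cell positions; salt-and-pepper
orientation preferences over {0°, 45°, 90°, 135°} with Beta(2,2) OSIs;
a drifting-grating block (8 directions × 8 trials + blanks) and interleaved
ten-target stimulation trials (16 per ensemble; 1 s stimulation recorded as
ten pulses at 10 Hz).  Ground-truth nontarget responses are either a
center–surround distance profile times a relative-tuning weight, or the
neural-field model's own prediction.  Targets respond with the direct
amplitude (1 ΔF/F); cells inside the off-target zone receive a
direct-activation surrogate with the PPSF's falloff (HWHM 8 µm radial,
18 µm axial) so the exclusion logic has real work to do — the surrogate is
confined to that zone so that analyzed (non-excluded) cells carry exactly
the configured network ground truth.  A failed target (per-trial success
flags, Bernoulli 0.92, with 5% deliberately weak trials) loses its own
direct response.  Running trials (10%), large registration shifts (3%),
artifact-occluded (1%) and unmatched (2%) cells fire the corresponding
exclusion rules at known rates.

Traces are built as `F = F0·(1 + ΔF/F_true + drift) + c·F_neuropil` with a
per-cell baseline near 100, a slow shared drift, and exponential-decay
calcium transients (τ = 1.5 s, GCaMP6s-like; rise neglected at 6 Hz).  Two
calibration choices make round trips exact rather than approximately right:
transients are truncated at their trial's boundary (no cross-trial
bleed-through into the next baseline), and each transient is scaled so its
mean over the analysis window equals the prescribed response amplitude.
Noise is i.i.d. Gaussian per frame with SD = (0.2 ΔF/F)/SNR — the SNR is
referenced to the single-action-potential transient scale of the indicator,
so the default SNR 5 gives a per-frame noise floor of 0.04 ΔF/F, typical of
6 Hz two-photon data.  All draws flow from one root seed through named
substreams (positions, tuning, design, behavior, noise); identical configs
give byte-identical outputs.

What the generator does **not** emulate: spiking or indicator nonlinearity,
direction selectivity, correlated (shared) noise beyond the neuropil
background, motion artifacts at the image level, opsin expression gradients,
or any dependence of the network response on pulse rate.  Passing the
round-trip benchmarks therefore shows the *pipeline* is correct and
well-calibrated under the stated statistical structure — not that the
analysis is robust to every pathology of real recordings.

## Problem sizes

The default verification runs use a 350×350×4 grid for model experiments
(16×16×4 against the dense-matrix oracle, where an exact real-space solve is
feasible); synthetic end-to-end runs use 1,500 cells, 20 ensembles and ~3,800
frames, with smaller populations in unit tests.  These sizes were chosen so
the full suite completes in about a minute on a laptop-class machine.

## Known limitations

* Steady-state linear response only: no transient dynamics, no rate
  nonlinearity, no interneuron subtypes; higher-order pathways appear only
  through the exact inversion.
* The narrow-scale and feature-kernel defaults are calibrated choices, not
  measured values; conclusions that depend on their precise magnitudes
  (rather than the regime structure) should sweep them.
* Ensemble OSI classification near the 0.7/0.3 thresholds is sensitive to
  trial noise in the recomputed tuning curves.
* The strided percentile baseline assumes drift is slow relative to the
  anchor spacing (50 frames ≈ 8 s by default).
* `min_target_distance` defaults to 3-D (spread is always 3-D); the 2-D
  option changes near-bin occupancy and hence fitted center parameters.
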