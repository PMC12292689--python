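# Methods

This note records the models implemented by `pianorehab`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Signal model and preprocessing

Surface EMG is treated under the standard amplitude-cascade model: a slow,
non-negative neural-drive envelope multiplies a fast, zero-mean, broadband
carrier whose energy lies mostly below 150 Hz. Preprocessing
(`signal_io.preprocess`) resamples to the 400 Hz analysis rate with a
polyphase anti-aliasing filter, applies a 4th-order zero-phase Butterworth
band-pass (20–150 Hz default; the lower edge removes motion artifact, the
upper edge matches the energy band actually analyzed), an optional mains
notch (off by default), and removes the residual channel offset left by
filter edge transients. Rectification is exposed as a flag: it must be on
before NMF (non-negativity) and off before the wavelet transform (the CWT
of a rectified signal would mix envelope and carrier spectra).

No upsampling is performed; recordings below the target rate are rejected
rather than interpolated.

## Time–frequency tensorization

Each channel is correlated with a bank of complex Morlet wavelets

    psi(t) = sigma^(-1/2) pi^(-1/4) exp(j omega0 t) exp(-t^2 / (2 sigma^2)),

with sigma = 1, omega0 = 2 pi fc, fc = 0.849. The L2-normalized form is
used; at integer dilation a (in samples) the analyzed frequency is
fc * fs / a, so 30 scales at 400 Hz span 339.6 Hz (scale 1) down to
11.3 Hz (scale 30). This axis intentionally follows the per-scale reading
of the scale–frequency relation; it does not fully tile 0–150 Hz uniformly
— the bank is geometric in frequency, which is inherent to wavelet
analysis. Convolution uses zero padding with the central segment retained.

**Magnitude smoothing.** The tensor entries are |CWT| magnitudes smoothed
along time with a Gaussian kernel (sigma = 0.1 s default; 0 disables).
This is the tensor-domain analogue of rectify-and-smooth envelope
extraction in matrix-based synergy analysis, and it is load-bearing: the
magnitude of a wavelet response to a stochastic carrier is
Rayleigh-distributed around the amplitude envelope, and the Rayleigh
fluctuation carries an irreducible (4 − pi)/4 ≈ 21% of tensor power that no
low-rank model can explain. On raw magnitudes the best achievable FIT is
therefore ≈ 0.79 regardless of rank, and a ≥ 90% FIT criterion can never
fire. Smoothing over ~0.25 s (several carrier correlation times at every
scale that carries energy) suppresses the fluctuation while preserving the
synergy envelopes, whose bursts are slower. The smoothing width trades
envelope time-resolution against residual carrier noise; 0.1 s suits
activation bursts of ≥ 200 ms.

## Non-negative CP decomposition

The tensor is factorized as a sum of R rank-one outer products
F_r ∘ T_r ∘ S_r with all factors non-negative. The solver is alternating
least squares over the mode-n unfoldings with Khatri–Rao products, in the
update order S (spatial) → F (frequency) → T (temporal). Non-negativity is
enforced by clipping negative entries after each unconstrained update —
the minimal mechanism consistent with the constraints. Details:

- **Initialization**: |N(0, 1)| factors, rescaled so the initial
  reconstruction matches the data magnitude (an off-scale start can make
  the first clipped sweep raise the residual).
- **Safeguard**: clipped ALS is not provably monotone; after a two-sweep
  warm-up, any sweep that raises the residual is rejected and the run
  stops at the previous iterate.
- **Convergence**: relative FIT change < 1e-5 or 200 sweeps; 5 seeded
  restarts, best FIT kept; per-restart FITs are retained for rank
  selection.
- **Normalization**: spatial columns are unit-norm with the scale absorbed
  into T, so muscle weights are comparable across subjects.
- **Degenerate input**: the all-zero tensor is assigned FIT = 1 (the zero
  model reconstructs it perfectly) with zero factors.

FIT is the standard relative reconstruction quality
1 − ‖X − X̂‖²_F / ‖X‖²_F: 1 iff exact, 0 for the null model, possibly
negative for a model worse than null.

**Rank selection** returns the smallest R whose mean FIT over restarts
reaches 0.90 while the gain from R+1 is at most 0.02; if no rank qualifies
the argmax-FIT rank is returned flagged. r_max is clipped to the smallest
tensor dimension. On tensors whose latent components have near-collinear
spatial signatures the rule is structurally blind — a component
contributing < 2% of tensor energy is indistinguishable from the
increment-stopping condition — which is why the synthetic generator draws
identifiable (one-dominant-muscle) weight columns (below).

The 2-D path is classical Lee–Seung multiplicative-update NMF (Frobenius
loss, provably non-increasing objective, history recorded), rank 2 by
default for the fatigue pipeline, with the same restart and normalization
conventions.

## Similarity assessment

Components of a subject and a reference model are paired once, by optimal
assignment on the Pearson correlations of spatial columns (deterministic
tie-break), and that pairing is reused for the frequency and temporal
comparisons — one consistent pairing avoids per-domain cherry-picking.
Temporal factors of unequal length are linearly resampled to the reference
length. Negative correlations are reported as-is. Similarity is invariant
to per-component positive rescaling and symmetric in the two models up to
pairing inversion. When ranks differ, the extra components of the
larger model are reported unpaired.

## Fatigue features and the CMFI

Windows are 1 s with 50% overlap: at 400 Hz this gives enough samples for
a stable spectrum while keeping the index responsive. Per window and
muscle:

- **RMS** — quadratic mean (rises with fatigue);
- **MF** — median of the Welch PSD (segment ≤ 256 samples, 50% overlap),
  crossing found by linear interpolation of cumulative power (falls);
- **PE** — permutation entropy, order 4, delay 1, normalized by log 4!
  (falls; 0 for constant or monotone windows);
- **FD** — Higuchi fractal dimension, k_max = 8 (falls; 1 for a line).

Features are min-max normalized over the recording and the three
decreasing features inverted, so every normalized feature increases with
fatigue; a `baseline_relative` mode normalizes against the first windows
instead, for online use where the session extrema are unknown. Degenerate
(zero-range) features normalize to 0 with a warning.

The per-muscle index is the convex combination I_FMI = T_R rf + T_M mf +
T_P pf + T_F ff. Weights default to 0.25 each and can be calibrated by
non-negative least squares of a fatigue reference (e.g. a perceived
exertion series) on the channel-averaged normalized features,
renormalized to sum 1; degenerate designs fall back to equal weights with
a warning.

The dominant synergy mode per sample is the argmax of the NMF activation
coefficients (ties to the lower index), aggregated to window level by
majority vote. The DMWCM column for a window is the muscle-weight column
of its dominant mode, renormalized to sum 1 so the CMFI
I_CFMI = Σ_i s_i^main · I_i^FMI is a convex combination — without this
renormalization the CMFI scale would depend on the arbitrary NMF factor
scaling. Monitoring raises a rest flag when the CMFI reaches the threshold
(0.7 default) and clears it below the resume level (0.6 default):
hysteresis prevents flag chatter near the threshold.

## Synthetic data generator

`synthgen` emulates the two study conditions end to end:

- **Synergy recordings**: channel i is Σ_r W_ir H_r(t) · c_i(t) + ε, with
  unit-variance Gaussian carriers band-passed to 20–150 Hz (independent
  per channel), Gaussian-burst activations (distinct main burst per
  component, peak 1), and additive N(0, noise_sd²) noise. Weight columns
  are drawn with one dominant muscle per synergy plus small co-activation:
  physiologically plausible, and necessary for the latent rank to be
  identifiable at all (see rank selection above). Default condition:
  4 channels, R = 3, 3 s at 400 Hz, noise power 5% of envelope power.
- **Fatigue sessions** (default 3 min, 400 Hz, 4 channels): a programmed
  per-feature ramp (RMS ×1.0→1.5, MF ×1.0→0.7, PE and FD ×1.0→0.8 by
  default) drives one coherent mechanism — a time-varying first-order
  low-pass whose cutoff tracks the MF ramp compresses the spectrum, an
  amplitude-whitening stage then imposes the RMS ramp exactly, and a
  slowly growing deterministic 2 Hz component (share tied to the PE/FD
  ramps) lowers signal complexity. The returned ground truth is the
  linear fatigue progress in [0, 1].

What the generator does *not* emulate: motor-unit action potentials,
electrode placement and crosstalk, inter-subject variability,
nonstationary task content, movement artifact. Passing tests therefore
demonstrate correctness of the algorithms under the stated signal model,
not clinical validity on patient recordings.

## Biomechanical simulator

Planar sagittal model per finger (flexion–extension only): phalanges are
uniform rods (lengths/masses per link; anthropometric index-finger
defaults), giving a configuration-dependent inertia matrix assembled from
COM Jacobians; Coriolis/centrifugal torques use Christoffel symbols with
dM/dθ by central finite differences (h = 1e-6). The key is a spring–damper
acting only in contact (compression = fingertip excursion past the key
top, capped at key travel; the key pushes, never pulls) through the
fingertip Jacobian transpose. The exoskeleton contributes passive
inertia/damping/structural-stiffness dynamics about a gravity-compensated
equilibrium *and* an active PD drive toward the desired trajectory — the
passive and active roles are deliberately separated. Reflected actuator
inertia (1e-3 kg m² per joint default) dominates the tiny phalanx inertias
and sets the system time scale; gains must be chosen against it or the
explicit integrator becomes stiffness-limited.

Hill-type muscle torque: F_max · f_l(l̃) · f_v(ṽ) · α · r_m(θ) with
f_l(l̃) = exp(−((l̃ − 1)/0.45)²), Hill hyperbolic f_v (shape 0.25,
eccentric branch saturating at 1.5), activation clamped to [0, 1] with a
warning, and the moment arm as the central finite difference of the
musculotendon length (virtual-work identity). Assistive force per joint is
Fa = τ/d_joint with d_joint the distance from the exoskeleton force
application point to the joint center (half link length by default).

Integration is fixed-step RK4, dt = 1 ms default, dt ≤ 2 ms enforced;
gravity is optional and off by default (key pressing is dominated by
actuation, and the energy-dissipation property is cleanest without it).
Divergence (non-finite state) raises an error carrying the last valid
time.

## Problem sizes and verification

The test suite and the acceptance script run entirely on generated data at
desk scale: 3 s × 4 channel tensors (30 × 1200 × 4) for synergy extraction,
40–180 s sessions for fatigue, ≤ 1.5 s simulations at 1 ms steps.
Independent oracles used in tests: a 200-restart bounded L-BFGS
factorization oracle on ≤ 4×6×3 tensors, scikit-learn NMF, Monte-Carlo
power/ramp statistics over 20–50 seeds, finite-difference Jacobians, and
closed forms (sine RMS = A/√2, spectral symmetry of MF, single-pattern
permutation entropy, unit fractal dimension of a line, RK4 order-4 error
scaling).

## Known limitations

- The wavelet frequency axis is geometric and does not cover 0–11 Hz;
  very slow envelope energy appears only through the magnitude smoothing.
- Clipped ALS is a heuristic for non-negative CP; it matches a dense
  multi-start oracle on small problems but carries no global guarantee.
- The CMFI depends on the min-max normalization window; the
  recording-level mode is retrospective, and the baseline-relative mode
  trades exactness of the [0, 1] range for online usability.
- The finger model omits abduction/adduction, joint limits, tendon
  routing across multiple joints, and soft-tissue contact compliance.
- Synthetic validation bounds transfer to real recordings only to the
  extent the amplitude-cascade signal model holds.
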