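# pianorehab

Analysis toolkit for piano-based hand rehabilitation: muscle-synergy
extraction from multichannel surface EMG by non-negative tensor
factorization, synergy-similarity assessment of rehabilitation progress,
real-time multi-muscle fatigue monitoring, and forward simulation of the
key–finger–exoskeleton biomechanics.

It is written for researchers and engineers building task-oriented hand
rehabilitation systems who need (a) an objective, EMG-based measure of how
closely a patient's muscle coordination approaches a healthy reference and
(b) an online fatigue index that can pause training before overexertion —
plus a physics model of the finger pressing a piano key under exoskeleton
assistance.

## Methods at a glance

**3-D muscle synergies.** Each preprocessed EMG channel (band-passed
20–150 Hz, 400 Hz) is transformed with a complex Morlet wavelet bank
(ψ(t) = σ^{-1/2} π^{-1/4} e^{jω₀t} e^{-t²/2σ²}, 30 integer scales, scale *a*
analyzing *f = f_c·F_s/a* with f_c ≈ 0.849). Stacking the smoothed
scalogram magnitudes over channels gives a non-negative frequency × time ×
space tensor **E**, factorized as

    E ≈ Σ_{r=1..R}  F_r ∘ T_r ∘ S_r,    F, T, S ≥ 0

by alternating least squares over the mode-n unfoldings with clipping
(CP-ALS), quality scored by FIT = 1 − ‖E − Ê‖²_F / ‖E‖²_F. The synergy
count R is the smallest rank with mean FIT ≥ 90% and a ≤ 2-point gain from
one more synergy. Rehabilitation progress is the per-component Pearson
correlation of a subject's S (spatial), F (frequency) and T (temporal)
factors against a reference model, after optimal spatial matching.

**Fatigue monitoring.** Sliding windows (1 s, 50% overlap) yield four
features per muscle: RMS amplitude (rises with fatigue), median frequency,
permutation entropy and Higuchi fractal dimension (all fall). After min-max
normalization and direction alignment they combine into a per-muscle index
I_FMI = T_R·rf + T_M·mf + T_P·pf + T_F·ff with convex weights (equal by
default, calibratable by non-negative least squares against a fatigue
reference). A rank-2 NMF of the rectified EMG identifies the momentarily
dominant synergy mode; its muscle-weight column (the DMWCM, normalized to
sum 1) mixes the per-muscle indices into the scalar CMFI, monitored with a
threshold/hysteresis rule that prompts rest.

**Biomechanics.** The finger is a planar rigid-link chain (three phalanges,
two for the thumb), the key a spring–damper F = k_s·x_k + b_s·ẋ_k acting
through the fingertip Jacobian transpose, the exoskeleton a passive
inertia–damping–stiffness element plus an active PD drive
τ_e = K_p(θ_d − θ) + K_d(θ̇_d − θ̇), and muscle torques follow a Hill-type
model τ_m = F_max · f(l̃) · f(ṽ) · α(t) · r_m(θ) with the moment arm
r_m = ∂l_mt/∂θ. The coupled dynamics are integrated with fixed-step RK4.

Because no public recordings exist for this protocol, the `synthgen` module
generates sEMG with *known* ground truth — band-limited stochastic carriers
amplitude-modulated by a known synergy envelope, and fatigue sessions with
programmed feature ramps — so every stage is testable end to end.

## Worked example

```python
import numpy as np
from pianorehab import synthgen, tfr
from pianorehab.decomposition import select_rank, cp_als

truth = synthgen.SynergyGroundTruth.random(rank=3, channels=4,
                                           samples=1200, fs=400.0, seed=7)
env = truth.muscle_weights @ truth.activations
truth.noise_sd = float(np.sqrt(0.05 * np.mean(env**2)))   # 5% noise power
rec = synthgen.generate_synergy_emg(truth, fs=400.0)

tensor = tfr.build_emg_tensor(rec, tfr.WaveletConfig())   # (30, 1200, 4)
sel = select_rank(tensor, r_max=6, restarts=5, seed=92)
model = cp_als(tensor, sel.rank, seed=92, restarts=5)
print(sel.rank, [round(f, 4) for f in sel.fit_curve], round(model.fit, 4))
```

prints

```
3 [0.6529, 0.8524, 0.9607, 0.9806] 0.9609
```

— the rule recovers the generator's three synergies (mean FIT crosses 90%
at rank 3 and gains only 2 points at rank 4), and the rank-3 model
reconstructs 96% of the tensor. The recovered muscle-weight columns match
the generating ones (one dominant muscle per synergy) up to permutation:

```
model.S ≈ [[0.18, 0.95, 0.05],      truth.muscle_weights ≈ [[0.99, 0.04, 0.04],
           [0.19, 0.26, 1.00],                               [0.13, 0.98, 0.14],
           [0.95, 0.00, 0.01],                               [0.01, 0.18, 0.99],
           [0.15, 0.16, 0.09]]                               [0.09, 0.07, 0.05]]
```

For fatigue, a 3-minute session with programmed ramps (RMS ×1.5, MF ×0.7,
PE/FD ×0.8) gives a CMFI trajectory rising from 0.24 to 0.77 over 359
windows that tracks the programmed ramp with Pearson r = 0.965, raising
the rest flag in 39 windows past the 0.7 threshold:

```python
from pianorehab import fatigue
program = synthgen.FatigueProgram(duration_s=180.0, seed=11)
rec, level = synthgen.generate_fatigue_emg(program, channels=4)
series = fatigue.fatigue_pipeline(rec, rank=2, seed=11, threshold=0.7)
```

The same stages are scriptable from a shell via the `pianorehab` CLI
(`synth`, `tensorize`, `decompose`, `assess`, `fatigue`, `simulate`); every
run writes a JSON manifest with its seed and config hash.

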