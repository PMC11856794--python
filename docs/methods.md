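# Methods

## Inverse problem and its assumptions

The probe is modelled as an undamped, uniform Euler–Bernoulli cantilever:
slender (length ≫ diameter), linear-elastic, with shear deformation,
rotary inertia, gravity and fluid loading neglected.  The tissue hook at
the free end prescribes the transverse displacement and transmits no
bending moment.  Under these assumptions each displacement harmonic maps
*exactly* to a force harmonic through the modal solution, so the inverse
problem is solved per harmonic in closed form; no regularisation is needed
as long as every retained harmonic stays clear of the clamped–pinned
resonances where the tip-condition determinant
`D(κ) = 2(cosh κ sin κ − cos κ sinh κ)` vanishes (first root κ ≈ 3.9266).
The resonance guard refuses (or optionally drops) harmonics above 80 % of
the first such resonance.  For the default probe (ϕ0.2 mm silver wire,
`L = 10 mm`, ρ = 10.5 g/cm³, E = 83 GPa) that guard sits near 2.76 kHz —
far above anything a 60 fps camera can encode — and the first *free*
cantilever resonance is ≈ 787 Hz, so beating at a few Hz is deeply
quasi-static and the dynamic machinery mostly provides a verified error
bound.  A deliberately compliant test probe (`L = 100 mm`, f₁ ≈ 7.9 Hz)
exercises the genuinely dynamic regime, where the inversion departs from
the static mapping by tens of percent and still round-trips against the
forward oracle to about 1 %.

Two printed-formula ambiguities were resolved on dimensional grounds and
are recorded in every run's provenance: the tip shear is evaluated as
`EI·y‴(L)` (only this has units of force, and it reproduces the static
term `3S₀EI/(2L³)`), with the sign fixed so the quasi-static limit is
`+3EI S/L³`; and the second modal coefficient is evaluated at `κ = kL`
(a position-dependent coefficient would contradict the separation ansatz).
Both choices are verified against the independent forward oracle.

The undamped model also means fluid damping of the wire in culture medium
is not inverted for.  The oracle supports optional mass- and
stiffness-proportional damping so the inversion's robustness to unmodelled
dissipation can be probed; at the sub-resonance frequency ratios of the
default probe the induced bias is far below the round-trip error bound.

## Spectral estimation of the beat waveform

The displacement record is truncated to an integer number of beat periods
(fundamental located as the dominant DFT bin, refined with Jacobsen's
three-bin estimator — exact for integer-period records) and expanded as
the Fourier *series* of the periodic beat: only harmonics of the beat
fundamental are retained, which synchronously averages the beats in the
record.  Off-comb bins carry measurement noise and beat-to-beat
variability; their median power provides a robust estimate of the white
noise floor, which is subtracted from the comb amplitudes in the power
domain (spectral subtraction — an exact no-op on noiseless records).
`window=None` disables truncation, comb selection and denoising for
non-periodic records.  Defaults: 25 beat harmonics, relative amplitude
floor 1e-3.  The DC term is never detrended: it carries the static
pre-stretch of the probe, so displacement must be referenced to the
unloaded cantilever position.

## Beat kinetics

Within each segmented beat window, forces are measured relative to a
diastolic baseline estimated as the 10th percentile of the window (the
window minimum is biased low by ~1.5–2 σ of any residual noise, which
would inflate `B_m` by several percent at camera noise levels;
`window_min` and `none` remain available).  The peak (`B_m`, `T_m`) is
refined by a parabola through the three samples bracketing the maximum —
60 fps grids are coarse relative to twitch peaks — and the 20 % threshold
crossings `T₁`, `T₂` are located by linear interpolation.  `FI` integrates
the baseline-subtracted force between the crossings by the trapezoid rule
with interpolated endpoints.  "Beating start" is operationalised as the
last upward 20 % crossing before the peak, which is robust to baseline
noise.  Segmentation finds prominent peaks (default ≥ 20 % of the global
range) and then re-runs with a refractory distance locked to the median
inter-peak interval, so diastolic noise bumps between genuine beats are
rejected.

## Synthetic study conditions

The generator emulates the measurement as the package expects to meet it:
a 10 µN, 1 Hz twitch train on the default probe, recorded at 60 fps with
a 65 nm/px camera scale (100× objective, 6.5 µm sensor pixels) and 0.5 px
Gaussian tracking noise followed by pixel quantisation.  The twitch pulse
is an alpha-function-like product of a saturating rise and an exponential
decay; the periodic steady state superposes pulse tails so the waveform is
smooth across period boundaries.  Preset time constants (atrial: rise
0.04 s, decay 0.06 s; ventricular: 0.10 s, 0.18 s) are fabricated working
values chosen only to realise the atrial/ventricular ordering of the
normalised kinetics; they are not measurements.  Generator truth for
recovery tests is defined as the metric definitions applied to the
noiseless periodic waveform on a dense grid, with the same baseline
convention as the analysis — truth and estimate then differ only by what
the measurement chain destroys.

What the generator does *not* emulate: beat-rate drift and arrhythmia,
beat-to-beat amplitude variability, gel viscoelasticity, focus drift,
illumination changes, and out-of-axis motion.  Passing tests therefore
demonstrate correctness of the mechanics and estimation chain under
controlled conditions, not robustness to every artefact of live
microscopy.

Noise is applied as jitter *then* quantisation (dithered quantisation):
noise reaches the tracker before the pixel grid rounds the reading, and
dither at or above half a pixel whitens the quantisation error.  Rounding
the noise-free periodic signal first would imprint the deterministic pixel
staircase — with strong in-band harmonics — onto every beat.

## Forward oracle

The finite-difference simulator discretises the beam equation on 50
spatial elements with ghost nodes: `y₋₁ = y₁` at the clamp, zero tip
moment, and the tip force entering through the third-derivative ghost
condition.  Static tip deflection converges to `PL³/3EI` at O(h²)
(0.08 % at 25 elements) and the free-vibration frequency matches the
closed-form eigenvalue to < 0.01 %.  Time integration is a Newmark scheme
with γ = 0.55 (unconditionally stable; the small offset above ½ adds
algorithmic damping only to spatial modes the step cannot resolve), so the
step is chosen for accuracy of the forcing band — default half the
applied-force grid spacing, 0.25 ms in the shipped studies — rather than
by an explicit-scheme stability bound, which would demand ~0.1 µs steps
for the stiff probe.  Forward simulations soft-start the twitch train with
a two-beat raised-cosine ramp and discard a four-beat settling window, so
the analysed displacement is the periodic steady state rather than a
superposition with the undamped free transient.

The oracle shares no modal code with the analytic inversion; their
agreement (force → displacement → force RMS mismatch ≤ ~1.5 % of peak
across 0.5–5 Hz on the stiff probe and sub-resonance rates on the
compliant one, measured at 240 Hz output with 8 recorded beats) is the
method's primary verification.

## Problem sizes and replicates

The shipped verification studies use 8 recorded beats (plus 2 ramp and
2 settle) for round-trip checks, 20 recorded beats for noisy parameter
recovery, 10 replicate noise seeds averaged for recovery statistics, and
100 seeded runs for the subtype-ordering frequency.  Peak-time estimation
on a round-topped twitch is the noise-limiting step: the ventricular peak
varies by only ~0.5 % over ±12 ms, so a single noisy record determines
`T_m` to roughly ±10 ms and `F′_c` to ~5–10 %; replicate averaging is the
appropriate remedy and is what the recovery study reports.

## Tip tracking

Tracking is 1-D along a user-chosen axis: a fixed reference patch around
the darkest feature of frame 0 (the hook) is matched by normalised
cross-correlation over integer shifts with parabolic sub-pixel refinement.
A fixed (not rolling) reference avoids drift accumulation on periodic
motion.  The peak correlation is the per-frame confidence; low-confidence
frames are interpolated from confident neighbours with a warning.  On
rendered ground truth the tracker achieves ~0.05 px displacement RMSE and
< 0.02 px interpolation bias; absolute positions carry an arbitrary
sub-pixel offset from the integer template centre, so displacements (not
absolute positions) are the meaningful output.

## Stimulus scheduler

The bioreactor model locks stretch and pulse timing to the motor rate γ:
one half-sine stretch (peak strain ε_m, width τ ≈ half the period) and one
rectangular electrical pulse (amplitude E_m, width υ, delay δ after
stretch onset) per rotation.  The shipped operating points are 1 Hz and
5 Hz with ε_m = 0.05, E_m = 100 mV, υ = 1 ms, δ = 0.

## Known limitations

* The working length `L` enters as `L³` in the static term; it is a
  required, sample-specific input and the dominant calibration
  uncertainty for real data.
* Comb-selection assumes a stable beat rate over the record; drifting
  rhythms need `window=None` and lose the noise averaging.
* The kinetics are reported per beat with mean ± SD only; group
  significance testing is out of scope.
* Forces at different static stretch ratios are reported as-is; no
  active/passive decomposition is attempted.
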