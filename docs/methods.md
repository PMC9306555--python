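# Methods

This note documents the models and numerical choices behind `navb0`:
what is computed, which parameters matter, what the synthetic scene
does and does not emulate, and where the design was genuinely open.

## The off-resonance model

The method assumes the per-frame field perturbation is spatially linear
over the imaging FOV, `Δω_p(r)/2π = Δf_0 + b·r` with `b` in Hz/m. For
EPI, a linear field is equivalent to a k-space shift that grows
linearly with time from excitation: a line acquired at time `t` is
displaced by `b_a · FOV_a · t` samples along axis `a`. With navigator
lines at echo indices 1, 2, 3 (constant echo spacing), line `l` carries
the shift `b_l = c + l·d`; `d_a = b_a · FOV_a · esp` samples per echo
and `c` absorbs any shift present at the first navigator echo. The
zeroth-order term `Δf_0` is not part of this six-coefficient model; it
is removed beforehand by its own correction step (below).

Unit conventions: times in seconds, fields in Hz, shim gradients in
µT/m with `γ̄ = 42.577478518 MHz/T`; k-space indices have DC at
`n // 2` on every axis, and a `+δ`-sample k-shift corresponds to the
image-domain ramp `exp(-2πi δ u)`, `u = (index - n//2)/n`.

## GRAPPA shift operators

`train_operator` solves the single-source-point form of GRAPPA: one
`J×J` matrix per axis mapping the channel vector at every k-space
location to the vector one sample further along that axis, fit by
Tikhonov-regularized least squares over all neighbor pairs in the
fully sampled calibration (default ridge `(1e-4 · σ_max)²` added to the
source Gram matrix). Sub-sample shifts are fractional matrix powers via
eigendecomposition with the principal branch of the complex power; a
Schur-based power is the fallback when the eigenbasis condition number
exceeds 1e8. Matrix-level identities (`G^0 = I`, `G^a G^b = G^{a+b}`,
`G^δ G^{-δ} = I`) therefore hold to machine precision; data-level shift
fidelity is limited by how well the coil-profile family is closed under
multiplication by a one-period phase ramp (2–5 % NRMSE per unit shift
on the standard scene).

The slice-axis operator needs 3D k-space structure, which SMS
acquisitions lack; it is trained on a proxy 3D calibration volume:
reconstructed calibration slices are stacked at their encoded plane
positions, all other planes zero, and the stack is Fourier-transformed
along the slice axis. Two hardening measures matter here:

* **Excited-slice placement.** The default scene excites the centered
  pair of the stack (planes {1, 3} of 4), i.e. positions symmetric
  about the z origin. Placing a slice at the stack edge puts its ideal
  slice-operator eigenvalue at `e^{iπ} = -1`, exactly on the branch cut
  of the principal complex power, where fractional kz shifts become
  sign-unstable.
* **Eigenvalue modulus floor** (`min_eig_modulus`, default 0.5 for the
  slice axis). The proxy volume's signal spans only the encoded
  planes, so weakly determined operator modes come out with small
  eigenvalue moduli and explode under negative fractional powers; an
  ideal shift operator is unitary on the signal subspace, so flooring
  the moduli is a conditioning repair, not a model change.

## Coefficient estimation

`OffResonanceModel.fit` minimizes the stacked three-line residual
`Σ_l ‖S_l^p − G^{c+l·d} S_l^0‖²` (normalized by the navigator energy).
The objective is nonlinear in the operator exponents, so the solver is
hierarchical: per-line readout shifts are first read off the
phase-ramp slope of the hybrid-space cross-product (the navigator is
fully sampled along the readout), giving `(c_x, d_x)` initial values;
the joint coefficient vector is then refined with Nelder–Mead
(`xatol = 1e-5`, soft barrier at ±1 sample — the calibrated validity
range of a unit-shift operator). The fit is deterministic given its
inputs. Axes without a trained operator are held at zero. A navigator
whose RMS amplitude falls below an (optional) noise floor returns a
zero estimate flagged `low_confidence`.

The optional `d_y` refinement follows the estimation step: `d_y` is the
least-constrained coefficient (a single ky line constrains the
phase-encode axis only through coil encoding), so it is perturbed on a
grid (default ±0.05 samples, 11 points) and the value maximizing the
Pearson correlation between the corrected intermediate reconstruction
and the fully sampled reference image wins; a flat correlation profile
(spread < 1e-4) keeps the initial value. Only `d_y` is refined.

## Per-frame correction

Each acquired imaging line at echo index `n = t_n / esp` has accrued
the shift `c + n·d`; `correct_frame` applies the inverse. The plain
contract applies `compose_shifts(-b(n))` per line with the trained
operators (axis order x → y → z, part of the contract since trained
operators do not commute exactly). The reconstruction pipeline enables
three refinements of the same model, chosen after observing that the
unregularized operators — though exquisitely accurate on noiseless
data — are strongly non-normal (spectral norms ≫ 1) and amplify
measurement noise under per-line fractional powers:

1. **Exact readout shifts** (`readout_exact`): the readout axis is
   fully sampled, so its per-line shift has a closed form (Fourier
   shift theorem), noise-neutral and exact.
2. **Constant/differential split** (`split_constant`): the
   phase-encode shift decomposes into a frame-constant part
   `c_y + n_center·d_y` (the shift accrued at the k-space center
   crossing) plus the echo-differential remainder `(n − n_center)·d_y`.
   The constant part of a k-shift is exactly an image-domain phase
   ramp on the acquired-line grid (the multiplicative CAIPI pattern
   commutes with it up to a benign constant per-slice phase); only the
   small differential part goes through operator powers, which keeps
   the high-energy central lines near identity.
3. **Noise-matched operators with direction matching**: the correction
   operator set is trained with a Wiener-level ridge `n_columns · σ²`
   (σ² the per-sample noise variance, measured as the mean squared
   difference between the reference frame and the collapsed
   calibration, which repeat the same signal), and negative shifts use
   a backward-trained operator under positive powers, so weakly
   encoded modes are damped rather than inverted.

Estimation keeps the high-fidelity (lightly regularized) operators:
its exponents are at most `3·|d| ≈ 0.3` samples, where noise gain is
negligible and accuracy dominates.

## Baseline reconstruction chain

Fixed order: Nyquist ghost correction → dynamic zeroth-order B0
correction → off-resonance estimation + correction → split-slice
GRAPPA SMS unaliasing → in-plane GRAPPA → root-sum-of-squares.

* **Ghost correction**: navigator lines 1/3 share readout polarity and
  line 2 opposes them; the 0th+1st-order phase of
  `p_2 · conj((p_1+p_3)/2)` in hybrid x-space (the averaging cancels
  linear inter-echo phase evolution) is removed from all even-echo
  lines, navigator included, which makes the step idempotent.
* **Zeroth-order B0**: the global offset is the difference in
  inter-line phase advance between the frame's navigator and the
  reference navigator, removed as `exp(+2πi Δf t_n)` per line.
* **Split-slice GRAPPA**: per-slice 5×5-tap kernels on the
  acquired-line grid, trained with the split objective (reproduce the
  own slice, null every other slice) against the CAIPI-phased per-slice
  calibrations. Targets keep the CAIPI phase — the phase pattern is
  multiplicative along ky, so phased-in → phased-out is realizable by a
  convolution kernel while phased-in → unphased-out is not; the phase
  is removed after synthesis. Tikhonov `(1e-3 · σ_max)²`; the trained
  object reports an inter-slice leakage matrix (~1 % on the standard
  scene).
* **In-plane GRAPPA**: missing lines synthesized from the two flanking
  acquired lines × 5 readout taps × J channels, trained on the
  fully sampled calibration, applied after slice separation.

## The synthetic scene

The generator emulates the validation experiments at desk scale; its
defaults are the study conditions used by the tests and the acceptance
script.

* **Object**: Shepp-Logan-style ellipse phantom with an added bright
  asymmetric feature (so left-right ghost replicas are unambiguous),
  smooth low-order complex phase, support scaled to 0.65 of the FOV
  (background ring ≥ 10 % of the FOV for artifact-power masks); slices
  of an MB group are rotated copies (8°/slice). Grid 64×64 (vs the
  larger in vivo matrices) keeps every study inside interactive
  runtimes.
* **Coils**: J = 12 (the validation coil had 15) Gaussian-amplitude
  channels on a ring (σ = 0.5 FOV), mild in-plane phase ramps (±2 rad
  across the FOV), slice-direction phase spread over the full circle
  across channels plus (x,y)-dependent cross terms and a ±50 % gain
  modulation; sum-of-squares normalized. The phase structure was
  chosen so operator training has adequate encoding on all three axes:
  stronger random ramps widen the coil k-space kernels and degrade
  in-plane operators, weaker slice structure starves the proxy-3D
  operator.
* **Timing**: echo spacing 0.5 ms (typical accelerated-EPI scale; the
  validation protocols do not state theirs), navigators at echoes
  1–3, imaging train from echo 4, ky bottom-up, FOV 0.192 m.
* **Perturbations**: per-frame, per-slice-group linear fields drawn
  zero-mean normal per axis with variances set so the expected field
  std across the FOV is 20 Hz (split equally over the active axes);
  frame 0 is always the unperturbed reference; draws are independent
  across frames and groups.
* **Noise**: i.i.d. complex Gaussian per k-space sample; the default
  30 dB (relative to the RMS of the clean collapsed k-space)
  corresponds to a peak image SNR of ~140 — ordinary fMRI territory.
* **MFI warping**: the retrospective corruption route is also provided
  as multifrequency interpolation with per-pixel least-squares
  expansion coefficients over the actual line times (the standard MFI
  coefficient choice); with 9 bins it matches the direct
  signal-equation evaluation to ~1e-5 NRMSE at the study's field
  scale. Pixelwise linear-interpolation weights are available as an
  option but need ~5× more bins for the same accuracy. The series
  generator itself uses the direct evaluation (it is exact).

**What passing tests do not show.** The scene has no ramp sampling
(uniform readout; the source experiments found full vs central
navigator use indistinguishable), no relaxation decay along the
readout, no physiological noise, no motion of the object itself (only
the field consequences of remote motion), and spatially *exactly*
linear perturbations — so the tests validate the estimator and the
correction under the model's own assumptions plus noise, not the
adequacy of the linear-field assumption for real anatomy.

## Known limitations

* Shift fidelity per unit shift is coil-limited (~2–5 % NRMSE); the
  echo-differential correction of frames with large `|d_y|` draws can
  inject operator error comparable to the (small) ghosting footprint
  such frames have on this phantom, which occasionally leaves a
  frame's entropy un-improved even as its nRMSE drops.
* The six-coefficient model cannot represent higher-order spatial
  field structure; `c`/`d` estimates absorb what they can and the
  residual reports the misfit.
* Operators are calibrated for shifts up to one sample; corrections
  beyond ~1.5 samples at late echoes are extrapolations (flagged, and
  optionally capped via `max_exponent`).
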