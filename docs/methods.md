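# Methods

## Scale space and γ-normalized derivatives

A volume is observed through Gaussian apertures: the scale-space
representation at scale t = σ² is the convolution with a normalized
Gaussian of standard deviation σ, and structural analysis is done with
Gaussian-derivative operators. Because derivative amplitudes shrink as
σ grows, an order-n derivative is multiplied by σ^(nγ) so responses are
comparable across scales; the strongest normalized response over σ then
marks the scale matching the local object width (for a Gaussian ridge of
width σ_obj probed with γ = 3/4, the maximum falls exactly at
σ = σ_obj, which the tests verify against the closed form
−σ^2γ·A·σ_obj/(σ_obj²+σ²)^{3/2}).

Derivatives are implemented as separable correlations with sampled
Gaussian-derivative kernels, not finite differences of the smoothed
image. The truncated kernels' discrete moments are corrected so the
operators are exact on low-order polynomials: order 1 annihilates
constants and maps a unit ramp to 1, order 2 annihilates constants and
ramps and maps x²/2 to 1. Without this correction a truncated
second-derivative kernel leaks ~10⁻³ of a constant background into the
Hessian, which matters precisely in the flat noisy regions the filter
is supposed to suppress. Kernels are truncated at 4σ per axis by
default (configurable; the property tests that check semigroup and
commutation identities at 10⁻⁶–10⁻⁸ use 8σ, since a 4σ tail alone
contributes ~10⁻⁴). Boundaries are mirrored, so constants are preserved
without edge bias.

σ is always a physical length: it is divided by the per-axis voxel
spacing before kernel construction, and derivative responses are
divided by spacing^order, so anisotropic voxels are handled throughout.
γ defaults to 1.0 (plain σ² normalization of second derivatives);
0.75, 1.25 and 1.5 are selectable, the literature having recommended
each for particular ridge profiles.

## Hessian eigenanalysis

The six unique components of the symmetric Hessian are computed once
per scale (the mixed derivative grids are shared between their two
slots). Eigenvalues are obtained by the closed-form trigonometric
solution for symmetric 3×3 matrices, vectorized over voxels —
per-voxel LAPACK calls are an order of magnitude slower at typical
volume sizes — and validated in the suite against `numpy.linalg.eigvalsh`
to 10⁻¹⁰ on random matrices. Exactly diagonal matrices bypass the
trigonometry and return their entries unchanged. Eigenvalues are
ordered |λ₁| ≤ |λ₂| ≤ |λ₃|; magnitude ties are broken by ascending
signed value, deterministically. Eigenvectors, needed only for
diagnostics such as tube-axis extraction, use the dense solver path.

Degenerate ratio guards: a voxel with λ₃ = 0 has no second-order
structure, so its vesselness is defined as 0 (the adjacent branch of
the measure already returns 0 for λ₃ > 0); λ₂ = 0 with λ₃ ≠ 0 sets
R_b = 0 (pure plate, no blobness). Dark-on-bright polarity negates the
eigenvalues before the branch test, so the measure is written once.

## Automatic noise suppression

The parameter c scales the Frobenius-norm factor 1 − e^(−S²/2c²) and is
the only filter parameter tied to the acquisition rather than the
objects. The automatic rule is: compute the Laplacian at every voxel,
take the maximum, divide by 10 (the divisor is exposed as a parameter).

Which Laplacian is meant is a genuine design choice, and the default
here is the plain discrete Laplacian of the raw image (6-neighbor
stencil, spacing-aware). The rationale is empirical and reproduced by
the validation suite: for Gaussian noise of standard deviation η the
plain-Laplacian rule lands at c ≈ 3η, which sits in the broad optimum
valley of the MSE-vs-c curve on the three-tube phantom — above the
noise Hessian norms, below tubular-structure norms at realistic
contrasts — and matches the rule's reference operating point
(c ≈ 2·η at SD = 100). Two scale-space alternatives are selectable
(`mode='multiscale'`: γ-normalized Gaussian Laplacian maximized over
the sweep's scale list, which shares units with S exactly;
`mode='single'`: smallest scale only), but both select c well below the
optimum (≈0.2–0.7η) on the same phantom, over-weighting smoothed noise.
A constant or structure-free volume has no positive Laplacian maximum
and raises a degenerate-input error rather than silently returning
c = 0. The rule is exactly equivariant under intensity scaling and
invariant under translation, which the tests assert.

Automation costs one extra pass over the image: the run log records a
single `laplacian_pass` stage beyond the manual-mode pipeline, and a
manual run given the auto-derived c is bit-identical to the automatic
run.

## Multiscale aggregation

Scale lists are arithmetic or geometric in σ (the "logarithmic" mode,
σ_i = σ_min·(σ_max/σ_min)^{i/(n−1)}, placing more scales at the fine
end; geometric-in-σ rather than in t = σ² is the package's choice).
The response volume is the per-voxel maximum of the per-scale measure
with no further inter-scale normalization beyond the σ^2γ factor; the
first scale achieving the maximum is recorded as the best scale. Only
one per-scale Hessian is resident at a time — the engine streams
scales, so memory is bounded by a handful of volume-sized buffers.
`sweep_noise_suppression` factorizes the measure into its c-independent
part and S², letting a whole manual c-grid be evaluated in a single
streaming pass over scales.

## Phantoms

The generator builds the validation scenes: tubes with Gaussian
(A·e^(−r²/2σ_obj²)) or bar (two-valued) cross-sections along straight
or curved polyline centerlines (distance computed against a densified
polyline via a KD-tree), Gaussian blob and plate distractors, separable
polynomial backgrounds of per-axis degree ≤ 3 in normalized [0,1]
coordinates, and i.i.d. Gaussian noise from a seeded Mersenne-Twister
generator (bit-reproducible per seed). Every phantom carries its ground
truth: a per-voxel tube mask and a centerline mask.

The three-tube scene (the manual-vs-automatic benchmark) uses a 96³
grid, z-aligned tubes of σ_obj = 2, 4, 8 at evenly spaced x positions,
amplitude 5000 on the native intensity scale, and noise SD = 100.
Amplitude and widths are the package's own defaults: a 16-bit-range
tube contrast is what makes a noise-suppression value of a few noise
standard deviations optimal (at contrasts comparable to the noise no
c-selection rule has a usable optimum), and the rescaled c-search grid
spans ~0.05×–2.6× the automatic value, a 50-fold bracket. Both
returned volumes are divided by the amplitude so the ideal image has
dynamic range 1 and MSE/PSNR can use L = 1. The curved-tube scene
(σ_obj = 1.5, 3, 6, sine-displaced centerlines, three blobs and a
plate, 72³) and the parallel-tube-over-polynomial scene (σ_obj = 1.5,
2.5, 4 along z with a smooth cubic ramp at 30 % of tube amplitude, 64³)
use amplitude 1000 with noise SD ∈ {0, 25, 50}.

What the phantoms do not emulate: point-spread-function anisotropy,
intensity quantization, fixed-pattern/tiling artifacts of mosaicked
confocal data, scanner reconstruction physics, and curved vessels with
varying radius along the centerline. Passing tests therefore show that
the measure, the scale logic and the c rule behave as designed under
additive Gaussian noise and smooth backgrounds — not that the filter is
validated for any particular instrument.

## Quality metrics

MSE = (1/N)Σ(xᵢ−yᵢ)² and PSNR = 10·log₁₀(L²/MSE) dB. L defaults to 1
with references rescaled to [0,1]; the two reference MSE/PSNR pairs
(0.00203 → 26.93 dB, 0.00214 → 26.69–26.70 dB) are mutually consistent
exactly at L = 1, which the suite asserts. MSE = 0 is reported as a
perfect-match flag, not an overflow.

## Problem sizes and numerical choices

The validation experiments run at desk scale: the three-tube benchmark
at 96³ with 12 logarithmic scales over σ = 1–12 (the widest tube has
σ_obj = 8, so larger probes add nothing on this grid), the
scene tests at 64³–72³ with 12 scales over 1–10, scale selection at 64³.
The production default remains 1–30 in 20 logarithmic steps, sized for
vascular trees whose diameters are unknown a priori. Response
tie-breaks (best scale) take the first scale; the c-grid unimodality
check requires a single strict interior minimum; all randomness flows
through explicit integer seeds.

## Known limitations

- The divisor 10 in the automatic rule is an empirical constant; it is
  exposed as a parameter, and the package makes no claim that it is
  optimal for acquisition regimes far from those emulated here.
- The plain-Laplacian c shares intensity units with the γ = 1
  normalized Frobenius norm only up to a length² factor; at unit voxel
  spacing the two coincide numerically, but exotic spacings deserve a
  manual sanity check of the derived c.
- `frangi` vesselness is the only measure the automatic rule applies
  to; the Sato measure has no noise-suppression factor.
- High derivative orders (> 2 per axis) fall back to uncorrected
  sampled kernels; only orders up to the Hessian are moment-corrected.
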