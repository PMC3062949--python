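# tubeness

Multiscale Hessian tubularity filtering of 3D gray-scale volumes, with
fully automatic selection of the background-noise-suppression parameter.

Blood vessels, neurites and airways form tree-like networks whose
diameters span orders of magnitude within a single micro-CT or confocal
volume. Enhancing such tubular structures — so they can be segmented,
skeletonized or measured — is classically done by analysing the
eigenvalues of the image Hessian across a range of Gaussian scales.
One parameter in that filter, the noise-suppression scale *c*, depends
on the acquisition (voxel size, noise level) rather than on the objects,
and is traditionally found by expensive trial-and-error reruns.
`tubeness` implements the multiscale filter together with a rule that
derives *c* from the image itself, making the filter fully automatic,
and ships the synthetic tube phantoms and MSE/PSNR metrics used to
validate it.

## The measure

At probe scale σ the Hessian **H** of the γ-normalized Gaussian
scale-space representation is computed per voxel and its eigenvalues are
ordered |λ₁| ≤ |λ₂| ≤ |λ₃|. A bright tube has λ₁ ≈ 0 and
λ₂ ≈ λ₃ ≪ 0. With

- R_a = |λ₂|/|λ₃| (plate vs. line),
- R_b = |λ₁|/√|λ₂λ₃| (blobness),
- S = √(λ₁² + λ₂² + λ₃²) (structure energy, Frobenius norm),

the vesselness at one scale is

    ν = 0                                               if λ₂ > 0 or λ₃ > 0
    ν = (1 − e^(−Ra²/2a²)) · e^(−Rb²/2b²) · (1 − e^(−S²/2c²))   otherwise

with a = b = 0.5 the standard tubular setting. The filter output is the
per-voxel maximum of ν over a list of scales (default 20 logarithmic
steps over σ = 1–30); the argmax scale estimates the local tube radius.
The Sato two-ratio line measure is available as an alternative.

**Automatic c**: compute the Laplacian at every voxel, take its maximum
(λ₁+λ₂+λ₃)_max, and set c to one tenth of it. Everything the rule needs
comes from the image being processed, so the filter runs unsupervised at
the cost of exactly one extra Laplacian pass.

## Worked example

```python
import tubeness as tb

# "ideal" three-tube phantom and its noise-degraded copy (SD = 100 on
# the native intensity scale, rescaled so the ideal has dynamic range 1)
ideal, degraded, _ = tb.make_three_tube_phantom(seed=7)

filt = tb.TubularityFilter(sigma_min=1.0, sigma_max=12.0, n_scales=12)
response = filt.fit_transform(degraded)   # fit derives c automatically
print(f"c = {filt.c_:.4f}")
print(tb.quality_report(ideal, tb.Volume(response)))
```

prints

```
c = 0.0615
MSE=0.00502522  PSNR=22.99 dB  L=1  N=884736
```

i.e. the automatically derived noise-suppression value c = 0.0615
yields a filtered volume within 0.005 mean-squared error of the clean
reference (23.0 dB peak signal-to-noise at dynamic range 1). A manual
grid search over c (`tb.sweep_noise_suppression`) improves on this by
less than half a decibel — the bound the validation suite asserts — at
twenty times the cost.

`TubularityFilter` follows the scikit-learn transformer protocol
(`get_params`/`set_params`/`clone`, fitted attributes `c_`, `scales_`,
`best_scale_`), so it composes with sklearn pipelines. The same
functionality is available from the shell:

```sh
tubeness run --input heart.mhd --output-dir out/        # fully automatic
tubeness run --input heart.mhd --noise-mode manual --c 194.3 --output-dir out/
tubeness sweep-c --phantom three-tube --c-min 10 --c-max 500
tubeness make-phantom curved-tube --seed 1 --out phantom.nrrd
```

Each run writes the response volume, the best-scale volume, maximum
intensity projections, and (when a reference is given) an MSE/PSNR
report; the log records every parameter and the derived c.

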