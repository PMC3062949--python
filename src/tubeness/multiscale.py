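"""Scale-list construction and the per-voxel max-over-scales response.

The filter response at a voxel is the maximum of the per-scale
objectness over an ordered list of probe scales; the argmax scale
estimates the local object width.  Logarithmic stepping (geometric in
σ) emphasizes finer scales.  Only one per-scale Hessian field is
resident at a time: the engine streams scales to keep large volumes in
desk memory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import InvalidParameterError
from .hessian import (
    ObjectnessParams,
    auto_c,
    eigen_sym3,
    frangi_vesselness,
    hessian_at_scale,
    sato_measure,
)
from .scale_space import GaussianProbe
from .volume import Volume

__all__ = ["ScaleSpec", "ResponseVolume", "make_scales", "multiscale_objectness",
           "sweep_noise_suppression"]


@dataclass(frozen=True)
class ScaleSpec:
    """An ordered family of Gaussian probe scales.

    ``step_function='logarithmic'`` produces the geometric progression
    σ_i = σ_min·(σ_max/σ_min)^(i/(n−1)); ``'linear'`` an arithmetic one.
    ``gamma`` is the derivative-normalization exponent used at every
    scale.
    """

    sigma_min: float
    sigma_max: float
    n_steps: int = 20
    step_function: str = "logarithmic"
    gamma: float = 1.0
    truncation_radius: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma_min <= 0 or self.sigma_max <= 0:
            raise InvalidParameterError("scale bounds must be > 0")
        if self.sigma_min > self.sigma_max:
            raise InvalidParameterError(
                f"sigma_min {self.sigma_min} > sigma_max {self.sigma_max}"
            )
        if self.n_steps < 1:
            raise InvalidParameterError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.step_function not in ("linear", "logarithmic"):
            raise InvalidParameterError(
                f"unknown step_function {self.step_function!r}"
            )

    def sigmas(self) -> list[float]:
        return make_scales(self)

    def probes(self) -> list[GaussianProbe]:
        return [
            GaussianProbe(s, gamma=self.gamma,
                          truncation_radius=self.truncation_radius)
            for s in self.sigmas()
        ]


@dataclass(frozen=True)
class ResponseVolume:
    """Best tubularity score per voxel plus the scale achieving it."""

    response: Volume
    best_scale: Volume
    c: Optional[float] = None  # the noise-suppression value actually used


def make_scales(spec: ScaleSpec) -> list[float]:
    """Ordered probe-scale list for a ScaleSpec (strictly increasing;
    first = σ_min, last = σ_max when n ≥ 2; [σ_min] when n = 1)."""
    if spec.n_steps == 1:
        return [spec.sigma_min]
    if spec.sigma_min == spec.sigma_max:
        raise InvalidParameterError(
            "sigma_min == sigma_max needs n_steps == 1 for strictly "
            "increasing scales"
        )
    if spec.step_function == "linear":
        vals = np.linspace(spec.sigma_min, spec.sigma_max, spec.n_steps)
    else:
        vals = np.geomspace(spec.sigma_min, spec.sigma_max, spec.n_steps)
    return [float(v) for v in vals]


def _measure_at_scale(vol: Volume, probe: GaussianProbe,
                      params: ObjectnessParams) -> np.ndarray:
    eig = eigen_sym3(hessian_at_scale(vol, probe))
    if params.measure == "frangi":
        return frangi_vesselness(eig, params)
    return sato_measure(eig.lam1, eig.lam2, eig.lam3, params)


def _resolve_c(vol: Volume, spec: ScaleSpec, params: ObjectnessParams,
               log: Optional[Callable[[str], None]]) -> ObjectnessParams:
    """Run auto-c if configured; returns params with a concrete c."""
    if params.measure != "frangi":
        return params
    if params.auto_c and params.c is None:
        c = auto_c(vol, spec, divisor=params.auto_c_divisor,
                   mode=params.auto_c_mode)
        if log is not None:
            log(f"auto_c: derived c = {c:.6g} "
                f"(divisor {params.auto_c_divisor:g}, "
                f"{spec.n_steps} scales {spec.sigma_min:g}-{spec.sigma_max:g})")
        return replace(params, c=c, auto_c=False)
    if params.c is None:
        raise InvalidParameterError(
            "manual mode requires an explicit c > 0 for the frangi measure"
        )
    return params


def multiscale_objectness(
    vol: Volume,
    spec: ScaleSpec,
    params: ObjectnessParams,
    log: Optional[Callable[[str], None]] = None,
    per_scale_hook: Optional[Callable[[float, np.ndarray], None]] = None,
) -> ResponseVolume:
    """Per-voxel maximum objectness over the scale list.

    For each scale: Hessian → eigenvalues → measure; a running per-voxel
    maximum is kept together with the first scale achieving it.  When
    ``params.auto_c`` is on and no c is given, c is derived once from
    the image (same scales, same normalization) before the sweep and
    recorded on the result.

    ``per_scale_hook(sigma, response)`` is invoked with each per-scale
    response for debugging/inspection.
    """
    params = _resolve_c(vol, spec, params, log)
    best = None
    best_sigma = None
    for probe in spec.probes():
        resp = _measure_at_scale(vol, probe, params)
        if best is None:
            best = resp.copy()
            best_sigma = np.full(vol.shape, probe.sigma)
        else:
            better = resp > best
            best = np.where(better, resp, best)
            best_sigma = np.where(better, probe.sigma, best_sigma)
        if per_scale_hook is not None:
            per_scale_hook(probe.sigma, resp)
    return ResponseVolume(
        response=vol.with_data(best),
        best_scale=vol.with_data(best_sigma),
        c=params.c if params.measure == "frangi" else None,
    )


def sweep_noise_suppression(
    vol: Volume,
    spec: ScaleSpec,
    params: ObjectnessParams,
    c_values: Sequence[float],
) -> list[ResponseVolume]:
    """Multiscale Frangi responses for a grid of manual c values.

    Equivalent to running :func:`multiscale_objectness` once per c, but
    streams the Hessian/eigenvalue work a single time: per scale the
    c-independent factor F = (1−e^(−Ra²/2a²))·e^(−Rb²/2b²) and S² are
    computed once, then each c's running maximum of F·(1−e^(−S²/2c²))
    is updated.
    """
    c_values = [float(c) for c in c_values]
    if any(c <= 0 for c in c_values):
        raise InvalidParameterError("all c values must be > 0")
    if params.measure != "frangi":
        raise InvalidParameterError("the c sweep applies to the frangi measure")
    bests = [None] * len(c_values)
    best_sigmas = [None] * len(c_values)
    for probe in spec.probes():
        eig = eigen_sym3(hessian_at_scale(vol, probe))
        # c-independent part: evaluate with the branch/ratio logic at a
        # reference c, divide the third factor back out
        ref = replace(params, c=1.0, auto_c=False)
        s2 = eig.lam1**2 + eig.lam2**2 + eig.lam3**2
        third_ref = 1.0 - np.exp(-s2 / 2.0)
        full_ref = frangi_vesselness(eig, ref)
        factor = np.divide(full_ref, third_ref,
                           out=np.zeros_like(full_ref), where=third_ref > 0)
        for i, c in enumerate(c_values):
            resp = factor * (1.0 - np.exp(-s2 / (2.0 * c**2)))
            if bests[i] is None:
                bests[i] = resp
                best_sigmas[i] = np.full(vol.shape, probe.sigma)
            else:
                better = resp > bests[i]
                bests[i] = np.where(better, resp, bests[i])
                best_sigmas[i] = np.where(better, probe.sigma, best_sigmas[i])
    return [
        ResponseVolume(response=vol.with_data(b),
                       best_scale=vol.with_data(bs), c=c)
        for b, bs, c in zip(bests, best_sigmas, c_values)
    ]
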