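"""Gaussian scale space and γ-normalized Gaussian derivatives.

The linear scale space of a volume ``I0`` is the family
``I(x; t) = (I0 * G(.; t))(x)`` with ``G`` a normalized Gaussian of
variance ``t = σ²``.  Derivatives are taken by convolving with sampled
Gaussian-derivative kernels (separable per axis), not by finite
differences of the smoothed image, and are normalized by
``σ^(order·γ)`` so responses are comparable across scales.

σ is always given in physical length units and converted per axis to
voxel units through the volume's spacing, so anisotropic voxels are
handled transparently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError
from .volume import Volume

__all__ = ["GaussianProbe", "gaussian_smooth", "gaussian_derivative"]

#: boundary handling for every convolution in this module
_BOUNDARY_MODE = "reflect"


@dataclass(frozen=True)
class GaussianProbe:
    """A Gaussian observation kernel.

    Parameters
    ----------
    sigma : float
        Standard deviation of the kernel in physical length units. The
        scale-space variance is ``t = sigma**2``.
    gamma : float
        Normalization exponent: an order-``n`` derivative response is
        multiplied by ``sigma**(n * gamma)``. ``gamma=0`` disables
        normalization.
    truncation_radius : float
        Kernel half-width in units of sigma (kernel support is
        ``±truncation_radius·σ`` per axis).
    """

    sigma: float
    gamma: float = 1.0
    truncation_radius: float = 4.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.gamma < 0:
            raise InvalidParameterError(f"gamma must be >= 0, got {self.gamma}")
        if self.truncation_radius < 3:
            raise InvalidParameterError(
                f"truncation_radius must be >= 3, got {self.truncation_radius}"
            )

    @property
    def t(self) -> float:
        """Scale-space variance t = σ²."""
        return self.sigma**2


def _voxel_sigmas(vol: Volume, probe: GaussianProbe) -> tuple[float, float, float]:
    return tuple(probe.sigma / s for s in vol.spacing)  # type: ignore[return-value]


def _derivative_kernel(sigma: float, order: int, truncation_radius: float) -> np.ndarray:
    """Sampled Gaussian-derivative correlation weights (voxel units).

    Derivatives of the Gaussian sampled on integer offsets, with the
    truncated kernel's discrete moments corrected so the operator is
    exact on low-order polynomials: order 0 sums to 1, order 1
    annihilates constants and maps a unit ramp to 1, order 2
    annihilates constants and ramps and maps x²/2 to 1.
    """
    radius = max(int(truncation_radius * sigma + 0.5), order)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    g /= g.sum()
    if order == 0:
        return g
    if order == 1:
        k = (x / sigma**2) * g          # correlation weights for d/dx
        return k / np.dot(k, x)
    if order == 2:
        k = ((x**2 - sigma**2) / sigma**4) * g
        k -= k.mean()                   # exact zero response to constants
        return k / (np.dot(k, x**2) / 2.0)
    raise InvalidParameterError(
        f"derivative order per axis must be 0, 1 or 2, got {order}"
    )


def gaussian_smooth(vol: Volume, probe: GaussianProbe) -> Volume:
    """Convolve a volume with a normalized Gaussian of width ``probe.sigma``.

    The output grid has the input's shape; boundaries are mirrored so a
    constant volume is preserved exactly and interior intensity carries
    no edge bias.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    out = ndimage.gaussian_filter(
        data,
        sigma=_voxel_sigmas(vol, probe),
        mode=_BOUNDARY_MODE,
        truncate=probe.truncation_radius,
    )
    return vol.with_data(out)


def gaussian_derivative(
    vol: Volume, probe: GaussianProbe, orders: tuple[int, int, int]
) -> Volume:
    """γ-normalized Gaussian derivative of a volume.

    Convolves ``vol`` with the order-``(m, n, p)`` Gaussian-derivative
    kernel at ``probe.sigma`` (orders follow the (z, y, x) axis order)
    and multiplies by the normalization factor ``σ^((m+n+p)·γ)``.
    Derivatives are with respect to *physical* coordinates: each axis
    response is divided by ``spacing_axis**order_axis``.

    ``orders=(0, 0, 0)`` reduces exactly to :func:`gaussian_smooth`.
    """
    orders = tuple(int(o) for o in orders)  # type: ignore[assignment]
    if len(orders) != 3 or any(o < 0 for o in orders):
        raise InvalidParameterError(
            f"derivative orders must be 3 non-negative integers, got {orders}"
        )
    out = np.asarray(vol.data, dtype=np.float64)
    for axis, (sigma_vox, order) in enumerate(zip(_voxel_sigmas(vol, probe), orders)):
        if order <= 2:
            kernel = _derivative_kernel(sigma_vox, order, probe.truncation_radius)
            out = ndimage.correlate1d(out, kernel, axis=axis, mode=_BOUNDARY_MODE)
        else:  # rare high orders: uncorrected sampled-derivative kernel
            out = ndimage.gaussian_filter1d(
                out, sigma_vox, axis=axis, order=order, mode=_BOUNDARY_MODE,
                truncate=probe.truncation_radius,
            )
    total = sum(orders)
    if total:
        # voxel-unit -> physical-unit derivatives, then γ-normalization
        scale = probe.sigma ** (total * probe.gamma)
        for spacing_axis, order_axis in zip(vol.spacing, orders):
            scale /= spacing_axis**order_axis
        out *= scale
    return vol.with_data(out)
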