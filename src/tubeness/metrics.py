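"""Objective image-quality measures: MSE and PSNR.

For an ideal image x and a degraded/processed image y with N voxels,
MSE = (1/N)·Σ(xᵢ−yᵢ)² and PSNR = 10·log10(L²/MSE) dB, with L the
dynamic range of allowable intensities.  Lower MSE / higher PSNR means
the processed image is closer to the ideal.  L defaults to 1.0: filter
responses live in [0,1] by construction, and references are rescaled to
[0,1] before comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .volume import Volume

__all__ = ["QualityReport", "mse", "psnr", "quality_report"]


@dataclass(frozen=True)
class QualityReport:
    """MSE/PSNR pair with the dynamic range and voxel count used."""

    mse: float
    psnr: float  # dB; math.inf flags a perfect match (mse = 0)
    dynamic_range: float
    n: int

    @property
    def perfect_match(self) -> bool:
        return self.mse == 0.0

    def __str__(self) -> str:
        p = "inf (perfect match)" if self.perfect_match else f"{self.psnr:.2f} dB"
        return (f"MSE={self.mse:.6g}  PSNR={p}  "
                f"L={self.dynamic_range:g}  N={self.n}")

    def as_dict(self) -> dict:
        return {"mse": self.mse, "psnr": self.psnr,
                "dynamic_range": self.dynamic_range, "n": self.n}


def _data(x) -> np.ndarray:
    return np.asarray(x.data if isinstance(x, Volume) else x, dtype=np.float64)


def mse(x, y) -> float:
    """Mean squared voxelwise difference between two same-shape images."""
    xd, yd = _data(x), _data(y)
    if xd.shape != yd.shape:
        raise InvalidInputError(
            f"shape mismatch: {xd.shape} vs {yd.shape}"
        )
    return float(np.mean((xd - yd) ** 2))


def psnr(mse_value: float, dynamic_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio 10·log10(L²/MSE) in dB.

    ``mse_value = 0`` returns ``math.inf`` as a perfect-match flag
    rather than overflowing.
    """
    if mse_value < 0:
        raise InvalidParameterError(f"mse must be >= 0, got {mse_value}")
    if dynamic_range <= 0:
        raise InvalidParameterError(
            f"dynamic range must be > 0, got {dynamic_range}"
        )
    if mse_value == 0:
        return math.inf
    return 10.0 * math.log10(dynamic_range**2 / mse_value)


def quality_report(x, y, dynamic_range: float = 1.0) -> QualityReport:
    """One-stop MSE + PSNR comparison of ``y`` against the ideal ``x``."""
    m = mse(x, y)
    return QualityReport(mse=m, psnr=psnr(m, dynamic_range),
                         dynamic_range=dynamic_range, n=int(_data(x).size))
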