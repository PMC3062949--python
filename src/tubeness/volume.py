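"""In-memory 3D volume container with physical voxel spacing.

Arrays are stored in ``(z, y, x)`` index order; ``spacing`` and ``origin``
follow the same axis order, so the physical coordinate of voxel
``(i, j, k)`` is ``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = ["Volume", "as_volume"]


@dataclass(frozen=True)
class Volume:
    """A 3D scalar intensity grid with per-axis physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar intensities. Converted to ``float64`` on construction unless
        already a floating or integer array (integers are kept as given so
        file round-trips stay bit-exact).
    spacing : tuple of 3 floats
        Physical edge length of a voxel along (z, y, x). Must be positive.
    origin : tuple of 3 floats
        Physical coordinate of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise InvalidInputError(
                f"volume data must be 3D, got ndim={data.ndim}"
            )
        if data.size == 0:
            raise InvalidInputError("volume data must be non-empty")
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(spacing) != 3 or len(origin) != 3:
            raise InvalidInputError("spacing and origin must have 3 components")
        if any(s <= 0 for s in spacing):
            raise InvalidInputError(f"spacing must be positive, got {spacing}")
        if np.issubdtype(data.dtype, np.floating) and not np.all(np.isfinite(data)):
            raise InvalidInputError("volume intensities must be finite")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def astype(self, dtype) -> "Volume":
        return Volume(self.data.astype(dtype), self.spacing, self.origin)

    def with_data(self, data: np.ndarray) -> "Volume":
        """New volume sharing this volume's spacing/origin."""
        return Volume(data, self.spacing, self.origin)


def as_volume(x, spacing=(1.0, 1.0, 1.0)) -> Volume:
    """Coerce an array or Volume to a Volume."""
    if isinstance(x, Volume):
        return x
    return Volume(np.asarray(x, dtype=np.float64), spacing)
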