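"""Hessian fields, eigenvalue analysis, and tubularity (objectness) measures.

At a probe scale σ the image Hessian is the symmetric 3×3 matrix of
γ-normalized second Gaussian derivatives; its magnitude-ordered
eigenvalues |λ1| ≤ |λ2| ≤ |λ3| describe the local second-order shape.
An ideal bright tube has |λ1| ≈ 0, λ2 ≈ λ3 ≪ 0: no curvature along the
axis, strong negative curvature across it.

Two classical eigenvalue combinations are provided: the Frangi
vesselness (three-factor measure with plate/blob/noise sensitivities
a, b, c) and the Sato line measure (two eigenvalue ratios with
sensitivities α1 < α2).  The noise-suppression scale c — the one
parameter that depends on the acquisition rather than the object — can
be derived automatically from the image itself as one tenth of the
maximum of the Laplacian (= Hessian trace = λ1+λ2+λ3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DegenerateInputError, InvalidInputError, InvalidParameterError
from .scale_space import GaussianProbe, gaussian_derivative
from .volume import Volume

__all__ = [
    "HessianField",
    "EigenTriple",
    "ObjectnessParams",
    "hessian_at_scale",
    "eigen_sym3",
    "frangi_vesselness",
    "sato_measure",
    "laplacian_field",
    "image_laplacian",
    "auto_c",
]

# second-derivative multi-indices in (z, y, x) axis order
_SECOND_ORDERS = {
    "zz": (2, 0, 0),
    "yy": (0, 2, 0),
    "xx": (0, 0, 2),
    "zy": (1, 1, 0),
    "zx": (1, 0, 1),
    "yx": (0, 1, 1),
}


@dataclass(frozen=True)
class HessianField:
    """Six unique components of the per-voxel symmetric Hessian at one scale.

    Only six of the nine entries are stored; the mixed components are
    computed once and shared (``Izy`` *is* ``Iyz``).
    """

    zz: np.ndarray
    yy: np.ndarray
    xx: np.ndarray
    zy: np.ndarray
    zx: np.ndarray
    yx: np.ndarray
    sigma: float

    def trace(self) -> np.ndarray:
        return self.zz + self.yy + self.xx


@dataclass(frozen=True)
class EigenTriple:
    """Per-voxel Hessian eigenvalues ordered |λ1| ≤ |λ2| ≤ |λ3|.

    ``e1``..``e3`` are the matching orthonormal eigenvector grids
    (shape ``(..., 3)``, (z, y, x) components) when requested.
    """

    lam1: np.ndarray
    lam2: np.ndarray
    lam3: np.ndarray
    e1: Optional[np.ndarray] = None
    e2: Optional[np.ndarray] = None
    e3: Optional[np.ndarray] = None


@dataclass(frozen=True)
class ObjectnessParams:
    """Sensitivity parameters of the objectness measures.

    ``a`` and ``b`` (plate and blob sensitivity) describe the object and
    default to the standard tubular setting 0.5/0.5; ``c`` scales the
    Frobenius-norm noise-suppression factor and is either given manually
    or derived by :func:`auto_c` when ``auto_c`` is on.
    """

    a: float = 0.5
    b: float = 0.5
    c: Optional[float] = None
    polarity: str = "bright"  # bright-on-dark | dark-on-bright
    measure: str = "frangi"  # frangi | sato
    alpha1: float = 0.5
    alpha2: float = 2.0
    auto_c: bool = True
    auto_c_divisor: float = 10.0
    auto_c_mode: str = "image"  # image | multiscale | single

    def __post_init__(self) -> None:
        if self.auto_c_mode not in ("image", "multiscale", "single"):
            raise InvalidParameterError(
                f"unknown auto_c_mode {self.auto_c_mode!r}"
            )
        if self.a <= 0 or self.b <= 0:
            raise InvalidParameterError("a and b must be > 0")
        if self.c is not None and self.c <= 0:
            raise InvalidParameterError(f"c must be > 0, got {self.c}")
        if not self.alpha1 < self.alpha2:
            raise InvalidParameterError(
                f"alpha1 < alpha2 required, got {self.alpha1}, {self.alpha2}"
            )
        if self.alpha1 <= 0:
            raise InvalidParameterError("alpha1 must be > 0")
        if self.polarity not in ("bright", "dark"):
            raise InvalidParameterError(f"unknown polarity {self.polarity!r}")
        if self.measure not in ("frangi", "sato"):
            raise InvalidParameterError(f"unknown measure {self.measure!r}")
        if self.auto_c_divisor <= 0:
            raise InvalidParameterError("auto_c_divisor must be > 0")


def hessian_at_scale(vol: Volume, probe: GaussianProbe) -> HessianField:
    """γ-normalized Hessian of a volume at one probe scale.

    Each component is an order-2 Gaussian derivative (normalized by
    σ^2γ); mixed components are computed once.
    """
    comps = {
        key: gaussian_derivative(vol, probe, orders).data
        for key, orders in _SECOND_ORDERS.items()
    }
    return HessianField(sigma=probe.sigma, **comps)


def _magnitude_sort(lams: np.ndarray) -> np.ndarray:
    """Sort the leading axis of a (3, ...) eigenvalue stack by |λ|,
    ties broken by ascending signed value."""
    order = np.lexsort((lams, np.abs(lams)), axis=0)
    return np.take_along_axis(lams, order, axis=0)


def eigen_sym3(field: HessianField, vectors: bool = False) -> EigenTriple:
    """Eigen-decomposition of a symmetric-3×3 field, magnitude-ordered.

    Eigenvalues use a closed-form trigonometric solution (vectorized over
    voxels); eigenvectors, when requested, come from a dense symmetric
    solver and are re-ordered to match.
    """
    comps = (field.zz, field.yy, field.xx, field.zy, field.zx, field.yx)
    for name, comp in zip(("zz", "yy", "xx", "zy", "zx", "yx"), comps):
        if not np.all(np.isfinite(comp)):
            bad = tuple(int(i) for i in np.argwhere(~np.isfinite(comp))[0])
            raise InvalidInputError(
                f"non-finite Hessian component {name} at voxel {bad}"
            )
    azz, ayy, axx, azy, azx, ayx = (np.asarray(c, dtype=np.float64) for c in comps)

    if vectors:
        w, v = np.linalg.eigh(_stack_sym(field))  # w ascending signed, v columns
        wm = np.moveaxis(w, -1, 0)  # (3, ...voxels)
        order = np.lexsort((wm, np.abs(wm)), axis=0)
        w_sorted = np.take_along_axis(wm, order, axis=0)
        vm = np.moveaxis(v, -1, 0)  # (3 eig, ...voxels, 3 comp)
        v_sorted = np.take_along_axis(vm, order[..., None], axis=0)
        return EigenTriple(
            lam1=w_sorted[0], lam2=w_sorted[1], lam3=w_sorted[2],
            e1=v_sorted[0], e2=v_sorted[1], e3=v_sorted[2],
        )

    # closed-form eigenvalues of A = [[azz, azy, azx], [azy, ayy, ayx], [azx, ayx, axx]]
    q = (azz + ayy + axx) / 3.0
    p1 = azy**2 + azx**2 + ayx**2
    p2 = (azz - q) ** 2 + (ayy - q) ** 2 + (axx - q) ** 2 + 2.0 * p1
    p = np.sqrt(p2 / 6.0)
    safe_p = np.where(p > 0, p, 1.0)
    b00 = (azz - q) / safe_p
    b11 = (ayy - q) / safe_p
    b22 = (axx - q) / safe_p
    b01 = azy / safe_p
    b02 = azx / safe_p
    b12 = ayx / safe_p
    detb = (
        b00 * (b11 * b22 - b12 * b12)
        - b01 * (b01 * b22 - b12 * b02)
        + b02 * (b01 * b12 - b11 * b02)
    )
    r = np.clip(detb / 2.0, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    w0 = q + 2.0 * p * np.cos(phi)                      # algebraically largest
    w2 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)  # algebraically smallest
    w1 = 3.0 * q - w0 - w2
    lams = _magnitude_sort(np.stack([w0, w1, w2]))
    diagonal = p1 == 0  # already diagonal: return the entries exactly
    if np.any(diagonal):
        lams = np.where(diagonal, _magnitude_sort(np.stack([azz, ayy, axx])), lams)
    return EigenTriple(lam1=lams[0], lam2=lams[1], lam3=lams[2])


def _stack_sym(field: HessianField) -> np.ndarray:
    H = np.empty(np.shape(field.zz) + (3, 3))
    H[..., 0, 0] = field.zz
    H[..., 1, 1] = field.yy
    H[..., 2, 2] = field.xx
    H[..., 0, 1] = H[..., 1, 0] = field.zy
    H[..., 0, 2] = H[..., 2, 0] = field.zx
    H[..., 1, 2] = H[..., 2, 1] = field.yx
    return H


def _eigs_of(eig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(eig, EigenTriple):
        return (np.asarray(eig.lam1, float), np.asarray(eig.lam2, float),
                np.asarray(eig.lam3, float))
    lam1, lam2, lam3 = eig
    return np.asarray(lam1, float), np.asarray(lam2, float), np.asarray(lam3, float)


def frangi_vesselness(eig, params: ObjectnessParams) -> np.ndarray:
    """Three-factor vesselness score in [0, 1].

    With magnitude-ordered eigenvalues and ratios Ra = |λ2|/|λ3|,
    Rb = |λ1|/√|λ2·λ3|, S = √(λ1²+λ2²+λ3²):

        ν = 0                                  if λ2 > 0 or λ3 > 0
        ν = (1 − e^(−Ra²/2a²)) · e^(−Rb²/2b²) · (1 − e^(−S²/2c²))

    Dark-on-bright polarity is handled by negating the eigenvalues
    before the sign test.  Voxels with λ3 = 0 (no second-order
    structure, ratios undefined) score 0.
    """
    if params.c is None or params.c <= 0:
        raise InvalidParameterError(
            "frangi_vesselness requires c > 0 (auto-c not resolved?)"
        )
    lam1, lam2, lam3 = _eigs_of(eig)
    if params.polarity == "dark":
        lam1, lam2, lam3 = -lam1, -lam2, -lam3
    scalar = lam1.ndim == 0
    lam1, lam2, lam3 = np.atleast_1d(lam1, lam2, lam3)

    valid = (lam2 <= 0) & (lam3 <= 0) & (lam3 != 0)
    a2, a3 = np.abs(lam2), np.abs(lam3)
    safe3 = np.where(valid, a3, 1.0)
    ra = a2 / safe3
    rb = np.abs(lam1) / np.sqrt(np.where(valid, a2 * a3, 1.0))
    rb = np.where(valid & (a2 == 0), 0.0, rb)  # λ1=λ2=0: pure plate, no blobness
    s2 = lam1**2 + lam2**2 + lam3**2
    score = (
        (1.0 - np.exp(-(ra**2) / (2.0 * params.a**2)))
        * np.exp(-(rb**2) / (2.0 * params.b**2))
        * (1.0 - np.exp(-s2 / (2.0 * params.c**2)))
    )
    score = np.where(valid, score, 0.0)
    return float(score[0]) if scalar else score


def sato_measure(lam1, lam2, lam3, params: ObjectnessParams) -> np.ndarray:
    """Two-ratio line measure using λc = min(−λ2, −λ3).

    Returns 0 where λc = 0; otherwise ``exp(−λ1²/2(α1·λc)²)`` for
    λ1 ≤ 0 and ``exp(−λ1²/2(α2·λc)²)`` for λ1 > 0, with α1 < α2 so
    blob-like voxels (λ1 strongly non-zero) are penalized less on the
    bright side.
    """
    lam1, lam2, lam3 = _eigs_of((lam1, lam2, lam3))
    if params.polarity == "dark":
        lam1, lam2, lam3 = -lam1, -lam2, -lam3
    scalar = lam1.ndim == 0
    lam1, lam2, lam3 = np.atleast_1d(lam1, lam2, lam3)

    lam_c = np.minimum(-lam2, -lam3)
    alpha = np.where(lam1 <= 0, params.alpha1, params.alpha2)
    safe = np.where(lam_c != 0, lam_c, 1.0)
    score = np.exp(-(lam1**2) / (2.0 * (alpha * safe) ** 2))
    score = np.where(lam_c == 0, 0.0, score)
    return float(score[0]) if scalar else score


def laplacian_field(vol: Volume, probe: GaussianProbe) -> Volume:
    """γ-normalized Laplacian (Ixx + Iyy + Izz = Hessian trace) at one scale."""
    out = None
    for orders in ((2, 0, 0), (0, 2, 0), (0, 0, 2)):
        d = gaussian_derivative(vol, probe, orders).data
        out = d if out is None else out + d
    return vol.with_data(out)


def image_laplacian(vol: Volume) -> Volume:
    """Plain discrete Laplacian of the image (6-neighbor second
    differences, divided by spacing² per axis, mirrored boundaries)."""
    from scipy import ndimage

    data = np.asarray(vol.data, dtype=np.float64)
    out = np.zeros_like(data)
    for axis, h in enumerate(vol.spacing):
        out += ndimage.correlate1d(
            data, np.array([1.0, -2.0, 1.0]) / h**2, axis=axis, mode="reflect"
        )
    return vol.with_data(out)


def auto_c(
    vol: Volume,
    scales=None,
    divisor: float = 10.0,
    gamma: float = 1.0,
    mode: str = "image",
    truncation_radius: float = 4.0,
) -> float:
    """Automatic noise-suppression parameter from the image itself.

    Algorithm: compute the Laplacian at every voxel, find its maximum
    value (λ1+λ2+λ3)_max, and return that maximum divided by ``divisor``
    (default 10, i.e. one tenth).

    Three interpretations of "the Laplacian" are offered:

    - ``mode='image'`` (default): the plain discrete Laplacian of the
      raw image (6-neighbor stencil).  For noise of standard deviation
      η this yields c ≈ 3·η, placing c above the noise Hessian norms
      and well below tubular-structure norms for realistic contrasts.
    - ``mode='multiscale'``: the γ-normalized Gaussian Laplacian,
      maximum over all listed ``scales`` — the same derivatives and
      units as the objectness sweep.
    - ``mode='single'``: the γ-normalized Gaussian Laplacian at the
      smallest listed scale only.

    Parameters
    ----------
    scales : sequence of float, or an object with a ``sigmas()`` method
        Probe scales (physical units); required for the scale-space
        modes, ignored by ``mode='image'``.
    """
    if divisor <= 0:
        raise InvalidParameterError(f"divisor must be > 0, got {divisor}")
    if mode not in ("image", "multiscale", "single"):
        raise InvalidParameterError(f"unknown auto-c mode {mode!r}")

    if mode == "image":
        lap_max = float(image_laplacian(vol).data.max())
    else:
        if hasattr(scales, "sigmas"):
            gamma = getattr(scales, "gamma", gamma)
            scales = scales.sigmas()
        if scales is None:
            raise InvalidParameterError(
                f"auto_c mode {mode!r} needs a scale list"
            )
        scales = [float(s) for s in np.atleast_1d(scales)]
        if not scales:
            raise InvalidParameterError("auto_c needs at least one scale")
        if mode == "single":
            scales = [min(scales)]
        lap_max = -np.inf
        for sigma in scales:
            probe = GaussianProbe(sigma=sigma, gamma=gamma,
                                  truncation_radius=truncation_radius)
            lap_max = max(lap_max, float(laplacian_field(vol, probe).data.max()))
    c = lap_max / divisor
    if not np.isfinite(c) or c <= 0:
        raise DegenerateInputError(
            f"maximum Laplacian is {lap_max:g}; cannot derive a positive c "
            "(constant or structure-free volume?)"
        )
    return c
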