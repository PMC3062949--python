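"""Synthetic 3D test volumes with known ground truth.

Scenes compose additively from: tubes (straight or curved centerlines
with Gaussian or bar cross-section intensity profiles), non-tubular
distractors (blobs, plates), smooth polynomial backgrounds, and
additive Gaussian noise from a seeded Mersenne-Twister generator.
Every phantom ships with a per-voxel tube mask and centerline
coordinates so downstream responses can be scored against truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidParameterError
from .volume import Volume

__all__ = [
    "TubeSpec",
    "DistractorSpec",
    "PhantomSpec",
    "Phantom",
    "make_tube",
    "make_polynomial_background",
    "add_gaussian_noise",
    "make_three_tube_phantom",
    "make_curved_tube_phantom",
    "make_parallel_tube_phantom",
]


@dataclass(frozen=True)
class TubeSpec:
    """One tube: a centerline polyline plus a radial intensity profile.

    ``centerline`` is an (N, 3) array of physical (z, y, x) points;
    straight tubes need only the two endpoints.  ``profile='gaussian'``
    gives intensity A·exp(−r²/2σ_obj²) with r the distance to the
    centerline; ``'bar'`` gives A inside r ≤ half_width, 0 outside.
    """

    centerline: np.ndarray
    profile: str = "gaussian"  # gaussian | bar
    sigma_obj: float = 2.0     # gaussian profile width
    half_width: float = 5.0    # bar profile half-width
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        cl = np.atleast_2d(np.asarray(self.centerline, dtype=np.float64))
        if cl.shape[1] != 3 or cl.shape[0] < 2:
            raise InvalidParameterError("centerline must be an (N>=2, 3) array")
        object.__setattr__(self, "centerline", cl)
        if self.profile not in ("gaussian", "bar"):
            raise InvalidParameterError(f"unknown profile {self.profile!r}")
        if self.amplitude < 0:
            raise InvalidParameterError("amplitude must be >= 0")
        if self.profile == "gaussian" and self.sigma_obj <= 0:
            raise InvalidParameterError("sigma_obj must be > 0")
        if self.profile == "bar" and self.half_width <= 0:
            raise InvalidParameterError("half_width must be > 0")


@dataclass(frozen=True)
class DistractorSpec:
    """A non-tubular object: Gaussian blob or Gaussian-profile plate."""

    kind: str  # blob | plate
    position: tuple[float, float, float]
    size: float
    amplitude: float = 1.0
    normal_axis: int = 0  # plate orientation: axis perpendicular to the plate

    def __post_init__(self) -> None:
        if self.kind not in ("blob", "plate"):
            raise InvalidParameterError(f"unknown distractor kind {self.kind!r}")
        if self.size <= 0 or self.amplitude < 0:
            raise InvalidParameterError("size must be > 0 and amplitude >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative scene description; identical spec + seed is bit-reproducible."""

    shape: tuple[int, int, int]
    tubes: tuple[TubeSpec, ...] = ()
    distractors: tuple[DistractorSpec, ...] = ()
    background: dict = field(default_factory=dict)  # {(i,j,k): coeff}
    noise_mean: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class Phantom:
    """A rendered scene with its ground truth."""

    clean: Volume                 # tubes + distractors + background, no noise
    noisy: Volume                 # clean + noise
    tube_mask: np.ndarray         # bool, r <= max(sigma_obj, half_width)
    centerline_mask: np.ndarray   # bool, voxels within 0.5 voxel of a centerline
    spec: PhantomSpec


def _grid_points(shape, spacing) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return np.stack([zz, yy, xx], axis=-1)


def _densify(polyline: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at roughly ``step`` spacing for distance queries."""
    pts = [polyline[0]]
    for a, b in zip(polyline[:-1], polyline[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / step)), 1)
        for i in range(1, n + 1):
            pts.append(a + (b - a) * (i / n))
    return np.asarray(pts)


def _distance_to_centerline(tube: TubeSpec, shape, spacing) -> np.ndarray:
    """Per-voxel distance to the (densified) centerline polyline."""
    cl = tube.centerline
    lo = np.zeros(3)
    hi = (np.asarray(shape) - 1) * np.asarray(spacing)
    if np.any(cl < lo - 1e-9) or np.any(cl > hi + 1e-9):
        warnings.warn("tube centerline extends outside the grid; clipping",
                      stacklevel=3)
        cl = np.clip(cl, lo, hi)
    dense = _densify(cl, step=0.25 * min(spacing))
    tree = cKDTree(dense)
    pts = _grid_points(shape, spacing).reshape(-1, 3)
    dist, _ = tree.query(pts, workers=-1)
    return dist.reshape(shape)


def make_tube(tube: TubeSpec, shape, spacing=(1.0, 1.0, 1.0)) -> Volume:
    """Render one tube into a fresh volume."""
    r = _distance_to_centerline(tube, shape, spacing)
    if tube.profile == "gaussian":
        data = tube.amplitude * np.exp(-(r**2) / (2.0 * tube.sigma_obj**2))
    else:
        data = np.where(r <= tube.half_width, tube.amplitude, 0.0)
    return Volume(data, spacing)


def _render_distractor(d: DistractorSpec, shape, spacing) -> np.ndarray:
    pts = _grid_points(shape, spacing)
    delta = pts - np.asarray(d.position)
    if d.kind == "blob":
        r2 = np.sum(delta**2, axis=-1)
    else:  # plate: Gaussian falloff along the normal axis only
        r2 = delta[..., d.normal_axis] ** 2
    return d.amplitude * np.exp(-r2 / (2.0 * d.size**2))


def make_polynomial_background(shape, coefficients,
                               spacing=(1.0, 1.0, 1.0)) -> Volume:
    """Polynomial intensity field in normalized [0,1]³ coordinates.

    ``coefficients`` maps exponent triples (i, j, k) for (z, y, x) to
    values; each exponent must be ≤ 3. E.g. ``{(0,0,0): 5}`` is a
    constant 5 and ``{(0,0,1): 100}`` a linear x-ramp of total rise 100.
    """
    shape = tuple(int(n) for n in shape)
    u = [np.arange(n) / max(n - 1, 1) for n in shape]
    zz, yy, xx = np.meshgrid(*u, indexing="ij")
    data = np.zeros(shape, dtype=np.float64)
    for (i, j, k), coeff in coefficients.items():
        if max(i, j, k) > 3 or min(i, j, k) < 0:
            raise InvalidParameterError(
                f"polynomial degree per axis must be 0..3, got {(i, j, k)}"
            )
        data += coeff * zz**i * yy**j * xx**k
    return Volume(data, spacing)


def _noise_rng(seed: int) -> np.random.Generator:
    # Mersenne-Twister core: long period, no neighborhood artifacts
    return np.random.Generator(np.random.MT19937(seed))


def add_gaussian_noise(vol: Volume, mean: float = 0.0, sd: float = 0.0,
                       seed: int = 0) -> Volume:
    """Add i.i.d. per-voxel Gaussian noise; sd = 0 returns the input unchanged."""
    if sd < 0:
        raise InvalidParameterError(f"sd must be >= 0, got {sd}")
    if sd == 0 and mean == 0:
        return vol
    rng = _noise_rng(seed)
    noise = rng.normal(loc=mean, scale=sd, size=vol.shape) if sd > 0 else mean
    return vol.with_data(np.asarray(vol.data, dtype=np.float64) + noise)


def render_phantom(spec: PhantomSpec) -> Phantom:
    """Render a full scene (tubes + distractors + background + noise)."""
    shape, spacing = spec.shape, spec.spacing
    clean = np.zeros(shape, dtype=np.float64)
    tube_mask = np.zeros(shape, dtype=bool)
    center_mask = np.zeros(shape, dtype=bool)
    for tube in spec.tubes:
        r = _distance_to_centerline(tube, shape, spacing)
        if tube.profile == "gaussian":
            clean += tube.amplitude * np.exp(-(r**2) / (2.0 * tube.sigma_obj**2))
            radius = tube.sigma_obj
        else:
            clean += np.where(r <= tube.half_width, tube.amplitude, 0.0)
            radius = tube.half_width
        tube_mask |= r <= radius
        center_mask |= r <= 0.5 * min(spacing)
    for d in spec.distractors:
        clean += _render_distractor(d, shape, spacing)
    if spec.background:
        clean += make_polynomial_background(shape, spec.background, spacing).data
    clean_vol = Volume(clean, spacing)
    noisy_vol = add_gaussian_noise(clean_vol, spec.noise_mean, spec.noise_sd,
                                   spec.seed)
    return Phantom(clean=clean_vol, noisy=noisy_vol, tube_mask=tube_mask,
                   centerline_mask=center_mask, spec=spec)


def _line(p0, p1) -> np.ndarray:
    return np.asarray([p0, p1], dtype=np.float64)


def make_three_tube_phantom(
    seed: int = 0,
    shape: tuple[int, int, int] = (96, 96, 96),
    widths: Sequence[float] = (2.0, 4.0, 8.0),
    amplitude: float = 5000.0,
    noise_sd: float = 100.0,
    normalize: bool = True,
) -> tuple[Volume, Volume, Phantom]:
    """Three parallel Gaussian-profile tubes of different width, plus noise.

    The clean scene is the "ideal image"; the noisy copy the "degraded
    image".  Tubes run along z at evenly spaced x positions.  With
    ``normalize=True`` (default) both returned volumes are divided by
    ``amplitude`` so the ideal image has dynamic range 1.0 and MSE/PSNR
    can use L = 1; the noise SD is specified on the native (pre-
    normalization) intensity scale.

    Returns ``(ideal, degraded, phantom)`` where ``phantom`` carries the
    native-scale scene and ground-truth masks.
    """
    nz, ny, nx = shape
    xs = [(i + 1) * nx / (len(widths) + 1) for i in range(len(widths))]
    tubes = tuple(
        TubeSpec(
            centerline=_line((0, ny / 2, x), (nz - 1, ny / 2, x)),
            profile="gaussian", sigma_obj=w, amplitude=amplitude,
        )
        for w, x in zip(widths, xs)
    )
    spec = PhantomSpec(shape=shape, tubes=tubes, noise_sd=noise_sd, seed=seed)
    ph = render_phantom(spec)
    scale = amplitude if normalize else 1.0
    ideal = Volume(ph.clean.data / scale, ph.clean.spacing)
    degraded = Volume(ph.noisy.data / scale, ph.noisy.spacing)
    return ideal, degraded, ph


def make_curved_tube_phantom(
    seed: int = 0,
    shape: tuple[int, int, int] = (72, 72, 72),
    widths: Sequence[float] = (1.5, 3.0, 6.0),
    amplitude: float = 1000.0,
    noise_sd: float = 25.0,
) -> Phantom:
    """Curved tubes of distinct widths amid blob/plate distractors and noise.

    Each tube follows a sine-displaced path through the volume; three
    blob distractors and one plate sit between the tubes.
    """
    nz, ny, nx = shape
    t = np.linspace(0.0, 1.0, 33)
    tubes = []
    for i, w in enumerate(widths):
        x0 = (i + 1) * nx / (len(widths) + 1)
        ampl_bend = 0.12 * ny
        cl = np.stack(
            [t * (nz - 1),
             ny / 2 + ampl_bend * np.sin(2 * np.pi * t + i),
             np.full_like(t, x0)],
            axis=1,
        )
        tubes.append(TubeSpec(centerline=cl, profile="gaussian",
                              sigma_obj=w, amplitude=amplitude))
    distractors = (
        DistractorSpec("blob", (0.2 * nz, 0.2 * ny, 0.5 * nx), size=4.0,
                       amplitude=amplitude),
        DistractorSpec("blob", (0.75 * nz, 0.8 * ny, 0.45 * nx), size=6.0,
                       amplitude=amplitude),
        DistractorSpec("blob", (0.5 * nz, 0.15 * ny, 0.15 * nx), size=3.0,
                       amplitude=amplitude),
        DistractorSpec("plate", (0.85 * nz, 0.5 * ny, 0.5 * nx), size=2.5,
                       amplitude=0.6 * amplitude, normal_axis=0),
    )
    spec = PhantomSpec(shape=shape, tubes=tuple(tubes), distractors=distractors,
                       noise_sd=noise_sd, seed=seed)
    return render_phantom(spec)


def make_parallel_tube_phantom(
    seed: int = 0,
    shape: tuple[int, int, int] = (64, 64, 64),
    widths: Sequence[float] = (1.5, 2.5, 4.0),
    amplitude: float = 1000.0,
    noise_sd: float = 0.0,
    background_scale: float = 0.3,
) -> Phantom:
    """Three z-aligned parallel Gaussian tubes over a polynomial background.

    The background is a smooth cubic ramp of peak magnitude
    ``background_scale * amplitude``, optionally degraded by noise.
    """
    nz, ny, nx = shape
    xs = [(i + 1) * nx / (len(widths) + 1) for i in range(len(widths))]
    tubes = tuple(
        TubeSpec(centerline=_line((0, ny / 2, x), (nz - 1, ny / 2, x)),
                 profile="gaussian", sigma_obj=w, amplitude=amplitude)
        for w, x in zip(widths, xs)
    )
    bg = amplitude * background_scale
    background = {(0, 0, 0): 0.2 * bg, (0, 0, 1): 0.5 * bg, (0, 1, 0): 0.3 * bg,
                  (0, 1, 1): 0.4 * bg, (0, 0, 3): 0.3 * bg}
    spec = PhantomSpec(shape=shape, tubes=tubes, background=background,
                       noise_sd=noise_sd, seed=seed)
    return render_phantom(spec)
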