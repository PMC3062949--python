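"""scikit-learn-style transformer wrapping the multiscale tubularity filter.

``TubularityFilter`` follows the estimator protocol: hyperparameters in
``__init__`` (never touched by ``fit``), data-dependent state in
fitted attributes with trailing underscores, ``get_params``/
``set_params`` from ``BaseEstimator`` so it composes with sklearn
model-selection utilities.  ``fit`` resolves the scale list and — in
automatic mode — derives the noise-suppression parameter ``c_`` from
the image; ``transform`` runs the max-over-scales sweep and returns the
response volume as an array in [0, 1].
"""

from __future__ import annotations

import math
from typing import Optional, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InvalidParameterError
from .hessian import ObjectnessParams
from .multiscale import ScaleSpec, multiscale_objectness
from .volume import Volume, as_volume

__all__ = ["TubularityFilter"]


class TubularityFilter(TransformerMixin, BaseEstimator):
    """Multiscale Hessian tubularity enhancement of a 3D volume.

    Parameters
    ----------
    sigma_min, sigma_max : float, default 1.0 / 30.0
        Probe-scale bounds in physical length units.
    n_scales : int, default 20
        Number of scales.
    step_function : {'logarithmic', 'linear'}, default 'logarithmic'
        Scale stepping; logarithmic (geometric in σ) emphasizes finer
        scales.
    gamma : float, default 1.0
        Derivative-normalization exponent (σ^(order·γ)).
    measure : {'frangi', 'sato'}, default 'frangi'
    a, b : float, default 0.5
        Plate and blob sensitivities of the frangi measure (the
        standard tubular setting).
    c : float or 'auto', default 'auto'
        Noise-suppression scale.  'auto' derives it during ``fit`` as
        ``max Laplacian / auto_c_divisor`` from the image itself.
    auto_c_divisor : float, default 10.0
    auto_c_mode : {'image', 'multiscale', 'single'}, default 'image'
        Which Laplacian feeds automatic selection: the plain discrete
        image Laplacian, or the scale-space Laplacian (max over all
        scales, or smallest scale only).
    polarity : {'bright', 'dark'}, default 'bright'
        Whether objects are bright on a dark background or vice versa.
    alpha1, alpha2 : float, default 0.5 / 2.0
        Sato sensitivities (alpha1 < alpha2).
    spacing : tuple of 3 floats, optional
        Voxel spacing used when a bare ndarray is passed; ignored for
        ``Volume`` inputs.

    Attributes
    ----------
    c_ : float or None
        The noise-suppression value resolved by ``fit`` (None for the
        sato measure, which has no c).
    scales_ : list of float
        The probe scales of the sweep.
    best_scale_ : ndarray
        After ``transform``: per-voxel scale achieving the maximum
        response.
    """

    def __init__(
        self,
        sigma_min: float = 1.0,
        sigma_max: float = 30.0,
        n_scales: int = 20,
        step_function: str = "logarithmic",
        gamma: float = 1.0,
        measure: str = "frangi",
        a: float = 0.5,
        b: float = 0.5,
        c: Union[str, float] = "auto",
        auto_c_divisor: float = 10.0,
        auto_c_mode: str = "image",
        polarity: str = "bright",
        alpha1: float = 0.5,
        alpha2: float = 2.0,
        truncation_radius: float = 4.0,
        spacing: Optional[tuple[float, float, float]] = None,
    ):
        self.sigma_min = sigma_min
        self.sigma_max = sigma_max
        self.n_scales = n_scales
        self.step_function = step_function
        self.gamma = gamma
        self.measure = measure
        self.a = a
        self.b = b
        self.c = c
        self.auto_c_divisor = auto_c_divisor
        self.auto_c_mode = auto_c_mode
        self.polarity = polarity
        self.alpha1 = alpha1
        self.alpha2 = alpha2
        self.truncation_radius = truncation_radius
        self.spacing = spacing

    # -- plumbing -----------------------------------------------------

    def _as_volume(self, X) -> Volume:
        if isinstance(X, Volume):
            return X
        X = np.asarray(X)
        if X.ndim != 3:
            raise InvalidParameterError(
                f"expected a 3D volume, got array with ndim={X.ndim}"
            )
        return as_volume(X, self.spacing or (1.0, 1.0, 1.0))

    def _scale_spec(self) -> ScaleSpec:
        return ScaleSpec(
            sigma_min=self.sigma_min,
            sigma_max=self.sigma_max,
            n_steps=self.n_scales,
            step_function=self.step_function,
            gamma=self.gamma,
            truncation_radius=self.truncation_radius,
        )

    def _objectness_params(self, resolved_c: Optional[float]) -> ObjectnessParams:
        return ObjectnessParams(
            a=self.a,
            b=self.b,
            c=resolved_c,
            polarity=self.polarity,
            measure=self.measure,
            alpha1=self.alpha1,
            alpha2=self.alpha2,
            auto_c=False,
            auto_c_divisor=self.auto_c_divisor,
            auto_c_mode=self.auto_c_mode,
        )

    # -- estimator API ------------------------------------------------

    def fit(self, X, y=None):
        """Resolve scales and (in automatic mode) the parameter c from X."""
        vol = self._as_volume(X)
        spec = self._scale_spec()
        self.scales_ = spec.sigmas()
        if self.measure == "sato":
            self.c_ = None
        elif self.c == "auto":
            from .hessian import auto_c

            self.c_ = auto_c(vol, spec, divisor=self.auto_c_divisor,
                             mode=self.auto_c_mode)
        else:
            c = float(self.c)
            if not c > 0 or not math.isfinite(c):
                raise InvalidParameterError(f"manual c must be > 0, got {self.c}")
            self.c_ = c
        self.n_features_in_ = vol.data.size
        return self

    def transform(self, X) -> np.ndarray:
        """Max-over-scales tubularity response of X, in [0, 1]."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "scales_")
        vol = self._as_volume(X)
        result = multiscale_objectness(
            vol, self._scale_spec(), self._objectness_params(self.c_)
        )
        self.best_scale_ = result.best_scale.data
        return result.response.data

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        return self.fit(X, y).transform(X)
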