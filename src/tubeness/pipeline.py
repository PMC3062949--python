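"""End-to-end run driver: load/generate → (auto-c) → sweep → artifacts.

``run_pipeline`` is the programmatic core behind the command line: it
loads a volume (or generates a named phantom), resolves the
noise-suppression parameter, runs the multiscale sweep, and writes the
response volume, best-scale volume, MIPs and an optional quality report.
Every parameter, the seed, and the derived c are logged, and the stage
log is structural: automatic mode differs from manual mode by exactly
one extra Laplacian pass.
"""

from __future__ import annotations

import json
import math
import os
import sys
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidParameterError, PipelineError
from .hessian import ObjectnessParams, auto_c
from .io import mip_project, read_volume, write_volume
from .metrics import QualityReport, quality_report
from .multiscale import ResponseVolume, ScaleSpec, multiscale_objectness
from .phantoms import make_curved_tube_phantom, make_parallel_tube_phantom, \
    make_three_tube_phantom
from .volume import Volume

__all__ = ["RunConfig", "RunResult", "run_pipeline"]

_PHANTOMS = ("three-tube", "curved-tube", "parallel-tube")


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one filtering run.

    Exactly one of ``input_path`` / ``phantom`` selects the input.
    ``noise_mode`` is 'automatic' (c derived from the image; ``c`` must
    be None) or 'manual' (an explicit ``c`` > 0 required).
    """

    input_path: Optional[str] = None
    phantom: Optional[str] = None       # three-tube | curved-tube | parallel-tube
    output_dir: Optional[str] = None
    reference_path: Optional[str] = None
    polarity: str = "bright"
    measure: str = "frangi"
    sigma_min: float = 1.0
    sigma_max: float = 30.0
    n_scales: int = 20
    step_function: str = "logarithmic"
    gamma: float = 1.0
    noise_mode: str = "automatic"       # automatic | manual
    c: Optional[float] = None
    auto_c_divisor: float = 10.0
    auto_c_mode: str = "image"
    seed: int = 0
    verbosity: int = 1
    output_format: str = "nrrd"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.phantom is None):
            raise InvalidParameterError(
                "exactly one of input_path / phantom must be given"
            )
        if self.phantom is not None and self.phantom not in _PHANTOMS:
            raise InvalidParameterError(
                f"unknown phantom {self.phantom!r}; choose from {_PHANTOMS}"
            )
        if self.noise_mode not in ("automatic", "manual"):
            raise InvalidParameterError(
                f"noise_mode must be 'automatic' or 'manual', got {self.noise_mode!r}"
            )
        if self.noise_mode == "manual":
            if self.measure == "frangi" and (self.c is None or self.c <= 0):
                raise InvalidParameterError(
                    "manual noise mode requires an explicit c > 0"
                )
        elif self.c is not None:
            raise InvalidParameterError(
                "automatic noise mode forbids an explicit c"
            )


@dataclass
class RunResult:
    """Artifacts of a completed run."""

    result: ResponseVolume
    c: Optional[float]
    stage_log: list[str] = field(default_factory=list)
    quality: Optional[QualityReport] = None
    written: list[str] = field(default_factory=list)


def _load_input(config: RunConfig, log) -> tuple[Volume, Optional[Volume]]:
    if config.input_path is not None:
        log(f"stage:load input={config.input_path}")
        vol = read_volume(config.input_path)
        ref = (read_volume(config.reference_path)
               if config.reference_path else None)
        return vol, ref
    log(f"stage:generate phantom={config.phantom} seed={config.seed}")
    if config.phantom == "three-tube":
        ideal, degraded, _ = make_three_tube_phantom(seed=config.seed)
        return degraded, ideal
    if config.phantom == "curved-tube":
        ph = make_curved_tube_phantom(seed=config.seed)
    else:
        ph = make_parallel_tube_phantom(seed=config.seed)
    ref = Volume(ph.clean.data / ph.clean.data.max(), ph.clean.spacing)
    return ph.noisy, ref


def run_pipeline(config: RunConfig, log_stream=None) -> RunResult:
    """Execute one configured run; see module docstring.

    Raises :class:`PipelineError` naming the failing stage; partial
    output files are removed on failure.
    """
    stage_log: list[str] = []

    def log(msg: str) -> None:
        stage_log.append(msg)
        if config.verbosity and log_stream is not None:
            print(msg, file=log_stream)

    log("stage:config " + json.dumps(
        {k: v for k, v in vars(config).items()}, default=str))

    stage = "load"
    written: list[str] = []
    try:
        vol, reference = _load_input(config, log)

        spec = ScaleSpec(
            sigma_min=config.sigma_min, sigma_max=config.sigma_max,
            n_steps=config.n_scales, step_function=config.step_function,
            gamma=config.gamma,
        )

        stage = "auto_c"
        c = config.c
        if config.measure == "frangi" and config.noise_mode == "automatic":
            log("stage:laplacian_pass (auto-c)")
            c = auto_c(vol, spec, divisor=config.auto_c_divisor,
                       mode=config.auto_c_mode)
            log(f"auto_c: derived c = {c:.6g}")
        elif config.measure == "frangi":
            log(f"manual mode: c = {c:.6g}")

        stage = "multiscale_sweep"
        log(f"stage:multiscale_sweep n_scales={config.n_scales} "
            f"range={config.sigma_min:g}-{config.sigma_max:g} "
            f"step={config.step_function} gamma={config.gamma:g} "
            f"measure={config.measure} polarity={config.polarity}")
        params = ObjectnessParams(
            c=c, polarity=config.polarity, measure=config.measure,
            auto_c=False, auto_c_divisor=config.auto_c_divisor,
        )
        result = multiscale_objectness(vol, spec, params)

        stage = "quality"
        quality = None
        if reference is not None:
            quality = quality_report(reference, result.response)
            log(f"quality: {quality}")

        stage = "write"
        if config.output_dir is not None:
            os.makedirs(config.output_dir, exist_ok=True)
            ext = "." + config.output_format.lstrip(".")
            for name, v in (("response", result.response),
                            ("best_scale", result.best_scale)):
                path = os.path.join(config.output_dir, name + ext)
                write_volume(v, path)
                written.append(path)
                log(f"stage:write {path}")
            for axis, name in enumerate("zyx"):
                path = os.path.join(config.output_dir, f"mip_{name}.tif")
                mip = mip_project(result.response, axis=axis)
                write_volume(Volume(mip[None], result.response.spacing), path)
                written.append(path)
            if quality is not None:
                path = os.path.join(config.output_dir, "quality.json")
                with open(path, "w") as fh:
                    json.dump(quality.as_dict(), fh, indent=2)
                written.append(path)
                log(f"stage:write {path}")
    except Exception as exc:
        for path in written:
            try:
                os.remove(path)
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    return RunResult(result=result, c=result.c, stage_log=stage_log,
                     quality=quality, written=written)
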