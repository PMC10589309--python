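"""Experiment drivers: regenerate the simulation studies at configurable scale.

Five reproducible experiments tie the modules together:

``speckle_statistics``
    per-pixel contrast error vs speckle-to-pixel size ratio and
    neighbourhood size, for independent instantaneous frames, with and
    without camera noise.
``exposure_sweep``
    error vs exposure-to-decorrelation-time ratio T/tau_c for
    exposure-integrated particle-simulation stacks.
``camera_grid``
    error relative to the noise-free contrast vs fill level, decomposed by
    noise source, for three camera quality tiers.
``sensitivity_curves``
    closed-form absolute and relative flow sensitivity vs exposure time for
    the three dynamics regimes.
``polarisation_check``
    contrast ratio of the two-pattern (unpolarised) sum vs a single
    polarised pattern.

Every driver is bit-reproducible given (config, seed); every output row
carries the seed and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import camera as cam
from .calibration import OrderedSpeckleSystem
from .contrast_metrics import (
    contrast_stack,
    global_contrast,
    per_pixel_error,
    speckle_size_fwhm,
)
from .contrast_theory import (
    SENSITIVITY_PRESETS,
    ModelParams,
    absolute_sensitivity,
    contrast_K,
    relative_sensitivity,
)
from .errors import ParameterError
from .field_synthesis import (
    FrameStack,
    fast_speckle,
    integrate_exposure,
    rescale_speckle,
    simulate_stack,
    unpolarised_sum,
)

logger = logging.getLogger("speckle_precision")

__all__ = [
    "ExperimentConfig",
    "run_speckle_statistics",
    "run_exposure_sweep",
    "run_camera_grid",
    "run_sensitivity_curves",
    "run_polarisation_check",
    "run_experiment",
]


@dataclass
class ExperimentConfig:
    """Scale factors and options shared by the experiment drivers.

    Defaults are a desk scale (minutes on one CPU); the numbers the
    experiments estimate are Monte-Carlo quantities, so larger
    ``n_frames``/``frame_size`` tighten them at proportional cost.
    """

    experiment: str = "speckle_statistics"
    seed: int = 0
    out_dir: Optional[str] = None

    # fast statistical generator (T/tau_c = 0 experiments)
    n_frames: int = 2000
    frame_size: int = 250
    base_fwhm: float = 5.0
    decimation_factors: Sequence[int] = (1, 2, 5, 10)
    neighbourhoods: Sequence[int] = (5, 7, 50)

    # particle method (temporal experiments)
    n_particles: int = 300
    temporal_frames: int = 10000
    temporal_size: int = 64
    pixel_pitch: float = 5.0
    tau_c: float = 20.0
    dt: float = 2.0
    temporal_fwhm: float = 2.0
    t_over_tauc: Sequence[float] = (0.5, 2.0, 5.0, 20.0)

    # camera
    camera_preset: str = "medium"
    fill: float = 0.3
    fill_grid: Sequence[float] = (
        0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.5, 0.6, 0.8, 1.0,
    )

    # sensitivity curves
    x_grid: Sequence[float] = tuple(np.geomspace(1e-2, 1e3, 121))

    # polarisation
    pol_frames: int = 200
    pol_size: int = 128
    pol_fwhm: float = 2.0

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _provenance(config: ExperimentConfig) -> dict:
    return {"seed": config.seed, "config_hash": config.config_hash()}


def _write_outputs(df: pd.DataFrame, config: ExperimentConfig, name: str) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / f"{name}.csv", index=False)
    (out / f"{name}_config.json").write_text(
        json.dumps(dict(config.to_dict(), config_hash=config.config_hash()), indent=1)
    )
    logger.info("wrote %s.csv (%d rows) to %s", name, len(df), out)


# ---------------------------------------------------------------------------
# speckle statistics (error vs speckle size x neighbourhood)
# ---------------------------------------------------------------------------

def run_speckle_statistics(config: ExperimentConfig) -> pd.DataFrame:
    """Error vs speckle FWHM x neighbourhood x {noise on, off}, T/tau_c = 0.

    A single stack is synthesized at the base speckle size and decimated
    down (box filter + downsample) so the per-size results share the same
    underlying speckle realisations, as in a physical aperture sweep.
    """
    shape = (config.frame_size, config.frame_size)
    stack = fast_speckle(
        shape, config.base_fwhm, config.n_frames, beta=1.0, seed=config.seed
    )
    spec = cam.CameraSpec.from_preset(config.camera_preset)
    rows = []
    for factor in config.decimation_factors:
        try:
            dec = rescale_speckle(stack, factor)
        except ParameterError as exc:
            warnings.warn(f"skipping decimation factor {factor}: {exc}")
            continue
        nominal = config.base_fwhm / factor
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            measured = speckle_size_fwhm(
                FrameStack(dec.frames[:8], dt=dec.dt)
            )
        noisy = cam.apply_camera(
            dec, spec, config.fill, cam.NoiseFlags.all(),
            seed=config.seed + 1000 + factor,
        )
        for w in config.neighbourhoods:
            if w > min(dec.shape):
                warnings.warn(
                    f"skipping neighbourhood {w} at factor {factor}: "
                    "frame too small"
                )
                continue
            for label, st in (("off", dec), ("on", noisy)):
                kmaps = contrast_stack(st, w)
                rep = per_pixel_error(kmaps, "dataset_mean", neighbourhood=w)
                rows.append(
                    {
                        "speckle_fwhm_nominal": nominal,
                        "speckle_fwhm_measured": measured,
                        "neighbourhood": w,
                        "T_over_tauc": 0.0,
                        "noise_on": label == "on",
                        "error_percent": rep.error_percent,
                        "mean_contrast": rep.mean_contrast,
                        "n_samples": rep.n_independent_samples,
                        **_provenance(config),
                    }
                )
    df = pd.DataFrame(rows)
    _write_outputs(df, config, "speckle_statistics")
    return df


# ---------------------------------------------------------------------------
# exposure sweep
# ---------------------------------------------------------------------------

def build_temporal_stream(
    config: ExperimentConfig, seed_offset: int = 0
) -> tuple[OrderedSpeckleSystem, FrameStack]:
    """Calibrated ordered-motion system plus its instantaneous frame stream."""
    system = OrderedSpeckleSystem.build(
        tau_c=config.tau_c,
        speckle_fwhm_px=config.temporal_fwhm,
        n_particles=config.n_particles,
        n_rows=config.temporal_size,
        n_cols=config.temporal_size,
        pixel_pitch=config.pixel_pitch,
        seed=config.seed + seed_offset,
    )
    stream = simulate_stack(
        system.cloud,
        system.sensor,
        system.motion,
        config.temporal_frames,
        config.dt,
        seed=config.seed + seed_offset + 7,
        tau_c_hint=config.tau_c,
    )
    return system, stream


def exposure_errors(
    stream: FrameStack,
    tau_c: float,
    t_over_tauc: Sequence[float],
    neighbourhoods: Sequence[int],
) -> pd.DataFrame:
    """Per-pixel contrast error per neighbourhood for each exposure ratio."""
    rows = []
    for x in t_over_tauc:
        T = x * tau_c
        m = T / stream.dt
        if abs(m - round(m)) > 1e-9 or round(m) < 1:
            warnings.warn(f"skipping T/tau_c={x}: T not a multiple of dt")
            continue
        exposures = integrate_exposure(stream, T)
        if exposures.n_frames < 2:
            warnings.warn(f"skipping T/tau_c={x}: fewer than 2 exposures")
            continue
        for w in neighbourhoods:
            if w > min(exposures.shape):
                continue
            kmaps = contrast_stack(exposures, w)
            rep = per_pixel_error(kmaps, "dataset_mean", neighbourhood=w)
            rows.append(
                {
                    "T_over_tauc": x,
                    "T_us": T,
                    "neighbourhood": w,
                    "n_exposures": exposures.n_frames,
                    "error_percent": rep.error_percent,
                    "mean_contrast": rep.mean_contrast,
                    "n_samples": rep.n_independent_samples,
                }
            )
    return pd.DataFrame(rows)


def run_exposure_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Error vs T/tau_c from exposure-integrated particle stacks.

    Also reports the ratio error(T/tau_c=20)/error(T/tau_c=5) per
    neighbourhood when both exposures are in the grid.
    """
    _, stream = build_temporal_stream(config)
    df = exposure_errors(
        stream, config.tau_c, config.t_over_tauc, config.neighbourhoods
    )
    for key, val in _provenance(config).items():
        df[key] = val
    ratios = []
    for w in sorted(df["neighbourhood"].unique()):
        sub = df[df["neighbourhood"] == w].set_index("T_over_tauc")
        if 20.0 in sub.index and 5.0 in sub.index:
            r = sub.loc[20.0, "error_percent"] / sub.loc[5.0, "error_percent"]
            ratios.append({"neighbourhood": w, "error_ratio_20_over_5": r})
            logger.info("error ratio 20/5 at %dx%d: %.3f", w, w, r)
    df.attrs["error_ratios"] = ratios
    _write_outputs(df, config, "exposure_sweep")
    return df


# ---------------------------------------------------------------------------
# camera grid
# ---------------------------------------------------------------------------

_GRID_CONDITIONS = ((5.0, 1.0), (20.0, 1.0), (5.0, 0.5))


def run_camera_grid(config: ExperimentConfig) -> pd.DataFrame:
    """Error vs fill level for three camera presets x three conditions.

    Conditions are (T/tau_c, beta) = (5, 1), (20, 1) and (5, 0.5); beta=0.5
    is realised by summing two independent polarisation channels.  The
    error is taken relative to the noise-free contrast of the same frames
    and decomposed by noise source.
    """
    _, stream_a = build_temporal_stream(config, seed_offset=0)
    _, stream_b = build_temporal_stream(config, seed_offset=101)
    flag_sets = [
        cam.NoiseFlags.none(),
        cam.NoiseFlags.only("shot"),
        cam.NoiseFlags.only("read"),
        cam.NoiseFlags.only("quantize"),
        cam.NoiseFlags.only("saturate"),
        cam.NoiseFlags.all(),
    ]
    rows = []
    for t_ratio, beta in _GRID_CONDITIONS:
        T = t_ratio * config.tau_c
        exp_a = integrate_exposure(stream_a, T)
        if beta == 0.5:
            exp_b = integrate_exposure(stream_b, T)
            clean = unpolarised_sum(exp_a, exp_b)
        else:
            clean = exp_a
        for preset in ("low", "medium", "high"):
            spec = cam.CameraSpec.from_preset(preset)
            df = cam.camera_error_curve(
                clean, spec, flag_sets, config.fill_grid,
                seed=config.seed + int(t_ratio * 10 + beta * 2),
            )
            df["preset"] = preset
            df["T_over_tauc"] = t_ratio
            df["beta"] = beta
            rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    for key, val in _provenance(config).items():
        out[key] = val
    _write_outputs(out, config, "camera_grid")
    return out


# ---------------------------------------------------------------------------
# sensitivity curves
# ---------------------------------------------------------------------------

def run_sensitivity_curves(config: ExperimentConfig) -> pd.DataFrame:
    """K, S_a and S_r vs exposure time for the regime/parameter presets."""
    rows = []
    for preset_name, entries in SENSITIVITY_PRESETS.items():
        for tissue, (regime, params) in entries.items():
            for x in config.x_grid:
                T = x * params.tau_c
                rows.append(
                    {
                        "parameterization": preset_name,
                        "tissue": tissue,
                        "regime": regime.name,
                        "beta": params.beta,
                        "rho": params.rho,
                        "C": params.C,
                        "tau_c_us": params.tau_c,
                        "T_us": T,
                        "x": x,
                        "K": contrast_K(T, params, regime),
                        "S_a": absolute_sensitivity(T, params, regime),
                        "S_r": relative_sensitivity(T, params, regime),
                        **_provenance(config),
                    }
                )
    df = pd.DataFrame(rows)
    _write_outputs(df, config, "sensitivity_curves")
    return df


# ---------------------------------------------------------------------------
# polarisation
# ---------------------------------------------------------------------------

def run_polarisation_check(config: ExperimentConfig) -> dict:
    """Contrast ratio of a two-channel (unpolarised) sum vs one channel.

    Two independent fully developed stacks are averaged element-wise; the
    expected global contrast ratio is 1/sqrt(2).  The confidence interval
    is the normal approximation over per-frame ratios (shrinks ~ 1/sqrt(n)).
    """
    shape = (config.pol_size, config.pol_size)
    a = fast_speckle(shape, config.pol_fwhm, config.pol_frames, 1.0, config.seed)
    b = fast_speckle(
        shape, config.pol_fwhm, config.pol_frames, 1.0, config.seed + 1
    )
    mixed = unpolarised_sum(a, b)
    k_single = np.array([global_contrast(f) for f in a.frames])
    k_mixed = np.array([global_contrast(f) for f in mixed.frames])
    ratios = k_mixed / k_single
    n = len(ratios)
    mean = float(ratios.mean())
    half = 1.96 * float(ratios.std(ddof=1)) / np.sqrt(n)
    report = {
        "contrast_ratio": mean,
        "ci_low": mean - half,
        "ci_high": mean + half,
        "expected": 1.0 / np.sqrt(2.0),
        "n_frames": n,
        "mean_contrast_polarised": float(k_single.mean()),
        "mean_contrast_unpolarised": float(k_mixed.mean()),
        **_provenance(config),
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "polarisation_check.json").write_text(json.dumps(report, indent=1))
    return report


_RUNNERS = {
    "speckle_statistics": run_speckle_statistics,
    "exposure_sweep": run_exposure_sweep,
    "camera_grid": run_camera_grid,
    "sensitivity_curves": run_sensitivity_curves,
    "polarisation_check": run_polarisation_check,
}


def run_experiment(config: ExperimentConfig):
    """Dispatch on ``config.experiment``."""
    try:
        runner = _RUNNERS[config.experiment]
    except KeyError:
        raise ParameterError(
            f"unknown experiment {config.experiment!r}; "
            f"choose from {sorted(_RUNNERS)}"
        ) from None
    return runner(config)
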