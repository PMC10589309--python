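"""Camera pipeline: photo-electrons, shot/read noise, saturation, digitization.

Ideal (normalized-unit) intensity frames are scaled so the sensor-average
photo-electron count equals ``fill * capacity``, then pass through the
physical chain photon -> electron -> read noise -> saturation -> ADC.  Each
noise source is independently switchable so its contribution to the
contrast error can be isolated.  Dark current is fixed at zero: LSCI
exposures are too short for it to matter.

Conversion gain is fixed at (2^bit_depth - 1)/capacity DN per electron so
that a full well maps exactly to the top of the digital range; the fill
level is then identical to <I>/I_max, the quantity available during a
recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, StateError
from .field_synthesis import FrameStack

__all__ = ["CameraSpec", "NoiseFlags", "apply_camera", "camera_error_curve"]


@dataclass(frozen=True)
class CameraSpec:
    """Sensor parameters: quantum efficiency, read noise, ADC depth, full well."""

    qe: float  # quantum efficiency (0, 1]
    read_sigma: float  # read noise std, electrons
    bit_depth: int  # 8 or 16
    capacity: float  # full-well capacity, electrons
    name: str = "custom"

    def __post_init__(self):
        if not (0 < self.qe <= 1):
            raise ParameterError("qe must be in (0, 1]")
        if self.read_sigma < 0:
            raise ParameterError("read_sigma must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ParameterError("bit_depth must be 8 or 16")
        if self.capacity <= 0:
            raise ParameterError("capacity must be positive")

    @property
    def dn_max(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def gain(self) -> float:
        """Conversion gain, DN per electron."""
        return self.dn_max / self.capacity

    @classmethod
    def from_preset(cls, name: str) -> "CameraSpec":
        try:
            return PRESETS[name]
        except KeyError:
            raise ParameterError(
                f"unknown camera preset {name!r}; choose from {sorted(PRESETS)}"
            ) from None


#: Quality tiers typical of cameras used for LSCI: a low-end board camera,
#: a machine-vision CMOS (e.g. Basler acA2040-90umNIR class) and a
#: scientific CMOS.
PRESETS = {
    "low": CameraSpec(qe=0.2, read_sigma=30.0, bit_depth=8, capacity=1200.0, name="low"),
    "medium": CameraSpec(
        qe=0.45, read_sigma=13.0, bit_depth=8, capacity=12400.0, name="medium"
    ),
    "high": CameraSpec(
        qe=0.8, read_sigma=1.0, bit_depth=16, capacity=30000.0, name="high"
    ),
}


@dataclass(frozen=True)
class NoiseFlags:
    """Independent switches for each signal-altering stage."""

    shot: bool = True
    read: bool = True
    quantize: bool = True
    saturate: bool = True

    @classmethod
    def none(cls) -> "NoiseFlags":
        return cls(shot=False, read=False, quantize=False, saturate=False)

    @classmethod
    def all(cls) -> "NoiseFlags":
        return cls()

    @classmethod
    def only(cls, *names: str) -> "NoiseFlags":
        valid = {f.name for f in dc_fields(cls)}
        for n in names:
            if n not in valid:
                raise ParameterError(f"unknown noise flag {n!r}")
        return cls(**{f: (f in names) for f in valid})

    def label(self) -> str:
        on = [f.name for f in dc_fields(self) if getattr(self, f.name)]
        return "+".join(on) if on else "none"


def apply_camera(
    stack: FrameStack,
    spec: CameraSpec,
    fill: float,
    flags: NoiseFlags = NoiseFlags.all(),
    seed: Optional[int] = None,
) -> FrameStack:
    """Convert a normalized-intensity stack to digitized camera output (DN).

    Pipeline per pixel: scale to a mean photo-electron count of
    ``fill * capacity`` (fill defined on the sensor-average flux); Poisson
    shot noise; additive Gaussian read noise; clipping at the full well;
    conversion to DN at (2^bit_depth - 1)/capacity; rounding; clipping of
    the digital range.  The clipping stages belong to the ``saturate`` flag
    so that the other noise sources can be studied in isolation.

    ``fill`` may exceed 1 (up to 1.2) to probe saturation.
    """
    if stack.units != "normalized":
        raise StateError("apply_camera expects a stack in normalized units")
    if not (0 < fill <= 1.2):
        raise ParameterError("fill must be in (0, 1.2]")
    rng = np.random.default_rng(seed)
    mean_in = float(stack.frames.mean())
    if mean_in <= 0:
        scale = 0.0
    else:
        scale = fill * spec.capacity / mean_in
    electrons = stack.frames.astype(np.float64) * scale
    if flags.shot:
        electrons = rng.poisson(electrons).astype(np.float64)
    if flags.read and spec.read_sigma > 0:
        electrons = electrons + rng.normal(0.0, spec.read_sigma, electrons.shape)
    if flags.saturate:
        electrons = np.clip(electrons, 0.0, spec.capacity)
    dn = electrons * spec.gain
    if flags.quantize:
        dn = np.round(dn)
    if flags.saturate:
        dn = np.clip(dn, 0, spec.dn_max)
    return FrameStack(
        frames=dn.astype(np.float32),
        dt=stack.dt,
        exposure_T=stack.exposure_T,
        units="DN",
        seed_record=dict(
            stack.seed_record,
            camera={"preset": spec.name, "fill": fill, "flags": flags.label(),
                    "seed": seed},
        ),
    )


def camera_error_curve(
    clean_stack: FrameStack,
    spec: CameraSpec,
    flag_sets: Sequence[NoiseFlags],
    fills: Sequence[float],
    seed: Optional[int] = None,
    neighbourhood: int = 5,
) -> pd.DataFrame:
    """Mean per-pixel contrast error vs fill level, per noise combination.

    For each fill and flag set the camera pipeline is applied to the clean
    stack and the error |K_noisy - K_clean|/K_clean * 100% is averaged over
    non-overlapping neighbourhoods and frames (reference: the noise-free
    contrast of the same frames).  Returns columns
    ``fill, flagset, error_percent, mean_dn``; ``fill`` equals <I>/I_max of
    the digitized output up to clipping losses.
    """
    from .contrast_metrics import contrast_stack, per_pixel_error, spatial_contrast

    kmaps_clean = [
        spatial_contrast(f, neighbourhood) for f in clean_stack.frames
    ]
    ss = np.random.SeedSequence(seed)
    rows = []
    for fill in fills:
        for fs in flag_sets:
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            noisy = apply_camera(clean_stack, spec, fill, fs, seed=sub_seed)
            kn = contrast_stack(noisy, neighbourhood)
            errs = []
            for km_clean, kvals in zip(kmaps_clean, kn):
                rep = per_pixel_error(
                    kvals[None], reference=km_clean, neighbourhood=neighbourhood
                )
                errs.append(rep.error_percent)
            rows.append(
                {
                    "fill": fill,
                    "flagset": fs.label(),
                    "error_percent": float(np.mean(errs)),
                    "mean_dn": float(noisy.frames.mean()),
                }
            )
    return pd.DataFrame(rows)
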