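"""Dynamic speckle synthesis from moving point scatterers.

Each scatterer is a point source of a spherical wave.  The intensity at a
sensor pixel is the squared modulus of the superposed fields,

    I = |sum_n exp(i k r_n) / r_n|^2,

with k = 2*pi/lambda and r_n the particle-to-pixel distance.  Displacing the
particles between frames and averaging consecutive frames produces
exposure-integrated dynamic speckle.  A fast statistical generator
(`fast_speckle`) produces independent fully developed speckle frames by pupil
filtering of complex Gaussian fields; it is an equivalent of the particle
method only for statistically independent frames (T/tau_c = 0).

Lengths are in micrometres and times in microseconds throughout.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Optional

import numpy as np

from .errors import DomainError, ParameterError

__all__ = [
    "ParticleCloud",
    "SensorGrid",
    "MotionModel",
    "FrameStack",
    "synthesize_frame",
    "advance",
    "simulate_stack",
    "integrate_exposure",
    "fast_speckle",
    "rescale_speckle",
    "unpolarised_sum",
]

DEFAULT_WAVELENGTH = 0.785  # um (785 nm near-infrared laser diode)

try:  # optional acceleration; the numpy path is the reference implementation
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticleCloud:
    """Point scatterers in a 3-D box, each a source of a spherical wave.

    Parameters
    ----------
    positions
        (N, 3) array of particle coordinates in um.  The box occupies
        ``[0, volume_extent[i])`` along each axis.
    wavelength
        Optical wavelength in um.
    volume_extent
        Box dimensions (x, y, z) in um.
    """

    positions: np.ndarray
    wavelength: float = DEFAULT_WAVELENGTH
    volume_extent: np.ndarray = field(
        default_factory=lambda: np.full(3, 50 * DEFAULT_WAVELENGTH)
    )

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        ext = np.asarray(self.volume_extent, dtype=np.float64)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 1:
            raise ParameterError("positions must be a non-empty (N, 3) array")
        if self.wavelength <= 0:
            raise ParameterError("wavelength must be positive")
        if ext.shape != (3,) or np.any(ext <= 0):
            raise ParameterError("volume_extent must be three positive lengths")
        if np.any(pos < 0) or np.any(pos > ext):
            raise ParameterError("all particles must lie inside volume_extent")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "volume_extent", ext)

    @property
    def wavenumber(self) -> float:
        """k = 2*pi/lambda in rad/um."""
        return 2.0 * math.pi / self.wavelength

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def uniform_random(
        cls,
        n_particles: int = 1000,
        volume_extent=None,
        wavelength: float = DEFAULT_WAVELENGTH,
        rng: Optional[np.random.Generator] = None,
        seed: Optional[int] = None,
    ) -> "ParticleCloud":
        """Cloud of uniformly random particles in a box (default 50λ cube)."""
        if volume_extent is None:
            volume_extent = np.full(3, 50 * wavelength)
        ext = np.asarray(volume_extent, dtype=np.float64)
        if rng is None:
            rng = np.random.default_rng(seed)
        pos = rng.uniform(0.0, 1.0, size=(n_particles, 3)) * ext
        return cls(positions=pos, wavelength=wavelength, volume_extent=ext)


@dataclass(frozen=True)
class SensorGrid:
    """Pixel grid of the camera sensor.

    The sensor plane is normal to z at ``distance`` from the centre of the
    particle volume; pixels are laid out symmetrically around the optical
    axis with spacing ``pixel_pitch`` (um).
    """

    n_rows: int
    n_cols: int
    pixel_pitch: float
    distance: float

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ParameterError("sensor must have at least one pixel")
        if self.pixel_pitch <= 0 or self.distance <= 0:
            raise ParameterError("pixel_pitch and distance must be positive")

    def pixel_positions(self, cloud: ParticleCloud) -> np.ndarray:
        """(P, 3) pixel coordinates in the cloud's frame of reference."""
        ext = cloud.volume_extent
        centre = ext / 2.0
        ys = (np.arange(self.n_rows) - (self.n_rows - 1) / 2.0) * self.pixel_pitch
        xs = (np.arange(self.n_cols) - (self.n_cols - 1) / 2.0) * self.pixel_pitch
        Y, X = np.meshgrid(ys, xs, indexing="ij")
        z = centre[2] + self.distance
        out = np.empty((self.n_rows * self.n_cols, 3), dtype=np.float64)
        out[:, 0] = X.ravel() + centre[0]
        out[:, 1] = Y.ravel() + centre[1]
        out[:, 2] = z
        return out


@dataclass(frozen=True)
class MotionModel:
    """Particle dynamics: ordered (flow-like) or unordered (diffusive).

    ``speed_modulation``, if given, multiplies the ordered velocity at time
    t (us); it is how pulsatile flow is injected (see `signal_quality`).
    """

    kind: Literal["ordered", "unordered"]
    velocity: Optional[np.ndarray] = None  # um/us, ordered motion
    diffusion_coefficient: float = 0.0  # um^2/us, unordered motion
    speed_modulation: Optional[Callable[[float], float]] = None

    def __post_init__(self):
        if self.kind not in ("ordered", "unordered"):
            raise ParameterError("kind must be 'ordered' or 'unordered'")
        if self.kind == "ordered":
            v = np.zeros(3) if self.velocity is None else np.asarray(
                self.velocity, dtype=np.float64
            )
            if v.shape != (3,):
                raise ParameterError("velocity must be a 3-vector")
            object.__setattr__(self, "velocity", v)
        else:
            if self.diffusion_coefficient < 0:
                raise ParameterError("diffusion_coefficient must be >= 0")


@dataclass
class FrameStack:
    """Time-ordered stack of 2-D intensity frames.

    ``exposure_T = 0`` marks instantaneous frames; `integrate_exposure`
    produces finite exposures.  ``units`` transitions from 'normalized' to
    'electrons'/'DN' only through the camera module.
    """

    frames: np.ndarray  # (T, rows, cols)
    dt: float
    exposure_T: float = 0.0
    units: Literal["normalized", "electrons", "DN"] = "normalized"
    seed_record: dict = field(default_factory=dict)

    def __post_init__(self):
        f = np.asarray(self.frames)
        if f.ndim == 2:
            f = f[None]
        if f.ndim != 3:
            raise ParameterError("frames must be (time, rows, cols)")
        self.frames = f

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape[1:]

    # ---- TIFF + JSON sidecar round trip ----------------------------------
    def to_tiff(self, path) -> None:
        """Write a multi-page TIFF (frame-major) plus a JSON sidecar."""
        import tifffile

        path = Path(path)
        if self.units == "normalized":
            data = self.frames.astype(np.float32)
        else:
            maxv = float(np.nanmax(self.frames)) if self.frames.size else 0.0
            data = self.frames.astype(np.uint8 if maxv <= 255 else np.uint16)
        tifffile.imwrite(path, data)
        meta = {
            "dt": self.dt,
            "exposure_T": self.exposure_T,
            "units": self.units,
            "seed_record": self.seed_record,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tiff(cls, path) -> "FrameStack":
        import tifffile

        path = Path(path)
        frames = tifffile.imread(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            frames=np.asarray(frames),
            dt=float(meta.get("dt", 1.0)),
            exposure_T=float(meta.get("exposure_T", 0.0)),
            units=meta.get("units", "normalized"),
            seed_record=meta.get("seed_record", {}),
        )


# ---------------------------------------------------------------------------
# field superposition kernel
# ---------------------------------------------------------------------------

if _HAVE_NUMBA:

    @njit(fastmath=True, cache=False)
    def _superpose_f32(pos, px, k):  # pragma: no cover - exercised via wrapper
        n_px = px.shape[0]
        n = pos.shape[0]
        out = np.empty(n_px, dtype=np.float32)
        for p in range(n_px):
            re = np.float32(0.0)
            im = np.float32(0.0)
            x, y, z = px[p, 0], px[p, 1], px[p, 2]
            for i in range(n):
                dx = pos[i, 0] - x
                dy = pos[i, 1] - y
                dz = pos[i, 2] - z
                r = math.sqrt(dx * dx + dy * dy + dz * dz)
                ph = k * r
                re += math.cos(ph) / r
                im += math.sin(ph) / r
            out[p] = re * re + im * im
        return out


def _superpose_numpy(pos: np.ndarray, px: np.ndarray, k: float) -> np.ndarray:
    d = pos[:, None, :] - px[None, :, :]
    r = np.sqrt((d * d).sum(-1))
    if np.any(r == 0):
        raise DomainError("particle coincident with a pixel (r = 0)")
    ph = k * r
    re = (np.cos(ph) / r).sum(0)
    im = (np.sin(ph) / r).sum(0)
    return (re * re + im * im).astype(np.float32)


def _superpose(pos: np.ndarray, px: np.ndarray, k: float) -> np.ndarray:
    if _HAVE_NUMBA:
        return _superpose_f32(
            np.ascontiguousarray(pos, dtype=np.float32),
            np.ascontiguousarray(px, dtype=np.float32),
            np.float32(k),
        )
    return _superpose_numpy(pos, px, k)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def synthesize_frame(cloud: ParticleCloud, sensor: SensorGrid) -> np.ndarray:
    """Instantaneous speckle frame: |sum_n exp(i k r_n)/r_n|^2 per pixel.

    Deterministic given the cloud and sensor.  Raises `DomainError` if the
    sensor plane can touch the particle volume (r_n = 0 possible).
    """
    if sensor.distance <= cloud.volume_extent[2] / 2.0:
        raise DomainError(
            "sensor plane intersects the particle volume; r_n = 0 possible"
        )
    px = sensor.pixel_positions(cloud)
    out = _superpose(cloud.positions, px, cloud.wavenumber)
    return out.reshape(sensor.n_rows, sensor.n_cols)


def advance(
    cloud: ParticleCloud,
    motion: MotionModel,
    dt: float,
    rng: Optional[np.random.Generator] = None,
    t: float = 0.0,
) -> ParticleCloud:
    """Displace particles by one time step of the motion model.

    Ordered motion shifts every particle by velocity*dt (optionally scaled
    by the speed modulation at time t); unordered motion adds independent
    zero-mean Gaussian steps of variance 2*D*dt per axis.

    Particles leaving the box are re-wrapped to keep the density constant.
    For ordered motion the wrap is periodic along the flow axis while the
    transverse coordinates are re-randomised: a scatterer leaving the volume
    is replaced by a fresh one entering upstream.  A purely periodic wrap
    would make the whole configuration recur exactly with period
    extent/speed, imprinting a spurious long-time correlation on every pixel.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    pos = cloud.positions.copy()
    ext = cloud.volume_extent
    if motion.kind == "ordered":
        scale = motion.speed_modulation(t) if motion.speed_modulation else 1.0
        step = motion.velocity * scale * dt
        pos += step
        if np.any(step != 0):
            flow_axis = int(np.argmax(np.abs(motion.velocity)))
            out_mask = (pos[:, flow_axis] < 0) | (pos[:, flow_axis] >= ext[flow_axis])
            if out_mask.any():
                if rng is None:
                    rng = np.random.default_rng()
                pos[out_mask, flow_axis] = np.mod(
                    pos[out_mask, flow_axis], ext[flow_axis]
                )
                for ax in range(3):
                    if ax != flow_axis:
                        pos[out_mask, ax] = rng.uniform(
                            0.0, ext[ax], out_mask.sum()
                        )
    else:
        if motion.diffusion_coefficient > 0:
            if rng is None:
                rng = np.random.default_rng()
            sigma = math.sqrt(2.0 * motion.diffusion_coefficient * dt)
            pos += rng.normal(0.0, sigma, size=pos.shape)
            pos = np.mod(pos, ext)
    return replace(cloud, positions=pos)


def simulate_stack(
    cloud: ParticleCloud,
    sensor: SensorGrid,
    motion: MotionModel,
    n_frames: int,
    dt: float,
    seed: Optional[int] = None,
    tau_c_hint: Optional[float] = None,
) -> FrameStack:
    """Stack of instantaneous frames with particles advanced between frames.

    ``tau_c_hint`` (us) triggers a warning when dt exceeds tau_c/10, i.e.
    when the frame interval undersamples the target decorrelation.
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    if tau_c_hint is not None and dt > tau_c_hint / 10.0:
        warnings.warn(
            f"dt={dt} exceeds tau_c/10={tau_c_hint / 10.0}; "
            "exposure integration will undersample the dynamics",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, sensor.n_rows, sensor.n_cols), dtype=np.float32)
    current = cloud
    for i in range(n_frames):
        frames[i] = synthesize_frame(current, sensor)
        if i < n_frames - 1:
            current = advance(current, motion, dt, rng=rng, t=i * dt)
    return FrameStack(
        frames=frames,
        dt=dt,
        exposure_T=0.0,
        units="normalized",
        seed_record={"seed": seed, "generator": "particle"},
    )


def integrate_exposure(stack: FrameStack, T: float) -> FrameStack:
    """Average non-overlapping blocks of m = T/dt frames into exposures."""
    if T < stack.dt:
        raise ParameterError("exposure T must be >= frame interval dt")
    m = T / stack.dt
    if abs(m - round(m)) > 1e-9:
        raise ParameterError("T must be an integer multiple of dt")
    m = int(round(m))
    n_blocks = stack.n_frames // m
    if n_blocks == 0:
        raise ParameterError("stack shorter than one exposure")
    if stack.n_frames % m:
        warnings.warn(
            f"dropping {stack.n_frames % m} trailing frames "
            f"(stack length not divisible by {m})",
            stacklevel=2,
        )
    rows, cols = stack.shape
    blocks = stack.frames[: n_blocks * m].reshape(n_blocks, m, rows, cols)
    out = blocks.mean(axis=1, dtype=np.float64).astype(np.float32)
    return FrameStack(
        frames=out,
        dt=T,
        exposure_T=T,
        units=stack.units,
        seed_record=dict(stack.seed_record, integrated_from_dt=stack.dt),
    )


# ---------------------------------------------------------------------------
# fast statistical generator
# ---------------------------------------------------------------------------

def _pupil_mask(shape, radius: float) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0]) * shape[0]
    fx = np.fft.fftfreq(shape[1]) * shape[1]
    FY, FX = np.meshgrid(fy, fx, indexing="ij")
    return (FY * FY + FX * FX) <= radius * radius


def _mask_fwhm(shape, radius: float) -> float:
    """Expected intensity-autocovariance FWHM for a given pupil radius.

    For a circular complex Gaussian field with spectral support ``mask`` the
    field coherence is the normalised inverse FFT of the mask and the
    intensity autocovariance is its squared modulus; no sampling needed.
    """
    from .contrast_metrics import _fwhm_of_autocov

    mask = _pupil_mask(shape, radius)
    mu = np.fft.ifft2(mask.astype(np.float64))
    acov = np.fft.fftshift(np.abs(mu) ** 2)
    return _fwhm_of_autocov(acov / acov.max())


def _calibrate_radius(shape, target_fwhm: float) -> float:
    """Bisect the pupil radius so the expected autocovariance FWHM matches."""
    n_min = min(shape)
    lo, hi = 1.0, n_min / math.sqrt(2.0)  # full square coverage ~ white noise
    f_lo, f_hi = _mask_fwhm(shape, lo), _mask_fwhm(shape, hi)
    if not (f_hi <= target_fwhm <= f_lo):
        raise ParameterError(
            f"speckle FWHM {target_fwhm} px unreachable on a {shape} frame "
            f"(reachable range ~[{f_hi:.2f}, {f_lo:.2f}] px)"
        )
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        f_mid = _mask_fwhm(shape, mid)
        if abs(f_mid - target_fwhm) < 5e-3 * target_fwhm:
            return mid
        if f_mid > target_fwhm:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fast_speckle(
    shape,
    speckle_fwhm: float,
    n_frames: int,
    beta: float = 1.0,
    seed: Optional[int] = None,
) -> FrameStack:
    """Statistically independent fully developed speckle frames.

    A complex Gaussian field is filtered with a circular pupil whose radius
    is calibrated so the intensity autocovariance FWHM equals
    ``speckle_fwhm`` (pixels).  ``beta = 0.5`` is realised as the mean of two
    independent intensity patterns (the unpolarised-detection statistics).

    Only valid as a stand-in for the particle method when frames are meant
    to be statistically independent (the T/tau_c = 0 experiments).
    """
    if speckle_fwhm < 0.3:
        raise ParameterError("speckle_fwhm must be >= 0.3 px")
    if beta not in (1.0, 0.5):
        raise ParameterError("beta must be 1 or 0.5")
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    shape = tuple(int(s) for s in shape)
    radius = _calibrate_radius(shape, speckle_fwhm)
    mask = _pupil_mask(shape, radius)
    norm = math.sqrt(mask.sum())
    rng = np.random.default_rng(seed)
    n_fields = n_frames * (2 if beta == 0.5 else 1)
    frames = np.empty((n_fields,) + shape, dtype=np.float32)
    for i in range(n_fields):
        g = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        f = np.fft.ifft2(g * mask) * (shape[0] * shape[1]) / norm
        frames[i] = (f.real**2 + f.imag**2) / 2.0  # mean intensity ~ 1
    if beta == 0.5:
        frames = 0.5 * (frames[0::2] + frames[1::2])
    return FrameStack(
        frames=frames,
        dt=np.inf,
        exposure_T=0.0,
        units="normalized",
        seed_record={
            "seed": seed,
            "generator": "fast_speckle",
            "pupil_radius": radius,
            "beta": beta,
        },
    )


def rescale_speckle(stack: FrameStack, factor: int) -> FrameStack:
    """Box-filter each frame with a factor x factor kernel and downsample.

    Divides the measured speckle-to-pixel size ratio by ~factor; this is the
    decimation chain used to derive small speckle sizes from a single
    synthesis at a large speckle size.
    """
    factor = int(factor)
    if factor < 1:
        raise ParameterError("factor must be >= 1")
    if factor == 1:
        return stack
    t, rows, cols = stack.frames.shape
    if rows % factor or cols % factor:
        raise ParameterError(
            f"frame dimensions {rows}x{cols} not divisible by {factor}"
        )
    out = (
        stack.frames.reshape(t, rows // factor, factor, cols // factor, factor)
        .mean(axis=(2, 4), dtype=np.float64)
        .astype(np.float32)
    )
    return FrameStack(
        frames=out,
        dt=stack.dt,
        exposure_T=stack.exposure_T,
        units=stack.units,
        seed_record=dict(stack.seed_record, decimated_by=factor),
    )


def unpolarised_sum(stack_a: FrameStack, stack_b: FrameStack) -> FrameStack:
    """Incoherent sum of two polarisation channels: element-wise mean.

    For independent fully developed inputs the contrast drops by 1/sqrt(2)
    relative to a single channel (beta 1 -> 0.5).
    """
    if stack_a.frames.shape != stack_b.frames.shape:
        raise ParameterError("stacks must have identical shapes")
    out = 0.5 * (
        stack_a.frames.astype(np.float64) + stack_b.frames.astype(np.float64)
    )
    return FrameStack(
        frames=out.astype(np.float32),
        dt=stack_a.dt,
        exposure_T=stack_a.exposure_T,
        units=stack_a.units,
        seed_record={
            "combined": [stack_a.seed_record, stack_b.seed_record],
            "operation": "unpolarised_sum",
        },
    )
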