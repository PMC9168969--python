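"""2-D surrogate for the mammographic imaging chain.

A spherical mass projected onto a detector produces an intensity profile
proportional to the chord length through the sphere: at radial offset
``rho`` from the lesion center the normalized signal is

    s(rho) = sqrt(r^2 - rho^2) / r        for rho <= r,  else 0,

peaking at 1 in the center and vanishing at the rim.  The lesion is added
to a textured background patch sampled at mammographic pixel pitch
(default 0.07 mm).  The background is isotropic power-law ("1/f^beta")
noise, a standard surrogate for mammographic texture; the full anatomy
simulation and vendor image processing of a real pipeline are out of
scope, so any comparison with human-reader results must go through the
observer model instead.

Coordinate convention: intensities are stored row-major, positions refer
to pixel centers, and the origin is the patch center.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np


@dataclass(frozen=True)
class PatchSpec:
    lesion_diameter: float  # mm
    pixel_pitch: float = 0.07  # mm
    patch_size: int = 256  # pixels per side
    lesion_contrast: float = 1.0  # peak amplitude above background
    background: str = "powerlaw"  # "powerlaw" | "flat"
    background_beta: float = 3.0  # power-spectrum exponent
    background_amplitude: float = 0.0  # RMS of the texture; 0 = noiseless
    background_level: float = 0.0  # flat pedestal
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.lesion_diameter <= 0:
            raise ValueError("lesion_diameter must be positive")
        if self.background not in ("powerlaw", "flat"):
            raise ValueError(f"unknown background model {self.background!r}")
        # the lesion must fit with >= 20% margin on each side
        if self.lesion_diameter * 1.4 > self.patch_size * self.pixel_pitch:
            raise ValueError(
                f"lesion of {self.lesion_diameter} mm does not fit a "
                f"{self.patch_size}-px patch at {self.pixel_pitch} mm pitch"
            )


def power_law_background(
    size: int, beta: float, amplitude: float, rng
) -> np.ndarray:
    """Isotropic 1/f^beta noise field with the requested RMS amplitude."""
    if amplitude == 0:
        return np.zeros((size, size))
    white = rng.standard_normal((size, size))
    fx = np.fft.fftfreq(size)
    f = np.hypot(*np.meshgrid(fx, fx, indexing="ij"))
    f[0, 0] = np.inf  # kill DC so the mean is zero
    filt = f ** (-beta / 2.0)
    field = np.fft.ifft2(np.fft.fft2(white) * filt).real
    return field * (amplitude / field.std())


def _lesion_signal(spec: PatchSpec) -> np.ndarray:
    r = spec.lesion_diameter / 2.0  # mm
    half = (spec.patch_size - 1) / 2.0
    idx = (np.arange(spec.patch_size) - half) * spec.pixel_pitch
    rho2 = idx[:, None] ** 2 + idx[None, :] ** 2
    signal = np.zeros_like(rho2)
    inside = rho2 <= r**2
    signal[inside] = np.sqrt(r**2 - rho2[inside]) / r
    return spec.lesion_contrast * signal


def render_patch(spec: PatchSpec) -> np.ndarray:
    """Render the lesion projection on its background; float intensities."""
    rng = np.random.default_rng(spec.seed)
    if spec.background == "powerlaw":
        bg = power_law_background(
            spec.patch_size, spec.background_beta, spec.background_amplitude, rng
        )
    else:
        bg = np.zeros((spec.patch_size, spec.patch_size))
    return bg + spec.background_level + _lesion_signal(spec)


def auto_measure(
    image: np.ndarray,
    pixel_pitch: float,
    center_hint: tuple[int, int] | None = None,
    threshold_frac: float = 0.1,
) -> tuple[float, float]:
    """Measure lesion extent (mm) along two orthogonal axes.

    The background level is estimated as the median of the four corner
    blocks, subtracted, and the contiguous run of pixels exceeding
    ``threshold_frac`` of the peak along the central row and column
    through ``center_hint`` (default: brightest pixel) gives the two
    sizes, rounded to 0.1 mm.  Raises ``LesionNotFoundError`` when no
    pixel clears the threshold.
    """
    img = np.asarray(image, dtype=float)
    k = max(img.shape[0] // 8, 2)
    corners = np.concatenate(
        [
            img[:k, :k].ravel(),
            img[:k, -k:].ravel(),
            img[-k:, :k].ravel(),
            img[-k:, -k:].ravel(),
        ]
    )
    prof = img - np.median(corners)
    noise_floor = 3.0 * corners.std() if corners.std() > 0 else 1e-9
    peak = prof.max()
    if peak <= noise_floor:
        raise LesionNotFoundError("no above-background region found")
    if center_hint is None:
        center_hint = np.unravel_index(np.argmax(prof), prof.shape)
    row, col = center_hint
    thr = threshold_frac * peak

    def _extent(line: np.ndarray, center: int) -> float:
        above = line > thr
        if not above[center]:
            raise LesionNotFoundError("center pixel below threshold")
        lo = center
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = center
        while hi < line.size - 1 and above[hi + 1]:
            hi += 1
        return round((hi - lo + 1) * pixel_pitch, 1)

    return _extent(prof[row, :], col), _extent(prof[:, col], row)


class LesionNotFoundError(RuntimeError):
    """auto_measure found no signal above the background."""


def write_patch(image: np.ndarray, spec: PatchSpec, path) -> None:
    """Write a 16-bit TIFF of the patch with a JSON sidecar of the spec.

    Intensities are linearly rescaled to the full 16-bit range; the
    sidecar records the spec (including ground-truth diameter) and the
    rescaling so the image is interpretable on its own.
    """
    import tifffile

    lo, hi = float(image.min()), float(image.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    u16 = ((image - lo) * scale).astype(np.uint16)
    tifffile.imwrite(str(path), u16)
    sidecar = dict(asdict(spec), intensity_offset=lo, intensity_scale=scale)
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
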