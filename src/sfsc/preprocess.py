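"""Corrections that extend the validity of the self-FSC.

The naive SFSC is trustworthy only when the noise is white and the signal
spectrum decays rapidly.  When those conditions fail they can be restored
from the data itself:

* colored noise  ->  estimate the per-shell noise variance (from the
  region outside a sphere enclosing the structure, or from a background
  slice of a tomogram) and *whiten* the measurement.  Whitening divides
  every Fourier coefficient by the noise standard deviation of its shell;
  it changes the signal but leaves the per-shell SSNR untouched.
* slowly decaying signal  ->  *upsample* by zero-padding in Fourier
  space.  On the upsampled grid the aliasing partners of every in-band
  frequency carry zero variance, and after subtracting the (known,
  post-whitening) noise floor from the correlation numerator the SFSC
  estimates the expected FSC directly, with no variance correction.

Noise profiles use the unnormalized power-spectrum convention
(mean |FFT|^2 per shell), matching :func:`sfsc.grid.power_spectrum`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlate import CorrelationCurve, sfsc
from .grid import Measurement, RadialProfile, build_shell_index, power_spectrum, radial_average

__all__ = [
    "NoiseModel",
    "estimate_noise_sphere",
    "estimate_noise_slice",
    "whiten",
    "upsample",
    "sfsc_upsampled",
]

#: Relative variance floor used when dividing by the noise spectrum.
FLOOR_FRACTION = 1e-6


@dataclass
class NoiseModel:
    """Per-shell noise variance used for whitening.

    ``sigma2`` holds the radial noise power (unnormalized convention);
    ``source`` records how it was obtained (``sphere_exterior``,
    ``background_slice`` or ``known``).  Division never uses values below
    ``floor`` (a small fraction of the peak, set on construction).
    """

    sigma2: RadialProfile
    source: str
    floor: float = 0.0

    def __post_init__(self) -> None:
        peak = float(np.nanmax(self.sigma2.value))
        if not peak > 0:
            raise ValueError("noise profile must contain positive power")
        if self.floor <= 0:
            self.floor = peak * FLOOR_FRACTION

    def floored(self) -> np.ndarray:
        """Per-shell variance with the floor applied (NaN -> floor)."""
        v = np.where(np.isfinite(self.sigma2.value), self.sigma2.value, 0.0)
        return np.maximum(v, self.floor)

    def smoothed(self, window: int) -> "NoiseModel":
        """Moving-average smoothing of the radial profile (odd window)."""
        if window <= 1:
            return self
        v = self.floored()
        kernel = np.ones(window) / window
        sm = np.convolve(np.pad(v, window // 2, mode="edge"), kernel, mode="valid")
        prof = RadialProfile(
            self.sigma2.shell.copy(), self.sigma2.frequency.copy(), sm[: len(v)],
            self.sigma2.n_indices.copy(), self.sigma2.complete.copy(),
            np.ones(len(v), dtype=bool),
        )
        return NoiseModel(sigma2=prof, source=self.source, floor=self.floor)


def estimate_noise_sphere(m: Measurement, radius: float) -> NoiseModel:
    """Noise spectrum from the region outside a sphere of ``radius`` (A).

    Masks the measurement to the exterior of a centered sphere assumed to
    enclose the structure, computes the spherically averaged power
    spectrum, and divides by the exterior volume fraction to undo the
    total-power attenuation of masking (the sharp mask still convolves
    the spectrum slightly; that residual leakage is accepted as a known
    bias of this deliberately simple estimator).
    """
    if m.ndim not in (2, 3):
        raise ValueError("sphere-exterior estimation needs a 2-D or 3-D measurement")
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    coords = np.meshgrid(
        *[(np.arange(n) - n / 2.0) * m.voxel_size for n in m.shape], indexing="ij"
    )
    dist2 = sum(c**2 for c in coords)
    exterior = dist2 >= radius**2
    if not exterior.any():
        raise ValueError(
            f"no samples outside radius {radius} A; the sphere covers the whole box"
        )
    fraction = exterior.mean()
    masked = Measurement(m.data * exterior, m.voxel_size, dict(m.meta))
    ps = power_spectrum(masked)
    prof = RadialProfile(
        ps.shell, ps.frequency, ps.value / fraction,
        ps.n_indices, ps.complete, ps.defined,
    )
    return NoiseModel(sigma2=prof, source="sphere_exterior")


def estimate_noise_slice(
    m: Measurement, axis: int, start: int, stop: int
) -> NoiseModel:
    """Noise spectrum from a background slab of a tomogram.

    For a 3-D measurement, extracts the planes ``start:stop`` along
    ``axis`` and averages their 2-D power spectra; the profile whitens
    2-D targets shaped like those planes.  A 2-D measurement may pass a
    row range (the full range reproduces its own power spectrum).
    """
    n = m.shape[axis]
    start, stop = int(start), int(stop)
    if not (0 <= start < stop <= n):
        raise ValueError(f"slab [{start}:{stop}) out of bounds for axis {axis} (length {n})")
    slab = np.moveaxis(m.data, axis, 0)[start:stop]
    if m.ndim == 3:
        planes = slab
        index = build_shell_index(planes.shape[1:])
        power = np.zeros(index.n_shells)
        for p in planes:
            power += radial_average(np.abs(np.fft.fftn(p)) ** 2, index,
                                    voxel_size=m.voxel_size).value
        power /= len(planes)
        base = radial_average(np.zeros(index.shape), index, voxel_size=m.voxel_size)
        prof = RadialProfile(base.shell, base.frequency, power,
                             base.n_indices, base.complete, base.defined)
    else:
        sub = Measurement(np.ascontiguousarray(slab), m.voxel_size, dict(m.meta))
        prof = power_spectrum(sub)
    return NoiseModel(sigma2=prof, source="background_slice")


def whiten(m: Measurement, noise: NoiseModel) -> Measurement:
    """Divide every Fourier coefficient by its shell's noise std.

    After whitening with the true noise spectrum the noise is white with
    unit per-coefficient power (unnormalized convention); the per-shell
    SSNR is unchanged.  Shells beyond the supplied profile fall back to
    the floor.
    """
    index = build_shell_index(m.shape)
    s2 = noise.floored()
    if len(s2) < index.n_shells:
        s2 = np.concatenate([s2, np.full(index.n_shells - len(s2), noise.floor)])
    weights = 1.0 / np.sqrt(s2[: index.n_shells])
    x = np.fft.fftn(m.data) * weights[index.radii]
    out = np.fft.ifftn(x).real
    meta = dict(m.meta)
    meta["whitened"] = True
    return Measurement(out, m.voxel_size, meta)


def upsample(m: Measurement, factor: int = 2) -> Measurement:
    """Band-limited upsampling by zero-padding in Fourier space.

    Fourier coefficients are embedded centrally in a grid with every axis
    doubled (the Nyquist plane is split symmetrically to keep the result
    exactly real) and scaled so the original samples are preserved at the
    even grid points.  The voxel size halves; all shells above the
    original Nyquist carry exactly zero power.
    """
    if factor != 2:
        raise ValueError("only factor-2 upsampling is supported")
    d = m.ndim
    xs = np.fft.fftshift(np.fft.fftn(m.data))
    out_shape = tuple(2 * n for n in m.shape)
    out = np.zeros(out_shape, dtype=complex)
    center = tuple(slice(n // 2, n // 2 + n) for n in m.shape)
    out[center] = xs
    # Split each original-Nyquist plane between -N/2 and +N/2 so the
    # padded spectrum stays Hermitian (exactly real inverse transform).
    for ax, n in enumerate(m.shape):
        lo = [slice(None)] * d
        hi = [slice(None)] * d
        lo[ax] = n // 2            # frequency -N/2 in the shifted layout
        hi[ax] = n // 2 + n        # frequency +N/2
        out[tuple(lo)] *= 0.5
        out[tuple(hi)] = out[tuple(lo)]
    data = np.fft.ifftn(np.fft.ifftshift(out)).real * (2**d)
    meta = dict(m.meta)
    meta["upsampled"] = True
    return Measurement(data, m.voxel_size / 2.0, meta)


def sfsc_upsampled(m_whitened: Measurement) -> CorrelationCurve:
    """Self-FSC with the upsampling and noise-floor corrections.

    Requires a *whitened* measurement (unit per-coefficient noise power).
    The measurement is upsampled by 2, split per axis, and the correlation
    numerator is reduced by the known noise floor (n_r * sigma^2/4 per
    shell, where sigma^2 is the per-coefficient noise power of the
    upsampled grid).  Because every aliasing partner of an in-band
    frequency has zero variance after zero-padding, the result estimates
    the expected FSC directly — no variance correction is applied or
    needed.  Shells are labelled on the original grid's frequency axis;
    the complete band is exactly the original Nyquist ball.
    """
    if not m_whitened.meta.get("whitened", False):
        raise ValueError(
            "sfsc_upsampled requires a whitened measurement (run whiten() first)"
        )
    up = upsample(m_whitened, 2)
    d = m_whitened.ndim
    # Whitened noise has unit per-coefficient power; upsampling scales
    # coefficients by 2**d, so the in-band noise power is 4**d and the
    # cross-term floor per coefficient is 4**d / 4.
    gamma = 4.0**d / 4.0
    curve = sfsc(up, gamma=gamma)
    meta = dict(curve.metadata)
    meta.update({
        "estimator": "upsampled_gamma",
        "variance_corrected": True,   # on the FSC scale by construction
        "upsampled": True,
    })
    return CorrelationCurve(curve.profile, "sfsc_corrected", meta)
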