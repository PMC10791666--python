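"""Shell-diagonal filtering of measurements driven by the self-FSC.

Under the Gaussian model the minimum-MSE linear estimate of the signal is
the Wiener filter, a per-shell multiplication by SSNR/(1 + SSNR).  Since
the (corrected) SFSC estimates the expected FSC = SSNR/(1 + SSNR), the
curve itself can be used directly as the shell weights — a data-driven,
parameter-free Wiener filter from a single measurement, which is the
tomogram-denoising application of this package.  A conventional hard
low-pass filter is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlate import (
    DEFAULT_THRESHOLD,
    CorrelationCurve,
    correct_variance,
    resolution_at_threshold,
    sfsc,
)
from .grid import Measurement, RadialProfile, build_shell_index
from .preprocess import NoiseModel, sfsc_upsampled, whiten

__all__ = ["FilterResult", "wiener_filter", "self_wiener", "lowpass"]


@dataclass
class FilterResult:
    """A filtered measurement plus the shell weights that produced it."""

    filtered: Measurement
    filter_profile: RadialProfile
    provenance: dict


def _apply_shell_weights(
    m: Measurement, weights: np.ndarray, freq: np.ndarray | None = None
) -> tuple[Measurement, RadialProfile]:
    """Multiply each Fourier shell of ``m`` by its weight.

    Shells beyond the supplied weights (corner frequencies) are zeroed.
    """
    index = build_shell_index(m.shape)
    w = np.zeros(index.n_shells)
    k = min(len(weights), index.n_shells)
    w[:k] = np.nan_to_num(weights[:k], nan=0.0)
    if np.any(w < 0) or np.any(w > 1 + 1e-9):
        raise ValueError("filter weights must lie in [0, 1]")
    w = np.clip(w, 0.0, 1.0)
    data = np.fft.ifftn(np.fft.fftn(m.data) * w[index.radii]).real
    profile = RadialProfile(
        shell=np.arange(index.n_shells),
        frequency=index.frequency_of_shell(m.voxel_size) if freq is None else freq,
        value=w,
        n_indices=index.shell_counts.copy(),
        complete=index.complete.copy(),
        defined=np.ones(index.n_shells, dtype=bool),
    )
    return Measurement(data, m.voxel_size, dict(m.meta)), profile


def wiener_filter(m: Measurement, ssnr: CorrelationCurve) -> FilterResult:
    """Apply the Wiener filter 1/(1 + 1/SSNR(r)) per Fourier shell.

    SSNR = 0 shells are zeroed, SSNR = inf shells pass unchanged;
    undefined shells are treated as pure noise (weight 0).  A negative
    SSNR is an error.
    """
    if ssnr.kind != "ssnr":
        raise ValueError(f"expected an ssnr curve, got kind '{ssnr.kind}'")
    v = ssnr.profile.value
    defined = np.asarray(ssnr.profile.defined)
    if np.any(v[defined] < 0):
        raise ValueError("SSNR must be nonnegative")
    weights = np.zeros(len(v))
    finite = defined & np.isfinite(v)
    weights[finite] = v[finite] / (1.0 + v[finite])
    weights[defined & np.isinf(v)] = 1.0
    filtered, profile = _apply_shell_weights(m, weights)
    return FilterResult(filtered, profile, {"source": "ssnr", "filter": "wiener"})


def self_wiener(
    m: Measurement,
    noise: NoiseModel | None = None,
    *,
    use_upsampling: bool = False,
    lowpass_at_threshold: bool = False,
    threshold: float = DEFAULT_THRESHOLD,
    filter_whitened: bool = False,
) -> FilterResult:
    """Data-driven Wiener filter: SFSC shell weights from ``m`` itself.

    Pipeline: whiten (when a noise model is given; otherwise the caller
    asserts white noise and rapid signal decay) -> SFSC with the
    applicable corrections (variance correction, or the upsampled
    noise-floor estimator when ``use_upsampling``) -> clamp negative
    shells to 0 -> weight the shells of the *original* measurement (or of
    the whitened one with ``filter_whitened=True``).  Optionally composes
    a hard low-pass at the curve's threshold crossing, which can subtly
    enhance contrast.
    """
    if noise is not None:
        mw = whiten(m, noise)
    else:
        mw = m
    if use_upsampling:
        curve = sfsc_upsampled(mw)
    else:
        curve = correct_variance(sfsc(mw))

    weights = np.where(np.asarray(curve.profile.defined), curve.profile.value, 0.0)
    weights = np.clip(weights, 0.0, 1.0)

    cutoff = None
    if lowpass_at_threshold:
        res = resolution_at_threshold(curve, threshold, voxel_size=m.voxel_size)
        cutoff = res.resolution
        freq = curve.profile.frequency
        weights = np.where(freq <= 1.0 / cutoff, weights, 0.0)

    target = mw if filter_whitened else m
    filtered, profile = _apply_shell_weights(target, weights)
    return FilterResult(
        filtered,
        profile,
        {
            "filter": "self_wiener",
            "curve_kind": curve.kind,
            "whitened": noise is not None,
            "upsampled": use_upsampling,
            "filter_whitened": filter_whitened,
            "lowpass_cutoff": cutoff,
        },
    )


def lowpass(m: Measurement, cutoff: float) -> FilterResult:
    """Hard (brick-wall) low-pass filter at ``cutoff`` Angstrom.

    Shells at resolutions finer than ``cutoff`` are zeroed; the cutoff
    must be no finer than Nyquist (2 * voxel size).
    """
    if cutoff < 2.0 * m.voxel_size:
        raise ValueError(
            f"cutoff {cutoff} A is finer than Nyquist {2 * m.voxel_size} A"
        )
    index = build_shell_index(m.shape)
    freq = index.frequency_of_shell(m.voxel_size)
    weights = (freq <= 1.0 / cutoff).astype(float)
    filtered, profile = _apply_shell_weights(m, weights)
    return FilterResult(filtered, profile, {"filter": "lowpass", "cutoff": cutoff})
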