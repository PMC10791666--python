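"""Fourier shell correlation, its single-measurement variant and SSNR.

The FSC between two measurements y1, y2 is, per shell S_r,

    FSC(r) = sum_{k in S_r} Re(conj(Y1[k]) Y2[k]) / (||Y1||_r ||Y2||_r).

The self-FSC (SFSC) replaces the two measurements by the even/odd
decimated halves of a single measurement, one split per axis, with the
odd half phase-corrected; the reported curve is the unweighted mean of
the per-axis curves.  Because the two halves share the same noise
realization through aliasing, the expected SFSC under white noise and a
rapidly decaying signal spectrum is lambda^2/(lambda^2 + 2 sigma^2)
rather than the FSC's lambda^2/(lambda^2 + sigma^2); the variance
correction v -> 2v/(1+v) maps one onto the other.  The SSNR follows as
v/(1-v), and a threshold crossing of the curve gives a resolution
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .grid import (
    Measurement,
    RadialProfile,
    ShellIndex,
    build_shell_index,
    shell_sum,
)
from .split import phase_correct_odd, split_all_axes, split_quadrants_2d

__all__ = [
    "CorrelationCurve",
    "ResolutionResult",
    "fsc",
    "sfsc",
    "checkerboard_sfsc",
    "correct_variance",
    "efsc_analytic",
    "esfsc_analytic_1d",
    "ssnr_from_curve",
    "ssnr_direct",
    "resolution_at_threshold",
    "DEFAULT_THRESHOLD",
]

#: Single-map resolution criterion: FSC threshold 1/7.
DEFAULT_THRESHOLD = 1.0 / 7.0


@dataclass
class CorrelationCurve:
    """A per-shell correlation (or SSNR) curve with its provenance.

    ``kind`` is one of ``fsc``, ``sfsc_raw``, ``sfsc_corrected``, ``efsc``,
    ``esfsc``, ``ssnr``.  ``metadata`` records every transformation applied
    (phase/variance corrections, whitening, upsampling, axes averaged) so
    that no correction is ever silent.
    """

    profile: RadialProfile
    kind: str
    metadata: dict = field(default_factory=dict)

    @property
    def value(self) -> np.ndarray:
        return self.profile.value

    @property
    def shell(self) -> np.ndarray:
        return self.profile.shell

    @property
    def frequency(self) -> np.ndarray:
        return self.profile.frequency


def _curve_profile(
    num: np.ndarray,
    den: np.ndarray,
    index: ShellIndex,
    voxel_size: float,
) -> RadialProfile:
    defined = (index.shell_counts > 0) & (den > 0)
    value = np.full(index.n_shells, np.nan)
    value[defined] = num[defined] / den[defined]
    return RadialProfile(
        shell=np.arange(index.n_shells),
        frequency=index.frequency_of_shell(voxel_size),
        value=value,
        n_indices=index.shell_counts.copy(),
        complete=index.complete.copy(),
        defined=defined,
    )


def _shell_correlation(
    fa: np.ndarray,
    fb: np.ndarray,
    index: ShellIndex,
    voxel_size: float,
    gamma: float = 0.0,
) -> RadialProfile:
    """Normalized cross-correlation over shells of two Fourier grids.

    ``gamma`` (per-coefficient) is subtracted from the numerator shell sum
    as ``n_r * gamma`` before normalization (the noise-floor subtraction
    of the upsampled estimator); 0 leaves the plain correlation.
    """
    num = shell_sum((np.conj(fa) * fb).real, index)
    if gamma:
        num = num - index.shell_counts * gamma
    pa = shell_sum(np.abs(fa) ** 2, index)
    pb = shell_sum(np.abs(fb) ** 2, index)
    den = np.sqrt(pa * pb)
    return _curve_profile(num, den, index, voxel_size)


def fsc(
    a: Measurement,
    b: Measurement,
    index: ShellIndex | None = None,
) -> CorrelationCurve:
    """Fourier shell correlation between two like-shaped measurements."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.isclose(a.voxel_size, b.voxel_size):
        raise ValueError("voxel sizes differ")
    if index is None:
        index = build_shell_index(a.shape)
    if index.shape != a.shape:
        raise ValueError("shell index shape does not match measurements")
    prof = _shell_correlation(
        np.fft.fftn(a.data), np.fft.fftn(b.data), index, a.voxel_size
    )
    return CorrelationCurve(prof, "fsc", {"voxel_size": a.voxel_size})


def _average_axis_curves(
    curves: list[RadialProfile],
) -> RadialProfile:
    """Unweighted mean of per-axis curves, shell by shell.

    A shell of the averaged curve is defined (complete) only where every
    per-axis curve defines (completes) it.
    """
    n = max(len(c) for c in curves)

    def pad(arr, fill):
        out = np.full(n, fill, dtype=arr.dtype if arr.dtype != bool else bool)
        out[: len(arr)] = arr
        return out

    values = np.stack([pad(c.value, np.nan) for c in curves])
    defined = np.stack([pad(np.asarray(c.defined), False) for c in curves])
    complete = np.stack([pad(c.complete, False) for c in curves])
    counts = np.stack([pad(c.n_indices, 0) for c in curves])
    freq = pad(curves[0].frequency, np.nan)
    for c in curves[1:]:
        f = pad(c.frequency, np.nan)
        m = np.isnan(freq)
        freq[m] = f[m]

    all_defined = defined.all(axis=0)
    mean = np.full(n, np.nan)
    mean[all_defined] = values[:, all_defined].mean(axis=0)
    return RadialProfile(
        shell=np.arange(n),
        frequency=freq,
        value=mean,
        n_indices=counts.min(axis=0),
        complete=complete.all(axis=0),
        defined=all_defined,
    )


def sfsc(
    m: Measurement,
    phase_correction: bool = True,
    gamma: float = 0.0,
) -> CorrelationCurve:
    """Self Fourier shell correlation of a single measurement.

    For each axis the measurement is split into even/odd halves, the odd
    half's DFT is phase-corrected, and the two halves are correlated over
    shells labelled on the *original* grid (half-grid index k keeps the
    shell of the original index k it aliases).  The returned curve is the
    unweighted mean of the per-axis curves, kind ``sfsc_raw``; per-axis
    curves are retained in ``metadata["per_axis"]``.

    ``phase_correction=False`` skips the odd-half phase factor (the raw
    correlation then oscillates like a scaled Bessel J0 for smooth 2-D
    signals — exposed for diagnostics only).  ``gamma`` is a
    per-coefficient numerator subtraction used by the upsampled estimator.
    """
    reference = max(m.shape)
    per_axis: list[RadialProfile] = []
    for pair in split_all_axes(m):
        fe = np.fft.fftn(pair.even.data)
        if phase_correction:
            fo = phase_correct_odd(pair)
        else:
            fo = np.fft.fftn(pair.odd.data)
        index = build_shell_index(
            pair.even.shape, reference_length=reference, norm_lengths=m.shape
        )
        per_axis.append(
            _shell_correlation(fe, fo, index, m.voxel_size, gamma=gamma)
        )
    prof = _average_axis_curves(per_axis)
    meta = {
        "phase_correction": phase_correction,
        "variance_corrected": False,
        "whitened": bool(m.meta.get("whitened", False)),
        "upsampled": bool(m.meta.get("upsampled", False)),
        "gamma": gamma,
        "axes": list(range(m.ndim)),
        "per_axis": per_axis,
        "voxel_size": m.voxel_size,
    }
    return CorrelationCurve(prof, "sfsc_raw", meta)


def checkerboard_sfsc(m: Measurement) -> CorrelationCurve:
    """Self-FSC from checkerboard (both-axis even/odd) splitting of an image.

    Decimates along both axes and correlates the diagonal quarter-grid
    pairs (ee, oo) and (eo, oe), each with the appropriate (+-1, +-1)
    original-pixel phase correction, averaging the two curves.  The pairs
    have independent noise, but decimating ``dim`` axes inflates the
    per-coefficient noise variance by 2**dim (= 4 here) instead of the
    per-axis scheme's 2 — this op exists to demonstrate that comparison.
    """
    if m.ndim != 2:
        raise ValueError("checkerboard SFSC is defined for 2-D images only")
    quads = split_quadrants_2d(m)
    n0, n1 = m.shape
    reference = max(m.shape)
    index = build_shell_index(
        quads["ee"].shape, reference_length=reference, norm_lengths=m.shape
    )
    from .split import _signed_index

    s0 = _signed_index(n0 // 2)
    s1 = _signed_index(n1 // 2)

    def corrected(key: str, t0: int, t1: int) -> np.ndarray:
        f = np.fft.fftn(quads[key].data)
        ph = np.exp(
            -2j * np.pi * (t0 * s0[:, None] / n0 + t1 * s1[None, :] / n1)
        )
        return f * ph

    curves = [
        _shell_correlation(
            np.fft.fftn(quads["ee"].data), corrected("oo", 1, 1), index, m.voxel_size
        ),
        _shell_correlation(
            np.fft.fftn(quads["eo"].data), corrected("oe", 1, -1), index, m.voxel_size
        ),
    ]
    prof = _average_axis_curves(curves)
    meta = {
        "scheme": "checkerboard",
        "phase_correction": True,
        "variance_corrected": False,
        "per_axis": curves,
        "voxel_size": m.voxel_size,
    }
    return CorrelationCurve(prof, "sfsc_raw", meta)


def correct_variance(c: CorrelationCurve) -> CorrelationCurve:
    """Map the raw SFSC onto the FSC scale: v -> 2v/(1+v).

    Under white noise and rapid signal decay the expected raw SFSC is
    lambda^2/(lambda^2 + 2 sigma^2); this monotone map (identity at 0 and
    1) removes the factor-2 noise inflation.  Applying it twice is an
    error.
    """
    if c.kind != "sfsc_raw":
        raise ValueError(f"variance correction expects kind 'sfsc_raw', got '{c.kind}'")
    if c.metadata.get("variance_corrected"):
        raise ValueError("variance correction already applied")
    v = c.profile.value
    with np.errstate(invalid="ignore", divide="ignore"):
        corrected = 2.0 * v / (1.0 + v)
    prof = replace(c.profile, value=corrected)
    meta = dict(c.metadata)
    meta["variance_corrected"] = True
    return CorrelationCurve(prof, "sfsc_corrected", meta)


def efsc_analytic(lambda2: RadialProfile, sigma2: RadialProfile) -> CorrelationCurve:
    """Expected FSC from generative per-shell variances: l2/(l2 + s2)."""
    if len(lambda2) != len(sigma2):
        raise ValueError("lambda2 and sigma2 must share shells")
    l2 = lambda2.value
    s2 = sigma2.value
    if np.nanmin(l2) < 0 or np.nanmin(s2) < 0:
        raise ValueError("variances must be nonnegative")
    den = l2 + s2
    value = np.full_like(den, np.nan)
    ok = den > 0
    value[ok] = l2[ok] / den[ok]
    prof = replace(lambda2, value=value, defined=ok & np.asarray(lambda2.defined))
    return CorrelationCurve(prof, "efsc", {})


def esfsc_analytic_1d(
    lambda2: Sequence[float], sigma2: Sequence[float], n: int
) -> np.ndarray:
    """Expected 1-D self-FSC per frequency index k = 0..N/2-1.

    From the even/odd aliasing identities,

        ESFSC[k] = (l2[k] - l2[k+M] + s2[k] - s2[k+M])
                 / (l2[k] + l2[k+M] + s2[k] + s2[k+M]),  M = N/2,

    which reduces to l2/(l2 + 2 s2) under white noise and rapid decay.
    Zero denominators yield NaN (undefined marker).
    """
    l2 = np.asarray(lambda2, dtype=float)
    s2 = np.asarray(sigma2, dtype=float)
    if l2.shape != (n,) or s2.shape != (n,):
        raise ValueError("lambda2 and sigma2 must be per-index arrays of length n")
    m = n // 2
    num = l2[:m] - l2[m:] + s2[:m] - s2[m:]
    den = l2[:m] + l2[m:] + s2[:m] + s2[m:]
    out = np.full(m, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def ssnr_from_curve(c: CorrelationCurve) -> CorrelationCurve:
    """Spectral SNR from a correlation curve: v/(1-v).

    Values >= 1 map to +inf (noise-free shells); negative values clamp to
    0 (noted in metadata) since a negative SSNR is meaningless.
    """
    v = c.profile.value.copy()
    clamped = int(np.sum(v[np.asarray(c.profile.defined)] < 0))
    v = np.clip(v, 0.0, None)
    out = np.full_like(v, np.nan)
    defined = np.asarray(c.profile.defined)
    sat = defined & (v >= 1.0)
    ok = defined & (v < 1.0)
    out[sat] = np.inf
    out[ok] = v[ok] / (1.0 - v[ok])
    prof = replace(c.profile, value=out, defined=defined.copy())
    meta = {"source_kind": c.kind, "negative_shells_clamped": clamped}
    return CorrelationCurve(prof, "ssnr", meta)


def ssnr_direct(ps: RadialProfile, sigma2: RadialProfile) -> CorrelationCurve:
    """SSNR from a power spectrum and a known noise profile.

    In expectation PS = n-scaled (lambda^2 + sigma^2) per shell, so
    max(PS - sigma^2, 0)/sigma^2 estimates the SSNR without any
    correlation; both profiles must be in the same power convention.
    """
    if len(ps) != len(sigma2):
        raise ValueError("profiles must share shells")
    p = ps.value
    s2 = sigma2.value
    out = np.full_like(p, np.nan)
    ok = np.asarray(ps.defined) & np.asarray(sigma2.defined) & (s2 > 0)
    out[ok] = np.clip(p[ok] - s2[ok], 0.0, None) / s2[ok]
    prof = replace(ps, value=out, defined=ok)
    return CorrelationCurve(prof, "ssnr", {"source": "noise-subtracted power"})


@dataclass
class ResolutionResult:
    """Resolution estimate from a threshold crossing of a curve."""

    resolution: float          # Angstrom
    crossing_shell: float      # fractional shell of the crossing
    threshold: float
    at_nyquist: bool = False   # curve never fell below the threshold


def resolution_at_threshold(
    c: CorrelationCurve,
    threshold: float = DEFAULT_THRESHOLD,
    voxel_size: float | None = None,
) -> ResolutionResult:
    """Resolution at the first threshold crossing of a correlation curve.

    Scans complete, defined shells from low frequency (DC excluded — its
    correlation is trivially dominated by the mean), finds the first shell
    where the curve falls below ``threshold`` and linearly interpolates
    the fractional crossing; the resolution is the inverse of the crossing
    frequency.  If the curve never drops below the threshold the Nyquist
    resolution (2 * voxel) is returned with ``at_nyquist=True``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if voxel_size is None:
        voxel_size = c.metadata.get("voxel_size")
    prof = c.profile.complete_shells()
    if len(prof) == 0:
        raise ValueError("curve has no complete shells to search")
    v = prof.value
    below = v < threshold
    if below[0]:
        raise ValueError(
            "no resolvable signal: curve below threshold at the first shell"
        )
    if not below.any():
        if voxel_size is None:
            raise ValueError("voxel_size required when curve never crosses threshold")
        return ResolutionResult(
            resolution=2.0 * voxel_size,
            crossing_shell=float(prof.shell[-1]),
            threshold=threshold,
            at_nyquist=True,
        )
    i = int(np.argmax(below))
    v0, v1 = v[i - 1], v[i]
    frac = (v0 - threshold) / (v0 - v1)
    r_star = prof.shell[i - 1] + frac * (prof.shell[i] - prof.shell[i - 1])
    f_star = prof.frequency[i - 1] + frac * (prof.frequency[i] - prof.frequency[i - 1])
    return ResolutionResult(
        resolution=float(1.0 / f_star),
        crossing_shell=float(r_star),
        threshold=threshold,
    )
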