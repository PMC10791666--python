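"""Synthetic measurements with known spectral statistics.

Generates the Gaussian model under which the self-FSC analysis holds
exactly: signal and noise are mean-zero Gaussian fields whose DFT
coefficients are independent with variances constant over radial shells
(lambda^2 for the signal, sigma^2 for the noise).  Spectral decay follows
the cryo-EM B-factor envelope

    amplitude(s) = exp(-B * s**2 / 4),   s in 1/Angstrom,

applied to amplitudes (so variances carry the square).  Because every
estimator in this package can be checked against the generative lambda^2
and sigma^2, these phantoms are the package's ground-truth harness.

Variance convention: ``lambda2``/``sigma2`` are per-coefficient variances
of the *normalized* (unitary) DFT, so by Parseval the real-space variance
of a field is the mean of its per-shell variances over the grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grid import Measurement, RadialProfile, ShellIndex, build_shell_index, radial_average

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "bfactor_envelope",
    "gaussian_field",
    "simulate",
]


@dataclass
class SimulationParams:
    """Generative settings for one synthetic measurement.

    shape
        Grid shape, every axis even.  The reference simulated-image
        geometry is 2-D 360x360 at 0.81 A/pixel; tests use smaller grids.
    voxel_size
        Sampling step in Angstrom.
    b_signal, b_noise
        B-factor (A^2) of the signal/noise amplitude envelope; 0 means a
        flat (white) spectrum.
    snr
        Real-space variance ratio Var(signal)/Var(noise).
    seed
        Seed for the field realizations.
    """

    shape: tuple[int, ...] = (360, 360)
    voxel_size: float = 0.81
    b_signal: float = 100.0
    b_noise: float = 0.0
    snr: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        if any(n % 2 for n in self.shape):
            raise ValueError("all axis lengths must be even")
        if self.b_signal < 0 or self.b_noise < 0:
            raise ValueError("B-factors must be nonnegative")
        if not self.snr > 0:
            raise ValueError("snr must be positive")


@dataclass
class GroundTruth:
    """A simulated measurement together with its generating distribution."""

    signal: Measurement
    noise: Measurement
    measurement: Measurement        # signal + noise, exactly
    lambda2: RadialProfile          # generative per-shell signal variance
    sigma2: RadialProfile           # generative per-shell noise variance
    params: SimulationParams

    def noise_model(self):
        """Generative noise profile as a :class:`~sfsc.preprocess.NoiseModel`.

        Converts the normalized-convention sigma^2 to the unnormalized
        power-spectrum convention used by the preprocessing module.
        """
        from .preprocess import NoiseModel

        n_total = int(np.prod(self.measurement.shape))
        prof = RadialProfile(
            shell=self.sigma2.shell.copy(),
            frequency=self.sigma2.frequency.copy(),
            value=self.sigma2.value * n_total,
            n_indices=self.sigma2.n_indices.copy(),
            complete=self.sigma2.complete.copy(),
            defined=self.sigma2.defined.copy(),
        )
        return NoiseModel(sigma2=prof, source="known")


def bfactor_envelope(index: ShellIndex, b: float, voxel_size: float) -> np.ndarray:
    """Per-shell amplitude weights exp(-B s^2/4) on the shells of ``index``.

    ``s`` is the shell's spatial frequency in 1/A.  B=0 gives all ones;
    weights are 1 at DC and non-increasing with radius.
    """
    if b < 0:
        raise ValueError("B-factor must be nonnegative")
    s = index.frequency_of_shell(voxel_size)
    return np.exp(-b * s**2 / 4.0)


def gaussian_field(
    index: ShellIndex,
    lambda2: np.ndarray | RadialProfile,
    seed: int | np.random.Generator,
    voxel_size: float = 1.0,
) -> Measurement:
    """Draw a real Gaussian field with per-shell DFT variance ``lambda2``.

    The field is constructed by per-shell Fourier filtering of a real-space
    white Gaussian field, which enforces Hermitian symmetry exactly: the
    normalized-DFT coefficients are mean-zero complex Gaussians with
    variance lambda2[shell] (independent up to the Hermitian constraint).
    Reproducible for a fixed integer seed.
    """
    lam = lambda2.value if isinstance(lambda2, RadialProfile) else np.asarray(lambda2, float)
    if len(lam) < index.n_shells:
        raise ValueError(f"lambda2 has {len(lam)} shells, index needs {index.n_shells}")
    if np.any(lam[: index.n_shells] < 0):
        raise ValueError("per-shell variances must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(index.shape)
    amp = np.sqrt(lam[: index.n_shells])[index.radii]
    data = np.fft.ifftn(np.fft.fftn(white) * amp).real
    return Measurement(data=data, voxel_size=voxel_size)


def simulate(params: SimulationParams) -> GroundTruth:
    """Generate signal, noise and measurement for ``params``.

    The signal's per-shell variance is the squared B-factor envelope for
    ``b_signal`` (unit variance at DC); the noise follows the ``b_noise``
    envelope, rescaled so the generative real-space variance ratio
    Var(signal)/Var(noise) equals ``snr`` exactly.  The reported
    ``lambda2``/``sigma2`` are the exact scaled generative variances, not
    empirical estimates.
    """
    index = build_shell_index(params.shape)
    lam2 = bfactor_envelope(index, params.b_signal, params.voxel_size) ** 2
    sig2 = bfactor_envelope(index, params.b_noise, params.voxel_size) ** 2

    # Real-space variance = grid mean of the per-coefficient variances
    # (Parseval, normalized convention).
    counts = index.shell_counts
    n_total = counts.sum()
    var_signal = float((lam2 * counts).sum() / n_total)
    var_noise_raw = float((sig2 * counts).sum() / n_total)
    sig2 = sig2 * (var_signal / (params.snr * var_noise_raw))

    rng = np.random.default_rng(params.seed)
    signal = gaussian_field(index, lam2, rng, voxel_size=params.voxel_size)
    noise = gaussian_field(index, sig2, rng, voxel_size=params.voxel_size)
    measurement = Measurement(
        data=signal.data + noise.data, voxel_size=params.voxel_size
    )

    freq = index.frequency_of_shell(params.voxel_size)
    shells = np.arange(index.n_shells)
    mk = lambda v: RadialProfile(  # noqa: E731
        shell=shells.copy(), frequency=freq.copy(), value=v,
        n_indices=counts.copy(), complete=index.complete.copy(),
        defined=np.ones_like(v, dtype=bool),
    )
    return GroundTruth(
        signal=signal, noise=noise, measurement=measurement,
        lambda2=mk(lam2), sigma2=mk(sig2), params=params,
    )
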