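"""Fourier-grid conventions shared by every other module.

A real-space array with a physical voxel size is wrapped in a
:class:`Measurement`.  Its discrete Fourier grid is partitioned into
concentric shells by :class:`ShellIndex`, and per-shell scalar curves
(power spectra, correlation curves, SSNR profiles) are carried as
:class:`RadialProfile` objects.

DFT convention
--------------
All spectra use the unnormalized forward transform (``numpy.fft.fftn``,
sums without any 1/N factor).  Correlation curves are scale-invariant
ratios, so the convention only affects raw power values; it is stated
here once and assumed everywhere.

Shell binning
-------------
Grid index ``k`` has per-axis signed normalized frequency
``f_d = k_d / norm_d`` in [-1/2, 1/2) and is assigned to shell
``round(||f|| * reference_length)``.  By default ``norm_d`` is the axis
length.  For grids obtained by even/odd decimation, the caller passes the
*original* axis lengths as ``norm_lengths`` so that a half-grid index
keeps the shell label (and physical frequency) of the full-grid index it
aliases; this makes curves from decimated and original grids commensurate.
Shell ``r`` maps to spatial frequency ``r / (reference_length * voxel)``
in 1/Angstrom.  DC is shell 0; shells whose full sphere extends beyond the
smallest per-axis Nyquist are flagged incomplete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Measurement",
    "ShellIndex",
    "RadialProfile",
    "build_shell_index",
    "radial_average",
    "power_spectrum",
]


@dataclass
class Measurement:
    """Real-valued 1-D/2-D/3-D data on a regular grid with a physical voxel size.

    Parameters
    ----------
    data:
        Real array of dimension 1-3.  Measurements fed to the even/odd
        splitting must have even axis lengths (checked by the splitting
        and simulation entry points; derived half-grids may be odd).
    voxel_size:
        Sampling step in Angstrom, uniform across axes.
    meta:
        Free-form provenance flags (e.g. ``whitened``, ``upsampled``) used
        as guards by downstream operations.
    """

    data: np.ndarray
    voxel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if np.iscomplexobj(self.data):
            raise ValueError("Measurement data must be real-valued")
        if self.data.ndim not in (1, 2, 3):
            raise ValueError(f"Measurement must be 1-D to 3-D, got {self.data.ndim}-D")
        for ax, n in enumerate(self.data.shape):
            if n == 0:
                raise ValueError(f"axis {ax} has zero length")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def nyquist(self) -> float:
        """Highest representable spatial frequency, 1/(2*voxel) in 1/A."""
        return 1.0 / (2.0 * self.voxel_size)


@dataclass
class RadialProfile:
    """A per-shell scalar curve indexed by shell radius and physical frequency.

    ``value`` may hold NaN at shells where the quantity is undefined (zero
    power, empty shell); ``defined`` marks valid entries explicitly so that
    callers never rely on NaN propagation.
    """

    shell: np.ndarray          # integer shell labels, contiguous from 0
    frequency: np.ndarray      # 1/Angstrom per shell
    value: np.ndarray
    n_indices: np.ndarray      # grid indices contributing to each shell
    complete: np.ndarray       # full spherical shell inside the sampled band?
    defined: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.defined is None:
            self.defined = np.isfinite(self.value)

    def __len__(self) -> int:
        return len(self.shell)

    def restrict(self, mask: np.ndarray) -> "RadialProfile":
        """Return a copy keeping only shells selected by ``mask``."""
        return RadialProfile(
            self.shell[mask], self.frequency[mask], self.value[mask],
            self.n_indices[mask], self.complete[mask], self.defined[mask],
        )

    def complete_shells(self, skip_dc: bool = True) -> "RadialProfile":
        """Default view: complete, defined shells (DC excluded by default)."""
        mask = self.complete & self.defined
        if skip_dc:
            mask = mask & (self.shell >= 1)
        return self.restrict(mask)


@dataclass
class ShellIndex:
    """Partition of a Fourier grid into radial shells.

    Attributes
    ----------
    shape:
        Axis lengths of the gridded data.
    norm_lengths:
        Per-axis lengths used to normalize frequency indices.  Equal to
        ``shape`` for ordinary grids; equal to the original lengths for
        even/odd half grids so shell labels stay commensurate.
    reference_length:
        Scale of the shell labels: shell r sits at normalized radius
        r/reference_length.
    radii:
        Integer shell label per grid index (fftn layout).
    """

    shape: tuple[int, ...]
    norm_lengths: tuple[int, ...]
    reference_length: int
    radii: np.ndarray
    shell_counts: np.ndarray
    complete: np.ndarray

    @property
    def n_shells(self) -> int:
        return len(self.shell_counts)

    def frequency_of_shell(self, voxel_size: float) -> np.ndarray:
        """Spatial frequency (1/A) of each shell for a grid sampled at
        ``voxel_size`` *on the reference grid* (the grid whose axis length
        is ``reference_length``)."""
        shells = np.arange(self.n_shells)
        return shells / (self.reference_length * voxel_size)

    def resolution_of_shell(self, voxel_size: float) -> np.ndarray:
        """Real-space resolution (A) of each shell; DC maps to inf."""
        with np.errstate(divide="ignore"):
            return 1.0 / self.frequency_of_shell(voxel_size)


def build_shell_index(
    shape: Sequence[int],
    reference_length: int | None = None,
    norm_lengths: Sequence[int] | None = None,
) -> ShellIndex:
    """Partition the Fourier grid of ``shape`` into radial shells.

    Parameters
    ----------
    shape:
        Axis lengths of the transform grid (fftn layout).
    reference_length:
        Shell-label scale; defaults to ``max(norm_lengths)``.  Passing the
        original length when indexing a decimated grid keeps shells
        commensurate with the original grid's shells.
    norm_lengths:
        Per-axis normalization of the frequency index, defaulting to
        ``shape``.  For an even/odd half grid pass the *original* axis
        lengths: half-grid index k then lands in the shell of the original
        index k it aliases.
    """
    shape = tuple(int(n) for n in shape)
    if len(shape) == 0:
        raise ValueError("empty shape")
    for ax, n in enumerate(shape):
        if n < 2:
            raise ValueError(f"axis {ax} must have length >= 2, got {n}")
    norm = tuple(int(n) for n in (norm_lengths if norm_lengths is not None else shape))
    if len(norm) != len(shape):
        raise ValueError("norm_lengths must match dimensionality of shape")
    if reference_length is None:
        reference_length = max(norm)
    reference_length = int(reference_length)
    if reference_length < max(shape):
        raise ValueError(
            f"reference_length {reference_length} smaller than largest axis {max(shape)}"
        )

    # Signed normalized frequency per axis: fftfreq(n) = k_signed/n, scaled
    # to the normalizing length.
    axes_f = [np.fft.fftfreq(n) * (n / nm) for n, nm in zip(shape, norm)]
    sq = np.zeros(shape)
    for d, f in enumerate(axes_f):
        fshape = [1] * len(shape)
        fshape[d] = shape[d]
        sq = sq + (f.reshape(fshape)) ** 2
    radii = np.rint(np.sqrt(sq) * reference_length).astype(np.int64)

    n_shells = int(radii.max()) + 1
    shell_counts = np.bincount(radii.ravel(), minlength=n_shells)

    # A shell is complete while its full sphere fits inside the sampled
    # band: normalized radius <= the smallest per-axis (normalized) Nyquist.
    min_nyq = min(n / (2 * nm) for n, nm in zip(shape, norm))
    shells = np.arange(n_shells)
    complete = shells <= np.floor(min_nyq * reference_length)

    return ShellIndex(
        shape=shape,
        norm_lengths=norm,
        reference_length=reference_length,
        radii=radii,
        shell_counts=shell_counts,
        complete=complete,
    )


def shell_sum(values: np.ndarray, index: ShellIndex) -> np.ndarray:
    """Sum ``values`` over each shell (helper for correlation numerators)."""
    if values.shape != index.shape:
        raise ValueError(f"array shape {values.shape} != index shape {index.shape}")
    return np.bincount(index.radii.ravel(), weights=values.ravel(),
                       minlength=index.n_shells)


def radial_average(
    power: np.ndarray,
    index: ShellIndex,
    voxel_size: float = 1.0,
) -> RadialProfile:
    """Arithmetic mean of ``power`` over each shell.

    ``power`` must be defined on the same grid as ``index``.  The returned
    profile's frequency axis uses ``voxel_size`` (of the reference grid).
    """
    sums = shell_sum(np.asarray(power, dtype=float), index)
    counts = index.shell_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return RadialProfile(
        shell=np.arange(index.n_shells),
        frequency=index.frequency_of_shell(voxel_size),
        value=means,
        n_indices=counts.copy(),
        complete=index.complete.copy(),
        defined=counts > 0,
    )


def power_spectrum(m: Measurement, index: ShellIndex | None = None) -> RadialProfile:
    """Spherically averaged power spectrum of a measurement.

    Per shell, the mean of ``|DFT(m)|**2`` (unnormalized transform).  The
    frequency axis is in 1/A: shell r sits at r/(reference_length*voxel).
    """
    if index is None:
        index = build_shell_index(m.shape)
    if index.shape != m.shape:
        raise ValueError("shell index shape does not match measurement")
    p = np.abs(np.fft.fftn(m.data)) ** 2
    return radial_average(p, index, voxel_size=m.voxel_size)
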