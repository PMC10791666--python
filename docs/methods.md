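# Methods

## Model

A measurement is `y = x + ε` on a regular 1-D/2-D/3-D grid with voxel
size `V` (Å).  Signal and noise are mean-zero Gaussian fields whose DFT
coefficients are independent with variances constant over radial shells:
`λ²(r)` for the signal and `σ²(r)` for the noise.  The per-shell SSNR is
`λ²/σ²`, the expected FSC between two independent measurements is
`EFSC = λ²/(λ²+σ²)`, and `SSNR = EFSC/(1−EFSC)`.

The self-FSC estimates this from one measurement.  Splitting `y` along one
axis into even samples `y_e[n] = y[2n]` and odd samples `y_o[n] = y[2n+1]`
ties the half-grid DFTs to the full-grid DFT (`M = N/2`,
`ω = exp(−2πi/N)`):

    Ŷe[k] = (Ŷ[k] + Ŷ[k+M]) / 2
    Ŷo[k] = (Ŷ[k] − Ŷ[k+M]) / (2 ω^k)

The two halves are correlated over shells after the odd half's residual
phase (a one-original-pixel shift) is removed; one split per axis, and the
reported curve is the unweighted mean of the per-axis curves.  Because the
halves share a noise realization through the aliasing terms, the expected
raw curve under white noise and rapid signal decay is `λ²/(λ²+2σ²)`; the
variance correction `v → 2v/(1+v)` places it on the FSC scale.

## Expected self-FSC and the two validity conditions

The exact per-frequency expectation of the raw estimator is

    ESFSC[k] = (λ²[k] − λ²[k+M] + σ²[k] − σ²[k+M])
             / (λ²[k] + λ²[k+M] + σ²[k] + σ²[k+M])

(implemented as `esfsc_analytic_1d` and used as an oracle in the tests).
It reduces to `λ²/(λ²+2σ²)` exactly when (1) the noise is white and
(2) `λ²[k] ≫ λ²[k+M]`.  Colored noise makes the σ-difference term positive
(overestimation); a flat signal spectrum cancels the λ-difference term
(underestimation).  Both failure modes are directional, which the tests
assert as sign tests against a two-realization FSC.

Note that condition (2) fails *structurally* near the half-grid Nyquist:
the aliasing partner of a frequency at radius `r` along the split axis
sits near radius `N/2 − r`, so no B-factor makes the ratio small when
`r → N/4`.  Upsampling is the remedy (below); without it, quantitative
agreement should only be expected on roughly the lower half of the
complete band.

## Corrections

**Whitening.**  Each Fourier coefficient is divided by
`sqrt(max(σ²(shell), floor))` with `floor = max(σ²)·1e−6` to avoid
amplitude blow-up at unsampled shells.  Whitening rescales signal and
noise alike, so the per-shell SSNR is untouched while the noise becomes
white with unit per-coefficient power (unnormalized-DFT convention).  Two
estimators of `σ²(r)` are provided:

* *sphere exterior* — the spherically averaged power spectrum of the
  measurement masked outside a centered sphere assumed to enclose the
  structure, divided by the exterior volume fraction to undo the
  total-power attenuation of masking.  The sharp mask still convolves the
  spectrum slightly; this residual leakage is accepted as a known bias of
  a deliberately simple estimator.  An optional moving-average smoothing
  of the radial profile (off by default) tames small-box noise.
* *background slice* — the mean 2-D power spectrum of planes selected
  above the region of interest in a tomogram, used to whiten same-shaped
  2-D targets.

**Upsampling.**  Fourier coefficients are embedded centrally in a grid of
doubled side length (the original-Nyquist plane split symmetrically
between ±N/2 so the inverse transform is exactly real) and rescaled so
the original samples are preserved at even grid points; the voxel size
halves.  Every aliasing partner of an in-band frequency is then exactly
zero, so only the shared-noise term biases the correlation numerator.
That term is known after whitening — per coefficient, a quarter of the
noise power — and is subtracted from the numerator shell sum
(`n_r · σ²/4`).  The result estimates the EFSC directly; no variance
correction is applied, and the complete band of the upsampled splits is
exactly the original Nyquist ball.

Two small properties of this estimator are worth knowing.  First, the
plug-in ratio has a Jensen-type bias of order `−2/(n_r − 2)` on shells
with few coefficients (visible on the first few shells of a pure-noise
input and accounted for in the tests).  Second, the band-edge shell
carries the split original-Nyquist coefficients, whose partners are not
zero; that single shell is excluded from quantitative comparisons.

## Resolution and denoising

`resolution_at_threshold` scans complete, defined shells from low
frequency (DC excluded — its correlation is trivially dominated by the
mean), linearly interpolates the first crossing below the threshold
(default 1/7), and reports the inverse of the crossing frequency.  A curve
that never crosses returns the Nyquist resolution `2V` with a flag; a
curve already below threshold at the first shell is an error ("no
resolvable signal").

`self_wiener` uses the corrected curve (or the upsampled estimator) as
per-shell multiplicative weights on the original measurement — valid
because the corrected curve estimates `EFSC = SSNR/(1+SSNR) = 1/(1+1/SSNR)`,
the Wiener weight itself.  Negative shells are clamped to 0 (a negative
Wiener weight is meaningless); weights may optionally be applied to the
whitened volume instead, and a hard low-pass at the threshold crossing
can be composed on top.  `wiener_filter` accepts an explicit SSNR curve;
`lowpass` is a brick-wall filter for comparison (no soft edge by default,
keeping comparisons sharp).

## Grid conventions

* **DFT**: unnormalized forward transform everywhere
  (`numpy.fft`); correlation curves are scale-invariant ratios, so this
  only affects raw power values.  Power-type radial profiles
  (`power_spectrum`, noise models) are per-shell means of `|FFT|²` in
  this convention; the generative `λ²`, `σ²` of the synthetic module use
  the normalized (unitary-DFT, per-coefficient) convention, under which
  the real-space variance is the grid mean of the per-shell variances;
  `GroundTruth.noise_model()` converts between the two.
* **Shell binning**: grid index `k` has per-axis normalized frequency
  `k_d/norm_d ∈ [−1/2, 1/2)` and belongs to shell
  `round(‖f‖·reference_length)`.  For ordinary grids `norm_d` is the axis
  length.  For even/odd half-grids the *original* lengths are used, so a
  half-grid index keeps the shell label (and the physical frequency
  `r/(reference_length·V)`) of the full-grid index it aliases — curves
  from decimated and original grids share one frequency axis.  DC is
  shell 0, reported but excluded from resolution searches; shells whose
  sphere extends beyond the smallest per-axis Nyquist are flagged
  incomplete, and default views truncate there (a decimated axis loses
  its Nyquist, so un-upsampled split curves are complete only to
  reference/4).
* **Phase correction**: the odd half's DFT is multiplied by
  `exp(−2πi·s/N)` with `s` the *signed* frequency index, which keeps every
  conjugate pair Hermitian (real shell sums).  The self-paired half-grid
  Nyquist coefficient uses the value the even/odd identity assigns to DFT
  index `M/2`.  Omitting the correction altogether makes the 2-D curve of
  a smooth signal collapse onto a scaled Bessel function `J0(2πr/N)` — the
  shell average of the uncancelled per-axis phase — which the tests use as
  a fingerprint.

## Checkerboard splitting

The older single-image scheme decimates in a checkerboard-like pattern
instead of axis by axis.  `split_checkerboard_2d` exposes the two
quincunx (parity-of-`i+j`) lattices with row-wise compaction;
`checkerboard_sfsc` implements the comparison the scheme is kept around
for: decimating along *both* axes and correlating the diagonal
quarter-grid pairs (even/even with odd/odd, even/odd with odd/even, each
phase-corrected for its diagonal offset).  The pairs have independent
noise, but splitting `dim` axes inflates the effective noise variance by
`2^dim` (= 4 in 2-D) versus the per-axis scheme's 2 — and the per-axis
scheme additionally preserves Nyquist on the unsplit axes, which is why
it is the default.  The inflation factors are fitted (≈2 vs ≈4) in the
acceptance script.

## Synthetic data

`simulate` draws signal and noise as Hermitian-symmetric Gaussian fields
by per-shell Fourier filtering of real-space white noise (exact realness,
bitwise reproducibility per seed).  Amplitude envelopes follow the
cryo-EM B-factor form `exp(−B·s²/4)` with `s` in 1/Å — the only
dimensionally consistent reading of the usual decay law (`B` in Å²);
variances carry the squared envelope.  The SNR parameter is the
real-space variance ratio `Var(x)/Var(ε)`, enforced exactly in the
generative variances; the reference image geometry is 2-D 360×360 at
0.81 Å/pixel, with the default well-behaved condition
`B_signal = 100 Å², B_noise = 0, SNR = 15`.

What the phantoms deliberately do not emulate: contrast transfer
functions, masking, missing wedges, spatially varying noise, and real
molecular structure (a Gaussian random field has the right second-order
statistics and nothing else).  Passing tests therefore demonstrate the
estimator under its stated statistical model, not robustness to every
real-data pathology — the advisory power-spectrum check in the CLI exists
precisely because users must judge the model's applicability.

## Problem sizes and tolerances

Tests and the acceptance script run on grids chosen to keep the whole
suite around a few seconds while leaving dozens of complete shells:
2-D comparisons at 128², the 3-D resolution harness at 64³ (B = 400 Å²,
SNR = 0.05, putting the 1/7 crossing near shell 10 of 32), 20 seeds for
curve averages and 10 for per-seed win counts.  Quantitative agreement
bounds are 0.05 mean absolute deviation on correlation curves (with the
analytic-EFSC comparisons restricted to shells where EFSC > 0.05), one
shell width for resolution agreement, and 3 standard errors for
Monte-Carlo means.  The noise-inflation comparison fits
`λ²/(λ²+ασ²)` on shells 2..N/6, where the rapid-decay condition holds by
construction (B = 100 Å², SNR = 0.6 at N = 128 puts the SSNR between ~2
and ~9 there, separating α = 2 from α = 4 decisively).

## Known limitations

* Isotropic voxel sizes only; no conical/directional or local resolution.
* The sphere-exterior noise estimator ignores mask-induced spectral
  leakage beyond the volume-fraction rescaling.
* Non-uniform (spatially varying) noise is out of model: the curve will
  not hug 1 at low frequency, which is the user-visible symptom, but no
  automatic detection is attempted.
* CTF effects are not modelled anywhere in the pipeline.
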