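"""Data-driven Wiener denoising from a single noisy image.

Because the corrected self-FSC estimates FSC = SSNR/(1+SSNR), it can be
used directly as the per-shell weights of a Wiener filter — no second
measurement, no hand-tuned SSNR.  On a synthetic phantom where the clean
signal is known we can measure the actual mean squared error, and compare
against a conventional hard low-pass filter at the 1/7-threshold cutoff.
"""

import numpy as np

import sfsc
from sfsc import SimulationParams, simulate

gt = simulate(SimulationParams((128, 128), voxel_size=0.81, b_signal=150.0,
                               b_noise=0.0, snr=2.0, seed=5))

wiener = sfsc.self_wiener(gt.measurement)
curve = sfsc.correct_variance(sfsc.sfsc(gt.measurement))
cutoff = sfsc.resolution_at_threshold(curve, voxel_size=0.81).resolution
lp = sfsc.lowpass(gt.measurement, cutoff=cutoff)


def mse(x):
    return float(np.mean((x - gt.signal.data) ** 2))


print(f"1/7-threshold cutoff used by the low-pass filter: {cutoff:.1f} A")
print(f"MSE raw measurement : {mse(gt.measurement.data):.4f}")
print(f"MSE low-pass        : {mse(lp.filtered.data):.4f}")
print(f"MSE self-Wiener     : {mse(wiener.filtered.data):.4f}")
print("The shell-wise Wiener weights (the SFSC curve itself) suppress")
print("noise-dominated shells smoothly and should give the lowest MSE.")
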