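"""Sharpen a blurred stack with projected Landweber deconvolution.

A bar phantom is blurred with a confocal-like Gaussian PSF (0.2 um lateral,
0.6 um axial); 25 Landweber iterations with the safe default step shrink the
data residual monotonically while keeping the estimate non-negative.
"""

import numpy as np
from scipy.signal import fftconvolve

from fibermito.morphometry3d import (
    ImageStack,
    gaussian_psf,
    landweber_deconvolve,
    landweber_residuals,
)

voxel_size = (1.0, 0.2, 0.2)  # um (z, y, x)
bar = np.zeros((16, 32, 32))
bar[6:10, 8:24, 14:18] = 1.0

psf = gaussian_psf(sigma_um=(0.6, 0.2, 0.2), voxel_size=voxel_size)
blurred = ImageStack(np.maximum(fftconvolve(bar, psf, mode="same"), 0.0), voxel_size)

restored = landweber_deconvolve(blurred, psf, iterations=25)
residuals = landweber_residuals(blurred, psf, iterations=25)

err_blur = np.abs(blurred.voxels - bar).sum()
err_rest = np.abs(restored.voxels - bar).sum()
print(f"residual ||y - Hx||: {residuals[0]:.3f} -> {residuals[-1]:.3f} over 25 iterations")
print(f"L1 error vs true bar: blurred {err_blur:.1f} -> restored {err_rest:.1f}")
# The residual sequence is non-increasing by construction; the restored stack
# is closer to the unblurred phantom, which is what makes the subsequent
# threshold-and-count morphometry less sensitive to the threshold choice.
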