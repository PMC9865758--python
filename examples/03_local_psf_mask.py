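"""The local method: PSF-mask deconvolution of an unfiltered backprojection.

Estimates the (2M+1)x(2M+1) point-spread function of acquisition followed by
unfiltered backprojection, solves for the correction mask whose convolution
with the PSF is a discrete impulse, applies it pixel-by-pixel and refines
negative pixels with exact dummy measurements of zero brightness.
"""

import numpy as np

from tomoreduce import (
    NoiseModel,
    default_geometry,
    default_phantom,
    estimate_psf,
    evaluate,
    fit_scale,
    forward_project,
    omega_mask,
    run_local,
    simulate_sinogram,
    unfiltered_backprojection,
)

geom = default_geometry()
truth = default_phantom()
clean = forward_project(truth, geom)
sino = simulate_sinogram(truth, geom, NoiseModel(sigma=0.01 * clean.max()),
                         seed=1)

psf = estimate_psf(geom, M=2)
print("PSF window (M=2), centre row:", np.round(psf.b[2], 2))

result = run_local(sino, geom, M=2)
mask = omega_mask(geom)
rep_lin = evaluate(result.linear_estimate, truth, fit_scale_flag=True, mask=mask)
rep_ref = evaluate(result.image, truth, mask=mask)
ufbp = unfiltered_backprojection(sino, geom)
scale = fit_scale(truth, ufbp, mask=mask)
rmse_ufbp = float(np.sqrt(np.mean((truth[mask] - scale * ufbp[mask]) ** 2)))

print(f"best-scaled unfiltered backprojection RMSE: {rmse_ufbp:.4f}")
print(f"masked linear estimate RMSE (best fit):     {rep_lin.rmse:.4f}")
print(f"non-negativity refined estimate RMSE:       {rep_ref.rmse:.4f}")
print(f"refined image minimum: {result.image.min()} (exactly non-negative)")
# The mask sharpens the blurred backprojection; the refinement zeroes the
# (unphysical) negative background and is reported on the true brightness
# scale, no scalar fit needed.
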