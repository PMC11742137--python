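"""Estimate the elemental-map -> WSI transform from landmark pairs.

Landmarks are corresponding points a user clicks in both modalities, in
physical micrometres.  The fit is least squares; the report gives the
per-landmark residuals and their RMSE.
"""

import numpy as np

from metalmap import (
    FixtureSpec,
    estimate_transform,
    make_fixture,
    registration_error,
)

# 1 µm of landmark placement jitter, realistic for careful manual clicks
fix = make_fixture(FixtureSpec(seed=3, landmark_noise_um=1.0))

T = estimate_transform(fix.landmarks, model="affine")
err = registration_error(T, fix.landmarks)
frob = np.linalg.norm(T.matrix - fix.true_transform.matrix)

print(f"fitted model: {T.model}, {len(fix.landmarks)} landmarks")
print(f"landmark RMSE: {err['rmse_um']:.2f} um "
      f"(noise injected: {fix.spec.landmark_noise_um} um)")
print(f"matrix error vs ground truth (Frobenius): {frob:.4f}")
print("transform JSON:")
print(T.to_json(rmse_um=err["rmse_um"]))
# RMSE near the injected 1 µm says the fit absorbed no structure beyond
# the click noise; sub-pixel at the 5 µm/px elemental scale.
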