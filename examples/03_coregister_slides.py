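"""Map the macrophage slide into the lymphocyte-slide frame.

Serial sections are related by a near-similarity transform.  Here the true
transform (rotation 2 deg, shift (30, -20) um) is recovered exactly from
noiseless landmarks, then refined landmark-free with ICP from a coarse start.
"""

import numpy as np

from sioi import Transform2D, apply_transform, estimate_transform, refine_icp

rng = np.random.default_rng(0)
th = np.radians(2.0)
true = Transform2D(np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]),
                   np.array([30.0, -20.0]), kind="similarity")

landmarks = rng.uniform(0, 2000, size=(8, 2))
fit = estimate_transform(landmarks, apply_transform(landmarks, true))
print("landmark fit: rotation %.4f deg, shift (%.2f, %.2f), rmse %.2e um"
      % (np.degrees(np.arctan2(fit.linear[1, 0], fit.linear[0, 0])),
         *fit.translation, fit.rmse_um))

cloud = rng.uniform(0, 2000, size=(3000, 2))  # e.g. PCK+ centroids
icp = refine_icp(cloud, apply_transform(cloud, true))
print("ICP (no landmarks): shift (%.2f, %.2f), rmse %.2e um"
      % (*icp.translation, icp.rmse_um))
# Both routes recover the planted transform; rmse_um reports the residual so
# a wrong ICP optimum would be visible rather than silently accepted.
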