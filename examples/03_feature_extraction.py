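"""Extract first-order plane-fit features on the standard 181-ROI grid.

Each circular ROI contributes (alpha, beta, gamma): the least-squares plane
g(x, y) ~ alpha (x_i - x) + beta (y_i - y) + gamma over the disc, i.e. the
local mean gradients and mean intensity.
"""

import numpy as np

import echoforce as ef

# the standard geometry: 700x660 field of view, 50 px lattice, radius 20
grid = ef.build_roi_grid(ef.default_content_mask())
print(f"default grid: {grid.n_rois} circular ROIs of radius {grid.radius} px "
      f"every {grid.spacing} px")
print(f"feature dimension: 3 x {grid.n_rois} = {grid.feature_dim}")

# plane fit on a synthetic gradient: a pure horizontal ramp g(x, y) = x
yy, xx = np.mgrid[0:60, 0:60]
alpha, beta, gamma = ef.fit_roi_plane(xx.astype(float), (30, 30), 20)
print(f"\nplane fit on g(x,y)=x at center (30,30): "
      f"alpha={alpha:+.3f} beta={beta:+.3f} gamma={gamma:.1f}")
print("(alpha = -1: gray level rises along x; gamma = the center's x)")

# features of rendered frames are linear in the applied forces
# (noise off and speckle scaled down so no pixel saturates at 255)
scene = ef.make_scene(width=400, height=360, noise_sd=0, seed=3)
scene.canvas_baseline *= 0.8
small = ef.build_roi_grid(ef.default_content_mask(400, 360))
base = ef.extract_features(ef.render_frame(scene, np.zeros(5)), small)
M = np.stack([ef.extract_features(ef.render_frame(scene, np.eye(5)[i]), small)
              - base for i in range(5)], axis=1)
f = np.array([0.3, 0.0, 0.6, 0.0, 0.1])
got = ef.extract_features(ef.render_frame(scene, f), small)
err = np.abs(got - (base + M @ f)).max()
print(f"\nlinearity check: |features(render(f)) - (base + M f)|_max = {err:.2e}")
print("(the linear image/force relationship the decoder relies on)")
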