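"""Collagen fiber straightness from traced centerlines.

Renders wavy-fiber images with known sinusoidal waviness (so the true
straightness parameter Ps = chord/arc is available in closed form), traces
the fibers back out of the pixels, and compares the recovered median Ps to
the analytic value.  Then emulates axial stretching by an affine transform
and shows the straightening plateau.
"""

import numpy as np
from scipy.ndimage import zoom

from arterymech import straightness as st
from arterymech import synthfibers as sf

print("waviness amplitude → straightness recovery (wavelength 40 μm):")
print(f"{'amp (μm)':>9} {'analytic Ps':>12} {'traced median':>14}")
for amp in (0.0, 2.0, 4.0, 6.0):
    spec = sf.FiberFieldSpec(n_fibers=12, waviness_amplitude_um=amp, seed=3)
    img, _ = sf.render_fiber_image(spec)
    vals = st.slice_ps_values(img, spec.pixel_size_um)
    print(f"{amp:9.1f} {sf.analytic_ps(amp, 40.0):12.3f} "
          f"{np.median(vals):14.3f}   ({len(vals)} fibers)")

print("\naffine axial stretch of one wavy image (amplitude 6 μm):")
spec = sf.FiberFieldSpec(
    n_fibers=12, orientation=sf.VonMisesOrientation(0.0, 6.0),
    waviness_amplitude_um=6.0, seed=1,
)
img, _ = sf.render_fiber_image(spec)
for s in (1.0, 1.2, 1.4, 1.6, 1.8, 2.0):
    stretched = zoom(img, (1, s), order=1)[:, : img.shape[1]]
    med = np.median(st.slice_ps_values(stretched, spec.pixel_size_um))
    print(f"  stretch {s:.1f}: median Ps = {med:.3f}")
print("Ps rises toward 1 and the increments shrink — fibers straighten "
      "during axial stretching and saturate, mirroring what stretch series "
      "of adventitial collagen show.")
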