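"""Slice-on-MEA forward model: method-of-images vs infinite medium.

A brain slice on a planar MEA sits under saline of higher conductivity;
image charges across the tissue-saline boundary correct the potential a
basis source produces.  The correction matters most for sources near the
boundary relative to the slice thickness.
"""

import numpy as np

from kcsdkit import SliceGeometry, moi_potential_basis, potential_basis_2d

sigma_tissue, sigma_saline = 0.3, 1.5  # S/m, typical slice vs ACSF
geom = SliceGeometry(thickness=0.3, sigma_tissue=sigma_tissue,
                     sigma_saline=sigma_saline, n_images=30)
print(f"image weight W = {geom.W:+.3f} "
      "(negative: saline conducts better than tissue)")

pts = np.array([[r, 0.0] for r in (0.1, 0.3, 1.0)])
v_inf = potential_basis_2d([0, 0], 0.2, 0.1, sigma_tissue, pts)
v_moi = moi_potential_basis([0, 0], 0.2, 0.1, geom, pts)

for (r, _), vi, vm in zip(pts, v_inf, v_moi):
    print(f"r = {r:.1f} mm: infinite-medium {vi:.4f}, slice (MoI) {vm:.4f}, "
          f"ratio {vm / vi:.3f}")
print("(the conductive bath shunts current: potentials in the slice are")
print(" weaker than an infinite-tissue model predicts)")
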