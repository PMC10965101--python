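"""Reconstruct CSD along a laminar probe from noisy potentials.

A dipolar ground-truth source with a split sink is forward-modeled onto a
32-contact probe on [0, 1], 5% uniform noise is added, the regularization
parameter is selected by leave-one-out cross-validation, and the
reconstruction is compared with the known truth.
"""

import numpy as np

from kcsdkit import (build_kernels, default_basis, default_estimation_space,
                     demo_1d_fixture, fit, select_parameters)

fx = demo_1d_fixture(seed=1)
setup = fx["setup"]
space = default_estimation_space(setup, 101)
R = float(setup.pairwise_distances().min())

scan, model = select_parameters(setup, fx["potentials"], space, method="cv",
                                R_grid=[R], h=fx["h"])
est = fit(model, fx["potentials"], lam=scan.lambda_best)

truth = fx["profile"].evaluate(space.points)
corr = np.corrcoef(est.csd[:, 0], truth)[0, 1]

print(f"electrodes: {setup.n_electrodes}, basis radius R = {R:.4f}")
print(f"CV-selected lambda: {scan.lambda_best:.3e}")
print(f"correlation of reconstruction with ground truth: {corr:.3f}")
print("(1.0 would be a perfect shape match; >0.9 means the dipole and its")
print(" split sink are recovered despite the electrode noise)")
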