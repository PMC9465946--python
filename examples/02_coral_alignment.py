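"""Align source feature covariance to the target with CORAL.

Fits the closed-form correlation-alignment transform, verifies that it
drives the covariance objective ||A^T C_s A - C_t||_F to numerical zero,
and shows the per-class variant.
"""

import numpy as np

from sleeptransfer import (
    ShiftConfig, apply_coral, apply_per_class_coral, empirical_covariance,
    fit_coral, fit_per_class_coral, make_domain_pair,
)

cfg = ShiftConfig(n_subjects=6, recordings_per_subject=(1, 1),
                  epochs_per_recording=100, shift=1.0, cov_scale=2.0, seed=1)
source, target = make_domain_pair(cfg)

fit = fit_coral(source, target, recenter="source")
Cs = empirical_covariance(source.features, fit.shrinkage).cov
Ct = empirical_covariance(target.features, fit.shrinkage).cov
residual = np.linalg.norm(fit.A.T @ Cs @ fit.A - Ct)
print(f"CORAL objective residual ||A'CsA - Ct||_F = {residual:.2e}")

transformed = apply_coral(fit, source)
Cz = empirical_covariance(transformed.features, fit.shrinkage).cov
print(f"transformed-source vs target covariance gap: "
      f"{np.linalg.norm(Cz - Ct):.2e}")
# The residual is floating-point noise and the transformed covariance gap
# sits at the size of the default regularization ridge: the closed form
# attains the optimum; only covariance is aligned, means are untouched
# under recenter="source".

pc = fit_per_class_coral(source, target, recenter="target")
z = apply_per_class_coral(pc, source)
for stage in ("W", "N2"):
    mt = target.features[target.labels == stage].mean(0)
    mz = z.features[z.labels == stage].mean(0)
    print(f"per-class CORAL, stage {stage}: "
          f"class-mean gap after transform = {np.linalg.norm(mz - mt):.2e}")
# With recenter="target" each source stage lands exactly on the matching
# target stage mean, with its covariance aligned class by class.
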