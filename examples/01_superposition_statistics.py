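"""RMSD and RMSF of a harmonic ensemble with a known fluctuation profile.

Generates a 20-site Gaussian-network ensemble, then measures the
per-frame RMSD to the reference and the per-site RMSF, comparing the
latter to the analytic prediction sqrt(3 k_B T / k * pinv(Gamma)_ii).
"""

import numpy as np

from mdpost import (
    HarmonicEnsembleSpec,
    generate_gnm_ensemble,
    gnm_site_covariance,
    rmsd_series,
    rmsf_profile,
)

i = np.arange(20)
reference = np.stack([5 * np.cos(0.6 * i), 5 * np.sin(0.6 * i), 1.5 * i], axis=1)
spec = HarmonicEnsembleSpec(reference=reference, spring_constant=1.0, n_frames=20000, seed=0)
traj = generate_gnm_ensemble(spec)

rmsd = rmsd_series(traj, reference=reference)
rmsf = rmsf_profile(traj, superpose=False)
analytic = np.sqrt(3.0 * np.diag(gnm_site_covariance(spec)))

print(f"mean RMSD to reference: {rmsd.mean():.3f} A (spread of the ensemble)")
print("site  RMSF_A  analytic_A")
for k in range(0, 20, 4):
    print(f"{k + 1:4d}  {rmsf[k]:6.3f}  {analytic[k]:9.3f}")
print("RMSF tracks the analytic mobility profile: chain ends fluctuate most.")
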