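"""Voxel-wise parameter estimation on a tiny noisy phantom.

Fingerprints are simulated per tissue, corrupted with complex Gaussian
noise, compressed to 15 coefficients, and fit by bounded variable-projection
nonlinear least squares.
"""

import numpy as np

from hybridqmt import (DictionaryGrid, FitConfig, PhantomSpec, build_dictionary,
                       compute_basis, default_schedule, fit_volume,
                       generate_phantom)
from hybridqmt.spin_model import PARAM_NAMES

schedule = default_schedule(n_reps=64, cycle_s=3.5, seed=3)
basis = compute_basis(build_dictionary(DictionaryGrid.default(3), schedule), rank=15)

spec = PhantomSpec(shape=(4, 4, 4), noise_sd=1e-5, seed=2)
labels, truth, data, meta = generate_phantom(spec, schedule, basis=basis)
print("per-tissue SNR:", {k: round(v) for k, v in meta["snr_per_tissue"].items()})

mask = labels > 0
cfg = FitConfig(n_starts=2, n_probes=24)
maps, diags = fit_volume(data, mask, schedule, basis, config=cfg, seed=0)

print(f"fit {int(mask.sum())} voxels; all converged: {bool(diags['converged'][mask].all())}")
for n in PARAM_NAMES:
    rel = np.abs(maps[n][mask] / truth[n][mask] - 1.0)
    print(f"  {n:4s}: median |error| = {100 * np.median(rel):6.2f} %")
print("Pool size and relaxation times are tight; exchange and semisolid R1")
print("carry more noise because the schedule encodes them more weakly.")
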