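"""Simulate the hybrid-state signal of one tissue.

An inversion-prepared train of rectangular pulses with smoothly varying flip
angle and duration drives the 2-pool spin system; the complex signal at each
echo forms the tissue's "fingerprint".
"""

import numpy as np

from hybridqmt import QMTParams, default_schedule, simulate_fingerprint

white_matter = QMTParams(m0s=0.20, R1f=0.40, R2f=13.0, Rx=70.0, R1s=3.0,
                         T2s=12e-6)
schedule = default_schedule(n_reps=100, cycle_s=3.5, seed=0)

fp = simulate_fingerprint(white_matter, schedule)
print(f"schedule: {schedule.n_reps} repetitions over {schedule.cycle_duration:.1f} s")
print(f"fingerprint: {len(fp)} complex samples, peak |s| = {np.abs(fp).max():.4f}")
print(f"first samples (post-inversion recovery): {np.round(fp[:4].real, 4)}")
print("Signals start negative after inversion and recover; the shape over the")
print("cycle encodes all six qMT parameters (pool size, relaxation, exchange).")
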