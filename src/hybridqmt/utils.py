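"""Small shared utilities."""

from __future__ import annotations

import hashlib
import json

import numpy as np


def effective_resolution(nominal_mm: float = 1.0) -> float:
    """Effective isotropic resolution of in-sphere k-space sampling.

    A radial ("koosh-ball") readout that covers only the inscribed sphere of
    the nominal k-space cube acquires a fraction pi/6 of the cube's volume;
    the voxel volume grows by the reciprocal, so the effective isotropic
    edge length is nominal * (6/pi)^(1/3) (1 mm nominal -> 1.24 mm).
    """
    if nominal_mm <= 0:
        raise ValueError("nominal resolution must be positive")
    return nominal_mm * (6.0 / np.pi) ** (1.0 / 3.0)


def snr_of(signal: np.ndarray, noise_sd: float) -> float:
    """SNR convention used throughout: ||s|| / (sigma * sqrt(T))."""
    s = np.asarray(signal)
    return float(np.linalg.norm(s) / (noise_sd * np.sqrt(s.size)))


def spec_hash(obj) -> str:
    """Stable short hash of a JSON-serializable spec (provenance stamping)."""
    def _keyed(o):
        if isinstance(o, dict):
            return {str(k): _keyed(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [_keyed(v) for v in o]
        return o

    payload = json.dumps(_keyed(obj), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def child_seed(master: int, *keys: int) -> int:
    """Deterministic sub-seed below 2^31 from a master seed and indices."""
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
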