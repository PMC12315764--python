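"""Dictionary generation and low-rank subspace compression.

The temporal dynamics of the hybrid-state signal live close to a low-rank
subspace: the left singular vectors of a dictionary of fingerprints
simulated over a grid of qMT parameters span the signal manifold well at a
small rank (default r = 15, matching the coefficient-image representation
used for reconstruction).  A voxel's signal s is stored as the coefficient
vector c = U^H s and reconstructed as U c.

Complex handling: the SVD is computed on the real/imaginary-stacked (2T x N)
dictionary; the resulting real basis is folded back to a complex T x r basis
and re-orthonormalized (complex QR), so U^H U = I holds in the complex inner
product.  The column sign/phase convention fixes the largest-magnitude
element of each basis vector to a positive real part.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .spin_model import PARAM_NAMES, QMTParams, SequenceSchedule, simulate_fingerprint

#: literature-plausible default grid bounds (m0s, R1f, R2f, Rx, R1s, T2s)
DEFAULT_GRID_BOUNDS: dict[str, tuple[float, float]] = {
    "m0s": (0.05, 0.35),
    "R1f": (0.3, 2.0),
    "R2f": (5.0, 25.0),
    "Rx": (5.0, 100.0),
    "R1s": (0.2, 5.0),
    "T2s": (5e-6, 20e-6),
}


@dataclass(frozen=True)
class DictionaryGrid:
    """Cartesian parameter grid; atoms are the row-major product of the lists."""

    values: dict[str, np.ndarray]
    cap: int = 100_000

    def __post_init__(self) -> None:
        vals = {}
        for name in PARAM_NAMES:
            if name not in self.values:
                raise ValueError(f"grid is missing parameter {name!r}")
            v = np.sort(np.atleast_1d(np.asarray(self.values[name], float)))
            if v[0] <= 0 or (name == "m0s" and v[-1] >= 1):
                raise ValueError(f"grid values for {name} out of physical bounds")
            vals[name] = v
        object.__setattr__(self, "values", vals)
        if self.n_atoms > self.cap:
            raise ValueError(
                f"grid has {self.n_atoms} atoms, exceeding the cap of {self.cap}; "
                "use a coarser grid or raise the cap")

    @property
    def n_atoms(self) -> int:
        return int(np.prod([len(v) for v in self.values.values()]))

    def atoms(self):
        """Iterate QMTParams in deterministic row-major order over PARAM_NAMES."""
        lists = [self.values[n] for n in PARAM_NAMES]
        for combo in itertools.product(*lists):
            yield QMTParams(*combo)

    def bounding_box(self, widen: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.values[n][0] for n in PARAM_NAMES])
        hi = np.array([self.values[n][-1] for n in PARAM_NAMES])
        span = hi - lo
        lo_w = np.maximum(lo - widen * span, 1e-9)
        hi_w = hi + widen * span
        if widen > 0:
            hi_w[0] = min(hi_w[0], 0.99)  # m0s stays a fraction
        return lo_w, hi_w

    @classmethod
    def default(cls, points_per_axis: int = 5, cap: int = 100_000) -> "DictionaryGrid":
        vals = {n: np.linspace(lo, hi, points_per_axis)
                for n, (lo, hi) in DEFAULT_GRID_BOUNDS.items()}
        return cls(values=vals, cap=cap)

    def fingerprint_hash(self) -> str:
        h = hashlib.sha256()
        for n in PARAM_NAMES:
            h.update(self.values[n].tobytes())
        return h.hexdigest()[:16]


def build_dictionary(grid: DictionaryGrid, schedule: SequenceSchedule,
                     r2sl: str = "interp") -> np.ndarray:
    """Simulate all atoms; returns complex (T x N_atoms) matrix, column j the
    fingerprint of atom j in row-major grid order."""
    D = np.empty((schedule.n_reps, grid.n_atoms), complex)
    for j, p in enumerate(grid.atoms()):
        D[:, j] = simulate_fingerprint(p, schedule, r2sl=r2sl)
    if not np.all(np.isfinite(D)):
        raise FloatingPointError("dictionary contains non-finite fingerprints")
    return D


@dataclass(frozen=True)
class SubspaceBasis:
    """Orthonormal complex basis U (T x r) with singular values and provenance."""

    U: np.ndarray
    singular_values: np.ndarray
    rank: int
    schedule_name: str = ""
    grid_hash: str = ""

    def __post_init__(self) -> None:
        if self.U.shape[1] != self.rank:
            raise ValueError("rank does not match basis shape")


def compute_basis(dictionary: np.ndarray, rank: int = 15, normalize: bool = True,
                  schedule_name: str = "", grid_hash: str = "") -> SubspaceBasis:
    """Rank-r left singular basis of the real/imag-stacked dictionary.

    ``normalize`` scales each atom to unit norm before the SVD so that no
    region of parameter space dominates by raw signal amplitude.
    """
    T, N = dictionary.shape
    if not 1 <= rank <= min(T, N):
        raise ValueError(f"rank {rank} out of range for dictionary {dictionary.shape}")
    D = dictionary
    if normalize:
        norms = np.linalg.norm(D, axis=0)
        D = D / np.where(norms > 0, norms, 1.0)
    stacked = np.vstack([D.real, D.imag])  # (2T x N) real
    Ur, s, _ = np.linalg.svd(stacked, full_matrices=False)
    if rank > 1 and s[min(rank, len(s)) - 1] / s[0] < 1e-12:
        import warnings
        warnings.warn(f"dictionary is rank deficient at rank {rank} "
                      f"(sigma_r/sigma_1 = {s[rank-1]/s[0]:.2e})")
    U = Ur[:T, :rank] + 1j * Ur[T:, :rank]
    # re-orthonormalize in the complex inner product (QR preserves the span)
    U, R = np.linalg.qr(U)
    # phase convention: largest-magnitude element has positive real part
    for j in range(U.shape[1]):
        k = int(np.argmax(np.abs(U[:, j])))
        ph = U[k, j] / abs(U[k, j])
        U[:, j] = U[:, j] / ph
    return SubspaceBasis(U=U, singular_values=s[:rank], rank=rank,
                         schedule_name=schedule_name, grid_hash=grid_hash)


def compress(fingerprint: np.ndarray, basis: SubspaceBasis) -> np.ndarray:
    """Coefficient vector c = U^H s."""
    s = np.asarray(fingerprint)
    if s.shape[-1] != basis.U.shape[0]:
        raise ValueError(
            f"fingerprint length {s.shape[-1]} does not match basis T={basis.U.shape[0]}")
    return s @ np.conj(basis.U)


def reconstruct(coefficients: np.ndarray, basis: SubspaceBasis) -> np.ndarray:
    """Fingerprint estimate s_hat = U c."""
    c = np.asarray(coefficients)
    if c.shape[-1] != basis.rank:
        raise ValueError(f"coefficient length {c.shape[-1]} does not match rank {basis.rank}")
    return c @ basis.U.T


def save_basis(path, basis: SubspaceBasis) -> None:
    meta = json.dumps({"rank": basis.rank, "schedule_name": basis.schedule_name,
                       "grid_hash": basis.grid_hash})
    np.savez(path, U_real=basis.U.real, U_imag=basis.U.imag,
             singular_values=basis.singular_values, meta=np.array(meta))


def load_basis(path) -> SubspaceBasis:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        return SubspaceBasis(U=z["U_real"] + 1j * z["U_imag"],
                             singular_values=z["singular_values"],
                             rank=int(meta["rank"]),
                             schedule_name=meta["schedule_name"],
                             grid_hash=meta["grid_hash"])
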