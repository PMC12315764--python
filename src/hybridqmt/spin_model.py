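"""2-pool Bloch–McConnell dynamics for hybrid-state qMT sequences.

The spin system is the free water pool (Cartesian magnetization xf, yf, zf)
exchanging at rate Rx with the semisolid pool (xs, zs; ys is neglected since
omega_x = 0 and R2s,l >> omega_z).  The state vector is augmented with a
constant 1 so relaxation toward thermal equilibrium is linear:

    s = (xf, yf, zf, xs, zs, 1),   ds/dt = A(theta, pulse) s,

with A the 6x6 matrix of the 2-pool Bloch–McConnell equations whose
semisolid transverse decay during an RF pulse is the linearized rate
R2s,l(T2s, alpha, TRF) from :mod:`hybridqmt.lineshape`.  A hybrid-state
sequence is an inversion-prepared train of rectangular pulses with smoothly
varying flip angle and pulse duration, fully balanced per TR; the signal of
one parameter set over the schedule ("fingerprint") is read at the echo,
TR/2 after each pulse center.

Six core parameters: m0s, R1f, R2f, Rx, R1s, T2s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm as _scipy_expm

from .lineshape import (LineshapeKernel, LineshapeKind, get_default_interpolator,
                        linearized_R2sl)

PARAM_NAMES = ("m0s", "R1f", "R2f", "Rx", "R1s", "T2s")


@dataclass(frozen=True)
class QMTParams:
    """The six unconstrained qMT parameters of one voxel or ROI.

    m0s is the fractional semisolid pool size (m0f = 1 - m0s); R1f, R2f the
    free pool's longitudinal/transverse relaxation rates (1/s); Rx the
    exchange rate (1/s); R1s the semisolid longitudinal relaxation rate
    (1/s); T2s the semisolid transverse relaxation time (s, ~10 µs).
    """

    m0s: float
    R1f: float
    R2f: float
    Rx: float
    R1s: float
    T2s: float

    def __post_init__(self) -> None:
        if not 0.0 < self.m0s < 1.0:
            raise ValueError(f"m0s must be in (0, 1), got {self.m0s}")
        for name in ("R1f", "R2f", "Rx", "R1s", "T2s"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if self.T2s >= 1.0 / self.R2f:
            raise ValueError(
                f"T2s = {self.T2s} must be far below the free pool's "
                f"T2f = {1.0 / self.R2f} (semisolid decays much faster)")

    @property
    def m0f(self) -> float:
        return 1.0 - self.m0s

    @property
    def R2s(self) -> float:
        return 1.0 / self.T2s

    @property
    def PSR(self) -> float:
        """Pool-size ratio m0s/m0f."""
        return self.m0s / self.m0f

    @property
    def forward_exchange_rate(self) -> float:
        """m0s * Rx, the quantity most prior qMT studies report."""
        return self.m0s * self.Rx

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, x) -> "QMTParams":
        return cls(*(float(v) for v in x))


@dataclass(frozen=True)
class RFPulse:
    """Rectangular RF pulse: flip angle alpha (rad), duration TRF (s), phase (rad)."""

    alpha: float
    TRF: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not (self.TRF > 0 and math.isfinite(self.TRF)):
            raise ValueError(f"TRF must be positive, got {self.TRF}")
        if not -math.pi <= self.alpha <= math.pi:
            raise ValueError(f"alpha must be in [-pi, pi], got {self.alpha}")

    @property
    def omega_y(self) -> float:
        """Constant Rabi frequency alpha/TRF in rad/s."""
        return self.alpha / self.TRF


@dataclass(frozen=True)
class SequenceSchedule:
    """Inversion-prepared hybrid-state pulse train.

    Per-repetition arrays ``alpha`` (rad), ``TRF`` (s) and ``TR`` (s); the
    echo is read TR/2 after the pulse center.  ``inversion`` is the
    preparation pulse at cycle start (None for no preparation), modeled as
    an instantaneous ideal pi rotation of the free pool plus
    generalized-Bloch saturation of the semisolid pool over its TRF.
    RF phase alternation (0/pi bSSFP convention) is on by default; echoes
    are demodulated by the pulse phase.
    """

    alpha: np.ndarray
    TRF: np.ndarray
    TR: np.ndarray
    inversion: RFPulse | None = RFPulse(alpha=math.pi, TRF=500e-6)
    omega_z: float = 0.0
    b1_scale: float = 1.0
    phase_alternation: bool = True
    name: str = "schedule"

    def __post_init__(self) -> None:
        for nm in ("alpha", "TRF", "TR"):
            object.__setattr__(self, nm, np.atleast_1d(np.asarray(getattr(self, nm), float)))
        n = len(self.alpha)
        if n == 0:
            raise ValueError("schedule needs at least one pulse")
        if len(self.TRF) != n or len(self.TR) != n:
            raise ValueError("alpha, TRF, TR must have equal length")
        if np.any(self.TRF <= 0) or np.any(self.TR <= 0):
            raise ValueError("TRF and TR must be positive")
        if np.any(self.TRF > self.TR):
            raise ValueError("TRF must not exceed TR")
        if not self.b1_scale > 0:
            raise ValueError("b1_scale must be positive")

    @property
    def n_reps(self) -> int:
        return len(self.alpha)

    @property
    def cycle_duration(self) -> float:
        return float(np.sum(self.TR))

    @property
    def phases(self) -> np.ndarray:
        """Per-pulse RF phase (0/pi alternation when enabled)."""
        if self.phase_alternation:
            return math.pi * (np.arange(self.n_reps) % 2).astype(float)
        return np.zeros(self.n_reps)


def evolution_matrix(params: QMTParams, pulse: RFPulse | None, omega_z: float,
                     R2sl: float | None) -> np.ndarray:
    """6x6 Bloch–McConnell evolution matrix, state order (xf, yf, zf, xs, zs, 1).

    During a pulse, ``R2sl`` is the linearized semisolid rate for (T2s,
    alpha, TRF); for free precession pass ``pulse=None`` (then the semisolid
    transverse component decays at the raw rate R2s = 1/T2s).
    """
    if pulse is None:
        wy = 0.0
        r2s = params.R2s if R2sl is None else R2sl
    else:
        wy = pulse.omega_y
        if R2sl is None:
            raise ValueError("R2sl is required during an RF pulse")
        r2s = R2sl
    m0s, m0f = params.m0s, params.m0f
    R1f, R2f, Rx, R1s = params.R1f, params.R2f, params.Rx, params.R1s
    A = np.zeros((6, 6))
    A[0, 0] = -R2f; A[0, 1] = -omega_z; A[0, 2] = wy
    A[1, 0] = omega_z; A[1, 1] = -R2f
    A[2, 0] = -wy; A[2, 2] = -R1f - Rx * m0s; A[2, 4] = Rx * m0f; A[2, 5] = m0f * R1f
    A[3, 3] = -r2s; A[3, 4] = wy
    A[4, 2] = Rx * m0s; A[4, 3] = -wy; A[4, 4] = -R1s - Rx * m0f; A[4, 5] = m0s * R1s
    return A


def equilibrium_state(params: QMTParams) -> np.ndarray:
    return np.array([0.0, 0.0, params.m0f, 0.0, params.m0s, 1.0])


# ---------------------------------------------------------------------------
# batched matrix exponential (Pade-13 scaling and squaring)
# ---------------------------------------------------------------------------

_PADE13 = (64764752532480000., 32382376266240000., 7771770303897600.,
           1187353796428800., 129060195264000., 10559470521600.,
           670442572800., 33522128640., 1323241920., 40840800.,
           960960., 16380., 182., 1.)
_THETA13 = 5.371920351148152


def expm_batch(mats: np.ndarray) -> np.ndarray:
    """Matrix exponential of a stack of small square matrices.

    Pade-13 approximant with uniform scaling-and-squaring across the batch
    (squaring count set by the largest 1-norm).  Equivalent to
    ``scipy.linalg.expm`` applied per slice, but vectorized; used because a
    single fingerprint simulation needs hundreds of 6x6 exponentials.
    """
    A = np.asarray(mats, float)
    single = A.ndim == 2
    if single:
        A = A[None]
    norm = float(np.max(np.sum(np.abs(A), axis=-2)))
    s = max(0, int(math.ceil(math.log2(norm / _THETA13)))) if norm > _THETA13 else 0
    A = A / (2.0 ** s)
    b = _PADE13
    n = A.shape[-1]
    I = np.broadcast_to(np.eye(n), A.shape)
    A2 = A @ A
    A4 = A2 @ A2
    A6 = A4 @ A2
    U = A @ (A6 @ (b[13] * A6 + b[11] * A4 + b[9] * A2)
             + b[7] * A6 + b[5] * A4 + b[3] * A2 + b[1] * I)
    V = (A6 @ (b[12] * A6 + b[10] * A4 + b[8] * A2)
         + b[6] * A6 + b[4] * A4 + b[2] * A2 + b[0] * I)
    F = np.linalg.solve(V - U, V + U)
    for _ in range(s):
        F = F @ F
    return F[0] if single else F


def propagate(state: np.ndarray, matrix: np.ndarray, duration: float) -> np.ndarray:
    """Piecewise-constant propagation: state' = expm(matrix * duration) @ state."""
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if duration == 0:
        return np.array(state, float)
    out = expm_batch(matrix * duration) @ np.asarray(state, float)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(
            f"non-finite state after propagation (duration={duration}, "
            f"matrix diag={np.diag(matrix)})")
    return out


# ---------------------------------------------------------------------------
# schedule-level propagators
# ---------------------------------------------------------------------------

def _inversion_operator(params: QMTParams, schedule: SequenceSchedule,
                        r2sl_of) -> np.ndarray:
    """Instantaneous inversion: ideal pi rotation about y on the free pool
    (xf -> -xf, zf -> -zf), generalized-Bloch saturation of (xs, zs) over the
    inversion pulse's duration (relaxation/exchange neglected during the
    pulse, which is short)."""
    inv = schedule.inversion
    P = np.eye(6)
    if inv is None:
        return P
    P[0, 0] = -1.0
    P[2, 2] = -1.0
    r2sl = float(r2sl_of(params.T2s, abs(inv.alpha), inv.TRF))
    w = inv.omega_y
    M = np.array([[-r2sl, w], [-w, 0.0]]) * inv.TRF
    S = expm_batch(M)
    P[3:5, 3:5] = S
    return P


def _rep_propagators(params: QMTParams, schedule: SequenceSchedule,
                     r2sl_of) -> tuple[np.ndarray, np.ndarray]:
    """Per-repetition propagators.

    Returns (P_echo, P_rep): P_echo[n] maps the state at the start of
    repetition n to the echo (TR/2 after pulse center); P_rep[n] maps it to
    the start of repetition n+1.
    """
    n = schedule.n_reps
    alpha = schedule.alpha * schedule.b1_scale
    # phase pi = rotation about -y: flip the sign of omega_y
    sgn = np.where(np.cos(schedule.phases) >= 0, 1.0, -1.0)
    wz = schedule.omega_z
    pulsed = alpha != 0.0
    r2s_eff = np.full(n, params.R2s)
    if np.any(pulsed):
        r2s_eff[pulsed] = np.asarray(
            r2sl_of(params.T2s, np.abs(alpha[pulsed]), schedule.TRF[pulsed]), float)
    wy = np.where(pulsed, sgn * alpha / schedule.TRF, 0.0)

    base = evolution_matrix(params, None, wz, None)  # free-precession template
    mats = np.empty((2 * n, 6, 6))
    mats[:n] = base
    mats[:n, 0, 2] = wy
    mats[:n, 2, 0] = -wy
    mats[:n, 3, 4] = wy
    mats[:n, 4, 3] = -wy
    mats[:n, 3, 3] = -r2s_eff
    mats[n:] = base
    durs = np.empty(2 * n)
    durs[:n] = schedule.TRF
    durs[n:] = 0.5 * (schedule.TR - schedule.TRF)  # echo-symmetric halves
    E = expm_batch(mats * durs[:, None, None])
    P_pulse, P_half = E[:n], E[n:]
    P_echo = P_half @ P_pulse
    P_rep = P_half @ P_echo
    return P_echo, P_rep


def _resolve_r2sl(method, kind=LineshapeKind.SUPER_LORENTZIAN):
    """Map a method spec to a callable (T2s, alpha, TRF) -> rate."""
    if callable(method):
        return method
    if method == "interp":
        return get_default_interpolator(kind)
    if method == "exact":
        def _exact(T2s, a, trf):
            kern = LineshapeKernel(kind, float(T2s))
            a, trf = np.broadcast_arrays(np.asarray(a, float), np.asarray(trf, float))
            if a.ndim == 0:
                return linearized_R2sl(kern, float(a), float(trf))
            return np.array([linearized_R2sl(kern, float(ai), float(ti))
                             for ai, ti in zip(a.ravel(), trf.ravel())]).reshape(a.shape)
        return _exact
    raise ValueError(f"unknown R2s,l method {method!r}")


def cycle_propagator(params: QMTParams, schedule: SequenceSchedule,
                     r2sl: str = "interp") -> np.ndarray:
    """Full-cycle affine propagator P (inversion then all repetitions)."""
    f = _resolve_r2sl(r2sl)
    _, P_rep = _rep_propagators(params, schedule, f)
    P = _inversion_operator(params, schedule, f)
    for i in range(schedule.n_reps):
        P = P_rep[i] @ P
    return P


def cyclic_steady_state(params: QMTParams, schedule: SequenceSchedule,
                        r2sl: str = "interp") -> np.ndarray:
    """State at cycle start (before inversion) satisfying P s = s.

    Solved exactly from the augmented affine form: with P = [[A, b], [0, 1]],
    the fixed point is s5 = (I - A)^{-1} b.
    """
    P = cycle_propagator(params, schedule, r2sl=r2sl)
    A = P[:5, :5]
    b = P[:5, 5]
    M = np.eye(5) - A
    if abs(np.linalg.det(M)) < 1e-300:
        raise np.linalg.LinAlgError(
            "singular (I - P) in cyclic steady-state solve: pathological schedule")
    s5 = np.linalg.solve(M, b)
    return np.append(s5, 1.0)


def simulate_fingerprint(params: QMTParams, schedule: SequenceSchedule,
                         r2sl: str = "interp") -> np.ndarray:
    """Complex signal s_t = xf + i*yf at each echo over one cycle.

    Starts from the cyclic steady state, applies the inversion preparation,
    then each repetition; echoes are demodulated by the RF phase so the
    fingerprint is smooth under bSSFP 0/pi phase alternation.
    """
    f = _resolve_r2sl(r2sl)
    P_echo, P_rep = _rep_propagators(params, schedule, f)
    P_inv = _inversion_operator(params, schedule, f)

    # fixed point of the full cycle, built from the same per-rep propagators
    P = P_inv.copy()
    for i in range(schedule.n_reps):
        P = P_rep[i] @ P
    A = P[:5, :5]
    b = P[:5, 5]
    s = np.append(np.linalg.solve(np.eye(5) - A, b), 1.0)

    s = P_inv @ s
    demod = np.exp(-1j * schedule.phases)
    out = np.empty(schedule.n_reps, complex)
    for i in range(schedule.n_reps):
        e = P_echo[i] @ s
        out[i] = (e[0] + 1j * e[1]) * demod[i]
        s = P_rep[i] @ s
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite fingerprint")
    return out


def default_schedule(n_reps: int = 100, cycle_s: float = 3.5,
                     flip_max: float = math.radians(60.0),
                     seed: int = 0, name: str | None = None) -> SequenceSchedule:
    """A documented stand-in hybrid-state schedule.

    Inversion preparation followed by a smoothly varying flip-angle train
    (sin^2 envelope modulated by a seed-dependent harmonic) with a matched
    smoothly varying pulse duration; constant TR = cycle_s / n_reps.  The
    pattern is deterministic given the arguments and is *not* the
    numerically optimized train used on the scanner — it is a smooth,
    full-rank-encoding surrogate.
    """
    if n_reps < 10:
        raise ValueError("n_reps must be >= 10")
    rng = np.random.default_rng(seed)
    phi, psi = rng.uniform(0, 2 * math.pi, size=2)
    u = np.arange(n_reps) / n_reps
    alpha_min = math.radians(1.5)
    env = np.sin(math.pi * u) ** 2 * (0.7 + 0.3 * np.sin(4 * math.pi * u + phi))
    alpha = alpha_min + (flip_max - alpha_min) * np.clip(env, 0.0, 1.0)
    TRF = 200e-6 + 800e-6 * (0.5 + 0.5 * np.sin(6 * math.pi * u + psi))
    TR = np.full(n_reps, cycle_s / n_reps)
    if np.any(TRF >= TR):
        raise ValueError("cycle too short: TR must exceed the pulse durations")
    return SequenceSchedule(alpha=alpha, TRF=TRF, TR=TR,
                            name=name or f"default(n={n_reps},seed={seed})")


def single_pool_fingerprint(R1: float, R2: float, schedule: SequenceSchedule) -> np.ndarray:
    """Independent single-pool (free water only) simulator, same readout
    convention; used as the m0s -> 0 limit oracle."""
    wz = schedule.omega_z
    alpha = schedule.alpha * schedule.b1_scale
    sgn = np.where(np.cos(schedule.phases) >= 0, 1.0, -1.0)

    def mat(wy):
        return np.array([[-R2, -wz, wy, 0.0],
                         [wz, -R2, 0.0, 0.0],
                         [-wy, 0.0, -R1, R1],
                         [0.0, 0.0, 0.0, 0.0]])

    s = np.array([0.0, 0.0, 1.0, 1.0])
    inv = schedule.inversion
    P_inv = np.eye(4)
    if inv is not None:
        P_inv[0, 0] = -1.0
        P_inv[2, 2] = -1.0
    # relax to cyclic steady state by long iteration
    P = P_inv.copy()
    steps = []
    for i in range(schedule.n_reps):
        half = _scipy_expm(mat(0.0) * 0.5 * (schedule.TR[i] - schedule.TRF[i]))
        pulse = _scipy_expm(mat(sgn[i] * alpha[i] / schedule.TRF[i]) * schedule.TRF[i])
        steps.append((pulse, half))
        P = half @ half @ pulse @ P
    A, b = P[:3, :3], P[:3, 3]
    s = np.append(np.linalg.solve(np.eye(3) - A, b), 1.0)
    s = P_inv @ s
    out = np.empty(schedule.n_reps, complex)
    demod = np.exp(-1j * schedule.phases)
    for i, (pulse, half) in enumerate(steps):
        e = half @ (pulse @ s)
        out[i] = (e[0] + 1j * e[1]) * demod[i]
        s = half @ e
    return out
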