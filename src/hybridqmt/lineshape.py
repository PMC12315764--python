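"""Semisolid-pool decay physics.

The macromolecular ("semisolid") proton pool in parenchymal tissue does not
relax exponentially: averaging the dipolar splitting over molecular
orientations yields the super-Lorentzian lineshape, whose time-domain free
induction decay is

    G(t) = int_0^{pi/2} sin(theta) * exp(-(t^2 / (8 T2s^2)) (3 cos^2(theta) - 1)^2) dtheta,

with G(0) = 1.  The generalized Bloch model carries this non-exponential
memory kernel through an RF pulse via the integro-differential equation

    zs'(t) = -omega_y^2 * int_0^t G(t - tau) zs(tau) dtau,

for the semisolid longitudinal magnetization zs under a rectangular pulse of
constant Rabi frequency omega_y = alpha / TRF (relaxation and exchange
switched off; they are handled by the evolution matrix).  For efficient
schedule-level simulation the non-exponential decay is replaced by an
effective exponential rate — the *linearized* rate R2s,l(T2s, alpha, TRF) —
chosen by root-finding such that a standard-Bloch (exponential) semisolid
pool ends the pulse with the same zs.

Because time enters only through the ratios t/T2s and TRF/T2s, the linearized
rate obeys the exact scaling identity

    R2s,l(c*T2s, alpha, c*TRF) = R2s,l(T2s, alpha, TRF) / c,

which :class:`R2slInterpolator` exploits to tabulate R2s,l * T2s on a 2-D
(alpha, log(TRF/T2s)) grid once and evaluate it by spline interpolation
during fitting.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.optimize import brentq


class LineshapeKind(str, enum.Enum):
    SUPER_LORENTZIAN = "super_lorentzian"
    LORENTZIAN = "lorentzian"
    GAUSSIAN = "gaussian"


@dataclass(frozen=True)
class LineshapeKernel:
    """Time-domain decay kernel of the semisolid pool.

    Parameters
    ----------
    kind:
        Kernel family. ``super_lorentzian`` is the physical choice for
        tissue; ``lorentzian`` (pure exponential) and ``gaussian`` are
        provided for testing and limits.
    T2s:
        Semisolid transverse relaxation time in seconds (typically ~10 µs).
    """

    kind: LineshapeKind
    T2s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", LineshapeKind(self.kind))
        if not (self.T2s > 0 and math.isfinite(self.T2s)):
            raise ValueError(f"T2s must be positive and finite, got {self.T2s}")

    def __call__(self, t):
        return kernel_value(self, t)


# 500-node Gauss-Legendre on theta in [0, pi/2]; fixed so kernel values are
# deterministic and reproducible across calls.
_N_QUAD = 500
_GL_X, _GL_W = np.polynomial.legendre.leggauss(_N_QUAD)
_THETA = 0.25 * math.pi * (_GL_X + 1.0)
_THETA_W = 0.25 * math.pi * _GL_W * np.sin(_THETA)
# (3 cos^2(theta) - 1)^2 at the quadrature nodes
_POLY2 = (3.0 * np.cos(_THETA) ** 2 - 1.0) ** 2


def kernel_value(kernel: LineshapeKernel, t):
    """Evaluate the decay kernel G(t) for t >= 0 (scalar or array).

    G(0) = 1 and G is non-increasing on t >= 0 for all kernel kinds.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("kernel_value requires t >= 0")
    T2s = kernel.T2s
    if kernel.kind is LineshapeKind.LORENTZIAN:
        out = np.exp(-t / T2s)
    elif kernel.kind is LineshapeKind.GAUSSIAN:
        out = np.exp(-0.5 * (t / T2s) ** 2)
    else:  # super-Lorentzian: quadrature over dipolar orientations
        u = (t[..., None] ** 2 / (8.0 * T2s**2)) * _POLY2
        out = np.sum(_THETA_W * np.exp(-u), axis=-1)
    return out if out.ndim else float(out)


def generalized_bloch_zs(kernel: LineshapeKernel, alpha: float, TRF: float,
                         n_steps: int = 10_000) -> float:
    """End-of-pulse zs under the generalized Bloch integro-differential equation.

    Solves zs'(t) = -omega_y^2 * int_0^t G(t-tau) zs(tau) dtau on [0, TRF]
    with zs(0) = 1 and constant omega_y = alpha/TRF, using an implicit
    trapezoidal (second-order) Volterra scheme.
    """
    zs = _volterra_zs_batch(kernel, np.atleast_1d(float(alpha)), TRF, n_steps)
    return float(zs[0])


def _volterra_zs_batch(kernel: LineshapeKernel, alphas: np.ndarray, TRF: float,
                       n_steps: int) -> np.ndarray:
    """Vectorized Volterra solve: one pulse duration, many flip angles."""
    dt = TRF / n_steps
    t = dt * np.arange(n_steps + 1)
    G = kernel_value(kernel, t)  # G[k] = G(k*dt); G[0] = 1
    w2 = (alphas / TRF) ** 2  # omega_y^2, shape (A,)
    A = alphas.size
    z = np.empty((n_steps + 1, A))
    z[0] = 1.0
    f = np.zeros(A)  # f_n = -w2 * I_n; I_0 = 0
    denom = 1.0 + 0.25 * dt * dt * w2 * G[0]
    for n in range(n_steps):
        # I_{n+1} = dt * [ G(t_{n+1})*z_0/2 + sum_{j=1..n} G(t_{n+1}-t_j) z_j
        #                  + G(0)*z_{n+1}/2 ]   (z_{n+1} term folded into denom)
        known = 0.5 * G[n + 1] * z[0]
        if n >= 1:
            known = known + G[1:n + 1][::-1] @ z[1:n + 1]
        rhs = z[n] + 0.5 * dt * f - 0.5 * dt * w2 * dt * known
        z[n + 1] = rhs / denom
        f = -w2 * dt * (known + 0.5 * G[0] * z[n + 1])
    return z[-1]


def exponential_model_zs(R2sl, alpha: float, TRF: float):
    """End-of-pulse zs for an exponential (standard-Bloch) semisolid pool.

    The transverse/longitudinal pair obeys xs' = -R2sl*xs + omega_y*zs,
    zs' = -omega_y*xs, with (xs, zs)(0) = (0, 1); hence
    zs'' + R2sl*zs' + omega_y^2*zs = 0, solved in closed form.
    """
    R2sl = np.asarray(R2sl, dtype=float)
    w = alpha / TRF
    disc = np.sqrt(np.asarray(R2sl**2 - 4.0 * w**2, dtype=complex))
    lam1 = 0.5 * (-R2sl + disc)
    lam2 = 0.5 * (-R2sl - disc)
    with np.errstate(invalid="ignore"):
        z = (lam2 * np.exp(lam1 * TRF) - lam1 * np.exp(lam2 * TRF)) / (lam2 - lam1)
    # degenerate (critically damped) entries: z = e^{lam t} (1 - lam t), lam = -R2sl/2
    deg = np.abs(lam2 - lam1) * TRF < 1e-12
    if np.any(deg):
        lam = -0.5 * R2sl
        z = np.where(deg, np.exp(lam * TRF) * (1.0 - lam * TRF), z)
    out = np.real(z)
    return out if out.ndim else float(out)


_R2SL_BRACKET = (1.0, 1e7)  # s^-1, physical search range
_memo: dict = {}


def linearized_R2sl(kernel: LineshapeKernel, alpha: float, TRF: float,
                    n_steps: int = 10_000, rtol: float = 1e-8) -> float:
    """Linearized semisolid relaxation rate R2s,l(T2s, alpha, TRF) in 1/s.

    Root-finds the rate at which an exponential-decay semisolid pool ends a
    rectangular pulse (flip ``alpha``, duration ``TRF``) with the same
    longitudinal magnetization zs as the generalized Bloch solution.
    Results are memoized per (kind, T2s, alpha, TRF) rounded at 1e-9.
    """
    if alpha == 0:
        raise ValueError(
            "alpha = 0: no saturation occurs; use the free-precession path "
            "(R2s = 1/T2s) instead of a linearized pulse rate")
    if not (alpha > 0 and TRF > 0):
        raise ValueError(f"require alpha > 0 and TRF > 0, got {alpha=}, {TRF=}")
    key = (kernel.kind.value, round(kernel.T2s, 9), round(alpha, 9), round(TRF, 9))
    hit = _memo.get(key)
    if hit is not None:
        return hit

    target = generalized_bloch_zs(kernel, alpha, TRF, n_steps=n_steps)
    lo, hi = _R2SL_BRACKET
    f = lambda r: exponential_model_zs(r, alpha, TRF) - target
    flo, fhi = f(lo), f(hi)
    # expand below 1/s if needed (very gentle pulses)
    while flo > 0 and lo > 1e-12:
        lo *= 1e-2
        flo = f(lo)
    if flo * fhi > 0:
        raise RuntimeError(
            f"R2s,l root not bracketed for {key}: f({lo})={flo:.3e}, "
            f"f({hi})={fhi:.3e}, target zs={target:.6f}")
    root = brentq(f, lo, hi, rtol=rtol, xtol=1e-12)
    _memo[key] = root
    return root


class R2slInterpolator:
    """Fast spline surrogate for the linearized rate.

    Tabulates g(alpha, rho) = R2s,l * T2s on a grid of flip angle alpha and
    log pulse-duration ratio rho = TRF/T2s (valid by the exact scaling
    identity), then evaluates by bivariate cubic spline.  One instance per
    kernel kind; the default table covers alpha in [5e-3, pi] rad and
    rho in [2, 2000], which encloses the schedules and T2s bounds used here.
    """

    def __init__(self, kind: LineshapeKind = LineshapeKind.SUPER_LORENTZIAN,
                 n_alpha: int = 40, n_ratio: int = 48,
                 alpha_range: tuple[float, float] = (5e-3, math.pi),
                 ratio_range: tuple[float, float] = (2.0, 2000.0),
                 n_steps: int = 3000) -> None:
        self.kind = LineshapeKind(kind)
        self.alphas = np.linspace(alpha_range[0], alpha_range[1], n_alpha)
        self.log_ratios = np.linspace(math.log(ratio_range[0]),
                                      math.log(ratio_range[1]), n_ratio)
        kernel = LineshapeKernel(self.kind, 1.0)  # unit T2s; scaling handles the rest
        table = np.empty((n_alpha, n_ratio))
        for j, lr in enumerate(self.log_ratios):
            TRF = math.exp(lr)
            targets = _volterra_zs_batch(kernel, self.alphas, TRF, n_steps)
            for i, (a, tz) in enumerate(zip(self.alphas, targets)):
                f = lambda r: exponential_model_zs(r, a, TRF) - tz
                lo, hi = 1e-8, 1e4
                root = brentq(f, lo, hi, rtol=1e-10, xtol=1e-14)
                table[i, j] = root  # = R2sl * T2s at unit T2s
        self._spline = RectBivariateSpline(self.alphas, self.log_ratios,
                                           np.log(table), kx=3, ky=3)

    def __call__(self, T2s, alpha, TRF):
        """Vectorized R2s,l in 1/s (inputs broadcast)."""
        T2s, alpha, TRF = np.broadcast_arrays(
            np.asarray(T2s, float), np.asarray(alpha, float), np.asarray(TRF, float))
        lr = np.log(TRF / T2s)
        g = np.exp(self._spline.ev(np.abs(alpha), lr))
        out = g / T2s
        return out if out.ndim else float(out)


_default_interp: dict[LineshapeKind, R2slInterpolator] = {}


def get_default_interpolator(kind=LineshapeKind.SUPER_LORENTZIAN) -> R2slInterpolator:
    kind = LineshapeKind(kind)
    if kind not in _default_interp:
        _default_interp[kind] = R2slInterpolator(kind)
    return _default_interp[kind]


def dump_R2sl_table(path, kernel: LineshapeKernel, alphas, TRFs) -> None:
    """Write a CSV lookup table (T2s_s, alpha_rad, TRF_s, R2sl_per_s)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["T2s_s", "alpha_rad", "TRF_s", "R2sl_per_s"])
        for a in alphas:
            for trf in TRFs:
                w.writerow([kernel.T2s, a, trf, linearized_R2sl(kernel, a, trf)])
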