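"""Independent oracle implementations used only by the tests.

These deliberately share no code path with the package: different
integration schemes, scipy's matrix exponential, and direct element-wise
transcriptions of the governing equations.
"""

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq


def superlorentzian_kernel_trapezoid(t, T2s, n_nodes=10_000):
    """Brute-force trapezoid quadrature of the super-Lorentzian kernel."""
    theta = np.linspace(0.0, np.pi / 2, n_nodes + 1)
    t = np.atleast_1d(np.asarray(t, float))
    integrand = np.sin(theta) * np.exp(
        -(t[:, None] ** 2 / (8.0 * T2s**2)) * (3.0 * np.cos(theta) ** 2 - 1.0) ** 2)
    vals = np.trapezoid(integrand, theta, axis=1)
    return vals if vals.size > 1 else float(vals[0])


def generalized_bloch_zs_heun(kernel_fn, alpha, TRF, dt_max=10e-9):
    """Fine-step explicit Heun solve of zs' = -w^2 int_0^t G(t-tau) zs dtau."""
    n = int(np.ceil(TRF / dt_max))
    dt = TRF / n
    w2 = (alpha / TRF) ** 2
    t = dt * np.arange(n + 1)
    G = np.asarray(kernel_fn(t), float)
    z = np.empty(n + 1)
    z[0] = 1.0
    # trapezoid weights for the memory integral at step k: G reversed
    for k in range(n):
        # f at t_k using z[0..k]
        if k == 0:
            fk = 0.0
        else:
            conv = G[:k + 1][::-1] * z[:k + 1]
            fk = -w2 * dt * (np.sum(conv) - 0.5 * conv[0] - 0.5 * conv[-1])
        zpred = z[k] + dt * fk
        conv2 = G[:k + 2][::-1] * np.append(z[:k + 1], zpred)
        fk1 = -w2 * dt * (np.sum(conv2) - 0.5 * conv2[0] - 0.5 * conv2[-1])
        z[k + 1] = z[k] + 0.5 * dt * (fk + fk1)
    return float(z[-1])


def linearized_rate_oracle(kernel_fn, alpha, TRF, dt_max=10e-9):
    """Fine-step generalized-Bloch solve + scipy-expm exponential matching."""
    target = generalized_bloch_zs_heun(kernel_fn, alpha, TRF, dt_max=dt_max)
    w = alpha / TRF

    def zs_exp(r):
        M = np.array([[-r, w], [-w, 0.0]]) * TRF
        return expm(M)[1, 1]

    return brentq(lambda r: zs_exp(r) - target, 1e-3, 1e8, rtol=1e-10)


def bloch_mcconnell_rhs(state, p, wy, wz, r2s):
    """Hand-coded component-wise right-hand side of the 2-pool equations."""
    xf, yf, zf, xs, zs, one = state
    m0s, m0f = p.m0s, 1.0 - p.m0s
    return np.array([
        -p.R2f * xf - wz * yf + wy * zf,
        wz * xf - p.R2f * yf,
        -wy * xf - (p.R1f + p.Rx * m0s) * zf + p.Rx * m0f * zs + m0f * p.R1f * one,
        -r2s * xs + wy * zs,
        p.Rx * m0s * zf - wy * xs - (p.R1s + p.Rx * m0f) * zs + m0s * p.R1s * one,
        0.0,
    ])


def rk4_propagate(state, matrix, duration, n_steps=100_000):
    """Fixed-step RK4 integration of the linear system s' = M s."""
    dt = duration / n_steps
    s = np.array(state, float)
    M = np.asarray(matrix, float)
    for _ in range(n_steps):
        k1 = M @ s
        k2 = M @ (s + 0.5 * dt * k1)
        k3 = M @ (s + 0.5 * dt * k2)
        k4 = M @ (s + dt * k3)
        s = s + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return s


def rk4_propagate_batch(states, matrices, duration, n_steps=100_000):
    """Batched RK4 on stacks of states/matrices (same duration)."""
    dt = duration / n_steps
    s = np.array(states, float)  # (B, 6)
    M = np.asarray(matrices, float)  # (B, 6, 6)
    for _ in range(n_steps):
        k1 = np.einsum("bij,bj->bi", M, s)
        k2 = np.einsum("bij,bj->bi", M, s + 0.5 * dt * k1)
        k3 = np.einsum("bij,bj->bi", M, s + 0.5 * dt * k2)
        k4 = np.einsum("bij,bj->bi", M, s + dt * k3)
        s = s + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return s
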