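"""Constrained-model "apparent" parameters.

Most of the qMT literature constrains the semisolid longitudinal relaxation
rate (typically R1s = R1f or R1s = 1/s).  The values such a constrained
model would report can be computed in closed form from the unconstrained
parameters:

    m0s,a = m0s * (1 - 2 m0f (R1s - R1f) / Rx)
    Rx,a  = (Rx + R1f) + m0f (R1s - R1f) + m0f m0s (R1s - R1f)^2 / Rx
    R1f,a = R1f + m0s (R1s - R1f) - m0f m0s (R1s - R1f)^2 / Rx

These are evaluated exactly as written.  Note the R1s = R1f limit gives
Rx,a = Rx + R1f — an R1f offset on the exchange rate rather than Rx itself;
this is a property of the formulas as stated, preserved deliberately.

All functions accept scalars or arrays (element-wise over maps), so applying
them to whole parameter volumes commutes with applying them per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spin_model import QMTParams


@dataclass(frozen=True)
class ApparentParams:
    """Apparent (constrained-model) pool size, exchange rate and free-pool R1."""

    m0s_a: float
    Rx_a: float
    R1f_a: float


def _unpack(p, m0s, R1f, R1s, Rx):
    if p is not None:
        m0s, R1f, R1s, Rx = p.m0s, p.R1f, p.R1s, p.Rx
    for name, v in (("m0s", m0s), ("R1f", R1f), ("R1s", R1s), ("Rx", Rx)):
        if v is None:
            raise TypeError(f"missing parameter {name}")
    Rx = np.asarray(Rx, float)
    if np.any(Rx == 0):
        raise ZeroDivisionError("Rx = 0: apparent parameters are undefined")
    return (np.asarray(m0s, float), np.asarray(R1f, float),
            np.asarray(R1s, float), Rx)


def apparent_m0s(p: QMTParams | None = None, *, m0s=None, R1f=None, R1s=None, Rx=None):
    """Apparent macromolecular pool size m0s,a."""
    m0s, R1f, R1s, Rx = _unpack(p, m0s, R1f, R1s, Rx)
    m0f = 1.0 - m0s
    out = m0s * (1.0 - 2.0 * m0f * (R1s - R1f) / Rx)
    return out if out.ndim else float(out)


def apparent_Rx(p: QMTParams | None = None, *, m0s=None, R1f=None, R1s=None, Rx=None):
    """Apparent magnetization exchange rate Rx,a."""
    m0s, R1f, R1s, Rx = _unpack(p, m0s, R1f, R1s, Rx)
    m0f = 1.0 - m0s
    d = R1s - R1f
    out = (Rx + R1f) + m0f * d + m0f * m0s * d**2 / Rx
    return out if out.ndim else float(out)


def apparent_R1f(p: QMTParams | None = None, *, m0s=None, R1f=None, R1s=None, Rx=None):
    """Apparent free-pool longitudinal relaxation rate R1f,a."""
    m0s, R1f, R1s, Rx = _unpack(p, m0s, R1f, R1s, Rx)
    m0f = 1.0 - m0s
    d = R1s - R1f
    out = R1f + m0s * d - m0f * m0s * d**2 / Rx
    return out if out.ndim else float(out)


def apparent_params(p: QMTParams) -> ApparentParams:
    return ApparentParams(m0s_a=apparent_m0s(p), Rx_a=apparent_Rx(p),
                          R1f_a=apparent_R1f(p))


def apparent_maps(maps: dict) -> dict:
    """Element-wise Eqs. applied to parameter maps (dict with m0s, R1f, R1s, Rx)."""
    kw = {k: np.asarray(maps[k], float) for k in ("m0s", "R1f", "R1s", "Rx")}
    return {"m0s_a": apparent_m0s(**kw), "Rx_a": apparent_Rx(**kw),
            "R1f_a": apparent_R1f(**kw)}


def m0s_to_psr(m0s):
    """Pool-size ratio PSR = m0s / (1 - m0s)."""
    m0s = np.asarray(m0s, float)
    if np.any(m0s >= 1):
        raise ValueError("m0s = 1 gives an infinite pool-size ratio")
    out = m0s / (1.0 - m0s)
    return out if out.ndim else float(out)


def psr_to_m0s(psr):
    """Inverse conversion m0s = PSR / (1 + PSR)."""
    psr = np.asarray(psr, float)
    out = psr / (1.0 + psr)
    return out if out.ndim else float(out)
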