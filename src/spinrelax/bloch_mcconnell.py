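"""Numerical two-site Bloch-McConnell propagators.

These simulate the actual magnetization evolution during a CPMG pulse train
or under a spin-lock field for a two-site exchanging system, with no
closed-form approximations.  They serve as the independent numerical
cross-check for the closed-form dispersion models in :mod:`spinrelax.dispersion`
(matrix exponentials vs. analytic expressions: two fully separate routes).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import expm


def cpmg_propagator_r2eff(pa: float, kex: float, dw_rad: float,
                          ra: float, rb: float, nu_cp: float,
                          t_relax: float) -> float:
    """R2eff from an explicit CPMG pulse-train propagation.

    The transverse magnetization of the two sites evolves under free
    precession + exchange + relaxation; ideal 180 deg pulses are applied as
    complex conjugation with inter-pulse delay tau_cp = 1/(2 nu_cp) (nu_cp is
    the 180-pulse repetition frequency).  The number of pulses is rounded to
    the nearest integer >= 2 fitting the constant time, and R2eff is computed
    from the total signal at the end of the constant-time period,
    R2eff = -(1/T) ln(|M(T)| / |M(0)|).
    """
    pb = 1.0 - pa
    kab = pb * kex
    kba = pa * kex
    # site a on resonance, site b shifted by dw
    ell = np.array(
        [[-ra - kab, kba],
         [kab, -rb - kba + 1j * dw_rad]],
        dtype=complex,
    )
    tau_cp = 1.0 / (2.0 * nu_cp)
    n = max(2, int(round(t_relax / tau_cp)))
    t_eff = n * tau_cp
    u_half = expm(ell * (tau_cp / 2.0))
    m = np.array([pa, pb], dtype=complex)
    for _ in range(n):
        m = u_half @ np.conj(u_half @ m)
    i0 = abs(pa + pb)
    i_t = abs(m.sum())
    return -math.log(i_t / i0) / t_eff


def _r1rho_matrix(pa: float, kex: float, delta_a: float, delta_b: float,
                  omega_1: float, r1: float, r2a: float, r2b: float) -> np.ndarray:
    """6x6 evolution matrix for (Max,May,Maz,Mbx,Mby,Mbz) in the rotating
    frame: offsets about z, spin-lock omega_1 about x, relaxation, exchange."""
    pb = 1.0 - pa
    kab = pb * kex
    kba = pa * kex

    def site_block(delta: float, r2: float) -> np.ndarray:
        return np.array(
            [[-r2, -delta, 0.0],
             [delta, -r2, -omega_1],
             [0.0, omega_1, -r1]]
        )

    top = np.hstack([site_block(delta_a, r2a) - kab * np.eye(3), kba * np.eye(3)])
    bot = np.hstack([kab * np.eye(3), site_block(delta_b, r2b) - kba * np.eye(3)])
    return np.vstack([top, bot])


def r1rho_propagator(pa: float, kex: float, dw_rad: float,
                     omega_sl: float, omega_off: float,
                     r1: float, r2a: float, r2b: float | None = None,
                     delays: np.ndarray | None = None) -> float:
    """R1rho from numerical propagation under a spin-lock field.

    ``omega_sl`` and ``omega_off`` in rad/s; ``omega_off`` is the offset of
    the population-average resonance from the spin-lock carrier; the two
    sites are split about it by ``dw_rad`` weighted by populations.  The
    magnetization starts (and is detected) along the average effective-field
    direction; R1rho is the log-linear decay rate of that projection over
    the sampled ``delays`` (default 10-200 ms).
    """
    if r2b is None:
        r2b = r2a
    pb = 1.0 - pa
    delta_a = omega_off - pb * dw_rad
    delta_b = omega_off + pa * dw_rad
    ell = _r1rho_matrix(pa, kex, delta_a, delta_b, omega_sl, r1, r2a, r2b)
    w_eff = math.hypot(omega_sl, omega_off)
    e = np.array([omega_sl / w_eff, 0.0, omega_off / w_eff])
    m0 = np.concatenate([pa * e, pb * e])
    if delays is None:
        delays = np.linspace(0.01, 0.2, 6)
    proj = []
    for t in delays:
        m = expm(ell * t) @ m0
        proj.append(e @ m[:3] + e @ m[3:])
    proj = np.asarray(proj)
    if np.any(proj <= 0):
        raise FloatingPointError("magnetization projection not positive")
    slope = np.polyfit(delays, np.log(proj), 1)[0]
    return -float(slope)


def r1rho_propagator_r2eff(pa: float, kex: float, dw_rad: float,
                           omega_sl: float, omega_off: float,
                           r1: float, r2_0: float) -> float:
    """R2eff implied by the propagated R1rho via the tilted-frame relation
    R2 = (R1rho - R1 cos^2 theta)/sin^2 theta, theta = arctan(wSL/woff)."""
    r1rho = r1rho_propagator(pa, kex, dw_rad, omega_sl, omega_off, r1, r2_0)
    theta = math.atan2(omega_sl, omega_off)
    s2, c2 = math.sin(theta) ** 2, math.cos(theta) ** 2
    return (r1rho - r1 * c2) / s2
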