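"""Spin-pair physical constants, spectral density functions and closed-form
relaxation rates.

All spectral densities are in s/rad, all rates in s^-1 and all frequencies
internally in rad/s.  Gyromagnetic ratios are stored as magnitudes together
with a sign flag; interaction constants follow the convention that the
dipolar constant ``d`` is a positive magnitude while the CSA constant ``c``
carries the sign of the shift anisotropy (negative for backbone amide 15N).
With this convention the CSA/dipolar correction factor kappa used by the
RCZZ analysis is positive for the 15N defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

# CODATA values, rad s^-1 T^-1 (magnitudes) and SI constants
GAMMA_H1 = 2.6752218708e8
GAMMA_MAG = {"N15": 2.71261804e7, "C13": 6.728284e7}
GAMMA_SIGN = {"N15": -1.0, "C13": +1.0}
MU0 = 4.0e-7 * math.pi
H_PLANCK = 6.62607015e-34

#: single effective high frequency used in reduced spectral density mapping
HIGH_FREQ_SCALE = 0.87

Nucleus = Literal["N15", "C13"]


class MagicAngleError(ValueError):
    """CSA/dipole angle at the magic angle: P2(cos beta) = 0, kappa singular."""


@dataclass(frozen=True)
class SpinSystem:
    """An X-H spin pair (X = 15N or 13C) with its interaction geometry.

    Parameters
    ----------
    nucleus:
        Heteronucleus, ``"N15"`` or ``"C13"``.
    r_xh:
        X-H internuclear distance in Angstrom.
    delta_sigma:
        CSA anisotropy (sigma_par - sigma_perp) in ppm, signed.
    beta:
        Angle between the CSA major axis and the X-H bond vector, degrees.
    """

    nucleus: Nucleus = "N15"
    r_xh: float = 1.02
    delta_sigma: float = -164.0
    beta: float = 18.0

    def __post_init__(self) -> None:
        if self.nucleus not in GAMMA_MAG:
            raise ValueError(f"unknown nucleus {self.nucleus!r}")
        if self.r_xh <= 0:
            raise ValueError("bond length r_xh must be positive")
        if abs(self.beta) > 90:
            raise ValueError("CSA/bond angle beta must satisfy |beta| <= 90 deg")

    @property
    def gamma_x(self) -> float:
        """Magnitude of the heteronuclear gyromagnetic ratio, rad/s/T."""
        return GAMMA_MAG[self.nucleus]

    @property
    def gamma_ratio(self) -> float:
        """Signed gamma_H / gamma_X (negative for 15N)."""
        return GAMMA_SIGN[self.nucleus] * GAMMA_H1 / GAMMA_MAG[self.nucleus]


def _for_carbon(spin_defaults: bool = True) -> "SpinSystem":
    """Generic aliphatic/aromatic 13C-1H pair; CSA matters little for the
    fitted-R2(0) dispersion analyses this package performs on carbon."""
    return SpinSystem(nucleus="C13", r_xh=1.09, delta_sigma=25.0, beta=0.0)


SpinSystem.carbon_default = staticmethod(_for_carbon)


@dataclass(frozen=True)
class FieldContext:
    """A static magnetic field, identified by its 1H Larmor frequency in MHz."""

    proton_mhz: float
    temperature: float = 298.0

    @property
    def omega_h(self) -> float:
        """1H Larmor frequency magnitude, rad/s."""
        return 2.0 * math.pi * self.proton_mhz * 1e6

    def omega_x(self, nucleus: Nucleus) -> float:
        """Heteronucleus Larmor frequency magnitude, rad/s."""
        return self.omega_h * GAMMA_MAG[nucleus] / GAMMA_H1

    def ppm_to_rad_s(self, ppm: float, nucleus: Nucleus) -> float:
        """Convert a chemical-shift difference in ppm of `nucleus` to rad/s."""
        return ppm * 1e-6 * self.omega_x(nucleus)


@dataclass(frozen=True)
class SpectralDensityTriple:
    """Reduced spectral density values J(0), J(omega_X), J(0.87 omega_H)."""

    j0: float
    jwx: float
    jwh_eff: float
    negative_j0: bool = field(default=False, compare=False)


def p2(x: float) -> float:
    """Second Legendre polynomial P2(x) = (3x^2 - 1)/2."""
    return 0.5 * (3.0 * x * x - 1.0)


def dipolar_constant(spin: SpinSystem, field: FieldContext | None = None) -> float:
    """Dipolar interaction constant d = mu0 h gH gX / (8 pi^2 r^3), rad/s.

    Field-independent; ``field`` is accepted for interface symmetry with
    :func:`csa_constant`.  Returned as a positive magnitude (sign flags for
    gamma are carried separately, see module docstring).
    """
    r = spin.r_xh * 1e-10
    if r <= 0:
        raise ValueError("bond length must be positive")
    return MU0 * H_PLANCK * GAMMA_H1 * spin.gamma_x / (8.0 * math.pi**2 * r**3)


def csa_constant(spin: SpinSystem, field: FieldContext) -> float:
    """CSA interaction constant c = omega_X (sigma_par - sigma_perp)/sqrt(3).

    Signed with delta_sigma, proportional to the static field. rad/s.
    """
    return field.omega_x(spin.nucleus) * spin.delta_sigma * 1e-6 / math.sqrt(3.0)


def kappa(spin: SpinSystem, field: FieldContext) -> float:
    """CSA/dipolar correction factor relating eta_xy to the exchange-free R2.

    kappa = -6[(d^2/8) + (c^2/6)] / (sqrt(3) c d P2(cos beta)).

    For the 15N defaults (r = 1.02 A, delta_sigma = -164 ppm, beta = 18 deg)
    at a 750 MHz field this evaluates to 1.2283.
    """
    d = dipolar_constant(spin, field)
    c = csa_constant(spin, field)
    p2b = p2(math.cos(math.radians(spin.beta)))
    if abs(p2b) < 1e-12:
        raise MagicAngleError("beta at the magic angle: P2(cos beta) = 0")
    if c == 0.0 or d == 0.0:
        raise ValueError("kappa undefined for vanishing c or d")
    return -6.0 * (d * d / 8.0 + c * c / 6.0) / (math.sqrt(3.0) * c * d * p2b)


# ---------------------------------------------------------------------------
# spectral density functions


def j_modelfree(omega, s2: float, tau_c: float, tau_i: float = 0.0):
    """Lipari-Szabo model-free spectral density, s/rad.

    J(w) = (2/5) [ S^2 tc/(1+(w tc)^2) + (1-S^2) t/(1+(w t)^2) ],
    1/t = 1/tc + 1/ti.  ``tau_i = 0`` collapses the internal-motion term.
    """
    if not 0.0 <= s2 <= 1.0:
        raise ValueError("order parameter s2 must lie in [0, 1]")
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    if tau_i < 0:
        raise ValueError("tau_i must be non-negative")
    omega = np.asarray(omega, dtype=float)
    j = s2 * tau_c / (1.0 + (omega * tau_c) ** 2)
    if tau_i > 0.0:
        tau = tau_c * tau_i / (tau_c + tau_i)
        j = j + (1.0 - s2) * tau / (1.0 + (omega * tau) ** 2)
    return 0.4 * j


def j_extended(omega, sf2: float, ss2: float, tau_c: float, tau_s: float):
    """Extended (two-timescale) model-free spectral density, s/rad.

    S^2 = Sf^2 Ss^2; the fast internal correlation time is taken in its
    tau_f -> 0 limit so only the slow internal motion contributes a second
    Lorentzian: J(w) = (2/5)[S^2 tc/(1+(w tc)^2) + (Sf^2-S^2) t'/(1+(w t')^2)].
    """
    for name, v in (("sf2", sf2), ("ss2", ss2)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    omega = np.asarray(omega, dtype=float)
    s2 = sf2 * ss2
    j = s2 * tau_c / (1.0 + (omega * tau_c) ** 2)
    if tau_s > 0.0:
        tau = tau_c * tau_s / (tau_c + tau_s)
        j = j + (sf2 - s2) * tau / (1.0 + (omega * tau) ** 2)
    return 0.4 * j


def axial_weights(nh_angle_deg: float) -> tuple[float, float, float]:
    """Woessner weights A1, A2, A3 for an axially symmetric rotor.

    ``nh_angle_deg`` is the angle between the X-H vector and the unique
    diffusion axis.  The weights sum to 1 for any angle.
    """
    c = math.cos(math.radians(nh_angle_deg))
    s2 = 1.0 - c * c
    a1 = p2(c) ** 2
    a2 = 3.0 * c * c * s2
    a3 = 0.75 * s2 * s2
    return a1, a2, a3


def axial_taus(tau_c: float, d_ratio: float) -> tuple[float, float, float]:
    """Correlation times of the three axial-rotor Lorentzians.

    tau_c is the isotropic-equivalent 1/(6 D_iso) with D_iso=(Dpar+2Dperp)/3.
    """
    d_iso = 1.0 / (6.0 * tau_c)
    d_perp = 3.0 * d_iso / (d_ratio + 2.0)
    d_par = d_ratio * d_perp
    return (
        1.0 / (6.0 * d_perp),
        1.0 / (5.0 * d_perp + d_par),
        1.0 / (2.0 * d_perp + 4.0 * d_par),
    )


def j_axial(omega, s2: float, tau_i: float, tau_c: float, d_ratio: float,
            nh_angle_deg: float):
    """Model-free spectral density under axially symmetric rotational diffusion.

    Three Lorentzians with Woessner weights depending on the angle between the
    bond vector and the symmetry axis, each dressed with the Lipari-Szabo
    internal-motion factor.  Reduces to :func:`j_modelfree` for d_ratio = 1.
    """
    if not 0.0 <= s2 <= 1.0:
        raise ValueError("order parameter s2 must lie in [0, 1]")
    omega = np.asarray(omega, dtype=float)
    weights = axial_weights(nh_angle_deg)
    taus = axial_taus(tau_c, d_ratio)
    j = np.zeros_like(omega, dtype=float)
    for a_k, t_k in zip(weights, taus):
        term = s2 * t_k / (1.0 + (omega * t_k) ** 2)
        if tau_i > 0.0:
            tk_i = t_k * tau_i / (t_k + tau_i)
            term = term + (1.0 - s2) * tk_i / (1.0 + (omega * tk_i) ** 2)
        j = j + a_k * term
    return 0.4 * j


# ---------------------------------------------------------------------------
# closed-form rates


def rates_from_j(spin: SpinSystem, field: FieldContext,
                 j: Callable[[np.ndarray], np.ndarray],
                 rex: float = 0.0) -> tuple[float, float, float]:
    """(R1, R2, NOE) from a spectral density callable.

    Standard dipolar + CSA expressions for an isolated X-H pair:

    R1  = (d^2/4)[J(wH-wX) + 3 J(wX) + 6 J(wH+wX)] + c^2 J(wX)
    R2  = (d^2/8)[4 J(0) + J(wH-wX) + 3 J(wX) + 6 J(wH) + 6 J(wH+wX)]
          + (c^2/6)[4 J(0) + 3 J(wX)] + Rex
    NOE = 1 + (d^2/4)(gH/gX)[6 J(wH+wX) - J(wH-wX)] / R1

    with the signed gyromagnetic ratio in the NOE term.
    """
    d = dipolar_constant(spin, field)
    c = csa_constant(spin, field)
    wh = field.omega_h
    wx = field.omega_x(spin.nucleus)
    j0, jx, jh, jmh, jph = np.atleast_1d(
        j(np.array([0.0, wx, wh, wh - wx, wh + wx]))
    )
    d2, c2 = d * d, c * c
    r1 = 0.25 * d2 * (jmh + 3.0 * jx + 6.0 * jph) + c2 * jx
    r2 = (d2 / 8.0) * (4.0 * j0 + jmh + 3.0 * jx + 6.0 * jh + 6.0 * jph) \
        + (c2 / 6.0) * (4.0 * j0 + 3.0 * jx) + rex
    if r1 == 0.0:
        raise ZeroDivisionError("R1 = 0: NOE undefined")
    noe = 1.0 + 0.25 * d2 * spin.gamma_ratio * (6.0 * jph - jmh) / r1
    return float(r1), float(r2), float(noe)


def eta_xy(spin: SpinSystem, field: FieldContext, j0: float, jwx: float) -> float:
    """Transverse CSA/dipolar cross-correlated relaxation rate, s^-1.

    Normalised so that kappa * eta_xy = [(d^2/8)+(c^2/6)] [4 J(0) + 3 J(wX)]
    exactly, i.e. kappa*eta_xy is the J(0)/J(wX) part of the exchange-free R2.
    Positive for the 15N defaults.
    """
    d = dipolar_constant(spin, field)
    c = csa_constant(spin, field)
    p2b = p2(math.cos(math.radians(spin.beta)))
    return -(math.sqrt(3.0) / 6.0) * c * d * p2b * (4.0 * j0 + 3.0 * jwx)


def reduced_spectral_density_map(r1: float, r2: float, noe: float,
                                 spin: SpinSystem, field: FieldContext
                                 ) -> SpectralDensityTriple:
    """Invert (R1, R2, NOE) to J(0), J(wX), J(0.87 wH).

    The mapping assumes the spectral density is flat across the three proton
    frequencies, J(wH-wX) ~ J(wH) ~ J(wH+wX) ~ J(0.87 wH), and Rex = 0; under
    that approximation it is the exact algebraic inverse of
    :func:`rates_from_j`:

        sigma      = (NOE - 1) R1 (gX/gH)
        J(0.87wH)  = 4 sigma / (5 d^2)
        J(wX)      = [4 R1 - (28/5) sigma] / (3 d^2 + 4 c^2)
        J(0)       = [6 R2 - 3 R1 - (18/5) sigma] / (3 d^2 + 4 c^2)

    A negative J(0) is permitted but flagged: it signals exchange (Rex > 0)
    or noise-dominated input.
    """
    if r1 <= 0:
        raise ValueError("R1 must be positive")
    d2 = dipolar_constant(spin, field) ** 2
    c2 = csa_constant(spin, field) ** 2
    sigma = (noe - 1.0) * r1 / spin.gamma_ratio
    jwh = 4.0 * sigma / (5.0 * d2)
    denom = 3.0 * d2 + 4.0 * c2
    jwx = (4.0 * r1 - 5.6 * sigma) / denom
    j0 = (6.0 * r2 - 3.0 * r1 - 3.6 * sigma) / denom
    return SpectralDensityTriple(j0=float(j0), jwx=float(jwx), jwh_eff=float(jwh),
                                 negative_j0=bool(j0 < 0))
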