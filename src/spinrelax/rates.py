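"""Reduction of peak-intensity series to relaxation rates and exchange maps.

Covers monoexponential R1/R1rho decays, R2 from tilted-frame R1rho,
heteronuclear NOE ratios, eta_xy from tanh intensity-ratio fits, and the
Hahn-echo RCZZ observables (R2_RCZZ and the slow-exchange map
Rex = R2_RCZZ - kappa*eta_xy + R1/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .spinphys import FieldContext

#: total RCZZ Hahn-echo period 2*tau_he = n/J_NH, seconds
RCZZ_ECHO_PERIOD = 0.1296

#: default on-resonance alignment filter: keep points with w_off/w_SL <= 0.4
ALIGNMENT_RATIO_MAX = 0.4


@dataclass
class IntensitySeries:
    """One residue's peak intensities versus an experimental condition.

    ``condition_type`` is one of ``"delay"`` (s), ``"nu_cp"`` (Hz) or
    ``"spinlock"``; ``values`` holds (condition value, intensity, replicate
    index) triples.  Intensities may be negative.
    """

    residue_id: int
    atom: str
    condition_type: str
    values: list[tuple[float, float, int]]
    noise_sigma: float | None = None

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        a = np.asarray(self.values, dtype=float)
        return a[:, 0], a[:, 1], a[:, 2].astype(int)


@dataclass
class RateRecord:
    """Per-residue relaxation rates with 1-sigma errors at one field."""

    residue_id: int
    field: FieldContext
    r1: float = math.nan
    r1_err: float = 0.0
    r2: float = math.nan
    r2_err: float = 0.0
    noe: float = math.nan
    noe_err: float = 0.0
    eta_xy: float | None = None
    eta_xy_err: float = 0.0
    r2_rczz: float | None = None
    r2_rczz_err: float = 0.0
    rex_map: float | None = None
    rex_map_err: float = 0.0
    flags: list[str] = dc_field(default_factory=list)


def pooled_replicate_sigma(x: np.ndarray, intensity: np.ndarray,
                           replicate: np.ndarray) -> float | None:
    """Noise estimate from repeat measurements: pooled standard deviation of
    replicate differences divided by sqrt(2).  None if no condition value has
    two or more replicates."""
    diffs = []
    for xv in np.unique(x):
        ys = intensity[x == xv]
        if ys.size >= 2:
            diffs.extend((ys - ys.mean()).tolist())
    if not diffs:
        return None
    d = np.asarray(diffs)
    # ddof: one mean per replicated condition
    n_groups = sum(1 for xv in np.unique(x) if (x == xv).sum() >= 2)
    return float(np.sqrt((d**2).sum() / max(1, d.size - n_groups)))


def fit_monoexponential(series: IntensitySeries, mc_draws: int = 0,
                        seed: int | None = None
                        ) -> tuple[float, float, float]:
    """Least-squares fit of I(t) = I0 exp(-R t); returns (R, sigma_R, I0).

    The starting point comes from a log-linear regression.  The rate error is
    covariance-based by default; with ``mc_draws > 0`` it is replaced by a
    seeded Monte-Carlo estimate using the series noise (pooled replicate
    scatter when available).  Non-convergence is reported as R = nan rather
    than raised.
    """
    t, intensity, replicate = series.as_arrays()
    if np.unique(t).size < 3:
        raise ValueError("need >= 3 distinct condition values for a decay fit")

    sigma = series.noise_sigma
    pooled = pooled_replicate_sigma(t, intensity, replicate)
    if pooled is not None:
        sigma = pooled

    pos = intensity > 0
    if pos.sum() >= 2:
        slope, icpt = np.polyfit(t[pos], np.log(intensity[pos]), 1)
        p0 = (math.exp(icpt), max(1e-6, -slope))
    else:
        p0 = (intensity.max(initial=1.0), 1.0)

    def model(tt, i0, r):
        return i0 * np.exp(-r * tt)

    try:
        popt, pcov = curve_fit(model, t, intensity, p0=p0, maxfev=10000)
    except RuntimeError:
        return math.nan, math.nan, math.nan
    i0, rate = popt
    err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else math.nan
    if sigma is not None:
        # curve_fit's unscaled covariance assumes unit point variance;
        # rescale from the residual-based estimate to the measured noise
        resid = intensity - model(t, *popt)
        dof = max(1, t.size - 2)
        s_resid = math.sqrt(float((resid**2).sum()) / dof)
        if s_resid > 0:
            err = err / s_resid * sigma
    if mc_draws > 0 and sigma is not None:
        rng = np.random.default_rng(seed)
        draws = []
        base = model(t, *popt)
        for _ in range(mc_draws):
            y = base + rng.normal(0.0, sigma, size=t.size)
            try:
                p, _ = curve_fit(model, t, y, p0=popt, maxfev=5000)
                draws.append(p[1])
            except RuntimeError:
                continue
        if len(draws) >= mc_draws // 2:
            err = float(np.std(draws, ddof=1))
    return float(rate), err, float(i0)


def r2_from_r1rho(r1rho: float, r1: float, omega_sl: float, omega_off: float,
                  min_sin2: float = 0.1) -> float:
    """R2 from the tilted-frame relation R1rho = R1 cos^2(t) + R2 sin^2(t),
    theta = arctan(w_SL/w_off); on-resonance (w_off = 0) gives theta = 90 deg
    and R2 = R1rho.  Frequencies in Hz (only their ratio matters)."""
    if omega_sl <= 0:
        raise ValueError("spin-lock field strength must be positive")
    theta = math.atan2(omega_sl, omega_off)
    s2 = math.sin(theta) ** 2
    if s2 < min_sin2:
        raise ValueError(
            f"effective field tilted too far from transverse (sin^2 theta = {s2:.3g})"
        )
    return (r1rho - r1 * (1.0 - s2)) / s2


def filter_alignment(points: Sequence[tuple[float, float]],
                     max_ratio: float = ALIGNMENT_RATIO_MAX) -> list[bool]:
    """Alignment pre-filter for on-resonance R1rho points: keep those with
    |w_off| / w_SL <= max_ratio (default 0.4)."""
    return [abs(off) / sl <= max_ratio for sl, off in points]


def het_noe(i_sat: float, i_ref: float, noise_sigma: float = 0.0
            ) -> tuple[float, float, bool]:
    """Heteronuclear NOE = I_sat/I_ref with first-order ratio error
    propagation.  Returns (NOE, sigma, flagged); flagged when the reference
    intensity is consistent with zero at the stated noise."""
    if i_ref == 0:
        raise ZeroDivisionError("reference intensity is zero")
    noe = i_sat / i_ref
    flagged = noise_sigma > 0 and abs(i_ref) < 3.0 * noise_sigma
    sigma = abs(noe) * math.hypot(
        noise_sigma / i_sat if i_sat != 0 else 0.0, noise_sigma / i_ref
    ) if noise_sigma else 0.0
    if i_sat == 0 and noise_sigma:
        sigma = noise_sigma / abs(i_ref)
    return noe, sigma, flagged


def fit_eta_xy(ratios: Sequence[tuple[float, float]],
               ratio_sigma: float | None = None) -> tuple[float, float]:
    """eta_xy from intensity ratios I_B/I_A = tanh(eta_xy T).

    A single (T, ratio) pair is solved in closed form atanh(ratio)/T; more
    points are fitted by least squares.  Ratios must satisfy |ratio| < 1.
    """
    ratios = list(ratios)
    if not ratios:
        raise ValueError("need at least one (T, ratio) pair")
    t = np.array([p[0] for p in ratios])
    r = np.array([p[1] for p in ratios])
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|I_B/I_A| >= 1 is outside the tanh model range")
    if len(ratios) == 1:
        eta = math.atanh(r[0]) / t[0]
        err = 0.0
        if ratio_sigma:
            err = ratio_sigma / ((1.0 - r[0] ** 2) * t[0])
        return float(eta), float(err)
    if np.all(r == 0.0):
        return 0.0, 0.0
    eta0 = float(np.mean(np.arctanh(np.clip(r, -0.999, 0.999)) / t))
    popt, pcov = curve_fit(lambda tt, eta: np.tanh(eta * tt), t, r, p0=(eta0,))
    err = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else math.nan
    if ratio_sigma is not None:
        resid = r - np.tanh(popt[0] * t)
        s = math.sqrt(float((resid**2).sum()) / max(1, t.size - 1))
        if s > 0 and math.isfinite(err):
            err = err / s * ratio_sigma
    return float(popt[0]), err


def rczz_r2(i: float, i_ref: float,
            tau_he_total: float = RCZZ_ECHO_PERIOD) -> float:
    """Hahn-echo RCZZ rate R2 = -(1/2 tau_he) ln(I/I_ref); ``tau_he_total``
    is the full echo period 2*tau_he (default 129.6 ms).  A non-positive
    intensity ratio (exchange-broadened beyond detection) returns nan."""
    if i_ref == 0:
        raise ZeroDivisionError("reference intensity is zero")
    ratio = i / i_ref
    if ratio <= 0:
        return math.nan
    return -math.log(ratio) / tau_he_total


def rex_from_rczz(r2_rczz: float, eta: float, r1: float, kappa_val: float,
                  r2_rczz_err: float = 0.0, eta_err: float = 0.0,
                  r1_err: float = 0.0) -> tuple[float, float]:
    """Slow-exchange contribution Rex = R2_RCZZ - kappa*eta_xy + R1/2.

    kappa*eta_xy is the exchange-free intrinsic transverse rate (CSA +
    dipolar only); the error is propagated in quadrature."""
    rex = r2_rczz - kappa_val * eta + 0.5 * r1
    err = math.sqrt(r2_rczz_err**2 + (kappa_val * eta_err) ** 2
                    + (0.5 * r1_err) ** 2)
    return rex, err


def cpmg_r2eff(i_cpmg: float, i_ref: float, t_relax: float,
               noise_sigma: float = 0.0) -> tuple[float, float]:
    """Constant-time CPMG effective rate R2eff = -(1/T) ln(I_CPMG/I_ref).

    Per-point sigma by first-order propagation of the intensity noise.
    A non-positive ratio yields (nan, nan): the point is flagged for
    exclusion, never imputed."""
    if t_relax <= 0:
        raise ValueError("constant time must be positive")
    if i_ref == 0:
        raise ZeroDivisionError("reference intensity is zero")
    ratio = i_cpmg / i_ref
    if ratio <= 0:
        return math.nan, math.nan
    r2 = -math.log(ratio) / t_relax
    sigma = 0.0
    if noise_sigma:
        sigma = math.hypot(noise_sigma / i_cpmg, noise_sigma / i_ref) / t_relax
    return r2, sigma
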