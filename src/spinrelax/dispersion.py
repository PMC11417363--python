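"""Two-site exchange relaxation-dispersion models and fitting.

CPMG dispersion uses the general two-site (Carver-Richards) closed form,
valid in all exchange regimes; spin-lock (R1rho) dispersion uses the
two-site fast-exchange form R2eff = R2(0) + phi_ex kex/(w_SL^2+w_off^2+kex^2)
with phi_ex = pa pb dw^2.  Fits are weighted least squares with a
multi-start grid (the Carver-Richards chi^2 surface is multimodal), support
shared kinetic parameters across residues and fields, fixed-dw fitting,
AIC model comparison and seeded Monte-Carlo parameter errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .spinphys import FieldContext, Nucleus

#: chi2_g/chi2_i above which a residue is flagged as inconsistent with the
#: shared-kinetics hypothesis and excluded from the global fit
CHI2_RATIO_CUTOFF = 2.0


@dataclass
class ExchangeParams:
    """Two-site exchange state A <-> B.

    pa is the major-state population; kex = kab + kba; dw_ppm the
    chemical-shift difference in ppm (converted per field/nucleus at use);
    ra/rb intrinsic transverse rates (assumed equal by default).
    """

    pa: float
    kex: float
    dw_ppm: float
    ra: float
    rb: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.pa < 1.0:
            raise ValueError("pa must lie strictly between 0 and 1")
        if self.kex <= 0:
            raise ValueError("kex must be positive")
        if self.rb is None:
            self.rb = self.ra
        if self.ra < 0 or self.rb < 0:
            raise ValueError("intrinsic rates must be non-negative")

    @property
    def pb(self) -> float:
        return 1.0 - self.pa

    def phi_ex(self, field: FieldContext, nucleus: Nucleus = "N15") -> float:
        """pa pb dw^2 in rad^2/s^2 at the given field."""
        dw = field.ppm_to_rad_s(self.dw_ppm, nucleus)
        return self.pa * self.pb * dw * dw


@dataclass
class CpmgCurve:
    """One residue's CPMG dispersion at one field.

    ``points`` is an (n, 3) array of (nu_cp [Hz, 180-pulse repetition
    frequency], R2eff [1/s], sigma [1/s]).
    """

    residue_id: int
    field: FieldContext
    points: np.ndarray
    t_relax: float = 0.08
    nucleus: Nucleus = "N15"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))


@dataclass
class R1rhoCurve:
    """One site's spin-lock dispersion: points (w_SL [Hz], w_off [Hz],
    R2eff [1/s], sigma).  r2_0_mode 'fixed_kappa_eta' (15N: R2(0) pinned to
    kappa*eta_xy, supplied in ``r2_0``) or 'fitted' (13C)."""

    residue_id: int
    nucleus: Nucleus
    field: FieldContext
    points: np.ndarray
    r1: float = 0.0
    r2_0_mode: str = "fixed_kappa_eta"
    r2_0: float | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        w2 = self.points[:, 0] ** 2 + self.points[:, 1] ** 2
        if np.any(w2 <= 0):
            raise ValueError("every point needs a non-zero effective field")


@dataclass
class FitResult:
    """Result of a dispersion fit."""

    model: str
    params: dict[str, float]
    chi2: float
    n_points: int
    n_params: int
    per_residue_chi2: dict[int, float] = dc_field(default_factory=dict)
    chi2_ratio: dict[int, float] = dc_field(default_factory=dict)
    mc_errors: dict[str, float] = dc_field(default_factory=dict)
    flags: list[str] = dc_field(default_factory=list)
    excluded: list[int] = dc_field(default_factory=list)

    @property
    def aic(self) -> float:
        """Akaike information criterion with measurement errors treated as
        known: AIC = chi^2 + 2 n_params."""
        return self.chi2 + 2.0 * self.n_params


# ---------------------------------------------------------------------------
# forward models


def carver_richards_r2eff(pa: float, kex: float, dw_rad: float,
                          ra: float, rb: float, nu_cp) -> np.ndarray:
    """General two-site exchange CPMG effective rate (Carver-Richards form).

    R2eff = 0.5 (Ra + Rb + kex) - nu_cp * arccosh(D+ cosh(eta+) - D- cos(eta-))

    with psi = [Ra - Rb + (pb - pa) kex]^2 - dw^2 + 4 pa pb kex^2,
    xi = 2 dw [Ra - Rb + (pb - pa) kex], D+- and eta+- in the standard form,
    eta+- prefactor 1/(sqrt(8) nu_cp) (nu_cp = 180-pulse repetition
    frequency, inter-pulse delay 1/(2 nu_cp)).  dw in rad/s, nu_cp in Hz.

    The form satisfies the required limits exactly: flat dispersion for
    dw = 0 (with Ra = Rb) and R2eff -> Ra for pb -> 0.
    """
    if not 0.0 < pa < 1.0 or kex <= 0:
        raise ValueError("need 0 < pa < 1 and kex > 0")
    nu_cp = np.asarray(nu_cp, dtype=float)
    if np.any(nu_cp <= 0):
        raise ValueError("nu_cp must be positive")
    pb = 1.0 - pa
    dr = ra - rb + (pb - pa) * kex
    psi = dr * dr - dw_rad * dw_rad + 4.0 * pa * pb * kex * kex
    xi = 2.0 * dw_rad * dr
    root = math.hypot(psi, xi)
    root = max(root, 1e-300)
    d_plus = 0.5 * (1.0 + (psi + 2.0 * dw_rad * dw_rad) / root)
    d_minus = 0.5 * (-1.0 + (psi + 2.0 * dw_rad * dw_rad) / root)
    eta_plus = np.sqrt(max(root + psi, 0.0)) / (math.sqrt(8.0) * nu_cp)
    eta_minus = np.sqrt(max(root - psi, 0.0)) / (math.sqrt(8.0) * nu_cp)

    if eta_plus.max() <= 300.0:
        z = d_plus * np.cosh(eta_plus) - d_minus * np.cos(eta_minus)
        bad = z < 1.0
        if bad.any():
            warnings.warn("arccosh argument < 1 clamped", RuntimeWarning,
                          stacklevel=2)
            z[bad] = 1.0
        out = np.arccosh(z)
    else:
        out = np.empty_like(nu_cp)
        big = eta_plus > 300.0  # cosh would overflow; asymptotic arccosh
        small = ~big
        if small.any():
            z = d_plus * np.cosh(eta_plus[small]) \
                - d_minus * np.cos(eta_minus[small])
            out[small] = np.arccosh(np.maximum(z, 1.0))
        # arccosh(z) ~ ln(2z); D+ >= 1 here so the log argument is positive
        ep = eta_plus[big]
        out[big] = ep + np.log(
            d_plus - 2.0 * d_minus * np.cos(eta_minus[big]) * np.exp(-ep)
        )
    return 0.5 * (ra + rb + kex) - nu_cp * out


def luz_meiboom_r2eff(phi_ex: float, kex: float, r2_0: float, nu_cp) -> np.ndarray:
    """Fast-exchange (Luz-Meiboom) CPMG closed form:
    R2eff = R2(0) + (phi_ex/kex)[1 - (4 nu_cp/kex) tanh(kex/(4 nu_cp))],
    phi_ex = pa pb dw^2 in rad^2/s^2."""
    nu_cp = np.asarray(nu_cp, dtype=float)
    x = kex / (4.0 * nu_cp)
    return r2_0 + (phi_ex / kex) * (1.0 - np.tanh(x) / x)


def fast_exchange_r1rho(phi_ex: float, kex: float, r2_0: float,
                        omega_sl, omega_off) -> np.ndarray:
    """Two-site fast-exchange spin-lock dispersion:

    R2eff = R2(0) + phi_ex kex / (w_SL^2 + w_off^2 + kex^2)

    phi_ex = pa pb dw^2 in rad^2/s^2; ``omega_sl``/``omega_off`` are given in
    Hz and converted to angular units internally (the denominator mixes them
    with kex^2 additively, so all three must share angular units).
    """
    if kex <= 0:
        raise ValueError("kex must be positive")
    wsl = 2.0 * math.pi * np.asarray(omega_sl, dtype=float)
    woff = 2.0 * math.pi * np.asarray(omega_off, dtype=float)
    return r2_0 + phi_ex * kex / (wsl**2 + woff**2 + kex**2)


# ---------------------------------------------------------------------------
# CPMG fitting


def _cpmg_start_r20(curves: Sequence[CpmgCurve]) -> dict[float, float]:
    """Plateau guess for the intrinsic rate per field: min R2eff."""
    r20 = {}
    for c in curves:
        f = c.field.proton_mhz
        m = float(np.min(c.points[:, 1]))
        r20[f] = min(r20.get(f, np.inf), m)
    return {f: max(0.1, v) for f, v in r20.items()}


def _weighted_residuals_cpmg(theta: np.ndarray, curves: Sequence[CpmgCurve],
                             model: str, fixed_dw: float | None,
                             fields: list[float]) -> np.ndarray:
    res = []
    if model == "general":
        log_kex, pb = theta[0], theta[1]
        i = 2
        if fixed_dw is None:
            dw_ppm = theta[i]
            i += 1
        else:
            dw_ppm = fixed_dw
        r20 = dict(zip(fields, theta[i:]))
        kex = 10.0**log_kex
        for c in curves:
            dw_rad = c.field.ppm_to_rad_s(dw_ppm, c.nucleus)
            pred = carver_richards_r2eff(1.0 - pb, kex, dw_rad,
                                         r20[c.field.proton_mhz],
                                         r20[c.field.proton_mhz],
                                         c.points[:, 0])
            res.append((pred - c.points[:, 1]) / c.points[:, 2])
    else:  # fast
        log_kex, phi_ppm2 = theta[0], theta[1]
        r20 = dict(zip(fields, theta[2:]))
        kex = 10.0**log_kex
        for c in curves:
            phi = phi_ppm2 * c.field.ppm_to_rad_s(1.0, c.nucleus) ** 2
            pred = luz_meiboom_r2eff(phi, kex, r20[c.field.proton_mhz],
                                     c.points[:, 0])
            res.append((pred - c.points[:, 1]) / c.points[:, 2])
    return np.concatenate(res)


KEX_START_GRID = (1e2, 1e3, 1e4, 1e5)
PB_START_GRID = (0.002, 0.02, 0.2)
DW_START_GRID = (1.0, 3.0)


def _multistart_lsq(fun, starts, lo, hi, args=(), n_polish: int = 2,
                    max_nfev: int = 400):
    """Two-stage multi-start least squares: cheap exploration from every
    start, full-precision polish of the best few basins."""
    coarse = []
    for x0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sol = least_squares(fun, np.clip(x0, lo, hi),
                                    bounds=(lo, hi), args=args,
                                    ftol=1e-4, xtol=1e-4, max_nfev=15,
                                    x_scale="jac")
            coarse.append(sol)
        except Exception:
            continue
    if not coarse:
        return None
    coarse.sort(key=lambda s: s.cost)
    best = None
    for s in coarse[:n_polish]:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sol = least_squares(fun, s.x, bounds=(lo, hi), args=args,
                                    ftol=1e-10, xtol=1e-10,
                                    max_nfev=max_nfev, x_scale="jac")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def fit_cpmg(curves: Sequence[CpmgCurve], model: str = "general",
             fixed_dw: float | None = None) -> FitResult:
    """Fit one residue's CPMG dispersion (1-2 fields) by multi-start
    weighted least squares.

    ``model`` is ``"general"`` (Carver-Richards: kex, pb, dw, per-field
    R2(0) with Ra = Rb within a field) or ``"fast"`` (Luz-Meiboom: kex,
    phi_ex in ppm^2, per-field R2(0)).  ``fixed_dw`` clamps dw (ppm) in the
    general model, e.g. to an independently known shift difference.
    Non-convergence from every start yields a flagged result, not an
    exception.
    """
    curves = list(curves)
    n_points = sum(c.points.shape[0] for c in curves)
    if n_points < 6:
        raise ValueError("need >= 6 dispersion points")
    fields = sorted({c.field.proton_mhz for c in curves})
    r20_init = _cpmg_start_r20(curves)
    r20_0 = [r20_init[f] for f in fields]

    starts: list[np.ndarray] = []
    if model == "general":
        for kex in KEX_START_GRID:
            for pb in PB_START_GRID:
                if fixed_dw is None:
                    for dw in DW_START_GRID:
                        starts.append(np.array([math.log10(kex), pb, dw, *r20_0]))
                else:
                    starts.append(np.array([math.log10(kex), pb, *r20_0]))
        lo = [2.0, 1e-6] + ([0.0] if fixed_dw is None else []) + [0.0] * len(fields)
        hi = [5.0, 0.5] + ([20.0] if fixed_dw is None else []) + [200.0] * len(fields)
        n_params = 2 + (0 if fixed_dw is not None else 1) + len(fields)
    elif model == "fast":
        amp = max(0.1, max(float(np.ptp(c.points[:, 1])) for c in curves))
        for kex in KEX_START_GRID:
            for phi in (0.1 * amp, amp):
                starts.append(np.array([math.log10(kex), phi, *r20_0]))
        lo = [2.0, 0.0] + [0.0] * len(fields)
        hi = [5.0, 1e3] + [200.0] * len(fields)
        n_params = 2 + len(fields)
    else:
        raise ValueError(f"unknown model {model!r}")

    best = _multistart_lsq(_weighted_residuals_cpmg, starts, lo, hi,
                           args=(curves, model, fixed_dw, fields))
    if best is None:
        return FitResult(model=model, params={}, chi2=math.nan,
                         n_points=n_points, n_params=n_params,
                         flags=["non-convergent"])
    theta = best.x
    params: dict[str, float] = {"kex": 10.0 ** theta[0]}
    if model == "general":
        params["pb"] = theta[1]
        i = 2
        if fixed_dw is None:
            params["dw_ppm"] = theta[2]
            i = 3
        else:
            params["dw_ppm"] = fixed_dw
        for f, v in zip(fields, theta[i:]):
            params[f"r20_{f:g}"] = v
    else:
        params["phi_ppm2"] = theta[1]
        for f, v in zip(fields, theta[2:]):
            params[f"r20_{f:g}"] = v
    chi2 = 2.0 * best.cost
    rid = curves[0].residue_id
    return FitResult(model=model, params=params, chi2=chi2,
                     n_points=n_points, n_params=n_params,
                     per_residue_chi2={rid: chi2}, chi2_ratio={rid: 1.0})


def _global_cpmg_residuals(theta: np.ndarray, order: list[int],
                           residue_curves: dict[int, list[CpmgCurve]],
                           share_pb: bool, fixed_dw: dict[int, float],
                           fields_of: dict[int, list[float]]) -> np.ndarray:
    kex = 10.0 ** theta[0]
    i = 1
    pb_shared = None
    if share_pb:
        pb_shared = theta[1]
        i = 2
    res = []
    for rid in order:
        pb = pb_shared if share_pb else theta[i]
        if not share_pb:
            i += 1
        if rid in fixed_dw:
            dw_ppm = fixed_dw[rid]
        else:
            dw_ppm = theta[i]
            i += 1
        for c in residue_curves[rid]:
            r20 = theta[i]
            i += 1
            dw_rad = c.field.ppm_to_rad_s(dw_ppm, c.nucleus)
            pred = carver_richards_r2eff(1.0 - pb, kex, dw_rad, r20, r20,
                                         c.points[:, 0])
            res.append((pred - c.points[:, 1]) / c.points[:, 2])
    return np.concatenate(res)


def fit_cpmg_global(residue_curves: dict[int, Sequence[CpmgCurve]],
                    shared: Sequence[str] = ("kex", "pb"),
                    fixed_dw: dict[int, float] | None = None,
                    chi2_ratio_cutoff: float = CHI2_RATIO_CUTOFF,
                    _rerun: bool = True) -> FitResult:
    """Global CPMG fit: shared kinetics (kex, optionally pb) across
    residues, per-residue dw (unless fixed), per-residue-per-field R2(0).

    Reports chi2_g/chi2_i per residue (global vs individual fit); residues
    whose ratio exceeds ``chi2_ratio_cutoff`` are flagged, excluded, and the
    fit is rerun on the remainder.
    """
    if "kex" not in shared:
        raise ValueError("kex must be shared in a global fit")
    share_pb = "pb" in shared
    fixed_dw = dict(fixed_dw or {})
    residue_curves = {rid: list(cs) for rid, cs in residue_curves.items()}
    if len(residue_curves) < 2:
        if len(residue_curves) == 1:
            (only,) = residue_curves.values()
            return fit_cpmg(only, model="general",
                            fixed_dw=fixed_dw.get(only[0].residue_id))
        raise ValueError("global fit needs >= 2 residues")

    order = sorted(residue_curves)
    indiv = {rid: fit_cpmg(residue_curves[rid], "general", fixed_dw.get(rid))
             for rid in order}
    ok = [rid for rid in order if "non-convergent" not in indiv[rid].flags]
    if len(ok) < 2:
        raise ValueError("fewer than 2 convergent residues")
    order = ok

    fields_of = {rid: [c.field.proton_mhz for c in residue_curves[rid]]
                 for rid in order}

    def pack(kex: float, pb: float, dw: dict[int, float],
             r20: dict[int, list[float]]) -> np.ndarray:
        v = [math.log10(kex)]
        if share_pb:
            v.append(pb)
        for rid in order:
            if not share_pb:
                v.append(pb)
            if rid not in fixed_dw:
                v.append(dw[rid])
            v.extend(r20[rid])
        return np.array(v)

    dw_indiv = {rid: indiv[rid].params.get("dw_ppm", 2.0) for rid in order}
    r20_indiv = {
        rid: [indiv[rid].params.get(f"r20_{c.field.proton_mhz:g}",
                                    float(np.min(c.points[:, 1])))
              for c in residue_curves[rid]]
        for rid in order
    }
    kex_med = float(np.median([indiv[rid].params["kex"] for rid in order]))
    pb_med = float(np.median([indiv[rid].params["pb"] for rid in order]))
    starts = [pack(kex_med, pb_med, dw_indiv, r20_indiv)]
    for kex in (3e2, 1e3, 3e3, 1e4, 3e4):
        for pb in (0.002, 0.02, 0.2):
            starts.append(pack(kex, pb, dw_indiv, r20_indiv))

    n_theta = starts[0].size
    lo = np.zeros(n_theta)
    hi = np.zeros(n_theta)
    lo[0], hi[0] = 2.0, 5.0
    mask_pb = np.zeros(n_theta, bool)
    i = 1
    if share_pb:
        mask_pb[1] = True
        i = 2
    for rid in order:
        if not share_pb:
            mask_pb[i] = True
            i += 1
        if rid not in fixed_dw:
            lo[i], hi[i] = 0.0, 20.0
            i += 1
        for _ in residue_curves[rid]:
            lo[i], hi[i] = 0.0, 200.0
            i += 1
    lo[mask_pb], hi[mask_pb] = 1e-6, 0.5

    best = _multistart_lsq(
        _global_cpmg_residuals, starts, lo, hi,
        args=(order, residue_curves, share_pb, fixed_dw, fields_of),
        max_nfev=800)
    if best is None:
        raise RuntimeError("global CPMG fit failed from every start")

    theta = best.x
    # unpack + per-residue chi2 under the global optimum
    kex = 10.0 ** theta[0]
    i = 1
    pb_shared = theta[1] if share_pb else None
    if share_pb:
        i = 2
    params: dict[str, float] = {"kex": kex}
    if share_pb:
        params["pb"] = float(pb_shared)
    per_res_chi2: dict[int, float] = {}
    n_params = 0
    for rid in order:
        pb = pb_shared if share_pb else theta[i]
        if not share_pb:
            params[f"pb_{rid}"] = float(pb)
            i += 1
        if rid in fixed_dw:
            dw_ppm = fixed_dw[rid]
        else:
            dw_ppm = theta[i]
            i += 1
        params[f"dw_ppm_{rid}"] = float(dw_ppm)
        chi2_r = 0.0
        for c in residue_curves[rid]:
            r20 = theta[i]
            i += 1
            params[f"r20_{rid}_{c.field.proton_mhz:g}"] = float(r20)
            dw_rad = c.field.ppm_to_rad_s(dw_ppm, c.nucleus)
            pred = carver_richards_r2eff(1.0 - pb, kex, dw_rad, r20, r20,
                                         c.points[:, 0])
            chi2_r += float(np.sum(((pred - c.points[:, 1]) / c.points[:, 2]) ** 2))
        per_res_chi2[rid] = chi2_r
    n_params = theta.size
    n_points = sum(c.points.shape[0] for rid in order
                   for c in residue_curves[rid])

    ratios = {}
    for rid in order:
        ci = indiv[rid].chi2
        ratios[rid] = per_res_chi2[rid] / ci if ci > 0 else math.inf

    flagged = [rid for rid in order if ratios[rid] > chi2_ratio_cutoff]
    result = FitResult(model="general-global", params=params,
                       chi2=2.0 * best.cost, n_points=n_points,
                       n_params=n_params, per_residue_chi2=per_res_chi2,
                       chi2_ratio=ratios,
                       flags=[f"excluded:{rid}" for rid in flagged])
    if flagged and _rerun and len(order) - len(flagged) >= 2:
        keep = {rid: residue_curves[rid] for rid in order if rid not in flagged}
        rerun = fit_cpmg_global(keep, shared, fixed_dw, chi2_ratio_cutoff,
                                _rerun=False)
        rerun.flags = result.flags + rerun.flags
        rerun.excluded = flagged
        rerun.chi2_ratio.update({rid: ratios[rid] for rid in flagged})
        return rerun
    return result


# ---------------------------------------------------------------------------
# R1rho fitting


def _r1rho_residuals(theta: np.ndarray, curves: Sequence[R1rhoCurve],
                     global_kex: bool) -> np.ndarray:
    res = []
    i = 1 if global_kex else 0
    for ci, c in enumerate(curves):
        kex = 10.0 ** (theta[0] if global_kex else theta[i])
        if not global_kex:
            i += 1
        phi = theta[i]
        i += 1
        if c.r2_0_mode == "fitted":
            r2_0 = theta[i]
            i += 1
        else:
            r2_0 = c.r2_0
        pred = fast_exchange_r1rho(phi, kex, r2_0, c.points[:, 0], c.points[:, 1])
        res.append((pred - c.points[:, 2]) / c.points[:, 3])
    return np.concatenate(res)


def fit_r1rho(curves: Sequence[R1rhoCurve], global_kex: bool = True
              ) -> FitResult:
    """Fit spin-lock dispersion curves to the fast-exchange model.

    Per-curve phi_ex (rad^2/s^2, >= 0); 15N curves use R2(0) fixed to
    kappa*eta_xy (``r2_0`` attribute), 13C curves fit R2(0).  With
    ``global_kex`` a single exchange rate is shared across all curves (mixed
    15N/13C allowed: the nucleus enters only through unit conversions done
    upstream).  chi2_g/chi2_i is reported per site when global.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves")
    for c in curves:
        if c.r2_0_mode != "fitted" and c.r2_0 is None:
            raise ValueError(f"curve {c.residue_id}: fixed r2_0 not supplied")

    amp = {id(c): max(1e-3, float(np.ptp(c.points[:, 2]))) for c in curves}

    def build_bounds_and_start(kex0: float) -> tuple[np.ndarray, list, list]:
        x0, lo, hi = [], [], []
        if global_kex:
            x0.append(math.log10(kex0)); lo.append(1.5); hi.append(6.0)
        for c in curves:
            if not global_kex:
                x0.append(math.log10(kex0)); lo.append(1.5); hi.append(6.0)
            w2 = (2 * math.pi) ** 2 * float(
                np.min(c.points[:, 0] ** 2 + c.points[:, 1] ** 2))
            phi0 = amp[id(c)] * (w2 + kex0**2) / kex0
            x0.append(phi0); lo.append(0.0); hi.append(1e12)
            if c.r2_0_mode == "fitted":
                x0.append(float(np.min(c.points[:, 2]))); lo.append(0.0)
                hi.append(500.0)
        return np.array(x0), lo, hi

    best = None
    for kex0 in np.logspace(2.5, 4.5, 5):
        x0, lo, hi = build_bounds_and_start(kex0)
        sol = _multistart_lsq(_r1rho_residuals, [x0], lo, hi,
                              args=(curves, global_kex), n_polish=1,
                              max_nfev=500)
        if sol is not None and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("R1rho fit failed from every start")

    theta = best.x
    params: dict[str, float] = {}
    per_res_chi2: dict[int, float] = {}
    i = 1 if global_kex else 0
    if global_kex:
        params["kex"] = 10.0 ** theta[0]
    flags = []
    for c in curves:
        rid = c.residue_id
        if not global_kex:
            params[f"kex_{rid}"] = 10.0 ** theta[i]
            i += 1
        phi = theta[i]
        i += 1
        params[f"phi_ex_{rid}"] = float(phi)
        if c.r2_0_mode == "fitted":
            params[f"r2_0_{rid}"] = float(theta[i])
            r2_0 = float(theta[i])
            i += 1
        else:
            r2_0 = c.r2_0
        kex = params.get("kex", params.get(f"kex_{rid}"))
        pred = fast_exchange_r1rho(phi, kex, r2_0, c.points[:, 0], c.points[:, 1])
        per_res_chi2[rid] = float(
            np.sum(((pred - c.points[:, 2]) / c.points[:, 3]) ** 2))

    n_points = sum(c.points.shape[0] for c in curves)
    result = FitResult(model="r1rho-fast" + ("-global" if global_kex else ""),
                       params=params, chi2=2.0 * best.cost,
                       n_points=n_points, n_params=theta.size,
                       per_residue_chi2=per_res_chi2, flags=flags)
    if global_kex and len(curves) > 1:
        for c in curves:
            sub = fit_r1rho([c], global_kex=False)
            ci = sub.chi2
            result.chi2_ratio[c.residue_id] = (
                per_res_chi2[c.residue_id] / ci if ci > 0 else math.inf)
    # flat data leave kex unconstrained: flag when the fitted dispersion
    # amplitude over each curve's sampled effective-field range is within
    # the noise for every curve
    flat = []
    for c in curves:
        kex = params.get("kex", params.get(f"kex_{c.residue_id}"))
        phi = params[f"phi_ex_{c.residue_id}"]
        w2 = (2 * math.pi) ** 2 * (c.points[:, 0] ** 2 + c.points[:, 1] ** 2)
        amp = phi * kex * (1.0 / (w2.min() + kex**2)
                           - 1.0 / (w2.max() + kex**2))
        flat.append(amp < 2.0 * float(np.median(c.points[:, 3])))
    if all(flat):
        result.flags.append("kex-unidentifiable:flat-dispersion")
    return result


# ---------------------------------------------------------------------------
# model comparison and Monte-Carlo errors


def aic_compare(fits: Sequence[FitResult], aicc: bool = False
                ) -> list[tuple[FitResult, float]]:
    """Rank fits of the *same data* by AIC (chi^2 + 2 n_params, errors
    treated as known).  With ``aicc`` the small-sample correction
    2p(p+1)/(n-p-1) is added.  Returns (fit, delta) sorted best-first."""
    fits = list(fits)
    if len({f.n_points for f in fits}) != 1:
        raise ValueError("fits compare different data (n_points differ)")

    def score(f: FitResult) -> float:
        s = f.aic
        if aicc:
            denom = f.n_points - f.n_params - 1
            if denom <= 0:
                return math.inf
            s += 2.0 * f.n_params * (f.n_params + 1) / denom
        return s

    ranked = sorted(fits, key=score)
    best = score(ranked[0])
    return [(f, score(f) - best) for f in ranked]


def _perturb_curves(curves, rng: np.random.Generator, value_col: int,
                    sigma_col: int):
    out = []
    for c in curves:
        pts = c.points.copy()
        pts[:, value_col] = pts[:, value_col] + rng.normal(
            0.0, pts[:, sigma_col])
        out.append(replace(c, points=pts))
    return out


def mc_parameter_errors(fit_fn: Callable[[list], FitResult], curves,
                        n_draws: int = 100, seed: int = 0,
                        value_col: int | None = None) -> dict[str, float]:
    """Monte-Carlo parameter uncertainties: refit ``n_draws`` datasets with
    each point perturbed by its Gaussian error; returns per-parameter sample
    standard deviations (key ``"_flagged"`` set to 1.0 when more than 20% of
    draws fail to converge).  Seeded and reproducible."""
    curves = list(curves)
    if value_col is None:
        value_col = 2 if isinstance(curves[0], R1rhoCurve) else 1
    sigma_col = value_col + 1
    rng = np.random.default_rng(seed)
    samples: dict[str, list[float]] = {}
    failures = 0
    for _ in range(n_draws):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                f = fit_fn(_perturb_curves(curves, rng, value_col, sigma_col))
        except Exception:
            failures += 1
            continue
        if not f.params or "non-convergent" in f.flags:
            failures += 1
            continue
        for k, v in f.params.items():
            samples.setdefault(k, []).append(v)
    errors = {k: float(np.std(v, ddof=1)) if len(v) > 1 else math.nan
              for k, v in samples.items()}
    if failures > 0.2 * n_draws:
        errors["_flagged"] = 1.0
    return errors
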