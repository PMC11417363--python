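"""Rotational diffusion estimation and model-free analysis.

The overall tumbling (isotropic tau_c or an axially symmetric tensor) is
estimated from R2/R1 ratios of residues without significant internal motion
or exchange; individual residues are then fitted with the Lipari-Szabo
model-free ladder (models 1-5) against their (R1, R2, NOE) data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.stats import chi2 as chi2_dist

from .rates import RateRecord
from .spinphys import (FieldContext, SpinSystem, j_axial, j_modelfree,
                       j_extended, rates_from_j)

#: water-viscosity ratio eta(313 K)/eta(293 K) used to rescale tau_c
VISCOSITY_RATIO_313_293 = 0.653 / 1.002

#: NOE below this marks significant fast internal motion (excluded from
#: tumbling estimation)
NOE_CUTOFF = 0.65

#: model ladder: model id -> (parameter names, count)
MODEL_PARAMS = {
    1: ("s2",),
    2: ("s2", "tau_i"),
    3: ("s2", "rex"),
    4: ("s2", "tau_i", "rex"),
    5: ("sf2", "ss2", "tau_s"),
}


@dataclass
class DiffusionTensor:
    """Overall rotational diffusion: isotropic or axially symmetric.

    ``tau_c`` is the isotropic-equivalent correlation time 1/(6 D_iso) in
    seconds; ``d_ratio`` = D_par/D_perp (1 for isotropic); ``axis`` the
    symmetry-axis unit vector in the molecular frame (upper hemisphere).
    """

    model: str = "isotropic"
    tau_c: float = 10e-9
    tau_c_err: float = 0.0
    d_ratio: float = 1.0
    d_ratio_err: float = 0.0
    axis: np.ndarray | None = None
    chi2: float = math.nan
    n_residues: int = 0

    def __post_init__(self) -> None:
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")
        if self.d_ratio <= 0:
            raise ValueError("d_ratio must be positive")
        if self.model == "isotropic" and self.d_ratio != 1.0:
            raise ValueError("isotropic tensor requires d_ratio = 1")
        if self.axis is not None:
            self.axis = np.asarray(self.axis, dtype=float)
            self.axis = self.axis / np.linalg.norm(self.axis)
            if self.axis[2] < 0:
                self.axis = -self.axis


@dataclass
class ModelFreeResult:
    """Per-residue model-free fit: selected model and its parameters."""

    residue_id: int
    model_id: int
    params: dict[str, float]
    param_errors: dict[str, float] = dc_field(default_factory=dict)
    chi2: float = math.nan
    selected: bool = False
    all_chi2: dict[int, float] = dc_field(default_factory=dict)

    @property
    def s2(self) -> float:
        if self.model_id == 5:
            return self.params["sf2"] * self.params["ss2"]
        return self.params["s2"]

    @property
    def rex(self) -> float:
        return self.params.get("rex", 0.0)


def rigid_r2_over_r1(tau_c: float, spin: SpinSystem, field: FieldContext
                     ) -> float:
    """R2/R1 of a rigid isotropic rotor (S^2 = 1, no internal motion)."""
    r1, r2, _ = rates_from_j(spin, field,
                             lambda w: j_modelfree(w, 1.0, tau_c, 0.0))
    return r2 / r1


def tc_from_r2_r1(ratio: float, spin: SpinSystem, field: FieldContext,
                  bracket: tuple[float, float] = (0.3e-9, 60e-9)) -> float:
    """Invert the rigid-rotor R2/R1 ratio to a correlation time by
    root-finding (the ratio is monotone increasing in tau_c)."""
    f = lambda tc: rigid_r2_over_r1(tc, spin, field) - ratio
    lo, hi = bracket
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"R2/R1 = {ratio:.3g} outside invertible range")
    return brentq(f, lo, hi, xtol=1e-15)


def _tumbling_subset(records: list[RateRecord], noe_cutoff: float,
                     trim_sd: float) -> list[RateRecord]:
    """Residues suitable for tumbling estimation: NOE >= cutoff and R2/R1
    within ``trim_sd`` standard deviations of the 10%-trimmed mean."""
    cand = [r for r in records
            if math.isfinite(r.noe) and r.noe >= noe_cutoff and r.r1 > 0]
    if len(cand) < 3:
        return cand
    ratios = np.array([r.r2 / r.r1 for r in cand])
    k = max(1, int(0.1 * ratios.size))
    srt = np.sort(ratios)
    trimmed = srt[k:-k] if ratios.size > 2 * k else srt
    mu, sd = trimmed.mean(), ratios.std(ddof=1)
    return [r for r, q in zip(cand, ratios) if abs(q - mu) <= trim_sd * sd]


def estimate_tc_isotropic(records: list[RateRecord],
                          spin: SpinSystem | None = None,
                          noe_cutoff: float = NOE_CUTOFF,
                          trim_sd: float = 1.5) -> tuple[float, float]:
    """Isotropic tumbling time from R2/R1 ratios.

    Residues with low NOE (fast internal motion) or outlying R2/R1
    (exchange) are excluded, each remaining residue's ratio is inverted by
    root-finding on the rigid-rotor forward model, and the trimmed-mean
    tau_c +- SEM (seconds) is returned.
    """
    spin = spin or SpinSystem()
    keep = _tumbling_subset(records, noe_cutoff, trim_sd)
    if len(keep) < 1:
        raise ValueError("no qualifying residues for tau_c estimation")
    tcs = []
    for r in keep:
        try:
            tcs.append(tc_from_r2_r1(r.r2 / r.r1, spin, r.field))
        except ValueError:
            continue
    if not tcs:
        raise ValueError("no residue R2/R1 ratio was invertible")
    tcs = np.asarray(tcs)
    sem = float(tcs.std(ddof=1) / math.sqrt(tcs.size)) if tcs.size > 1 else 0.0
    return float(tcs.mean()), sem


def _axial_ratio(tau_c: float, d_ratio: float, angle_deg: float,
                 spin: SpinSystem, field: FieldContext) -> float:
    j = lambda w: j_axial(w, 1.0, 0.0, tau_c, d_ratio, angle_deg)
    r1, r2, _ = rates_from_j(spin, field, j)
    return r2 / r1


def _angles_to_axis(theta: float, phi: float) -> np.ndarray:
    return np.array([math.sin(theta) * math.cos(phi),
                     math.sin(theta) * math.sin(phi),
                     math.cos(theta)])


def fit_axial_tensor(records: list[RateRecord],
                     nh_vectors: dict[int, np.ndarray],
                     spin: SpinSystem | None = None,
                     noe_cutoff: float = NOE_CUTOFF,
                     trim_sd: float = 1.5,
                     ratio_sigma_frac: float = 0.02) -> DiffusionTensor:
    """Fit an axially symmetric diffusion tensor to per-residue R2/R1.

    Free parameters: tau_c, D_par/D_perp and the symmetry-axis polar angles;
    the per-residue angle enters through the supplied N-H unit vectors.
    The axial model is accepted over isotropic by AIC; with fewer than 8
    usable residues (or a degenerate vector spread) the isotropic estimate
    is returned with a warning flag.
    """
    spin = spin or SpinSystem()
    keep = [r for r in _tumbling_subset(records, noe_cutoff, trim_sd)
            if r.residue_id in nh_vectors]
    tc_iso, tc_iso_err = estimate_tc_isotropic(records, spin, noe_cutoff,
                                               trim_sd)
    vecs = np.array([nh_vectors[r.residue_id] /
                     np.linalg.norm(nh_vectors[r.residue_id]) for r in keep])
    degenerate = len(keep) >= 8 and np.linalg.matrix_rank(
        np.cov(vecs.T), tol=1e-3) < 3
    if len(keep) < 8 or degenerate:
        warnings.warn("too few residues or degenerate N-H vector spread; "
                      "falling back to isotropic tumbling", stacklevel=2)
        return DiffusionTensor(model="isotropic", tau_c=tc_iso,
                               tau_c_err=tc_iso_err, n_residues=len(keep))

    ratios = np.array([r.r2 / r.r1 for r in keep])
    sig = np.array([
        (r.r2 / r.r1) * math.hypot(
            r.r2_err / r.r2 if r.r2_err > 0 else ratio_sigma_frac,
            r.r1_err / r.r1 if r.r1_err > 0 else ratio_sigma_frac)
        for r in keep
    ])
    sig[sig <= 0] = ratio_sigma_frac * ratios[sig <= 0]

    def residuals(theta):
        tc, ratio, th, ph = theta
        axis = _angles_to_axis(th, ph)
        cosang = np.clip(vecs @ axis, -1.0, 1.0)
        pred = np.array([
            _axial_ratio(tc, ratio, math.degrees(math.acos(c)), spin, r.field)
            for c, r in zip(cosang, keep)
        ])
        return (pred - ratios) / sig

    best = None
    for ratio0 in (0.8, 1.0, 1.3):
        for th0, ph0 in ((0.6, 0.5), (1.2, 2.5), (2.0, 4.5)):
            x0 = np.array([tc_iso, ratio0, th0, ph0])
            try:
                sol = least_squares(
                    residuals, x0,
                    bounds=([1e-10, 0.3, 0.0, -math.pi],
                            [60e-9, 3.0, math.pi, 2 * math.pi]),
                    xtol=1e-12, ftol=1e-12, max_nfev=300)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError("axial tensor fit failed from every start")

    tc, ratio, th, ph = best.x
    chi2_ax = 2.0 * best.cost
    # isotropic comparison on the same residuals
    pred_iso = np.array([rigid_r2_over_r1(tc_iso, spin, r.field) for r in keep])
    chi2_iso = float(np.sum(((pred_iso - ratios) / sig) ** 2))
    aic_ax = chi2_ax + 2 * 4
    aic_iso = chi2_iso + 2 * 1
    if aic_iso <= aic_ax:
        return DiffusionTensor(model="isotropic", tau_c=tc_iso,
                               tau_c_err=tc_iso_err, chi2=chi2_iso,
                               n_residues=len(keep))
    return DiffusionTensor(model="axial", tau_c=float(tc), d_ratio=float(ratio),
                           axis=_angles_to_axis(th, ph), chi2=chi2_ax,
                           n_residues=len(keep))


# ---------------------------------------------------------------------------
# per-residue model-free fitting


def _j_factory(model_id: int, theta: np.ndarray, tensor: DiffusionTensor,
               nh_angle_deg: float | None):
    tc = tensor.tau_c
    axial = tensor.model == "axial" and nh_angle_deg is not None

    if model_id == 5:
        sf2, ss2, tau_s = theta
        return lambda w: j_extended(w, sf2, ss2, tc, tau_s)
    s2 = theta[0]
    tau_i = theta[1] if model_id in (2, 4) else 0.0
    if axial:
        return lambda w: j_axial(w, s2, tau_i, tc, tensor.d_ratio, nh_angle_deg)
    return lambda w: j_modelfree(w, s2, tc, tau_i)


def _model_rex(model_id: int, theta: np.ndarray) -> float:
    if model_id == 3:
        return theta[1]
    if model_id == 4:
        return theta[2]
    return 0.0


def _fit_one_model(model_id: int, record: RateRecord, tensor: DiffusionTensor,
                   spin: SpinSystem, nh_angle_deg: float | None
                   ) -> tuple[np.ndarray, float]:
    obs = np.array([record.r1, record.r2, record.noe])
    err = np.array([record.r1_err or 0.02 * record.r1,
                    record.r2_err or 0.02 * record.r2,
                    record.noe_err or 0.02])
    tc = tensor.tau_c

    def residuals(theta):
        j = _j_factory(model_id, theta, tensor, nh_angle_deg)
        r1, r2, noe = rates_from_j(spin, record.field, j,
                                   rex=_model_rex(model_id, theta))
        return (np.array([r1, r2, noe]) - obs) / err

    # bounds and starts per model; internal times bounded below tau_c
    if model_id == 1:
        lo, hi = [0.0], [1.0]
        starts = [[0.85], [0.4]]
    elif model_id == 2:
        lo, hi = [0.0, 0.0], [1.0, 0.95 * tc]
        starts = [[0.85, 20e-12], [0.6, 0.5e-9], [0.4, 2e-9]]
    elif model_id == 3:
        lo, hi = [0.0, 0.0], [1.0, 50.0]
        starts = [[0.85, 1.0], [0.85, 8.0]]
    elif model_id == 4:
        lo, hi = [0.0, 0.0, 0.0], [1.0, 0.95 * tc, 50.0]
        starts = [[0.85, 20e-12, 2.0], [0.6, 0.5e-9, 2.0]]
    elif model_id == 5:
        lo, hi = [0.0, 0.0, 1e-12], [1.0, 1.0, 0.95 * tc]
        starts = [[0.85, 0.6, 1e-9], [0.8, 0.4, 2e-9], [0.95, 0.8, 0.3e-9]]
    else:
        raise ValueError(f"unknown model id {model_id}")

    # scale internal times to ns for conditioning
    scale = np.ones(len(lo))
    for k, name in enumerate(MODEL_PARAMS[model_id]):
        if name in ("tau_i", "tau_s"):
            scale[k] = 1e-9

    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                lambda u: residuals(u * scale),
                np.asarray(x0) / scale,
                bounds=(np.asarray(lo) / scale, np.asarray(hi) / scale),
                xtol=1e-12, ftol=1e-12, max_nfev=200)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return np.full(len(lo), np.nan), math.inf
    return best.x * scale, 2.0 * best.cost


def fit_modelfree(record: RateRecord, tensor: DiffusionTensor,
                  nh_vector: np.ndarray | None = None,
                  spin: SpinSystem | None = None,
                  alpha: float = 0.05) -> ModelFreeResult:
    """Model-free fit of one residue's (R1, R2, NOE) with model selection.

    Models, in increasing complexity: 1 (S2), 2 (S2, tau_i), 3 (S2, Rex),
    4 (S2, tau_i, Rex), 5 (Sf2, Ss2, tau_s; extended form).  The ladder
    accepts the simplest model whose chi^2 passes the alpha-level critical
    value for its degrees of freedom (ties broken by AIC); models 4/5 have
    zero degrees of freedom at a single field and are compared by AIC when
    all simpler models are rejected.  If no model is acceptable the
    best-chi^2 result is returned unselected.
    """
    spin = spin or SpinSystem()
    nh_angle = None
    if tensor.model == "axial" and nh_vector is not None and tensor.axis is not None:
        v = np.asarray(nh_vector, float)
        v = v / np.linalg.norm(v)
        nh_angle = math.degrees(math.acos(abs(float(np.clip(v @ tensor.axis,
                                                            -1, 1)))))

    n_data = 3
    fits: dict[int, tuple[np.ndarray, float]] = {}
    all_chi2: dict[int, float] = {}

    def result_for(mid: int, selected: bool) -> ModelFreeResult:
        theta, c2 = fits[mid]
        params = dict(zip(MODEL_PARAMS[mid], map(float, theta)))
        return ModelFreeResult(residue_id=record.residue_id, model_id=mid,
                               params=params, chi2=c2, selected=selected,
                               all_chi2=dict(all_chi2))

    # stage 1: one-parameter model
    for mid in (1,):
        fits[mid] = _fit_one_model(mid, record, tensor, spin, nh_angle)
        all_chi2[mid] = fits[mid][1]
        if fits[mid][1] <= chi2_dist.ppf(1 - alpha, n_data - 1):
            return result_for(mid, True)

    # stage 2: two-parameter models
    passing = []
    for mid in (2, 3):
        fits[mid] = _fit_one_model(mid, record, tensor, spin, nh_angle)
        all_chi2[mid] = fits[mid][1]
        if fits[mid][1] <= chi2_dist.ppf(1 - alpha, n_data - 2):
            passing.append(mid)
    if passing:
        best = min(passing, key=lambda m: fits[m][1] + 2 * len(MODEL_PARAMS[m]))
        return result_for(best, True)

    # stage 3: three-parameter models (zero dof at one field) by AIC
    for mid in (4, 5):
        fits[mid] = _fit_one_model(mid, record, tensor, spin, nh_angle)
        all_chi2[mid] = fits[mid][1]
    best = min((4, 5), key=lambda m: fits[m][1] + 2 * len(MODEL_PARAMS[m]))
    # with zero dof a residual chi^2 comparable to one noise unit still
    # indicates misfit; accept unless clearly above the chi2(1) critical value
    ok = fits[best][1] <= chi2_dist.ppf(1 - alpha, 1)
    return result_for(best, ok)


def scale_tc_viscosity(tau_c: float,
                       ratio: float = VISCOSITY_RATIO_313_293) -> float:
    """Rescale a correlation time by a solvent viscosity ratio (default:
    water at 313 K vs 293 K, 0.653/1.002 mPa s)."""
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    return tau_c * ratio
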