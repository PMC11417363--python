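"""Ground-truth generators for every observable the pipeline consumes.

A :class:`GroundTruthProfile` describes a pseudo-protein with the dynamic
architecture typical of an RRM domain carrying a binding-coupled
disorder-order transition: a rigid beta-sheet/helix core (S2 ~ 0.85-0.95),
flexible termini with nanosecond internal motions described by the extended
model-free form, and designated exchange residues grouped under shared
two-site exchange parameters (a beta4-strand group and a C-terminal helix
group in the free state; a fast interface group in the bound state).
All randomness is seeded: identical seeds give identical outputs.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import asdict, dataclass, field as dc_field

import numpy as np

from .dispersion import (CpmgCurve, ExchangeParams, R1rhoCurve,
                         carver_richards_r2eff, fast_exchange_r1rho)
from .modelfree import DiffusionTensor
from .rates import RCZZ_ECHO_PERIOD, RateRecord, IntensitySeries
from .spinphys import (FieldContext, SpinSystem, eta_xy, j_axial, j_extended,
                       j_modelfree, kappa, rates_from_j)

#: default CPMG grids (Hz), chosen so the pulse count in the constant time
#: (80 ms at 750 MHz, 64 ms at 900 MHz) is a whole number
CPMG_GRID_750 = (25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 250.0, 300.0,
                 400.0, 500.0, 625.0, 750.0)
CPMG_GRID_900 = (31.25, 62.5, 125.0, 187.5, 250.0, 312.5, 375.0, 500.0,
                 625.0, 750.0)
CPMG_T_RELAX = {750.0: 0.080, 900.0: 0.064}

ETA_XY_DELAYS = (0.016, 0.032, 0.040)
R1_DELAYS = (0.08, 0.20, 0.36, 0.52, 0.70, 0.90, 1.05, 1.20)


@dataclass
class ResidueTruth:
    """Ground-truth dynamics of one pseudo-residue."""

    residue_id: int
    region: str
    motion: str  # "simple" (S2, tau_i) or "extended" (Sf2, Ss2, tau_s)
    s2: float = 0.9
    tau_i: float = 0.0
    sf2: float = 1.0
    ss2: float = 1.0
    tau_s: float = 0.0
    rex: float = 0.0
    exch_group: str | None = None
    dw_ppm: float = 0.0
    nh_vector: tuple[float, float, float] = (0.0, 0.0, 1.0)

    @property
    def s2_total(self) -> float:
        return self.sf2 * self.ss2 if self.motion == "extended" else self.s2

    def j_callable(self, tensor: DiffusionTensor):
        """Spectral density of this residue under the profile's tumbling."""
        tc = tensor.tau_c
        if self.motion == "extended":
            return lambda w: j_extended(w, self.sf2, self.ss2, tc, self.tau_s)
        if tensor.model == "axial":
            v = np.asarray(self.nh_vector, float)
            v = v / np.linalg.norm(v)
            ang = math.degrees(math.acos(abs(float(np.clip(v @ tensor.axis,
                                                           -1, 1)))))
            return lambda w: j_axial(w, self.s2, self.tau_i, tc,
                                     tensor.d_ratio, ang)
        return lambda w: j_modelfree(w, self.s2, tc, self.tau_i)


@dataclass
class GroundTruthProfile:
    """A seeded pseudo-protein: per-residue dynamics, exchange groups,
    tumbling tensor and the fields at which data are simulated."""

    preset: str
    seed: int
    residues: list[ResidueTruth]
    exchange_groups: dict[str, ExchangeParams]
    tensor: DiffusionTensor
    rate_field_mhz: float = 700.0
    dispersion_fields_mhz: tuple[float, ...] = (750.0, 900.0)
    temperature: float = 298.0

    def rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, salt])

    def exchange_residues(self, group: str | None = None) -> list[ResidueTruth]:
        return [r for r in self.residues if r.exch_group is not None
                and (group is None or r.exch_group == group)]

    def to_json(self) -> str:
        d = {
            "preset": self.preset, "seed": self.seed,
            "rate_field_mhz": self.rate_field_mhz,
            "dispersion_fields_mhz": list(self.dispersion_fields_mhz),
            "temperature": self.temperature,
            "residues": [asdict(r) for r in self.residues],
            "exchange_groups": {k: {"pa": g.pa, "kex": g.kex,
                                    "dw_ppm": g.dw_ppm, "ra": g.ra,
                                    "rb": g.rb}
                                for k, g in self.exchange_groups.items()},
            "tensor": {"model": self.tensor.model, "tau_c": self.tensor.tau_c,
                       "d_ratio": self.tensor.d_ratio,
                       "axis": None if self.tensor.axis is None
                       else list(map(float, self.tensor.axis))},
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthProfile":
        d = json.loads(text)
        residues = [ResidueTruth(**{**r, "nh_vector": tuple(r["nh_vector"])})
                    for r in d["residues"]]
        groups = {k: ExchangeParams(**g)
                  for k, g in d["exchange_groups"].items()}
        t = d["tensor"]
        tensor = DiffusionTensor(model=t["model"], tau_c=t["tau_c"],
                                 d_ratio=t["d_ratio"], axis=t["axis"])
        return cls(preset=d["preset"], seed=d["seed"], residues=residues,
                   exchange_groups=groups, tensor=tensor,
                   rate_field_mhz=d["rate_field_mhz"],
                   dispersion_fields_mhz=tuple(d["dispersion_fields_mhz"]),
                   temperature=d["temperature"])


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_profile(preset: str = "free_rrm1_like", seed: int = 0,
                 n_residues: int = 120, **overrides) -> GroundTruthProfile:
    """Build a ground-truth profile.

    Presets
    -------
    free_rrm1_like:
        tau_c = 6.5 ns isotropic; rigid core S2 in [0.85, 0.95] with
        tau_i 10-50 ps; flexible termini S2 in [0.3, 0.7] (extended form,
        tau_s 0.5-2 ns); a beta4 exchange group (kex 900 1/s, pb 2%) and a
        C-terminal group (kex 850 1/s, pb 0.3%).
    bound_rrm1_like:
        tau_c = 11.8 ns, axial tensor D_par/D_perp = 1.26; an interface
        exchange group with kex 7000 1/s (fast regime).
    uniform_rigid:
        all residues S2 = 0.9, tau_i = 20 ps, no exchange.

    Keyword overrides replace the preset's exchange-group parameters
    (``beta4=ExchangeParams(...)`` etc.) or the tumbling time (``tau_c``).
    """
    rng = np.random.default_rng([seed, 101])
    vecs = _unit_vectors(rng, n_residues)
    residues: list[ResidueTruth] = []
    groups: dict[str, ExchangeParams] = {}

    def extended(i: int, region: str, group: str | None = None) -> ResidueTruth:
        sf2 = rng.uniform(0.70, 0.90)
        ss2 = rng.uniform(0.45, 0.80)
        return ResidueTruth(
            residue_id=i, region=region, motion="extended", sf2=sf2, ss2=ss2,
            tau_s=rng.uniform(0.5e-9, 2.0e-9), exch_group=group,
            nh_vector=tuple(vecs[i - 1]))

    def core_like(i: int, region: str, lo: float = 0.85, hi: float = 0.95,
                  group: str | None = None) -> ResidueTruth:
        return ResidueTruth(
            residue_id=i, region=region, motion="simple",
            s2=rng.uniform(lo, hi), tau_i=rng.uniform(10e-12, 50e-12),
            exch_group=group, nh_vector=tuple(vecs[i - 1]))

    if preset == "uniform_rigid":
        tensor = DiffusionTensor(model="isotropic",
                                 tau_c=overrides.get("tau_c", 6.5e-9))
        for i in range(1, n_residues + 1):
            residues.append(ResidueTruth(residue_id=i, region="core",
                                         motion="simple", s2=0.9,
                                         tau_i=20e-12,
                                         nh_vector=tuple(vecs[i - 1])))
        return GroundTruthProfile(preset=preset, seed=seed, residues=residues,
                                  exchange_groups={}, tensor=tensor)

    # region layout scaled to n_residues (reference layout at n = 120)
    def span(frac_lo: float, frac_hi: float) -> range:
        return range(1 + round(frac_lo * n_residues),
                     1 + round(frac_hi * n_residues))

    if preset == "free_rrm1_like":
        tensor = DiffusionTensor(model="isotropic",
                                 tau_c=overrides.get("tau_c", 6.5e-9))
        groups["beta4"] = overrides.get(
            "beta4", ExchangeParams(pa=0.98, kex=900.0, dw_ppm=2.0, ra=0.0))
        groups["cterm"] = overrides.get(
            "cterm", ExchangeParams(pa=0.997, kex=850.0, dw_ppm=3.0, ra=0.0))
        for i in span(0.0, 0.10):
            residues.append(extended(i, "N-term"))
        for i in span(0.10, 0.60):
            residues.append(core_like(i, "core"))
        for i in span(0.60, 0.68):
            residues.append(core_like(i, "alpha2", 0.80, 0.92))
        for i in span(0.68, 0.75):
            r = core_like(i, "beta4", group="beta4")
            r.rex = rng.uniform(2.0, 6.0)
            r.dw_ppm = rng.uniform(1.0, 3.0)
            residues.append(r)
        for i in span(0.75, 0.87):
            r = core_like(i, "alpha3", 0.70, 0.88, group="cterm")
            r.rex = rng.uniform(2.0, 6.0)
            r.dw_ppm = rng.uniform(1.5, 3.5)
            residues.append(r)
        for i in span(0.87, 1.0):
            residues.append(extended(i, "C-term"))
    elif preset == "bound_rrm1_like":
        tensor = DiffusionTensor(
            model="axial", tau_c=overrides.get("tau_c", 11.8e-9),
            d_ratio=overrides.get("d_ratio", 1.26), axis=(0.0, 0.0, 1.0))
        groups["interface"] = overrides.get(
            "interface",
            ExchangeParams(pa=0.97, kex=7000.0, dw_ppm=1.0, ra=0.0))
        for i in span(0.0, 0.08):
            residues.append(extended(i, "N-term"))
        for i in span(0.08, 0.62):
            residues.append(core_like(i, "core"))
        for i in span(0.62, 0.78):
            r = core_like(i, "interface", 0.82, 0.93, group="interface")
            r.rex = rng.uniform(1.0, 4.0)
            r.dw_ppm = rng.uniform(0.5, 1.5)
            residues.append(r)
        for i in span(0.78, 0.90):
            residues.append(core_like(i, "alpha3", 0.80, 0.92))
        for i in span(0.90, 1.0):
            residues.append(extended(i, "C-term"))
    else:
        raise ValueError(f"unknown preset {preset!r}")

    return GroundTruthProfile(preset=preset, seed=seed, residues=residues,
                              exchange_groups=groups, tensor=tensor)


# ---------------------------------------------------------------------------
# forward simulation


def simulate_rates(profile: GroundTruthProfile, noise_rate: float = 0.02,
                   noise_noe: float = 0.02,
                   field_mhz: float | None = None,
                   spin: SpinSystem | None = None) -> list[RateRecord]:
    """Closed-form (R1, R2, NOE) for every residue plus seeded Gaussian
    noise (fractional on rates, additive on NOE).  Exchange residues have
    their ground-truth Rex added to R2."""
    spin = spin or SpinSystem()
    field = FieldContext(field_mhz or profile.rate_field_mhz,
                         profile.temperature)
    rng = profile.rng(1)
    out = []
    for res in profile.residues:
        r1, r2, noe = rates_from_j(spin, field, res.j_callable(profile.tensor),
                                   rex=res.rex)
        r1n = r1 * (1.0 + noise_rate * rng.standard_normal())
        r2n = r2 * (1.0 + noise_rate * rng.standard_normal())
        noen = noe + noise_noe * rng.standard_normal()
        out.append(RateRecord(residue_id=res.residue_id, field=field,
                              r1=r1n, r1_err=noise_rate * r1,
                              r2=r2n, r2_err=noise_rate * r2,
                              noe=noen, noe_err=noise_noe))
    return out


def intrinsic_r2(res: ResidueTruth, profile: GroundTruthProfile,
                 field: FieldContext, spin: SpinSystem) -> float:
    """Exchange-free transverse rate of a residue at a field."""
    _, r2, _ = rates_from_j(spin, field, res.j_callable(profile.tensor))
    return r2


def simulate_cpmg_group(exch: ExchangeParams, dw_ppm: dict[int, float],
                        r20: dict[int, dict[float, float]],
                        fields_mhz: tuple[float, ...] = (750.0, 900.0),
                        sigma: float = 0.4, seed: int = 0,
                        grids: dict[float, tuple[float, ...]] | None = None,
                        nucleus: str = "N15",
                        n_offsets: int = 2) -> dict[int, list[CpmgCurve]]:
    """Two-field CPMG curves for residues sharing one exchange process.

    ``dw_ppm`` maps residue -> shift difference; ``r20`` maps residue ->
    {field_mhz: intrinsic rate}.  Gaussian noise of standard deviation
    ``sigma`` (1/s) is added to every R2eff point.  ``n_offsets`` replicates
    of the grid are emitted per field with independent noise, emulating the
    acquisition of each dispersion at several CPMG carrier offsets (two in
    the emulated experiments).
    """
    grids = grids or {750.0: CPMG_GRID_750, 900.0: CPMG_GRID_900}
    rng = np.random.default_rng([seed, 7])
    out: dict[int, list[CpmgCurve]] = {}
    for rid, dw in dw_ppm.items():
        curves = []
        for f in fields_mhz:
            field = FieldContext(f)
            grid = np.tile(np.asarray(grids[f]), n_offsets)
            dw_rad = field.ppm_to_rad_s(dw, nucleus)
            r20_rf = r20[rid][f]
            r2eff = carver_richards_r2eff(exch.pa, exch.kex, dw_rad,
                                          r20_rf, r20_rf, grid)
            noisy = r2eff + sigma * rng.standard_normal(grid.size)
            pts = np.column_stack([grid, noisy, np.full(grid.size, sigma)])
            curves.append(CpmgCurve(residue_id=rid, field=field, points=pts,
                                    t_relax=CPMG_T_RELAX.get(f, 0.08)))
        out[rid] = curves
    return out


def simulate_cpmg(profile: GroundTruthProfile, sigma: float = 0.4,
                  spin: SpinSystem | None = None,
                  emit_intensities: bool = False):
    """CPMG dispersion curves for every exchange residue of the profile.

    Intrinsic rates come from the residue's own exchange-free spectral
    density at each field.  With ``emit_intensities`` the corresponding
    (I_CPMG, I_ref) pairs implied by the constant-time relation are also
    returned, for end-to-end tests through the intensity route.
    """
    spin = spin or SpinSystem()
    curves: dict[int, list[CpmgCurve]] = {}
    intensities: dict[int, list[tuple[float, float, float, float]]] = {}
    for gname, exch in profile.exchange_groups.items():
        members = profile.exchange_residues(gname)
        dw = {r.residue_id: r.dw_ppm for r in members}
        r20 = {r.residue_id:
               {f: intrinsic_r2(r, profile, FieldContext(f), spin)
                for f in profile.dispersion_fields_mhz}
               for r in members}
        got = simulate_cpmg_group(exch, dw, r20,
                                  fields_mhz=profile.dispersion_fields_mhz,
                                  sigma=sigma,
                                  seed=profile.seed * 1009
                                  + zlib.crc32(gname.encode()) % 997)
        curves.update(got)
    if emit_intensities:
        for rid, cs in curves.items():
            rows = []
            for c in cs:
                for nu, r2eff, _ in c.points:
                    i_ref = 100.0
                    rows.append((c.field.proton_mhz, nu,
                                 i_ref * math.exp(-r2eff * c.t_relax), i_ref))
            intensities[rid] = rows
        return curves, intensities
    return curves


def simulate_r1rho(profile: GroundTruthProfile, noise_frac: float = 0.03,
                   spin: SpinSystem | None = None,
                   n13c_sites: int = 0,
                   sl_field_mhz: float = 750.0) -> list[R1rhoCurve]:
    """Spin-lock dispersion curves for the profile's exchange residues.

    15N curves follow the emulated acquisition grid (off-resonance: 1400 Hz spin
    lock, ten offsets spanning tilt angles 90-19.5 deg; on-resonance: 800,
    900, 1100 Hz) with R2(0) pinned to kappa*eta_xy of the residue's own
    spectral density.  Optionally the last ``n13c_sites`` exchange residues
    are emitted as 13C sites (spin-lock 700-6000 Hz on-resonance, fitted
    R2(0)) sharing the same exchange kinetics, mimicking a protein/RNA
    joint dataset.
    """
    spin = spin or SpinSystem()
    spin_c = SpinSystem.carbon_default()
    field = FieldContext(sl_field_mhz, profile.temperature)
    rng = profile.rng(3)
    members = profile.exchange_residues()
    curves: list[R1rhoCurve] = []
    tilt = np.deg2rad(np.linspace(90.0, 19.5, 10))
    sl = 1400.0
    offres = [(sl, sl / math.tan(t) if t < math.pi / 2 else 0.0)
              for t in tilt]
    onres = [(800.0, 0.0), (900.0, 0.0), (1100.0, 0.0)]
    c13_grid = [(w, 0.3 * w) for w in np.geomspace(700.0, 6000.0, 10)]

    for k, res in enumerate(members):
        exch = profile.exchange_groups[res.exch_group]
        is_c13 = k >= len(members) - n13c_sites
        nuc = "C13" if is_c13 else "N15"
        dw_rad = field.ppm_to_rad_s(res.dw_ppm, nuc)
        phi = exch.pa * exch.pb * dw_rad**2
        j = res.j_callable(profile.tensor)
        if is_c13:
            r1 = rates_from_j(spin_c, field, j)[0]
            r2_0 = float(rng.uniform(12.0, 20.0))
            grid = c13_grid
            mode = "fitted"
        else:
            j0, jx = float(j(0.0)), float(j(field.omega_x("N15")))
            r2_0 = kappa(spin, field) * eta_xy(spin, field, j0, jx)
            r1 = rates_from_j(spin, field, j)[0]
            grid = offres + onres
            mode = "fixed_kappa_eta"
        pts = []
        for wsl, woff in grid:
            r2eff = float(fast_exchange_r1rho(phi, exch.kex, r2_0, wsl, woff))
            noise = noise_frac * r2eff
            pts.append((wsl, woff, r2eff + noise * rng.standard_normal(),
                        max(1e-3, noise)))
        curves.append(R1rhoCurve(residue_id=res.residue_id, nucleus=nuc,
                                 field=field, points=np.array(pts), r1=r1,
                                 r2_0_mode=mode,
                                 r2_0=None if is_c13 else r2_0))
    return curves


def simulate_rczz(profile: GroundTruthProfile, ratio_noise: float = 0.0,
                  spin: SpinSystem | None = None,
                  field_mhz: float = 750.0) -> dict:
    """RCZZ / eta_xy observables for every residue of the profile.

    For each residue the cross-correlated rate eta_xy follows from its own
    spectral density; the Hahn-echo rate is built by inverting the
    slow-exchange relation, R2_RCZZ = kappa*eta_xy - R1/2 + Rex, and
    emitted as an (I, I_ref) intensity pair through the exponential echo
    decay; eta_xy is emitted as tanh(eta*T) ratio series; R1 as a
    monoexponential decay series with two replicates.

    Returns a dict with keys ``eta_ratios`` (residue -> [(T, ratio)]),
    ``rczz`` (residue -> (I, I_ref)), ``r1_series`` (residue ->
    IntensitySeries), ``truth`` (residue -> dict) and ``kappa``.
    """
    spin = spin or SpinSystem()
    field = FieldContext(field_mhz, profile.temperature)
    rng = profile.rng(4)
    kap = kappa(spin, field)
    out = {"eta_ratios": {}, "rczz": {}, "r1_series": {}, "truth": {},
           "kappa": kap, "field_mhz": field_mhz}
    for res in profile.residues:
        j = res.j_callable(profile.tensor)
        j0, jx = float(j(0.0)), float(j(field.omega_x(spin.nucleus)))
        eta = eta_xy(spin, field, j0, jx)
        r1 = rates_from_j(spin, field, j)[0]
        r2_rczz = kap * eta - 0.5 * r1 + res.rex
        ratios = [(t, math.tanh(eta * t) * (1.0 + ratio_noise *
                                            rng.standard_normal()))
                  for t in ETA_XY_DELAYS]
        i_ref = 100.0
        i = i_ref * math.exp(-r2_rczz * RCZZ_ECHO_PERIOD) \
            * (1.0 + ratio_noise * rng.standard_normal())
        vals = []
        for t in R1_DELAYS:
            for rep in (0, 1):
                vals.append((t, 100.0 * math.exp(-r1 * t) *
                             (1.0 + ratio_noise * rng.standard_normal()), rep))
        out["eta_ratios"][res.residue_id] = ratios
        out["rczz"][res.residue_id] = (i, i_ref)
        out["r1_series"][res.residue_id] = IntensitySeries(
            residue_id=res.residue_id, atom="N", condition_type="delay",
            values=vals, noise_sigma=None)
        out["truth"][res.residue_id] = {"eta_xy": eta, "r1": r1,
                                        "r2_rczz": r2_rczz, "rex": res.rex}
    return out
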