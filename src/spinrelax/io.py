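"""Readers and writers for the package's table dialects.

All tables are tab-separated with a header line; column order is free.
Units are fixed by the schema: delays in s, CPMG and spin-lock frequencies
in Hz, rates in 1/s, fields as 1H MHz.  PDB coordinate files are read only
to extract N-H bond unit vectors for anisotropic diffusion fitting.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dispersion import CpmgCurve, FitResult, R1rhoCurve
from .rates import IntensitySeries, RateRecord
from .spinphys import FieldContext

INTENSITY_COLUMNS = ["residue", "atom", "condition_type", "condition_value",
                     "intensity", "replicate"]
RATE_COLUMNS = ["residue", "r1", "r1_err", "r2", "r2_err", "noe", "noe_err",
                "field_mhz", "temperature_k"]
DISPERSION_COLUMNS = ["residue", "atom", "field_mhz", "nucleus", "exp_type",
                      "nu_cp_hz", "omega_sl_hz", "omega_off_hz", "r2eff",
                      "sigma", "t_relax_s", "r1", "r2_0"]


class TableFormatError(ValueError):
    """A table violates its schema; the message names the offending lines."""


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    return df


def _numeric(df: pd.DataFrame, cols: list[str], path) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() & df[c].notna() & (df[c].str.strip() != "")
        if bad.any():
            lines = [str(i + 2) for i in df.index[bad]]  # +2: header + 1-based
            raise TableFormatError(
                f"{path}: non-numeric value in column {c!r} at line(s) "
                + ", ".join(lines))
        out[c] = vals
    return out


def read_intensity_table(path) -> list[IntensitySeries]:
    """Read an intensity table into one series per (residue, atom,
    condition_type).  Duplicate (residue, atom, condition, value, replicate)
    rows are rejected with their line numbers."""
    df = _read_tsv(path, INTENSITY_COLUMNS)
    df = _numeric(df, ["residue", "condition_value", "intensity", "replicate"],
                  path)
    key = ["residue", "atom", "condition_type", "condition_value", "replicate"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        lines = [str(i + 2) for i in df.index[df.duplicated(subset=key)]]
        raise TableFormatError(f"{path}: duplicate rows at line(s) "
                               + ", ".join(lines))
    series = []
    for (rid, atom, ctype), g in df.groupby(
            ["residue", "atom", "condition_type"], sort=True):
        values = list(zip(g["condition_value"], g["intensity"],
                          g["replicate"].astype(int)))
        series.append(IntensitySeries(residue_id=int(rid), atom=str(atom),
                                      condition_type=str(ctype),
                                      values=values))
    return series


def write_intensity_table(path, series: list[IntensitySeries]) -> None:
    rows = []
    for s in series:
        for x, y, rep in s.values:
            rows.append({"residue": s.residue_id, "atom": s.atom,
                         "condition_type": s.condition_type,
                         "condition_value": x, "intensity": y,
                         "replicate": rep})
    pd.DataFrame(rows, columns=INTENSITY_COLUMNS).to_csv(
        path, sep="\t", index=False)


def write_rate_table(path, records: list[RateRecord]) -> None:
    rows = []
    for r in records:
        row = {"residue": r.residue_id, "r1": r.r1, "r1_err": r.r1_err,
               "r2": r.r2, "r2_err": r.r2_err, "noe": r.noe,
               "noe_err": r.noe_err, "field_mhz": r.field.proton_mhz,
               "temperature_k": r.field.temperature}
        for opt in ("eta_xy", "eta_xy_err", "r2_rczz", "r2_rczz_err",
                    "rex_map", "rex_map_err"):
            v = getattr(r, opt)
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                row[opt] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_rate_table(path) -> list[RateRecord]:
    df = _read_tsv(path, RATE_COLUMNS)
    num_cols = [c for c in df.columns if c != "residue"] + ["residue"]
    df = _numeric(df, num_cols, path)
    out = []
    for _, row in df.iterrows():
        rec = RateRecord(
            residue_id=int(row["residue"]),
            field=FieldContext(float(row["field_mhz"]),
                               float(row["temperature_k"])),
            r1=row["r1"], r1_err=row["r1_err"], r2=row["r2"],
            r2_err=row["r2_err"], noe=row["noe"], noe_err=row["noe_err"])
        for opt in ("eta_xy", "eta_xy_err", "r2_rczz", "r2_rczz_err",
                    "rex_map", "rex_map_err"):
            if opt in df.columns and pd.notna(row[opt]):
                setattr(rec, opt, float(row[opt]))
        out.append(rec)
    return out


def write_dispersion_table(path, cpmg: dict[int, list[CpmgCurve]] | None = None,
                           r1rho: list[R1rhoCurve] | None = None) -> None:
    rows = []
    for curves in (cpmg or {}).values():
        for c in curves:
            for nu, r2eff, sigma in c.points:
                rows.append({"residue": c.residue_id, "atom": "N",
                             "field_mhz": c.field.proton_mhz,
                             "nucleus": c.nucleus, "exp_type": "cpmg",
                             "nu_cp_hz": nu, "omega_sl_hz": "",
                             "omega_off_hz": "", "r2eff": r2eff,
                             "sigma": sigma, "t_relax_s": c.t_relax,
                             "r1": "", "r2_0": ""})
    for c in r1rho or []:
        for wsl, woff, r2eff, sigma in c.points:
            rows.append({"residue": c.residue_id, "atom": "N",
                         "field_mhz": c.field.proton_mhz,
                         "nucleus": c.nucleus, "exp_type": "r1rho",
                         "nu_cp_hz": "", "omega_sl_hz": wsl,
                         "omega_off_hz": woff, "r2eff": r2eff,
                         "sigma": sigma, "t_relax_s": "", "r1": c.r1,
                         "r2_0": "" if c.r2_0 is None else c.r2_0})
    pd.DataFrame(rows, columns=DISPERSION_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_dispersion_table(path) -> tuple[dict[int, list[CpmgCurve]],
                                         list[R1rhoCurve]]:
    df = _read_tsv(path, ["residue", "field_mhz", "exp_type", "r2eff",
                          "sigma"])
    num = ["residue", "field_mhz", "nu_cp_hz", "omega_sl_hz", "omega_off_hz",
           "r2eff", "sigma", "t_relax_s", "r1", "r2_0"]
    df = _numeric(df, [c for c in num if c in df.columns], path)
    cpmg: dict[int, list[CpmgCurve]] = {}
    r1rho: list[R1rhoCurve] = []
    for (rid, fmhz, etype), g in df.groupby(
            ["residue", "field_mhz", "exp_type"], sort=True):
        rid = int(rid)
        field = FieldContext(float(fmhz))
        nucleus = str(g["nucleus"].iloc[0]) if "nucleus" in g else "N15"
        if etype == "cpmg":
            pts = np.column_stack([g["nu_cp_hz"], g["r2eff"], g["sigma"]])
            t_relax = float(g["t_relax_s"].iloc[0]) \
                if "t_relax_s" in g and pd.notna(g["t_relax_s"].iloc[0]) \
                else 0.08
            cpmg.setdefault(rid, []).append(
                CpmgCurve(residue_id=rid, field=field, points=pts,
                          t_relax=t_relax, nucleus=nucleus))
        else:
            pts = np.column_stack([g["omega_sl_hz"], g["omega_off_hz"],
                                   g["r2eff"], g["sigma"]])
            r1 = float(g["r1"].iloc[0]) if "r1" in g and pd.notna(
                g["r1"].iloc[0]) else 0.0
            has_r20 = "r2_0" in g and pd.notna(g["r2_0"].iloc[0])
            r1rho.append(R1rhoCurve(
                residue_id=rid, nucleus=nucleus, field=field, points=pts,
                r1=r1,
                r2_0_mode="fixed_kappa_eta" if has_r20 else "fitted",
                r2_0=float(g["r2_0"].iloc[0]) if has_r20 else None))
    return cpmg, r1rho


def fit_result_to_json(fit: FitResult) -> dict:
    return {
        "model": fit.model,
        "params": fit.params,
        "chi2": fit.chi2,
        "n_points": fit.n_points,
        "n_params": fit.n_params,
        "aic": fit.aic,
        "per_residue_chi2": {str(k): v for k, v in fit.per_residue_chi2.items()},
        "chi2_ratio": {str(k): v for k, v in fit.chi2_ratio.items()},
        "mc_errors": fit.mc_errors,
        "flags": fit.flags,
        "excluded": fit.excluded,
    }


def write_fit_report(path, fits: dict[str, FitResult]) -> None:
    Path(path).write_text(json.dumps(
        {k: fit_result_to_json(f) for k, f in fits.items()}, indent=1))


def read_nh_vectors(path, chain: str | None = None,
                    model_index: int = 0) -> dict[int, np.ndarray]:
    """N->H amide bond unit vectors per residue from a PDB file.

    Uses the first (or ``model_index``-th) model; residues lacking an amide
    proton (H or HN) are skipped with a warning; no protons are built.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    model = list(structure)[model_index]
    out: dict[int, np.ndarray] = {}
    skipped = []
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        for res in ch:
            if "N" not in res:
                continue
            h = res["H"] if "H" in res else (res["HN"] if "HN" in res else None)
            if h is None:
                skipped.append(res.id[1])
                continue
            v = h.coord - res["N"].coord
            n = np.linalg.norm(v)
            if n == 0:
                skipped.append(res.id[1])
                continue
            out[res.id[1]] = v / n
    if skipped:
        warnings.warn(f"{len(skipped)} residue(s) without amide H skipped",
                      stacklevel=2)
    return out
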