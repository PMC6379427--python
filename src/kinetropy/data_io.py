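"""Tabular containers and CSV readers/writers for every pipeline input.

Four plain-text dialects are supported, all comma-separated with "." as the
decimal mark:

* ``shifts.csv``      -- state,residue,restype,methyl,dH_ppm,dC_ppm
* ``decays.csv``      -- residue,restype,methyl,delay_s,I_tq,I_sq,err_tq,err_sq
* ``dispersion.csv``  -- residue,restype,methyl,field_MHz,nu_cpmg_hz,intensity,
  ref_intensity,replicate_id
* ``itc.csv``         -- injection,volume_uL,heat_ucal with ``# key,value``
  metadata lines (cell_conc_M, syringe_conc_M, cell_volume_mL, temperature_K)

State order is the order of first appearance in the file, never alphabetical:
titration trajectories depend on the declared cycle order.  Missing
methyl/state combinations are simply absent rows, never zeros.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import DuplicateRecordError, FormatError, ValidationError

_FLOAT_FMT = "%.15g"  # round-trips doubles to >= 15 significant digits

ILV_TYPES = frozenset("ILV")


class MethylId(NamedTuple):
    """Identity of one ILV methyl group: residue number, residue type and
    methyl label (e.g. ``"d1"`` for Ile Cdelta1, ``"g2"`` for Val Cgamma2)."""

    residue_number: int
    residue_type: str
    methyl_label: str

    @property
    def label(self) -> str:
        """Compact human-readable tag, e.g. ``"I10-d1"``."""
        return f"{self.residue_type}{self.residue_number}-{self.methyl_label}"

    def validate(self) -> "MethylId":
        if self.residue_number < 1:
            raise ValidationError(f"residue_number must be >= 1: {self}")
        if self.residue_type not in ILV_TYPES:
            raise ValidationError(
                f"residue_type must be one of I/L/V, got {self.residue_type!r}")
        return self


# ---------------------------------------------------------------------------
# chemical shifts
# ---------------------------------------------------------------------------

@dataclass
class StateShiftTable:
    """Per-methyl (dH, dC) chemical shifts across an ordered series of
    ligation states.

    ``shifts`` maps (MethylId, state) -> (dH_ppm, dC_ppm).  Entries may be
    missing for some combinations; absence is explicit, never encoded as 0.
    """

    states: list[str]
    shifts: dict[tuple[MethylId, str], tuple[float, float]]

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValidationError("state names must be unique")
        for (mid, state), (dh, dc) in self.shifts.items():
            if state not in self.states:
                raise ValidationError(f"entry references unknown state {state!r}")
            if not (np.isfinite(dh) and np.isfinite(dc)):
                raise ValidationError(f"non-finite shift for {mid} in {state!r}")

    @property
    def n_entries(self) -> int:
        return len(self.shifts)

    def methyls(self) -> list[MethylId]:
        seen: dict[MethylId, None] = {}
        for mid, _ in self.shifts:
            seen.setdefault(mid, None)
        return list(seen)

    def get(self, methyl: MethylId, state: str) -> tuple[float, float] | None:
        return self.shifts.get((methyl, state))

    def profile(self, methyl: MethylId,
                states: Iterable[str] | None = None) -> np.ndarray | None:
        """(n_states, 2) array of (dH, dC) for one methyl, or None if any
        requested state is missing for it."""
        states = list(states) if states is not None else self.states
        rows = []
        for s in states:
            v = self.shifts.get((methyl, s))
            if v is None:
                return None
            rows.append(v)
        return np.asarray(rows, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {"state": s, "residue": m.residue_number, "restype": m.residue_type,
             "methyl": m.methyl_label, "dH_ppm": dh, "dC_ppm": dc}
            for (m, s), (dh, dc) in self.shifts.items()
        ]
        df = pd.DataFrame(recs, columns=["state", "residue", "restype",
                                         "methyl", "dH_ppm", "dC_ppm"])
        order = {s: i for i, s in enumerate(self.states)}
        if len(df):
            df = df.sort_values(["state", "residue", "methyl"],
                                key=lambda c: c.map(order) if c.name == "state" else c)
        return df.reset_index(drop=True)


_SHIFT_COLS = ["state", "residue", "restype", "methyl", "dH_ppm", "dC_ppm"]


def read_shift_table(path: str | Path) -> StateShiftTable:
    """Read a shifts.csv file.  Rows with unparseable numbers are rejected
    with their (1-based data) row index named in the error."""
    df = _read_csv(path, _SHIFT_COLS)
    states: list[str] = []
    shifts: dict[tuple[MethylId, str], tuple[float, float]] = {}
    for i, row in df.iterrows():
        try:
            mid = MethylId(int(row["residue"]), str(row["restype"]),
                           str(row["methyl"])).validate()
            dh, dc = float(row["dH_ppm"]), float(row["dC_ppm"])
            if not (np.isfinite(dh) and np.isfinite(dc)):
                raise ValueError("non-finite shift")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: unparseable row {i + 1}: {exc}") from exc
        state = str(row["state"])
        if state not in states:
            states.append(state)
        key = (mid, state)
        if key in shifts:
            raise DuplicateRecordError(
                f"{path}: duplicate entry for {mid} in state {state!r}")
        shifts[key] = (dh, dc)
    return StateShiftTable(states=states, shifts=shifts)


def write_shift_table(table: StateShiftTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# TQ/SQ intensity decays
# ---------------------------------------------------------------------------

@dataclass
class IntensityDecaySet:
    """Triple-/single-quantum-filtered peak intensities versus relaxation
    delay, one decay series per methyl.

    ``data`` columns: residue, restype, methyl, delay_s, I_tq, I_sq,
    err_tq, err_sq.  Delays are strictly increasing within each methyl and a
    series needs at least 5 points to be fittable.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        if (d["delay_s"] < 0).any():
            bad = d.loc[d["delay_s"] < 0, "delay_s"].iloc[0]
            raise ValidationError(f"negative relaxation delay: {bad} s")
        if not np.isfinite(d[["I_tq", "I_sq"]].to_numpy()).all():
            raise ValidationError("non-finite intensity")
        for mid, grp in self.groupby_methyl():
            t = grp["delay_s"].to_numpy()
            if not np.all(np.diff(t) > 0):
                raise ValidationError(f"delays not strictly increasing for {mid}")

    def groupby_methyl(self):
        for key, grp in self.data.groupby(["residue", "restype", "methyl"],
                                          sort=True):
            yield MethylId(int(key[0]), str(key[1]), str(key[2])), grp


_DECAY_COLS = ["residue", "restype", "methyl", "delay_s", "I_tq", "I_sq",
               "err_tq", "err_sq"]


def read_decay_table(path: str | Path) -> IntensityDecaySet:
    df = _read_csv(path, _DECAY_COLS)
    df = _coerce_numeric(df, ["delay_s", "I_tq", "I_sq", "err_tq", "err_sq"], path)
    df["residue"] = df["residue"].astype(int)
    return IntensityDecaySet(df)


def write_decay_table(decays: IntensityDecaySet, path: str | Path) -> None:
    decays.data.to_csv(path, index=False, float_format=_FLOAT_FMT,
                       columns=_DECAY_COLS)


# ---------------------------------------------------------------------------
# CPMG dispersion
# ---------------------------------------------------------------------------

@dataclass
class DispersionSet:
    """CPMG peak intensities versus refocusing frequency, possibly at two
    static fields, with replicate points retained (replicate_id > 0 marks a
    repeat of the same nu_CPMG; replicates feed the per-point error model)."""

    data: pd.DataFrame
    t_cp: float = 0.040  # constant-time relaxation delay, s

    def __post_init__(self) -> None:
        d = self.data
        if (d["nu_cpmg_hz"] <= 0).any():
            raise ValidationError("nu_CPMG must be positive")
        if (d["field_MHz"] <= 0).any():
            raise ValidationError("field_MHz must be positive")
        if self.t_cp <= 0:
            raise ValidationError("constant-time delay must be positive")

    def groupby_methyl(self):
        for key, grp in self.data.groupby(["residue", "restype", "methyl"],
                                          sort=True):
            yield MethylId(int(key[0]), str(key[1]), str(key[2])), grp

    def fields(self) -> list[float]:
        return sorted(self.data["field_MHz"].unique())


_DISP_COLS = ["residue", "restype", "methyl", "field_MHz", "nu_cpmg_hz",
              "intensity", "ref_intensity", "replicate_id"]


def read_dispersion_table(path: str | Path, t_cp: float = 0.040) -> DispersionSet:
    df = _read_csv(path, _DISP_COLS)
    df = _coerce_numeric(df, ["field_MHz", "nu_cpmg_hz", "intensity",
                              "ref_intensity"], path)
    df["residue"] = df["residue"].astype(int)
    df["replicate_id"] = df["replicate_id"].astype(int)
    return DispersionSet(df, t_cp=t_cp)


def write_dispersion_table(disp: DispersionSet, path: str | Path) -> None:
    disp.data.to_csv(path, index=False, float_format=_FLOAT_FMT,
                     columns=_DISP_COLS)


# ---------------------------------------------------------------------------
# ITC isotherms
# ---------------------------------------------------------------------------

@dataclass
class Isotherm:
    """One ITC titration: integrated heat per injection plus the cell and
    syringe bookkeeping needed by the binding model.

    heats_ucal     -- integrated heat of each injection, microcal
    volumes_uL     -- injected volume per injection, microliter
    cell_conc_M    -- total macromolecule concentration loaded in the cell
    syringe_conc_M -- ligand concentration in the syringe
    cell_volume_mL -- active cell volume
    """

    heats_ucal: np.ndarray
    volumes_uL: np.ndarray
    cell_conc_M: float
    syringe_conc_M: float
    cell_volume_mL: float
    temperature_K: float = 300.0

    def __post_init__(self) -> None:
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        self.volumes_uL = np.asarray(self.volumes_uL, dtype=float)
        if self.heats_ucal.shape != self.volumes_uL.shape:
            raise ValidationError("heats and volumes must have equal length")
        if len(self.heats_ucal) < 6:
            raise ValidationError("an isotherm needs at least 6 injections")
        for name in ("cell_conc_M", "syringe_conc_M", "cell_volume_mL",
                     "temperature_K"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if (self.volumes_uL <= 0).any():
            raise ValidationError("injection volumes must be > 0")

    @property
    def n_injections(self) -> int:
        return len(self.heats_ucal)


_ITC_COLS = ["injection", "volume_uL", "heat_ucal"]
_ITC_META = ["cell_conc_M", "syringe_conc_M", "cell_volume_mL", "temperature_K"]


def read_isotherm(path: str | Path) -> Isotherm:
    meta: dict[str, float] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line[1:].strip().split(",")
                if len(parts) == 2:
                    meta[parts[0].strip()] = float(parts[1])
            else:
                body_lines.append(line)
    missing = [k for k in _ITC_META if k not in meta]
    if missing:
        raise FormatError(f"{path}: missing metadata lines for {missing}")
    df = _read_csv(_io.StringIO("".join(body_lines)), _ITC_COLS, label=path)
    df = _coerce_numeric(df, ["volume_uL", "heat_ucal"], path)
    idx = df["injection"].astype(int).to_numpy()
    if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
        raise ValidationError(f"{path}: injection index must run 1..n in order")
    return Isotherm(
        heats_ucal=df["heat_ucal"].to_numpy(),
        volumes_uL=df["volume_uL"].to_numpy(),
        cell_conc_M=meta["cell_conc_M"],
        syringe_conc_M=meta["syringe_conc_M"],
        cell_volume_mL=meta["cell_volume_mL"],
        temperature_K=meta["temperature_K"],
    )


def write_isotherm(iso: Isotherm, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cell_conc_M,{iso.cell_conc_M:.15g}\n")
        fh.write(f"# syringe_conc_M,{iso.syringe_conc_M:.15g}\n")
        fh.write(f"# cell_volume_mL,{iso.cell_volume_mL:.15g}\n")
        fh.write(f"# temperature_K,{iso.temperature_K:.15g}\n")
        fh.write("injection,volume_uL,heat_ucal\n")
        for i, (v, q) in enumerate(zip(iso.volumes_uL, iso.heats_ucal), start=1):
            fh.write(f"{i},{v:.15g},{q:.15g}\n")


# ---------------------------------------------------------------------------
# generic result reporting
# ---------------------------------------------------------------------------

def write_report(results, path: str | Path, metadata: dict | None = None) -> None:
    """Write a stage result as CSV plus a JSON metadata sidecar.

    Accepts a DataFrame, a dict of columns, or any object with a
    ``to_frame()`` method.  The sidecar ``<path>.meta.json`` records the
    metadata dict so figure-level quantities can be regenerated."""
    path = Path(path)
    if hasattr(results, "to_frame") and not isinstance(results, pd.DataFrame):
        df = results.to_frame()
    elif isinstance(results, pd.DataFrame):
        df = results
    else:
        df = pd.DataFrame(results)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    with open(sidecar, "w") as fh:
        json.dump(metadata or {}, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


# ---------------------------------------------------------------------------
# shared CSV plumbing
# ---------------------------------------------------------------------------

def _read_csv(path_or_buf, required_cols: list[str], label=None) -> pd.DataFrame:
    label = label or path_or_buf
    try:
        df = pd.read_csv(path_or_buf, comment="#", dtype=str,
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{label}: empty file (no header)") from exc
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise FormatError(f"{label}: missing required columns {missing}")
    return df[required_cols]


def _coerce_numeric(df: pd.DataFrame, cols: list[str], label) -> pd.DataFrame:
    df = df.copy()
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() & df[c].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise FormatError(f"{label}: non-numeric value in column {c!r}, "
                              f"row {row}")
        df[c] = vals
    return df
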