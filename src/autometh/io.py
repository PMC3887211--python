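"""Readers and writers for the formats the pipeline consumes and emits.

FASTA via Biopython, MGF via pyteomics, tables via pandas; plus a plain
two-column m/z-intensity text reader for fingerprint peak lists. Parse
failures name the file and, where possible, the offending line or row.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from pyteomics import mgf

from .errors import InputError
from .kinetics import TimeCourse
from .peaks import PeakList

log = logging.getLogger("autometh")


def read_fasta(path: str | Path, seq_id: str | None = None) -> tuple[str, str]:
    """Read one protein sequence from a FASTA file.

    Returns ``(record id, sequence)``. With multiple records and no
    ``seq_id``, the first is used and a warning logged.
    """
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise InputError(f"{path}: {exc}") from exc
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    if seq_id is not None:
        for rec in records:
            if rec.id == seq_id:
                return rec.id, str(rec.seq).upper()
        raise InputError(f"{path}: no record with id {seq_id!r}")
    if len(records) > 1:
        log.warning(
            "%s: %d records, using first (%s)", path, len(records), records[0].id
        )
    return records[0].id, str(records[0].seq).upper()


def read_mgf(path: str | Path) -> list[PeakList]:
    """Read all spectra from a Mascot generic format file as MS2 peak lists."""
    spectra = []
    try:
        with mgf.read(str(path)) as reader:
            for spec in reader:
                params = spec.get("params", {})
                pepmass = params.get("pepmass", (None,))
                charge = params.get("charge")
                spectra.append(
                    PeakList(
                        mz=spec["m/z array"],
                        intensity=spec["intensity array"],
                        ms_level=2,
                        precursor_mz=float(pepmass[0]) if pepmass[0] is not None else None,
                        precursor_charge=int(charge[0]) if charge else None,
                        title=str(params.get("title", "")),
                    )
                )
    except InputError:
        raise
    except Exception as exc:
        raise InputError(f"{path}: malformed MGF ({exc})") from exc
    if not spectra:
        raise InputError(f"{path}: no BEGIN IONS/END IONS blocks found")
    return spectra


def write_mgf(path: str | Path, spectra: list[PeakList]) -> None:
    """Write MS2 peak lists as MGF (PEPMASS/CHARGE from precursor fields)."""
    entries = []
    for i, s in enumerate(spectra):
        params = {"title": s.title or f"spectrum_{i}"}
        if s.precursor_mz is not None:
            params["pepmass"] = s.precursor_mz
        if s.precursor_charge is not None:
            params["charge"] = s.precursor_charge
        entries.append(
            {"m/z array": s.mz, "intensity array": s.intensity, "params": params}
        )
    mgf.write(entries, str(path), file_mode="w")


def read_peaklist_text(path: str | Path) -> PeakList:
    """Read a plain two-column (m/z, intensity) peak list (whitespace or
    comma separated; a lone m/z column gets unit intensities)."""
    mzs, intens = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            try:
                mzs.append(float(fields[0]))
                intens.append(float(fields[1]) if len(fields) > 1 else 1.0)
            except (ValueError, IndexError) as exc:
                raise InputError(f"{path}: line {lineno}: {line!r} is not numeric") from exc
    if not mzs:
        raise InputError(f"{path}: no peaks found")
    return PeakList(mz=np.asarray(mzs), intensity=np.asarray(intens), ms_level=1)


def write_peaklist_text(path: str | Path, peaklist: PeakList) -> None:
    with open(path, "w") as fh:
        for m, i in zip(peaklist.mz, peaklist.intensity):
            fh.write(f"{m:.6f}\t{i:.6f}\n")


def _read_numeric_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, FileNotFoundError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing} (headers required)")
    for col in required:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise InputError(
                f"{path}: non-numeric value {df[col][bad[0]]!r} in column "
                f"{col!r}, data row {bad[0] + 1}"
            )
        if converted.isna().any():
            raise InputError(f"{path}: empty cell in column {col!r}")
        df[col] = converted
    return df


def read_timecourse_csv(path: str | Path) -> TimeCourse:
    """Read a time,signal[,label] CSV as a :class:`TimeCourse` (time in hours)."""
    df = _read_numeric_csv(path, ("time", "signal"))
    label = str(df["label"].iloc[0]) if "label" in df.columns else ""
    return TimeCourse(t=df["time"].to_numpy(), signal=df["signal"].to_numpy(), label=label)


def read_pairs_csv(path: str | Path) -> pd.DataFrame:
    """Read a conc,rate CSV for order / Michaelis-Menten fitting."""
    return _read_numeric_csv(path, ("conc", "rate"))


def write_json_report(path: str | Path, report: dict) -> None:
    """Write a machine-readable report; keys are sorted for diffability."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class RunConfig:
    """Resolved run configuration, written beside every pipeline output."""

    ms1_tol: float = 0.3
    ms2_tol: float = 0.5
    precursor_tol: float = 0.05
    protease: str = "trypsin"
    max_missed: int = 1
    variable_mods: tuple[str, ...] = ("methyl",)
    any_site: bool = False
    parent_offset: int = 1
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        for name in ("ms1_tol", "ms2_tol", "precursor_tol"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be > 0")
        self.variable_mods = tuple(self.variable_mods)

    def to_json(self, path: str | Path) -> None:
        write_json_report(path, asdict(self))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise InputError(f"{path}: invalid JSON ({exc})") from exc
        return cls(**data)
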