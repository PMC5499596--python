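"""File I/O: time-course / melting-curve / lane-table CSV, strand FASTA.

All CSV writers prepend comment lines (``#``-prefixed) recording the
package version, the seed and a hash of the generating configuration, so a
file's provenance travels with it; readers skip comments. Numeric payloads
are written with 12 significant digits, making write -> read round trips
lossless at that precision and re-runs with identical configuration
byte-identical.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .errors import ParseError
from .kinetics import TimeCourse
from .strands import Strand
from .thermo import MeltingCurve

TIMECOURSE_COLUMNS = ("time_min", "frac_amino_remaining", "frac_product")
_FLOAT_FMT = "%.12g"


def config_hash(config: dict | None) -> str:
    """Short deterministic hash of a configuration mapping."""
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header_lines(seed: int | None, config: dict | None) -> str:
    return (
        f"# eptlig v{__version__}\n"
        f"# seed={'NA' if seed is None else seed} config_hash={config_hash(config)}\n"
    )


def _write_csv(df: pd.DataFrame, path: str | Path, seed, config) -> Path:
    path = Path(path)
    buf = _io.StringIO()
    df.to_csv(buf, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    path.write_text(_header_lines(seed, config) + buf.getvalue())
    return path


def _read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except Exception as exc:
        raise ParseError(f"cannot parse CSV: {exc}", location=str(path)) from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"missing required column(s) {missing}", location=str(path))
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise ParseError(
                f"non-numeric value in column {col!r}", location=f"{path}, data row {row}"
            )
    return df


def write_timecourse(tc: TimeCourse, path: str | Path, seed: int | None = None,
                     config: dict | None = None) -> Path:
    """Write a time course as CSV with a provenance comment header."""
    data = {"time_min": tc.times}
    for col, attr in (
        ("frac_amino_remaining", "frac_amino_remaining"),
        ("frac_product", "frac_product"),
        ("frac_ept_active", "frac_ept_active"),
    ):
        v = getattr(tc, attr)
        if v is not None:
            data[col] = v
    return _write_csv(pd.DataFrame(data), path, seed, config or tc.meta)


def read_timecourse(path: str | Path) -> TimeCourse:
    """Read a time-course CSV (columns ``time_min`` plus at least one of
    the fraction columns); CRLF and LF files are both accepted."""
    df = _read_csv(path, required=("time_min",))
    frac_cols = [c for c in df.columns if c.startswith("frac_")]
    if not frac_cols:
        raise ParseError("no fraction columns found", location=str(path))
    t = df["time_min"].to_numpy(float)
    if np.any(np.diff(t) < 0):
        row = int(np.argmax(np.diff(t) < 0)) + 3
        raise ParseError("times must be non-decreasing", location=f"{path}, data row {row}")
    for c in frac_cols:
        v = df[c].to_numpy(float)
        bad = np.where((v < 0) | (v > 1))[0]
        if len(bad):
            raise ParseError(
                f"column {c!r} value {v[bad[0]]} outside [0, 1]",
                location=f"{path}, data row {int(bad[0]) + 2}",
            )
    kwargs = {c: df[c].to_numpy(float) for c in frac_cols if c in
              ("frac_amino_remaining", "frac_product", "frac_ept_active")}
    return TimeCourse(times=t, provenance="user", **kwargs)


def write_melting_curve(curve: MeltingCurve, path: str | Path, seed: int | None = None,
                        config: dict | None = None) -> Path:
    df = pd.DataFrame({"temp_C": curve.temperatures, "frac_duplex": curve.theta})
    return _write_csv(df, path, seed, config or {"total_conc": curve.total_conc})


def read_melting_curve(path: str | Path, total_conc: float) -> MeltingCurve:
    """Read a melting curve CSV (``temp_C,frac_duplex``); the per-strand
    total concentration is supplied by the caller (config or --conc)."""
    df = _read_csv(path, required=("temp_C", "frac_duplex"))
    return MeltingCurve(
        temperatures=df["temp_C"].to_numpy(float),
        theta=df["frac_duplex"].to_numpy(float),
        total_conc=total_conc,
    )


def write_lane_table(df: pd.DataFrame, path: str | Path, seed: int | None = None,
                     config: dict | None = None) -> Path:
    return _write_csv(df, path, seed, config)


def read_lane_table(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, required=("lane", "i_remaining", "i_product"))


def write_strands(strands: list[Strand], fasta_path: str | Path) -> tuple[Path, Path]:
    """Write strands to FASTA plus a JSON sidecar with role/end-chemistry
    metadata (FASTA cannot carry it)."""
    fasta_path = Path(fasta_path)
    records = [
        SeqRecord(Seq(s.sequence), id=s.id, description=f"role={s.role} end_chem={s.end_chem}")
        for s in strands
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    sidecar = fasta_path.with_suffix(".json")
    meta = {
        s.id: {"role": s.role, "end_chem": s.end_chem, "label": s.label,
               "two_prime_ome": list(s.two_prime_ome)}
        for s in strands
    }
    sidecar.write_text(json.dumps(meta, indent=2) + "\n")
    return fasta_path, sidecar


def read_strands(fasta_path: str | Path) -> list[Strand]:
    """Read strands from FASTA plus their JSON sidecar (if present)."""
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise ParseError(f"no such file: {fasta_path}")
    sidecar = fasta_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    strands = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        m = meta.get(rec.id, {})
        strands.append(
            Strand(
                id=rec.id,
                sequence=str(rec.seq),
                role=m.get("role", "template"),
                end_chem=m.get("end_chem", "none"),
                label=m.get("label"),
                two_prime_ome=tuple(m.get("two_prime_ome", ())),
            )
        )
    if not strands:
        raise ParseError("no FASTA records found", location=str(fasta_path))
    return strands
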