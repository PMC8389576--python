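"""Plain-text I/O: trace TSV files, coefficient CSV tables, protocol JSON.

Trace dialect (emulating a fluorometer text export): UTF-8 TSV with header
``time_s  fluorescence  actinic_ppfd  pulse_flag``, "." decimal separator,
times in seconds from trace start (OJIP traces use fractional seconds, one
dialect for everything), pulse_flag ∈ {0, 1}.  A JSON sidecar
(``<name>.meta.json``) carries protocol_id, plant_id, cytotype,
photoperiod_h and the simulation seed.

All readers *reject* malformed input with the file and first offending line
named in the error; nothing is silently coerced.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .trace import PROTOCOL_IDS, FluorescenceTrace

TRACE_COLUMNS = ("time_s", "fluorescence", "actinic_ppfd", "pulse_flag")

#: controlled coefficient vocabulary; rETR is parameterized by its PPFD step
COEFFICIENT_VOCABULARY = (
    "phi_PSII", "phi_max", "NPQ", "qE", "qI", "qP", "qL", "PQ",
    "ABS/RC", "TR0/RC", "ET0/RC", "DI0/RC", "PI_ABS",
)
_RETR_RE = re.compile(r"^rETR@\d+(\.\d+)?$")

TABLE_COLUMNS = ("plant_id", "cytotype", "photoperiod_h", "coefficient", "value")


def is_valid_coefficient_name(name: str) -> bool:
    return name in COEFFICIENT_VOCABULARY or bool(_RETR_RE.match(name))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".tsv" \
        else path.with_name(path.stem + ".meta.json")


def write_trace(trace: FluorescenceTrace, path: str | Path) -> Path:
    """Write a trace as TSV plus its JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(TRACE_COLUMNS) + "\n")
        for t, f, a, p in zip(trace.time_s, trace.fluorescence,
                              trace.actinic_ppfd, trace.pulse_flag):
            fh.write(f"{float(t)!r}\t{float(f)!r}\t{float(a)!r}\t{int(p)}\n")
    meta = {"protocol_id": trace.protocol_id, **trace.meta}
    _sidecar_path(path).write_text(json.dumps(meta, indent=2), encoding="utf-8")
    return path


def read_trace(path: str | Path) -> FluorescenceTrace:
    """Read a TSV trace (and its sidecar, if present), enforcing the trace
    invariants with file+line context on failure."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != TRACE_COLUMNS:
        raise FormatError(
            f"{path}, line 1: header {header} does not match {TRACE_COLUMNS}")
    cols = {c: [] for c in TRACE_COLUMNS}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(
                f"{path}, line {lineno}: expected 4 tab-separated fields, "
                f"got {len(parts)}")
        try:
            t, f, a = float(parts[0]), float(parts[1]), float(parts[2])
            p = int(parts[3])
        except ValueError as exc:
            raise FormatError(f"{path}, line {lineno}: {exc}") from None
        if p not in (0, 1):
            raise FormatError(
                f"{path}, line {lineno}: pulse_flag must be 0 or 1, got {parts[3]}")
        if f <= 0:
            raise FormatError(
                f"{path}, line {lineno}: fluorescence must be > 0, got {f}")
        if cols["time_s"] and t <= cols["time_s"][-1]:
            raise FormatError(
                f"{path}, line {lineno}: time_s not strictly increasing "
                f"({t} after {cols['time_s'][-1]})")
        cols["time_s"].append(t)
        cols["fluorescence"].append(f)
        cols["actinic_ppfd"].append(a)
        cols["pulse_flag"].append(bool(p))
    if not cols["time_s"]:
        raise FormatError(f"{path}: no data rows")

    sidecar = _sidecar_path(path)
    meta, protocol_id = {}, "YIELD"
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
        protocol_id = meta.pop("protocol_id", "YIELD")
        if protocol_id not in PROTOCOL_IDS:
            raise FormatError(
                f"{sidecar}: unknown protocol_id {protocol_id!r}")
    try:
        return FluorescenceTrace(
            time_s=np.array(cols["time_s"]),
            fluorescence=np.array(cols["fluorescence"]),
            actinic_ppfd=np.array(cols["actinic_ppfd"]),
            pulse_flag=np.array(cols["pulse_flag"]),
            protocol_id=protocol_id,
            meta=meta,
        )
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from None


def validate_coefficient_table(table: pd.DataFrame, source: str = "table") -> pd.DataFrame:
    """Enforce the tidy coefficient-table contract: exact columns, controlled
    vocabulary, one row per (plant, coefficient), finite values."""
    if tuple(table.columns) != TABLE_COLUMNS:
        raise ValidationError(
            f"{source}: columns {tuple(table.columns)} do not match {TABLE_COLUMNS}")
    bad = sorted({n for n in table["coefficient"] if not is_valid_coefficient_name(n)})
    if bad:
        raise ValidationError(
            f"{source}: unknown coefficient name(s) {bad}; valid names are "
            f"{COEFFICIENT_VOCABULARY} plus rETR@<ppfd>")
    dup = table.duplicated(subset=["plant_id", "coefficient"])
    if dup.any():
        first = table[dup].iloc[0]
        raise ValidationError(
            f"{source}: duplicate (plant, coefficient) pair "
            f"({first['plant_id']}, {first['coefficient']})")
    if not np.isfinite(table["value"].to_numpy(dtype=float)).all():
        raise ValidationError(f"{source}: non-finite coefficient values")
    return table


def write_coefficients(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_coefficient_table(table, source=str(path))
    path.parent.mkdir(parents=True, exist_ok=True)
    out = table.copy()
    out["value"] = out["value"].map(repr)
    out.to_csv(path, index=False)
    return path


def read_coefficients(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    try:
        table = pd.read_csv(path, dtype={"plant_id": str, "cytotype": str})
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from None
    try:
        table["photoperiod_h"] = table["photoperiod_h"].astype(float)
        table["value"] = table["value"].astype(float)
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from None
    return validate_coefficient_table(table, source=str(path))
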