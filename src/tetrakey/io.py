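"""Readers/writers for the fixed CSV schemas, report serialization, and
run configuration.

CSV dialect is fixed (UTF-8, comma separator, ``.`` decimal point) so
results do not depend on the locale of the machine that produced or
consumes a file.
"""

from __future__ import annotations

import csv
import io as _io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

from .errors import ValidationError
from .keys import UNKNOWN, DichotomousKey, StateVector, TraversalResult
from .measurements import INDEX_FIELDS, MeasurementSet, compute_indices

__all__ = [
    "SPECIMEN_CSV_COLUMNS",
    "RunConfig",
    "Specimen",
    "parse_coordinate",
    "read_specimen_csv",
    "write_specimen_csv",
    "read_state_csv",
    "write_state_csv",
    "write_index_report",
    "write_identification_report",
]

#: Exact header of a specimen measurement CSV (order matters).
SPECIMEN_CSV_COLUMNS = (
    "specimen_id", "taxon_hint",
    "HL", "HW", "SL", "EL", "PH", "PW", "WL",
    "PSL", "PTL", "PTH", "PTW", "PPL", "PPH", "PPW",
    "latitude", "longitude", "locality", "collection_note",
)

_MEASUREMENT_COLUMNS = SPECIMEN_CSV_COLUMNS[2:16]


@dataclass(frozen=True)
class RunConfig:
    """Run-wide options shared by the CLI subcommands."""

    halfwidth: float = 0.005
    key_id: str = "india_species_groups"
    seed: int = 0
    output_format: str = "text"  # text | csv | json
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.halfwidth < 0:
            raise ValidationError(f"halfwidth must be >= 0, got {self.halfwidth}")
        if not (isinstance(self.seed, int) and self.seed >= 0):
            raise ValidationError(f"seed must be a nonnegative integer, got {self.seed!r}")
        if self.output_format not in ("text", "csv", "json"):
            raise ValidationError(f"unknown output format {self.output_format!r}")


@dataclass(frozen=True)
class Specimen:
    specimen_id: str
    measurements: MeasurementSet
    taxon_hint: str = ""
    latitude: float | None = None
    longitude: float | None = None
    locality: str = ""
    collection_note: str = ""
    row_number: int | None = None


_COORD_RE = re.compile(r"^\s*([+-]?\d+(?:\.\d+)?)\s*([NSEWnsew])?\s*$")


def parse_coordinate(raw: str, where: str = "coordinate") -> float | None:
    """Accept signed decimal degrees or hemisphere-suffixed values
    (``"11.975817 N"``); normalize to signed decimal degrees."""
    if raw is None or raw.strip() == "":
        return None
    m = _COORD_RE.match(raw)
    if not m:
        raise ValidationError(f"{where}: cannot parse coordinate {raw!r}")
    value = float(m.group(1))
    hemi = (m.group(2) or "").upper()
    if hemi in ("S", "W"):
        if value < 0:
            raise ValidationError(f"{where}: sign and hemisphere conflict in {raw!r}")
        value = -value
    return value


def _parse_cell(raw: str, row: int, column: str) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        value = float(raw)
    except ValueError:
        raise ValidationError(f"row {row}, column {column}: not a number: {raw!r}")
    if value <= 0:
        raise ValidationError(
            f"row {row}, column {column}: measurement must be > 0 mm, got {raw!r}")
    return value


def read_specimen_csv(path: str | Path) -> list[Specimen]:
    """Parse a specimen measurement table; empty measurement cells
    become absent measurements.  Errors name the offending row/column."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file")
        if tuple(h.strip() for h in header) != SPECIMEN_CSV_COLUMNS:
            raise ValidationError(
                f"{path}: header mismatch; expected {','.join(SPECIMEN_CSV_COLUMNS)}")
        specimens: list[Specimen] = []
        for row_number, row in enumerate(reader, start=2):
            if not row or all(c.strip() == "" for c in row):
                continue
            if len(row) != len(SPECIMEN_CSV_COLUMNS):
                raise ValidationError(
                    f"row {row_number}: expected {len(SPECIMEN_CSV_COLUMNS)} cells, "
                    f"got {len(row)}")
            cells = dict(zip(SPECIMEN_CSV_COLUMNS, row))
            values = {c: _parse_cell(cells[c], row_number, c)
                      for c in _MEASUREMENT_COLUMNS}
            specimens.append(Specimen(
                specimen_id=cells["specimen_id"].strip(),
                taxon_hint=cells["taxon_hint"].strip(),
                measurements=MeasurementSet.from_dict(values),
                latitude=parse_coordinate(cells["latitude"], f"row {row_number}, latitude"),
                longitude=parse_coordinate(cells["longitude"], f"row {row_number}, longitude"),
                locality=cells["locality"].strip(),
                collection_note=cells["collection_note"].strip(),
                row_number=row_number,
            ))
    return specimens


def _format_mm(value: float | None, decimals: int = 3) -> str:
    return "" if value is None else f"{value:.{decimals}f}"


def write_specimen_csv(specimens: Iterable[Specimen], path: str | Path,
                       decimals: int = 3) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SPECIMEN_CSV_COLUMNS)
        for s in specimens:
            writer.writerow(
                [s.specimen_id, s.taxon_hint]
                + [_format_mm(s.measurements[c], decimals) for c in _MEASUREMENT_COLUMNS]
                + ["" if s.latitude is None else repr(s.latitude),
                   "" if s.longitude is None else repr(s.longitude),
                   s.locality, s.collection_note])


def read_state_csv(path: str | Path, key: DichotomousKey
                   ) -> list[tuple[str, StateVector]]:
    """Parse a state-vector table: ``specimen_id`` plus one column per
    character id; empty cells mean UNKNOWN."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise ValidationError(f"{path}: empty file")
        if not header or header[0] != "specimen_id":
            raise ValidationError(f"{path}: first column must be specimen_id")
        unknown_cols = [c for c in header[1:] if c not in key.characters]
        if unknown_cols:
            raise ValidationError(
                f"{path}: columns not in key {key.key_id!r}: {unknown_cols}")
        out: list[tuple[str, StateVector]] = []
        for row_number, row in enumerate(reader, start=2):
            if not row or all(c.strip() == "" for c in row):
                continue
            states: dict[str, Any] = {}
            for col, raw in zip(header[1:], row[1:]):
                raw = raw.strip()
                if raw == "":
                    states[col] = UNKNOWN
                    continue
                cd = key.characters[col]
                if cd.kind == "boolean":
                    if raw.lower() not in ("true", "false"):
                        raise ValidationError(
                            f"row {row_number}, column {col}: expected true/false, got {raw!r}")
                    value: Any = raw.lower() == "true"
                elif cd.kind == "count":
                    try:
                        value = int(raw)
                    except ValueError:
                        raise ValidationError(
                            f"row {row_number}, column {col}: expected integer, got {raw!r}")
                elif cd.kind == "quantitative":
                    value = float(raw)
                else:
                    value = raw
                try:
                    states[col] = cd.validate_value(value)
                except ValidationError as exc:
                    raise ValidationError(f"row {row_number}: {exc}") from exc
            out.append((row[0].strip(), StateVector(key, states)))
    return out


def write_state_csv(rows: Sequence[tuple[str, Mapping[str, Any]]],
                    key: DichotomousKey, path: str | Path) -> None:
    columns = ["specimen_id"] + sorted(key.characters)
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(columns)
        for specimen_id, sv in rows:
            cells = [specimen_id]
            for col in columns[1:]:
                v = sv.get(col, UNKNOWN)
                if v is UNKNOWN:
                    cells.append("")
                elif isinstance(v, bool):
                    cells.append("true" if v else "false")
                else:
                    cells.append(str(v))
            writer.writerow(cells)


def write_index_report(specimens: Iterable[Specimen], path: str | Path,
                       include_raw: bool = False) -> None:
    """One row per specimen: reported (rounding-rule) indices, and
    optionally the raw ratios."""
    header = ["specimen_id"] + list(INDEX_FIELDS)
    if include_raw:
        header += [f"{i}_raw" for i in INDEX_FIELDS]
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for s in specimens:
            idx = compute_indices(s.measurements)
            reported = idx.reported()
            row = [s.specimen_id] + [
                "" if reported[i] is None else f"{reported[i]:g}" for i in INDEX_FIELDS]
            if include_raw:
                row += ["" if idx[i] is None else f"{idx[i]:.6f}" for i in INDEX_FIELDS]
            writer.writerow(row)


def _result_to_dict(specimen_id: str, result: TraversalResult) -> dict[str, Any]:
    return {
        "specimen_id": specimen_id,
        "outcomes": list(result.outcomes),
        "ambiguous": result.ambiguous,
        "path": [{"couplet": c, "lead": label, "text": text}
                 for c, label, text in result.path],
        "consulted": sorted(result.consulted),
        "warnings": list(result.warnings),
    }


def write_identification_report(
    results: Sequence[tuple[str, TraversalResult]],
    path: str | Path,
    output_format: str = "json",
    allow_empty: bool = False,
) -> None:
    """Serialize key-traversal results.

    ``json`` round-trips losslessly (sorted keys, fixed separators);
    ``csv`` is one row per specimen; ``text`` prints the decision path
    with the verbatim lead texts.
    """
    if not results and not allow_empty:
        raise ValidationError("refusing to write an empty report (pass allow_empty)")
    path = Path(path)
    if output_format == "json":
        payload = [_result_to_dict(sid, r) for sid, r in results]
        path.write_text(
            json.dumps(payload, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
            encoding="utf-8")
    elif output_format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["specimen_id", "outcomes", "ambiguous", "path", "warnings"])
            for sid, r in results:
                writer.writerow([
                    sid,
                    "|".join(r.outcomes),
                    "true" if r.ambiguous else "false",
                    ">".join(f"{c}{label}" for c, label, _ in r.path),
                    "|".join(r.warnings),
                ])
    elif output_format == "text":
        buf = _io.StringIO()
        for sid, r in results:
            buf.write(f"specimen {sid}\n")
            for c, label, text in r.path:
                buf.write(f"  couplet {c}{label}: {text}\n")
            outcome = " | ".join(r.outcomes) if r.outcomes else "(no outcome)"
            flag = " (ambiguous)" if r.ambiguous else ""
            buf.write(f"  -> {outcome}{flag}\n")
            for w in r.warnings:
                buf.write(f"  warning: {w}\n")
        path.write_text(buf.getvalue(), encoding="utf-8")
    else:
        raise ValidationError(f"unknown report format {output_format!r}")
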