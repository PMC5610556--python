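"""Checklist of Indian *Tetramorium*, species-group diagnoses, and
specimen-to-species matching against type-series measurement ranges.

The checklist (42 valid + 2 excluded records) and the worker
measurement ranges of the two recently described species ship as
packaged data; only those two species carry ranges, so every other
species is reported ``not_checkable`` by :func:`match_specimen` rather
than being scored against guessed ranges.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Any, Iterable, Iterator, Mapping

from . import keys as keys_mod
from .errors import ValidationError
from .measurements import (
    INDEX_DEFINITIONS,
    INDEX_FIELDS,
    MeasurementRange,
    MeasurementSet,
    compute_indices,
    index_interval,
)

__all__ = [
    "SpeciesRecord",
    "SpeciesDatabase",
    "GroupDiagnosis",
    "FaunaSummary",
    "SpeciesMatch",
    "MatchResult",
    "load_species_table",
    "load_group_diagnoses",
    "fauna_summary",
    "apply_diagnosis",
    "match_specimen",
]

NAMED_GROUPS = (
    "angulinode", "bicarinatum", "caespitum", "ciliatum", "fergusoni",
    "inglebyi", "melleum", "mixtum", "obesum", "simillimum", "tonganum",
    "tortuosum", "walshi",
)


@dataclass(frozen=True)
class SpeciesRecord:
    species: str
    authority: str
    species_group: str  # one of NAMED_GROUPS or "unclear"
    endemic: bool
    exotic: bool
    status: str  # valid | excluded
    exclusion_reason: str = ""
    comments: str = ""
    measurement_range: MeasurementRange | None = None
    indices_printed: dict[str, tuple[float, ...]] | None = None
    type_locality: dict[str, float] | None = None
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in ("valid", "excluded"):
            raise ValidationError(
                f"{self.species}: status must be valid|excluded, got {self.status!r}")
        if self.status == "excluded" and not self.exclusion_reason:
            raise ValidationError(f"{self.species}: excluded without exclusion_reason")
        if self.endemic and self.exotic:
            raise ValidationError(f"{self.species}: cannot be both endemic and exotic")
        if self.species_group not in NAMED_GROUPS + ("unclear",):
            raise ValidationError(
                f"{self.species}: unknown species group {self.species_group!r}")


class SpeciesDatabase:
    """Immutable collection of checklist records, keyed by epithet+status."""

    def __init__(self, records: Iterable[SpeciesRecord]):
        self._records = tuple(records)

    def __iter__(self) -> Iterator[SpeciesRecord]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def get(self, species: str, status: str = "valid") -> SpeciesRecord:
        for r in self._records:
            if r.species == species and r.status == status:
                return r
        raise KeyError(f"no {status} record for species {species!r}")

    @property
    def valid(self) -> tuple[SpeciesRecord, ...]:
        return tuple(r for r in self._records if r.status == "valid")

    @property
    def excluded(self) -> tuple[SpeciesRecord, ...]:
        return tuple(r for r in self._records if r.status == "excluded")

    def with_ranges(self) -> tuple[SpeciesRecord, ...]:
        return tuple(r for r in self.valid if r.measurement_range is not None)


@dataclass(frozen=True)
class GroupDiagnosis:
    group: str
    predicate: Any  # keys._Predicate over the species-group key's characters
    template: dict[str, Any]
    applicability_note: str = ""


@dataclass(frozen=True)
class FaunaSummary:
    n_species_valid: int
    n_endemic: int
    n_exotic: int
    n_excluded: int
    n_named_groups: int
    endemism_rate_percent: int

    def as_dict(self) -> dict[str, int]:
        return {
            "n_species_valid": self.n_species_valid,
            "n_endemic": self.n_endemic,
            "n_exotic": self.n_exotic,
            "n_excluded": self.n_excluded,
            "n_named_groups": self.n_named_groups,
            "endemism_rate_percent": self.endemism_rate_percent,
        }


@dataclass(frozen=True)
class SpeciesMatch:
    species: str
    verdicts: dict[str, str]  # index -> in_range | out_of_range | not_checkable
    score: float | None  # None when nothing was checkable
    n_checkable: int

    @property
    def checkable(self) -> bool:
        return self.n_checkable > 0

    @property
    def failed_indices(self) -> tuple[str, ...]:
        return tuple(i for i in INDEX_FIELDS if self.verdicts.get(i) == "out_of_range")


@dataclass(frozen=True)
class MatchResult:
    candidates: tuple[SpeciesMatch, ...]  # scored first (desc), ties alphabetical
    halfwidth: float
    unexplained_indices: tuple[str, ...] = ()

    def best(self) -> SpeciesMatch | None:
        scored = [c for c in self.candidates if c.score is not None]
        return scored[0] if scored else None

    def __getitem__(self, species: str) -> SpeciesMatch:
        for c in self.candidates:
            if c.species == species:
                return c
        raise KeyError(species)


def _parse_flag(raw: str, where: str) -> bool:
    v = raw.strip().lower()
    if v in ("yes", "true", "1"):
        return True
    if v in ("no", "false", "0", ""):
        return False
    raise ValidationError(f"{where}: bad boolean flag {raw!r}")


def load_species_table() -> SpeciesDatabase:
    """Load the packaged checklist and attach measurement ranges to the
    species that have published type-series ranges."""
    data = resources.files("tetrakey.data")
    ranges = json.loads((data / "species_ranges.json").read_text(encoding="utf-8"))

    records: list[SpeciesRecord] = []
    text = (data / "species_checklist.csv").read_text(encoding="utf-8")
    reader = csv.DictReader(text.splitlines())
    expected = ["species_group", "species", "authority", "endemic", "exotic",
                "status", "exclusion_reason", "comments"]
    if reader.fieldnames != expected:
        raise ValidationError(
            f"species table header mismatch: {reader.fieldnames} != {expected}")
    for i, row in enumerate(reader, start=2):
        where = f"species table row {i} ({row.get('species')})"
        species = row["species"].strip()
        if not species:
            raise ValidationError(f"{where}: empty species epithet")
        extra = ranges.get(species, {})
        mrange = None
        indices_printed = None
        if extra and row["status"].strip() == "valid":
            holotype = MeasurementSet.from_dict(
                {k: v[2] for k, v in extra["measurements_mm"].items()},
                recorded_decimals=2)
            mrange = MeasurementRange(
                measurements={k: (v[0], v[1]) for k, v in extra["measurements_mm"].items()},
                n=extra["n"],
                holotype=holotype,
            )
            indices_printed = {k: tuple(v) for k, v in extra["indices_printed"].items()}
        records.append(SpeciesRecord(
            species=species,
            authority=row["authority"].strip(),
            species_group=row["species_group"].strip(),
            endemic=_parse_flag(row["endemic"], where),
            exotic=_parse_flag(row["exotic"], where),
            status=row["status"].strip(),
            exclusion_reason=row["exclusion_reason"].strip(),
            comments=row["comments"].strip(),
            measurement_range=mrange,
            indices_printed=indices_printed,
            type_locality=extra.get("type_locality"),
            notes=tuple(extra.get("notes", ())),
        ))
    return SpeciesDatabase(records)


def load_group_diagnoses() -> dict[str, GroupDiagnosis]:
    """Species-group diagnoses as predicates (and full canonical state
    templates) over the species-group key's character vocabulary."""
    data = resources.files("tetrakey.data")
    doc = json.loads((data / "group_diagnoses.json").read_text(encoding="utf-8"))
    key = keys_mod.load_key(doc["key_id"])
    out: dict[str, GroupDiagnosis] = {}
    for group, entry in doc["groups"].items():
        predicate = keys_mod._parse_predicate(
            entry["predicate"], key.characters, f"diagnosis {group}")
        template = dict(keys_mod.StateVector(key, entry["template"]))
        missing = set(key.characters) - set(template)
        if missing:
            raise ValidationError(f"diagnosis {group}: template missing {sorted(missing)}")
        out[group] = GroupDiagnosis(
            group=group,
            predicate=predicate,
            template=template,
            applicability_note=entry.get("applicability_note", ""),
        )
    return out


def diagnosis_notes() -> tuple[str, ...]:
    doc = json.loads((resources.files("tetrakey.data") / "group_diagnoses.json"
                      ).read_text(encoding="utf-8"))
    return tuple(doc.get("notes", ()))


def _round_half_away(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def fauna_summary(db: SpeciesDatabase) -> FaunaSummary:
    """Checklist totals; the endemism rate is rounded half away from
    zero to an integer percentage."""
    if len(db) == 0:
        raise ValidationError("empty species database")
    valid = db.valid
    n_valid = len(valid)
    n_endemic = sum(r.endemic for r in valid)
    return FaunaSummary(
        n_species_valid=n_valid,
        n_endemic=n_endemic,
        n_exotic=sum(r.exotic for r in valid),
        n_excluded=len(db.excluded),
        n_named_groups=len({r.species_group for r in valid} - {"unclear"}),
        endemism_rate_percent=_round_half_away(100.0 * n_endemic / n_valid),
    )


def apply_diagnosis(
    sv: Mapping[str, Any],
    diagnoses: Mapping[str, GroupDiagnosis],
    key: keys_mod.DichotomousKey | None = None,
) -> frozenset[str]:
    """Groups whose diagnosis remains satisfiable given the observed
    states; unknown characters are treated permissively."""
    if key is None:
        key = keys_mod.load_key("india_species_groups")
    sv = keys_mod.StateVector(key, dict(sv))
    constraints = {}
    for cid, cd in key.characters.items():
        value = sv.get(cid, keys_mod.UNKNOWN)
        constraints[cid] = (frozenset(cd.domain_values()) if value is keys_mod.UNKNOWN
                            else frozenset({value}))
    hits = set()
    for group, diag in diagnoses.items():
        if diag.predicate.constrain(constraints, key.characters) is not None:
            hits.add(group)
    return frozenset(hits)


def match_specimen(
    m: MeasurementSet,
    db: SpeciesDatabase,
    halfwidth: float = 0.005,
) -> MatchResult:
    """Score a specimen against every species that has published
    measurement ranges.

    Each index computable from the specimen is tested for membership in
    the species' feasible index interval (range endpoints widened by
    ``halfwidth``); the score is the fraction of checkable indices in
    range.  Species without ranges are reported ``not_checkable``.
    """
    raw = compute_indices(m)
    candidates: list[SpeciesMatch] = []
    for record in db.valid:
        verdicts: dict[str, str] = {}
        n_in = n_checked = 0
        for index in INDEX_FIELDS:
            num, den = INDEX_DEFINITIONS[index]
            value = raw[index]
            r = record.measurement_range
            if value is None or r is None or num not in r or den not in r:
                verdicts[index] = "not_checkable"
                continue
            feasible = index_interval(r, num, den, halfwidth)
            n_checked += 1
            if value in feasible:
                verdicts[index] = "in_range"
                n_in += 1
            else:
                verdicts[index] = "out_of_range"
        candidates.append(SpeciesMatch(
            species=record.species,
            verdicts=verdicts,
            score=(n_in / n_checked) if n_checked else None,
            n_checkable=n_checked,
        ))
    # scored candidates first, descending; unscorable ones trail alphabetically
    candidates.sort(key=lambda c: (c.score is None, -(c.score or 0.0), c.species))
    unexplained = tuple(
        i for i in INDEX_FIELDS
        if raw[i] is not None and all(c.verdicts.get(i) == "not_checkable"
                                      for c in candidates))
    return MatchResult(
        candidates=tuple(candidates),
        halfwidth=halfwidth,
        unexplained_indices=unexplained if candidates else tuple(raw.present()),
    )
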