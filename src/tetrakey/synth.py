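"""Seeded generators for specimen tables and character-state vectors
with known ground truth.

Measurements are sampled independently per field inside the published
type-series ranges (uniform, or normal truncated to the range with
sd = range/4).  This ignores real allometric correlation between body
parts — acceptable here because the fixtures exercise interval logic,
not biology.

Out-of-range rows displace exactly one named measurement above its
range maximum.  The displacement is the larger of the requested
magnitude (a fraction of the range width) and the smallest displacement
that provably pushes at least one index of the perturbed field outside
the species' halfwidth-widened feasible interval, so every perturbed
specimen is detectable by the matcher.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
from scipy import stats

from . import keys as keys_mod
from .errors import ValidationError
from .io import Specimen, write_specimen_csv, write_state_csv
from .measurements import (
    INDEX_DEFINITIONS,
    MeasurementRange,
    MeasurementSet,
)
from .species import GroupDiagnosis, SpeciesDatabase, load_group_diagnoses, load_species_table

__all__ = [
    "GeneratorSpec",
    "index_family",
    "min_detectable_displacement",
    "generate_specimens",
    "generate_state_vectors",
]

_DISTRIBUTIONS = ("uniform", "truncated_normal")
#: Safety margin (mm) added on top of the provable displacement bound.
_DISPLACEMENT_MARGIN = 0.002


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic batch; a fixed seed gives
    byte-identical output."""

    target: str  # species epithet (specimens) or group name (state vectors)
    n: int
    distribution: str = "uniform"
    out_of_range_fraction: float = 0.0
    perturbation_magnitude: float = 0.5  # fraction of range width
    unknown_rate: float = 0.0
    halfwidth: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError(f"n must be >= 0, got {self.n}")
        if self.distribution not in _DISTRIBUTIONS:
            raise ValidationError(
                f"distribution must be one of {_DISTRIBUTIONS}, got {self.distribution!r}")
        for name in ("out_of_range_fraction", "unknown_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.perturbation_magnitude < 0:
            raise ValidationError("perturbation_magnitude must be >= 0")
        if not (isinstance(self.seed, int) and self.seed >= 0):
            raise ValidationError(f"seed must be a nonnegative integer, got {self.seed!r}")


def index_family(field: str) -> tuple[str, ...]:
    """Indices whose numerator or denominator is the given measurement."""
    return tuple(i for i, (num, den) in INDEX_DEFINITIONS.items()
                 if field in (num, den))


def min_detectable_displacement(r: MeasurementRange, field: str,
                                halfwidth: float) -> float:
    """Smallest upward displacement of ``field`` beyond its range max
    that forces some index of its family out of the widened feasible
    interval for every in-range choice of the partner measurement.

    For an index with perturbed side f and partner g (f/g or g/f alike)
    the worst case requires
    ``f_new > g_max * (f_max + h) / (g_min - h)``.
    """
    f_lo, f_hi = r[field]
    best = math.inf
    for idx in index_family(field):
        num, den = INDEX_DEFINITIONS[idx]
        partner = den if num == field else num
        if partner not in r:
            continue
        g_lo, g_hi = r[partner]
        if g_lo - halfwidth <= 0:
            continue
        needed = g_hi * (f_hi + halfwidth) / (g_lo - halfwidth) - f_hi
        best = min(best, needed)
    if not math.isfinite(best):
        raise ValidationError(
            f"no index family member of {field} allows a detectable perturbation")
    return max(best, 0.0)


def _sample_in_range(rng: np.random.Generator, r: MeasurementRange,
                     distribution: str) -> dict[str, float]:
    values: dict[str, float] = {}
    for field_name in sorted(r.measurements):
        lo, hi = r[field_name]
        if hi == lo:
            v = lo
        elif distribution == "uniform":
            v = float(rng.uniform(lo, hi))
        else:
            mid, sd = (lo + hi) / 2.0, (hi - lo) / 4.0
            a, b = (lo - mid) / sd, (hi - mid) / sd
            v = float(stats.truncnorm.rvs(a, b, loc=mid, scale=sd, random_state=rng))
        # keep recorded precision; endpoints sit on the 3-decimal grid,
        # so rounding never leaves the closed range
        values[field_name] = round(v, 3)
    return values


def generate_specimens(
    spec: GeneratorSpec,
    out_dir: str | Path | None = None,
    db: SpeciesDatabase | None = None,
) -> tuple[list[Specimen], list[dict[str, Any]]]:
    """Sample specimen measurement rows for a species with published
    ranges; returns (specimens, ground-truth rows) and optionally
    writes ``specimens.csv`` + ``truth.csv`` under ``out_dir``."""
    if db is None:
        db = load_species_table()
    with_ranges = {rec.species: rec for rec in db.with_ranges()}
    if spec.target not in with_ranges:
        raise ValidationError(
            f"species {spec.target!r} has no packaged measurement ranges; "
            f"available: {sorted(with_ranges)}")
    r = with_ranges[spec.target].measurement_range
    rng = np.random.default_rng(spec.seed)

    n_perturbed = int(round(spec.n * spec.out_of_range_fraction))
    perturbed_rows = set(
        map(int, rng.choice(spec.n, size=n_perturbed, replace=False))
    ) if n_perturbed else set()
    fields = sorted(r.measurements)

    specimens: list[Specimen] = []
    truth: list[dict[str, Any]] = []
    for i in range(spec.n):
        values = _sample_in_range(rng, r, spec.distribution)
        perturbed_field = ""
        if i in perturbed_rows:
            perturbed_field = fields[int(rng.integers(len(fields)))]
            lo, hi = r[perturbed_field]
            width = hi - lo
            delta = max(
                spec.perturbation_magnitude * width,
                min_detectable_displacement(r, perturbed_field, spec.halfwidth)
                + _DISPLACEMENT_MARGIN,
            )
            values[perturbed_field] = math.ceil((hi + delta) * 1000) / 1000
        specimen_id = f"{spec.target}-synth-{i:05d}"
        specimens.append(Specimen(
            specimen_id=specimen_id,
            taxon_hint=spec.target,
            measurements=MeasurementSet.from_dict(values),
        ))
        truth.append({
            "specimen_id": specimen_id,
            "species": spec.target,
            "in_range": not perturbed_field,
            "perturbed_field": perturbed_field,
        })

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_specimen_csv(specimens, out_dir / "specimens.csv")
        _write_truth(truth, ["specimen_id", "species", "in_range", "perturbed_field"],
                     out_dir / "truth.csv")
    return specimens, truth


def generate_state_vectors(
    spec: GeneratorSpec,
    out_dir: str | Path | None = None,
    diagnoses: Mapping[str, GroupDiagnosis] | None = None,
) -> tuple[list[tuple[str, dict[str, Any]]], list[dict[str, Any]]]:
    """Sample state vectors from a species group's diagnosis template,
    masking each character to UNKNOWN with probability ``unknown_rate``.

    With ``unknown_rate`` 0 every vector traverses the species-group
    key to the target group; with masking, the target group is always
    among the partial-traversal outcomes.
    """
    if diagnoses is None:
        diagnoses = load_group_diagnoses()
    if spec.target not in diagnoses:
        raise ValidationError(
            f"no encoded diagnosis for group {spec.target!r}; "
            f"available: {sorted(diagnoses)}")
    template = diagnoses[spec.target].template
    key = keys_mod.load_key("india_species_groups")
    rng = np.random.default_rng(spec.seed)

    rows: list[tuple[str, dict[str, Any]]] = []
    truth: list[dict[str, Any]] = []
    for i in range(spec.n):
        sv: dict[str, Any] = {}
        for char in sorted(template):
            masked = spec.unknown_rate > 0 and rng.random() < spec.unknown_rate
            sv[char] = keys_mod.UNKNOWN if masked else template[char]
        specimen_id = f"{spec.target}-states-{i:05d}"
        rows.append((specimen_id, sv))
        truth.append({"specimen_id": specimen_id, "group": spec.target})

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_state_csv(rows, key, out_dir / "states.csv")
        _write_truth(truth, ["specimen_id", "group"], out_dir / "truth.csv")
    return rows, truth


def _write_truth(rows: list[dict[str, Any]], columns: list[str], path: Path) -> None:
    import csv

    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(columns)
        for row in rows:
            writer.writerow(
                [("true" if v else "false") if isinstance(v, bool) else str(v)
                 for v in (row[c] for c in columns)])
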