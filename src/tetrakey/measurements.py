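"""Worker morphometrics: linear measurements, ratio indices, and
rounding-aware interval arithmetic.

Fourteen linear measurements (in mm) are taken per worker specimen and
thirteen dimensionless indices are derived from them, each an
index = numerator/denominator x 100.  Published values are printed at a
coarser precision than they were recorded at, so recomputing an index
from printed measurements does not generally reproduce the printed
index.  This module therefore works with *feasible intervals*: the set
of index values attainable when every printed measurement is allowed to
move by the half-width of its last printed decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterator, Mapping

from .errors import ValidationError

__all__ = [
    "MEASUREMENT_FIELDS",
    "INDEX_DEFINITIONS",
    "INDEX_FIELDS",
    "MeasurementSet",
    "IndexSet",
    "MeasurementRange",
    "IndexInterval",
    "IndexVerdict",
    "ConsistencyReport",
    "compute_indices",
    "round_index",
    "format_index",
    "printed_band",
    "index_interval",
    "consistency_check",
]

#: Measurement abbreviations in canonical (recording) order.
MEASUREMENT_FIELDS: tuple[str, ...] = (
    "HL", "HW", "SL", "EL", "PH", "PW", "WL",
    "PSL", "PTH", "PTL", "PTW", "PPH", "PPL", "PPW",
)

#: index -> (numerator measurement, denominator measurement)
INDEX_DEFINITIONS: dict[str, tuple[str, str]] = {
    "OI": ("EL", "HW"),
    "CI": ("HW", "HL"),
    "SI": ("SL", "HW"),
    "DMI": ("PW", "WL"),
    "LMI": ("PH", "WL"),
    "PSLI": ("PSL", "HL"),
    "PeNI": ("PTW", "PW"),
    "LPeI": ("PTL", "PTH"),
    "DPeI": ("PTW", "PTL"),
    "PpNI": ("PPW", "PW"),
    "LPpI": ("PPL", "PPH"),
    "DPpI": ("PPW", "PPL"),
    "PPI": ("PPW", "PTW"),
}

INDEX_FIELDS: tuple[str, ...] = tuple(INDEX_DEFINITIONS)

#: Default rounding half-width (mm) for values printed at two decimals.
DEFAULT_HALFWIDTH = 0.005


def _check_measurement(name: str, value: float | None) -> float | None:
    if value is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"measurement {name}: not a number: {value!r}")
    if not math.isfinite(v):
        raise ValidationError(f"measurement {name}: not finite: {value!r}")
    if v <= 0:
        raise ValidationError(f"measurement {name}: must be > 0 mm, got {v}")
    return v


@dataclass(frozen=True)
class MeasurementSet:
    """The 14 linear measurements of a single worker, in mm.

    Any subset may be absent (``None``); derived indices then come out
    absent rather than raising.  ``recorded_decimals`` records the
    precision the values were taken at (2 or 3 decimal places).
    """

    HL: float | None = None
    HW: float | None = None
    SL: float | None = None
    EL: float | None = None
    PH: float | None = None
    PW: float | None = None
    WL: float | None = None
    PSL: float | None = None
    PTH: float | None = None
    PTL: float | None = None
    PTW: float | None = None
    PPH: float | None = None
    PPL: float | None = None
    PPW: float | None = None
    recorded_decimals: int = 3

    def __post_init__(self) -> None:
        if self.recorded_decimals not in (2, 3):
            raise ValidationError(
                f"recorded_decimals must be 2 or 3, got {self.recorded_decimals}"
            )
        for name in MEASUREMENT_FIELDS:
            object.__setattr__(self, name, _check_measurement(name, getattr(self, name)))

    def __getitem__(self, name: str) -> float | None:
        if name not in MEASUREMENT_FIELDS:
            raise KeyError(name)
        return getattr(self, name)

    def present(self) -> tuple[str, ...]:
        return tuple(m for m in MEASUREMENT_FIELDS if getattr(self, m) is not None)

    def as_dict(self) -> dict[str, float | None]:
        return {m: getattr(self, m) for m in MEASUREMENT_FIELDS}

    @classmethod
    def from_dict(cls, values: Mapping[str, float | None], recorded_decimals: int = 3
                  ) -> "MeasurementSet":
        unknown = set(values) - set(MEASUREMENT_FIELDS)
        if unknown:
            raise ValidationError(f"unknown measurement field(s): {sorted(unknown)}")
        return cls(recorded_decimals=recorded_decimals,
                   **{k: values.get(k) for k in MEASUREMENT_FIELDS})


@dataclass(frozen=True)
class IndexSet:
    """Raw (unrounded) ratio indices of one specimen, on the x100 scale."""

    values: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(INDEX_FIELDS)
        if unknown:
            raise ValidationError(f"unknown index field(s): {sorted(unknown)}")

    def __getitem__(self, name: str) -> float | None:
        if name not in INDEX_FIELDS:
            raise KeyError(name)
        return self.values.get(name)

    def __iter__(self) -> Iterator[str]:
        return iter(INDEX_FIELDS)

    def present(self) -> tuple[str, ...]:
        return tuple(i for i in INDEX_FIELDS if self.values.get(i) is not None)

    def reported(self) -> dict[str, float | None]:
        """All indices passed through the reporting-rounding rule."""
        return {i: (None if self[i] is None else round_index(self[i]))
                for i in INDEX_FIELDS}


@dataclass(frozen=True)
class MeasurementRange:
    """Closed per-measurement intervals [min, max] for a type series."""

    measurements: dict[str, tuple[float, float]]
    n: int = 1
    holotype: MeasurementSet | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"sample size N must be >= 1, got {self.n}")
        for name, (lo, hi) in self.measurements.items():
            if name not in MEASUREMENT_FIELDS:
                raise ValidationError(f"unknown measurement field: {name}")
            if not (0 < lo <= hi):
                raise ValidationError(
                    f"range for {name} must satisfy 0 < min <= max, got [{lo}, {hi}]")
            if self.holotype is not None:
                point = self.holotype[name]
                if point is not None and not (lo <= point <= hi):
                    raise ValidationError(
                        f"holotype {name}={point} outside range [{lo}, {hi}]")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.measurements[name]

    def __contains__(self, name: str) -> bool:
        return name in self.measurements

    @classmethod
    def from_point(cls, m: MeasurementSet) -> "MeasurementRange":
        vals = {k: (v, v) for k, v in m.as_dict().items() if v is not None}
        return cls(measurements=vals, n=1, holotype=m)


@dataclass(frozen=True)
class IndexInterval:
    """Closed feasible interval [lo, hi] of an index, x100 scale."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi):
            raise ValidationError(f"bad index interval [{self.lo}, {self.hi}]")

    def __contains__(self, value: float) -> bool:
        return self.lo <= value <= self.hi

    def intersects(self, lo: float, hi: float) -> bool:
        return lo <= self.hi and hi >= self.lo

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass(frozen=True)
class IndexVerdict:
    index: str
    verdict: str  # consistent | inconsistent | not_checkable
    feasible: IndexInterval | None = None
    printed: tuple[float, ...] = ()


@dataclass(frozen=True)
class ConsistencyReport:
    verdicts: dict[str, IndexVerdict]
    halfwidth: float

    def __getitem__(self, index: str) -> IndexVerdict:
        return self.verdicts[index]

    @property
    def all_consistent(self) -> bool:
        checked = [v for v in self.verdicts.values() if v.verdict != "not_checkable"]
        return bool(checked) and all(v.verdict == "consistent" for v in checked)

    def counts(self) -> dict[str, int]:
        out = {"consistent": 0, "inconsistent": 0, "not_checkable": 0}
        for v in self.verdicts.values():
            out[v.verdict] += 1
        return out


def compute_indices(m: MeasurementSet) -> IndexSet:
    """Compute all 13 raw indices; an index is absent iff its numerator
    or denominator measurement is absent."""
    values: dict[str, float | None] = {}
    for index, (num, den) in INDEX_DEFINITIONS.items():
        a, b = m[num], m[den]
        values[index] = None if a is None or b is None else 100.0 * a / b
    return IndexSet(values=values)


def round_index(raw: float) -> float:
    """Apply the reporting-precision rule to a raw index value.

    The value is first rounded half-away-from-zero to the nearest
    integer; if that integer is >= 10 it is the reported value,
    otherwise the raw value is reported at one decimal place (again
    half away from zero).  This reproduces every printed index format
    in the type-series tables, including small values such as 3.2 and
    borderline values whose integer rounding crosses 10.
    """
    try:
        v = float(raw)
    except (TypeError, ValueError):
        raise ValidationError(f"index value not a number: {raw!r}")
    if not math.isfinite(v) or v < 0:
        raise ValidationError(f"index value must be finite and >= 0, got {raw!r}")
    d = Decimal(repr(v))
    as_int = d.quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    if as_int >= 10:
        return float(as_int)
    return float(d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def format_index(raw: float) -> str:
    """Reported value as it would be printed (``"126"`` or ``"3.2"``)."""
    v = round_index(raw)
    if float(v).is_integer() and v >= 10:
        return str(int(v))
    return f"{v:.1f}"


def printed_band(printed: float) -> tuple[float, float]:
    """Closed rounding band of a printed index value.

    Integer-formatted values carry +/-0.5, one-decimal values +/-0.05.
    """
    if printed < 0:
        raise ValidationError(f"printed index must be >= 0, got {printed}")
    half = 0.5 if float(printed).is_integer() else 0.05
    return printed - half, printed + half


def index_interval(
    r: MeasurementRange | MeasurementSet,
    numerator: str,
    denominator: str,
    rounding_halfwidth: float = DEFAULT_HALFWIDTH,
) -> IndexInterval:
    """Feasible [lo, hi] of 100*num/den with both measurements allowed
    to move by +/-``rounding_halfwidth`` around their recorded range.

    The ratio of positives is monotone increasing in the numerator and
    decreasing in the denominator, so the bounds are attained at the
    endpoint combinations.
    """
    if rounding_halfwidth < 0:
        raise ValidationError(f"rounding halfwidth must be >= 0, got {rounding_halfwidth}")
    if isinstance(r, MeasurementSet):
        r = MeasurementRange.from_point(r)
    for name in (numerator, denominator):
        if name not in r:
            raise ValidationError(f"measurement {name} absent from range")
    n_lo, n_hi = r[numerator]
    d_lo, d_hi = r[denominator]
    h = rounding_halfwidth
    if d_lo - h <= 0:
        raise ValidationError(
            f"denominator {denominator} interval reaches <= 0 after widening by {h}")
    lo = 100.0 * max(n_lo - h, 0.0) / (d_hi + h)
    hi = 100.0 * (n_hi + h) / (d_lo - h)
    return IndexInterval(lo=lo, hi=hi)


def consistency_check(
    printed: Mapping[str, float | tuple[float, ...] | None],
    r: MeasurementRange | MeasurementSet,
    rounding_halfwidth: float = DEFAULT_HALFWIDTH,
) -> ConsistencyReport:
    """Check printed index values (points or (min, max[, holotype])
    tuples) against the feasible intervals of a measurement range.

    A printed value is *consistent* iff its own rounding band
    intersects the feasible interval; a range is consistent iff every
    printed endpoint is.  Missing measurements or missing printed
    values give ``not_checkable``.
    """
    if isinstance(r, MeasurementSet):
        r = MeasurementRange.from_point(r)
    verdicts: dict[str, IndexVerdict] = {}
    for index in INDEX_FIELDS:
        num, den = INDEX_DEFINITIONS[index]
        p = printed.get(index)
        if p is None or num not in r or den not in r:
            verdicts[index] = IndexVerdict(index=index, verdict="not_checkable")
            continue
        points = tuple(float(x) for x in (p if isinstance(p, (tuple, list)) else (p,)))
        feasible = index_interval(r, num, den, rounding_halfwidth)
        ok = all(feasible.intersects(*printed_band(pt)) for pt in points)
        verdicts[index] = IndexVerdict(
            index=index,
            verdict="consistent" if ok else "inconsistent",
            feasible=feasible,
            printed=points,
        )
    return ConsistencyReport(verdicts=verdicts, halfwidth=rounding_halfwidth)
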