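"""Dichotomous identification keys as data, plus deterministic and
partial-knowledge traversal.

A key is an ordered set of numbered couplets, each offering exactly two
leads; a lead either jumps to another couplet (GOTO) or names a
terminal taxon/group.  Lead predicates are small boolean expressions
over a controlled character vocabulary declared in the key file, so the
mapping from prose to logic is editable data, not code.

Three keys ship with the package (``PACKAGED_KEYS``); arbitrary key
files in the same JSON format can be loaded by path.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping

from .errors import AmbiguousState, KeyConflict, KeyStructureError, ValidationError

__all__ = [
    "PACKAGED_KEYS",
    "UNKNOWN",
    "CharacterDefinition",
    "StateVector",
    "Lead",
    "Couplet",
    "DichotomousKey",
    "KeyDiagnostics",
    "TraversalResult",
    "load_key",
    "validate_key",
    "traverse",
    "traverse_partial",
]

PACKAGED_KEYS = ("india_species_groups", "inglebyi_group", "tonganum_group")

#: Sentinel for an unobserved character state.
UNKNOWN = None

_COMPARE_OPS = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "in": lambda a, b: a in b,
    "not_in": lambda a, b: a not in b,
    "le": lambda a, b: a <= b,
    "lt": lambda a, b: a < b,
    "ge": lambda a, b: a >= b,
    "gt": lambda a, b: a > b,
}


@dataclass(frozen=True)
class CharacterDefinition:
    """One observable character: its kind, legal states, and provenance."""

    character_id: str
    kind: str  # categorical | boolean | count | quantitative
    states: tuple = ()
    domain: tuple[float, float] | None = None  # for count/quantitative
    description: str = ""
    figure: str = ""
    gap_states: tuple = ()  # states that satisfy neither lead of some couplet

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "boolean", "count", "quantitative"):
            raise KeyStructureError(
                f"character {self.character_id}: unknown kind {self.kind!r}")
        if self.kind == "categorical" and not self.states:
            raise KeyStructureError(
                f"character {self.character_id}: categorical without states")
        if self.kind in ("count", "quantitative"):
            if self.domain is None or not self.domain[0] < self.domain[1]:
                raise KeyStructureError(
                    f"character {self.character_id}: numeric domain must have lo < hi")
        bad = set(self.gap_states) - set(self.states)
        if bad:
            raise KeyStructureError(
                f"character {self.character_id}: gap states not in states: {bad}")

    @property
    def enumerable(self) -> bool:
        return self.kind in ("categorical", "boolean", "count")

    def domain_values(self) -> tuple:
        """All legal values, for enumerable kinds."""
        if self.kind == "categorical":
            return tuple(self.states)
        if self.kind == "boolean":
            return (True, False)
        if self.kind == "count":
            lo, hi = self.domain
            return tuple(range(int(lo), int(hi) + 1))
        raise KeyStructureError(
            f"character {self.character_id}: quantitative domain is not enumerable")

    def validate_value(self, value: Any) -> Any:
        if self.kind == "quantitative":
            v = float(value)
            lo, hi = self.domain
            if not lo <= v <= hi:
                raise ValidationError(
                    f"{self.character_id}={value!r} outside domain [{lo}, {hi}]")
            return v
        allowed = self.domain_values()
        if value not in allowed:
            raise ValidationError(
                f"{self.character_id}={value!r} not in {allowed}")
        return value


class _Predicate:
    """Conjunction/disjunction expression over characters."""

    def chars(self) -> frozenset[str]:
        raise NotImplementedError

    def evaluate(self, sv: Mapping[str, Any]) -> bool:
        raise NotImplementedError

    def per_char_allowed(self, characters: Mapping[str, CharacterDefinition]
                         ) -> dict[str, frozenset]:
        """Allowed value set per mentioned character.

        Exact for the grammar enforced at parse time: conjunctions of
        single-character atoms, and disjunctions restricted to atoms on
        one character.
        """
        raise NotImplementedError

    def constrain(self, constraints: Mapping[str, frozenset],
                  characters: Mapping[str, CharacterDefinition]
                  ) -> dict[str, frozenset] | None:
        """Intersect a char->allowed-set map with this predicate;
        ``None`` if unsatisfiable."""
        out = dict(constraints)
        for char, allowed in self.per_char_allowed(characters).items():
            narrowed = out[char] & allowed
            if not narrowed:
                return None
            out[char] = narrowed
        return out


@dataclass(frozen=True)
class _Atom(_Predicate):
    char: str
    op: str
    value: Any

    def chars(self) -> frozenset[str]:
        return frozenset({self.char})

    def evaluate(self, sv: Mapping[str, Any]) -> bool:
        observed = sv.get(self.char, UNKNOWN)
        if observed is UNKNOWN:
            raise AmbiguousState(
                f"character {self.char!r} is unknown", character=self.char, couplet=-1)
        return _COMPARE_OPS[self.op](observed, self.value)

    def per_char_allowed(self, characters):
        cd = characters[self.char]
        allowed = frozenset(v for v in cd.domain_values()
                            if _COMPARE_OPS[self.op](v, self.value))
        return {self.char: allowed}


@dataclass(frozen=True)
class _All(_Predicate):
    children: tuple[_Predicate, ...]

    def chars(self) -> frozenset[str]:
        return frozenset().union(*(c.chars() for c in self.children))

    def evaluate(self, sv):
        return all(c.evaluate(sv) for c in self.children)

    def per_char_allowed(self, characters):
        out: dict[str, frozenset] = {}
        for child in self.children:
            for char, allowed in child.per_char_allowed(characters).items():
                out[char] = out[char] & allowed if char in out else allowed
        return out


@dataclass(frozen=True)
class _Any(_Predicate):
    children: tuple[_Atom, ...]  # parse-time restriction: same char throughout

    def chars(self) -> frozenset[str]:
        return frozenset().union(*(c.chars() for c in self.children))

    def evaluate(self, sv):
        return any(c.evaluate(sv) for c in self.children)

    def per_char_allowed(self, characters):
        out: dict[str, frozenset] = {}
        for child in self.children:
            for char, allowed in child.per_char_allowed(characters).items():
                out[char] = out[char] | allowed if char in out else allowed
        return out


def _parse_predicate(node: Any, characters: Mapping[str, CharacterDefinition],
                     where: str) -> _Predicate:
    if not isinstance(node, Mapping):
        raise KeyStructureError(f"{where}: predicate must be an object, got {node!r}")
    if "all" in node:
        children = tuple(_parse_predicate(c, characters, where) for c in node["all"])
        if not children:
            raise KeyStructureError(f"{where}: empty 'all'")
        return _All(children)
    if "any" in node:
        children = tuple(_parse_predicate(c, characters, where) for c in node["any"])
        if not children:
            raise KeyStructureError(f"{where}: empty 'any'")
        if not all(isinstance(c, _Atom) for c in children) or \
                len({c.char for c in children}) != 1:
            raise KeyStructureError(
                f"{where}: 'any' must hold atoms on a single character")
        return _Any(children)
    for k in ("char", "op", "value"):
        if k not in node:
            raise KeyStructureError(f"{where}: atom missing {k!r}: {node!r}")
    char, op, value = node["char"], node["op"], node["value"]
    if char not in characters:
        raise KeyStructureError(f"{where}: undeclared character {char!r}")
    if op not in _COMPARE_OPS:
        raise KeyStructureError(f"{where}: unknown op {op!r}")
    if op in ("in", "not_in"):
        value = tuple(value)
    return _Atom(char=char, op=op, value=value)


@dataclass(frozen=True)
class Lead:
    text: str
    predicate: _Predicate
    goto: int | None = None
    terminal: str | None = None
    advisory: _Predicate | None = None

    def __post_init__(self) -> None:
        if (self.goto is None) == (self.terminal is None):
            raise KeyStructureError(
                f"lead {self.text!r}: exactly one of goto/terminal required")


@dataclass(frozen=True)
class Couplet:
    number: int
    leads: tuple[Lead, Lead]

    def __post_init__(self) -> None:
        if len(self.leads) != 2:
            raise KeyStructureError(
                f"couplet {self.number} must have exactly two leads",
                couplet=self.number)


@dataclass(frozen=True)
class DichotomousKey:
    key_id: str
    title: str
    characters: dict[str, CharacterDefinition]
    couplets: dict[int, Couplet]
    notes: tuple[str, ...] = ()

    def terminals(self) -> frozenset[str]:
        return frozenset(
            lead.terminal
            for c in self.couplets.values() for lead in c.leads
            if lead.terminal is not None)

    def full_domain(self) -> dict[str, frozenset]:
        return {cid: frozenset(cd.domain_values())
                for cid, cd in self.characters.items() if cd.enumerable}


class StateVector(dict):
    """Observed character states for one specimen, validated against a
    key's character table; missing/None entries mean UNKNOWN."""

    def __init__(self, key: DichotomousKey, states: Mapping[str, Any]):
        validated = {}
        for char, value in states.items():
            if char not in key.characters:
                raise ValidationError(f"undeclared character: {char!r}")
            if value is not UNKNOWN:
                value = key.characters[char].validate_value(value)
            validated[char] = value
        super().__init__(validated)
        self.key_id = key.key_id


@dataclass(frozen=True)
class TraversalResult:
    outcomes: tuple[str, ...]
    path: tuple[tuple[int, str, str], ...]  # (couplet, lead label A/B, lead text)
    ambiguous: bool
    consulted: frozenset[str]
    warnings: tuple[str, ...] = ()

    @property
    def outcome(self) -> str:
        if self.ambiguous:
            raise ValueError("ambiguous result has no single outcome")
        return self.outcomes[0]


def _key_from_dict(doc: Mapping[str, Any]) -> DichotomousKey:
    for req in ("key_id", "characters", "couplets"):
        if req not in doc:
            raise KeyStructureError(f"key file missing {req!r}")
    characters: dict[str, CharacterDefinition] = {}
    for c in doc["characters"]:
        cd = CharacterDefinition(
            character_id=c["id"],
            kind=c["kind"],
            states=tuple(c.get("states", ())),
            domain=tuple(c["domain"]) if c.get("domain") else None,
            description=c.get("description", ""),
            figure=c.get("figure", ""),
            gap_states=tuple(c.get("gap_states", ())),
        )
        if cd.character_id in characters:
            raise KeyStructureError(f"duplicate character id {cd.character_id!r}")
        characters[cd.character_id] = cd

    couplets: dict[int, Couplet] = {}
    for c in doc["couplets"]:
        number = c.get("number")
        if not isinstance(number, int) or number < 1:
            raise KeyStructureError(f"bad couplet number: {number!r}")
        if number in couplets:
            raise KeyStructureError(f"duplicate couplet {number}", couplet=number)
        raw_leads = c.get("leads", ())
        if len(raw_leads) != 2:
            raise KeyStructureError(
                f"couplet {number}: needs exactly 2 leads, got {len(raw_leads)}",
                couplet=number)
        leads = []
        for label, rl in zip("AB", raw_leads):
            where = f"couplet {number} lead {label}"
            pred = _parse_predicate(rl["predicate"], characters, where)
            advisory = (_parse_predicate(rl["advisory"], characters, where + " advisory")
                        if rl.get("advisory") else None)
            leads.append(Lead(
                text=rl.get("text", ""),
                predicate=pred,
                goto=rl.get("goto"),
                terminal=rl.get("terminal"),
                advisory=advisory,
            ))
        couplets[number] = Couplet(number=number, leads=tuple(leads))

    key = DichotomousKey(
        key_id=doc["key_id"],
        title=doc.get("title", ""),
        characters=characters,
        couplets=couplets,
        notes=tuple(doc.get("notes", ())),
    )
    _check_structure(key)
    return key


def _check_structure(key: DichotomousKey) -> None:
    if 1 not in key.couplets:
        raise KeyStructureError("key has no couplet 1")
    for couplet in key.couplets.values():
        for lead in couplet.leads:
            if lead.goto is not None and lead.goto not in key.couplets:
                raise KeyStructureError(
                    f"couplet {couplet.number}: GOTO nonexistent couplet {lead.goto}",
                    couplet=couplet.number)
    # acyclicity by DFS from couplet 1
    state: dict[int, int] = {}

    def visit(n: int, trail: tuple[int, ...]) -> None:
        if state.get(n) == 1:
            raise KeyStructureError(
                f"cycle through couplet {n}: {trail + (n,)}", couplet=n)
        if state.get(n) == 2:
            return
        state[n] = 1
        for lead in key.couplets[n].leads:
            if lead.goto is not None:
                visit(lead.goto, trail + (n,))
        state[n] = 2

    visit(1, ())


def load_key(key_id: str | Path) -> DichotomousKey:
    """Load a packaged key by id, or any key file in the same JSON
    format by path."""
    key_id = str(key_id)
    if key_id in PACKAGED_KEYS:
        text = (resources.files("tetrakey.data") / "keys" / f"{key_id}.json"
                ).read_text(encoding="utf-8")
    else:
        path = Path(key_id)
        if not path.exists():
            raise KeyStructureError(
                f"unknown key id (not one of {PACKAGED_KEYS}) and no such file: {key_id}")
        text = path.read_text(encoding="utf-8")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise KeyStructureError(f"key file is not valid JSON: {exc}") from exc
    return _key_from_dict(doc)


@dataclass(frozen=True)
class KeyDiagnostics:
    key_id: str
    n_couplets: int
    n_terminals: int
    unreachable: tuple[int, ...]
    tree_shaped: bool
    terminal_count_matches_tree: bool | None  # None when not tree-shaped
    warnings: tuple[str, ...]

    @property
    def structurally_sound(self) -> bool:
        return not self.unreachable and (self.terminal_count_matches_tree is not False)


def validate_key(key: DichotomousKey) -> KeyDiagnostics:
    """Structural diagnostics: reachability, tree shape/terminal count,
    and per-couplet overlap and gap warnings.

    Overlap: some assignment of the consulted characters satisfies both
    leads.  Gap: some assignment satisfies neither.  Both are checked
    by exhaustive enumeration over the (small) per-couplet domains.
    """
    reachable: set[int] = set()
    stack = [1]
    while stack:
        n = stack.pop()
        if n in reachable:
            continue
        reachable.add(n)
        for lead in key.couplets[n].leads:
            if lead.goto is not None:
                stack.append(lead.goto)
    unreachable = tuple(sorted(set(key.couplets) - reachable))

    indegree: dict[int, int] = {n: 0 for n in key.couplets}
    for couplet in key.couplets.values():
        for lead in couplet.leads:
            if lead.goto is not None:
                indegree[lead.goto] += 1
    tree_shaped = all(v <= 1 for n, v in indegree.items() if n != 1) and indegree[1] == 0
    n_terminals = len(key.terminals())
    terminal_count_ok = (n_terminals == len(key.couplets) + 1) if tree_shaped else None

    warnings: list[str] = []
    for number in sorted(key.couplets):
        a, b = key.couplets[number].leads
        chars = sorted(a.predicate.chars() | b.predicate.chars())
        defs = [key.characters[c] for c in chars]
        if not all(d.enumerable for d in defs):
            warnings.append(
                f"couplet {number}: non-enumerable character, overlap/gap not checked")
            continue
        overlaps: list[tuple] = []
        gaps: list[tuple] = []
        for combo in itertools.product(*(d.domain_values() for d in defs)):
            sv = dict(zip(chars, combo))
            sat_a, sat_b = a.predicate.evaluate(sv), b.predicate.evaluate(sv)
            if sat_a and sat_b:
                overlaps.append(combo)
            elif not sat_a and not sat_b:
                gaps.append(combo)
        if overlaps:
            warnings.append(
                f"couplet {number}: leads overlap for {chars}: "
                f"{overlaps[:5]}{'...' if len(overlaps) > 5 else ''}")
        if gaps:
            warnings.append(
                f"couplet {number}: gap (neither lead) for {chars}: "
                f"{gaps[:10]}{'...' if len(gaps) > 10 else ''}")

    return KeyDiagnostics(
        key_id=key.key_id,
        n_couplets=len(key.couplets),
        n_terminals=n_terminals,
        unreachable=unreachable,
        tree_shaped=tree_shaped,
        terminal_count_matches_tree=terminal_count_ok,
        warnings=tuple(warnings),
    )


def traverse(key: DichotomousKey, sv: Mapping[str, Any]) -> TraversalResult:
    """Deterministic traversal of a fully observed specimen.

    At every couplet exactly one lead must hold; an unknown consulted
    character raises :class:`AmbiguousState` (use
    :func:`traverse_partial` instead), and both-true / both-false
    raises :class:`KeyConflict` naming the couplet.
    """
    path: list[tuple[int, str, str]] = []
    consulted: set[str] = set()
    warnings: list[str] = []
    number = 1
    for _ in range(len(key.couplets) + 1):
        couplet = key.couplets[number]
        a, b = couplet.leads
        needed = a.predicate.chars() | b.predicate.chars()
        consulted |= needed
        for char in sorted(needed):
            if sv.get(char, UNKNOWN) is UNKNOWN:
                raise AmbiguousState(
                    f"couplet {number} consults {char!r} which is unknown; "
                    "use traverse_partial for set-valued identification",
                    character=char, couplet=number)
        sat_a, sat_b = a.predicate.evaluate(sv), b.predicate.evaluate(sv)
        if sat_a == sat_b:
            kind = "both leads" if sat_a else "neither lead"
            raise KeyConflict(
                f"couplet {number}: {kind} satisfied by the observed states",
                couplet=number)
        label, lead = ("A", a) if sat_a else ("B", b)
        if lead.advisory is not None:
            adv_chars = lead.advisory.chars()
            if all(sv.get(c, UNKNOWN) is not UNKNOWN for c in adv_chars):
                if not lead.advisory.evaluate(sv):
                    warnings.append(
                        f"couplet {number} lead {label}: advisory characters "
                        f"{sorted(adv_chars)} disagree with the chosen lead")
        path.append((number, label, lead.text))
        if lead.terminal is not None:
            return TraversalResult(
                outcomes=(lead.terminal,), path=tuple(path), ambiguous=False,
                consulted=frozenset(consulted), warnings=tuple(warnings))
        number = lead.goto
    raise KeyConflict("traversal exceeded couplet count", couplet=number)


def traverse_partial(key: DichotomousKey, sv: Mapping[str, Any]) -> TraversalResult:
    """Set of terminals reachable under some completion of the UNKNOWN
    characters.

    Characters set to a declared gap state (a state satisfying neither
    lead of its couplet, e.g. ordinal ``intermediate``) are treated as
    UNKNOWN here, preserving the uncertainty instead of dead-ending.
    Implemented by branch-and-prune constraint propagation, exact for
    the packaged predicate grammar.
    """
    constraints: dict[str, frozenset] = {}
    for cid, cd in key.characters.items():
        if not cd.enumerable:
            raise ValidationError(
                f"traverse_partial requires enumerable characters; {cid} is not")
        value = sv.get(cid, UNKNOWN)
        if value is not UNKNOWN:
            value = cd.validate_value(value)
        if value is UNKNOWN or value in cd.gap_states:
            constraints[cid] = frozenset(cd.domain_values())
        else:
            constraints[cid] = frozenset({value})

    outcomes: set[str] = set()
    consulted: set[str] = set()

    def walk(number: int, current: Mapping[str, frozenset]) -> None:
        couplet = key.couplets[number]
        consulted.update(couplet.leads[0].predicate.chars())
        consulted.update(couplet.leads[1].predicate.chars())
        for lead in couplet.leads:
            narrowed = lead.predicate.constrain(current, key.characters)
            if narrowed is None:
                continue
            if lead.terminal is not None:
                outcomes.add(lead.terminal)
            else:
                walk(lead.goto, narrowed)

    walk(1, constraints)
    ordered = tuple(sorted(outcomes))
    return TraversalResult(
        outcomes=ordered, path=(), ambiguous=len(ordered) != 1,
        consulted=frozenset(consulted))
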