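"""Shared fixtures: printed type-series values (frozen as test inputs)
and independent oracles (grid search, exhaustive enumeration)."""

from __future__ import annotations

import itertools

import pytest

from tetrakey import keys as keys_mod
from tetrakey import species as species_mod
from tetrakey.measurements import MeasurementSet

# Printed holotype measurement vectors (mm, two decimals) — inputs.
JARAWA_HOLOTYPE = {
    "HL": 0.56, "HW": 0.52, "SL": 0.32, "EL": 0.05, "PH": 0.27, "PW": 0.35,
    "WL": 0.62, "PSL": 0.10, "PTL": 0.14, "PTH": 0.17, "PTW": 0.16,
    "PPL": 0.17, "PPH": 0.18, "PPW": 0.20,
}
KRISHNANI_HOLOTYPE = {
    "HL": 0.61, "HW": 0.54, "SL": 0.43, "EL": 0.14, "PH": 0.28, "PW": 0.40,
    "WL": 0.74, "PSL": 0.02, "PTL": 0.22, "PTH": 0.20, "PTW": 0.19,
    "PPL": 0.25, "PPH": 0.17, "PPW": 0.20,
}

# Printed holotype index values — inputs for the consistency suite.
JARAWA_PRINTED = {
    "CI": 94, "SI": 60, "OI": 10, "DMI": 56, "LMI": 44, "PSLI": 18,
    "PeNI": 45, "LPeI": 81, "DPeI": 112, "PpNI": 57, "LPpI": 91,
    "DPpI": 120, "PPI": 126,
}
KRISHNANI_PRINTED = {
    "CI": 88, "SI": 80, "OI": 26, "DMI": 54, "LMI": 38, "PSLI": 3.2,
    "PeNI": 47, "LPeI": 112, "DPeI": 84, "PpNI": 49, "LPpI": 143,
    "DPpI": 78, "PPI": 103,
}


@pytest.fixture(scope="session")
def jarawa_holotype() -> MeasurementSet:
    return MeasurementSet.from_dict(JARAWA_HOLOTYPE, recorded_decimals=2)


@pytest.fixture(scope="session")
def krishnani_holotype() -> MeasurementSet:
    return MeasurementSet.from_dict(KRISHNANI_HOLOTYPE, recorded_decimals=2)


@pytest.fixture(scope="session")
def db():
    return species_mod.load_species_table()


@pytest.fixture(scope="session")
def diagnoses():
    return species_mod.load_group_diagnoses()


@pytest.fixture(scope="session")
def group_key():
    return keys_mod.load_key("india_species_groups")


@pytest.fixture(scope="session")
def inglebyi_key():
    return keys_mod.load_key("inglebyi_group")


@pytest.fixture(scope="session")
def tonganum_key():
    return keys_mod.load_key("tonganum_group")


# ---------------------------------------------------------------- oracles

def grid_search_interval(num_range, den_range, h, step=1e-4):
    """Independent oracle for index_interval: dense grid over both
    widened measurement intervals."""
    n_lo, n_hi = num_range[0] - h, num_range[1] + h
    d_lo, d_hi = den_range[0] - h, den_range[1] + h
    assert d_lo > 0
    lo, hi = float("inf"), float("-inf")
    n = n_lo
    while n <= n_hi + step / 2:
        d = d_lo
        while d <= d_hi + step / 2:
            v = 100.0 * n / d
            lo, hi = min(lo, v), max(hi, v)
            d += step
        n += step
    return lo, hi


def enumerate_terminals(key, sv):
    """Independent oracle for traverse_partial: strict traversal over
    every completion of the UNKNOWN (or declared-gap-state) characters."""
    free, fixed = [], {}
    for cid, cd in key.characters.items():
        value = sv.get(cid, keys_mod.UNKNOWN)
        if value is keys_mod.UNKNOWN or value in cd.gap_states:
            free.append(cid)
        else:
            fixed[cid] = value
    terminals = set()
    domains = [key.characters[c].domain_values() for c in free]
    for combo in itertools.product(*domains):
        full = dict(fixed)
        full.update(zip(free, combo))
        try:
            terminals.add(keys_mod.traverse(key, full).outcome)
        except keys_mod.KeyConflict:
            pass  # gap-state completion: reaches no terminal
    return terminals
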