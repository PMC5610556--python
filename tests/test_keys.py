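import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetrakey.errors import (
    AmbiguousState,
    KeyConflict,
    KeyStructureError,
    ValidationError,
)
from tetrakey.keys import (
    PACKAGED_KEYS,
    UNKNOWN,
    StateVector,
    load_key,
    traverse,
    traverse_partial,
    validate_key,
)

from conftest import enumerate_terminals

# A fully observed state vector keying out to the inglebyi group.
JARAWA_STATES = {
    "branched_hairs": False,
    "gastral_pilosity_type": "simple",
    "antennal_segments": 12,
    "antennal_scrobes": "absent",
    "head_cordate": False,
    "clypeal_lateral_ridge": "sharp_high",
    "sting_appendage": "dentiform",
    "frontal_carinae": "very_short_or_absent",
    "gaster_base_horns": True,
    "ommatidia_longest_row": 3,
    "mesosomal_dorsum_hairs": "long_fine",
    "clypeal_median_impression": False,
    "propodeal_spines_relative": "shorter",
    "metatibial_hairs": "appressed_to_decumbent",
}


class TestLoadKey:
    @pytest.mark.parametrize("key_id,n_couplets,n_terminals", [
        ("india_species_groups", 12, 13),
        ("inglebyi_group", 4, 5),
        ("tonganum_group", 4, 5),
    ])
    def test_packaged_shapes(self, key_id, n_couplets, n_terminals):
        k = load_key(key_id)
        assert len(k.couplets) == n_couplets
        assert len(k.terminals()) == n_terminals

    def test_inglebyi_terminals(self, inglebyi_key):
        assert inglebyi_key.terminals() == {
            "inglebyi", "elisabethae", "triangulatum", "myops", "jarawa"}

    def test_tonganum_retains_nonindian_species(self, tonganum_key):
        assert "tonganum" in tonganum_key.terminals()
        assert tonganum_key.terminals() == {
            "krishnani", "barryi", "christiei", "tonganum", "salvatum"}

    def test_group_key_terminals_are_the_13_groups(self, group_key):
        assert len(group_key.terminals()) == 13
        assert all(t.endswith(" group") for t in group_key.terminals())

    def test_bad_goto_rejected(self, tmp_path):
        doc = json.loads(
            json.dumps({
                "key_id": "broken",
                "characters": [{"id": "x", "kind": "boolean"}],
                "couplets": [
                    {"number": 1, "leads": [
                        {"text": "a", "predicate": {"char": "x", "op": "eq", "value": True},
                         "goto": 2},
                        {"text": "b", "predicate": {"char": "x", "op": "eq", "value": False},
                         "terminal": "t1"}]},
                    {"number": 2, "leads": [
                        {"text": "c", "predicate": {"char": "x", "op": "eq", "value": True},
                         "goto": 9},
                        {"text": "d", "predicate": {"char": "x", "op": "eq", "value": False},
                         "terminal": "t2"}]},
                ]}))
        path = tmp_path / "broken.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(KeyStructureError, match="couplet 2"):
            load_key(path)

    def test_cycle_rejected(self, tmp_path):
        doc = {
            "key_id": "cyclic",
            "characters": [{"id": "x", "kind": "boolean"}],
            "couplets": [
                {"number": 1, "leads": [
                    {"text": "a", "predicate": {"char": "x", "op": "eq", "value": True},
                     "goto": 2},
                    {"text": "b", "predicate": {"char": "x", "op": "eq", "value": False},
                     "terminal": "t"}]},
                {"number": 2, "leads": [
                    {"text": "c", "predicate": {"char": "x", "op": "eq", "value": True},
                     "goto": 1},
                    {"text": "d", "predicate": {"char": "x", "op": "eq", "value": False},
                     "terminal": "u"}]},
            ]}
        path = tmp_path / "cyclic.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(KeyStructureError, match="cycle"):
            load_key(path)

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyStructureError):
            load_key("no_such_key")


class TestValidateKey:
    def test_group_key_structure(self, group_key):
        diag = validate_key(group_key)
        assert diag.unreachable == ()
        assert diag.tree_shaped
        assert diag.n_couplets == 12
        assert diag.n_terminals == 13
        assert diag.terminal_count_matches_tree

    def test_ommatidia_gap_reported(self, group_key):
        diag = validate_key(group_key)
        gap_warnings = [w for w in diag.warnings if "couplet 8" in w]
        assert len(gap_warnings) == 1
        assert all(s in gap_warnings[0] for s in ("(7,)", "(8,)", "(9,)"))

    def test_only_documented_gaps_warned(self, group_key, inglebyi_key, tonganum_key):
        warnings = validate_key(group_key).warnings
        assert {w.split(":")[0] for w in warnings} == {
            "couplet 3", "couplet 8", "couplet 12"}
        assert all("gap" in w for w in warnings)
        assert not any("overlap" in w for w in warnings)
        assert [w.split(":")[0] for w in validate_key(inglebyi_key).warnings] == ["couplet 2"]
        assert validate_key(tonganum_key).warnings == ()

    def test_species_keys_validate(self, inglebyi_key, tonganum_key):
        for k in (inglebyi_key, tonganum_key):
            diag = validate_key(k)
            assert diag.unreachable == () and diag.tree_shaped
            assert diag.n_terminals == diag.n_couplets + 1 == 5

    def test_overlap_warning_on_synthetic_key(self, tmp_path):
        doc = {
            "key_id": "overlap",
            "characters": [{"id": "n", "kind": "count", "domain": [1, 5]}],
            "couplets": [
                {"number": 1, "leads": [
                    {"text": "a", "predicate": {"char": "n", "op": "le", "value": 3},
                     "terminal": "small"},
                    {"text": "b", "predicate": {"char": "n", "op": "ge", "value": 3},
                     "terminal": "large"}]},
            ]}
        path = tmp_path / "overlap.json"
        path.write_text(json.dumps(doc))
        diag = validate_key(load_key(path))
        assert any("overlap" in w for w in diag.warnings)


class TestTraverse:
    def test_jarawa_vector_reaches_inglebyi_group(self, group_key):
        result = traverse(group_key, JARAWA_STATES)
        assert result.outcome == "inglebyi group"
        assert not result.ambiguous
        assert [c for c, _, _ in result.path] == [1, 3, 5, 6, 7, 8]
        assert result.consulted >= {"branched_hairs", "antennal_segments",
                                    "gaster_base_horns", "ommatidia_longest_row"}

    def test_krishnani_terminates_at_couplet_one(self, tonganum_key):
        result = traverse(tonganum_key, {"propodeal_armament": "unarmed"})
        assert result.outcome == "krishnani"
        assert len(result.path) == 1
        assert result.path[0][0] == 1
        assert "unarmed" in result.path[0][2]

    def test_large_eyes_one_step(self, inglebyi_key):
        result = traverse(inglebyi_key,
                          {"eye_vs_scape_width": "longer_than_scape_width"})
        assert result.outcome == "inglebyi"
        assert len(result.path) == 1

    def test_unknown_consulted_raises(self, tonganum_key):
        with pytest.raises(AmbiguousState) as exc:
            traverse(tonganum_key, {"propodeal_armament": UNKNOWN})
        assert exc.value.couplet == 1
        assert "traverse_partial" in str(exc.value)

    def test_gap_state_raises_conflict(self, group_key):
        sv = dict(JARAWA_STATES, gaster_base_horns=False,
                  frontal_carinae="developed",
                  propodeal_spines_relative="intermediate")
        with pytest.raises(KeyConflict) as exc:
            traverse(group_key, sv)
        assert exc.value.couplet == 12

    def test_advisory_conflict_warns_but_does_not_divert(self, group_key):
        sv = dict(JARAWA_STATES, clypeal_lateral_ridge="low")
        result = traverse(group_key, sv)
        assert result.outcome == "inglebyi group"
        assert any("couplet 5" in w for w in result.warnings)

    def test_path_bounded_by_couplet_count(self, group_key, diagnoses):
        for diag in diagnoses.values():
            result = traverse(group_key, diag.template)
            assert len(result.path) <= len(group_key.couplets)


class TestTraversePartial:
    def test_all_unknown_reaches_all_terminals(self, tonganum_key):
        result = traverse_partial(tonganum_key, {})
        assert set(result.outcomes) == tonganum_key.terminals()
        assert result.ambiguous

    def test_fully_specified_matches_traverse(self, group_key):
        strict = traverse(group_key, JARAWA_STATES)
        partial = traverse_partial(group_key, JARAWA_STATES)
        assert partial.outcomes == (strict.outcome,)
        assert not partial.ambiguous

    def test_armed_propodeum_excludes_krishnani(self, tonganum_key):
        result = traverse_partial(tonganum_key, {"propodeal_armament": "armed"})
        assert set(result.outcomes) == {"barryi", "christiei", "tonganum", "salvatum"}
        # oracle: exhaustive enumeration over completions
        assert set(result.outcomes) == enumerate_terminals(
            tonganum_key, {"propodeal_armament": "armed"})

    def test_gap_state_behaves_as_unknown(self, inglebyi_key):
        sv = {"eye_vs_scape_width": "shorter_than_scape_width",
              "propodeal_spines_relative": "intermediate"}
        result = traverse_partial(inglebyi_key, sv)
        assert set(result.outcomes) == {"elisabethae", "triangulatum", "myops", "jarawa"}

    @pytest.mark.parametrize("key_name", ["inglebyi_group", "tonganum_group"])
    def test_matches_enumeration_on_random_vectors(self, key_name):
        import random

        key = load_key(key_name)
        rng = random.Random(42)
        chars = sorted(key.characters)
        for _ in range(40):
            sv = {}
            for c in chars:
                values = (UNKNOWN,) + key.characters[c].domain_values()
                sv[c] = rng.choice(values)
            expected = enumerate_terminals(key, sv)
            got = set(traverse_partial(key, sv).outcomes)
            assert got == expected, sv

    def test_matches_enumeration_on_group_key_samples(self, group_key):
        import random

        rng = random.Random(7)
        chars = sorted(group_key.characters)
        for _ in range(25):
            sv = {}
            unknowns = rng.sample(chars, k=rng.randint(0, 5))
            for c in chars:
                sv[c] = (UNKNOWN if c in unknowns
                         else rng.choice(group_key.characters[c].domain_values()))
            expected = enumerate_terminals(group_key, sv)
            got = set(traverse_partial(group_key, sv).outcomes)
            assert got == expected

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_knowledge_monotonicity(self, data):
        key = load_key("tonganum_group")
        chars = sorted(key.characters)
        sv = {c: data.draw(
            st.sampled_from((UNKNOWN,) + key.characters[c].domain_values()), label=c)
            for c in chars}
        base = set(traverse_partial(key, sv).outcomes)
        unknown_chars = [c for c in chars if sv[c] is UNKNOWN]
        if not unknown_chars:
            return
        c = data.draw(st.sampled_from(unknown_chars), label="added")
        value = data.draw(st.sampled_from(key.characters[c].domain_values()))
        refined = dict(sv, **{c: value})
        assert set(traverse_partial(key, refined).outcomes) <= base


class TestStateVector:
    def test_rejects_undeclared_character(self, group_key):
        with pytest.raises(ValidationError):
            StateVector(group_key, {"wing_count": 2})

    def test_rejects_out_of_domain_value(self, group_key):
        with pytest.raises(ValidationError):
            StateVector(group_key, {"antennal_segments": 13})
        with pytest.raises(ValidationError):
            StateVector(group_key, {"sting_appendage": "hooked"})

    def test_unknown_allowed(self, group_key):
        sv = StateVector(group_key, {"antennal_segments": UNKNOWN})
        assert sv["antennal_segments"] is UNKNOWN
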