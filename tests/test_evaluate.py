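import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from ordbench import (
    Mode,
    classify_leaves,
    classify_messages,
    evaluate_reaction,
    lenient_equal_compound,
    lenient_equal_product,
    match_messages,
    node_distance,
)
from ordbench.evaluate import _dist
from ordbench.schema import MessageNode, count_leaves


def _brute_force_min(gt, pred):
    n = max(len(gt), len(pred))
    pg = list(gt) + [None] * (n - len(gt))
    pp = list(pred) + [None] * (n - len(pred))
    return min(
        sum(_dist(pg[i], pp[j]) for i, j in enumerate(perm))
        for perm in itertools.permutations(range(n))
    )


def _rand_compound(rng):
    return {
        "identifiers": [{"type": "NAME", "value": rng.choice("abcdefgh")}],
        "amount": {"mass": {"value": float(rng.randint(1, 5)), "units": "GRAM"}},
        "reaction_role": rng.choice(["REACTANT", "SOLVENT", "CATALYST"]),
    }


class TestNodeDistance:
    def test_identical_compounds_have_zero_distance(self, compound_pair):
        gt, _ = compound_pair
        assert node_distance(MessageNode(gt), MessageNode(dict(gt))) == 0

    def test_altered_value_plus_extra_leaf_costs_two(self, compound_pair):
        gt, pred = compound_pair
        assert node_distance(MessageNode(gt), MessageNode(pred)) == 2

    def test_distance_to_empty_is_leaf_count(self, compound_pair):
        gt, _ = compound_pair
        assert node_distance(MessageNode(gt), None) == count_leaves(gt) == 4

    def test_numeric_equality_ignores_serialization_dialect(self):
        a = MessageNode({"amount": {"mass": {"value": 5, "units": "GRAM"}}})
        b = MessageNode({"amount": {"mass": {"value": 5.0, "units": " GRAM "}}})
        assert node_distance(a, b) == 0

    def test_type_mismatch_is_a_contract_violation(self):
        a = MessageNode({}, message_type="Compound")
        b = MessageNode({}, message_type="ReactionWorkup")
        with pytest.raises(TypeError):
            node_distance(a, b)

    def test_repeated_sublists_are_aligned_not_positional(self):
        a = {"identifiers": [{"type": "NAME", "value": "x"}, {"type": "SMILES", "value": "C"}]}
        b = {"identifiers": [{"type": "SMILES", "value": "C"}, {"type": "NAME", "value": "x"}]}
        assert node_distance(MessageNode(a), MessageNode(b)) == 0

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    def test_symmetric_premetric(self, seed_a, seed_b):
        a = _rand_compound(random.Random(seed_a))
        b = _rand_compound(random.Random(seed_b))
        na, nb = MessageNode(a), MessageNode(b)
        assert node_distance(na, nb) == node_distance(nb, na) >= 0
        assert node_distance(na, MessageNode(dict(a))) == 0


class TestMatching:
    def test_extra_prediction_pairs_with_pad_as_addition(self):
        rng = random.Random(0)
        a, b = _rand_compound(rng), _rand_compound(rng)
        pairs = match_messages([a], [a, b])
        modes = sorted(p.mode for p in pairs)
        assert modes == sorted([Mode.ACCURATE, Mode.ADDITION])

    def test_one_altered_one_removed(self):
        rng = random.Random(1)
        c1, c2, c3 = (_rand_compound(rng) for _ in range(3))
        c2_alt = {**c2, "amount": {"mass": {"value": 99.0, "units": "GRAM"}}}
        pairs = match_messages([c1, c2, c3], [c1, c2_alt])
        by_mode = {p.mode: p for p in pairs}
        assert by_mode[Mode.ACCURATE].gt == c1
        assert by_mode[Mode.ALTERATION].gt == c2
        assert by_mode[Mode.REMOVAL].gt == c3
        tally = classify_messages(pairs, "Compound")
        assert (tally.accurate, tally.alteration, tally.removal, tally.addition) == (1, 1, 1, 0)
        assert tally.total == 3

    def test_total_cost_matches_brute_force_on_random_instances(self):
        rng = random.Random(123)
        for _ in range(60):
            gt = [_rand_compound(rng) for _ in range(rng.randint(0, 5))]
            pred = [_rand_compound(rng) for _ in range(rng.randint(0, 5))]
            pairs = match_messages(gt, pred)
            assert sum(p.distance for p in pairs) == _brute_force_min(gt, pred)

    def test_ties_prefer_lowest_indices(self):
        a = {"reaction_role": "REACTANT"}
        pairs = match_messages([a, dict(a)], [dict(a), dict(a)])
        assert [(p.gt_index, p.pred_index) for p in pairs] == [(0, 0), (1, 1)]


class TestLeafClassification:
    def test_altered_pair_yields_one_alteration_one_addition(self, compound_pair):
        gt, pred = compound_pair
        pairs = match_messages([gt], [pred])
        tallies = classify_leaves(pairs, "Compound")
        assert tallies["amount"].alteration == 1
        assert tallies["reaction_role"].addition == 1
        assert tallies["identifiers"].accurate == 2
        assert tallies["amount"].accurate == 1  # units leaf

    def test_removed_message_contributes_every_leaf_as_removal(self, compound_pair):
        gt, _ = compound_pair
        pairs = match_messages([gt], [])
        tallies = classify_leaves(pairs, "Compound")
        total_removals = sum(t.removal for t in tallies.values())
        assert total_removals == count_leaves(gt) == 4

    def test_accurate_pair_contributes_every_leaf_as_accurate(self, compound_pair):
        gt, _ = compound_pair
        pairs = match_messages([gt], [dict(gt)])
        tallies = classify_leaves(pairs, "Compound")
        assert sum(t.accurate for t in tallies.values()) == 4
        assert all(t.removal == t.addition == t.alteration == 0 for t in tallies.values())


class TestLenientEquivalence:
    def test_texture_and_color_differences_are_forgiven(self):
        a = {
            "identifiers": [{"type": "NAME", "value": "p"}],
            "measurements": [{"type": "AMOUNT", "amount": {"mass": {"value": 1.0, "units": "GRAM"}}}],
            "texture": {"type": "CRYSTAL"},
            "isolated_color": "white",
        }
        b = {**a, "texture": {"type": "OIL"}, "isolated_color": "brown"}
        assert lenient_equal_product(a, b)

    def test_identifier_difference_is_not_forgiven(self):
        a = {"identifiers": [{"type": "NAME", "value": "p"}]}
        b = {"identifiers": [{"type": "NAME", "value": "q"}]}
        assert not lenient_equal_product(a, b)
        assert lenient_equal_product(a, dict(a))

    def test_compound_lenient_ignores_reaction_role_only(self, compound_pair):
        gt, pred = compound_pair
        role_only = {**gt, "reaction_role": "SOLVENT"}
        assert lenient_equal_compound(gt, role_only)
        assert not lenient_equal_compound(gt, pred)  # amount still differs


class TestEvaluateReaction:
    def test_identity_prediction_is_fully_accurate(self, small_corpus):
        rec = small_corpus[0]
        res = evaluate_reaction(rec.record, rec.record)
        for t in res.message_tallies.values():
            assert t.removal == t.addition == t.alteration == 0
        for t in res.leaf_tallies.values():
            assert t.accurate == t.total and t.addition == 0

    def test_deleted_workup_counts_one_removal(self, small_corpus):
        import copy

        rec = small_corpus[2]
        pred = copy.deepcopy(rec.record.data)
        removed = pred["workups"].pop()
        res = evaluate_reaction(rec.record, MessageNode(pred))
        t = res.message_tallies["ReactionWorkup"]
        assert (t.removal, t.addition, t.alteration) == (1, 0, 0)
        assert res.leaf_tallies["workup"].removal == count_leaves(removed)

    def test_conditions_admit_only_accurate_or_alteration(self, small_corpus):
        import copy

        rec = small_corpus[4]
        pred = copy.deepcopy(rec.record.data)
        pred["conditions"]["temperature"]["setpoint"]["value"] += 500
        res = evaluate_reaction(rec.record, MessageNode(pred))
        t = res.message_tallies["ReactionConditions"]
        assert (t.accurate, t.alteration, t.removal, t.addition) == (0, 1, 0, 0)

    def test_unparseable_prediction_counts_total_removal(self, small_corpus):
        rec = small_corpus[5]
        res = evaluate_reaction(rec.record, None)
        for mtype in ("Compound", "ProductCompound", "ReactionWorkup"):
            t = res.message_tallies[mtype]
            assert t.removal == t.total and t.accurate == 0

    def test_conservation_and_stringency(self, small_corpus):
        """accurate + removal + alteration equals the ground-truth count,
        and a message counted ACCURATE has zero leaf-level failures."""
        import copy

        rec = small_corpus[6]
        pred = copy.deepcopy(rec.record.data)
        pred["workups"].pop(0)
        res = evaluate_reaction(rec.record, MessageNode(pred))
        gt_counts = {
            "Compound": len(
                [c for inp in rec.record.data["inputs"].values() for c in inp["components"]]
            ),
            "ProductCompound": 1,
            "ReactionWorkup": len(rec.record.data["workups"]),
            "ReactionConditions": 1,
        }
        for mtype, t in res.message_tallies.items():
            assert t.accurate + t.removal + t.alteration == t.total == gt_counts[mtype]
        for pairs in res.pairs.values():
            for p in pairs:
                if p.mode is Mode.ACCURATE:
                    assert p.distance == 0
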