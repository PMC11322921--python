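import random
from collections import Counter

import pytest

from ordbench import (
    MessageNode,
    RoleConfusion,
    build_popularity_table,
    compare_names,
    extract_names,
    macro_f1,
    popularity_predict,
    role_confusion,
)
from ordbench.names_roles import ROLES


def _record(compounds, products=()):
    def comp(name, role=None):
        c = {"identifiers": [{"type": "NAME", "value": name}]}
        if role:
            c["reaction_role"] = role
        return c

    data = {"inputs": {"m1": {"components": [comp(n, r) for n, r in compounds]}}}
    if products:
        data["outcomes"] = [{"products": [comp(n, "PRODUCT") for n in products]}]
    return MessageNode(data)


class TestExtractNames:
    def test_inputs_and_products_collected(self):
        rec = _record([("THF", "SOLVENT"), ("NaH", "REACTANT")], products=["compound 5"])
        assert sorted(extract_names(rec)) == ["NaH", "THF", "compound 5"]

    def test_empty_record_gives_empty_multiset(self):
        assert extract_names(MessageNode(None)) == []

    def test_referencing_tokens_are_names_too(self):
        rec = _record([("the desired product", "REACTANT")])
        assert extract_names(rec) == ["the desired product"]

    def test_whitespace_normalized_case_preserved(self):
        rec = _record([("  Sodium   Hydride ", "REACTANT")])
        assert extract_names(rec) == ["Sodium Hydride"]


class TestCompareNames:
    def test_identical_sets_all_accurate(self):
        t = compare_names(["a", "b"], ["b", "a"])
        assert (t.accurate, t.removal, t.addition, t.alteration) == (2, 0, 0, 0)

    def test_unrecognized_referencing_token_is_a_removal(self):
        t = compare_names(["tryptophan methyl ester", "9"], ["tryptophan methyl ester"])
        assert (t.accurate, t.removal, t.addition, t.alteration) == (1, 1, 0, 0)

    def test_excess_entity_is_an_addition(self):
        t = compare_names(["A"], ["A", "1H"])
        assert (t.accurate, t.removal, t.addition, t.alteration) == (1, 0, 1, 0)

    def test_near_miss_is_an_alteration(self):
        t = compare_names(["4-chloroaniline"], ["4-chloroanilin"])
        assert (t.accurate, t.alteration) == (0, 1)

    def test_conservation_laws(self):
        gt = ["a", "b", "c", "dd"]
        pred = ["a", "x", "yy"]
        t = compare_names(gt, pred)
        assert t.accurate + t.removal + t.alteration == len(gt)
        assert t.accurate + t.addition + t.alteration == len(pred)


class TestPopularityBaseline:
    def test_strict_argmax(self):
        table = {"THF": Counter({"SOLVENT": 10, "REACTANT": 1})}
        assert popularity_predict("THF", table, 0) == "SOLVENT"

    def test_deterministic_given_name_and_seed(self):
        assert all(
            popularity_predict("novel", {}, 7) == popularity_predict("novel", {}, 7)
            for _ in range(20)
        )

    def test_tie_is_uniform_within_three_sigma(self):
        table = {"A": Counter({"REACTANT": 5, "SOLVENT": 5})}
        rng = random.Random(0)
        n = 10_000
        draws = Counter(popularity_predict("A", table, rng) for _ in range(n))
        # binomial p=1/2: 3 sigma band around n/2
        sigma = (n * 0.5 * 0.5) ** 0.5
        for role in ("REACTANT", "SOLVENT"):
            assert abs(draws[role] - n / 2) < 3 * sigma
        assert draws["CATALYST"] == 0

    def test_unseen_name_uniform_over_all_roles(self):
        rng = random.Random(1)
        n = 9_999
        draws = Counter(popularity_predict(f"x{i}", {}, rng) for i in range(n))
        sigma = (n * (1 / 3) * (2 / 3)) ** 0.5
        for role in ROLES:
            assert abs(draws[role] - n / 3) < 3 * sigma

    def test_table_built_from_corpus(self):
        recs = [
            _record([("THF", "SOLVENT")]),
            _record([("THF", "REACTANT")]),
            _record([("NaH", "REACTANT")]),
        ]
        table = build_popularity_table(recs)
        assert table["THF"] == Counter({"SOLVENT": 1, "REACTANT": 1})
        assert table["NaH"] == Counter({"REACTANT": 1})
        assert build_popularity_table([]) == {}


class TestRoleConfusion:
    def test_perfect_prediction_is_diagonal(self):
        gt = [_record([("a", "REACTANT"), ("b", "SOLVENT"), ("c", "CATALYST")])]
        cm = role_confusion(gt, gt)
        for r in ROLES:
            assert cm.counts[r][r] == 1
            assert cm.row_total(r) == 1
        assert all(cm.counts[r]["MISSING"] == cm.counts[r]["ERROR"] == 0 for r in ROLES)

    def test_dropped_compound_is_missing(self):
        gt = [_record([("a", "CATALYST"), ("b", "REACTANT")])]
        pred = [_record([("b", "REACTANT")])]
        cm = role_confusion(gt, pred)
        assert cm.counts["CATALYST"]["MISSING"] == 1
        assert cm.counts["REACTANT"]["REACTANT"] == 1

    def test_wrong_name_is_error(self):
        gt = [_record([("palladium acetate", "CATALYST")])]
        pred = [_record([("palladium diacetate", "CATALYST")])]
        cm = role_confusion(gt, pred)
        assert cm.counts["CATALYST"]["ERROR"] == 1

    def test_row_sums_equal_per_role_ground_truth_counts(self, small_corpus):
        gt = [r.record for r in small_corpus]
        cm = role_confusion(gt, gt)
        want = Counter()
        for rec in small_corpus:
            for inp in rec.record.data["inputs"].values():
                for c in inp["components"]:
                    if c.get("reaction_role") in ROLES:
                        want[c["reaction_role"]] += 1
        for r in ROLES:
            assert cm.row_total(r) == want[r]

    def test_row_normalization_uses_true_instance_counts(self):
        cm = RoleConfusion()
        cm.bump("REACTANT", "REACTANT")
        cm.bump("REACTANT", "MISSING")
        norm = cm.normalized()
        assert norm["REACTANT"]["REACTANT"] == 50.0
        assert norm["REACTANT"]["MISSING"] == 50.0


class TestMacroF1:
    def test_perfect_diagonal_is_one(self):
        cm = RoleConfusion()
        for r in ROLES:
            for _ in range(5):
                cm.bump(r, r)
        assert macro_f1(cm) == 1.0

    def test_constant_predictor_on_balanced_set(self):
        cm = RoleConfusion()
        for r in ROLES:
            for _ in range(10):
                cm.bump(r, "REACTANT")
        assert macro_f1(cm) == pytest.approx(1 / 6)

    def test_single_class_ground_truth_uses_zero_convention(self):
        cm = RoleConfusion()
        for _ in range(10):
            cm.bump("REACTANT", "REACTANT")
        assert macro_f1(cm) == pytest.approx(1 / 3)

    def test_all_empty_matrix_is_undefined(self):
        assert macro_f1(RoleConfusion()) is None

    def test_missing_counts_as_false_negative(self):
        cm = RoleConfusion()
        for _ in range(5):
            cm.bump("SOLVENT", "SOLVENT")
        cm.bump("SOLVENT", "MISSING")
        # precision 1, recall 5/6 for SOLVENT; other classes contribute 0
        f1 = 2 * (1 * 5 / 6) / (1 + 5 / 6)
        assert macro_f1(cm) == pytest.approx(f1 / 3)
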