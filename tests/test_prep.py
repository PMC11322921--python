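import copy
import json

import pytest

from ordbench import (
    CorpusRecord,
    GenConfig,
    MessageNode,
    admit_record,
    dedupe,
    gen_corpus,
    parse_record,
    prep_report,
    render_prompt,
    scrub_implicit,
    split,
    token_filter,
)
from ordbench.prep import ConfigError, PromptExample, default_tokenizer


def _record(data):
    return MessageNode(data=data)


def _corpus_record(data, text, sid="r1"):
    return CorpusRecord(record=_record(data), procedure_text=text, source_id=sid)


class TestAdmission:
    def test_input_with_empty_components_rejected(self):
        rec = _corpus_record(
            {"inputs": {"m1": {"components": []}}}, "A paragraph."
        )
        assert admit_record(rec) is False

    def test_missing_procedure_text_rejected(self, small_corpus):
        rec = small_corpus[0]
        assert admit_record(CorpusRecord(rec.record, "", rec.source_id)) is False
        assert admit_record(CorpusRecord(rec.record, "   \n", rec.source_id)) is False

    def test_populated_inputs_with_paragraph_admitted(self, small_corpus):
        assert all(admit_record(r) for r in small_corpus)


class TestScrubbing:
    def test_product_name_absent_from_text_removed_and_logged(self):
        rec = _corpus_record(
            {
                "outcomes": [
                    {
                        "products": [
                            {"identifiers": [{"type": "NAME", "value": "title compound 7"}]}
                        ]
                    }
                ]
            },
            "The product was obtained as a white solid.",
        )
        out, removed = scrub_implicit(rec)
        assert removed == ["outcomes[0].products[0].identifiers[0]"]
        assert out.record.data is None or "outcomes" not in (out.record.data or {})

    @pytest.mark.parametrize(
        "recorded,stated,kept", [(83.0, "85%", False), (85.0, "85%", True)]
    )
    def test_yield_scrub_depends_on_integer_value_in_text(self, recorded, stated, kept):
        rec = _corpus_record(
            {
                "outcomes": [
                    {
                        "products": [
                            {
                                "identifiers": [{"type": "NAME", "value": "product 1"}],
                                "measurements": [
                                    {"type": "YIELD", "percentage": {"value": recorded}}
                                ],
                            }
                        ]
                    }
                ]
            },
            f"gave product 1 ({stated} yield).",
        )
        out, removed = scrub_implicit(rec)
        prod = out.record.data["outcomes"][0]["products"][0]
        assert ("measurements" in prod) is kept
        assert (removed == []) is kept

    def test_yield_match_is_word_bounded(self):
        # "8" must not match inside "85%"
        rec = _corpus_record(
            {
                "outcomes": [
                    {
                        "products": [
                            {"measurements": [{"type": "YIELD", "percentage": {"value": 8.0}}]}
                        ]
                    }
                ]
            },
            "gave the product (85% yield).",
        )
        _, removed = scrub_implicit(rec)
        assert removed == ["outcomes[0].products[0].measurements[0]"]

    def test_scrub_is_idempotent(self, small_corpus):
        rec = small_corpus[3]
        once, removed1 = scrub_implicit(rec)
        twice, removed2 = scrub_implicit(once)
        assert removed2 == []
        assert twice.record.data == once.record.data

    def test_consistent_mode_scrubs_nothing(self, small_corpus):
        for rec in small_corpus:
            _, removed = scrub_implicit(rec)
            assert removed == []

    def test_omit_product_name_mode_scrubs_exactly_the_product_name(self):
        corpus = gen_corpus(GenConfig(n_reactions=6, seed=9, p_omit_product_name=1.0))
        for rec in corpus:
            _, removed = scrub_implicit(rec)
            assert len(removed) == 1
            assert removed[0].startswith("outcomes[0].products[0].identifiers")


class TestPromptRendering:
    def test_completion_round_trips_to_same_tree(self, spec, small_corpus):
        rec = small_corpus[0]
        ex = render_prompt(rec)
        assert parse_record(ex.completion, spec).data == rec.record.data

    def test_rendering_is_deterministic_and_contains_text(self, small_corpus):
        rec = small_corpus[1]
        a, b = render_prompt(rec), render_prompt(rec)
        assert (a.prompt, a.completion) == (b.prompt, b.completion)
        assert rec.procedure_text in a.prompt
        assert a.token_count == default_tokenizer(a.prompt + a.completion)

    def test_missing_placeholder_is_a_configuration_error(self, small_corpus):
        with pytest.raises(ConfigError):
            render_prompt(small_corpus[0], template="no placeholders here")


class TestDedupe:
    def _ex(self, prompt, completion="c"):
        return PromptExample(prompt=prompt, completion=completion)

    def test_first_occurrence_kept_in_order(self):
        out = dedupe([self._ex("a"), self._ex("a"), self._ex("b")])
        assert [e.prompt for e in out] == ["a", "b"]

    def test_empty_is_identity(self):
        assert dedupe([]) == []

    def test_conflicting_completion_dropped_and_logged(self):
        conflicts = []
        out = dedupe(
            [self._ex("a", "first"), self._ex("a", "second")], conflicts=conflicts
        )
        assert [e.completion for e in out] == ["first"]
        assert conflicts == [("a", "second")]

    def test_idempotent(self, small_corpus):
        exs = [render_prompt(r) for r in small_corpus] * 2
        once = dedupe(exs)
        assert dedupe(once) == once


class TestTokenFilterAndSplit:
    @pytest.mark.parametrize("n_tokens,kept", [(2048, True), (2049, False), (0, True)])
    def test_limit_is_inclusive(self, n_tokens, kept):
        ex = PromptExample(prompt="x " * n_tokens, completion="")
        got_kept, got_dropped = token_filter([ex], tokenizer=lambda s: n_tokens)
        assert (len(got_kept) == 1) is kept

    def test_split_sizes_follow_ratios(self):
        exs = [PromptExample(prompt=str(i), completion="") for i in range(100)]
        labeled = split(exs, seed=3)
        from collections import Counter

        c = Counter(e.split for e in labeled)
        assert (c["train"], c["validation"], c["test"]) == (80, 10, 10)

    def test_split_of_ten_gives_eight_one_one(self):
        exs = [PromptExample(prompt=str(i), completion="") for i in range(10)]
        from collections import Counter

        c = Counter(e.split for e in split(exs, seed=0))
        assert (c["train"], c["validation"], c["test"]) == (8, 1, 1)

    def test_split_is_deterministic_and_partitions(self):
        def run():
            exs = [PromptExample(prompt=str(i), completion="") for i in range(37)]
            return [e.split for e in split(exs, seed=11)]

        a, b = run(), run()
        assert a == b
        assert set(a) == {"train", "validation", "test"}

    def test_too_few_examples_is_a_configuration_error(self):
        with pytest.raises(ConfigError):
            split([PromptExample(prompt="a", completion="")], seed=0)


class TestPrepReport:
    def test_printed_retention_figure(self):
        rep = prep_report(1500000, 1400000, 1339260, 1300613)
        assert rep.retention_pct == 97.1

    @pytest.mark.parametrize("within,expected", [(50, 100.0), (0, 0.0)])
    def test_degenerate_retentions(self, within, expected):
        assert prep_report(50, 50, 50, within).retention_pct == expected

    def test_zero_denominator_is_undefined(self):
        assert prep_report(0, 0, 0, 0).retention_pct is None

    def test_non_monotone_counts_rejected(self):
        with pytest.raises(ConfigError):
            prep_report(10, 20, 5, 1)
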