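"""Prompt assembly, reply parsing, mock screening, and two-stage triage."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from screeneval import (
    BackendConfig,
    Citation,
    MockRatingBackend,
    RatingVector,
    build_prompt,
    parse_response,
    screen_corpus,
    triage,
)
from screeneval.rater_harness import (
    NO_ABSTRACT_MARKER,
    BackendError,
    HarnessError,
    RatingValidationError,
    ResponseParseError,
)


class TestBuildPrompt:
    def test_contains_picos_labels_and_title_in_order(self, small_corpus, colorectal_picos):
        prompt = build_prompt(small_corpus[0], colorectal_picos)
        for label in ("Population:", "Intervention:", "Comparison:",
                      "Outcomes:", "Study design:"):
            assert label in prompt
        assert small_corpus[0].title in prompt
        sections = ["## Role", "## Task", "## Article", "## PICOS"]
        positions = [prompt.index(s) for s in sections]
        assert positions == sorted(positions)

    def test_missing_abstract_renders_marker(self, colorectal_picos):
        bare = Citation(id="x", title="A title", abstract="   ", topic="COLORECTAL")
        assert NO_ABSTRACT_MARKER in build_prompt(bare, colorectal_picos)

    def test_deterministic(self, small_corpus, colorectal_picos):
        a = build_prompt(small_corpus[0], colorectal_picos)
        b = build_prompt(small_corpus[0], colorectal_picos)
        assert a == b

    def test_unknown_template_rejected(self, small_corpus, colorectal_picos):
        with pytest.raises(ValueError, match="template"):
            build_prompt(small_corpus[0], colorectal_picos, template="nonexistent")


class TestParseResponse:
    def test_well_formed(self):
        r = parse_response('{"explanation":"matches PICOS population","rating":4}')
        assert r.value == 4 and "population" in r.explanation

    def test_prose_preamble_before_json(self):
        r = parse_response('Sure, here is my assessment:\n{"rating":5,"explanation":"..."}')
        assert r.value == 5

    def test_first_rating_bearing_object_wins(self):
        text = '{"note":"warm-up"} {"rating":2,"explanation":"a"} {"rating":5}'
        assert parse_response(text).value == 2

    def test_out_of_scale_rejected(self):
        with pytest.raises(RatingValidationError):
            parse_response('{"rating":7}')

    def test_no_json_rejected(self):
        with pytest.raises(ResponseParseError):
            parse_response("I would rate this a 4 out of 5.")

    def test_non_integral_rating_rejected(self):
        with pytest.raises(RatingValidationError):
            parse_response('{"rating":3.5}')

    @given(st.integers(1, 5), st.text(max_size=40).filter(lambda s: s.strip()))
    def test_round_trips_serialized_ratings(self, value, explanation):
        text = json.dumps({"explanation": explanation, "rating": value})
        r = parse_response(text)
        assert r.value == value and r.explanation == explanation


class FlakyBackend:
    """Returns garbage a fixed number of times, then a valid reply."""

    def __init__(self, failures, reply='{"rating":3,"explanation":"ok"}'):
        self.failures = failures
        self.reply = reply
        self.calls = 0

    def __call__(self, prompt):
        self.calls += 1
        if self.calls <= self.failures:
            return "not json at all"
        return self.reply


class TestScreenCorpus:
    def test_mock_pipeline_rates_everything(self, small_corpus, colorectal_picos):
        picos_map = {"COLORECTAL": colorectal_picos}
        result = screen_corpus(small_corpus, picos_map, MockRatingBackend(), BackendConfig())
        assert len(result.ratings.item_ids) == 20
        assert result.ratings.n_missing == 0
        assert not result.failures
        # on-topic abstracts should overlap the PICOS frame substantially
        assert result.ratings.values.min() >= 3

    def test_retry_contract(self, small_corpus, colorectal_picos):
        backend = FlakyBackend(failures=2)
        result = screen_corpus(
            small_corpus[:1], {"COLORECTAL": colorectal_picos},
            backend, BackendConfig(max_retries=2),
        )
        assert result.ratings.values[0] == 3
        assert result.n_retries == 2

    def test_exhausted_retries_record_missing_with_reason(self, small_corpus, colorectal_picos):
        backend = FlakyBackend(failures=99)
        result = screen_corpus(
            small_corpus[:3], {"COLORECTAL": colorectal_picos},
            backend, BackendConfig(max_retries=1),
        )
        assert result.ratings.n_missing == 3
        assert all("ResponseParseError" in reason for reason in result.failures.values())

    def test_backend_failure_preserves_partial_results(self, small_corpus, colorectal_picos):
        calls = {"n": 0}

        def backend(prompt):
            calls["n"] += 1
            if calls["n"] > 2:
                raise BackendError("connection refused")
            return '{"rating":4,"explanation":"ok"}'

        with pytest.raises(HarnessError) as exc_info:
            screen_corpus(
                small_corpus[:5], {"COLORECTAL": colorectal_picos},
                backend, BackendConfig(max_retries=0),
            )
        partial = exc_info.value.partial
        assert len(partial.ratings.item_ids) == 2
        assert partial.ratings.values.tolist() == [4.0, 4.0]

    def test_mock_backend_deterministic(self, small_corpus, colorectal_picos):
        picos_map = {"COLORECTAL": colorectal_picos}
        r1 = screen_corpus(small_corpus, picos_map, MockRatingBackend(seed=1), BackendConfig())
        r2 = screen_corpus(small_corpus, picos_map, MockRatingBackend(seed=1), BackendConfig())
        assert np.array_equal(r1.ratings.values, r2.ratings.values)

    def test_missing_picos_rejected(self, small_corpus, colorectal_picos):
        with pytest.raises(ValueError, match="PICOS"):
            screen_corpus(small_corpus, {"DVT": colorectal_picos},
                          MockRatingBackend(), BackendConfig())


def rv(values):
    return RatingVector([f"i{k}" for k in range(len(values))], np.asarray(values, float))


class TestTriage:
    def test_three_band_example(self):
        labels = [t.label for t in triage(rv([1, 3, 5]), low=2, high=5)]
        assert labels == ["auto_exclude", "human_review", "auto_include"]

    def test_everything_included_at_floor(self):
        labels = {t.label for t in triage(rv([1, 2, 3, 4, 5]), low=1, high=1)}
        assert labels == {"auto_include"}

    def test_degenerate_top_band(self):
        labels = [t.label for t in triage(rv([1, 2, 3, 4, 5]), low=5, high=5)]
        assert labels == ["auto_exclude"] * 4 + ["auto_include"]

    def test_missing_rating_goes_to_human_review(self):
        labels = [t.label for t in triage(rv([np.nan]), low=2, high=4)]
        assert labels == ["human_review"]

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            triage(rv([3]), low=4, high=2)

    @given(
        st.lists(st.integers(1, 5), min_size=1, max_size=40),
        st.integers(1, 5), st.integers(1, 5),
    )
    def test_partition_and_monotone_exclusion(self, values, low, high):
        if low > high:
            low, high = high, low
        labels = [t.label for t in triage(rv(values), low, high)]
        assert len(labels) == len(values)  # every item gets exactly one label
        excluded = {i for i, lab in enumerate(labels) if lab == "auto_exclude"}
        if low < 5:
            stricter = [t.label for t in triage(rv(values), low + 1, max(low + 1, high))]
            excluded_stricter = {i for i, lab in enumerate(stricter) if lab == "auto_exclude"}
            assert excluded <= excluded_stricter
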