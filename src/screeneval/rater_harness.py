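"""Prompt assembly, backend contract, reply parsing and two-stage triage.

The harness turns a citation plus a PICOS eligibility frame (Population,
Intervention, Comparison, Outcomes, Study design) into a four-block prompt
— role, task, article, PICOS — asks a *rating backend* for a reply, and
parses an explain-then-rate JSON object out of the reply text into an
ordinal 1-5 relevance rating.  Asking the model to explain before rating
exploits autoregressive decoding: the rating token is conditioned on the
model's own stated reasoning.

A backend is anything callable as ``reply_text = backend(prompt_text)``.
Tests and simulations use :class:`MockRatingBackend`, a deterministic
keyword-overlap rater; :class:`OpenAIChatBackend` implements the same
contract against any OpenAI-compatible chat-completion endpoint and is
never exercised by the test suite.
"""

from __future__ import annotations

import json
import logging
import re
import time
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from .corpus_io import Citation
from .roc_threshold import RatingVector

__all__ = [
    "PICOS",
    "BackendConfig",
    "Rating",
    "TriageLabel",
    "ScreenResult",
    "MockRatingBackend",
    "OpenAIChatBackend",
    "BackendError",
    "ResponseParseError",
    "RatingValidationError",
    "HarnessError",
    "build_prompt",
    "parse_response",
    "screen_corpus",
    "triage",
]

logger = logging.getLogger(__name__)

TRIAGE_LABELS = ("auto_exclude", "human_review", "auto_include")

NO_ABSTRACT_MARKER = "[no abstract available]"


class BackendError(RuntimeError):
    """The backend could not produce a reply (network, auth, timeout...)."""


class ResponseParseError(ValueError):
    """No JSON object with a rating could be extracted from the reply."""


class RatingValidationError(ValueError):
    """A rating was extracted but is not an integer in 1..5."""


class HarnessError(RuntimeError):
    """Backend failed even after retries; partial results are attached."""

    def __init__(self, message: str, partial: "ScreenResult | None" = None):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class PICOS:
    """Eligibility frame for one topic; all five component fields required."""

    population: str
    intervention: str
    comparison: str
    outcomes: str
    study_design: str
    topic_title: str = ""

    def __post_init__(self) -> None:
        for name in ("population", "intervention", "comparison", "outcomes", "study_design"):
            if not getattr(self, name).strip():
                raise ValueError(f"PICOS component {name!r} must be non-empty")

    @staticmethod
    def map_from_yaml(path: str | Path) -> dict[str, "PICOS"]:
        """Load a topic -> PICOS mapping from a YAML config file."""
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return {topic: PICOS(**spec) for topic, spec in raw.items()}


@dataclass(frozen=True)
class BackendConfig:
    """Backend parameters; temperature 0 requests deterministic-leaning decoding."""

    model_name: str = "mock"
    temperature: float = 0.0
    max_retries: int = 2
    timeout: float = 60.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.max_retries < 0:
            raise ValueError("max_retries must be >= 0")


@dataclass(frozen=True)
class Rating:
    """One parsed reply: an ordinal relevance score and its explanation."""

    value: int
    explanation: str = ""

    def __post_init__(self) -> None:
        if self.value not in (1, 2, 3, 4, 5):
            raise RatingValidationError(f"rating must be in 1..5, got {self.value!r}")


@dataclass(frozen=True)
class TriageLabel:
    label: str

    def __post_init__(self) -> None:
        if self.label not in TRIAGE_LABELS:
            raise ValueError(f"label must be one of {TRIAGE_LABELS}")


_TEMPLATES: dict[str, str] = {}


def _template(name: str) -> str:
    if name not in _TEMPLATES:
        resource = files("screeneval.data").joinpath(f"prompt_{name}.txt")
        try:
            _TEMPLATES[name] = resource.read_text(encoding="utf-8")
        except FileNotFoundError as exc:
            raise ValueError(f"unknown prompt template {name!r}") from exc
    return _TEMPLATES[name]


def build_prompt(citation: Citation, picos: PICOS, template: str = "default") -> str:
    """Render the four-block prompt; deterministic for fixed inputs.

    A citation without an abstract renders an explicit marker so the model
    is never silently shown an empty field.
    """
    abstract = citation.abstract.strip() or NO_ABSTRACT_MARKER
    return _template(template).format(
        topic_title=picos.topic_title or citation.topic,
        title=citation.title,
        abstract=abstract,
        ref_type=citation.ref_type or "unknown",
        pub_year=citation.pub_year if citation.pub_year is not None else "unknown",
        population=picos.population,
        intervention=picos.intervention,
        comparison=picos.comparison,
        outcomes=picos.outcomes,
        study_design=picos.study_design,
    )


_decoder = json.JSONDecoder()


def parse_response(text: str) -> Rating:
    """Extract the first JSON object carrying a ``rating`` key from a reply.

    Replies are expected to hold ``{"explanation": ..., "rating": n}``,
    possibly surrounded by prose; with explain-then-rate prompting the first
    rating-bearing object is the decision.  Raises
    :class:`ResponseParseError` when no such object exists and
    :class:`RatingValidationError` when the rating is not an integer 1..5.
    """
    pos = 0
    found_any = False
    while True:
        start = text.find("{", pos)
        if start == -1:
            break
        try:
            obj, end = _decoder.raw_decode(text, start)
        except json.JSONDecodeError:
            pos = start + 1
            continue
        found_any = True
        if isinstance(obj, dict) and "rating" in obj:
            raw = obj["rating"]
            if isinstance(raw, bool) or not isinstance(raw, (int, float, str)):
                raise RatingValidationError(f"rating has unusable type: {raw!r}")
            try:
                value = int(raw)
            except (TypeError, ValueError) as exc:
                raise RatingValidationError(f"rating not coercible to int: {raw!r}") from exc
            if float(raw) != value:
                raise RatingValidationError(f"rating must be integral, got {raw!r}")
            explanation = str(obj.get("explanation", "") or "")
            if not explanation:
                logger.info("backend reply omitted an explanation")
            return Rating(value=value, explanation=explanation)
        pos = end
    if found_any:
        raise ResponseParseError("reply contained JSON but no 'rating' key")
    raise ResponseParseError("no JSON object found in backend reply")


@dataclass
class ScreenResult:
    """Ratings plus audit trail for one screening run."""

    ratings: RatingVector
    explanations: dict[str, str]
    failures: dict[str, str]
    n_retries: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": self.ratings.item_ids,
                "rating": self.ratings.values,
                "explanation": [
                    self.explanations.get(i, "") for i in self.ratings.item_ids
                ],
            }
        )


def screen_corpus(
    corpus: Sequence[Citation],
    picos_map: Mapping[str, PICOS],
    backend: Callable[[str], str],
    config: BackendConfig,
    template: str = "default",
) -> ScreenResult:
    """Rate every citation through the backend; failures become missing ratings.

    Parse and validation errors are retried up to ``config.max_retries``
    times, then recorded as missing with a reason.  A backend that raises
    :class:`BackendError` even after retries aborts the run with a
    :class:`HarnessError` carrying the partial results.
    """
    missing_topics = {c.topic for c in corpus} - set(picos_map)
    if missing_topics:
        raise ValueError(f"no PICOS defined for topics: {sorted(missing_topics)}")
    values: list[float] = []
    ids: list[str] = []
    explanations: dict[str, str] = {}
    failures: dict[str, str] = {}
    n_retries = 0
    for citation in corpus:
        prompt = build_prompt(citation, picos_map[citation.topic], template)
        t0 = time.perf_counter()
        rating = None
        last_error = "no attempt made"
        for attempt in range(config.max_retries + 1):
            try:
                rating = parse_response(backend(prompt))
                break
            except (ResponseParseError, RatingValidationError) as exc:
                last_error = f"{type(exc).__name__}: {exc}"
                if attempt < config.max_retries:
                    n_retries += 1
                    logger.warning("retrying %s after %s", citation.id, last_error)
            except BackendError as exc:
                last_error = f"BackendError: {exc}"
                if attempt < config.max_retries:
                    n_retries += 1
                    logger.warning("retrying %s after backend error: %s", citation.id, exc)
                else:
                    partial = ScreenResult(
                        RatingVector(ids, np.array(values, float)),
                        explanations, failures, n_retries,
                    )
                    raise HarnessError(
                        f"backend failed on {citation.id} after "
                        f"{config.max_retries} retries: {exc}",
                        partial=partial,
                    ) from exc
        ids.append(citation.id)
        if rating is None:
            values.append(np.nan)
            failures[citation.id] = last_error
            logger.warning("citation %s left unrated: %s", citation.id, last_error)
        else:
            values.append(float(rating.value))
            explanations[citation.id] = rating.explanation
        logger.debug(
            "screened %s in %.3fs", citation.id, time.perf_counter() - t0
        )
    if failures:
        logger.info("%d/%d citations left unrated", len(failures), len(corpus))
    return ScreenResult(
        RatingVector(ids, np.array(values, float)), explanations, failures, n_retries
    )


def triage(
    ratings: RatingVector, low: int, high: int
) -> list[TriageLabel]:
    """Two-stage triage: auto-exclude below ``low``, auto-include at/above ``high``.

    Everything in between goes to human review, as does a missing rating
    (an unrated citation is never silently excluded).  Requires
    ``1 <= low <= high <= 5``.
    """
    if not 1 <= low <= high <= 5:
        raise ValueError(f"need 1 <= low <= high <= 5, got low={low}, high={high}")
    labels = []
    for v in ratings.values:
        if np.isnan(v):
            labels.append(TriageLabel("human_review"))
        elif v < low:
            labels.append(TriageLabel("auto_exclude"))
        elif v >= high:
            labels.append(TriageLabel("auto_include"))
        else:
            labels.append(TriageLabel("human_review"))
    return labels


_WORD = re.compile(r"[a-z]{4,}")
_STOPWORDS = frozenset(
    "with this that from have been were will their which study studies "
    "using between among these those than more most other".split()
)


def _content_words(text: str) -> set[str]:
    return {w for w in _WORD.findall(text.lower()) if w not in _STOPWORDS}


class MockRatingBackend:
    """Deterministic keyword-overlap rater implementing the backend contract.

    Rates ``1 + min(4, overlap // 2)`` where ``overlap`` counts distinct
    content words shared between the prompt's article block and its PICOS
    block.  Purely a function of the prompt text, so identical prompts give
    identical replies; the ``seed`` is accepted for interface parity and
    recorded but never consulted.
    """

    def __init__(self, seed: int = 0):
        self.seed = seed

    def __call__(self, prompt: str) -> str:
        art = re.search(r"## Article\n(.*?)(?=\n## )", prompt, re.S)
        pic = re.search(r"## PICOS\n(.*)", prompt, re.S)
        article_words = _content_words(art.group(1) if art else prompt)
        picos_words = _content_words(pic.group(1) if pic else "")
        overlap = len(article_words & picos_words)
        value = 1 + min(4, overlap // 2)
        reply = {
            "explanation": f"{overlap} content words shared with the PICOS frame",
            "rating": value,
        }
        return json.dumps(reply)


class OpenAIChatBackend:
    """Chat-completion backend for any OpenAI-compatible HTTP endpoint.

    Same contract as the mock: prompt text in, reply text out.  Requires a
    live endpoint and credentials, so the test suite never touches it.
    """

    def __init__(
        self,
        config: BackendConfig,
        api_key: str,
        base_url: str = "https://api.openai.com/v1",
    ):
        self.config = config
        self.api_key = api_key
        self.base_url = base_url.rstrip("/")

    def __call__(self, prompt: str) -> str:
        import urllib.error
        import urllib.request

        payload = json.dumps(
            {
                "model": self.config.model_name,
                "temperature": self.config.temperature,
                "messages": [{"role": "user", "content": prompt}],
            }
        ).encode()
        req = urllib.request.Request(
            f"{self.base_url}/chat/completions",
            data=payload,
            headers={
                "Content-Type": "application/json",
                "Authorization": f"Bearer {self.api_key}",
            },
        )
        try:
            with urllib.request.urlopen(req, timeout=self.config.timeout) as resp:
                body = json.loads(resp.read().decode())
        except (urllib.error.URLError, OSError, json.JSONDecodeError) as exc:
            raise BackendError(str(exc)) from exc
        try:
            return body["choices"][0]["message"]["content"]
        except (KeyError, IndexError, TypeError) as exc:
            raise BackendError(f"unexpected completion payload: {body!r}") from exc
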