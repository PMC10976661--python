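"""Citation corpus I/O, deduplication, abstract filtering and per-topic sampling.

A screening corpus is a flat list of bibliographic records (title, abstract,
reference type, year, topic).  Two plain-text formats are supported: RFC-4180
CSV with a fixed documented header, and RIS, the tagged interchange format
reference managers emit (``TY``/``TI``/``AB``/``PY`` etc.).  The pipeline
mirrors the usual pre-screening hygiene: drop duplicate records, drop records
with no abstract, then draw a seeded per-topic random subsample.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Citation",
    "CorpusFilterLog",
    "SamplePlan",
    "read_corpus",
    "write_corpus",
    "filter_corpus",
    "sample_per_topic",
]

logger = logging.getLogger(__name__)

CSV_HEADER = ["id", "title", "abstract", "ref_type", "pub_year", "topic", "source_db"]

# RIS tag -> Citation field
_RIS_FIELDS = {
    "ID": "id",
    "TI": "title",
    "AB": "abstract",
    "TY": "ref_type",
    "PY": "pub_year",
    "KW": "topic",
    "DB": "source_db",
    "DO": "doi",
}
_RIS_LINE = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")


@dataclass
class Citation:
    """One bibliographic record flowing through dedup, sampling and screening."""

    id: str
    title: str
    abstract: str = ""
    ref_type: str = ""
    pub_year: int | None = None
    topic: str = ""
    source_db: str = ""
    doi: str = ""
    extra: dict[str, list[str]] = field(default_factory=dict)

    def has_abstract(self) -> bool:
        return bool(self.abstract.strip())


@dataclass(frozen=True)
class CorpusFilterLog:
    """Record counts through the dedup + missing-abstract filter."""

    n_input: int
    n_duplicates_removed: int
    n_missing_abstract_removed: int
    n_final: int

    def __post_init__(self) -> None:
        counts = (self.n_input, self.n_duplicates_removed,
                  self.n_missing_abstract_removed, self.n_final)
        if any(c < 0 for c in counts):
            raise ValueError("filter-log counts must be non-negative")
        if self.n_final != self.n_input - self.n_duplicates_removed - self.n_missing_abstract_removed:
            raise ValueError("filter-log counts are inconsistent")


@dataclass
class SamplePlan:
    """Per-topic sampling request; ``proportions`` is filled by the sampler."""

    per_topic_n: int = 200
    seed: int = 0
    proportions: dict[str, float] = field(default_factory=dict)


def read_corpus(path: str | Path, format: str) -> list[Citation]:
    """Read a corpus from a CSV or RIS file.

    A record with no abstract is read as an empty abstract, not an error —
    the missing-abstract filter runs later.  Malformed records raise with
    the offending record index.
    """
    path = Path(path)
    if format == "csv":
        corpus = _read_csv(path)
    elif format == "ris":
        corpus = _read_ris(path)
    else:
        raise ValueError(f"unsupported format {format!r}; use 'csv' or 'ris'")
    if not corpus:
        logger.warning("corpus file %s contained no records", path)
    return corpus


def _read_csv(path: Path) -> list[Citation]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        missing = set(CSV_HEADER) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"CSV {path} is missing columns: {sorted(missing)}")
        corpus = []
        for i, row in enumerate(reader):
            try:
                year = int(row["pub_year"]) if row["pub_year"] else None
            except ValueError as exc:
                raise ValueError(f"record {i}: bad pub_year {row['pub_year']!r}") from exc
            corpus.append(
                Citation(
                    id=row["id"],
                    title=row["title"],
                    abstract=row["abstract"],
                    ref_type=row["ref_type"],
                    pub_year=year,
                    topic=row["topic"],
                    source_db=row["source_db"],
                )
            )
    return corpus


def _read_ris(path: Path) -> list[Citation]:
    corpus: list[Citation] = []
    fields: dict[str, list[str]] = {}
    last_tag: str | None = None
    n_anonymous = 0

    def flush(record_index: int) -> None:
        nonlocal n_anonymous
        if not fields:
            return
        kw: dict = {"extra": {}}
        for tag, values in fields.items():
            value = " ".join(values)
            if tag in _RIS_FIELDS:
                name = _RIS_FIELDS[tag]
                if name == "pub_year":
                    m = re.match(r"(\d{4})", value)
                    if not m:
                        raise ValueError(f"record {record_index}: bad PY tag {value!r}")
                    kw[name] = int(m.group(1))
                else:
                    kw[name] = value
            else:
                kw["extra"][tag] = list(values)
        if "id" not in kw:
            kw["id"] = f"ris-{len(corpus):04d}"
            n_anonymous += 1
        kw.setdefault("title", "")
        corpus.append(Citation(**kw))
        fields.clear()

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            m = _RIS_LINE.match(line)
            if m:
                tag, value = m.group(1), m.group(2)
                if tag == "ER":
                    flush(len(corpus))
                    last_tag = None
                else:
                    fields.setdefault(tag, []).append(value)
                    last_tag = tag
            elif last_tag is not None:  # continuation line
                fields[last_tag][-1] += " " + line.strip()
            else:
                raise ValueError(f"malformed RIS line (no tag in scope): {line!r}")
    flush(len(corpus))
    return corpus


def write_corpus(corpus: Sequence[Citation], path: str | Path, format: str) -> None:
    """Write a corpus as CSV (fixed header) or RIS (known tags + preserved extras)."""
    path = Path(path)
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_HEADER)
            for c in corpus:
                writer.writerow([
                    c.id, c.title, c.abstract, c.ref_type,
                    "" if c.pub_year is None else c.pub_year, c.topic, c.source_db,
                ])
    elif format == "ris":
        with open(path, "w", encoding="utf-8") as fh:
            for c in corpus:
                fh.write(f"TY  - {c.ref_type}\n")
                fh.write(f"ID  - {c.id}\n")
                fh.write(f"TI  - {c.title}\n")
                if c.abstract:
                    fh.write(f"AB  - {c.abstract}\n")
                if c.pub_year is not None:
                    fh.write(f"PY  - {c.pub_year}\n")
                if c.doi:
                    fh.write(f"DO  - {c.doi}\n")
                if c.topic:
                    fh.write(f"KW  - {c.topic}\n")
                if c.source_db:
                    fh.write(f"DB  - {c.source_db}\n")
                for tag, values in c.extra.items():
                    for v in values:
                        fh.write(f"{tag}  - {v}\n")
                fh.write("ER  - \n")
    else:
        raise ValueError(f"unsupported format {format!r}; use 'csv' or 'ris'")


def _normalized_title_key(c: Citation) -> tuple:
    title = re.sub(r"[^\w\s]", "", c.title.lower())
    title = re.sub(r"\s+", " ", title).strip()
    return ("title", title, c.pub_year)


def _dedup_key(c: Citation, recipe: str) -> tuple:
    if recipe == "doi-title":
        if c.doi.strip():
            return ("doi", c.doi.strip().lower())
        return _normalized_title_key(c)
    if recipe == "title":
        return _normalized_title_key(c)
    raise ValueError(f"unknown dedup key recipe {recipe!r}; use 'doi-title' or 'title'")


def filter_corpus(
    corpus: Iterable[Citation], dedup_key: str = "doi-title"
) -> tuple[list[Citation], CorpusFilterLog]:
    """Deduplicate (first occurrence wins) then drop records without abstracts.

    ``dedup_key='doi-title'`` collapses records sharing a DOI, falling back
    to a normalized title (lowercased, punctuation stripped, whitespace
    collapsed) plus publication year for records without one;
    ``'title'`` always uses the normalized-title key.  "Missing abstract"
    means empty after whitespace stripping.  Idempotent.
    """
    corpus = list(corpus)
    seen: set[tuple] = set()
    deduped: list[Citation] = []
    for c in corpus:
        key = _dedup_key(c, dedup_key)
        if key in seen:
            continue
        seen.add(key)
        deduped.append(c)
    n_dup = len(corpus) - len(deduped)
    final = [c for c in deduped if c.has_abstract()]
    n_blank = len(deduped) - len(final)
    log = CorpusFilterLog(
        n_input=len(corpus),
        n_duplicates_removed=n_dup,
        n_missing_abstract_removed=n_blank,
        n_final=len(final),
    )
    return final, log


def sample_per_topic(
    corpus: Sequence[Citation], plan: SamplePlan
) -> tuple[list[Citation], SamplePlan]:
    """Seeded uniform per-topic subsampling without replacement.

    Topics with fewer records than ``plan.per_topic_n`` are taken whole.
    Topics are processed in sorted name order with a single generator seeded
    once, so the same corpus and seed always yield the same sample.  The
    returned plan has ``proportions`` filled with sampled/total per topic.
    """
    if any(not c.topic for c in corpus):
        raise ValueError("every citation needs a topic before per-topic sampling")
    rng = np.random.default_rng(plan.seed)
    by_topic: dict[str, list[Citation]] = {}
    for c in corpus:
        by_topic.setdefault(c.topic, []).append(c)

    chosen_ids: set[str] = set()
    proportions: dict[str, float] = {}
    for topic in sorted(by_topic):
        records = by_topic[topic]
        n_take = min(plan.per_topic_n, len(records))
        idx = rng.choice(len(records), size=n_take, replace=False)
        chosen_ids.update(records[i].id for i in idx)
        proportions[topic] = n_take / len(records)

    sampled = [c for c in corpus if c.id in chosen_ids]
    filled = SamplePlan(per_topic_n=plan.per_topic_n, seed=plan.seed, proportions=proportions)
    return sampled, filled
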