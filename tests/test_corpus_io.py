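"""Corpus reading/writing, dedup + abstract filtering, per-topic sampling."""

import numpy as np
import pytest

from screeneval import (
    Citation,
    SamplePlan,
    filter_corpus,
    read_corpus,
    sample_per_topic,
    write_corpus,
)

RIS_THREE_RECORDS = """\
TY  - JOUR
ID  - r1
TI  - CT colonography in colorectal cancer screening
AB  - A diagnostic accuracy study of CT colonography.
PY  - 2019
KW  - COLORECTAL
ER  -
TY  - JOUR
ID  - r2
TI  - Ultrasound for deep vein thrombosis
PY  - 2020
KW  - DVT
ER  -
TY  - CONF
ID  - r3
TI  - SPECT bone metastasis detection
AB  - SPECT and SPECT/CT accuracy for bone
  metastases in cancer patients.
PY  - 2018
KW  - SPECT
ER  -
"""


class TestReadWrite:
    def test_ris_missing_abstract_reads_as_empty(self, tmp_path):
        path = tmp_path / "c.ris"
        path.write_text(RIS_THREE_RECORDS)
        corpus = read_corpus(path, "ris")
        assert len(corpus) == 3
        assert corpus[1].abstract == ""
        assert corpus[0].pub_year == 2019
        assert corpus[2].ref_type == "CONF"
        # continuation line folded into the AB value
        assert "metastases in cancer patients" in corpus[2].abstract

    def test_empty_file_gives_empty_corpus(self, tmp_path, caplog):
        path = tmp_path / "empty.ris"
        path.write_text("")
        with caplog.at_level("WARNING"):
            assert read_corpus(path, "ris") == []
        assert "no records" in caplog.text

    def test_csv_round_trip_preserves_fields(self, tmp_path, small_corpus):
        path = tmp_path / "c.csv"
        write_corpus(small_corpus, path, "csv")
        back = read_corpus(path, "csv")
        assert [
            (c.id, c.title, c.abstract, c.ref_type, c.pub_year, c.topic, c.source_db)
            for c in back
        ] == [
            (c.id, c.title, c.abstract, c.ref_type, c.pub_year, c.topic, c.source_db)
            for c in small_corpus
        ]

    def test_ris_round_trip_preserves_fields(self, tmp_path, small_corpus):
        path = tmp_path / "c.ris"
        write_corpus(small_corpus, path, "ris")
        back = read_corpus(path, "ris")
        for orig, rec in zip(small_corpus, back):
            assert (rec.id, rec.title, rec.abstract, rec.pub_year, rec.topic) == (
                orig.id, orig.title, orig.abstract, orig.pub_year, orig.topic
            )

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            read_corpus(tmp_path / "x.bib", "bibtex")

    def test_bad_year_names_record(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "id,title,abstract,ref_type,pub_year,topic,source_db\n"
            "a,T,A,JOUR,not-a-year,X,\n"
        )
        with pytest.raises(ValueError, match="record 0"):
            read_corpus(path, "csv")


def _make_record(i, title, abstract="some abstract text", year=2020):
    return Citation(id=f"rec{i:05d}", title=title, abstract=abstract,
                    pub_year=year, topic="COLORECTAL")


class TestFilter:
    def test_published_pipeline_counts(self):
        """A corpus shaped like one topic's search pipeline: 3263 found,
        1564 duplicates, 338 missing abstracts, 1361 final."""
        base = [
            _make_record(i, f"unique colonography study {i}",
                         abstract="" if i < 338 else "abstract text")
            for i in range(1699)
        ]
        dupes = [
            Citation(id=f"dup{j:05d}", title=base[j % 1699].title,
                     abstract="abstract text", pub_year=2020, topic="COLORECTAL")
            for j in range(1564)
        ]
        final, log = filter_corpus(base + dupes)
        assert (log.n_input, log.n_duplicates_removed,
                log.n_missing_abstract_removed, log.n_final) == (3263, 1564, 338, 1361)
        assert len(final) == 1361

    def test_clean_corpus_passes_through(self, small_corpus):
        final, log = filter_corpus(small_corpus)
        assert final == small_corpus
        assert (log.n_duplicates_removed, log.n_missing_abstract_removed) == (0, 0)

    def test_title_normalization_collapses_case_and_whitespace(self):
        a = _make_record(0, "CT Colonography:  a Study")
        b = _make_record(1, "ct colonography a study   ")
        final, log = filter_corpus([a, b])
        assert log.n_duplicates_removed == 1
        assert final == [a]  # first occurrence wins

    def test_doi_key_overrides_title(self):
        a = Citation(id="a", title="Title one", abstract="x", doi="10.1/xyz")
        b = Citation(id="b", title="Completely different", abstract="y", doi="10.1/XYZ")
        final, log = filter_corpus([a, b])
        assert log.n_duplicates_removed == 1 and final == [a]

    def test_idempotent(self, small_corpus, rng):
        noisy = small_corpus + [small_corpus[3], _make_record(99, "t", abstract=" ")]
        once, log1 = filter_corpus(noisy)
        twice, log2 = filter_corpus(once)
        assert once == twice
        assert log2.n_duplicates_removed == 0 and log2.n_missing_abstract_removed == 0


class TestSampling:
    @staticmethod
    def _corpus(sizes):
        corpus = []
        for topic, n in sizes.items():
            for i in range(n):
                corpus.append(Citation(id=f"{topic}-{i}", title=f"{topic} {i}",
                                       abstract="a", topic=topic))
        return corpus

    def test_proportions_match_published_table(self):
        corpus = self._corpus({"COLORECTAL": 1361, "PAD": 98})
        sampled, plan = sample_per_topic(corpus, SamplePlan(per_topic_n=200, seed=1))
        assert plan.proportions["COLORECTAL"] == pytest.approx(200 / 1361)
        assert round(100 * plan.proportions["COLORECTAL"], 1) == 14.7
        assert plan.proportions["PAD"] == 1.0
        by_topic = {"COLORECTAL": 0, "PAD": 0}
        for c in sampled:
            by_topic[c.topic] += 1
        assert by_topic == {"COLORECTAL": 200, "PAD": 98}

    def test_same_seed_same_sample(self):
        corpus = self._corpus({"A": 500, "B": 300})
        s1, _ = sample_per_topic(corpus, SamplePlan(per_topic_n=100, seed=42))
        s2, _ = sample_per_topic(corpus, SamplePlan(per_topic_n=100, seed=42))
        assert [c.id for c in s1] == [c.id for c in s2]

    def test_sample_is_subset_without_replacement(self):
        corpus = self._corpus({"A": 50})
        sampled, _ = sample_per_topic(corpus, SamplePlan(per_topic_n=30, seed=0))
        ids = [c.id for c in sampled]
        assert len(ids) == len(set(ids)) == 30
        assert set(ids) <= {c.id for c in corpus}

    def test_missing_topic_rejected(self):
        with pytest.raises(ValueError, match="topic"):
            sample_per_topic([Citation(id="x", title="t", abstract="a")],
                             SamplePlan(seed=0))
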