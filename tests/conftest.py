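"""Shared fixtures: published classification counts and small corpora."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from screeneval import Citation, ConfusionCounts, ratings_fixture_from_cumulative

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# Published whole-dataset counts for the ordinal AI rater: cumulative
# (TP, FP) at each inclusion threshold, out of 148 gold positives and
# 1050 gold negatives.
AI_CUMULATIVE = {2: (141, 486), 3: (140, 366), 4: (107, 138), 5: (15, 13)}
N_POS, N_NEG = 148, 1050

# The AI rater's confusion table at its Youden-optimal threshold (>=3).
AI_COUNTS_T3 = ConfusionCounts(tp=140, fp=366, tn=684, fn=8)

CONSENSUS_COUNTS = {
    "sensitive": ConfusionCounts(tp=133, fp=119, tn=931, fn=15),
    "voting": ConfusionCounts(tp=92, fp=19, tn=1031, fn=56),
    "specific": ConfusionCounts(tp=47, fp=3, tn=1047, fn=101),
}


@pytest.fixture(scope="session")
def ai_ratings_fixture():
    """Item-level ordinal ratings + gold reconstructed from the cumulative counts."""
    return ratings_fixture_from_cumulative(AI_CUMULATIVE, N_POS, N_NEG)


@pytest.fixture
def small_corpus():
    return [
        Citation(
            id=f"c{i:02d}",
            title=f"CT colonography accuracy study number {i}",
            abstract=(
                "Computed tomography colonography detecting colorectal polyps "
                f"and cancer in adults, diagnostic accuracy cohort {i}."
            ),
            ref_type="JOUR",
            pub_year=2015 + (i % 8),
            topic="COLORECTAL",
        )
        for i in range(20)
    ]


@pytest.fixture
def colorectal_picos():
    from screeneval import PICOS

    return PICOS(
        population="adults undergoing screening for colorectal polyps or cancer",
        intervention="computed tomography colonography",
        comparison="optical colonoscopy",
        outcomes="diagnostic accuracy for detecting colorectal polyps and cancer",
        study_design="diagnostic accuracy studies",
        topic_title="CT colonography for colorectal polyps and cancer",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)
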