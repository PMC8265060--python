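import numpy as np
import pytest

from adrassess import (
    CrossTab,
    LCAT_SCALE,
    Scale,
    Category,
    load_bundled_tool,
    reference_ratings,
)


@pytest.fixture(scope="session")
def lcat_tool():
    return load_bundled_tool("LCAT")


@pytest.fixture(scope="session")
def laat_tool():
    return load_bundled_tool("LAAT")


@pytest.fixture(scope="session")
def lcat_ratings():
    """The reconstructed 26 paired causality ratings."""
    return reference_ratings("LCAT")


@pytest.fixture(scope="session")
def lcat_crosstab():
    """The minimum-disagreement causality table (rows rater 2, cols rater 1,
    categories in ascending score order unlikely..definite)."""
    counts = np.array(
        [
            [3, 0, 0, 0],
            [1, 7, 0, 0],
            [0, 3, 6, 1],
            [0, 0, 0, 5],
        ]
    )
    return CrossTab(LCAT_SCALE, counts)


@pytest.fixture
def toy_tool_doc():
    """Smallest legal decision graph: one question, two outcome leaves."""
    return {
        "tool": "TOY",
        "start": "q1",
        "questions": [
            {"id": "q1", "yes": "hit", "no": "miss", "texts": {"en": {"original": "Yes?"}}}
        ],
        "outcomes": [
            {"id": "miss", "score": 0, "labels": {"en": "Miss"}},
            {"id": "hit", "score": 1, "labels": {"en": "Hit"}},
        ],
    }


def generic_scale(k: int) -> Scale:
    return Scale("GEN", tuple(Category(f"c{i}", i) for i in range(k)))
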