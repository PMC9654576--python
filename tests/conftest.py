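from fractions import Fraction

import pytest

from ethodiv import CountVector


def brute_force_simpson(counts: dict[str, int]) -> Fraction | None:
    """Probability that two scans drawn without replacement share a behavior.

    Independent oracle: materialise every observation as a labelled slot
    and count matching ordered pairs directly.  Exact rational arithmetic,
    no shared code with the implementation under test.
    """
    slots = [label for label, n in counts.items() for _ in range(n)]
    total = len(slots)
    if total < 2:
        return None
    matches = sum(
        1
        for i in range(total)
        for j in range(total)
        if i != j and slots[i] == slots[j]
    )
    return Fraction(matches, total * (total - 1))


@pytest.fixture
def uneven_cv() -> CountVector:
    """A small vector with singletons, doubletons and a dominant behavior."""
    return CountVector({"rest": 11, "feed": 3, "groom": 2, "play": 1, "dig": 1})
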