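import numpy as np
import pytest

from atomsort import Peak2D, PeakList, ReferenceCompound, ReferenceDatabase


def random_peak_list(rng: np.random.Generator, n: int, intensity: bool = False) -> PeakList:
    h = rng.uniform(0, 10, n)
    c = rng.uniform(0, 160, n)
    if intensity:
        ints = rng.uniform(0, 1e6, n)
        return PeakList([Peak2D(float(a), float(b), float(i)) for a, b, i in zip(h, c, ints)])
    return PeakList([Peak2D(float(a), float(b)) for a, b in zip(h, c)])


@pytest.fixture
def three_peak_extract() -> PeakList:
    return PeakList([Peak2D(1.0, 10.0), Peak2D(2.0, 20.0), Peak2D(3.0, 30.0)])


@pytest.fixture
def tiny_db(three_peak_extract) -> ReferenceDatabase:
    return ReferenceDatabase(
        [
            ReferenceCompound("exact", PeakList(list(three_peak_extract))),
            ReferenceCompound(
                "offset", PeakList([Peak2D(1.1, 11.0), Peak2D(2.9, 29.0)])
            ),
        ]
    )
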