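import numpy as np
import pytest

from phylogeocat.seqio import SequenceAlignment
from phylogeocat.niche import ClimateStack, Grid


@pytest.fixture
def toy_alignment() -> SequenceAlignment:
    """Four 12-bp sequences with one A/G (transition) and one A/T
    (transversion) polymorphism."""
    return SequenceAlignment(
        (
            ("s1", "AAAACCCCGGGG"),
            ("s2", "AAAACCCCGGGG"),
            ("s3", "AGAACCCCGGGG"),
            ("s4", "AAATCCCCGGGG"),
        )
    )


@pytest.fixture
def random_alignment() -> SequenceAlignment:
    """20 x 80 alignment with scattered polymorphism, seeded."""
    rng = np.random.default_rng(42)
    base = rng.choice(list("ACGT"), size=80)
    records = []
    for i in range(20):
        seq = base.copy()
        for _ in range(rng.integers(0, 6)):
            pos = rng.integers(0, 80)
            seq[pos] = rng.choice(list("ACGT"))
        records.append((f"t{i:02d}", "".join(seq)))
    return SequenceAlignment(tuple(records))


@pytest.fixture
def gradient_stack() -> ClimateStack:
    """Two noiseless analytic layers on a 20x20 grid: value = row + col
    gradients with known closed forms."""
    rows = np.arange(20)[:, None].astype(float)
    cols = np.arange(20)[None, :].astype(float)
    return ClimateStack(
        layers={
            "bio5": Grid(values=20.0 + 0.5 * rows + 0.0 * cols, xll=70.0, yll=10.0, cellsize=0.5),
            "bio13": Grid(values=100.0 + 2.0 * cols + 0.0 * rows, xll=70.0, yll=10.0, cellsize=0.5),
        }
    )
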