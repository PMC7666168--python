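import numpy as np
import pytest

from tubeflex import bent

TUBE_DIAMETER = 63.3   # A
TUBE_RADIUS = TUBE_DIAMETER / 2
RISE = 38.46           # A per ring
INNER_SPACING = 38.5   # A, inside-edge ring spacing of the bent tube


@pytest.fixture
def toy_ring():
    """A C6 toy ring whose subunits span one rise in z, so that adjacent
    rings of a stacked tube are in restraint-network contact, with marker
    atoms at the exact inner (-x) and outer (+x) tube edge."""
    rng = np.random.default_rng(0)
    sub = np.column_stack([rng.uniform(26.0, TUBE_RADIUS, 8),
                           np.zeros(8),
                           np.linspace(0.0, 36.0, 8)])
    labels, positions = [], []
    for k in range(6):
        a = np.radians(60.0 * k)
        rot = np.array([[np.cos(a), -np.sin(a), 0],
                        [np.sin(a), np.cos(a), 0],
                        [0, 0, 1]])
        labels.extend(f"s{k}/R{i}:CA" for i in range(8))
        positions.append(sub @ rot.T)
    labels += ["inmark/R0:CA", "outmark/R0:CA"]
    positions.append(np.array([[-TUBE_RADIUS, 0.0, 0.0],
                               [TUBE_RADIUS, 0.0, 0.0]]))
    return bent.AtomSet(labels, np.vstack(positions))


@pytest.fixture
def two_blob_positions():
    """Two well-separated atom clusters; the first is the one to jitter."""
    rng = np.random.default_rng(1)
    blob_a = rng.normal(0.0, 1.5, (10, 3))
    blob_b = blob_a + np.array([24.0, 0.0, 0.0])
    return np.vstack([blob_a, blob_b])
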