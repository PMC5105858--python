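import numpy as np
import pytest

from sibsam.genome_map import Chromosome, GenomeMap, make_synthetic_map


def uniform_map(n_windows: int, cm_per_window: float = 1.0, label: str = "1",
                is_x: bool = False) -> GenomeMap:
    """Single-chromosome map with uniform windows (test scaffolding)."""
    edges = np.arange(n_windows + 1) * cm_per_window
    bp = np.arange(n_windows + 1) * 1000
    return GenomeMap(
        [Chromosome(label, is_x, bp[:-1], bp[1:], edges[:-1], edges[1:])]
    )


@pytest.fixture
def profile_map():
    """Factory: a one-chromosome map sized to a given profile."""

    def _make(values):
        return uniform_map(len(np.asarray(values)))

    return _make


@pytest.fixture(scope="session")
def tiny_map():
    """Small three-chromosome synthetic Drosophila-like map."""
    return make_synthetic_map(30, seed=3)
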