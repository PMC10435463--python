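import numpy as np
import pytest
from hypothesis import settings

import occudiff as od
from occudiff.simulate import CTRL, KO, simulate_tracks

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout():
    return od.GenomeLayout((("chrA", 25_000), ("chrB", 10_000)))


@pytest.fixture(scope="session")
def geneset(layout):
    """Two genes on chrA (one per strand, gene g1 with two exons); chrB gene-free."""
    g1 = od.GeneModel(
        "g1",
        od.Interval("chrA", 5_000, 9_000, "+"),
        (od.Interval("chrA", 5_000, 5_600, "+"), od.Interval("chrA", 8_000, 9_000, "+")),
    )
    g2 = od.GeneModel(
        "g2",
        od.Interval("chrA", 15_000, 20_000, "-"),
        (od.Interval("chrA", 15_000, 20_000, "-"),),
    )
    return od.GeneSet({"g1": g1, "g2": g2}, layout)


@pytest.fixture(scope="session")
def small_truth():
    cfg = od.SimulationConfig(
        n_chroms=1, chrom_length=800_000, n_genes=60, seed=11
    )
    return od.simulate_genome(cfg)


@pytest.fixture(scope="session")
def small_tracks(small_truth):
    return simulate_tracks(small_truth)


def constant_track(layout, value, step=50):
    data = {
        name: np.full(-(-length // step), float(value))
        for name, length in layout.chromosomes
    }
    return od.SignalTrack(layout, step, data)
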