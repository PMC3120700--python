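import numpy as np
import pytest

from hmboost.core import GeneModel, TagTrack
from hmboost.simulate import SimulationDesign


@pytest.fixture
def plus_gene() -> GeneModel:
    """Two-exon plus-strand gene: TSS 100000, exon1 1000 bp, intron 2000 bp."""
    return GeneModel(
        id="gplus", chrom="chr1", strand="+", tss=100_000,
        exons=((100_000, 100_999), (103_000, 103_999)),
    )


@pytest.fixture
def minus_gene() -> GeneModel:
    """Two-exon minus-strand gene: TSS 200000 (5' end at highest coord)."""
    return GeneModel(
        id="gminus", chrom="chr1", strand="-", tss=200_000,
        exons=((199_001, 200_000), (196_001, 197_000)),
    )


@pytest.fixture
def small_design() -> SimulationDesign:
    """Fast design for unit-level pipeline checks."""
    return SimulationDesign(n_specific=40, n_housekeeping=60, seed=7)


def track_from(chrom_positions: dict[str, list[int]], mark="markA") -> TagTrack:
    return TagTrack(
        mark_name=mark,
        tags={c: np.asarray(p, dtype=np.int64) for c, p in chrom_positions.items()},
    )


@pytest.fixture
def uniform_track(plus_gene, minus_gene) -> TagTrack:
    """Deterministic dense track: one tag every 50 bp across both loci."""
    pos = list(range(95_000, 106_000, 50)) + list(range(195_000, 205_000, 50))
    return track_from({"chr1": pos})
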