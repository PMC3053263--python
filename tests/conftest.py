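import numpy as np
import pytest

from chipcompare import synthetic as syn
from chipcompare.core import BinnedTrack, GenomeModel, ReadSet


def make_readset(reads_by_chrom, read_length=36):
    """Build a ReadSet from {chrom: [(pos, '+'|'-'), ...]}."""
    positions = {c: np.array([p for p, _ in rows], dtype=np.int64)
                 for c, rows in reads_by_chrom.items()}
    strands = {c: np.array([s == "+" for _, s in rows], dtype=bool)
               for c, rows in reads_by_chrom.items()}
    return ReadSet(read_length=read_length, positions=positions, strands=strands)


def flat_genome(lengths=(10_000,), gc=0.5, bin_size=50):
    """A genome with a constant GC track, for tests where GC must not matter."""
    names = [f"chr{i + 1}" for i in range(len(lengths))]
    values = {c: np.full(-(-L // bin_size), gc) for c, L in zip(names, lengths)}
    track = BinnedTrack(bin_size=bin_size, values=values, value_kind="fraction")
    return GenomeModel(chrom_names=names, chrom_lengths=dict(zip(names, lengths)),
                       gc_track=track)


@pytest.fixture
def small_genome():
    return flat_genome((10_000, 6_000))


@pytest.fixture
def megabase_genome():
    """1 Mb toy genome with a realistic smoothly varying GC track."""
    return syn.make_genome(2, [500_000, 500_000], seed=17)
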