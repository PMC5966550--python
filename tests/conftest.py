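import random

import pytest

from trna_arrays.detector import DetectorConfig
from trna_arrays.trna_io import ContigCalls, GeneCall


def make_genes(intervals, contig_id="c1", strand="+", kind="tRNA",
               isotype="G", anticodon="gcc"):
    """GeneCalls from (start, end) pairs, all sharing the given attributes."""
    return [GeneCall(contig_id, s, e, strand, kind, isotype, anticodon)
            for s, e in intervals]


def make_contig(intervals, contig_id="c1", contig_index=1, **kw):
    return ContigCalls(contig_id, contig_index,
                       make_genes(intervals, contig_id=contig_id, **kw))


def random_instance(rng: random.Random, max_genes=200):
    """Random sorted (start, end) intervals with mixed tight/loose gaps so
    both dense clusters and sparse stretches occur."""
    n = rng.randint(0, max_genes)
    genes = []
    pos = rng.randint(1, 1000)
    for _ in range(n):
        length = rng.randint(60, 95)
        genes.append((pos, pos + length - 1))
        if rng.random() < 0.6:
            gap = rng.randint(5, 400)  # dense stretch
        else:
            gap = rng.randint(400, 8000)  # sparse stretch
        pos += length + gap
    return genes


@pytest.fixture
def small_cfg():
    return DetectorConfig(min_trnas=3, min_density=2.0)


@pytest.fixture
def default_cfg():
    return DetectorConfig()
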