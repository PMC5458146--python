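import numpy as np
import pytest

from paleospread.occurrence_io import OccurrenceRecord, TaxonRank


def make_record(
    i=0,
    taxon="Synthetica speciesA",
    rank=TaxonRank.SPECIES,
    coll="c1",
    ref="r1",
    lat=10.0,
    lon=10.0,
    max_ma=100.0,
    min_ma=99.0,
    flags=frozenset(),
):
    return OccurrenceRecord(
        occurrence_id=f"o{i}",
        taxon_name=taxon,
        taxon_rank=rank,
        collection_id=coll,
        reference_id=ref,
        palaeolat=lat,
        palaeolon=lon,
        interval_max_ma=max_ma,
        interval_min_ma=min_ma,
        flags=flags,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_collection_pool():
    """A small pool over 3 collections, enumerable over all 6 orders.

    Taxon occurrence counts: A x4, B x2, C x1, D x1, E x1; C/D/E are
    single-collection taxa.
    """
    occ = [
        ("A", "c1"), ("B", "c1"), ("A", "c2"), ("C", "c2"), ("B", "c2"),
        ("D", "c3"), ("A", "c3"), ("E", "c3"), ("A", "c1"),
    ]
    return [make_record(i, t, coll=c) for i, (t, c) in enumerate(occ)]
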