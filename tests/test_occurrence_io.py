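"""Reading, cleaning, time-binning and pool diagnostics."""

import numpy as np
import pytest

from paleospread import occurrence_io as oio
from paleospread.occurrence_io import (
    FilterConfig,
    TaxonRank,
    TimeBin,
    apply_taxon_filters,
    assign_time_bins,
    collapse_duplicates,
    default_bin_scheme,
    pool_diagnostics,
    read_occurrence_table,
    reference_threshold_filter,
    write_occurrence_table,
)
from paleospread.synthetic import WorldConfig, generate_world

from conftest import make_record


class TestReadWrite:
    def test_empty_file_header_only(self, tmp_path):
        p = tmp_path / "empty.csv"
        cols = oio.Dialect().mandatory
        p.write_text(",".join(cols) + "\n")
        records, errors = read_occurrence_table(p)
        assert records == [] and errors == []

    def test_out_of_bounds_latitude_collected_not_dropped(self, tmp_path):
        p = tmp_path / "bad.csv"
        rows = []
        for i, lat in enumerate([10.0, 95.0, -45.0]):
            rows.append(
                f"o{i},c{i},Taxon sp,species,{lat},20.0,r{i},100,99"
            )
        p.write_text(
            "occurrence_no,collection_no,accepted_name,accepted_rank,"
            "paleolat,paleolng,reference_no,max_ma,min_ma\n" + "\n".join(rows)
        )
        records, errors = read_occurrence_table(p)
        assert len(records) == 2
        assert len(errors) == 1
        assert errors[0].row == 2 and "palaeolat" in errors[0].message

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        p = tmp_path / "nocol.csv"
        p.write_text("occurrence_no,collection_no\no1,c1\n")
        with pytest.raises(ValueError, match="mandatory"):
            read_occurrence_table(p)

    def test_synthetic_world_round_trips_exactly(self, tmp_path):
        records, _ = generate_world(WorldConfig(n_collections=20, rng_seed=5))
        assert len(records) > 100
        p = tmp_path / "world.csv"
        write_occurrence_table(records, p)
        back, errors = read_occurrence_table(p)
        assert errors == []
        # bit-for-bit strings, full-precision floats; bin annotation not serialized
        from dataclasses import replace

        assert back == [replace(r, time_bin=None) for r in records]


class TestTaxonFilters:
    def test_unflagged_species_records_all_retained(self):
        records = [make_record(i) for i in range(10)]
        kept, tally = apply_taxon_filters(records)
        assert len(kept) == 10
        assert tally["removed_total"] == 0

    def test_every_flag_category_excludes(self):
        flags = ["marine", "flying", "ichno", "oo", "soft_tissue"]
        records = [make_record(i, flags=frozenset({f})) for i, f in enumerate(flags)]
        kept, tally = apply_taxon_filters(records)
        assert kept == []
        assert all(tally[f"flag_{f}"] == 1 for f in flags)

    def test_hand_counted_fixture(self):
        records = (
            [make_record(i) for i in range(13)]
            + [make_record(13 + i, flags=frozenset({"ichno"})) for i in range(4)]
            + [make_record(17 + i, rank=TaxonRank.INDETERMINATE) for i in range(3)]
        )
        kept, tally = apply_taxon_filters(records)
        assert len(kept) == 13
        assert tally["flag_ichno"] == 4 and tally["indeterminate"] == 3

    def test_filtering_is_idempotent(self):
        records = [
            make_record(i, flags=frozenset({"marine"}) if i % 3 == 0 else frozenset())
            for i in range(30)
        ]
        once, _ = apply_taxon_filters(records)
        twice, tally = apply_taxon_filters(once)
        assert twice == once and tally["removed_total"] == 0

    def test_name_list_exclusion(self):
        records = [make_record(0, taxon="Wastebasketus sp"), make_record(1)]
        kept, tally = apply_taxon_filters(
            records, FilterConfig(exclude_names=frozenset({"Wastebasketus sp"}))
        )
        assert len(kept) == 1 and tally["name_excluded"] == 1


class TestTimeBins:
    BINS = [TimeBin("Tr4", 237.0, 201.3), TimeBin("J1", 201.3, 191.9)]

    @pytest.mark.parametrize(
        "max_ma,min_ma,expected",
        [
            (210.0, 205.0, "Tr4"),  # entirely inside
            (202.0, 199.0, None),  # spans the 201.3 boundary -> unassigned
            (237.0, 201.3, "Tr4"),  # boundary-equal ages count as inside
            (191.0, 190.0, None),  # younger than the scheme
        ],
    )
    def test_containment_rule(self, max_ma, min_ma, expected):
        [r] = assign_time_bins(
            [make_record(max_ma=max_ma, min_ma=min_ma)], self.BINS
        )
        assert r.time_bin == expected

    def test_assignment_matches_bruteforce_containment(self, rng):
        bins = default_bin_scheme()
        records = []
        for i in range(100):
            a = rng.uniform(45, 255)
            b = a - rng.uniform(0, 15)
            records.append(make_record(i, max_ma=a, min_ma=max(0.0, b)))
        assigned = assign_time_bins(records, bins)
        for r in assigned:
            expected = None
            for bn in bins:
                if r.interval_max_ma <= bn.start_ma and r.interval_min_ma >= bn.end_ma:
                    expected = bn.name
                    break
            assert r.time_bin == expected

    def test_overlapping_scheme_rejected(self):
        bad = [TimeBin("a", 100.0, 90.0), TimeBin("b", 95.0, 85.0)]
        with pytest.raises(ValueError):
            assign_time_bins([make_record()], bad)

    def test_assigned_records_partition(self):
        bins = default_bin_scheme()
        records = [make_record(i, max_ma=m, min_ma=m - 1.0) for i, m in
                   enumerate(np.linspace(70, 250, 50))]
        assigned = assign_time_bins(records, bins)
        for r in assigned:
            n_containing = sum(
                1 for b in bins if b.contains(r.interval_max_ma, r.interval_min_ma)
            )
            assert (r.time_bin is not None) == (n_containing >= 1)


class TestPoolDiagnostics:
    def test_single_taxon_pool(self):
        pool = [make_record(i, taxon="A", coll=f"c{i % 3}") for i in range(5)]
        d = pool_diagnostics(pool)
        assert d.raw_richness == 1 and d.dominance == 1.0

    def test_all_singletons_have_zero_coverage(self):
        pool = [make_record(i, taxon=f"t{i}", coll=f"c{i}") for i in range(10)]
        assert pool_diagnostics(pool).goods_u == 0.0

    def test_hand_counted_u_and_dominance(self):
        # A x4, B x3, C x2 across multiple collections; D x1 single-collection
        occ = [("A", "c1"), ("A", "c2"), ("A", "c3"), ("A", "c1"),
               ("B", "c1"), ("B", "c2"), ("B", "c3"),
               ("C", "c2"), ("C", "c3"), ("D", "c1")]
        pool = [make_record(i, t, coll=c) for i, (t, c) in enumerate(occ)]
        d = pool_diagnostics(pool)
        assert d.dominance == pytest.approx(0.4)
        assert d.goods_u == pytest.approx(0.9)

    def test_empty_pool_signalled_not_available(self):
        d = pool_diagnostics([])
        assert d.n_occurrences == 0 and d.goods_u is None and d.dominance is None

    def test_permutation_invariance(self, rng, three_collection_pool):
        base = pool_diagnostics(three_collection_pool)
        shuffled = list(three_collection_pool)
        rng.shuffle(shuffled)
        assert pool_diagnostics(shuffled) == base


class TestReferenceThreshold:
    def test_boundary_semantics(self):
        flags = reference_threshold_filter(
            [{"n_references": 21}, {"n_references": 20}, {"n_references": 0}]
        )
        assert flags == [True, True, False]

    def test_matches_elementwise_comparison(self, rng):
        ns = rng.integers(0, 60, 50)
        flags = reference_threshold_filter([{"n_references": int(n)} for n in ns])
        assert flags == [n >= 20 for n in ns]


class TestCollapseDuplicates:
    def test_same_taxon_same_collection_collapses(self):
        records = [make_record(0, "A", coll="c1"), make_record(1, "A", coll="c1"),
                   make_record(2, "A", coll="c2")]
        assert len(collapse_duplicates(records)) == 2


def test_default_scheme_is_valid_and_9myr():
    bins = default_bin_scheme()
    assert bins[0].name == "Tr1" and bins[-1].name == "Pg2"
    for a, b in zip(bins, bins[1:]):
        assert b.start_ma <= a.end_ma
    durations = [b.duration_myr for b in bins]
    assert 5.0 <= np.median(durations) <= 11.0
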