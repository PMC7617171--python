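import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fossilbridge import pbdb_io
from fossilbridge.pbdb_io import (
    BinnedCounts,
    OccurrenceRecord,
    bin_family,
    clean_occurrences,
    draw_collection_ages,
    read_occurrences,
)


def _rec(species="Sp a", family="Famidae", coll=1, max_ma=50.0, min_ma=45.0, **kw):
    return OccurrenceRecord(
        species_name=species, family=family, collection_id=coll,
        max_ma=max_ma, min_ma=min_ma, **kw,
    )


class TestRead:
    def test_passthrough_with_trace_flag(self, occurrence_csv):
        records = read_occurrences(occurrence_csv)
        assert len(records) == 8
        assert sum(r.is_trace for r in records) == 1
        assert records[0].max_ma == 66.0 and records[0].min_ma == 60.0
        # missing fields preserved, not dropped, at read time
        assert records[5].species_name is None
        assert records[6].family is None

    def test_inverted_age_range_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "accepted_name,family,collection_no,max_ma,min_ma\nA b,F,1,10.0,20.0\n"
        )
        with pytest.raises(ValueError, match="row 0"):
            read_occurrences(path)

    def test_unmappable_column_is_fatal(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("name,family,collection_no,max_ma,min_ma\nA b,F,1,20,10\n")
        with pytest.raises(ValueError, match="accepted_name"):
            read_occurrences(path)


class TestClean:
    def test_filters_and_report(self, occurrence_csv):
        records = read_occurrences(occurrence_csv)
        kept, rep = clean_occurrences(records)
        assert rep.n_input == 8
        assert rep.n_removed_no_family == 1
        assert rep.n_removed_no_species == 1
        assert rep.n_removed_trace == 1
        assert rep.n_removed_age_range == 0
        assert rep.n_output == len(kept) == 5
        assert rep.n_output == rep.n_input - (
            rep.n_removed_no_family + rep.n_removed_no_species
            + rep.n_removed_age_range + rep.n_removed_trace
        )

    @pytest.mark.parametrize(
        "age_range,kept", [(25.0, False), (20.0, True), (19.9, True)]
    )
    def test_age_range_cut_is_strict(self, age_range, kept):
        # ranges wider than 20 Myr are too uncertain; exactly 20 stays
        recs = [_rec(max_ma=50.0 + age_range, min_ma=50.0)]
        out, rep = clean_occurrences(recs)
        assert (len(out) == 1) is kept
        assert rep.n_removed_age_range == (0 if kept else 1)

    def test_first_failing_rule_wins(self):
        rec = _rec(species=None, family=None, max_ma=99.0, min_ma=10.0, is_trace=True)
        _, rep = clean_occurrences([rec])
        assert rep.n_removed_no_family == 1
        assert rep.n_removed_no_species == 0
        assert rep.n_removed_trace == 0

    def test_clean_is_idempotent(self, occurrence_csv):
        records = read_occurrences(occurrence_csv)
        once, _ = clean_occurrences(records)
        twice, rep = clean_occurrences(once)
        assert twice == once
        assert rep.n_output == rep.n_input


class TestCollectionAges:
    def test_shared_collection_shares_age(self):
        recs = [_rec(coll=7), _rec(species="Sp b", coll=7), _rec(species="Sp c", coll=8)]
        dated = draw_collection_ages(recs, seed=0)
        assert dated[0].age == dated[1].age
        assert all(r.min_ma <= r.age <= r.max_ma for r in dated)

    def test_degenerate_interval(self):
        dated = draw_collection_ages([_rec(max_ma=33.0, min_ma=33.0)], seed=1)
        assert dated[0].age == 33.0

    def test_uniform_mean(self):
        recs = [_rec(coll=i, max_ma=70.0, min_ma=60.0) for i in range(10_000)]
        ages = [r.age for r in draw_collection_ages(recs, seed=3)]
        assert abs(np.mean(ages) - 65.0) < 0.2

    def test_reproducible(self):
        recs = [_rec(coll=i) for i in range(20)]
        a = [r.age for r in draw_collection_ages(recs, seed=11)]
        b = [r.age for r in draw_collection_ages(recs, seed=11)]
        assert a == b


class TestBinning:
    def _dated(self, triples):
        return [
            OccurrenceRecord(
                species_name=s, family="F", collection_id=i,
                max_ma=age, min_ma=age, age=age,
            )
            for i, (s, age) in enumerate(triples)
        ]

    def test_bin_convention_and_dedup(self):
        recs = self._dated(
            [("A a", 65.4), ("A a", 65.2), ("A a", 65.9), ("B b", 65.1), ("C c", 12.5)]
        )
        bc = bin_family(recs, "F", n_extant=0)
        assert bc.counts[65] == 2  # duplicate species collapse within the bin
        assert bc.counts[12] == 1
        assert bc.counts.sum() == 3

    def test_order_invariance(self):
        triples = [("A a", 65.4), ("B b", 65.1), ("C c", 12.5), ("A a", 12.1)]
        fwd = bin_family(self._dated(triples), "F", 0)
        rev = bin_family(self._dated(triples[::-1]), "F", 0)
        assert np.array_equal(fwd.counts, rev.counts)

    def test_sum_equals_distinct_species_bin_pairs(self):
        triples = [("A a", 65.4), ("A a", 65.2), ("B b", 65.9), ("A a", 12.0)]
        bc = bin_family(self._dated(triples), "F", 0)
        pairs = {(s, int(a)) for s, a in triples}
        assert bc.counts.sum() == len(pairs)

    def test_no_data_family_errors(self):
        with pytest.raises(ValueError, match="no data"):
            bin_family(self._dated([("A a", 5.0)]), "Other", 0)

    def test_pipeline_reproducible(self, occurrence_csv):
        def run():
            kept, _ = clean_occurrences(read_occurrences(occurrence_csv))
            dated = draw_collection_ages(kept, seed=9)
            return bin_family(dated, "Alphidae", n_extant=3).counts

        assert np.array_equal(run(), run())


@settings(derandomize=True, max_examples=100)
@given(
    st.lists(
        st.tuples(
            st.one_of(st.none(), st.sampled_from(["Sp a", "Sp b"])),
            st.one_of(st.none(), st.sampled_from(["Fam"])),
            st.floats(min_value=0.0, max_value=100.0),
            st.floats(min_value=0.0, max_value=30.0),
            st.booleans(),
        ),
        max_size=30,
    )
)
def test_cleaning_is_idempotent_and_conserves_counts(rows):
    recs = [
        _rec(species=s, family=f, coll=i, max_ma=lo + width, min_ma=lo, is_trace=tr)
        for i, (s, f, lo, width, tr) in enumerate(rows)
    ]
    once, rep = clean_occurrences(recs)
    assert rep.n_input == len(recs)
    assert rep.n_output == rep.n_input - (
        rep.n_removed_no_family + rep.n_removed_no_species
        + rep.n_removed_age_range + rep.n_removed_trace
    )
    twice, rep2 = clean_occurrences(once)
    assert twice == once
    assert rep2.n_output == rep2.n_input


class TestBinnedCounts:
    def test_rejects_all_zero(self):
        with pytest.raises(ValueError, match="empty"):
            BinnedCounts(family="X", counts=np.zeros(4, dtype=int), n_extant=1)

    def test_derived_fossil_ages(self, extinct_counts):
        # oldest nonzero bin is 6 -> older edge 7; youngest nonzero bin 3
        assert extinct_counts.oldest_fossil == 7.0
        assert extinct_counts.youngest_fossil == 3.0
        assert not extinct_counts.is_extant
        assert extinct_counts.n_fossils == 4
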