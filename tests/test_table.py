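"""Community-table I/O, aggregation, exclusion and ranking."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from commstruct.table import (
    AbundanceVector,
    CommunityTable,
    TableFormatError,
    TableValidationError,
    TaxonRecord,
    aggregate,
    exclude_taxa,
    read_table,
    relative_abundance,
    write_table,
)
from conftest import make_random_table


class TestReadTable:
    def test_single_row(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text("taxon_id,species,family,order,guild,count\n"
                     "a,spA,famX,ordI,predator,7\n")
        t = read_table(p)
        assert t.total == 7 and len(t) == 1
        assert t.records[0].species == "spA"

    def test_four_row_fixture(self, four_row_csv):
        t = read_table(four_row_csv)
        assert t.total == 20 and len(t) == 4

    def test_duplicate_taxon_id_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("taxon_id,species,family,order,guild,count\n"
                     "a,spA,famX,ordI,predator,1\n"
                     "a,spB,famX,ordI,predator,2\n")
        with pytest.raises(TableValidationError, match="duplicate"):
            read_table(p)

    @pytest.mark.parametrize("bad,err", [
        ("a,spA,famX,ordI,predator,-3", "negative"),
        ("a,spA,famX,ordI,predator,2.5", "not an integer"),
        ("a,spA,famX,ordI,predator,many", "not an integer"),
    ])
    def test_bad_counts_name_the_row(self, tmp_path, bad, err):
        p = tmp_path / "bad.csv"
        p.write_text(f"taxon_id,species,family,order,guild,count\n{bad}\n")
        with pytest.raises(TableValidationError, match=f"row 2.*{err}"):
            read_table(p)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "mc.csv"
        p.write_text("taxon_id,species,family,order,count\na,spA,f,o,3\n")
        with pytest.raises(TableFormatError, match="guild"):
            read_table(p)

    def test_zero_count_rows_retained_and_flagged(self, tmp_path):
        p = tmp_path / "z.csv"
        p.write_text("taxon_id,species,family,order,guild,count\n"
                     "a,spA,famX,ordI,predator,0\n"
                     "b,spB,famX,ordI,predator,4\n")
        t = read_table(p)
        assert len(t) == 2 and t.n_zero_count == 1 and t.total == 4

    def test_round_trip_preserves_counts_labels_and_filters(self, tmp_path, rng):
        t = exclude_taxa(make_random_table(rng, n_taxa=8), "family", "f0")
        p = tmp_path / "rt.csv"
        write_table(t, p)
        t2 = read_table(p)
        assert [r.count for r in t2.records] == [r.count for r in t.records]
        assert [r.species for r in t2.records] == [r.species for r in t.records]
        assert t2.metadata.get("filters") == t.metadata.get("filters")


class TestAggregate:
    def test_family_additivity(self):
        t = CommunityTable(records=(
            TaxonRecord("a", "spA", "famX", "ordI", "predator", 3),
            TaxonRecord("b", "spB", "famX", "ordI", "predator", 4),
        ))
        v = aggregate(t, "family")
        assert v.counts == (7,) and v.labels == ("famX",)

    def test_tie_break_by_first_appearance(self):
        t = CommunityTable(records=(
            TaxonRecord("a", "a", "f1", "o", "predator", 10),
            TaxonRecord("b", "b", "f2", "o", "predator", 5),
            TaxonRecord("c", "c", "f3", "o", "predator", 5),
        ))
        v = aggregate(t, "species")
        assert v.counts == (10, 5, 5) and v.labels == ("a", "b", "c")

    def test_unknown_level_rejected(self, four_row_csv):
        with pytest.raises(ValueError, match="level"):
            aggregate(read_table(four_row_csv), "genus")

    @given(st.integers(0, 10_000))
    def test_total_conserved_across_levels(self, seed):
        t = make_random_table(np.random.default_rng(seed))
        n = {lv: sum(aggregate(t, lv).counts) for lv in ("species", "family", "order")}
        assert n["species"] == n["family"] == n["order"] == t.total


class TestExcludeTaxa:
    def test_dominant_family_removed(self):
        t = CommunityTable(records=(
            TaxonRecord("a", "ant", "Formicidae", "Hymenoptera", "predator", 80),
            TaxonRecord("b", "beetle", "Carabidae", "Coleoptera", "predator", 20),
        ))
        t2 = exclude_taxa(t, "family", "Formicidae")
        assert t2.total == 20 and len(t2) == 1
        assert t.total == 100  # original untouched
        assert "exclude family=Formicidae" in t2.metadata["filters"]

    def test_absent_label_warns_and_returns_same_table(self, four_row_csv):
        t = read_table(four_row_csv)
        with pytest.warns(UserWarning, match="no record"):
            t2 = exclude_taxa(t, "family", "Nosuchidae")
        assert t2 is t

    @given(st.integers(0, 10_000))
    def test_exclusion_commutes_with_aggregation(self, seed):
        t = make_random_table(np.random.default_rng(seed))
        label = t.records[0].family
        left = aggregate(exclude_taxa(t, "family", label), "family") \
            if any(r.family != label and r.count > 0 for r in t.records) else None
        if left is None:
            return
        full = aggregate(t, "family")
        dropped = {lab: n for lab, n in zip(full.labels, full.counts) if lab != label}
        assert dict(zip(left.labels, left.counts)) == dropped


class TestRelativeAbundance:
    @pytest.mark.parametrize("counts,expected", [
        ((5,), (1.0,)),
        ((3, 1), (0.75, 0.25)),
        ((10, 5, 3, 2), (0.50, 0.25, 0.15, 0.10)),
    ])
    def test_proportions(self, counts, expected):
        v = AbundanceVector(level="species", counts=counts,
                            labels=tuple(f"s{i}" for i in range(len(counts))))
        assert np.allclose(relative_abundance(v), expected)
        assert abs(sum(relative_abundance(v)) - 1.0) < 1e-12

    def test_vector_invariants(self):
        with pytest.raises(ValueError):
            AbundanceVector(level="species", counts=(1, 2), labels=("a", "b"))
        with pytest.raises(ValueError):
            AbundanceVector(level="species", counts=(2, 0), labels=("a", "b"))
        with pytest.raises(ValueError):
            AbundanceVector(level="species", counts=(), labels=())
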