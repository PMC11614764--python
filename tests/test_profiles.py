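"""Lineage parsing, table IO, de-duplication, aggregation, prevalence, Jaccard."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from keystonenet.lineage import RANKS, LineageError, TaxonLineage
from keystonenet.profiles import (
    AbundanceTable,
    ProfileParseError,
    SampleMetadata,
    aggregate_to_rank,
    filter_prevalence,
    read_taxonomic_profile,
    select_one_sample_per_participant,
    site_similarity,
    write_abundance_tsv,
)

from conftest import species_lineage


class TestLineage:
    @pytest.mark.parametrize(
        "s,terminal",
        [
            ("k__Bacteria", "kingdom"),
            ("k__Bacteria|p__Firmicutes|c__Clostridia", "class"),
            (
                "k__Bacteria|p__Firmicutes|c__Clostridia|o__Eubacteriales|"
                "f__Oscillospiraceae|g__Agathobaculum|s__Agathobaculum_butyriciproducens",
                "species",
            ),
        ],
    )
    def test_roundtrip_and_terminal_rank(self, s, terminal):
        lin = TaxonLineage.from_string(s)
        assert str(lin) == s
        assert lin.terminal_rank == terminal

    @pytest.mark.parametrize(
        "bad",
        [
            "k__Bacteria|s__X",  # skips intermediate ranks
            "p__Firmicutes",  # starts below kingdom
            "k__Bacteria|g__X|p__Y",  # out of order
            "x__Nonsense",
        ],
    )
    def test_malformed_lineages_rejected(self, bad):
        with pytest.raises(LineageError):
            TaxonLineage.from_string(bad)

    @settings(max_examples=50, deadline=None)
    @given(
        depth=st.integers(min_value=1, max_value=7),
        data=st.data(),
    )
    def test_roundtrip_property(self, depth, data):
        names = tuple(
            data.draw(st.text(alphabet="abcXYZ_123", min_size=1, max_size=8))
            for _ in range(depth)
        )
        lin = TaxonLineage(names)
        assert TaxonLineage.from_string(str(lin)) == lin
        assert lin.terminal_rank == RANKS[depth - 1]


class TestReadProfile:
    def test_terminal_rank_filtering_and_rounding(self, tmp_path):
        p = tmp_path / "profile.tsv"
        p.write_text(
            "clade_name\tsampleA\tsampleB\n"
            "k__Bacteria|p__Firmicutes\t1\t2\n"
            "k__Bacteria|p__Firmicutes|c__C|o__O|f__F|g__G\t5\t6\n"
            "k__Bacteria|p__Firmicutes|c__C|o__O|f__F|g__G|s__G_sp\t10.4\t10.6\n"
        )
        table = read_taxonomic_profile(p, rank="species")
        assert table.n_taxa == 1
        assert table.counts.tolist() == [[10], [11]]
        genus = read_taxonomic_profile(p, rank="genus")
        assert genus.n_taxa == 1 and genus.counts.tolist() == [[5], [6]]

    def test_malformed_lineage_names_row(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("clade\ts1\nk__Bacteria|s__X\t3\n")
        with pytest.raises(ProfileParseError, match="k__Bacteria|s__X"):
            read_taxonomic_profile(p, rank="species")

    def test_non_numeric_cell_names_sample(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("clade\ts1\nk__Bacteria\toops\n")
        with pytest.raises(ProfileParseError, match="s1"):
            read_taxonomic_profile(p, rank="kingdom")

    def test_write_read_roundtrip_bit_exact(self, tmp_path, small_table):
        p = tmp_path / "table.tsv"
        write_abundance_tsv(small_table, p)
        back = read_taxonomic_profile(p, rank="species")
        assert back.sample_ids == small_table.sample_ids
        assert [str(t) for t in back.taxa] == [str(t) for t in small_table.taxa]
        np.testing.assert_array_equal(back.counts, small_table.counts)


class TestDeduplication:
    def _meta(self):
        return SampleMetadata(
            participant={"s1": "p1", "s2": "p1", "s3": "p2", "s4": "p2"},
            dataset={s: "d" for s in ["s1", "s2", "s3", "s4"]},
        )

    def test_one_per_participant(self, small_table):
        out = select_one_sample_per_participant(small_table, self._meta(), seed=0)
        assert out.n_samples == 2
        kept = set(out.sample_ids)
        assert len(kept & {"s1", "s2"}) == 1 and len(kept & {"s3", "s4"}) == 1

    def test_identity_when_unique(self, small_table):
        meta = SampleMetadata(participant={s: s for s in small_table.sample_ids})
        out = select_one_sample_per_participant(small_table, meta, seed=5)
        assert out.sample_ids == small_table.sample_ids
        np.testing.assert_array_equal(out.counts, small_table.counts)

    def test_missing_metadata_lists_orphans(self, small_table):
        meta = SampleMetadata(participant={"s1": "p1"})
        with pytest.raises(KeyError, match="s2"):
            select_one_sample_per_participant(small_table, meta, seed=0)

    def test_selection_uniform_across_seeds(self, small_table):
        # over many seeds each of a participant's 2 samples is chosen ~50/50,
        # matching an independent uniform-choice oracle's expectation
        meta = self._meta()
        picks = [
            "s1" in select_one_sample_per_participant(small_table, meta, seed=s).sample_ids
            for s in range(100)
        ]
        assert select_one_sample_per_participant(
            small_table, meta, seed=7
        ).sample_ids == select_one_sample_per_participant(small_table, meta, seed=7).sample_ids
        assert 30 <= sum(picks) <= 70  # binomial(100, 0.5) within ~4 sd


class TestAggregate:
    def test_additivity_within_genus(self, small_table):
        genus = aggregate_to_rank(small_table, "genus")
        assert genus.n_taxa == 2
        np.testing.assert_array_equal(
            genus.counts[:, 0], small_table.counts[:, 0] + small_table.counts[:, 1]
        )

    def test_identity_at_own_rank(self, small_table):
        out = aggregate_to_rank(small_table, "species")
        np.testing.assert_array_equal(out.counts, small_table.counts)

    def test_rank_below_table_errors(self, small_table):
        genus = aggregate_to_rank(small_table, "genus")
        with pytest.raises(ValueError):
            aggregate_to_rank(genus, "species")

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_conservation_per_sample(self, seed):
        rng = np.random.default_rng(seed)
        taxa = [
            species_lineage(g, f"sp{i}") for g in ["A", "B", "C"] for i in range(3)
        ]
        counts = rng.integers(0, 100, size=(5, 9))
        table = AbundanceTable([f"s{i}" for i in range(5)], taxa, counts, "species")
        for rank in ("genus", "family", "order", "phylum", "kingdom"):
            agg = aggregate_to_rank(table, rank)
            np.testing.assert_array_equal(agg.counts.sum(axis=1), counts.sum(axis=1))


class TestPrevalence:
    def _table(self, presence_counts, n_samples=10):
        taxa = [species_lineage("G", f"sp{i}") for i in range(len(presence_counts))]
        counts = np.zeros((n_samples, len(presence_counts)), dtype=int)
        for j, k in enumerate(presence_counts):
            counts[:k, j] = 1
        return AbundanceTable([f"s{i}" for i in range(n_samples)], taxa, counts, "species")

    def test_boundary_inclusive(self):
        table = self._table([2, 1, 5])
        out = filter_prevalence(table, 0.20)
        assert [t.terminal_name for t in out.taxa] == ["G_sp0", "G_sp2"]

    def test_threshold_zero_keeps_all(self):
        table = self._table([0, 1, 10])
        out = filter_prevalence(table, 0.0)
        assert out.n_taxa == 3

    def test_idempotent(self):
        table = self._table([1, 2, 3, 9])
        once = filter_prevalence(table, 0.20)
        twice = filter_prevalence(once, 0.20)
        np.testing.assert_array_equal(once.counts, twice.counts)

    def test_empty_result_warns(self):
        table = self._table([1, 1])
        with pytest.warns(UserWarning):
            out = filter_prevalence(table, 0.9)
        assert out.n_taxa == 0


class TestSiteSimilarity:
    def _presence_table(self, rows):
        rows = np.asarray(rows)
        taxa = [species_lineage("G", f"sp{i}") for i in range(rows.shape[1])]
        return AbundanceTable(
            [f"s{i}" for i in range(rows.shape[0])], taxa, rows, "species"
        )

    def test_worked_example(self):
        # {A,B,C} vs {B,C,D}: intersection 2, union 4
        table = self._presence_table([[1, 1, 1, 0], [0, 1, 1, 1]])
        mean, sim = site_similarity(table)
        assert mean == pytest.approx(0.5)
        assert sim[0, 1] == pytest.approx(0.5)

    def test_identical_and_disjoint(self):
        table = self._presence_table([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]])
        _, sim = site_similarity(table)
        assert sim[0, 1] == 1.0 and sim[0, 2] == 0.0

    def test_matches_exhaustive_pair_oracle(self):
        rng = np.random.default_rng(3)
        rows = rng.integers(0, 2, size=(5, 12))
        mean, sim = site_similarity(self._presence_table(rows))
        oracle = []
        for i, j in itertools.combinations(range(5), 2):
            inter = np.sum(rows[i].astype(bool) & rows[j].astype(bool))
            union = np.sum(rows[i].astype(bool) | rows[j].astype(bool))
            expect = inter / union if union else 0.0
            oracle.append(expect)
            assert sim[i, j] == pytest.approx(expect)
            assert sim[j, i] == pytest.approx(expect)
        assert mean == pytest.approx(np.mean(oracle))
        assert 0.0 <= mean <= 1.0

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            site_similarity(self._presence_table([[1, 0]]))
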