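import logging

import numpy as np
import pandas as pd
import pytest

from tsskit.dataset import (
    LabeledDataset,
    WindowInstance,
    WindowParams,
    build_dataset,
    extract_window,
    read_biomart_export,
    read_dataset,
    sample_negative_anchors,
    split_by_chromosome,
    undersample_majority,
    write_dataset,
)
from tsskit.errors import (
    AmbiguousBaseError,
    BoundaryError,
    ChromosomeLookupError,
    ConfigurationError,
    DatasetParseError,
    SchemaError,
)
from tsskit.synthetic import reverse_complement


class TestExtractWindow:
    def test_default_geometry_spans_reference(self):
        """Default 700/3/300 window at tss=1000 covers positions 300..1302 and
        puts the TSS base at window position 701."""
        seq = "A" * 2000
        marked = seq[:999] + "G" + seq[1000:]  # G at position 1000 (1-based)
        window = extract_window({"c": marked}, "c", 1000, "+")
        assert len(window) == 1003
        assert window[700] == "G"

    def test_plus_strand_hand_enumeration(self):
        params = WindowParams(upstream_flank=2, codon_length=3, downstream_flank=1)
        window = extract_window({"c": "ACGTACGT"}, "c", 4, "+", params)
        assert window == "CGTACG"  # reference positions 2..7

    def test_minus_strand_hand_reverse_complement(self):
        params = WindowParams(upstream_flank=2, codon_length=3, downstream_flank=1)
        window = extract_window({"c": "ACGTACGT"}, "c", 4, "-", params)
        assert window == reverse_complement("ACGTAC")  # positions 1..6
        assert window == "GTACGT"

    def test_strand_symmetry_with_symmetric_flanks(self):
        """With equal flanks the two strands give reverse-complement windows."""
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 100))
        params = WindowParams(upstream_flank=6, codon_length=3, downstream_flank=4)
        plus = extract_window({"c": seq}, "c", 50, "+", params)
        # anchor the minus-strand window so it covers the same reference span:
        # plus spans [44, 56]; minus with up=4, down=6 spans [tss-8, tss+4]
        sym = WindowParams(upstream_flank=4, codon_length=3, downstream_flank=6)
        minus = extract_window({"c": seq}, "c", 52, "-", sym)
        assert minus == reverse_complement(plus)

    def test_out_of_bounds_and_unknown_chromosome(self):
        with pytest.raises(BoundaryError):
            extract_window({"c": "ACGT" * 100}, "c", 5, "+")
        with pytest.raises(ChromosomeLookupError):
            extract_window({"c": "ACGT" * 300}, "missing", 600, "+")

    def test_ambiguous_base_raises(self):
        seq = "A" * 500 + "N" + "A" * 500
        params = WindowParams(upstream_flank=5, codon_length=3, downstream_flank=5)
        with pytest.raises(AmbiguousBaseError):
            extract_window({"c": seq}, "c", 499, "+", params)


class TestNegativeSampling:
    @staticmethod
    def _record(start=1000, end=5999, chromosome="c", strand="+", tid="T1"):
        frame = pd.DataFrame(
            [
                {
                    "transcript_id": tid,
                    "chromosome": chromosome,
                    "strand": strand,
                    "transcript_start": start,
                    "transcript_end": end,
                    "tss": start,
                }
            ]
        )
        return next(frame.itertuples(index=False))

    def test_exact_count_distinct_non_tss(self):
        assembly = {"c": "A" * 10_000}
        params = WindowParams(100, 3, 100)
        rec = self._record()
        anchors = sample_negative_anchors(rec, {1500, 2000}, 10, params, assembly, 0)
        assert len(anchors) == len(set(anchors)) == 10
        assert not set(anchors) & {1500, 2000}
        assert all(1000 <= a <= 5999 for a in anchors)

    def test_too_few_eligible_returns_all_with_warning(self, caplog):
        assembly = {"c": "A" * 10_000}
        params = WindowParams(100, 3, 100)
        rec = self._record(start=2000, end=2004)  # 5 positions, 1 is the TSS
        with caplog.at_level(logging.WARNING):
            anchors = sample_negative_anchors(rec, {2000}, 10, params, assembly, 0)
        assert sorted(anchors) == [2001, 2002, 2003, 2004]
        assert any("eligible" in r.message for r in caplog.records)

    def test_zero_eligible_returns_empty_with_warning(self, caplog):
        assembly = {"c": "A" * 10_000}
        params = WindowParams(100, 3, 100)
        rec = self._record(start=2000, end=2000)
        with caplog.at_level(logging.WARNING):
            anchors = sample_negative_anchors(rec, {2000}, 5, params, assembly, 0)
        assert anchors == []
        assert caplog.records

    def test_sampling_uniform_over_eligible_positions(self):
        """Empirical coverage over a small eligible set stays within 3 sigma of
        the multinomial expectation across many seeds."""
        assembly = {"c": "A" * 10_000}
        params = WindowParams(100, 3, 100)
        rec = self._record(start=3000, end=3019)  # 20 positions, none TSS
        n_draws, per_draw = 2_500, 4
        counts = np.zeros(20)
        for seed in range(n_draws):
            for a in sample_negative_anchors(rec, set(), per_draw, params, assembly, seed):
                counts[a - 3000] += 1
        total = n_draws * per_draw
        p = 1 / 20
        sd = np.sqrt(total * p * (1 - p))
        assert np.all(np.abs(counts - total * p) <= 3 * sd)

    def test_determinism_given_seed(self):
        assembly = {"c": "A" * 10_000}
        params = WindowParams(100, 3, 100)
        rec = self._record()
        a1 = sample_negative_anchors(rec, {1500}, 10, params, assembly, 11)
        a2 = sample_negative_anchors(rec, {1500}, 10, params, assembly, 11)
        assert a1 == a2


class TestBuildDataset:
    def test_default_ratio_counts(self, default_fixture):
        (assembly, annotation), _ = default_fixture
        ds = build_dataset(assembly, annotation, seed=1)
        assert ds.n_positive == 20
        assert ds.n_negative == 200
        assert ds.negative_ratio == 10.0

    def test_one_to_one_ratio(self, default_fixture):
        (assembly, annotation), _ = default_fixture
        ds = build_dataset(assembly, annotation, n_negatives_per_positive=1, seed=1)
        assert ds.n_negative == ds.n_positive

    def test_every_window_has_standard_length(self, default_fixture):
        (assembly, annotation), _ = default_fixture
        ds = build_dataset(assembly, annotation, seed=1)
        assert {len(inst.sequence) for inst in ds.instances} == {1003}

    def test_motif_sits_after_upstream_flank(self, small_window_fixture, small_dataset):
        """Positive windows carry the planted motif starting at window
        position upstream_flank + 1 (here 11)."""
        _, config = small_window_fixture
        matches = []
        for inst in small_dataset.instances:
            if inst.label == 1:
                region = inst.sequence[10 : 10 + len(config.motif)]
                matches.append(
                    np.mean([a == b for a, b in zip(region, config.motif)])
                )
        assert np.mean(matches) > 0.85  # 5% per-base corruption

    def test_negatives_never_anchor_on_a_tss(self, small_window_fixture, small_dataset):
        (_, annotation), _ = small_window_fixture
        tss = {
            (rec.chromosome, rec.tss) for rec in annotation.itertuples(index=False)
        }
        for inst in small_dataset.instances:
            if inst.label == 0:
                assert (inst.chromosome, inst.anchor) not in tss

    def test_empty_annotation_rejected(self, default_fixture):
        (assembly, annotation), _ = default_fixture
        with pytest.raises(ConfigurationError):
            build_dataset(assembly, annotation.iloc[:0])


class TestSplit:
    def test_default_chromosome_assignment(self):
        def inst(chrom):
            return WindowInstance("ACGT", 1, chrom, 1, "+", "t")

        ds = LabeledDataset([inst("1"), inst("2"), inst("16")])
        split = split_by_chromosome(ds)
        assert [i.chromosome for i in split.validation.instances] == ["16"]
        assert [i.chromosome for i in split.test.instances] == ["1"]
        assert [i.chromosome for i in split.train.instances] == ["2"]

    def test_empty_test_set_routes_to_train(self, small_dataset):
        split = split_by_chromosome(small_dataset, {"3"}, set())
        assert len(split.test) == 0
        assert len(split.train) + len(split.validation) == len(small_dataset)

    def test_partition_conserves_instances(self, small_dataset):
        split = split_by_chromosome(small_dataset, {"3"}, {"2"})
        assert len(split.train) + len(split.validation) + len(split.test) == len(
            small_dataset
        )
        for part, chroms in [
            (split.validation, {"3"}),
            (split.test, {"2"}),
            (split.train, {"1"}),
        ]:
            assert {i.chromosome for i in part.instances} <= chroms

    def test_overlapping_sets_rejected(self, small_dataset):
        with pytest.raises(ConfigurationError):
            split_by_chromosome(small_dataset, {"1", "2"}, {"2"})


class TestUndersample:
    def test_reduces_to_target_ratio(self, small_dataset):
        balanced = undersample_majority(small_dataset, 1.0, seed=0)
        assert balanced.n_positive == small_dataset.n_positive
        assert balanced.n_negative == balanced.n_positive

    def test_idempotent_at_current_ratio(self, small_dataset):
        same = undersample_majority(small_dataset, 10.0, seed=0)
        assert len(same) == len(small_dataset)

    def test_deterministic_given_seed(self, small_dataset):
        a = undersample_majority(small_dataset, 1.0, seed=3)
        b = undersample_majority(small_dataset, 1.0, seed=3)
        assert [i.anchor for i in a.instances] == [i.anchor for i in b.instances]

    def test_zero_negatives_rejected(self, small_dataset):
        with pytest.raises(ConfigurationError):
            undersample_majority(small_dataset, 0.0, seed=0)


class TestDatasetIO:
    def test_round_trip(self, tmp_path, small_dataset):
        path = tmp_path / "ds.csv"
        write_dataset(small_dataset, path)
        loaded = read_dataset(path)
        assert loaded.instances == small_dataset.instances
        assert loaded.provenance["seed"] == small_dataset.provenance["seed"]

    def test_wrong_length_sequence_names_record(self, tmp_path, small_dataset):
        path = tmp_path / "ds.csv"
        write_dataset(small_dataset, path)
        lines = path.read_text().split("\n")
        lines[3] = "ACGT," + lines[3].split(",", 1)[1]
        path.write_text("\n".join(lines))
        with pytest.raises(DatasetParseError, match="record 3|line 4"):
            read_dataset(path)

    def test_empty_dataset_round_trip(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_dataset(LabeledDataset([], {"seed": 0}), path)
        assert len(read_dataset(path)) == 0


class TestBiomartImport:
    HEADER = "transcript_id\tchromosome\tstrand\ttranscript_start\ttranscript_end\ttss"

    def test_null_rows_dropped_and_counted(self, tmp_path):
        rows = [
            "T1\t1\t+\t100\t900\t100",
            "T2\t1\t-\t200\t950\t950",
            "T3\t2\t1\t300\t800\t",  # null TSS
            "T4\t2\t-1\t400\t700\t700",
            "T5\t3\t+\t500\t600\t500",
        ]
        path = tmp_path / "mart.tsv"
        path.write_text(self.HEADER + "\n" + "\n".join(rows) + "\n")
        annotation, sequences, n_dropped = read_biomart_export(path)
        assert len(annotation) == 4
        assert n_dropped == 1
        assert sequences is None
        assert list(annotation.strand) == ["+", "-", "-", "+"]

    def test_extra_columns_ignored(self, tmp_path):
        path = tmp_path / "mart.tsv"
        path.write_text(
            self.HEADER + "\tgene_biotype\nT1\t1\t+\t100\t900\t100\tprotein_coding\n"
        )
        annotation, _, n_dropped = read_biomart_export(path)
        assert len(annotation) == 1 and n_dropped == 0

    def test_header_only_yields_empty(self, tmp_path):
        path = tmp_path / "mart.tsv"
        path.write_text(self.HEADER + "\n")
        annotation, _, _ = read_biomart_export(path)
        assert len(annotation) == 0

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "mart.tsv"
        path.write_text("transcript_id\tchromosome\nT1\t1\n")
        with pytest.raises(SchemaError, match="strand"):
            read_biomart_export(path)
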