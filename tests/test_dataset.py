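"""Mutation-table parsing, validation, augmentation, folds, summaries."""

from fractions import Fraction

import numpy as np
import pytest

import plmddg as p
from plmddg.errors import (
    ConfigurationError,
    PositionRangeError,
    RecordValueError,
    SequenceMismatchError,
    TableFormatError,
    UsageError,
)


def rec(wt="N", pos=3, mut="A", ddg=1.0, cid="C1", chain="A", **kw):
    return p.MutationRecord(cid, chain, wt, pos, mut, ddg, "DSB", "train", **kw)


class TestReadTable:
    def test_well_formed_rows_parse_in_order(self, tiny_table):
        table, _, _ = tiny_table
        records = p.read_mutation_table(table)
        assert len(records) == 3
        assert [r.mutation_name for r in records] == ["N139A", "F52A", "N139D"]
        assert records[0].ddg == 2.28
        assert records[0].wt_aa == "N" and records[0].mut_aa == "A"
        assert all(not r.is_reverse for r in records)

    def test_empty_table_gives_empty_collection(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(
            "complex_id\tchain\twt_aa\tposition\tmut_aa\tddg\t"
            "binding_class\tpartition\n"
        )
        assert p.read_mutation_table(path) == []

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("complex_id\tchain\n1ABC\tA\n")
        with pytest.raises(TableFormatError, match="missing required column"):
            p.read_mutation_table(path)

    def test_non_numeric_ddg_names_the_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "complex_id\tchain\twt_aa\tposition\tmut_aa\tddg\t"
            "binding_class\tpartition\n"
            "1ABC\tA\tN\t5\tA\toops\tDSB\ttrain\n"
        )
        with pytest.raises(RecordValueError, match="row 2"):
            p.read_mutation_table(path)

    def test_unknown_binding_class_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "complex_id\tchain\twt_aa\tposition\tmut_aa\tddg\t"
            "binding_class\tpartition\n"
            "1ABC\tA\tN\t5\tA\t1.0\tRNA\ttrain\n"
        )
        with pytest.raises(RecordValueError, match="binding class"):
            p.read_mutation_table(path)

    def test_dialect_maps_column_names(self, tmp_path):
        path = tmp_path / "renamed.csv"
        path.write_text(
            "pdb,ch,wt,resi,mt,value,cls,part\n"
            "3OSF,A,N,139,A,2.28,DSB,train\n"
        )
        records = p.read_mutation_table(
            path,
            dialect={"complex_id": "pdb", "chain": "ch", "wt_aa": "wt",
                     "position": "resi", "mut_aa": "mt", "ddg": "value",
                     "binding_class": "cls", "partition": "part"},
        )
        assert records[0].ddg == 2.28

    def test_duplicate_rows_kept_but_flagged(self, tmp_path):
        path = tmp_path / "dup.tsv"
        row = "3OSF\tA\tN\t139\tA\t2.28\tDSB\ttrain\n"
        path.write_text(
            "complex_id\tchain\twt_aa\tposition\tmut_aa\tddg\t"
            "binding_class\tpartition\n" + row + row
        )
        records = p.read_mutation_table(path)
        assert [r.is_duplicate for r in records] == [False, True]


class TestRecordInvariants:
    def test_identical_wt_and_mut_rejected(self):
        with pytest.raises(RecordValueError):
            rec(wt="A", mut="A")

    def test_nonpositive_position_rejected(self):
        with pytest.raises(RecordValueError):
            rec(pos=0)


class TestValidateAgainstSequence:
    def test_matching_residue_passes(self):
        r = rec(wt="D", pos=3)
        assert p.validate_against_sequence(r, "ACDEF") is r

    def test_mismatch_reports_expected_and_found(self):
        with pytest.raises(SequenceMismatchError, match="expected E, found D"):
            p.validate_against_sequence(rec(wt="E", pos=3, mut="A"), "ACDEF")

    def test_out_of_range_position(self):
        with pytest.raises(PositionRangeError):
            p.validate_against_sequence(rec(pos=6), "ACDEF")

    def test_reverse_record_checks_mutant_residue(self):
        fwd = rec(wt="D", pos=3, mut="K")
        reverse = p.reverse_augment([fwd])[1]
        # the original chain still shows D at the site
        assert p.validate_against_sequence(reverse, "ACDEF") is reverse


class TestReverseAugment:
    def test_doubles_and_negates(self):
        records = [rec(wt="N", pos=139, mut="A", ddg=2.28)]
        out = p.reverse_augment(records)
        assert len(out) == 2
        r = out[1]
        assert (r.wt_aa, r.mut_aa, r.ddg, r.is_reverse) == ("A", "N", -2.28, True)

    def test_empty_input(self):
        assert p.reverse_augment([]) == []

    def test_double_augmentation_forbidden(self):
        out = p.reverse_augment([rec()])
        with pytest.raises(UsageError):
            p.reverse_augment(out)

    def test_involution_on_labels(self):
        rng = np.random.default_rng(0)
        records = [rec(pos=i + 1, ddg=float(rng.normal())) for i in range(20)]
        out = p.reverse_augment(records)
        fwd, back = out[:20], out[20:]
        for f, b in zip(fwd, back):
            assert (b.wt_aa, b.mut_aa) == (f.mut_aa, f.wt_aa)
            assert b.ddg == -f.ddg  # exact sign flip, no rounding

    def test_mean_ddg_exactly_zero(self):
        records = [rec(pos=i + 1, ddg=v)
                   for i, v in enumerate([2.28, -0.33, 1.07, 0.004])]
        out = p.reverse_augment(records)
        total = sum(Fraction(r.ddg) for r in out)
        assert total == 0
        assert abs(np.mean([r.ddg for r in out])) < 1e-12


class TestSplitFolds:
    def make_augmented(self, n=276):
        records = [rec(cid=f"C{i//6}", pos=(i % 50) + 1,
                       wt="NDEKRQ"[i % 6], mut="AGHWYF"[i % 6],
                       ddg=float(i)) for i in range(n)]
        return p.reverse_augment(records)

    def test_pairwise_sizes_and_coassignment(self):
        aug = self.make_augmented(276)
        folds = p.split_folds(aug, k=10, seed=1, pairing="pairwise")
        sizes = np.bincount(folds, minlength=10)
        assert sorted(set(sizes.tolist())) <= [54, 56]
        assert sizes.sum() == 552
        # forward and reverse of each pair share a fold
        assert (folds[:276] == folds[276:]).all()

    def test_partition_property(self):
        aug = self.make_augmented(30)
        folds = p.split_folds(aug, k=5, seed=3)
        assert folds.shape == (60,)
        assert set(folds) == set(range(5))

    def test_by_complex_groups_complexes(self):
        aug = self.make_augmented(60)
        folds = p.split_folds(aug, k=2, seed=0, pairing="by_complex")
        for cid in {r.complex_id for r in aug}:
            fs = {f for r, f in zip(aug, folds) if r.complex_id == cid}
            assert len(fs) == 1

    def test_k_of_one_rejected(self):
        with pytest.raises(ConfigurationError):
            p.split_folds([rec()], k=1, seed=0)

    def test_k_larger_than_groups_rejected(self):
        with pytest.raises(ConfigurationError):
            p.split_folds([rec(), rec(pos=9)], k=5, seed=0, pairing="pairwise")

    def test_same_seed_is_deterministic(self):
        aug = self.make_augmented(40)
        a = p.split_folds(aug, k=4, seed=7)
        b = p.split_folds(aug, k=4, seed=7)
        assert (a == b).all()


class TestSummarize:
    def test_per_wt_mean(self):
        records = [rec(wt="R", mut="A", ddg=1.0), rec(wt="R", mut="K", ddg=3.0)]
        s = p.summarize(records)
        assert s.per_wt_mean_ddg["R"] == 2.0

    def test_flank_window_clipped_at_ends(self):
        r = rec(cid="C1", wt="D", pos=3, mut="A")
        seqs = {"C1_A": "ACDEFGH"}
        s = p.summarize([r], seqs)
        # offsets -5..-1,+1..+5 from position 3 clip to {A,C,E,F,G,H}
        assert set(s.flank_aa_frequency) == set("ACEFGH")
        assert all(v == pytest.approx(1 / 6) for v in
                   s.flank_aa_frequency.values())

    def test_empty_input(self):
        s = p.summarize([])
        assert s.n_records == 0 and s.per_wt_mean_ddg == {}

    def test_frequency_maps_are_probability_vectors(self, synthetic_dataset):
        seqs, records, _ = synthetic_dataset
        s = p.summarize(records, seqs)
        assert sum(s.mutant_aa_frequency.values()) == pytest.approx(1, abs=1e-9)
        assert sum(s.flank_aa_frequency.values()) == pytest.approx(1, abs=1e-9)

    def test_reverse_records_excluded(self):
        aug = p.reverse_augment([rec(ddg=2.0)])
        s = p.summarize(aug)
        assert s.n_records == 1 and s.mean_ddg == 2.0
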