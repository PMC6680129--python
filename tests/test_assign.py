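from collections import Counter

import pysam
import pytest

from hybridase.assign import (AlignedFragment, assignment_summary,
                              classify_fragment, count_gene_alleles,
                              merge_alignments, read_fragments, split_by_allele)
from hybridase.models import Gene, GeneModels, Transcript
from hybridase.sites import DivergentSite, FdsIndex

# two FDSs inside one exon: pos (1-based) 101 A/C and 151 G/T
IDX = FdsIndex([DivergentSite("chr1", 101, "A", "C"),
                DivergentSite("chr1", 151, "G", "T")])


def _frag(bases, source="both", unique=True, blocks=((90, 190),)):
    return AlignedFragment(
        name="f", chrom="chr1", blocks=tuple(blocks),
        fds_bases=bases, mapq=60, uniquely_mapped=unique, source=source)


class TestClassify:
    def test_all_a_bases_gives_alleleA(self):
        call = classify_fragment(_frag({100: "A", 150: "G"}), IDX)
        assert call.call == "alleleA" and call.n_sites_A == 2

    def test_mixed_bases_ambiguous(self):
        call = classify_fragment(_frag({100: "A", 150: "T"}), IDX)
        assert call.call == "ambiguous"

    def test_no_fds_uninformative(self):
        assert classify_fragment(_frag({}), IDX).call == "uninformative"

    def test_third_base_ignored_not_forcing_ambiguity(self):
        """A base matching neither allele counts as 'neither' only."""
        call = classify_fragment(_frag({100: "A", 150: "C"}), IDX)
        assert call.call == "alleleA"
        assert call.n_sites_neither == 1


def _write_sam(path, rows, extra_header=""):
    """rows: (name, flag, pos1, cigar, seq, mapq)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100000\n" + extra_header)
        for name, flag, pos, cigar, seq, mapq in rows:
            fh.write(f"{name}\t{flag}\tchr1\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*\n")


class TestReadFragments:
    def test_pairs_grouped_and_bases_extracted(self, tmp_path):
        sam = tmp_path / "x.sam"
        _write_sam(sam, [
            ("r1", 99, 91, "20M", "T" * 10 + "A" + "T" * 9, 60),
            ("r1", 147, 141, "20M", "C" * 10 + "G" + "C" * 9, 60),
        ])
        frags = read_fragments(str(sam), IDX, "reference")
        assert len(frags) == 1
        assert frags[0].fds_bases == {100: "A", 150: "G"}
        assert frags[0].uniquely_mapped

    def test_low_mapq_not_unique(self, tmp_path):
        sam = tmp_path / "x.sam"
        _write_sam(sam, [("r1", 99, 91, "20M", "T" * 20, 10)])
        assert not read_fragments(str(sam), IDX, "reference")[0].uniquely_mapped

    def test_secondary_taints_name(self, tmp_path):
        sam = tmp_path / "x.sam"
        _write_sam(sam, [
            ("r1", 99, 91, "20M", "T" * 20, 60),
            ("r1", 355, 500, "20M", "T" * 20, 60),  # secondary
        ])
        assert not read_fragments(str(sam), IDX, "reference")[0].uniquely_mapped

    def test_spliced_cigar_skips_intron(self, tmp_path):
        sam = tmp_path / "x.sam"
        # 10M90N10M starting at 96: covers 95..105 and 195..205 (0-based)
        seq = "T" * 5 + "A" + "T" * 14
        _write_sam(sam, [("r1", 99, 96, "10M90N10M", seq, 60)])
        frags = read_fragments(str(sam), IDX, "reference")
        assert frags[0].fds_bases == {100: "A"}  # 150 is inside the intron gap


class TestMerge:
    def test_identical_position_kept_once_as_both(self):
        r = _frag({100: "A"}, source="reference")
        p = _frag({100: "A"}, source="pseudogenome")
        merged, tally = merge_alignments([r], [p])
        assert len(merged) == 1 and merged[0].source == "both"
        assert tally["both"] == 1

    def test_unique_in_one_mapping_included(self):
        r = _frag({100: "A"}, source="reference", unique=False)
        p = _frag({100: "A"}, source="pseudogenome")
        merged, tally = merge_alignments([r], [p])
        assert len(merged) == 1 and merged[0].source == "pseudogenome"
        assert tally["pseudogenome_only"] == 1

    def test_position_conflict_dropped_and_tallied(self):
        r = _frag({100: "A"}, source="reference", blocks=((90, 190),))
        p = _frag({100: "A"}, source="pseudogenome", blocks=((290, 390),))
        merged, tally = merge_alignments([r], [p])
        assert not merged
        assert tally["position_conflict_dropped"] == 1

    def test_partition_accounts_for_every_name(self):
        frags_r = [_frag({}, source="reference") for _ in range(3)]
        for i, f in enumerate(frags_r):
            f.name = f"r{i}"
        frags_r[2].uniquely_mapped = False
        merged, tally = merge_alignments(frags_r, [])
        assert sum(tally.values()) == 3


def _models_one_gene():
    t = Transcript("t1", "g1", "chr1", "+", [(50, 250)])
    return GeneModels({"g1": Gene("g1", "chr1", "+", "protein_coding", [t])})


class TestCounting:
    def test_direct_arithmetic_30_10(self):
        frags = []
        for i in range(30):
            f = _frag({100: "A"})
            f.name = f"a{i}"
            frags.append(f)
        for i in range(10):
            f = _frag({100: "C"})
            f.name = f"b{i}"
            frags.append(f)
        counts, tally = count_gene_alleles(frags, _models_one_gene(), IDX,
                                           {"g1": 2}, sample="s")
        row = counts.iloc[0]
        assert (row.countA, row.countB) == (30, 10)
        assert row.countA / (row.countA + row.countB) == pytest.approx(0.75)

    def test_mapping_average_may_be_half_integral(self):
        """Ref mapping sees 32 A fragments, pseudo mapping 30: average 31."""
        frags = []
        for i in range(30):
            f = _frag({100: "A"}, source="both")
            f.name = f"c{i}"
            frags.append(f)
        for i in range(2):
            f = _frag({100: "A"}, source="reference")
            f.name = f"r{i}"
            frags.append(f)
        counts, _ = count_gene_alleles(frags, _models_one_gene(), IDX)
        assert counts.iloc[0].countA == pytest.approx(31.0)
        # a single ref-only fragment on its own averages to one half
        solo = _frag({100: "A"}, source="reference")
        counts, _ = count_gene_alleles([solo], _models_one_gene(), IDX)
        assert counts.iloc[0].countA == pytest.approx(0.5)

    def test_gene_without_informative_fragments_zero(self):
        counts, _ = count_gene_alleles([], _models_one_gene(), IDX)
        assert counts.iloc[0].countA == 0 and counts.iloc[0].countB == 0


class TestSummaryAndSplit:
    def test_proportions_sum_to_one(self):
        tally = Counter(alleleA=40, alleleB=50, ambiguous=5, uninformative=5)
        s = assignment_summary(tally)
        assert sum(s.values()) == pytest.approx(1.0)
        assert s["alleleA"] == pytest.approx(0.4)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            assignment_summary(Counter())

    def test_split_counts_match_fixture(self, tmp_path):
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100000}]})
        frags = []
        for i in range(40):
            f = _frag({100: "A"})
            f.name = f"a{i}"
            frags.append(f)
        for i in range(60):
            f = _frag({100: "C"})
            f.name = f"b{i}"
            frags.append(f)
        n_a, n_b = split_by_allele(frags, IDX, tmp_path / "a.sam",
                                   tmp_path / "b.sam", header)
        assert (n_a, n_b) == (40, 60)

    def test_zero_assigned_gives_empty_valid_files(self, tmp_path):
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100000}]})
        n_a, n_b = split_by_allele([], IDX, tmp_path / "a.sam",
                                   tmp_path / "b.sam", header)
        assert (n_a, n_b) == (0, 0)
        with pysam.AlignmentFile(str(tmp_path / "a.sam"), check_sq=False) as af:
            assert list(af) == []


class TestSimulatorTruth:
    def test_error_free_assignment_is_exact(self, clean_study):
        """At error_rate 0, every assigned fragment matches its truth label."""
        index = FdsIndex(clean_study.sites)
        sid = next(iter(clean_study.design))
        frags = read_fragments(clean_study.sample_paths[sid]["sam"], index, "both")
        assert all(f.uniquely_mapped for f in frags)
        calls = Counter()
        for f in frags:
            call = classify_fragment(f, index)
            calls[call.call] += 1
            if call.call in ("alleleA", "alleleB"):
                assert call.call[-1] == f.truth_allele
            assert call.call != "ambiguous"  # impossible without errors
        # partition property
        assert sum(calls.values()) == len(frags)
        total_truth = len(clean_study.truth.fragments[sid])
        assert len(frags) == total_truth
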