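import numpy as np
import pandas as pd
import pysam
import pytest

from homeolyze import partition as pt
from homeolyze.io_formats import GeneModel, SnpIndex


HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 10_000}]}
)


def make_read(start, seq, qual=40, mapped=True, chrom="chr1",
              secondary=False, cigar=None):
    a = pysam.AlignedSegment(HEADER)
    a.query_name = "r"
    a.query_sequence = seq
    a.flag = (4 if not mapped else 0) | (256 if secondary else 0)
    if mapped:
        a.reference_name = chrom
        a.reference_start = start
        a.cigarstring = cigar or f"{len(seq)}M"
        a.mapping_quality = 60
    a.query_qualities = pysam.qualitystring_to_array(
        chr(qual + 33) * len(seq)
    )
    return a


@pytest.fixture()
def snps():
    # 0-based positions 99 and 109 (1-based 100, 110)
    return SnpIndex.from_records(
        [("chr1", 100, "A", "G"), ("chr1", 110, "C", "T")]
    )


class TestClassifyRead:
    def test_single_snp_a_allele(self, snps):
        read = make_read(95, "TTTT" + "A" + "TTTTT")  # base A at ref 99
        assert pt.classify_read(read, snps.lookup()) == "A"

    def test_single_snp_d_allele(self, snps):
        read = make_read(95, "TTTT" + "G" + "TTTTT")
        assert pt.classify_read(read, snps.lookup()) == "D"

    def test_both_alleles_is_chimeric(self, snps):
        seq = list("T" * 20)
        seq[99 - 95] = "A"   # A allele at first SNP
        seq[109 - 95] = "T"  # D allele at second SNP
        read = make_read(95, "".join(seq))
        assert pt.classify_read(read, snps.lookup()) == "X"

    def test_no_snp_overlap_is_n(self, snps):
        read = make_read(500, "T" * 20)
        assert pt.classify_read(read, snps.lookup()) == "N"

    def test_third_base_abstains(self, snps):
        read = make_read(95, "TTTT" + "C" + "TTTTT")  # neither A nor G
        assert pt.classify_read(read, snps.lookup()) == "N"

    def test_low_quality_base_abstains(self, snps):
        read = make_read(95, "TTTTATTTTT", qual=10)
        assert pt.classify_read(read, snps.lookup(), min_baseq=20) == "N"

    def test_deletion_skips_snp_column(self, snps):
        # 4M6D6M: SNP at ref 99 falls inside the deletion; the G bases would
        # vote D if an aligned base were (incorrectly) taken from the gap,
        # and abstain at the second SNP (alleles C/T)
        read = make_read(95, "GGGGGGGGGG", cigar="4M6D6M")
        assert pt.classify_read(read, snps.lookup()) == "N"

    def test_unmapped_read_is_caller_error(self, snps):
        with pytest.raises(ValueError, match="mapped"):
            pt.classify_read(make_read(0, "TTTT", mapped=False), snps.lookup())

    def test_unknown_chrom_is_n_with_counter(self):
        lookup = SnpIndex.from_records([("chr9", 5, "A", "C")]).lookup()
        counter = {}
        read = make_read(10, "T" * 10)
        assert pt.classify_read(read, lookup, warn_counter=counter) == "N"
        assert counter["unknown_chrom"] == 1

    def test_raising_threshold_never_uninforms_n(self, snps):
        """Monotonicity: an N read stays N when the threshold rises."""
        lookup = snps.lookup()
        rng = np.random.default_rng(0)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), 12))
            read = make_read(int(rng.integers(90, 112)), seq,
                             qual=int(rng.integers(2, 41)))
            classes = [pt.classify_read(read, lookup, min_baseq=t)
                       for t in (0, 20, 41)]
            for lo, hi in zip(classes, classes[1:]):
                assert not (lo == "N" and hi != "N")


class TestGeneAssignment:
    @pytest.fixture()
    def genes(self):
        return [
            GeneModel("G1", "chr1", "+", exons=((0, 200),)),
            GeneModel("G2", "chr1", "+", exons=((230, 400),)),
        ]

    def test_max_overlap_wins(self, genes):
        trees = pt._exon_trees(genes)
        read = make_read(170, "T" * 40)  # 30 bp in G1, 0 in gap+G2
        assert pt.assign_gene(read, trees) == "G1"
        read = make_read(190, "T" * 50)  # 10 bp G1, 10 bp G2 -> tie
        assert pt.assign_gene(read, trees) is None

    def test_no_overlap_unassigned(self, genes):
        trees = pt._exon_trees(genes)
        assert pt.assign_gene(make_read(205, "T" * 20), trees) is None


class TestCountByGene:
    def write_sam(self, tmp_path, reads):
        p = tmp_path / "in.sam"
        with pysam.AlignmentFile(str(p), "w", header=HEADER) as fh:
            for r in reads:
                fh.write(r)
        return p

    def test_hand_tally(self, tmp_path, snps):
        genes = [GeneModel("G", "chr1", "+", exons=((0, 300),))]
        reads = [
            make_read(95, "TTTTATTTTT"),   # A
            make_read(95, "TTTTATTTTT"),   # A
            make_read(95, "TTTTGTTTTT"),   # D
            make_read(200, "T" * 10),       # N
            make_read(95, "TTTTATTTTT", secondary=True),  # ignored
        ]
        path = self.write_sam(tmp_path, reads)
        res = pt.count_by_gene(path, genes, snps, sample_id="s")
        row = res.counts.set_index("gene_id").loc["G"]
        assert (row["n_A"], row["n_D"], row["n_X"], row["n_N"]) == (2, 1, 0, 1)
        assert res.n_mapped == 4

    def test_requires_gene_models(self, tmp_path, snps):
        path = self.write_sam(tmp_path, [])
        with pytest.raises(ValueError, match="no gene models"):
            pt.count_by_gene(path, [], snps)


class TestSummary:
    def test_read_accounting_fractions(self):
        """F1-hybrid style row: categorized fraction (A+D+X)/mapped."""
        counts = pd.DataFrame(
            [("g", "F1", 8_000, 8_400, 100, 15_100)],
            columns=["gene_id", "sample_id", "n_A", "n_D", "n_X", "n_N"],
        )
        res = pt.PartitionResult(sample_id="F1", counts=counts)
        summary = pt.summarize_partition([res]).iloc[0]
        assert summary["mapped"] == 31_600
        assert summary["pct_categorized"] == pytest.approx(
            100 * (8_000 + 8_400 + 100) / 31_600
        )

    def test_all_n_sample_zero_categorized(self):
        counts = pd.DataFrame(
            [("g", "s", 0, 0, 0, 5)],
            columns=["gene_id", "sample_id", "n_A", "n_D", "n_X", "n_N"],
        )
        res = pt.PartitionResult(sample_id="s", counts=counts)
        assert pt.summarize_partition([res]).iloc[0]["pct_categorized"] == 0.0


class TestOracleOnSimulatedReads:
    def test_perfect_accuracy_without_errors(self, readsim):
        """Error-free planted-allele reads classify to their origin tag."""
        lookup = readsim["snp_index"].lookup()
        informative = correct = 0
        for path in readsim["sams"].values():
            with pysam.AlignmentFile(str(path)) as fh:
                for read in fh:
                    cls = pt.classify_read(read, lookup)
                    if cls in ("A", "D"):
                        informative += 1
                        correct += cls == read.get_tag("ZO")
                    else:
                        assert cls == "N"  # no chimeras planted
        assert informative > 500
        assert correct == informative

    def test_class_conservation(self, readsim):
        counts, summary = pt.partition_samples(
            readsim["sams"], readsim["genes"], readsim["snp_index"]
        )
        per_sample = counts.groupby("sample_id")[
            ["n_A", "n_D", "n_X", "n_N"]
        ].sum()
        for row in summary.itertuples():
            gene_total = per_sample.loc[row.sample_id].sum()
            assert row.A + row.D + row.X + row.N == row.mapped
            assert gene_total <= row.mapped  # difference = unassigned reads
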