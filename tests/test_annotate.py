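import numpy as np
import pysam
import pytest

from svarbiter.annotate import (
    annotate_sites,
    clipping_fraction,
    collect_reads,
    discordance_fractions,
    insert_size_stats,
    longread_indel_rates,
    oneclass_columns,
    reference_context,
    region_depth,
)
from svarbiter.core import (
    DatasetSpec,
    GenomicInterval,
    SVCall,
    SVType,
    Technology,
    Zygosity,
)
from svarbiter.io import read_repeat_track, read_snp_genotypes

import oracles_util as oracle

CHROM = "chr1"
HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": CHROM, "LN": 100_000}]}
)


def mk_read(
    name,
    pos,
    cigar,
    flag_secondary=False,
    mapq=60,
    paired=False,
    mate_pos=None,
    tlen=0,
    mate_unmapped=False,
    mate_reverse=True,
    reverse=False,
    proper=True,
):
    a = pysam.AlignedSegment(HEADER)
    a.query_name = name
    a.reference_id = 0
    a.reference_start = pos
    a.cigarstring = cigar
    qlen = a.infer_query_length()
    a.query_sequence = "A" * qlen
    a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
    a.mapping_quality = mapq
    a.is_secondary = flag_secondary
    if paired:
        a.is_paired = True
        a.is_proper_pair = proper and not mate_unmapped
        a.is_reverse = reverse
        a.mate_is_reverse = mate_reverse
        a.mate_is_unmapped = mate_unmapped
        a.next_reference_id = 0
        a.next_reference_start = mate_pos if mate_pos is not None else pos
        a.template_length = tlen
    return a


def write_bam(path, reads):
    reads = sorted(reads, key=lambda r: r.reference_start)
    with pysam.AlignmentFile(str(path), "wb", header=HEADER) as fh:
        for r in reads:
            fh.write(r)
    pysam.index(str(path))
    return str(path)


def region(start, end):
    return GenomicInterval(CHROM, start, end)


class TestCollectReads:
    def test_overlap_rules_and_filters(self, tmp_path):
        bam_path = write_bam(
            tmp_path / "a.bam",
            [
                mk_read("partial", 95, "100M"),        # [95,195) overlaps [100,200)
                mk_read("inside", 120, "50M"),
                mk_read("abut", 200, "100M"),          # starts at region end: out
                mk_read("before", 0, "100M"),          # [0,100): half-open, out
                mk_read("secondary", 130, "50M", flag_secondary=True),
            ],
        )
        with pysam.AlignmentFile(bam_path) as bam:
            got = {r.query_name for r in collect_reads(bam, region(100, 200))}
        assert got == {"partial", "inside"}

    def test_empty_region_returns_nothing(self, tmp_path):
        bam_path = write_bam(tmp_path / "b.bam", [mk_read("r", 0, "100M")])
        with pysam.AlignmentFile(bam_path) as bam:
            assert collect_reads(bam, region(50, 50)) == []


class TestRegionDepth:
    def test_tiling_reads(self, tmp_path):
        reads = [mk_read(f"r{i}", 100, "100M") for i in range(10)]
        bam_path = write_bam(tmp_path / "c.bam", reads)
        with pysam.AlignmentFile(bam_path) as bam:
            rr = collect_reads(bam, region(100, 200))
            assert region_depth(rr, region(100, 200)) == pytest.approx(10.0)

    def test_no_reads_zero_and_empty_region_error(self):
        assert region_depth([], region(0, 100)) == 0.0
        with pytest.raises(ValueError):
            region_depth([], region(5, 5))

    def test_partial_overlap_matches_pileup_oracle(self, tmp_path):
        reads = [mk_read("half", 50, "100M"), mk_read("del", 90, "30M40D30M")]
        bam_path = write_bam(tmp_path / "d.bam", reads)
        reg = region(100, 200)
        with pysam.AlignmentFile(bam_path) as bam:
            rr = collect_reads(bam, reg)
            got = region_depth(rr, reg)
        expect = oracle.naive_depth(oracle.scan_reads(bam_path, reg), reg)
        assert got == pytest.approx(expect, abs=1e-12)
        # half read: [100,150) -> 50; del read: [100,120) + [160,190) -> 50;
        # the 40D segment contributes no depth
        assert got == pytest.approx((50 + 20 + 30) / 100)


class TestClippingFraction:
    def test_examples(self):
        full = [mk_read(f"r{i}", 0, "100M") for i in range(4)]
        assert clipping_fraction(full) == 0.0
        one_clip = full[:3] + [mk_read("c", 0, "50S50M")]
        assert clipping_fraction(one_clip) == pytest.approx(0.25)

    def test_small_clip_below_threshold_not_counted(self):
        reads = [mk_read("c3", 0, "3S97M")]
        assert clipping_fraction(reads, min_clip=5) == 0.0
        assert clipping_fraction(reads, min_clip=3) == 1.0

    def test_hard_clip_counts(self):
        assert clipping_fraction([mk_read("h", 0, "10H90M")]) == 1.0

    def test_no_reads_masked(self):
        assert clipping_fraction([]) is None


class TestInsertSizeStats:
    def test_gap_separated_mates(self):
        # mates of aligned length 100 each, 50 bp gap: end-to-end 250
        r = mk_read("p", 100, "100M", paired=True, mate_pos=250, tlen=250)
        mean, sd = insert_size_stats([r])
        assert mean == pytest.approx(250)
        assert sd is None  # single pair: sd undefined

    def test_overlapping_mates_negative_gap(self):
        r = mk_read("p", 100, "100M", paired=True, mate_pos=180, tlen=180)
        mean, _ = insert_size_stats([r])
        assert mean == pytest.approx(180)

    def test_single_end_masked(self):
        mean, sd = insert_size_stats([mk_read("s", 0, "100M")])
        assert mean is None and sd is None

    def test_pair_counted_once_at_leftmost(self):
        left = mk_read("p", 100, "100M", paired=True, mate_pos=250, tlen=250)
        right = mk_read("p", 250, "100M", paired=True, mate_pos=100, tlen=-250,
                        reverse=True, mate_reverse=False)
        mean, sd = insert_size_stats([left, right])
        assert mean == pytest.approx(250)
        assert sd is None


class TestDiscordanceFractions:
    def test_proper_pairs_only(self):
        reads = [
            mk_read(f"p{i}", 100, "100M", paired=True, mate_pos=300, tlen=300)
            for i in range(5)
        ]
        disc, mu = discordance_fractions(reads, insert_cutoff=420)
        assert disc == 0.0 and mu == 0.0

    def test_mate_unmapped_fraction(self):
        reads = [
            mk_read(f"p{i}", 100, "100M", paired=True, mate_pos=300, tlen=300)
            for i in range(8)
        ] + [
            mk_read(f"u{i}", 100, "100M", paired=True, mate_unmapped=True, tlen=0)
            for i in range(2)
        ]
        disc, mu = discordance_fractions(reads, insert_cutoff=420)
        assert mu == pytest.approx(0.2)
        assert disc == 0.0  # unmapped-mate reads excluded from discordance

    def test_stretched_insert_counts_discordant(self):
        cutoff = 420.0
        reads = [
            mk_read("span", 100, "100M", paired=True, mate_pos=1300,
                    tlen=int(3 * cutoff), proper=False)
        ]
        disc, _ = discordance_fractions(reads, insert_cutoff=cutoff)
        assert disc == 1.0

    def test_same_strand_orientation_counts_discordant(self):
        reads = [
            mk_read("ss", 100, "100M", paired=True, mate_pos=300, tlen=300,
                    mate_reverse=False, proper=False)
        ]
        disc, _ = discordance_fractions(reads, insert_cutoff=420)
        assert disc == 1.0


class TestLongReadIndelRates:
    def test_published_baseline_applied(self):
        # a clean 1000-bp read normalised with the published PacBio rates
        r = mk_read("lr", 0, "1000M")
        nd, ni, diff = longread_indel_rates([r], (0.0428, 0.0948))
        assert nd == pytest.approx(-0.0428)
        assert ni == pytest.approx(-0.0948)
        assert diff == pytest.approx(nd - ni)

    def test_zero_baseline_zero_ops(self):
        r = mk_read("lr", 0, "1000M")
        assert longread_indel_rates([r], (0.0, 0.0)) == (0.0, 0.0, 0.0)

    def test_deletion_rate_from_cigar(self):
        r = mk_read("lr", 0, "500M100D500M")
        nd, ni, diff = longread_indel_rates([r], (0.0, 0.0))
        assert nd == pytest.approx(0.1)  # 100 deleted bases / 1000-bp read
        assert ni == 0.0
        assert diff == pytest.approx(0.1)

    def test_no_reads_masked(self):
        assert longread_indel_rates([], (0.0, 0.0)) == (None, None, None)


class TestReferenceContext:
    def write_fasta(self, tmp_path, seq):
        p = tmp_path / "ref.fa"
        p.write_text(f">{CHROM}\n{seq}\n")
        return str(p)

    def test_gc_repeats_and_snps(self, tmp_path):
        from pyfaidx import Fasta

        seq = "A" * 100 + "GGCC" + "A" * 100
        fasta = Fasta(self.write_fasta(tmp_path, seq))
        rpt = tmp_path / "rmsk.tsv"
        rpt.write_text(f"{CHROM}\t100\t102\tSINE/Alu\n")
        track = read_repeat_track(str(rpt))
        vcf = tmp_path / "s.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            f"##contig=<ID={CHROM},length=204>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            f"{CHROM}\t101\t.\tG\tA\t50\tPASS\t.\tGT\t0/1\n"
            f"{CHROM}\t102\t.\tG\tT\t50\tPASS\t.\tGT\t0/1\n"
            f"{CHROM}\t103\t.\tC\tA\t50\tPASS\t.\tGT\t1/1\n"
        )
        snps = read_snp_genotypes(str(vcf))
        sv = SVCall(GenomicInterval(CHROM, 100, 104))  # the GGCC stretch
        ctx = reference_context(sv, fasta, track, snps)
        assert ctx["GC_Content"] == pytest.approx(1.0)
        assert ctx["Repeat_SINE"] == pytest.approx(0.5)  # 2 of 4 bases
        assert (ctx["Het_SNPs"], ctx["Hom_SNPs"]) == (2.0, 1.0)
        assert ctx["SV_Length"] == 4.0


class TestAnnotateSites:
    def test_oneclass_long_has_no_insert_columns(self):
        cols = oneclass_columns(Technology.UNPAIRED_LONG)
        assert not any("Insert" in c for c in cols)
        assert "M_DelMinusIns" in cols

    def test_deterministic_repeat_run(self, suite, random_calls):
        ds = suite.datasets[0]
        a = annotate_sites(random_calls[:15], ds, subset="oneclass")
        b = annotate_sites(random_calls[:15], ds, subset="oneclass")
        assert a.equals(b)

    def test_hom_deletion_depth_vs_random(self, suite, random_calls):
        ds = suite.datasets[0]
        homs = [s for s in suite.genome.truth
                if s.sv_type is SVType.DELETION and s.zygosity is Zygosity.HOM]
        t = annotate_sites(homs, ds, subset="oneclass")
        r = annotate_sites(random_calls[:20], ds, subset="oneclass")
        assert t.values["M_Cov"].max() < 1.0
        assert r.values["M_Cov"].mean() > 0.7 * ds.mean_coverage

    def test_het_deletion_depth_half_of_flank(self, suite):
        ds = suite.datasets[0]
        hets = [s for s in suite.genome.truth
                if s.sv_type is SVType.DELETION and s.zygosity is Zygosity.HET]
        t = annotate_sites(hets, ds, subset="clustering")
        ratio = t.values["M_Cov"] / ((t.values["L_Cov"] + t.values["R_Cov"]) / 2)
        assert abs(ratio.mean() - 0.5) < 0.15

    def test_failed_partition_masks_row_with_flag(self, suite):
        ds = suite.datasets[0]
        bogus = SVCall(GenomicInterval("chrMISSING", 10, 500))
        tab = annotate_sites([bogus], ds, subset="oneclass")
        assert tab.mask.iloc[0].all()
        assert "partition_failed" in tab.row_flags["chrMISSING:10-500"]


class TestOracleEquivalence:
    """Every annotation equals a naive full-scan recomputation (shared with
    the acceptance suite, exercised here on a few sites per dataset)."""

    def test_paired_annotations_match_bruteforce(self, suite, random_calls):
        from svarbiter.core import partition_site

        ds = suite.datasets[0]
        sites = list(suite.genome.truth[:3]) + list(random_calls[:3])
        tab = annotate_sites(sites, ds, subset="full")
        contig_len = len(suite.genome.reference)
        for sv in sites:
            part = partition_site(sv, 100, contig_len)
            reads = oracle.scan_reads(ds.bam_path, part.M)
            sid = sv.site_id
            assert tab.values.loc[sid, "M_Cov"] == pytest.approx(
                oracle.naive_depth(reads, part.M), abs=1e-9
            )
            assert tab.values.loc[sid, "M_ReadCount"] == len(reads)
            clip = oracle.naive_clip_fraction(reads)
            got = tab.values.loc[sid, "M_SoftClip"]
            if clip is None:
                assert tab.mask.loc[sid, "M_SoftClip"]
            else:
                assert got == pytest.approx(clip, abs=1e-9)
            mean, sd = oracle.naive_insert_stats(reads)
            if mean is not None:
                assert tab.values.loc[sid, "M_InsertMean"] == pytest.approx(mean, abs=1e-9)
            disc, mu = oracle.naive_discordance(reads, ds.discordant_insert_cutoff)
            if disc is not None:
                assert tab.values.loc[sid, "M_Discordant"] == pytest.approx(disc, abs=1e-9)
            if mu is not None:
                assert tab.values.loc[sid, "M_MateUnmapped"] == pytest.approx(mu, abs=1e-9)

    def test_longread_annotations_match_bruteforce(self, suite, random_calls):
        from svarbiter.core import partition_site

        ds = suite.datasets[2]
        sites = list(suite.genome.truth[:3]) + list(random_calls[:3])
        tab = annotate_sites(sites, ds, subset="full")
        contig_len = len(suite.genome.reference)
        for sv in sites:
            part = partition_site(sv, 100, contig_len)
            reads = oracle.scan_reads(ds.bam_path, part.M)
            nd, ni, diff = oracle.naive_longread_rates(
                reads, ds.long_read_indel_baseline
            )
            sid = sv.site_id
            if nd is None:
                assert tab.mask.loc[sid, "M_Del"]
            else:
                assert tab.values.loc[sid, "M_Del"] == pytest.approx(nd, abs=1e-9)
                assert tab.values.loc[sid, "M_Ins"] == pytest.approx(ni, abs=1e-9)
                assert tab.values.loc[sid, "M_DelMinusIns"] == pytest.approx(diff, abs=1e-9)
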