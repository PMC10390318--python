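"""I/O round trips, genotype masking and the joint site filter."""
import math

import numpy as np
import pytest

from introscan import variantio as vio
from introscan.simpop import SimConfig, simulate_cohort
from introscan.variantio import MISSING, GenomicInterval, IBDSegment

from conftest import build_table

TOY_VCF = """\
##fileformat=VCFv4.2
##INFO=<ID=FS,Number=1,Type=Float,Description="x">
##INFO=<ID=MQ,Number=1,Type=Float,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="x">
##contig=<ID=chr1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
chr1\t100\t.\tA\tG\t50\tPASS\tFS=2;MQ=58\tGT:GQ\t0/1:40\t0/0:50
chr1\t200\t.\tC\tT\t60\tPASS\tFS=1;MQ=60\tGT:GQ\t./.:10\t1/1:60
chr1\t300\t.\tG\tA,T\t70\tPASS\tFS=3;MQ=55\tGT:GQ\t1/2:30\t0/0:30
chr1\t400\t.\tT\tC\t80\tPASS\tMQ=50\tGT:GQ\t0|1:35\t1|1:45
chr1\t500\t.\tA\tC\t90\tPASS\tFS=4;MQ=52\tGT:GQ\t0/0:25\t0/1:33
"""


@pytest.fixture
def toy_vcf(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    return p


class TestReadVCF:
    def test_multiallelic_excluded_and_fields_parsed(self, toy_vcf):
        with pytest.warns(UserWarning, match="multiallelic"):
            t = vio.read_vcf(toy_vcf)
        assert t.n_sites == 4
        assert list(t.pos) == [100, 200, 400, 500]
        assert t.genotypes[0].tolist() == [1, 0]
        assert t.chrom_lengths == {"chr1": 100000}
        assert t.qual[0] == 50
        assert t.fs[0] == 2 and t.mq[0] == 58
        assert math.isnan(t.fs[2])  # record at pos 400 has no FS
        assert t.gq[0].tolist() == [40, 50]

    def test_missing_call_is_missing(self, toy_vcf):
        with pytest.warns(UserWarning):
            t = vio.read_vcf(toy_vcf)
        assert t.genotypes[1, 0] == MISSING
        assert t.genotypes[1, 1] == 2

    def test_phased_record_populates_haplotypes(self, toy_vcf):
        with pytest.warns(UserWarning):
            t = vio.read_vcf(toy_vcf)
        i = list(t.pos).index(400)
        assert t.phased_haplotypes[i, 0].tolist() == [0, 1]
        assert t.phased_haplotypes[i, 1].tolist() == [1, 1]
        assert t.genotypes[i].tolist() == [1, 2]
        # unphased records leave haplotypes unset
        assert t.phased_haplotypes[0, 0].tolist() == [MISSING, MISSING]

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            vio.read_vcf(tmp_path / "absent.vcf")

    def test_no_biallelic_snps_warns_not_raises(self, tmp_path):
        p = tmp_path / "empty.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t10\t.\tA\tG,T\t50\tPASS\t.\tGT\t0/1\n"
        )
        with pytest.warns(UserWarning, match="no biallelic"):
            t = vio.read_vcf(p)
        assert t.n_sites == 0


class TestVCFRoundTrip:
    def test_simulated_cohort_round_trips_exactly(self, tmp_path):
        cfg = SimConfig(
            seq_length=300_000, n_oh=4, n_onl=5, n_onc=3, n_og=2, seed=5
        )
        table, _ = simulate_cohort(cfg)
        path = tmp_path / "cohort.vcf"
        vio.write_vcf(table, path)
        back = vio.read_vcf(path)
        assert back.sample_ids == table.sample_ids
        np.testing.assert_array_equal(back.pos, table.pos)
        np.testing.assert_array_equal(back.genotypes, table.genotypes)
        np.testing.assert_array_equal(back.gq, table.gq)
        np.testing.assert_array_equal(back.phased_haplotypes, table.phased_haplotypes)
        np.testing.assert_array_equal(back.qual, table.qual)
        np.testing.assert_array_equal(back.fs, table.fs)
        np.testing.assert_array_equal(back.mq, table.mq)
        assert list(back.ref) == list(table.ref)
        assert list(back.alt) == list(table.alt)
        assert back.chrom_lengths == table.chrom_lengths


class TestMaskLowGQ:
    def test_boundary_strict_less_than(self, make_table):
        t = make_table([[1, 1, 1]], gq=[[9, 10, 11]])
        m = vio.mask_low_gq(t, 10)
        assert m.genotypes[0].tolist() == [MISSING, 1, 1]

    def test_no_gq_is_noop_with_warning(self, make_table):
        t = make_table([[1, 2]])
        with pytest.warns(UserWarning, match="no GQ"):
            m = vio.mask_low_gq(t)
        np.testing.assert_array_equal(m.genotypes, t.genotypes)

    def test_negative_threshold_rejected(self, make_table):
        t = make_table([[1]], gq=[[30]])
        with pytest.raises(ValueError):
            vio.mask_low_gq(t, -1)

    def test_masks_phased_haplotypes_too(self, make_phased_table):
        t = make_phased_table([[0, 1, 1, 1]])
        t.gq = np.asarray([[5, 60]], dtype=np.int16)
        m = vio.mask_low_gq(t)
        assert m.genotypes[0, 0] == MISSING
        assert m.phased_haplotypes[0, 0].tolist() == [MISSING, MISSING]
        assert m.phased_haplotypes[0, 1].tolist() == [1, 1]


def reevaluate_filter(
    table, qual_min=30.0, fs_max=60.0, mq_min=40.0, pass_frac_min=0.8,
    maf_min=0.05, missing_max=0.20, gq_min=10,
):
    """Independent per-site boolean oracle: plain-python clause evaluation."""
    keep = []
    for i in range(table.n_sites):
        g = [int(x) for x in table.genotypes[i]]
        n = len(g)
        called = [x for x in g if x != MISSING]
        missing_rate = 1 - len(called) / n
        if called:
            p = sum(called) / (2 * len(called))
            maf = min(p, 1 - p)
        else:
            maf = -1
        if table.gq is not None:
            n_pass = sum(
                1 for j in range(n)
                if g[j] != MISSING and table.gq[i, j] >= gq_min
            )
        else:
            n_pass = len(called)
        ok = True
        if not math.isnan(table.qual[i]) and table.qual[i] < qual_min:
            ok = False
        if not math.isnan(table.fs[i]) and table.fs[i] > fs_max:
            ok = False
        if not math.isnan(table.mq[i]) and table.mq[i] < mq_min:
            ok = False
        if n_pass / n < pass_frac_min:
            ok = False
        if maf < maf_min:
            ok = False
        if missing_rate > missing_max:
            ok = False
        keep.append(ok)
    return keep


class TestFilterSites:
    def test_each_clause_rejects_one_site(self, make_table):
        """Seven sites: one violating each clause plus one passing all."""
        n = 10
        hi = [[60] * n]
        base = [1, 1, 0, 0, 2, 2, 0, 1, 0, 1]  # maf 0.4, no missing
        rows, quals, fss, mqs, gqs = [], [], [], [], []

        def add(g, qual=100.0, fs=1.0, mq=55.0, gq=None):
            rows.append(g)
            quals.append(qual)
            fss.append(fs)
            mqs.append(mq)
            gqs.append(gq if gq is not None else [60] * n)

        add(base, qual=29.0)                       # QUAL clause
        add(base, fs=60.5)                         # FS clause
        add(base, mq=39.0)                         # MQ clause
        add(base, gq=[9, 9, 9, 9] + [60] * 6)      # pass-fraction clause (0.6)
        add([0] * n)                               # MAF clause (monomorphic)
        add([MISSING] * 3 + base[3:])              # missing clause (0.3)
        add(base)                                  # survivor
        t = make_table(rows, qual=quals, fs=fss, mq=mqs, gq=gqs)
        kept, stats = vio.filter_sites(t, pass_frac_min=0.65)
        assert kept.n_sites == 1
        assert kept.pos[0] == t.pos[6]
        oracle = reevaluate_filter(t, pass_frac_min=0.65)
        assert oracle == [False] * 6 + [True]

    def test_boundary_values_survive(self, make_table):
        # maf exactly 0.05: 20 alleles, one alt
        g = [[1] + [0] * 9]
        t = make_table(g, qual=[30.0], fs=[60.0], mq=[40.0], gq=[[10] * 10])
        kept, stats = vio.filter_sites(t)
        assert kept.n_sites == 1
        assert stats.maf[0] == pytest.approx(0.05)

    def test_missing_annotations_pass(self, make_table):
        t = make_table(
            [[1, 1, 0, 0]], qual=[100.0], fs=[math.nan], mq=[math.nan]
        )
        kept, _ = vio.filter_sites(t)
        assert kept.n_sites == 1

    def test_empty_table(self, make_table):
        t = build_table(np.zeros((0, 3), dtype=np.int8))
        kept, _ = vio.filter_sites(t)
        assert kept.n_sites == 0

    def test_invalid_thresholds(self, make_table):
        t = make_table([[1, 1]])
        with pytest.raises(ValueError):
            vio.filter_sites(t, maf_min=0.6)
        with pytest.raises(ValueError):
            vio.filter_sites(t, missing_max=1.5)
        with pytest.raises(ValueError):
            vio.filter_sites(t, qual_min=-5)

    def test_idempotent_and_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n_sites, n_samp = 200, 12
            g = rng.integers(0, 3, size=(n_sites, n_samp)).astype(np.int8)
            g[rng.random((n_sites, n_samp)) < 0.15] = MISSING
            t = build_table(
                g,
                qual=rng.uniform(0, 200, n_sites),
                fs=rng.uniform(0, 120, n_sites),
                mq=rng.uniform(20, 70, n_sites),
                gq=rng.integers(0, 99, size=(n_sites, n_samp)),
            )
            kept, _ = vio.filter_sites(t)
            oracle = reevaluate_filter(t)
            np.testing.assert_array_equal(kept.pos, t.pos[np.asarray(oracle)])
            again, _ = vio.filter_sites(kept)
            np.testing.assert_array_equal(again.pos, kept.pos)
            np.testing.assert_array_equal(again.genotypes, kept.genotypes)


class TestTsTv:
    def test_hand_counts(self, make_table):
        t = make_table(
            [[1, 1]] * 3, ref=["A", "C", "A"], alt=["G", "T", "C"]
        )
        assert vio.ts_tv_ratio(t) == pytest.approx(2.0)

    def test_all_transitions_is_infinite(self, make_table):
        t = make_table([[1, 1]] * 2, ref=["A", "C"], alt=["G", "T"])
        assert math.isinf(vio.ts_tv_ratio(t))

    def test_empty_table_rejected(self):
        t = build_table(np.zeros((0, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            vio.ts_tv_ratio(t)


class TestIBDSegments:
    def test_coordinate_conversion(self, tmp_path):
        p = tmp_path / "ibd.tsv"
        p.write_text("S1\t1\tS2\t2\tchr1\t1001\t2000\t9.3\n")
        segs = vio.read_ibd_segments(p)
        assert segs[0].interval.start == 1000
        assert segs[0].interval.end == 2000
        assert segs[0].lod == 9.3

    def test_malformed_lines_skipped_with_warning(self, tmp_path):
        p = tmp_path / "ibd.tsv"
        p.write_text(
            "S1\t1\tS2\t2\tchr1\t1001\t2000\t9.3\n"
            "S1\t1\tS2\t2\tchr1\t5000\t4000\t2.0\n"   # end < start
            "garbage line\n"
        )
        with pytest.warns(UserWarning, match="malformed"):
            segs = vio.read_ibd_segments(p)
        assert len(segs) == 1

    def test_zero_parseable_lines_is_format_error(self, tmp_path):
        p = tmp_path / "ibd.tsv"
        p.write_text("not\tan\tibd\tfile\n")
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                vio.read_ibd_segments(p)

    def test_round_trip(self, tmp_path):
        segs = [
            IBDSegment("A", 1, "B", 2, GenomicInterval("chr1", 0, 5000), 5.0),
            IBDSegment("A", 2, "C", 1, GenomicInterval("chr2", 100, 900), 0.8),
            IBDSegment("B", 1, "C", 2, GenomicInterval("chr1", 10, 20), 0.01),
        ]
        p = tmp_path / "out.tsv"
        vio.write_ibd_segments(segs, p)
        assert vio.read_ibd_segments(p) == segs


GFF_TOY = """\
##gff-version 3
chr1\tsrc\tgene\t101\t160\t.\t+\t.\tID=geneF
chr1\tsrc\tmRNA\t101\t160\t.\t+\t.\tID=geneF.t1;Parent=geneF
chr1\tsrc\tCDS\t101\t112\t.\t+\t0\tID=cdsF1;Parent=geneF.t1
chr1\tsrc\tCDS\t131\t139\t.\t+\t0\tID=cdsF2;Parent=geneF.t1
chr1\tsrc\tgene\t201\t260\t.\t-\t.\tID=geneR
chr1\tsrc\tmRNA\t201\t260\t.\t-\t.\tID=geneR.t1;Parent=geneR
chr1\tsrc\tCDS\t201\t212\t.\t-\t0\tID=cdsR1;Parent=geneR.t1
chr1\tsrc\tCDS\t231\t239\t.\t-\t0\tID=cdsR2;Parent=geneR.t1
chr1\tsrc\tgene\t301\t320\t.\t+\t.\tID=geneBad
chr1\tsrc\tmRNA\t301\t320\t.\t+\t.\tID=geneBad.t1;Parent=geneBad
chr1\tsrc\tCDS\t301\t310\t.\t+\t0\tID=cdsB;Parent=geneBad.t1
"""


@pytest.fixture
def toy_annotation(tmp_path):
    gff = tmp_path / "toy.gff3"
    gff.write_text(GFF_TOY)
    fasta = tmp_path / "toy.fa"
    rng = np.random.default_rng(0)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
    fasta.write_text(f">chr1\n{seq}\n")
    return gff, fasta


class TestGeneModels:
    def test_forward_strand_parts_in_genomic_order(self, toy_annotation):
        with pytest.warns(UserWarning, match="malformed"):
            models, genome = vio.read_gene_models(*toy_annotation)
        by_id = {m.gene_id: m for m in models}
        f = by_id["geneF.t1"]
        assert [(iv.start, iv.end) for iv, _ in f.cds_parts] == [(100, 112), (130, 139)]

    def test_reverse_strand_transcript_order_descends(self, toy_annotation):
        with pytest.warns(UserWarning):
            models, _ = vio.read_gene_models(*toy_annotation)
        r = {m.gene_id: m for m in models}["geneR.t1"]
        assert [(iv.start, iv.end) for iv, _ in r.cds_parts] == [(230, 239), (200, 212)]

    def test_length_not_multiple_of_three_excluded(self, toy_annotation):
        with pytest.warns(UserWarning, match="malformed"):
            models, _ = vio.read_gene_models(*toy_annotation)
        assert "geneBad.t1" not in {m.gene_id for m in models}

    def test_absent_contig_raises_with_name(self, tmp_path):
        gff = tmp_path / "bad.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chrX\tsrc\tmRNA\t1\t9\t.\t+\t.\tID=t1\n"
            "chrX\tsrc\tCDS\t1\t9\t.\t+\t0\tID=c1;Parent=t1\n"
        )
        fasta = tmp_path / "g.fa"
        fasta.write_text(">chr1\nACGTACGTACGT\n")
        with pytest.raises(ValueError, match="chrX"):
            vio.read_gene_models(gff, fasta)


class TestBed:
    def test_format_and_round_trip(self, tmp_path):
        p = tmp_path / "x.bed"
        vio.write_bed([GenomicInterval("chr1", 0, 100)], p)
        assert p.read_text() == "chr1\t0\t100\n"
        back = vio.read_bed(p)
        assert back[0][0] == GenomicInterval("chr1", 0, 100)

    def test_deterministic_ordering(self, tmp_path):
        p = tmp_path / "x.bed"
        vio.write_bed(
            [GenomicInterval("chr2", 5, 9), GenomicInterval("chr1", 50, 60),
             GenomicInterval("chr1", 0, 10)],
            p,
        )
        lines = p.read_text().splitlines()
        assert lines == ["chr1\t0\t10", "chr1\t50\t60", "chr2\t5\t9"]

    def test_empty_list_empty_file(self, tmp_path):
        p = tmp_path / "x.bed"
        vio.write_bed([], p)
        assert p.read_text() == ""

    def test_vcf_to_bed_coordinate_identity(self, toy_vcf, tmp_path):
        with pytest.warns(UserWarning):
            t = vio.read_vcf(toy_vcf)
        ivs = [GenomicInterval("chr1", int(p) - 1, int(p)) for p in t.pos]
        bed = tmp_path / "sites.bed"
        vio.write_bed(ivs, bed)
        back = [iv for iv, _ in vio.read_bed(bed)]
        assert [iv.start + 1 for iv in back] == list(t.pos)


class TestInvariantEnforcement:
    def test_interval_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    def test_ibd_self_pair_rejected(self):
        with pytest.raises(ValueError):
            IBDSegment("A", 1, "A", 1, GenomicInterval("chr1", 0, 10), 1.0)

    def test_table_validate_catches_bad_genotype(self, make_table):
        t = make_table([[1, 1]])
        t.genotypes[0, 0] = 5
        with pytest.raises(ValueError):
            t.validate()
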