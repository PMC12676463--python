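import pytest

from evalkit.errors import FormatError, ParameterError
from evalkit.variants import (
    HitRow,
    VariantRecord,
    VariantSet,
    apply_variants,
    classify,
    count_multiallelic,
    parse_vcf,
    read_hit_table,
    recurrence_filter,
    repeat_hit_filter,
    size_filter,
    split_multiallelic,
    trim_alleles,
    write_vcf,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
    '##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="l">\n'
    '##INFO=<ID=END,Number=1,Type=Integer,Description="e">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
    "##contig=<ID=chr1,length=100000>\n"
)


def make_vcf(tmp_path, body, samples=("s1",)):
    path = tmp_path / "in.vcf"
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        cols += "\tFORMAT\t" + "\t".join(samples)
    path.write_text(VCF_HEADER + cols + "\n" + body)
    return path


def rec(pos, ref, alts, gts=None, info=None, chrom="chr1"):
    return VariantRecord(
        chrom, pos, ref, tuple(alts) if isinstance(alts, (list, tuple)) else (alts,),
        info=info or {},
        genotypes=gts or {"s1": (1,)},
    )


class TestVcfIO:
    def test_single_record_round_trip(self, tmp_path):
        path = make_vcf(tmp_path, "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t1\n")
        vset = parse_vcf(path)
        assert len(vset) == 1
        r = vset.records[0]
        assert (r.chrom, r.pos, r.ref, r.alts) == ("chr1", 100, "A", ("T",))
        assert r.presence == {"s1": 1}
        out = tmp_path / "out.vcf"
        write_vcf(vset, out)
        again = parse_vcf(out)
        r2 = again.records[0]
        assert (r2.chrom, r2.pos, r2.ref, r2.alts, r2.presence) == (
            r.chrom, r.pos, r.ref, r.alts, r.presence,
        )

    def test_symbolic_deletion_svlen_from_end(self, tmp_path):
        path = make_vcf(
            tmp_path, "chr1\t1001\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=1100\tGT\t1\n"
        )
        r = parse_vcf(path).records[0]
        assert r.svlen == -100
        assert r.end == 1100

    def test_empty_body(self, tmp_path):
        vset = parse_vcf(make_vcf(tmp_path, ""))
        assert len(vset) == 0 and vset.samples == ["s1"]

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("chr1\t100\t.\tA\tT\t.\t.\t.\n")
        with pytest.raises(FormatError):
            parse_vcf(path)

    def test_unsorted_input_sorted_with_warning(self, tmp_path):
        body = (
            "chr1\t500\t.\tA\tT\t.\tPASS\t.\tGT\t1\n"
            "chr1\t100\t.\tC\tG\t.\tPASS\t.\tGT\t1\n"
        )
        with pytest.warns(UserWarning, match="unsorted"):
            vset = parse_vcf(make_vcf(tmp_path, body))
        assert [r.pos for r in vset.records] == [100, 500]

    def test_permissive_gt_less_records(self, tmp_path):
        path = tmp_path / "nogt.vcf"
        path.write_text(
            VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\t.\tA\tT\t.\tPASS\t.\n"
        )
        vset = parse_vcf(path, permissive_sample="asm1")
        assert vset.samples == ["asm1"]
        assert vset.records[0].presence == {"asm1": 1}

    def test_bundle_truth_round_trip(self, bundle, tmp_path):
        out = tmp_path / "truth.vcf"
        write_vcf(bundle.truth, out)
        again = parse_vcf(out)
        assert len(again) == len(bundle.truth)
        for a, b in zip(bundle.truth.records, again.records):
            assert (a.chrom, a.pos, a.ref, a.alts) == (b.chrom, b.pos, b.ref, b.alts)
            assert a.svlen == b.svlen and a.end == b.end
            assert a.presence == b.presence


class TestSplitMultiallelic:
    def test_snp_site_splits_per_alt(self):
        r = rec(100, "A", ("T", "G"), gts={"s1": (1,), "s2": (2,)})
        parts = split_multiallelic(r)
        assert [(p.pos, p.ref, p.alts[0]) for p in parts] == [
            (100, "A", "T"), (100, "A", "G"),
        ]
        assert parts[0].presence == {"s1": 1, "s2": 0}
        assert parts[1].presence == {"s1": 0, "s2": 1}

    def test_trimming_insertion_and_deletion(self):
        parts = split_multiallelic(rec(50, "ATT", ("ATTTT", "A")))
        ins, dele = parts
        assert (ins.pos, ins.ref, ins.alts[0]) == (50, "A", "ATT")
        assert (dele.pos, dele.ref, dele.alts[0]) == (50, "ATT", "A")

    def test_split_application_matches_multiallelic(self):
        """Applying each split record to its carrier reproduces the original
        multiallelic application on a toy sequence."""
        seq = "GGGGATTCCCC"  # REF ATT at 1-based pos 5
        ref = {"c": seq}
        multi = rec(5, "ATT", ("ATTTT", "A"),
                    gts={"s1": (1,), "s2": (2,)}, chrom="c")
        # direct application of each original alt allele
        direct_s1 = seq[:4] + "ATTTT" + seq[7:]
        direct_s2 = seq[:4] + "A" + seq[7:]
        parts = split_multiallelic(multi)
        vset = VariantSet(parts, ["s1", "s2"])
        assert apply_variants(ref, vset, "s1")["c"] == direct_s1
        assert apply_variants(ref, vset, "s2")["c"] == direct_s2

    def test_biallelic_returned_unchanged(self):
        r = rec(100, "A", "T")
        assert split_multiallelic(r) == [r]

    def test_remerge_reconstructs_alt_set(self):
        r = rec(100, "AC", ("AT", "A", "ACC"))
        parts = split_multiallelic(r)
        assert len(parts) == 3
        assert all(p.chrom == r.chrom for p in parts)
        # each split allele, re-padded onto the original REF, is an original alt
        recovered = set()
        for p in parts:
            offset = p.pos - r.pos
            alt = r.ref[:offset] + p.alts[0] + r.ref[offset + len(p.ref):]
            recovered.add(alt)
        assert recovered == set(r.alts)


class TestClassify:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("A", "T", "SNP"),
            ("AC", "TG", "MNP"),
            ("A", "A" + "C" * 51, "SV_INS"),
            ("A" + "C" * 30, "A", "DEL"),
            ("A", "A" + "C" * 30, "INS"),
            ("A" + "G" * 50, "A", "SV_DEL"),
        ],
    )
    def test_types(self, ref, alt, expected):
        assert classify(rec(100, ref, alt)) == expected

    def test_symbolic_and_other(self):
        assert classify(rec(100, "N", "<DEL>", info={"SVLEN": -200})) == "SV_DEL"
        assert classify(rec(100, "N", "<INV>", info={"SVLEN": 200, "END": 299})) == "OTHER"
        assert classify(rec(100, "N", "<DUP>", info={"SVLEN": 200, "END": 299})) == "OTHER"

    def test_padding_invariance(self):
        padded = rec(100, "GAT", ("GATTTT",))
        trimmed_pos, trimmed_ref, trimmed_alt = trim_alleles(100, "GAT", "GATTTT")
        assert classify(padded) == classify(
            rec(trimmed_pos, trimmed_ref, trimmed_alt)
        )

    def test_multiallelic_rejected(self):
        with pytest.raises(ParameterError):
            classify(rec(100, "A", ("T", "G")))


class TestCounts:
    def test_count_multiallelic(self):
        biallelic = VariantSet([rec(1, "A", "T"), rec(9, "C", "G")], ["s1"])
        assert count_multiallelic(biallelic) == 0
        mixed = VariantSet([rec(1, "A", ("T", "G")), rec(9, "C", "G")], ["s1"])
        assert count_multiallelic(mixed) == 1

    def test_bundle_planted_count(self, bundle):
        # the generator emits biallelic truth records only
        assert count_multiallelic(bundle.truth) == 0


class TestFilters:
    def two_sample_set(self):
        return VariantSet(
            [
                rec(100, "A", "A" + "C" * 150, gts={"s1": (1,), "s2": (0,)}),
                rec(900, "A", "A" + "C" * 150, gts={"s1": (1,), "s2": (1,)}),
                rec(1700, "A", "A" + "C" * 100, gts={"s1": (1,), "s2": (1,)}),
            ],
            ["s1", "s2"],
        )

    def test_recurrence_drops_singletons(self):
        out = recurrence_filter(self.two_sample_set(), 2)
        assert [r.pos for r in out.records] == [900, 1700]

    def test_recurrence_min_one_is_identity(self):
        vset = self.two_sample_set()
        assert len(recurrence_filter(vset, 1)) == len(vset)

    def test_recurrence_bad_min(self):
        with pytest.raises(ParameterError):
            recurrence_filter(self.two_sample_set(), 0)

    def test_size_strictly_greater(self):
        out = size_filter(self.two_sample_set(), 100)
        assert [r.pos for r in out.records] == [100, 900]  # 100 bp record dropped
        out2 = size_filter(self.two_sample_set(), 100, strict_greater=False)
        assert len(out2) == 3

    def test_snp_dropped_by_size(self):
        vset = VariantSet([rec(5, "A", "T")], ["s1"])
        assert len(size_filter(vset, 100)) == 0

    def test_filters_commute_and_idempotent(self):
        vset = self.two_sample_set()
        a = size_filter(recurrence_filter(vset, 2), 100)
        b = recurrence_filter(size_filter(vset, 100), 2)
        assert [r.pos for r in a.records] == [r.pos for r in b.records] == [900]
        assert [r.pos for r in size_filter(a, 100).records] == [900]


class TestHitTable:
    def test_top_hit_by_coverage(self):
        hits = [
            HitRow("q1", "te1", 95.0, 85.0),
            HitRow("q1", "te2", 90.0, 92.0),
        ]
        best = repeat_hit_filter(hits)
        assert best["q1"].subject == "te2"

    def test_low_coverage_query_excluded(self):
        assert repeat_hit_filter([HitRow("q1", "te1", 99.0, 75.0)]) == {}

    def test_tie_breaks_identity_then_subject(self):
        hits = [
            HitRow("q1", "teB", 90.0, 92.0),
            HitRow("q1", "teA", 90.0, 92.0),
            HitRow("q1", "teC", 95.0, 92.0),
        ]
        assert repeat_hit_filter(hits)["q1"].subject == "teC"
        hits = hits[:2]
        assert repeat_hit_filter(hits)["q1"].subject == "teA"

    def test_empty_table(self):
        assert repeat_hit_filter([]) == {}

    def test_read_table(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            "q1\tte1\t95.5\t100\t0\t0\t1\t100\t1\t100\t1e-50\t180\t88.0\n"
        )
        (row,) = read_hit_table(p)
        assert (row.query, row.subject) == ("q1", "te1")
        assert row.pct_identity == 95.5 and row.query_coverage == 88.0

    def test_bad_coverage_rejected(self):
        with pytest.raises(FormatError):
            HitRow("q", "s", 90.0, 150.0)


class TestApplyVariants:
    def test_ref_mismatch_detected(self):
        ref = {"c": "AAAA"}
        vset = VariantSet([rec(2, "G", "T", chrom="c")], ["s1"])
        with pytest.raises(FormatError, match="REF mismatch"):
            apply_variants(ref, vset, "s1")

    def test_full_reconstruction(self, bundle, tmp_path):
        out = tmp_path / "t.vcf"
        write_vcf(bundle.truth, out)
        reparsed = parse_vcf(out)
        for sample in bundle.config.samples:
            assert apply_variants(bundle.reference, reparsed, sample) == (
                bundle.haplotypes[sample]
            )
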