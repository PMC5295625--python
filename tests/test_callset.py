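"""Callset normalization, union merging, provenance and intersections."""

import itertools

import numpy as np
import pytest

from poolvar.callset import (
    AlleleKey,
    Callset,
    VariantSite,
    aligner_consistency,
    classify_sites,
    fasta_fetcher,
    fuse_alleles,
    intersection_summary,
    merge_union,
    normalize_allele,
    overlap_with_reference_callset,
    read_callset,
    write_vcf,
)

TOY_REF = {"chr1": "GGACACACACTTAGCTAGCTTACGTACG"}


def apply_variant(seq: str, pos: int, ref: str, alt: str) -> str:
    """Independent oracle: substitute the ref allele by the alt in a sequence."""
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref):]


def toy_fetch(chrom, pos1):
    return TOY_REF[chrom][pos1 - 1]


class TestNormalization:
    def test_equivalent_deletion_representations_converge(self):
        # deleting any AC unit from the ACACAC run of GGACACACACTT yields the
        # same haplotype; every representation must left-align to pos 2 GAC>G
        seq = TOY_REF["chr1"]
        reps = [(2, "GAC", "G"), (4, "CAC", "C"), (6, "CAC", "C"), (8, "CAC", "C")]
        haplotypes = {apply_variant(seq, p, r, a) for p, r, a in reps}
        assert len(haplotypes) == 1  # the representations really are equivalent
        keys = {normalize_allele("chr1", p, r, a, toy_fetch) for p, r, a in reps}
        assert keys == {AlleleKey("chr1", 2, "GAC", "G")}

    def test_padded_snp_trimmed(self):
        key = normalize_allele("chr1", 12, "TAG", "TCG", toy_fetch)
        assert key == AlleleKey("chr1", 13, "A", "C")

    def test_normalization_preserves_the_haplotype(self):
        rng = np.random.default_rng(3)
        seq = TOY_REF["chr1"]
        for _ in range(200):
            pos = int(rng.integers(3, 20))
            if rng.random() < 0.5:  # deletion with anchor
                dlen = int(rng.integers(1, 4))
                ref, alt = seq[pos - 1 : pos + dlen], seq[pos - 1]
            else:  # insertion
                ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
                ref, alt = seq[pos - 1], seq[pos - 1] + ins
            if ref == alt:
                continue
            # pad with reference context on both sides: same event
            pad_ref = seq[pos - 2] + ref + seq[pos - 1 + len(ref)]
            pad_alt = seq[pos - 2] + alt + seq[pos - 1 + len(ref)]
            k1 = normalize_allele("chr1", pos, ref, alt, toy_fetch)
            k2 = normalize_allele("chr1", pos - 1, pad_ref, pad_alt, toy_fetch)
            assert k1 == k2
            assert apply_variant(seq, k1.pos, k1.ref, k1.alt) == apply_variant(
                seq, pos, ref, alt
            )

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            normalize_allele("chr1", 5, "A", "A", toy_fetch)


class TestReadCallset:
    def test_single_snp(self, write_vcf_text, write_fasta):
        fa = write_fasta(TOY_REF)
        vcf = write_vcf_text([("chr1", 13, "A", "G")], contigs={"chr1": 28})
        cs = read_callset(vcf, ("bwa", "x"), fa)
        assert cs.sites == [VariantSite("chr1", 13, "A", ("G",))]
        assert cs.sites[0].vtype == "biallelic_SNP"

    def test_multiallelic_record_split_and_refused(self, write_vcf_text, write_fasta):
        fa = write_fasta(TOY_REF)
        vcf = write_vcf_text([("chr1", 13, "A", "G,T")], contigs={"chr1": 28})
        cs = read_callset(vcf, ("bwa", "x"), fa)
        assert len(cs.alleles) == 2
        (site,) = cs.sites
        assert site.alts == ("G", "T") and site.vtype == "multiallelic"

    def test_ref_mismatch_is_hard_error(self, write_vcf_text, write_fasta):
        fa = write_fasta(TOY_REF)
        vcf = write_vcf_text([("chr1", 13, "C", "G")], contigs={"chr1": 28})
        with pytest.raises(ValueError, match="REF mismatch"):
            read_callset(vcf, ("bwa", "x"), fa)

    def test_indel_representations_merge_across_callers(self, write_vcf_text, write_fasta):
        fa = write_fasta(TOY_REF)
        v1 = write_vcf_text([("chr1", 2, "GAC", "G")], name="a.vcf", contigs={"chr1": 28})
        v2 = write_vcf_text([("chr1", 6, "CAC", "C")], name="b.vcf", contigs={"chr1": 28})
        sites, prov = merge_union(
            [read_callset(v1, ("bwa", "a"), fa), read_callset(v2, ("bwa", "b"), fa)]
        )
        assert len(sites) == 1
        assert prov[sites[0]] == {("bwa", "a"), ("bwa", "b")}


def make_callset(pid, keys):
    return Callset(pid, alleles={AlleleKey("chr1", p, r, a) for p, r, a in keys})


class TestMergeUnion:
    def test_disjoint_sets_union(self):
        a = make_callset("A", [(i, "A", "G") for i in (10, 20, 30)])
        b = make_callset("B", [(i, "A", "G") for i in (40, 50, 60, 70)])
        sites, prov = merge_union([a, b])
        assert len(sites) == 7
        assert all(len(p) == 1 for p in prov.values())

    def test_identical_callsets(self):
        keys = [(i, "C", "T") for i in (5, 6, 7)]
        sites, prov = merge_union([make_callset("A", keys), make_callset("B", keys)])
        assert len(sites) == 3
        assert all(p == {"A", "B"} for p in prov.values())

    def test_duplicate_pipeline_id_rejected(self):
        a = make_callset("A", [(1, "A", "G")])
        with pytest.raises(ValueError, match="duplicate"):
            merge_union([a, make_callset("A", [(2, "A", "G")])])

    def test_union_commutative_and_idempotent(self):
        rng = np.random.default_rng(11)
        def random_cs(pid):
            return make_callset(
                pid,
                [(int(p), "A", rng.choice(["C", "G", "T"])) for p in rng.integers(1, 60, 25)],
            )
        a, b = random_cs("A"), random_cs("B")
        s_ab, p_ab = merge_union([a, b])
        s_ba, p_ba = merge_union([b, a])
        assert s_ab == s_ba and p_ab == p_ba
        # re-merging the union with one input changes nothing
        union_cs = Callset("U", alleles=a.alleles | b.alleles)
        s_again, _ = merge_union([union_cs, Callset("B2", alleles=set(b.alleles))])
        assert s_again == s_ab

    def test_vtype_partition_sums_to_union_size(self):
        rng = np.random.default_rng(7)
        alleles = set()
        for _ in range(80):
            p = int(rng.integers(1, 40))
            kind = rng.random()
            if kind < 0.5:
                alleles.add(AlleleKey("chr1", p, "A", str(rng.choice(["C", "G", "T"]))))
            elif kind < 0.75:
                alleles.add(AlleleKey("chr1", p, "AT", "A"))
            else:
                alleles.add(AlleleKey("chr1", p, "A", "ATT"))
        sites, _ = merge_union([Callset("X", alleles=alleles)])
        counts = classify_sites(sites)
        assert sum(counts.values()) == len(sites)

    def test_cross_caller_alts_become_multiallelic(self):
        a = make_callset("A", [(10, "A", "G")])
        b = make_callset("B", [(10, "A", "T")])
        sites, prov = merge_union([a, b])
        assert sites[0].vtype == "multiallelic"
        assert prov[sites[0]] == {"A", "B"}


class TestIntersectionSummary:
    def test_single_pipeline(self):
        sites, prov = merge_union([make_callset("A", [(1, "A", "G"), (2, "A", "G")])])
        s = intersection_summary(prov)
        assert s.per_pipeline == {"A": 2}
        assert s.pairwise.loc["A", "A"] == 2
        assert s.exclusive_by_k == {1: 2}

    def test_nested_callsets(self):
        inner = [(i, "A", "G") for i in range(1, 6)]
        outer = inner + [(i, "A", "G") for i in range(6, 11)]
        _, prov = merge_union([make_callset("A", inner), make_callset("B", outer)])
        s = intersection_summary(prov)
        assert s.pairwise.loc["A", "B"] == 5  # shared(A,B) = |A|

    def test_random_provenance_matches_enumeration(self):
        rng = np.random.default_rng(13)
        pipelines = ["p1", "p2", "p3", "p4"]
        callsets = [
            make_callset(
                pid, [(int(p), "A", "G") for p in rng.choice(100, size=30, replace=False)]
            )
            for pid in pipelines
        ]
        sites, prov = merge_union(callsets)
        s = intersection_summary(prov)
        # brute-force pairwise intersections from the raw allele sets
        by_pid = {cs.pipeline_id: {a.pos for a in cs.alleles} for cs in callsets}
        for x, y in itertools.product(pipelines, pipelines):
            assert s.pairwise.loc[x, y] == len(by_pid[x] & by_pid[y])
        assert sum(s.exclusive_by_k.values()) == len(sites)


class TestAlignerConsistency:
    def test_identical_and_disjoint(self):
        keys = [(i, "A", "G") for i in range(1, 11)]
        _, prov = merge_union(
            [make_callset(("bowtie2", "varscan"), keys), make_callset(("bwa", "varscan"), keys)]
        )
        assert aligner_consistency(prov, "varscan") == 1.0
        _, prov2 = merge_union(
            [
                make_callset(("bowtie2", "varscan"), [(i, "A", "G") for i in range(1, 6)]),
                make_callset(("bwa", "varscan"), [(i, "A", "G") for i in range(6, 11)]),
            ]
        )
        assert aligner_consistency(prov2, "varscan") == 0.0

    def test_87_shared_of_100_union(self):
        a = [(i, "A", "G") for i in range(1, 94)]     # 93 sites
        b = [(i, "A", "G") for i in range(7, 101)]    # 94 sites; 87 shared
        _, prov = merge_union(
            [make_callset(("bowtie2", "varscan"), a), make_callset(("bwa", "varscan"), b)]
        )
        assert aligner_consistency(prov, "varscan") == pytest.approx(0.87)

    def test_caller_missing_under_one_aligner_is_error(self):
        _, prov = merge_union([make_callset(("bwa", "gatk"), [(1, "A", "G")])])
        with pytest.raises(ValueError, match="gatk"):
            aligner_consistency(prov, "gatk")


class TestReferenceOverlap:
    def test_full_and_empty_overlap(self):
        sites, _ = merge_union([make_callset("A", [(i, "A", "G") for i in range(1, 6)])])
        external = [AlleleKey("chr1", i, "A", "G") for i in range(1, 6)]
        assert overlap_with_reference_callset(sites, external).fraction == 1.0
        assert overlap_with_reference_callset(sites, []).n_overlap == 0

    def test_planted_134_of_1000(self):
        keys = [(i, "A", "G") for i in range(1, 1001)]
        sites, _ = merge_union([make_callset("A", keys)])
        external = [AlleleKey("chr1", i, "A", "G") for i in range(1, 135)]
        res = overlap_with_reference_callset(sites, external)
        assert res.n_overlap == 134
        assert res.fraction == pytest.approx(0.134)

    def test_maf_stratification(self):
        keys = [(i, "A", "G") for i in range(1, 11)]
        sites, _ = merge_union([make_callset("A", keys)])
        maf = {s: (0.005 if s.pos <= 5 else 0.2) for s in sites}
        external = [AlleleKey("chr1", i, "A", "G") for i in (1, 2, 6)]
        res = overlap_with_reference_callset(sites, external, maf=maf)
        assert res.by_maf_bin["sum"].sum() == 3


def test_vcf_roundtrip_preserves_sites_and_provenance(tmp_path, write_fasta):
    fa = write_fasta(TOY_REF)
    sites, prov = merge_union(
        [
            make_callset(("bwa", "ngsep"), [(13, "A", "G"), (15, "C", "T")]),
            make_callset(("bowtie2", "ngsep"), [(13, "A", "G")]),
        ]
    )
    out = tmp_path / "merged.vcf"
    write_vcf(sites, out, provenance=prov, contig_lengths={"chr1": 28})
    back = read_callset(out, "roundtrip", fa)
    assert back.sites == sites
    assert "PIPELINES=bowtie2:ngsep,bwa:ngsep" in out.read_text()
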