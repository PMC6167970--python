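"""Unit and property tests for the RAD locus-retention cascade."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import make_record, typed_record
from gilakit import rad_filtering as rf
from gilakit.rad_filtering import MISSING_GT, FilterConfig


# ---------------------------------------------------------------------------
# decomposition / indels


def test_mnp_decomposes_to_per_base_snps():
    rec = make_record(
        pos=10, ref="AT", alts=("GC",), genotypes=["0/0", "0/1", "1/1", MISSING_GT]
    )
    out = rf.decompose_complex_variants([rec])
    assert [(r.pos, r.ref, r.alts) for r in out] == [(10, "A", ("G",)), (11, "T", ("C",))]
    for r in out:
        assert r.genotypes == ["0/0", "0/1", "1/1", MISSING_GT]


def test_mnp_invariant_column_dropped_and_alleles_remapped():
    # second base identical in ref and alt: only one SNP comes out
    rec = make_record(pos=5, ref="AT", alts=("GT",), genotypes=["0/1"], n=1)
    out = rf.decompose_complex_variants([rec])
    assert len(out) == 1 and out[0].pos == 5 and out[0].alts == ("G",)
    # two alts agreeing at a base collapse to one alt with remapped genotypes
    rec2 = make_record(pos=5, ref="AA", alts=("GA", "GT"), genotypes=["1/2"], n=1)
    out2 = rf.decompose_complex_variants([rec2])
    assert [(r.pos, r.ref, r.alts) for r in out2] == [(5, "A", ("G",)), (6, "A", ("T",))]
    assert out2[0].genotypes == ["1/1"]  # both alts share G at base 1
    assert out2[1].genotypes == ["0/1"]  # only alt 2 differs at base 2


def test_snps_and_indels_pass_through_decomposition():
    snp = make_record(ref="A", alts=("G",))
    indel = make_record(pos=2, ref="A", alts=("AG",))
    out = rf.decompose_complex_variants([snp, indel])
    assert out == [snp, indel]


def test_remove_indels():
    snp = make_record(ref="A", alts=("G",))
    ins = make_record(pos=2, ref="A", alts=("AG",))
    dele = make_record(pos=3, ref="AG", alts=("A",))
    assert rf.remove_indels([snp, ins, dele]) == [snp]


def test_empty_allele_rejected():
    rec = make_record(ref="", alts=("G",))
    with pytest.raises(ValueError, match="empty allele"):
        rf.decompose_complex_variants([rec])


# ---------------------------------------------------------------------------
# mtDNA contig removal


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_mtdna_contig_removal(rng):
    mt = _random_seq(rng, 2000)
    mito = mt[400:520]  # verbatim substring: must be removed
    comp = str.maketrans("ACGT", "TGCA")
    mito_rc = mito.translate(comp)[::-1]  # reverse complement: must be removed
    nuclear = _random_seq(rng, 120)  # random: retained
    records = [
        make_record(contig="m1"), make_record(contig="m2"),
        make_record(contig="n1"), make_record(contig="nosq"),
    ]
    seqs = {"m1": mito, "m2": mito_rc, "n1": nuclear}
    kept, removed = rf.remove_mtdna_contigs(records, mt, seqs)
    assert removed == ["m1", "m2"]
    assert {r.contig for r in kept} == {"n1", "nosq"}  # no sequence -> retained


def test_mtdna_identity_threshold(rng):
    mt = _random_seq(rng, 2000)
    base = mt[100:220]
    # shares a 31-mer seed but half the contig is scrambled: identity < 0.90
    diverged = base[:40] + _random_seq(rng, 80)
    records = [make_record(contig="c")]
    kept, removed = rf.remove_mtdna_contigs(records, mt, {"c": diverged})
    assert removed == [] and len(kept) == 1


def test_mtdna_empty_reference_raises():
    with pytest.raises(ValueError, match="empty mtDNA"):
        rf.remove_mtdna_contigs([make_record()], "", {})


# ---------------------------------------------------------------------------
# missingness rule (85% of 19)


def test_missingness_boundary_16_vs_17_of_19():
    cfg = FilterConfig()
    fails = typed_record("lo", n_typed=16, n_total=19)
    passes = typed_record("hi", n_typed=17, n_total=19)
    out = rf.filter_locus_missingness([fails, passes], cfg)
    assert {r.contig for r in out} == {"hi"}


def test_missingness_individual_must_be_typed_at_every_record():
    # typed 17 at the first record but a disjoint 17 at the second:
    # jointly-typed count drops below 17 and the contig is dropped
    cfg = FilterConfig()
    r1 = typed_record("c", 17, 19, pos=1)
    gts = [MISSING_GT, MISSING_GT] + ["0/1"] * 17
    r2 = make_record(contig="c", pos=2, genotypes=gts, n=19)
    assert rf.filter_locus_missingness([r1, r2], cfg) == []


# ---------------------------------------------------------------------------
# haplotype collapsing


def obs_frame(rows):
    return pd.DataFrame(rows, columns=["contig", "individual", "combination", "count"])


def hap_records(contig="c", n_sites=2, n=3):
    return [make_record(contig=contig, pos=i + 1, n=n) for i in range(n_sites)]


def test_collapse_prunes_error_and_flags():
    recs = hap_records()
    obs = obs_frame(
        [
            ("c", "ok_het", "AC", 60), ("c", "ok_het", "GT", 36), ("c", "ok_het", "AT", 4),
            ("c", "paralog", "AC", 30), ("c", "paralog", "GT", 30), ("c", "paralog", "AT", 40),
        ]
    )
    calls = rf.collapse_reads_to_haplotypes(obs, recs, error_fraction=0.05)
    het = calls["c"]["ok_het"]
    assert het.flag == "ok" and het.haplotypes == ("AC", "GT")  # 4% combo pruned
    assert calls["c"]["paralog"].flag == "paralog_suspect"


def test_collapse_boundary_exactly_error_fraction_survives():
    recs = hap_records()
    # 5 of 100 reads == exactly the 0.05 threshold: survives (>= rule)
    obs = obs_frame([("c", "i", "AC", 95), ("c", "i", "GT", 5)])
    calls = rf.collapse_reads_to_haplotypes(obs, recs, error_fraction=0.05)
    assert calls["c"]["i"].haplotypes == ("AC", "GT")


def test_collapse_rejects_wrong_combination_length():
    recs = hap_records(n_sites=3)
    obs = obs_frame([("c", "i", "AC", 10)])
    with pytest.raises(ValueError, match="combination length"):
        rf.collapse_reads_to_haplotypes(obs, recs)


def test_collapse_rejects_unknown_contig():
    obs = obs_frame([("zz", "i", "A", 10)])
    with pytest.raises(ValueError, match="unknown contig"):
        rf.collapse_reads_to_haplotypes(obs, hap_records())


# ---------------------------------------------------------------------------
# depth/completeness rule (14 of 19 at depth >= 20)


def _calls(n_ok, n_total=19):
    inds = [f"i{k:02d}" for k in range(n_total)]
    return {
        "c": {
            ind: rf.HaplotypeCall(flag="ok" if k < n_ok else "low_data",
                                  haplotypes=("A",) if k < n_ok else ())
            for k, ind in enumerate(inds)
        }
    }, inds


def test_haplotype_rule_exactly_14_at_depth_20_kept():
    calls, inds = _calls(14)
    depths = {"c": {ind: 20 for ind in inds}}
    assert rf.filter_haplotyped_loci(calls, depths, FilterConfig()) == ["c"]


def test_haplotype_rule_one_individual_at_depth_19_drops_locus():
    calls, inds = _calls(14)
    depths = {"c": {ind: 20 for ind in inds}}
    depths["c"][inds[0]] = 19  # 13 qualify
    assert rf.filter_haplotyped_loci(calls, depths, FilterConfig()) == []


def test_haplotype_rule_ok_flag_required():
    calls, inds = _calls(13)  # 13 ok + 6 low_data, all deep
    depths = {"c": {ind: 100 for ind in inds}}
    assert rf.filter_haplotyped_loci(calls, depths, FilterConfig()) == []


# ---------------------------------------------------------------------------
# monotonicity under threshold tightening


def test_filters_monotone_under_tightening():
    rng = np.random.default_rng(7)
    records = []
    for i in range(60):
        n_typed = int(rng.integers(10, 20))
        records.append(typed_record(f"c{i:02d}", n_typed, 19))
    loose = FilterConfig(min_individual_fraction=0.6)
    tight = FilterConfig(min_individual_fraction=0.85)
    kept_loose = {r.contig for r in rf.filter_locus_missingness(records, loose)}
    kept_tight = {r.contig for r in rf.filter_locus_missingness(records, tight)}
    assert kept_tight <= kept_loose

    calls, inds = _calls(15)
    depths = {"c": {ind: int(d) for ind, d in zip(inds, rng.integers(5, 60, 19))}}
    for lo, hi in [(5, 20), (10, 40)]:
        k_lo = set(rf.filter_haplotyped_loci(calls, depths, FilterConfig(min_depth=lo)))
        k_hi = set(rf.filter_haplotyped_loci(calls, depths, FilterConfig(min_depth=hi)))
        assert k_hi <= k_lo


# ---------------------------------------------------------------------------
# VCF round trip and genotype matrix


def test_vcf_round_trip(tmp_path):
    records = [
        make_record(contig="a", pos=3, ref="A", alts=("G", "T"),
                    genotypes=["0/1", "1/2", MISSING_GT], depths=[30, 41, 0], n=3),
        make_record(contig="b", pos=1, ref="C", alts=("T",),
                    genotypes=["0/0", MISSING_GT, "1/1"], depths=[25, 0, 9], n=3),
    ]
    inds = ["s1", "s2", "s3"]
    path = tmp_path / "out.vcf"
    rf.write_vcf(records, inds, path)
    back, back_inds = rf.read_vcf(path)
    assert back_inds == inds
    assert [(r.contig, r.pos, r.ref, r.alts, r.genotypes) for r in back] == [
        (r.contig, r.pos, r.ref, r.alts, r.genotypes) for r in records
    ]
    # depth survives except where the genotype is missing (written as ".")
    assert list(back[0].depths) == [30, 41, 0]


def test_text_fallback_parser_agrees(tmp_path):
    records = [make_record(genotypes=["0/1", MISSING_GT], depths=[12, 0], n=2)]
    path = tmp_path / "t.vcf"
    rf.write_vcf(records, ["x", "y"], path)
    a = rf.read_vcf(path)
    b = rf._read_vcf_text(path)
    assert a[1] == b[1]
    assert [(r.pos, r.genotypes, list(r.depths)) for r in a[0]] == [
        (r.pos, r.genotypes, list(r.depths)) for r in b[0]
    ]


def test_export_genotype_matrix_shape(tmp_path):
    records = [make_record(contig="a", pos=1, n=3, genotypes=["0/0", "0/1", "1/1"])]
    gm = rf.export_genotype_matrix(records, ["i", "j", "k"], tmp_path / "m.vcf")
    assert gm.genotypes.shape == (1, 3)
    assert gm.genotypes.loc[("a", 1), "j"] == "0/1"
    assert (tmp_path / "m.vcf").exists()


def test_locus_record_validation():
    with pytest.raises(ValueError, match="1-based"):
        make_record(pos=0)
    with pytest.raises(ValueError, match="depths"):
        make_record(depths=[-1, 2, 3, 4])


def test_filter_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(min_individual_fraction=0.0)
    with pytest.raises(ValueError):
        FilterConfig(min_individuals_haplotyped=20, total_individuals=19)
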