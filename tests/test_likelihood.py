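"""Alignment likelihoods, plain and variant-aware."""

import math

import numpy as np
import pytest

from remapq.likelihood import (
    KnownVariant,
    KnownVariantIndex,
    af_penalty,
    log_likelihood,
    log_likelihood_variant_aware,
    q2p,
)
from remapq.model import AlignmentStatus, PenaltyConfig, expand_alignment

from conftest import random_alignment

S = AlignmentStatus


def naive_log_likelihood(cand, cfg):
    """Independent per-position summation oracle."""
    total = 0.0
    for status, q in zip(cand.statuses, cand.qualities):
        if status == S.MATCH:
            total += math.log10(1.0 - 10 ** (-q / 10.0))
        elif status == S.MISMATCH:
            total += -q / 10.0
        elif status == S.GAP_OPEN:
            total += -q / 10.0 - cfg.gamma_open
        elif status == S.GAP_EXT:
            total += -q / 10.0 - cfg.gamma_ext
        elif status == S.SOFT_CLIP:
            total += -q / 10.0 - cfg.gamma_soft
        elif status == S.HARD_CLIP:
            total += -q / 10.0 - cfg.gamma_hard
    return total


@pytest.mark.parametrize("q,p", [(0, 1.0), (10, 0.1), (30, 0.001)])
def test_q2p(q, p):
    assert q2p(q) == pytest.approx(p)


def test_q2p_rejects_negative():
    with pytest.raises(ValueError):
        q2p(-1)


@pytest.mark.parametrize("af,gamma", [(1.0, 0.0), (0.1, 1.0),
                                      (0.5, 0.3010299957)])
def test_af_penalty(af, gamma):
    assert af_penalty(af) == pytest.approx(gamma, abs=1e-9)


def test_af_penalty_rejects_nonpositive():
    with pytest.raises(ValueError):
        af_penalty(0.0)


def test_single_mismatch_q20(make_record, config):
    cand = expand_alignment(make_record("1M", "0A0", quals=[20]))
    assert log_likelihood(cand, config) == pytest.approx(-2.0)


def test_ten_matches_q20(make_record, config):
    cand = expand_alignment(make_record("10M", "10", quals=[20] * 10))
    assert log_likelihood(cand, config) == pytest.approx(
        10 * math.log10(0.99))


def test_gap_open_penalty(make_record, config):
    # 1M anchors the alignment; the inserted base carries the gap term
    cand = expand_alignment(make_record("1M1I", "1", quals=[40, 20]))
    anchor = math.log10(1 - 1e-4)
    assert log_likelihood(cand, config) == pytest.approx(
        anchor + (-2.0 - config.gamma_open))


def test_matches_naive_summation_on_random_candidates(header, config):
    rng = np.random.default_rng(7)
    for _ in range(200):
        rec, *_ = random_alignment(rng, header)
        cand = expand_alignment(rec)
        ll = log_likelihood(cand, config)
        oracle = naive_log_likelihood(cand, config)
        assert ll == pytest.approx(oracle, rel=1e-9, abs=1e-12)
        assert ll < 0.0


def test_converting_a_match_to_mismatch_decreases_by_closed_form(
        make_record, config):
    q = 20
    clean = expand_alignment(make_record("10M", "10", quals=[q] * 10))
    dirty = expand_alignment(make_record("10M", "4A5", quals=[q] * 10))
    delta = (log_likelihood(clean, config)
             - log_likelihood(dirty, config))
    # the mismatch loses its match factor and gains the error factor
    assert delta == pytest.approx(q / 10 - abs(math.log10(1 - q2p(q))))
    assert delta == pytest.approx(
        naive_log_likelihood(clean, config)
        - naive_log_likelihood(dirty, config))
    assert delta > 0


def _snv_index(chrom="chr1", pos=102, ref="A", alt="C", af=None):
    return KnownVariantIndex([
        KnownVariant(chrom, pos, "SNV", ref, alt, af)])


def test_known_snv_with_af_beats_plain_term(make_record, config):
    # mismatch at position 102 (start=100), read base C, Q=30, AF=0.5
    rec = make_record("5M", "2A2", seq="AACAA", quals=[30] * 5)
    cand = expand_alignment(rec)
    plain = log_likelihood(cand, config)
    aware = log_likelihood_variant_aware(
        cand, _snv_index(af=0.5), config)
    expected_contrib = math.log10(1 - 0.001) - af_penalty(0.5)
    assert aware - plain == pytest.approx(expected_contrib - (-3.0))
    assert expected_contrib == pytest.approx(-0.30146, abs=1e-4)


def test_snv_with_other_alt_leaves_likelihood_unchanged(make_record, config):
    rec = make_record("5M", "2A2", seq="AACAA", quals=[30] * 5)
    cand = expand_alignment(rec)
    plain = log_likelihood(cand, config)
    aware = log_likelihood_variant_aware(
        cand, _snv_index(alt="G"), config)
    assert aware == pytest.approx(plain)


def test_snv_with_disagreeing_ref_is_skipped(make_record, config, caplog):
    rec = make_record("5M", "2A2", seq="AACAA", quals=[30] * 5)
    cand = expand_alignment(rec)
    plain = log_likelihood(cand, config)
    with caplog.at_level("WARNING"):
        aware = log_likelihood_variant_aware(
            cand, _snv_index(ref="T", alt="C"), config)
    assert aware == pytest.approx(plain)
    assert "disagrees" in caplog.text


def test_strict_literal_mode_never_improves_point_variants(make_record,
                                                           config):
    rec = make_record("5M", "2A2", seq="AACAA", quals=[30] * 5)
    cand = expand_alignment(rec)
    plain = log_likelihood(cand, config)
    strict = log_likelihood_variant_aware(
        cand, _snv_index(af=0.5), config, strict_literal=True)
    assert strict == pytest.approx(plain)


def test_known_mnp_matched_as_whole_block(make_record, config):
    rec = make_record("6M", "2AA2", seq="AACCAA", quals=[30] * 6)
    cand = expand_alignment(rec)
    plain = log_likelihood(cand, config)
    idx = KnownVariantIndex([KnownVariant("chr1", 102, "MNP", "AA", "CC")])
    aware = log_likelihood_variant_aware(cand, idx, config)
    expected = 2 * math.log10(1 - 0.001) - config.gamma_mnp
    assert aware - plain == pytest.approx(expected - (-6.0))


def test_known_insertion_replaces_gap_penalties(make_record, config):
    # 2M 2I 2M; insertion GG before reference position 102
    rec = make_record("2M2I2M", "4", seq="AAGGAA", quals=[30] * 6)
    cand = expand_alignment(rec)
    plain = log_likelihood(cand, config)
    idx = KnownVariantIndex([KnownVariant("chr1", 102, "INDEL", "", "GG")])
    aware = log_likelihood_variant_aware(cand, idx, config)
    # gap penalties (gamma_open + gamma_ext) replaced by one gamma_indel
    assert aware - plain == pytest.approx(
        config.gamma_open + config.gamma_ext - config.gamma_indel)


def test_known_deletion_matched_by_position_and_sequence(make_record, config):
    rec = make_record("2M2D2M", "2^GT2", quals=[30] * 4)
    cand = expand_alignment(rec)
    plain = log_likelihood(cand, config)
    idx = KnownVariantIndex([KnownVariant("chr1", 102, "INDEL", "GT", "")])
    aware = log_likelihood_variant_aware(cand, idx, config)
    assert aware - plain == pytest.approx(
        config.gamma_open + config.gamma_ext - config.gamma_indel)
    # wrong deleted sequence: no change
    cand2 = expand_alignment(make_record("2M2D2M", "2^GT2", quals=[30] * 4))
    log_likelihood(cand2, config)
    idx2 = KnownVariantIndex([KnownVariant("chr1", 102, "INDEL", "CC", "")])
    assert log_likelihood_variant_aware(cand2, idx2, config) == \
        pytest.approx(plain)


def test_variant_aware_is_monotone_improvement(header, config):
    """Variant-aware >= plain on random candidates with random planted
    SNVs; equal when no variant overlaps."""
    rng = np.random.default_rng(11)
    for _ in range(150):
        rec, *_ = random_alignment(rng, header)
        cand = expand_alignment(rec)
        plain = log_likelihood(cand, config)
        variants = KnownVariantIndex()
        mm = np.flatnonzero(cand.statuses == S.MISMATCH)
        for i in mm[:: 2]:  # plant variants on half the mismatches
            variants.add(KnownVariant(
                "chr1", int(cand.ref_pos[i]), "SNV",
                str(cand.ref_bases[i]), str(cand.read_bases[i]),
                float(rng.uniform(0.05, 1.0))))
        aware = log_likelihood_variant_aware(cand, variants, config)
        assert aware >= plain - 1e-12
        empty = log_likelihood_variant_aware(
            cand, KnownVariantIndex(), config)
        assert empty == pytest.approx(plain)


def test_vcf_loading_with_af_and_multiallelic(tmp_path):
    vcf = tmp_path / "known.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=AF,Number=A,Type=Float,Description="AF">\n'
        "##contig=<ID=chr1,length=1000000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t101\t.\tA\tC,G\t.\t.\tAF=0.25,0.5\n"
        "chr1\t201\t.\tAT\tA\t.\t.\t.\n"
        "chr1\t301\t.\tA\tAGG\t.\t.\tAF=0.1\n"
        "chr1\t401\t.\tAC\tGT\t.\t.\t.\n")
    idx = KnownVariantIndex.from_vcf(str(vcf))
    assert len(idx) == 5
    snvs = idx.lookup("chr1", 100)
    assert {v.alt_allele for v in snvs} == {"C", "G"}
    assert {v.alt_af for v in snvs} == {0.25, 0.5}
    (deletion,) = idx.lookup("chr1", 201)
    assert deletion.kind == "INDEL" and deletion.ref_allele == "T"
    (ins,) = idx.lookup("chr1", 301)
    assert ins.alt_allele == "GG" and ins.alt_af == pytest.approx(0.1)
    (mnp,) = idx.lookup("chr1", 400)
    assert mnp.kind == "MNP"
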