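"""Posterior normalisation, mapQ scaling and the paired-end model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from remapq.model import PenaltyConfig, ReadGroup, expand_alignment
from remapq.posterior import (
    CandidatePair,
    FragmentModel,
    PairGroup,
    estimate_fragment_model,
    make_soft_clipped_mate,
    mapq,
    mate_distance,
    orphan_to_pair,
    pairing_density,
    pe_posteriors,
    se_posteriors,
    select_best,
)


def make_candidate(make_record, start=100, log_lik=-1.0, length=10,
                   name="read1", chrom="chr1"):
    cand = expand_alignment(make_record(
        f"{length}M", str(length), start=start, name=name, chrom=chrom))
    cand.log_lik = log_lik
    return cand


class TestSePosteriors:
    def test_single_candidate_gets_posterior_one_and_capped_mapq(
            self, make_record, config):
        c = make_candidate(make_record)
        se_posteriors(ReadGroup("read1", [c]), config)
        assert c.posterior == pytest.approx(1.0)
        assert c.mapq == config.mapq_cap

    def test_two_equal_candidates_split_evenly(self, make_record, config):
        a = make_candidate(make_record, start=100)
        b = make_candidate(make_record, start=500)
        se_posteriors(ReadGroup("read1", [a, b]), config)
        assert a.posterior == pytest.approx(0.5)
        assert b.posterior == pytest.approx(0.5)
        assert a.mapq == b.mapq == 3

    def test_unit_log_lik_gap_gives_ten_elevenths(self, make_record, config):
        a = make_candidate(make_record, start=100, log_lik=-1.0)
        b = make_candidate(make_record, start=500, log_lik=-2.0)
        se_posteriors(ReadGroup("read1", [a, b]), config)
        assert a.posterior == pytest.approx(10 / 11)
        assert b.posterior == pytest.approx(1 / 11)

    def test_prior_weight_is_alignment_length(self, make_record, config):
        a = make_candidate(make_record, start=100, length=20)
        b = make_candidate(make_record, start=500, length=10)
        a.log_lik = b.log_lik = -1.0
        se_posteriors(ReadGroup("read1", [a, b]), config)
        assert a.posterior == pytest.approx(2 / 3)

    def test_log_space_matches_naive_linear(self, make_record, config):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(1, 10))
            cands = [make_candidate(make_record, start=100 + 10 * i,
                                    log_lik=float(-rng.uniform(0, 50)))
                     for i in range(n)]
            se_posteriors(ReadGroup("read1", list(cands)), config)
            lin = np.array([c.align_length * 10.0 ** c.log_lik
                            for c in cands])
            lin /= lin.sum()
            for c, p in zip(cands, lin):
                assert c.posterior == pytest.approx(p, rel=1e-9)

    @given(lls=st.lists(st.floats(-200, -0.01), min_size=1, max_size=8),
           perm_seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_sum_to_one_and_permutation_invariant(self, lls, perm_seed,
                                                  shared_record_factory):
        config = PenaltyConfig()
        cands = [make_candidate(shared_record_factory, start=100 + 10 * i,
                                log_lik=ll) for i, ll in enumerate(lls)]
        se_posteriors(ReadGroup("read1", list(cands)), config)
        assert sum(c.posterior for c in cands) == pytest.approx(1.0,
                                                                abs=1e-9)
        first = {id(c): c.posterior for c in cands}
        rng = np.random.default_rng(perm_seed)
        shuffled = list(cands)
        rng.shuffle(shuffled)
        se_posteriors(ReadGroup("read1", shuffled), config)
        for c in cands:
            assert c.posterior == pytest.approx(first[id(c)], rel=1e-12)


@pytest.fixture(scope="module")
def shared_record_factory(request):
    import pysam
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "queryname"},
        "SQ": [{"SN": "chr1", "LN": 1_000_000}]})

    def build(cigar, md, start=100, name="read1", chrom="chr1"):
        import re
        rec = pysam.AlignedSegment(header)
        rec.query_name = name
        rl = sum(int(n) for n, op in re.findall(r"(\d+)([MIS=X])", cigar))
        rec.query_sequence = "A" * rl
        rec.query_qualities = [20] * rl
        rec.reference_id = 0
        rec.reference_start = start
        rec.cigarstring = cigar
        rec.set_tag("MD", md)
        return rec

    return build


class TestMapq:
    @pytest.mark.parametrize("p,q", [(0.0, 0), (0.9, 10), (0.5, 3),
                                     (0.99, 20)])
    def test_closed_forms(self, p, q, config):
        assert mapq(p, config) == q

    def test_cap_on_underflow(self, config):
        assert mapq(1.0, config) == config.mapq_cap
        assert mapq(1.0 - 1e-300, config) == config.mapq_cap

    def test_monotone_in_posterior(self, config):
        ps = np.linspace(0, 1, 101)
        qs = [mapq(p, config) for p in ps]
        assert all(b >= a for a, b in zip(qs, qs[1:]))


class TestFragmentModel:
    def test_recovers_gaussian_parameters(self):
        rng = np.random.default_rng(17)
        d = rng.normal(300, 30, 10_000)
        m = estimate_fragment_model(d, min_n=1000)
        assert m.reliable
        assert m.mean == pytest.approx(300, abs=3 * 30 / math.sqrt(10_000))
        assert m.sd == pytest.approx(30, abs=1.0)

    def test_too_few_pairs_is_unreliable(self):
        m = estimate_fragment_model([300.0] * 10 + [310.0] * 10, min_n=1000)
        assert not m.reliable

    def test_degenerate_spread_is_unreliable(self):
        m = estimate_fragment_model([250.0] * 2000, min_n=1000)
        assert m.sd == 0.0 and not m.reliable


class TestPairingDensity:
    def test_gaussian_mode(self):
        m = FragmentModel(mean=300, sd=50, reliable=True)
        assert pairing_density(300, m) == pytest.approx(
            1 / (50 * math.sqrt(2 * math.pi)))
        assert pairing_density(350, m) == pytest.approx(
            pairing_density(300, m) * math.exp(-0.5))
        assert pairing_density(250, m) == pytest.approx(
            pairing_density(350, m))

    def test_unreliable_model_is_constant(self):
        m = FragmentModel(reliable=False, constant_density=1.0)
        assert pairing_density(0, m) == pairing_density(10_000, m) == 1.0


def _pair(make_record, start_f, start_r, name="frag1", log_lik=-2.0):
    fwd = make_candidate(make_record, start=start_f, name=name,
                         log_lik=log_lik)
    rev = make_candidate(make_record, start=start_r, name=name,
                         log_lik=log_lik)
    rev.strand = "-"
    return CandidatePair(fwd=fwd, rev=rev,
                         mate_distance=mate_distance(fwd, rev))


class TestPePosteriors:
    def test_single_pair_posterior_one(self, make_record, config):
        g = PairGroup("frag1", [_pair(make_record, 100, 390)])
        pe_posteriors(g, FragmentModel(mean=300, sd=50, reliable=True),
                      config)
        assert g.pairs[0].posterior == pytest.approx(1.0)

    def test_gaussian_distance_ratio(self, make_record, config):
        model = FragmentModel(mean=300, sd=50, reliable=True)
        at_mu = _pair(make_record, 100, 100 + 300 - 10)      # d = mu
        at_mu2s = _pair(make_record, 1000, 1000 + 400 - 10)  # d = mu + 2sd
        g = PairGroup("frag1", [at_mu, at_mu2s])
        pe_posteriors(g, model, config)
        ratio = at_mu.posterior / at_mu2s.posterior
        assert ratio == pytest.approx(math.exp(2.0), rel=1e-9)
        assert at_mu.posterior == pytest.approx(0.8808, abs=1e-4)

    def test_constant_density_reduces_to_se_product_form(self, make_record,
                                                         config):
        """With a constant pairing density the pair posterior equals the SE
        posterior over pseudo-candidates carrying L_fwd*L_rev and
        ll_fwd+ll_rev."""
        model = FragmentModel(reliable=False)
        rng = np.random.default_rng(5)
        pairs = []
        for i in range(4):
            p = _pair(make_record, 100 + 1000 * i, 400 + 1000 * i,
                      log_lik=float(-rng.uniform(1, 20)))
            p.rev.log_lik = float(-rng.uniform(1, 20))
            pairs.append(p)
        g = PairGroup("frag1", pairs)
        pe_posteriors(g, model, config)
        pseudo = [make_candidate(make_record, start=100 + 10 * i)
                  for i in range(4)]
        for ps, p in zip(pseudo, pairs):
            ps.align_length = p.fwd.align_length * p.rev.align_length
            ps.log_lik = p.fwd.log_lik + p.rev.log_lik
        se_posteriors(ReadGroup("read1", pseudo), config)
        for ps, p in zip(pseudo, pairs):
            assert p.posterior == pytest.approx(ps.posterior, rel=1e-9)

    def test_pair_posteriors_sum_to_one(self, make_record, config):
        model = FragmentModel(mean=300, sd=30, reliable=True)
        pairs = [_pair(make_record, 100 * i, 100 * i + 280 + 7 * i)
                 for i in range(1, 6)]
        g = PairGroup("frag1", pairs)
        pe_posteriors(g, model, config)
        assert sum(p.posterior for p in pairs) == pytest.approx(1.0,
                                                                abs=1e-9)


class TestOrphans:
    def test_soft_clipped_pseudo_mate_log_lik(self, make_record, config):
        mapped = make_candidate(make_record, length=10)
        pair = orphan_to_pair(mapped, config, mate_qualities=[20] * 10)
        pseudo = pair.rev if pair.fwd is mapped else pair.fwd
        # every base soft-clipped: 10 * (-20/10 - gamma_soft)
        assert pseudo.log_lik == pytest.approx(10 * (-2.0 - 1.0))

    def test_template_fallback_uses_mapped_mate_profile(self, make_record,
                                                        config):
        mapped = make_candidate(make_record, length=10)
        pair = orphan_to_pair(mapped, config)
        pseudo = pair.rev if pair.fwd is mapped else pair.fwd
        assert len(pseudo.qualities) == mapped.align_length
        assert pseudo.qualities[0] == pytest.approx(20.0)

    def test_concordant_pair_outscores_orphaned_same_fwd(self, make_record,
                                                         config):
        """A true concordant pair beats the identical forward candidate
        paired with a soft-clipped pseudo-mate in one posterior pool."""
        model = FragmentModel(mean=300, sd=30, reliable=True)
        conc = _pair(make_record, 100, 390, log_lik=-0.5)
        conc.rev.log_lik = -0.5
        orphan = orphan_to_pair(
            make_candidate(make_record, start=100, log_lik=-0.5), config,
            mate_qualities=[20] * 10)
        g = PairGroup("frag1", [conc, orphan])
        pe_posteriors(g, model, config)
        assert conc.posterior > orphan.posterior


class TestSelectBest:
    def test_order_and_primary_mapq(self, make_record, config):
        cands = [make_candidate(make_record, start=s, log_lik=ll)
                 for s, ll in [(100, -1.0), (500, -2.0), (900, -3.0)]]
        g = ReadGroup("read1", list(cands))
        se_posteriors(g, config)
        ordered = select_best(g, config)
        assert [c.start for c in ordered] == [100, 500, 900]
        assert ordered[0].is_primary and not ordered[1].is_primary
        # closed form: posteriors ~ [0.9009, 0.0901, 0.0090]
        assert ordered[0].mapq == mapq(ordered[0].posterior, config)

    def test_exact_tie_broken_by_smaller_locus(self, make_record, config):
        a = make_candidate(make_record, start=500)
        b = make_candidate(make_record, start=100)
        g = ReadGroup("read1", [a, b])
        se_posteriors(g, config)
        ordered = select_best(g, config)
        assert ordered[0] is b and ordered[0].start == 100
        assert ordered[0].mapq == ordered[1].mapq == 3

    def test_permuting_candidates_never_changes_primary(self, make_record,
                                                        config):
        rng = np.random.default_rng(9)
        cands = [make_candidate(make_record, start=100 * i,
                                log_lik=float(-rng.uniform(0, 5)))
                 for i in range(1, 7)]
        g = ReadGroup("read1", list(cands))
        se_posteriors(g, config)
        primary = select_best(g, config)[0]
        for _ in range(10):
            shuffled = list(cands)
            rng.shuffle(shuffled)
            g2 = ReadGroup("read1", shuffled)
            se_posteriors(g2, config)
            assert select_best(g2, config)[0] is primary
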