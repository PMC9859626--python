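"""Fisher's exact test implementation and the paired somatic cascade."""

from fractions import Fraction
from math import factorial

import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from varlod.datamodel import CallerConfig, ContingencyTable, Observation, SiteEvidence
from varlod.paired_engine import (
    classify_paired,
    fisher_one_sided_p,
    fisher_point_probability,
)


def point_prob_exact(n1, n0, c1, c0) -> Fraction:
    """Arbitrary-precision factorial evaluation of the point probability."""
    num = (
        factorial(n1 + n0) * factorial(c1 + c0) * factorial(c1 + n1) * factorial(c0 + n0)
    )
    den = (
        factorial(n1) * factorial(n0) * factorial(c1) * factorial(c0)
        * factorial(n1 + n0 + c1 + c0)
    )
    return Fraction(num, den)


def one_sided_exact(n1, n0, c1, c0) -> Fraction:
    """Full enumeration of the lower tail at fixed margins."""
    row_n, col_v, col_r = n1 + n0, n1 + c1, n0 + c0
    total = Fraction(0)
    for k in range(0, n1 + 1):
        nn0 = row_n - k
        cc1 = col_v - k
        cc0 = col_r - nn0
        if min(nn0, cc1, cc0) < 0:
            continue
        total += point_prob_exact(k, nn0, cc1, cc0)
    return total


class TestPointProbability:
    def test_degenerate_margin_is_one(self):
        assert fisher_point_probability(ContingencyTable(0, 10, 0, 10)) == pytest.approx(1.0)

    def test_row_swap_symmetry(self):
        a = fisher_point_probability(ContingencyTable(3, 17, 9, 41))
        b = fisher_point_probability(ContingencyTable(9, 41, 3, 17))
        assert a == pytest.approx(b)

    def test_against_factorial_oracle(self):
        t = ContingencyTable(0, 20, 8, 12)
        want = float(point_prob_exact(0, 20, 8, 12))
        assert fisher_point_probability(t) == pytest.approx(want, rel=1e-12)

    @settings(max_examples=150, deadline=None)
    @given(
        n1=st.integers(0, 50), n0=st.integers(0, 50),
        c1=st.integers(0, 50), c0=st.integers(0, 50),
    )
    def test_loggamma_matches_exact_to_1e10(self, n1, n0, c1, c0):
        # tables up to N = 200
        got = fisher_point_probability(ContingencyTable(n1, n0, c1, c0))
        want = point_prob_exact(n1, n0, c1, c0)
        assert got == pytest.approx(float(want), rel=1e-10)


class TestOneSidedP:
    def test_maximal_n1_gives_one(self):
        # n1 at its maximum feasible value: the tail is everything
        t = ContingencyTable(5, 0, 0, 10)
        assert fisher_one_sided_p(t) == pytest.approx(1.0)

    def test_point_never_exceeds_tail(self):
        for t in [ContingencyTable(1, 99, 20, 80), ContingencyTable(4, 6, 2, 8)]:
            assert fisher_point_probability(t) <= fisher_one_sided_p(t) + 1e-12

    def test_against_enumeration_oracle(self):
        t = ContingencyTable(1, 99, 20, 80)
        want = float(one_sided_exact(1, 99, 20, 80))
        assert fisher_one_sided_p(t) == pytest.approx(want, rel=1e-9)

    @settings(max_examples=120, deadline=None)
    @given(
        n1=st.integers(0, 15), n0=st.integers(0, 15),
        c1=st.integers(0, 15), c0=st.integers(0, 15),
    )
    def test_matches_enumeration_and_scipy(self, n1, n0, c1, c0):
        got = fisher_one_sided_p(ContingencyTable(n1, n0, c1, c0))
        want = float(one_sided_exact(n1, n0, c1, c0))
        assert got == pytest.approx(want, rel=1e-9)
        # independent cross-check: hypergeometric lower tail on n1
        _, scipy_p = stats.fisher_exact([[n1, n0], [c1, c0]], alternative="less")
        assert got == pytest.approx(scipy_p, rel=1e-7)

    @settings(max_examples=80, deadline=None)
    @given(
        n1=st.integers(1, 12), n0=st.integers(0, 12),
        c1=st.integers(0, 12), c0=st.integers(1, 12),
    )
    def test_tumor_enrichment_never_raises_p(self, n1, n0, c1, c0):
        # moving one variant read from normal to tumor (fixed totals of
        # variant and reference reads) cannot make the tumor look less
        # enriched
        before = fisher_one_sided_p(ContingencyTable(n1, n0, c1, c0))
        after = fisher_one_sided_p(ContingencyTable(n1 - 1, n0 + 1, c1 + 1, c0 - 1))
        assert after <= before + 1e-12

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


def _normal_site(n_ref, n_alt, ref="C", alt="T", q=30):
    obs = [Observation(f"n{i}", ref, q, "+", 5, i) for i in range(n_ref)]
    obs += [Observation(f"m{i}", alt, q, "+", 5, n_ref + i) for i in range(n_alt)]
    return SiteEvidence("chr1", 100, obs)


class TestClassifyPaired:
    def test_absent_in_normal_emits_directly(self, config):
        d = classify_paired(10.0, 20, 200, 0, 200, (0, 0), config)
        assert d.emit and d.path_taken == "absent_in_normal"

    def test_half_tumor_frequency_in_normal_rejected(self, config):
        # normal VAF 5% vs tumor 10%: fails both the absolute and the
        # relative (.2 x tumor) bound
        d = classify_paired(10.0, 20, 200, 10, 200, (5, 5), config)
        assert not d.emit and d.path_taken == "nf_gate_fail"

    def test_single_strand_normal_support_emits(self, config):
        d = classify_paired(10.0, 20, 200, 3, 200, (3, 0), config)
        assert d.emit and d.path_taken == "same_direction_normal"

    def test_zero_normal_coverage_rejects(self, config):
        d = classify_paired(10.0, 20, 200, 0, 0, (0, 0), config)
        assert not d.emit and d.path_taken == "no_normal_coverage"

    def test_weak_normal_lod_emits(self, config):
        # 1% in normal vs 10% tumor: below the .5 gate, and 2 reads of 200
        # at q30 give a normal LOD under threshold
        site = _normal_site(198, 2)
        d = classify_paired(10.0, 20, 200, 2, 200, (1, 1), config,
                            normal_site=site, ref="C", alt="T")
        assert d.lod_normal is not None and d.lod_normal < config.lod_threshold
        assert d.emit and d.path_taken == "lod_gate_pass"

    def test_strong_normal_lod_falls_through_to_fet(self):
        # force the relative gate open (nf high) with a convincing normal
        # signal: FET decides, and here it must reject
        config = CallerConfig(nf=0.2)
        site = _normal_site(164, 36)
        d = classify_paired(100.0, 200, 200, 36, 200, (18, 18), config,
                            normal_site=site, ref="C", alt="T")
        assert d.lod_normal is not None and d.lod_normal >= config.lod_threshold
        assert d.path_taken in ("fet_pass", "fet_fail")
        assert d.fet_p is not None

    def test_indel_path_skips_lod_gate(self, config):
        # no base-level normal evidence supplied: cascade goes straight to
        # FET after the frequency gates
        d = classify_paired(20.0, 40, 200, 1, 200, (1, 1), config, normal_site=None)
        assert d.lod_normal is None
        assert d.fet_p is not None and d.emit

    @pytest.mark.parametrize("normal_support", range(3, 30, 3))
    def test_never_emits_double_stranded_high_normal(self, config, normal_support):
        # invariant: normal VAF above both bounds with two-strand support
        # is never emitted
        tumor_vaf = 10.0
        nd = 100
        nvaf = 100.0 * normal_support / nd
        assert nvaf >= max(100 * config.nf, config.normal_ratio * tumor_vaf)
        d = classify_paired(tumor_vaf, 20, 200, normal_support, nd,
                            (normal_support // 2, normal_support - normal_support // 2),
                            config)
        assert not d.emit
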