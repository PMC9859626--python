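"""Duplicate collapsing, VAF arithmetic, the filter ledger, origin labels."""

import pytest
from hypothesis import given, settings, strategies as st

from varlod.datamodel import CallerConfig, VariantCandidate
from varlod.quantify_filter import (
    apply_variant_filters,
    classify_origin,
    compute_vaf,
    group_duplicates,
    load_hotspot_sites,
    load_population_sites,
    site_base_quality,
    supporting_group_count,
)

from conftest import make_read


class TestGroupDuplicates:
    def test_identical_signatures_collapse(self):
        reads = [make_read(start=100, seq="ACGT", read_id=f"r{i}") for i in range(4)]
        groups = group_duplicates(reads)
        assert len(groups) == 1 and groups[0].size() == 4

    def test_two_signatures_two_groups(self):
        reads = [make_read(start=100, seq="ACGT", read_id=f"r{i}") for i in range(2)]
        reads += [make_read(start=101, seq="ACGT", read_id=f"s{i}") for i in range(2)]
        assert len(group_duplicates(reads)) == 2

    def test_strand_separates_groups(self):
        a = make_read(start=100, seq="ACGT", read_id="a", strand="+")
        b = make_read(start=100, seq="ACGT", read_id="b", strand="-")
        assert len(group_duplicates([a, b])) == 2

    def test_mate_start_in_signature(self):
        a = make_read(start=100, seq="ACGT", read_id="a", mate_start=300)
        b = make_read(start=100, seq="ACGT", read_id="b", mate_start=350)
        assert len(group_duplicates([a, b])) == 2


class TestSupportingGroups:
    def _groups(self, n_members=5):
        reads = [make_read(start=100, seq="ACGT", read_id=f"r{i}") for i in range(n_members)]
        return group_duplicates(reads)

    def test_fully_mutated_group_counts_once(self):
        groups = self._groups(5)
        assert supporting_group_count(groups, {f"r{i}" for i in range(5)}) == 1

    def test_exactly_point_eight_not_supporting(self):
        # 4 of 5 mutated is exactly .8: the strict inequality excludes it
        groups = self._groups(5)
        assert supporting_group_count(groups, {"r0", "r1", "r2", "r3"}) == 0

    def test_singleton_mutated_supports(self):
        groups = self._groups(1)
        assert supporting_group_count(groups, {"r0"}) == 1

    def test_boundary_recovered_by_sweep(self):
        # the support threshold sits between 4/5 and 5/5
        groups = self._groups(5)
        flips = [
            supporting_group_count(groups, {f"r{i}" for i in range(k)}) for k in range(6)
        ]
        assert flips == [0, 0, 0, 0, 0, 1]


class TestComputeVaf:
    def test_simple_fraction(self):
        assert compute_vaf(5, 10) == pytest.approx(50.0)

    def test_spanning_only_denominator(self):
        # 12 overlapping reads of which 10 span all indel sites, 2 support
        assert compute_vaf(2, 10) == pytest.approx(20.0)

    def test_zero_depth_errors(self):
        with pytest.raises(ValueError):
            compute_vaf(0, 0)

    @settings(max_examples=40, deadline=None)
    @given(k=st.integers(1, 6), n_unique=st.integers(2, 12), n_mut=st.integers(0, 12))
    def test_duplication_invariance(self, k, n_unique, n_mut):
        # copying every read k times must not move the VAF: collapsing
        # undoes amplification exactly
        n_mut = min(n_mut, n_unique)
        base, dup = [], []
        for i in range(n_unique):
            for c in range(1):
                base.append(make_read(start=100 + i, seq="ACGT", read_id=f"u{i}"))
            for c in range(k):
                dup.append(make_read(start=100 + i, seq="ACGT", read_id=f"u{i}c{c}"))
        carriers_base = {f"u{i}" for i in range(n_mut)}
        carriers_dup = {f"u{i}c{c}" for i in range(n_mut) for c in range(k)}
        vaf_base = compute_vaf(
            supporting_group_count(group_duplicates(base), carriers_base),
            len(group_duplicates(base)),
        )
        vaf_dup = compute_vaf(
            supporting_group_count(group_duplicates(dup), carriers_dup),
            len(group_duplicates(dup)),
        )
        assert vaf_base == pytest.approx(vaf_dup)


class TestSiteQuality:
    def test_maximum_rule(self):
        assert site_base_quality([20, 30, 25]) == 30
        assert site_base_quality([15]) == 15
        assert site_base_quality([30, 30]) == 30

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            site_base_quality([])


class TestFilterLedger:
    def _cand(self, **kw):
        base = dict(
            contig="chr1", pos=100, ref="C", alt="T", vtype="SNV",
            tumor_depth=8, tumor_support=2, vaf_tumor=25.0,
            site_base_quality=30, strand_support=(1, 1),
        )
        base.update(kw)
        return VariantCandidate(**base)

    def test_all_defaults_satisfied_pass(self, config):
        assert apply_variant_filters(self._cand(), config).is_pass

    def test_each_floor_labels(self, config):
        assert "low_support" in apply_variant_filters(
            self._cand(tumor_support=1), config).filters
        assert "low_depth" in apply_variant_filters(
            self._cand(tumor_depth=7), config).filters
        assert "low_site_quality" in apply_variant_filters(
            self._cand(site_base_quality=10), config).filters

    def test_vaf_floor_configurable(self):
        config = CallerConfig(min_vaf=1.0)
        assert "low_vaf" in apply_variant_filters(
            self._cand(vaf_tumor=0.5), config).filters

    def test_strand_filter_off_by_default(self, config):
        assert apply_variant_filters(self._cand(strand_support=(2, 0)), config).is_pass
        strict = CallerConfig(strand_filter=True)
        assert not apply_variant_filters(self._cand(strand_support=(2, 0)), strict).is_pass

    def test_labels_are_a_set(self, config):
        c = self._cand(tumor_support=0, tumor_depth=0)
        once = apply_variant_filters(c, config).filters
        twice = apply_variant_filters(c, config).filters
        assert once == twice


class TestClassifyOrigin:
    def _cand(self):
        return VariantCandidate("chr1", 99, "C", "T", "SNV")

    def test_population_af_above_threshold_is_germline(self, config):
        pop = {("chr1", 100, "C", "T"): 0.02}
        assert classify_origin(self._cand(), pop, set(), config) == "germline"

    def test_hotspot_is_somatic(self, config):
        hot = {("chr1", 100, "C", "T")}
        assert classify_origin(self._cand(), {}, hot, config) == "somatic"

    def test_both_sources_is_both(self, config):
        pop = {("chr1", 100, "C", "T"): 0.05}
        hot = {("chr1", 100, "C", "T")}
        assert classify_origin(self._cand(), pop, hot, config) == "both"

    def test_af_below_threshold_is_unknown(self, config):
        pop = {("chr1", 100, "C", "T"): 0.001}
        assert classify_origin(self._cand(), pop, set(), config) == "unknown"

    def test_tsv_loaders(self, tmp_path, config):
        pop_path = tmp_path / "pop.tsv"
        pop_path.write_text("chr1\t100\tC\tT\t0.02\nbadline\n")
        hot_path = tmp_path / "hot.tsv"
        hot_path.write_text("chr1\t100\tC\tT\n")
        pop = load_population_sites(str(pop_path))
        hot = load_hotspot_sites(str(hot_path))
        assert classify_origin(self._cand(), pop, hot, config) == "both"
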