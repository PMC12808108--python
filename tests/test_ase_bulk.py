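"""Variant filtering, pooling, the folded Xi estimate and the classifier."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xreact import ase_bulk
from tests.conftest import make_summaries


def _site(vid, gene="G1", ref="A", alt="G", qual=500.0, pos=100):
    return {
        "variant_id": vid, "gene": gene, "chrom": "chrX", "pos": pos,
        "ref_allele": ref, "alt_allele": alt,
        "kind": ase_bulk.variant_kind(ref, alt), "qual": qual,
    }


def _counts(vid, reads, samples=None):
    samples = samples or [f"s{i}" for i in range(len(reads))]
    return [
        {"variant_id": vid, "sample_id": s, "cell_type": "iPSC", "ref_reads": r // 2, "total_reads": r}
        for s, r in zip(samples, reads)
    ]


class TestFilterVariants:
    def test_each_rule_removes_and_tallies(self):
        sites = pd.DataFrame([
            _site("keep1"),
            _site("keep2"),
            _site("qual99", qual=99.0),            # quality boundary: <100 removed
            _site("longdel", ref="A" + "T" * 60, alt="A"),  # 60 bp deletion
            _site("nogene", gene=""),
            _site("lowcov"),
            _site("keep3"),
        ])
        counts = pd.DataFrame(
            sum((_counts(v, [30, 30, 30]) for v in sites["variant_id"]), start=[])
        )
        counts.loc[(counts["variant_id"] == "lowcov") & (counts["sample_id"] == "s1"), "total_reads"] = 4
        kept, tally = ase_bulk.filter_variants(sites, counts)
        assert set(kept["variant_id"]) == {"keep1", "keep2", "keep3"}
        assert tally == {"not_genic": 1, "not_biallelic": 0, "quality": 1,
                         "long_indel": 1, "low_coverage": 1}

    def test_short_indel_and_exact_qual_kept(self):
        sites = pd.DataFrame([_site("ok", ref="A", alt="ATTT", qual=100.0)])
        counts = pd.DataFrame(_counts("ok", [10, 10]))
        kept, _ = ase_bulk.filter_variants(sites, counts)
        assert list(kept["variant_id"]) == ["ok"]

    def test_unknown_variant_is_hard_error(self):
        sites = pd.DataFrame([_site("v1")])
        counts = pd.DataFrame(_counts("ghost", [10]))
        with pytest.raises(ValueError, match="ghost"):
            ase_bulk.filter_variants(sites, counts)


class TestPooling:
    def test_pooled_sums_and_folded_estimate(self):
        counts = pd.DataFrame([
            {"variant_id": "v", "sample_id": "a", "cell_type": "iPSC", "ref_reads": 10, "total_reads": 20},
            {"variant_id": "v", "sample_id": "b", "cell_type": "iPSC", "ref_reads": 15, "total_reads": 30},
        ])
        s = ase_bulk.pool_by_cell_type(counts).iloc[0]
        assert (s["no_ref"], s["no_total"]) == (25, 50)
        assert s["allelic_ratio"] == 0.5
        assert s["xi_prob_hat"] == 0.5

    @pytest.mark.parametrize("ref,total,expected", [(2, 100, 0.02), (98, 100, 0.02)])
    def test_both_branches_of_the_folded_ratio(self, ref, total, expected):
        counts = pd.DataFrame(
            [{"variant_id": "v", "sample_id": "a", "cell_type": "NPC",
              "ref_reads": ref, "total_reads": total}]
        )
        s = ase_bulk.pool_by_cell_type(counts).iloc[0]
        assert s["xi_prob_hat"] == pytest.approx(expected)

    def test_low_group_coverage_untestable(self):
        counts = pd.DataFrame(
            [{"variant_id": "v", "sample_id": "a", "cell_type": "NPC",
              "ref_reads": 5, "total_reads": 19}]
        )
        assert not ase_bulk.pool_by_cell_type(counts)["testable"].iloc[0]

    @given(ref=st.integers(0, 1000), alt=st.integers(0, 1000))
    def test_folded_estimate_symmetric_under_allele_swap(self, ref, alt):
        total = ref + alt
        if total == 0:
            return
        a = min(ref / total, 1 - ref / total)
        b = min(alt / total, 1 - alt / total)
        assert a == pytest.approx(b, abs=1e-15)


class TestBinomialTest:
    def test_zero_count_gives_one(self):
        assert ase_bulk.test_xi_expression(0, 50, 0.025) == 1.0

    def test_full_count_single_outcome_tail(self):
        assert ase_bulk.test_xi_expression(20, 20, 0.025) == pytest.approx(0.025**20, rel=1e-12)

    def test_matches_bruteforce_pmf_summation(self):
        # independent oracle: exact-integer binomial coefficients
        p0 = 0.025
        expected = sum(
            math.comb(100, k) * p0**k * (1 - p0) ** (100 - k) for k in range(5, 101)
        )
        assert ase_bulk.test_xi_expression(5, 100, p0) == pytest.approx(expected, rel=1e-12)

    def test_monotone_nonincreasing_in_count(self):
        p = ase_bulk.test_xi_expression(np.arange(0, 201), 200, 0.1)
        assert np.all(np.diff(p) <= 1e-15)

    def test_zero_total_is_untestable(self):
        assert np.isnan(ase_bulk.test_xi_expression(0, 0, 0.025))


class TestBH:
    def test_adjusted_at_least_raw_and_monotone(self):
        raw = np.array([0.001, 0.04, 0.02, 0.5, 0.0001])
        adj = ase_bulk._bh(raw)
        assert np.all(adj >= raw - 1e-15)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-15)


def _three_ct_summary(vid, per_ct):
    return [(vid, ct, ref, total) for ct, (ref, total) in per_ct.items()]


class TestClassifier:
    def test_extreme_reactivated(self):
        rows = _three_ct_summary("v1", {"iPSC": (198, 200), "NPC": (160, 200), "neuron": (200, 200)})
        calls = ase_bulk.classify_variants(make_summaries(rows))
        assert calls["category"].iloc[0] == "reactivated"

    def test_balanced_everywhere_is_escape(self):
        rows = _three_ct_summary("v1", {"iPSC": (90, 200), "NPC": (90, 200), "neuron": (90, 200)})
        calls = ase_bulk.classify_variants(make_summaries(rows))
        assert calls["category"].iloc[0] == "escape"

    def test_late_silenced(self):
        rows = _three_ct_summary("v1", {"iPSC": (140, 200), "NPC": (199, 200), "neuron": (1, 200)})
        calls = ase_bulk.classify_variants(make_summaries(rows))
        assert calls["category"].iloc[0] == "late_silenced"

    def test_monoallelic_everywhere_is_inactive(self):
        rows = _three_ct_summary("v1", {"iPSC": (200, 200), "NPC": (199, 200), "neuron": (200, 200)})
        calls = ase_bulk.classify_variants(make_summaries(rows))
        assert calls["category"].iloc[0] == "inactive"

    def test_missing_cell_type_untestable(self):
        rows = _three_ct_summary("v1", {"iPSC": (100, 200), "NPC": (100, 200), "neuron": (3, 10)})
        calls = ase_bulk.classify_variants(make_summaries(rows))
        assert calls["category"].iloc[0] == "untestable"

    def test_conflicting_duplicates_raise(self):
        rows = _three_ct_summary("v1", {"iPSC": (100, 200), "NPC": (100, 200), "neuron": (90, 200)})
        dup = make_summaries(rows + [("v1", "iPSC", 50, 200)])
        with pytest.raises(ValueError, match="conflicting"):
            ase_bulk.classify_variants(dup)

    def test_deterministic(self, bulk_fixture):
        counts, sites, _ = bulk_fixture
        a = ase_bulk.classify_bulk(sites, counts)
        b = ase_bulk.classify_bulk(sites, counts)
        pd.testing.assert_frame_equal(a, b)


class TestCurationFlag:
    def _calls_and_counts(self, minor_by_rep):
        # escape-like variant driven by NPC; minor allele = alt
        total = 50
        counts = []
        for ct in ("iPSC", "NPC", "neuron"):
            for j, minor in enumerate(minor_by_rep):
                m = minor if ct != "iPSC" else 0
                counts.append({"variant_id": "v1", "sample_id": f"{ct}_r{j}", "cell_type": ct,
                               "ref_reads": total - m, "total_reads": total})
        counts = pd.DataFrame(counts)
        summaries = ase_bulk.pool_by_cell_type(counts)
        calls = ase_bulk.classify_variants(summaries)
        return counts, calls

    def test_single_replicate_support_flagged(self):
        counts, calls = self._calls_and_counts([0, 0, 0, 30])
        flagged = ase_bulk.flag_replicate_inconsistency(counts, calls)
        if calls["category"].iloc[0] in ("reactivated", "escape", "late_silenced"):
            assert bool(flagged["curation_flag"].iloc[0])

    def test_even_support_not_flagged(self):
        counts, calls = self._calls_and_counts([8, 7, 9, 6])
        flagged = ase_bulk.flag_replicate_inconsistency(counts, calls)
        assert not bool(flagged["curation_flag"].iloc[0])

    def test_exact_count_of_flagged_calls(self):
        # 40 reactivated variants, 3 with single-replicate minor-allele support
        rng = np.random.default_rng(5)
        counts = []
        for i in range(40):
            vid = f"v{i:02d}"
            single = i < 3
            for ct in ("iPSC", "NPC", "neuron"):
                for j in range(4):
                    if ct == "iPSC":
                        minor = 0
                    elif single:
                        minor = 40 if j == 0 else 0
                    else:
                        minor = int(rng.integers(8, 14))
                    counts.append({"variant_id": vid, "sample_id": f"{ct}_r{j}",
                                   "cell_type": ct, "ref_reads": 60 - minor, "total_reads": 60})
        counts = pd.DataFrame(counts)
        calls = ase_bulk.classify_variants(ase_bulk.pool_by_cell_type(counts))
        assert (calls["category"] == "reactivated").all()
        flagged = ase_bulk.flag_replicate_inconsistency(counts, calls)
        assert int(flagged["curation_flag"].sum()) == 3

    def test_demotion_option(self):
        counts, calls = self._calls_and_counts([0, 0, 0, 30])
        demoted = ase_bulk.flag_replicate_inconsistency(counts, calls, demote=True)
        assert (demoted.loc[demoted["curation_flag"], "category"] == "inactive").all()
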