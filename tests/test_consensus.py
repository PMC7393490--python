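"""Merging, voting rules, VAF selection, confidence tags, VCF output."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import literal_adaptive_vote, literal_majority_vote
from somaticmerge.callers import CallerId, CallerRecord, CallSet
from somaticmerge.consensus import (
    Confidence,
    MergedTable,
    Scheme,
    VotingConfig,
    majority_vote,
    merge,
    read_merged_vcf,
    select_reported_vaf,
    vaf_adaptive_vote,
    write_merged_vcf,
)
from somaticmerge.variants import VariantKey

C = CallerId
SEVEN = (C.STRELKA, C.MUTECT2, C.LOFREQ, C.VARDICT, C.MUSE, C.MUTECT, C.VARSCAN)


def key(pos, ref="A", alt="T"):
    return VariantKey("chr1", pos, ref, alt)


def record(caller, k, vaf=0.2):
    return CallerRecord(k, caller, vaf)


def callset(caller, keys, vaf=0.2):
    return CallSet.from_records(caller, [record(caller, k, vaf) for k in keys])


def adaptive_config(n_callers, **overrides):
    """Adaptive config over the first n of the seven callers (anchors first)."""
    params = dict(
        snv_callers=SEVEN[:n_callers],
        indel_callers=SEVEN[:n_callers],
        snv_scheme=Scheme.VAF_ADAPTIVE,
    )
    params.update(overrides)
    return VotingConfig(**params)


class TestMajorityVote:
    @pytest.mark.parametrize(
        "n_support,n_callers,expected",
        [(2, 4, True), (1, 4, False), (3, 7, False), (4, 7, True), (0, 3, False), (2, 3, True)],
    )
    def test_fraction_cutoff_uses_ceiling(self, n_support, n_callers, expected):
        assert majority_vote(n_support, n_callers, cutoff=0.5) is expected

    def test_min_count_mode(self):
        assert majority_vote(3, 7, min_count=3)
        assert not majority_vote(2, 7, min_count=3)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(1, 7), st.integers(1, 7),
           st.floats(0.05, 1.0, allow_nan=False))
    def test_monotone_in_support_and_antitone_in_cutoff(self, n_support, n_callers, cutoff):
        if n_support > n_callers:
            return
        passed = majority_vote(n_support, n_callers, cutoff)
        if passed and n_support < n_callers:
            assert majority_vote(n_support + 1, n_callers, cutoff)
        if not passed and n_support > 0:
            assert not majority_vote(n_support - 1, n_callers, cutoff)


class TestVafAdaptiveVote:
    @pytest.mark.parametrize(
        "support,vaf,expected,rule",
        [
            ({C.STRELKA, C.MUTECT2}, 0.05, True, 1),
            ({C.MUTECT2}, 0.01, True, 2),
            ({C.LOFREQ}, 0.20, False, None),
            ({C.STRELKA, C.MUTECT2}, 0.03, True, 1),   # boundary inclusive
            ({C.STRELKA, C.MUTECT2}, 0.1, True, 1),    # boundary inclusive
            ({C.STRELKA, C.MUTECT2}, 0.029, True, 2),  # below rule 1 but MuTect2 called
            ({C.STRELKA, C.MUTECT2}, 0.101, True, 3),  # above rule 1, 2-of-4 majority
            ({C.STRELKA}, 0.02, False, None),  # low VAF but no MuTect2, below majority
            ({C.MUTECT2}, None, False, None),          # missing VAF disables rules 1-2
        ],
    )
    def test_rule_order_and_boundaries(self, support, vaf, expected, rule):
        config = adaptive_config(4)
        decision, got_rule = vaf_adaptive_vote(support, vaf, config, 4)
        assert decision is expected
        assert got_rule == rule

    def test_anchor_subset_enforced(self):
        with pytest.raises(ValueError, match="anchor"):
            adaptive_config(4, snv_callers=(C.LOFREQ, C.MUSE, C.MUTECT, C.VARSCAN))

    @pytest.mark.parametrize("n", [3, 4, 7])
    def test_exhaustive_agreement_with_literal_rules(self, n):
        """All 2^n support patterns x a VAF boundary grid agree with literal
        re-encodings of the printed voting rules."""
        config = adaptive_config(n)
        grid = [None, 0.0, 0.01, 0.029, 0.03, 0.05, 0.1, 0.101, 0.5]
        for bits in itertools.product([0, 1], repeat=n):
            support = {c for c, b in zip(SEVEN[:n], bits) if b}
            for vaf in grid:
                names = {c.value for c in support}
                assert vaf_adaptive_vote(support, vaf, config, n)[0] is literal_adaptive_vote(
                    names, vaf, n
                )
                assert majority_vote(len(support), n, 0.5) is literal_majority_vote(
                    len(support), n
                )

    @pytest.mark.parametrize("n", [3, 4, 7])
    def test_majority_pass_contained_in_adaptive_pass(self, n):
        config = adaptive_config(n)
        grid = [None, 0.0, 0.01, 0.029, 0.03, 0.05, 0.1, 0.101, 0.5]
        for bits in itertools.product([0, 1], repeat=n):
            support = {c for c, b in zip(SEVEN[:n], bits) if b}
            for vaf in grid:
                if majority_vote(len(support), n, 0.5):
                    assert vaf_adaptive_vote(support, vaf, config, n)[0]

    @pytest.mark.parametrize("n", [3, 4, 7])
    def test_adding_support_never_flips_pass_to_reject(self, n):
        config = adaptive_config(n)
        for bits in itertools.product([0, 1], repeat=n):
            support = {c for c, b in zip(SEVEN[:n], bits) if b}
            for vaf in [None, 0.01, 0.05, 0.2]:
                if not vaf_adaptive_vote(support, vaf, config, n)[0]:
                    continue
                for extra in set(SEVEN[:n]) - support:
                    assert vaf_adaptive_vote(support | {extra}, vaf, config, n)[0]


class TestSelectReportedVaf:
    def test_priority_semantics(self):
        support = {
            C.STRELKA: record(C.STRELKA, key(1), 0.12),
            C.LOFREQ: record(C.LOFREQ, key(1), 0.10),
        }
        assert select_reported_vaf(support, (C.MUTECT2, C.STRELKA, C.LOFREQ)) == 0.12

    def test_single_supporter(self):
        support = {C.LOFREQ: record(C.LOFREQ, key(1), 0.07)}
        assert select_reported_vaf(support, (C.MUTECT2, C.STRELKA, C.LOFREQ)) == 0.07

    def test_all_missing_is_missing(self):
        support = {C.LOFREQ: CallerRecord(key(1), C.LOFREQ, None)}
        assert select_reported_vaf(support, (C.LOFREQ,)) is None

    def test_skips_priority_callers_without_vaf(self):
        support = {
            C.MUTECT2: CallerRecord(key(1), C.MUTECT2, None),
            C.VARSCAN: record(C.VARSCAN, key(1), 0.3),
        }
        assert select_reported_vaf(support, (C.MUTECT2, C.VARSCAN)) == 0.3


class TestMerge:
    def test_union_and_support(self):
        k1, k2, k3 = key(10), key(20), key(30)
        config = VotingConfig(snv_callers=(C.LOFREQ, C.MUTECT2), indel_callers=(C.LOFREQ, C.MUTECT2))
        table = merge([callset(C.LOFREQ, [k1, k2]), callset(C.MUTECT2, [k2, k3])], config)
        assert set(table.variants) == {k1, k2, k3}
        assert set(table.variants[k2].support) == {C.LOFREQ, C.MUTECT2}
        assert table.variants[k2].n_support == 2

    def test_identical_sets_dedupe(self):
        k1 = key(10)
        config = VotingConfig(snv_callers=(C.LOFREQ, C.MUTECT2), indel_callers=())
        table = merge([callset(C.LOFREQ, [k1]), callset(C.MUTECT2, [k1])], config)
        assert len(table) == 1
        assert table.variants[k1].n_support == 2

    def test_single_callset_rejected(self):
        config = VotingConfig(snv_callers=(C.LOFREQ, C.MUTECT2), indel_callers=())
        with pytest.raises(ValueError, match="two"):
            merge([callset(C.LOFREQ, [key(1)])], config)

    def test_duplicate_caller_rejected(self):
        config = VotingConfig(snv_callers=(C.LOFREQ, C.MUTECT2), indel_callers=())
        with pytest.raises(ValueError, match="duplicate"):
            merge([callset(C.LOFREQ, [key(1)]), callset(C.LOFREQ, [key(2)])], config)

    def test_random_split_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(11)
        keys = [key(int(p)) for p in rng.choice(np.arange(100, 50_000), size=500, replace=False)]
        callers = (C.LOFREQ, C.MUSE, C.MUTECT2, C.STRELKA)
        membership = {c: {k for k in keys if rng.random() < 0.5} for c in callers}
        config = VotingConfig(snv_callers=callers, indel_callers=callers)
        table = merge([callset(c, membership[c]) for c in callers], config)
        union = set().union(*membership.values())
        assert set(table.variants) == union
        for k in union:
            assert set(table.variants[k].support) == {c for c in callers if k in membership[c]}


class TestDecisions:
    def test_majority_consensus(self):
        k = key(10)
        config = adaptive_config(4)
        sets = [callset(c, [k], vaf=0.3) for c in SEVEN[:3]] + [callset(SEVEN[3], [])]
        table = merge(sets, config)
        mv = table.variants[k]
        assert mv.decision and mv.confidence is Confidence.CONSENSUS

    def test_lowvaf_rescue_tagged(self):
        k = key(10)
        config = adaptive_config(4)
        sets = [callset(C.MUTECT2, [k], vaf=0.02)] + [
            callset(c, []) for c in (C.STRELKA, C.LOFREQ, C.VARDICT)
        ]
        table = merge(sets, config)
        mv = table.variants[k]
        assert mv.decision and mv.confidence is Confidence.LOWVAF and mv.vote_rule == 2

    def test_min_tumor_vaf_demotes_after_voting(self):
        k = key(10)
        config = adaptive_config(4, min_tumor_vaf=0.05)
        sets = [callset(C.MUTECT2, [k], vaf=0.02)] + [
            callset(c, []) for c in (C.STRELKA, C.LOFREQ, C.VARDICT)
        ]
        mv = merge(sets, config).variants[k]
        assert not mv.decision
        assert mv.confidence is Confidence.REJECT
        assert mv.reject_reason == "min_tumor_vaf"

    def test_indels_use_majority_even_under_adaptive_snv_scheme(self):
        k = VariantKey("chr1", 10, "AT", "A")
        config = adaptive_config(4)
        sets = [callset(C.MUTECT2, [k], vaf=0.02)] + [
            callset(c, []) for c in (C.STRELKA, C.LOFREQ, C.VARDICT)
        ]
        mv = merge(sets, config).variants[k]
        assert not mv.decision  # 1-of-4 indel: the low-VAF rescue is SNV-only


class TestVcfOutput:
    def _table(self):
        config = adaptive_config(4)
        k1, k2, k3 = key(10), key(20, "C", "G"), key(30)
        sets = [
            callset(C.STRELKA, [k1, k2], vaf=0.05),
            callset(C.MUTECT2, [k1, k2], vaf=0.06),
            callset(C.LOFREQ, [k1], vaf=0.04),
            callset(C.VARDICT, [k3], vaf=0.4),
        ]
        return merge(sets, config)

    def test_emit_all_false_drops_rejected(self, tmp_path):
        table = self._table()
        out = tmp_path / "passing.vcf"
        write_merged_vcf(table, out, emit_all=False)
        rows = read_merged_vcf(out)
        assert len(rows) == 2
        assert all(r["filter"] in ("PASS", "LowVAF") for r in rows)

    def test_round_trip_preserves_annotations(self, tmp_path):
        table = self._table()
        out = tmp_path / "merged.vcf"
        write_merged_vcf(table, out, emit_all=True)
        rows = read_merged_vcf(out)
        assert [r["key"] for r in rows] == [mv.key for mv in table]
        for row, mv in zip(rows, table):
            assert set(row["callers"]) == set(mv.support)
            assert row["ncallers"] == mv.n_support
            assert row["tvaf"] == pytest.approx(mv.tumor_vaf, abs=1e-6)

    def test_empty_table_writes_header_only(self, tmp_path):
        config = adaptive_config(4)
        out = tmp_path / "empty.vcf"
        write_merged_vcf(MergedTable({}, config), out)
        text = out.read_text()
        assert "##INFO=<ID=CALLERS" in text and "##FILTER=<ID=Rejected" in text
        assert not [l for l in text.splitlines() if not l.startswith("#")]

    def test_output_is_deterministic(self, tmp_path):
        a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_merged_vcf(self._table(), a)
        write_merged_vcf(self._table(), b)
        assert a.read_bytes() == b.read_bytes()


def test_presets_encode_recommended_caller_sets():
    wgs = VotingConfig.preset("wgs")
    assert wgs.snv_scheme is Scheme.MAJORITY
    assert set(wgs.snv_callers) == {C.LOFREQ, C.MUSE, C.MUTECT2, C.STRELKA}
    assert set(wgs.indel_callers) == {C.LOFREQ, C.MUTECT2, C.STRELKA}
    deep = VotingConfig.preset("deep")
    assert deep.snv_scheme is Scheme.VAF_ADAPTIVE
    assert set(deep.snv_callers) == {C.LOFREQ, C.MUTECT2, C.STRELKA, C.VARDICT}
    assert set(deep.indel_callers) == {C.LOFREQ, C.MUTECT2, C.VARDICT}
    with pytest.raises(ValueError, match="preset"):
        VotingConfig.preset("wes9")
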