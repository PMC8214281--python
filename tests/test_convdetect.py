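"""Quartet topology tests, tract extraction, donor inference, merging,
and period assignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import quartetconv as qc
from quartetconv import convdetect, seqdist
from quartetconv.records import ConversionCall, Quartet

from oracles import maximal_segments_brute

SCORE_VALUES = [-1.0, -0.5, 0.0, 0.5, 1.0]


def _quartet(**kw):
    defaults = dict(genome_a="A", genome_b="B", o1="o1", o2="o2", s1="s1", s2="s2")
    defaults.update(kw)
    return Quartet(**defaults)


def _ctx_from_seqs(o1, o2, s1, s2):
    aln = seqdist.align_quartet(("o1", "o2", "s1", "s2"), (o1, o2, s1, s2))
    return convdetect.QuartetContext.build(_quartet(), aln)


def _mutate_syn(seq, n, rng):
    """Apply n synonymous point changes (third positions of fourfold codons)."""
    from quartetconv._codon import AA_BY_CODON

    s = list(seq)
    changed = 0
    while changed < n:
        k = int(rng.integers(0, len(s) // 3)) * 3
        codon = "".join(s[k : k + 3])
        for b in "TCAG":
            alt = codon[:2] + b
            if alt != codon and AA_BY_CODON.get(alt) == AA_BY_CODON.get(codon):
                s[k + 2] = b
                changed += 1
                break
    return "".join(s)


@pytest.fixture(scope="module")
def base_seq():
    rng = np.random.default_rng(77)
    from quartetconv.simgenome import _SENSE_CODONS

    return "ATG" + "".join(
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), 149)
    )


class TestWcvKs:
    def test_converted_topology_called(self, base_seq, rng):
        # paralogues identical, orthologues diverged: conversion signal
        o1 = base_seq
        o2 = base_seq
        s1 = _mutate_syn(base_seq, 12, rng)
        s2 = _mutate_syn(base_seq, 14, rng)
        ctx = _ctx_from_seqs(o1, o2, s1, s2)
        call = convdetect.detect_wcv_ks(ctx, "A", n_boot=200, rng=rng)
        assert call is not None
        assert call.methods == {"wcv_ks"}
        assert call.support >= 0.95

    def test_expected_topology_silent(self, base_seq, rng):
        # paralogues far apart, orthologues close: no call
        o1 = base_seq
        o2 = _mutate_syn(base_seq, 60, rng)
        s1 = _mutate_syn(o1, 3, rng)
        s2 = _mutate_syn(o2, 3, rng)
        ctx = _ctx_from_seqs(o1, o2, s1, s2)
        assert convdetect.detect_wcv_ks(ctx, "A", n_boot=100, rng=rng) is None

    def test_zero_divergence_tie_never_calls(self, base_seq, rng):
        ctx = _ctx_from_seqs(base_seq, base_seq, base_seq, base_seq)
        assert convdetect.detect_wcv_ks(ctx, "A", n_boot=100, rng=rng) is None
        assert convdetect.detect_wcv_identity(ctx, "A") is None

    def test_bootstrap_support_invariant_to_column_order(self, base_seq, rng):
        o1 = base_seq
        o2 = _mutate_syn(base_seq, 2, rng)
        s1 = _mutate_syn(base_seq, 10, rng)
        s2 = _mutate_syn(base_seq, 12, rng)
        ctx = _ctx_from_seqs(o1, o2, s1, s2)
        call = convdetect.detect_wcv_ks(ctx, "A", n_boot=1000, rng=np.random.default_rng(1))
        # permute codon columns jointly and re-test
        n = len(o1) // 3
        perm = np.random.default_rng(2).permutation(n)
        def shuffle(seq):
            return "".join(seq[3 * i : 3 * i + 3] for i in perm)
        ctx2 = _ctx_from_seqs(shuffle(o1), shuffle(o2), shuffle(s1), shuffle(s2))
        call2 = convdetect.detect_wcv_ks(ctx2, "A", n_boot=1000, rng=np.random.default_rng(3))
        assert call is not None and call2 is not None
        assert abs(call.support - call2.support) < 0.03


class TestWcvIdentity:
    def test_rule_and_strictness(self, base_seq, rng):
        o1 = base_seq
        o2 = base_seq
        s1 = _mutate_syn(base_seq, 6, rng)  # synonymous changes keep aa identity 1
        ctx = _ctx_from_seqs(o1, o2, s1, s1)
        # identities all 1.0 (synonymous divergence only): strict test silent
        assert convdetect.detect_wcv_identity(ctx, "A") is None

    def test_aa_level_conversion_called(self, base_seq, rng):
        from quartetconv.simgenome import _mutate

        o1 = base_seq
        o2 = base_seq
        s1 = _mutate(base_seq, 0.05, 1.0, np.random.default_rng(5))
        s2 = _mutate(base_seq, 0.05, 1.0, np.random.default_rng(6))
        ctx = _ctx_from_seqs(o1, o2, s1, s2)
        call = convdetect.detect_wcv_identity(ctx, "A")
        assert call is not None and call.methods == {"wcv_identity"}


class TestSiteScores:
    def test_score_values(self):
        # col pattern: paralogues equal / orthologues differ -> +1, etc.
        o1 = "ATGAAA"
        o2 = "ATGAAA"
        s1 = "ATGAAG"
        s2 = "ATGAAT"
        ctx = _ctx_from_seqs(o1, o2, s1, s2)
        ss = convdetect.build_site_scores(ctx, "A")
        assert ss.scores[:5].tolist() == [0.0] * 5
        assert ss.scores[5] == 1.0  # both orthologue pairs differ, paralogues equal
        ctx2 = _ctx_from_seqs("ATGAAA", "ATGAAG", "ATGAAA", "ATGAAG")
        ss2 = convdetect.build_site_scores(ctx2, "A")
        assert ss2.scores[5] == -1.0  # paralogues differ, orthologues identical

    def test_half_scores(self):
        # only one orthologue pair differs -> dO = 0.5
        ctx = _ctx_from_seqs("ATGAAA", "ATGAAA", "ATGAAG", "ATGAAA")
        ss = convdetect.build_site_scores(ctx, "A")
        assert ss.scores[5] == 0.5


class TestRuzzoTompa:
    def test_uniform_positive_run(self):
        segs = convdetect.ruzzo_tompa(np.ones(10))
        assert segs == [(0, 10, 10.0)]

    def test_spec_example_single_segment(self):
        segs = convdetect.ruzzo_tompa(np.array([1, 1, 1, -1, 1, 1.0]))
        assert segs == [(0, 6, 4.0)]

    def test_empty_and_all_negative(self):
        assert convdetect.ruzzo_tompa(np.array([])) == []
        assert convdetect.ruzzo_tompa(np.array([-1.0, -0.5])) == []

    @given(
        st.lists(st.sampled_from(SCORE_VALUES), min_size=1, max_size=20),
        st.integers(0, 10**6),
    )
    @settings(max_examples=400, deadline=None, derandomize=True)
    def test_equals_exhaustive_enumeration(self, values, _seed):
        got = [(s, e, round(t, 9)) for s, e, t in sorted(convdetect.ruzzo_tompa(np.array(values)))]
        want = [(s, e, round(t, 9)) for s, e, t in maximal_segments_brute(values)]
        assert got == want


class TestDetectPcv:
    def test_ten_site_run_is_one_tract(self, rng):
        tracts = convdetect.detect_pcv(np.ones(10), rng=rng)
        assert len(tracts) == 1
        start, end, total, support = tracts[0]
        assert (start, end, total) == (0, 10, 10.0)

    def test_short_segment_fails_min_len(self, rng):
        s = np.array([1, 1, 1, -1, 1, 1.0])
        assert convdetect.detect_pcv(s, rng=rng) == []

    def test_empty_scores(self, rng):
        assert convdetect.detect_pcv(np.array([]), rng=rng) == []

    def test_masking_recovers_second_tract(self, rng):
        s = np.concatenate([np.ones(12), -np.ones(30), np.ones(11)])
        tracts = convdetect.detect_pcv(s, rng=rng)
        assert [(t[0], t[1]) for t in tracts] == [(0, 12), (42, 53)]

    def test_weak_segment_needs_bootstrap_support(self):
        # a +2.5 segment in heavy negative background is below min_score
        rng = np.random.default_rng(8)
        s = np.concatenate([-np.ones(100), np.array([0.5] * 3 + [0.0] * 5 + [0.5] * 2), -np.ones(100)])
        tracts = convdetect.detect_pcv(s, min_score=2.0, rng=rng)
        assert len(tracts) == 1
        assert tracts[0][3] >= 0.95  # passed the shuffle test


class TestDonor:
    def test_clear_margin(self, base_seq):
        from quartetconv.simgenome import _mutate

        rng = np.random.default_rng(9)
        o1 = base_seq
        o2 = base_seq  # converted: identical to o1
        s1 = _mutate(base_seq, 0.02, 0.4, rng)  # o1's orthologue stays close
        s2 = _mutate(base_seq, 0.40, 0.4, rng)  # o2 lost its own history
        ctx = _ctx_from_seqs(o1, o2, s1, s2)
        assert convdetect.infer_donor(ctx, "A") == "o1"

    def test_margin_below_threshold_uncertain(self, base_seq):
        ctx = _ctx_from_seqs(base_seq, base_seq, base_seq, base_seq)
        assert convdetect.infer_donor(ctx, "A") == "uncertain"


class TestMergeCalls:
    def _call(self, **kw):
        d = dict(genome="A", gene1="g1", gene2="g2")
        d.update(kw)
        return ConversionCall(**d)

    def test_same_pair_across_quartets_merged(self):
        calls = [
            self._call(methods={"wcv_ks"}, donor="g1", support=0.97),
            self._call(gene1="g2", gene2="g1", methods={"pcv"}, donor="g1",
                       tracts=[(10, 25)], tract_support=[1.0]),
        ]
        merged = qc.merge_calls(calls)
        assert len(merged) == 1
        m = merged[0]
        assert m.methods == {"wcv_ks", "pcv"}
        assert m.donor == "g1"
        assert m.tracts == [(10, 25)]

    def test_conflicting_donors_uncertain(self):
        merged = qc.merge_calls([
            self._call(methods={"pcv"}, donor="g1"),
            self._call(methods={"pcv"}, donor="g2"),
        ])
        assert merged[0].donor == "uncertain"

    def test_disjoint_tracts_kept_overlaps_unioned(self):
        merged = qc.merge_calls([
            self._call(methods={"pcv"}, tracts=[(10, 25)], tract_support=[1.0]),
            self._call(methods={"pcv"}, tracts=[(20, 30), (40, 60)],
                       tract_support=[1.0, 0.98]),
        ])
        assert merged[0].tracts == [(10, 30), (40, 60)]

    def test_idempotent(self):
        calls = [
            self._call(methods={"wcv_ks"}, donor="g1", support=0.99),
            self._call(methods={"pcv"}, tracts=[(5, 40)], tract_support=[1.0]),
            self._call(genome="B", methods={"pcv"}, donor="g2",
                       tracts=[(1, 15)], tract_support=[0.96]),
        ]
        once = qc.merge_calls(calls)
        twice = qc.merge_calls(once)
        assert twice == once


class TestAssignPeriod:
    def _calls(self, genome, pairs):
        return [
            ConversionCall(genome=genome, gene1=a, gene2=b, methods={"pcv"})
            for a, b in pairs
        ]

    def test_shared_is_A_unique_is_B(self):
        merged = {
            "X1": self._calls("X1", [("x1a", "x1b"), ("x1c", "x1d")]),
            "X2": self._calls("X2", [("x2a", "x2b")]),
        }
        pair_map = {
            frozenset(("x1a", "x1b")): frozenset(("x2a", "x2b")),
            frozenset(("x2a", "x2b")): frozenset(("x1a", "x1b")),
            frozenset(("x1c", "x1d")): frozenset(("x2c", "x2d")),
        }
        summary = qc.assign_period(merged, ("X1", "X2"), pair_map)
        periods = {c.gene1: c.period for c in merged["X1"]}
        assert periods == {"x1a": "A", "x1c": "B"}
        assert merged["X2"][0].period == "A"
        assert summary["X1"]["period_A"] == 1 and summary["X1"]["period_B"] == 1

    def test_missing_sibling_unassigned(self):
        merged = {"X1": self._calls("X1", [("a", "b")])}
        assert qc.assign_period(merged, ("X1", "X2"), {}) == {}
        assert merged["X1"][0].period == "unassigned"
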