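"""Spliced-leader and relic-leader detection."""

import itertools

import numpy as np
import pytest

import glacialis as gl
from glacialis.leader import (
    DEFAULT_RELIC_UNIT,
    DINOSL_CONSENSUS,
    LeaderParams,
    count_relic_leaders,
    expand_degenerate,
    leader_summary,
    match_leader,
    unit_gap_fraction,
)
from glacialis.core_io import Interval, SeqRecord

# Independent brute-force oracle: tiny IUPAC table of its own, naive
# enumeration of every admissible 5'-flush (offset, leader-start) register
# with full 3' extension.
_ORACLE_IUPAC = {"D": "AGT", "N": "ACGT", "A": "A", "C": "C", "G": "G", "T": "T"}


def oracle_match(seq: str, p: LeaderParams):
    cons = p.consensus
    best = None
    for o in range(1, min(p.t_max_start, len(seq)) + 1):
        for ls in range(1, p.max_leader_start + 1):
            if o > 1 and ls > 1:
                continue  # double-trimmed registers are not candidates
            le = min(len(cons), ls + (len(seq) - o + 1) - 1)
            if le < p.min_leader_end:
                continue
            mism = sum(
                seq[o - 1 + i] not in _ORACLE_IUPAC[cons[ls - 1 + i]]
                for i in range(le - ls + 1)
            )
            if mism > p.max_mismatch:
                continue
            key = (le - ls + 1, -mism, -o, -ls)
            if best is None or key > best[0]:
                best = (key, (o, ls, le, mism))
    return best[1] if best else None


def resolved(d: str = "T") -> str:
    return d + DINOSL_CONSENSUS[1:]


BODY = "GATTACAGGCCTAGCTTAGGACTTACCGGTTACAGATTACAGGCCTAACCTGAGGACTCTTACCGGTTACA"


class TestExpandDegenerate:
    @pytest.mark.parametrize(
        "pattern, expected",
        [
            ("DCC", ["ACC", "GCC", "TCC"]),
            ("ACG", ["ACG"]),
        ],
    )
    def test_enumeration(self, pattern, expected):
        assert expand_degenerate(pattern) == expected

    def test_n_expands_fourfold(self):
        assert len(expand_degenerate("NCC")) == 4

    def test_invalid_code_named(self):
        with pytest.raises(ValueError, match="X"):
            expand_degenerate("AXC")

    def test_full_consensus_three_expansions(self):
        assert len(expand_degenerate(DINOSL_CONSENSUS)) == 3


class TestMatchLeader:
    def test_full_leader_d_as_t(self):
        m = match_leader(SeqRecord("t", "T" + DINOSL_CONSENSUS[1:] + BODY))
        assert (m.t_start, m.l_start, m.l_end, m.mismatches) == (1, 1, 22, 0)

    def test_truncated_to_position_two(self):
        m = match_leader(SeqRecord("t", DINOSL_CONSENSUS[1:] + BODY))
        assert (m.l_start, m.l_end, m.mismatches) == (2, 22, 0)

    def test_two_substitutions_rejected_one_accepted(self):
        leader = list(resolved())
        leader[4] = "A" if leader[4] != "A" else "C"  # consensus position 5
        one = "".join(leader)
        assert match_leader(SeqRecord("t", one + BODY)).mismatches == 1
        leader[11] = "A" if leader[11] != "A" else "C"  # position 12 as well
        two = "".join(leader)
        assert match_leader(SeqRecord("t", two + BODY)) is None

    def test_alignment_short_of_position_twenty_rejected(self):
        # transcript ends at consensus position 19: l_end 19 < 20
        assert match_leader(SeqRecord("t", resolved()[:19])) is None

    def test_offset_start_within_five(self):
        m = match_leader(SeqRecord("t", "CCGA" + resolved() + BODY))
        assert m.t_start == 5 and m.l_start == 1 and m.mismatches == 0

    def test_monotone_in_max_mismatch_and_t_max_start(self, rng):
        base = LeaderParams()
        for _ in range(200):
            n = int(rng.integers(40, 90))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            s = int(rng.integers(1, 9))
            t = resolved(str(rng.choice(list("TAG"))))[s - 1 :] + seq
            got = match_leader(SeqRecord("t", t), base)
            for p2 in (
                LeaderParams(max_mismatch=2),
                LeaderParams(t_max_start=8),
                LeaderParams(max_mismatch=3, t_max_start=10),
            ):
                if got is not None:
                    assert match_leader(SeqRecord("t", t), p2) is not None

    def test_agrees_with_bruteforce_oracle_on_random_transcripts(self, rng):
        p = LeaderParams()
        for i in range(300):
            body = "".join(rng.choice(list("ACGT"), size=58))
            s = int(rng.integers(1, 23))
            leader = list(resolved(str(rng.choice(list("TAG"))))[s - 1 :])
            for _ in range(int(rng.integers(0, 3))):
                if leader:
                    j = int(rng.integers(0, len(leader)))
                    leader[j] = str(rng.choice(list("ACGT")))
            t = ("".join(leader) + body)[:80]
            got = match_leader(SeqRecord("t", t), p)
            want = oracle_match(t, p)
            got_t = None if got is None else (got.t_start, got.l_start, got.l_end, got.mismatches)
            assert got_t == want, f"case {i}: {t}"


class TestRelics:
    def test_single_planted_relic(self):
        t = resolved() + DEFAULT_RELIC_UNIT + BODY
        m = match_leader(SeqRecord("t", t))
        assert count_relic_leaders(SeqRecord("t", t), m) == 1

    def test_four_planted_relics(self):
        t = resolved() + DEFAULT_RELIC_UNIT * 4 + BODY
        m = match_leader(SeqRecord("t", t))
        assert count_relic_leaders(SeqRecord("t", t), m) == 4

    def test_no_relic_in_plain_body(self):
        t = resolved() + BODY
        m = match_leader(SeqRecord("t", t))
        assert count_relic_leaders(SeqRecord("t", t), m) == 0

    def test_truncated_leader_with_relics(self):
        t = resolved()[7:] + DEFAULT_RELIC_UNIT * 2 + BODY  # leader from position 8
        m = match_leader(SeqRecord("t", t))
        assert m.l_start == 8
        assert count_relic_leaders(SeqRecord("t", t), m) == 2


class TestSummary:
    def test_empty_input_gives_zero_summary(self):
        s = leader_summary([])
        assert s.n_total == 0 and s.n_leader == 0
        assert s.leader_fraction is None
        assert s.start_position_pct == {}

    def test_histogram_sums_to_hundred_and_matches_truncation_mix(self):
        cfg = gl.SynthConfig(
            seed=21,
            p_leader=1.0,
            truncation_distribution={1: 0.5, 2: 0.5},
            relic_count_distribution={0: 1.0},
        )
        sim = gl.simulate_genome(cfg)
        tx = gl.simulate_transcripts(sim.truth, cfg, n_transcripts=600)
        s = leader_summary(tx)
        assert s.n_leader == 600
        assert sum(s.start_position_pct.values()) == pytest.approx(100.0)
        assert s.start_position_pct[1] == pytest.approx(50.0, abs=6.0)
        assert s.start_position_pct[2] == pytest.approx(50.0, abs=6.0)


class TestUnitGapFraction:
    def test_mixed_gaps(self):
        spans = [
            Interval("c", 0, 1000),
            Interval("c", 2000, 3000),  # gap 1000
            Interval("c", 10000, 11000),  # gap 7000
        ]
        gaps, frac = unit_gap_fraction(spans, threshold=5000)
        assert sorted(gaps) == [1000, 7000]
        assert frac == pytest.approx(0.5)

    def test_single_span_no_gaps(self):
        gaps, frac = unit_gap_fraction([Interval("c", 0, 10)])
        assert gaps == [] and frac is None

    def test_abutting_spans_gap_zero(self):
        spans = [Interval("c", 0, 10), Interval("c", 10, 20), Interval("c", 20, 30)]
        gaps, frac = unit_gap_fraction(spans)
        assert gaps == [0, 0] and frac == 1.0
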