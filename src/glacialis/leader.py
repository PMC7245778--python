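"""Detection of the dinoflagellate spliced leader (DinoSL) and relic leaders
on full-length transcripts.

Mature nuclear mRNAs of dinoflagellates carry a 22-nt trans-spliced leader
(consensus ``DCCGTAGCCATTTTGGCTCAAG``, D = T/A/G) at their 5' end. When a
mature transcript is re-integrated into the genome and re-expressed, the old
leader survives downstream of the new one as a "relic"; successive cycles
stack multiple relics. Both signals are recovered here with exhaustive
ungapped scanning: at the scale of a 22-nt query this is exact, and the
acceptance rules -- not the search heuristic -- define the result.

Acceptance rules for the primary leader: the alignment must start within the
first ``t_max_start`` (5) bases of the transcript, end at or beyond consensus
position ``min_leader_end`` (20), contain no gaps and at most ``max_mismatch``
(1) mismatches. The leader-side start is additionally bounded by
``max_leader_start`` (default 8, the 3'-most conserved CC position): shorter
suffix matches are indistinguishable from chance at these rule settings, so
they are not reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_io import Interval, SeqRecord, merge_intervals

DINOSL_CONSENSUS = "DCCGTAGCCATTTTGGCTCAAG"
#: The relic unit is never printed in the literature we follow; the default
#: is the consensus with the degenerate first base dropped.
DEFAULT_RELIC_UNIT = DINOSL_CONSENSUS[1:]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class LeaderParams:
    """Acceptance rules for primary-leader and relic-leader matching."""

    consensus: str = DINOSL_CONSENSUS
    relic_unit: str = DEFAULT_RELIC_UNIT
    t_max_start: int = 5
    min_leader_end: int = 20
    max_leader_start: int = 8
    max_mismatch: int = 1
    max_gap: int = 0  # scanning is ungapped; kept for interface fidelity
    relic_q_start_max: int = 11
    relic_t_start_max: int = 5
    relic_end_slack: int = 5
    relic_max_mismatch_per_unit: int = 2
    max_relics: int = 8

    def __post_init__(self) -> None:
        for name in (
            "t_max_start", "min_leader_end", "max_leader_start", "max_mismatch",
            "max_gap", "relic_q_start_max", "relic_t_start_max",
            "relic_end_slack", "relic_max_mismatch_per_unit", "max_relics",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for ch in self.consensus + self.relic_unit:
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC code {ch!r}")


@dataclass(frozen=True)
class LeaderMatch:
    """An accepted leader alignment (all coordinates 1-based)."""

    transcript_id: str
    t_start: int
    l_start: int
    l_end: int
    mismatches: int
    relic_count: int = 0

    @property
    def aligned_length(self) -> int:
        return self.l_end - self.l_start + 1


def expand_degenerate(consensus: str) -> list[str]:
    """Cartesian expansion of IUPAC degeneracy, in code-alphabet order."""
    sets = []
    for ch in consensus:
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r}")
        sets.append(sorted(IUPAC[ch]))
    return ["".join(p) for p in itertools.product(*sets)]


def _bases_match(pattern_base: str, transcript_base: str) -> bool:
    p = IUPAC.get(pattern_base)
    t = IUPAC.get(transcript_base)
    if p is None or t is None:
        return pattern_base == transcript_base
    return bool(p & t)


def match_leader(
    transcript: SeqRecord, params: LeaderParams | None = None
) -> LeaderMatch | None:
    """Best accepted ungapped leader alignment on a transcript, or None.

    Candidate alignments are registers flush at the 5' end -- either the
    transcript starts inside the leader (t_start = 1, l_start >= 1: a
    5'-truncated transcript) or the leader is complete after a few extra
    transcript bases (t_start >= 1, l_start = 1). Each candidate extends
    ungapped to the end of the consensus (or of the transcript) and its
    mismatches are counted over that whole window: trimming a mismatching
    5' or 3' flank to sneak under the mismatch cap is not allowed, which is
    what rejects near-miss variants carrying two in-register mismatches.
    Among accepted candidates the longest wins, ties broken by fewer
    mismatches, then smaller transcript start, then smaller leader start.
    """
    p = params or LeaderParams()
    seq = transcript.seq.upper()
    cons = p.consensus
    L = len(cons)
    best: tuple | None = None
    best_match: LeaderMatch | None = None
    for o in range(1, min(p.t_max_start, len(seq)) + 1):
        avail = len(seq) - o + 1
        l_starts = range(1, min(L, p.max_leader_start) + 1) if o == 1 else (1,)
        for ls in l_starts:
            le = min(L, ls + avail - 1)
            if le < p.min_leader_end:
                continue
            mism = 0
            for i in range(le - ls + 1):
                if not _bases_match(cons[ls - 1 + i], seq[o - 1 + i]):
                    mism += 1
                    if mism > p.max_mismatch:
                        break
            if mism > p.max_mismatch:
                continue
            key = (le - ls + 1, -mism, -o, -ls)
            if best is None or key > best:
                best = key
                best_match = LeaderMatch(
                    transcript.id, t_start=o, l_start=ls, l_end=le,
                    mismatches=mism,
                )
    return best_match


def _relic_query_hits(
    seq: str, query: str, leader_budget: int, p: LeaderParams
) -> bool:
    """True iff an ungapped alignment of ``query`` to ``seq`` satisfies the
    relic coordinate rules.

    Mismatches are budgeted per query segment: the leading consensus
    segment may carry ``leader_budget`` mismatches and each 21-nt relic
    segment at most ``relic_max_mismatch_per_unit`` -- a pooled budget
    would let the trailing, partially-aligned unit absorb every allowance
    and over-count relics by one.
    """
    Q = len(query)
    C = len(p.consensus)
    U = len(p.relic_unit)
    min_qend = Q - p.relic_end_slack
    for qs in range(1, min(p.relic_q_start_max, Q) + 1):
        for ts in range(1, min(p.relic_t_start_max, len(seq)) + 1):
            max_len = min(Q - qs + 1, len(seq) - ts + 1)
            if qs + max_len - 1 < min_qend:
                continue
            seg_mism = 0
            seg = 0  # 0 = consensus segment, 1.. = relic units
            for j in range(max_len):
                qpos = qs + j  # 1-based on query
                new_seg = 0 if qpos <= C else 1 + (qpos - C - 1) // U
                if new_seg != seg:
                    seg, seg_mism = new_seg, 0
                if not _bases_match(query[qpos - 1], seq[ts - 1 + j]):
                    seg_mism += 1
                    limit = leader_budget if seg == 0 else p.relic_max_mismatch_per_unit
                    if seg_mism > limit:
                        break
                if qpos >= min_qend:
                    return True
    return False


def count_relic_leaders(
    transcript: SeqRecord, match: LeaderMatch, params: LeaderParams | None = None
) -> int:
    """Number of relic leader units following the primary leader.

    For k = max_relics .. 1 the query ``consensus + relic_unit * k`` is
    aligned ungapped to the transcript; k is accepted if a hit starts within
    the first ``relic_q_start_max`` bases of the query and the first
    ``relic_t_start_max`` bases of the transcript, and ends within
    ``relic_end_slack`` bases of the query end, with at most
    ``relic_max_mismatch_per_unit`` mismatches in each relic unit beyond
    those of the primary leader. The largest accepted k is returned,
    else 0.
    """
    p = params or LeaderParams()
    seq = transcript.seq.upper()
    for k in range(p.max_relics, 0, -1):
        query = p.consensus + p.relic_unit * k
        if _relic_query_hits(seq, query, match.mismatches, p):
            return k
    return 0


@dataclass
class LeaderSummary:
    """Leader classes over a transcript set (fractions in [0, 1])."""

    n_total: int
    n_leader: int
    leader_fraction: float | None
    start_position_pct: dict[int, float]
    relic_count_histogram: dict[int, int]
    n_relic_one: int
    n_relic_multi: int
    fraction_relic_one: float | None
    fraction_relic_multi: float | None
    per_transcript: list[LeaderMatch | None] = field(repr=False, default_factory=list)


def leader_summary(
    transcripts: Iterable[SeqRecord], params: LeaderParams | None = None
) -> LeaderSummary:
    """Match every transcript and summarise leader classes.

    The start-position histogram is reported as percentages of
    leader-bearing transcripts over consensus positions (sums to 100 when
    any leader is found); relic fractions are of all transcripts.
    """
    p = params or LeaderParams()
    matches: list[LeaderMatch | None] = []
    n_total = 0
    for rec in transcripts:
        n_total += 1
        m = match_leader(rec, p)
        if m is not None:
            k = count_relic_leaders(rec, m, p)
            m = LeaderMatch(
                m.transcript_id, m.t_start, m.l_start, m.l_end, m.mismatches, k
            )
        matches.append(m)
    found = [m for m in matches if m is not None]
    n_leader = len(found)
    start_pct: dict[int, float] = {}
    relic_hist: dict[int, int] = {}
    if n_leader:
        for m in found:
            start_pct[m.l_start] = start_pct.get(m.l_start, 0.0) + 1
            relic_hist[m.relic_count] = relic_hist.get(m.relic_count, 0) + 1
        start_pct = {
            pos: 100.0 * n / n_leader for pos, n in sorted(start_pct.items())
        }
    n_one = sum(1 for m in found if m.relic_count == 1)
    n_multi = sum(1 for m in found if m.relic_count >= 2)
    return LeaderSummary(
        n_total=n_total,
        n_leader=n_leader,
        leader_fraction=(n_leader / n_total) if n_total else None,
        start_position_pct=start_pct,
        relic_count_histogram=dict(sorted(relic_hist.items())),
        n_relic_one=n_one,
        n_relic_multi=n_multi,
        fraction_relic_one=(n_one / n_total) if n_total else None,
        fraction_relic_multi=(n_multi / n_total) if n_total else None,
        per_transcript=matches,
    )


def unit_gap_fraction(
    spans: Iterable[Interval] | Mapping[str, Sequence[Interval]],
    threshold: int = 5000,
) -> tuple[list[int], float | None]:
    """Distances between adjacent transcriptional-unit spans per contig and
    the fraction of distances <= ``threshold``.

    Overlapping spans are merged first. With fewer than two spans on every
    contig the gap list is empty and the fraction undefined (None).
    """
    if isinstance(spans, Mapping):
        flat = [iv for ivs in spans.values() for iv in ivs]
    else:
        flat = list(spans)
    gaps: list[int] = []
    by_contig: dict[str, list[Interval]] = {}
    for iv in flat:
        by_contig.setdefault(iv.contig, []).append(iv)
    for contig in by_contig:
        # merge strictly overlapping spans; abutting spans stay distinct
        # (their gap is 0, which the fraction must count)
        merged: list[Interval] = []
        for iv in sorted(by_contig[contig], key=lambda i: (i.start, i.end)):
            if merged and iv.start < merged[-1].end:
                last = merged.pop()
                iv = Interval(contig, last.start, max(last.end, iv.end))
            merged.append(iv)
        by_contig[contig] = merged
    for ivs in by_contig.values():
        for a, b in zip(ivs, ivs[1:]):
            gaps.append(b.start - a.end)
    if not gaps:
        return [], None
    frac = sum(1 for g in gaps if g <= threshold) / len(gaps)
    return gaps, frac
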