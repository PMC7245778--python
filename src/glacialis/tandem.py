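"""Tandemly repeated gene arrays and their conservation statistic x.

Gene families are single-linkage components of a qualifying-similarity
graph (E <= 1e-10, query or subject coverage > 50%). A tandem block is a
maximal run of same-family genes in gene order, allowing a bounded number
of intervening genes of other families. For each block, x is the mean
pairwise percent identity over all member pairs, computed separately for
the encoded proteins, the CDS, and the intergenic spacers between members;
blocks of the same family are aggregated as mean/sd/min/max of x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from Bio import Align
from Bio.Seq import Seq

from .core_io import GeneModel, SeqRecord, TabularHit
from .architecture import group_by_scaffold

#: Fixed published alignment scores: the first gap column costs the open
#: penalty, each additional column the extension penalty.
ALIGN_SCORES = {"match": 1, "mismatch": -1, "gap_open": -2, "gap_extend": -1}


def _aligner(mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.match_score = ALIGN_SCORES["match"]
    a.mismatch_score = ALIGN_SCORES["mismatch"]
    a.open_gap_score = ALIGN_SCORES["gap_open"]
    a.extend_gap_score = ALIGN_SCORES["gap_extend"]
    return a


def pairwise_identity(
    a: SeqRecord, b: SeqRecord, mode: str = "global"
) -> tuple[float, int]:
    """Percent identity of the optimal pairwise alignment of two sequences.

    Identity = matches / aligned columns * 100, where aligned columns
    include internal gap columns; terminal gap columns are excluded in
    global mode (the denominator runs from the first to the last aligned
    pair).
    """
    if mode not in ("global", "local"):
        raise ValueError(f"unknown mode {mode!r}")
    if not a.seq or not b.seq:
        raise ValueError("cannot align an empty sequence")
    aln = _aligner(mode).align(a.seq, b.seq)[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return 0.0, 0
    matches = 0
    pairs = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        pairs += ea - sa
        matches += sum(
            1 for x, y in zip(a.seq[sa:ea], b.seq[sb:eb]) if x == y
        )
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    columns = int(span_a + span_b - pairs)
    return float(100.0 * matches / columns), columns


def build_families(
    hits: Iterable[TabularHit],
    lengths: Mapping[str, int],
    max_evalue: float = 1e-10,
    min_cov_pct: float = 50.0,
) -> dict[str, str]:
    """Single-linkage families from qualifying similarity hits.

    An edge qid-sid is kept iff evalue <= ``max_evalue`` and the alignment
    covers more than ``min_cov_pct`` percent of the query OR of the subject
    length; self-hits are ignored. Families are connected components; every
    id in ``lengths`` gets a label (singletons allowed). Labels are
    deterministic: components sorted by their smallest member id.
    """
    parent: dict[str, str] = {pid: pid for pid in lengths}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for h in hits:
        if h.qid == h.sid:
            continue
        for pid in (h.qid, h.sid):
            if pid not in lengths:
                raise ValueError(f"no length supplied for id {pid!r}")
        if h.evalue > max_evalue:
            continue
        cov_q = 100.0 * h.length / lengths[h.qid]
        cov_s = 100.0 * h.length / lengths[h.sid]
        if cov_q > min_cov_pct or cov_s > min_cov_pct:
            ra, rb = find(h.qid), find(h.sid)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    components: dict[str, list[str]] = {}
    for pid in lengths:
        components.setdefault(find(pid), []).append(pid)
    labels: dict[str, str] = {}
    for i, root in enumerate(sorted(components), 1):
        for pid in components[root]:
            labels[pid] = f"fam{i:05d}"
    return labels


@dataclass
class TandemBlock:
    """A run of adjacent same-family gene copies on one scaffold."""

    scaffold_id: str
    gene_ids: tuple[str, ...]
    family: str
    strand_uniform: bool
    x_protein: float | None = None
    x_cds: float | None = None
    x_intergenic: float | None = None

    @property
    def size(self) -> int:
        return len(self.gene_ids)


def find_tandem_arrays(
    genes: Iterable[GeneModel],
    families: Mapping[str, str],
    max_intervening: int = 1,
) -> list[TandemBlock]:
    """Maximal same-family runs in gene order with at most
    ``max_intervening`` genes of other families between consecutive
    members; blocks need >= 2 members."""
    blocks: list[TandemBlock] = []
    for sid, gs in sorted(group_by_scaffold(genes).items()):
        fam_positions: dict[str, list[int]] = {}
        for pos, g in enumerate(gs):
            fam = families.get(g.gene_id)
            if fam is None:
                raise ValueError(f"gene {g.gene_id} has no family label")
            fam_positions.setdefault(fam, []).append(pos)
        for fam in sorted(fam_positions):
            positions = fam_positions[fam]
            run = [positions[0]]
            for p in positions[1:]:
                if p - run[-1] - 1 <= max_intervening:
                    run.append(p)
                else:
                    if len(run) >= 2:
                        blocks.append(_make_block(sid, gs, run, fam))
                    run = [p]
            if len(run) >= 2:
                blocks.append(_make_block(sid, gs, run, fam))
    return blocks


def _make_block(sid: str, gs: Sequence[GeneModel], run: Sequence[int], fam: str) -> TandemBlock:
    members = [gs[p] for p in run]
    return TandemBlock(
        scaffold_id=sid,
        gene_ids=tuple(g.gene_id for g in members),
        family=fam,
        strand_uniform=len({g.strand for g in members}) == 1,
    )


class AggregateStats(NamedTuple):
    mean: float
    sd: float
    min: float
    max: float
    n_blocks: int


def _mean_pairwise(seqs: Sequence[SeqRecord]) -> float | None:
    vals = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            ident, _cols = pairwise_identity(seqs[i], seqs[j], mode="global")
            vals.append(ident)
    return fmean(vals) if vals else None


def block_conservation(
    blocks: Sequence[TandemBlock],
    scaffolds: Mapping[str, str] | Sequence[SeqRecord],
    genes: Mapping[str, GeneModel] | Sequence[GeneModel],
) -> tuple[list[TandemBlock], dict[str, dict[str, AggregateStats]]]:
    """Per-block x for proteins, CDS and intergenic spacers, plus
    per-family aggregation (mean, sd, min, max of x over blocks).

    x is the mean pairwise global percent identity over all member pairs
    (spacer pairs for the intergenic class). Zero-length spacers are
    skipped with a warning.
    """
    if not isinstance(scaffolds, Mapping):
        scaffolds = {s.id: s.seq for s in scaffolds}
    if not isinstance(genes, Mapping):
        genes = {g.gene_id: g for g in genes}
    out: list[TandemBlock] = []
    for blk in blocks:
        seq = scaffolds[blk.scaffold_id]
        members = [genes[gid] for gid in blk.gene_ids]
        cds = [SeqRecord(g.gene_id, g.spliced_seq(seq)) for g in members]
        proteins = []
        for rec in cds:
            trimmed = rec.seq[: len(rec.seq) // 3 * 3]
            aa = str(Seq(trimmed).translate()).rstrip("*")
            if aa:
                proteins.append(SeqRecord(rec.id, aa, "protein"))
        spacers: list[SeqRecord] = []
        for a, b in zip(members, members[1:]):
            s = seq[a.span_end : b.span_start - 1]
            if not s:
                warnings.warn(
                    f"block {blk.family} on {blk.scaffold_id}: zero-length "
                    f"spacer between {a.gene_id} and {b.gene_id}; skipped",
                    stacklevel=2,
                )
                continue
            spacers.append(SeqRecord(f"{a.gene_id}|{b.gene_id}", s))
        out.append(
            TandemBlock(
                blk.scaffold_id, blk.gene_ids, blk.family, blk.strand_uniform,
                x_protein=_mean_pairwise(proteins),
                x_cds=_mean_pairwise(cds),
                x_intergenic=_mean_pairwise(spacers),
            )
        )
    aggregate: dict[str, dict[str, AggregateStats]] = {}
    by_family: dict[str, list[TandemBlock]] = {}
    for blk in out:
        by_family.setdefault(blk.family, []).append(blk)
    for fam, blks in sorted(by_family.items()):
        aggregate[fam] = {}
        for attr in ("x_protein", "x_cds", "x_intergenic"):
            vals = [getattr(b, attr) for b in blks if getattr(b, attr) is not None]
            if not vals:
                continue
            arr = np.asarray(vals)
            aggregate[fam][attr.removeprefix("x_")] = AggregateStats(
                mean=float(arr.mean()),
                sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                min=float(arr.min()),
                max=float(arr.max()),
                n_blocks=len(arr),
            )
    return out, aggregate
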