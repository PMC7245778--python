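"""Readers/writers for the standard flat formats the pipeline touches, plus
the interval algebra every stage reuses.

Coordinate conventions
----------------------
Internally everything is 0-based half-open (:class:`Interval`). Conversion
happens only at format boundaries: GFF3 and 12-column hit tables are 1-based
inclusive on disk (and in :class:`GeneModel` / :class:`TabularHit`, which
mirror their formats), BED is 0-based half-open.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float | None:
    """G+C percentage over unambiguous (ACGT) bases; None if there are none."""
    a = seq.count("A")
    c = seq.count("C")
    g = seq.count("G")
    t = seq.count("T")
    denom = a + c + g + t
    if denom == 0:
        return None
    return 100.0 * (g + c) / denom


@dataclass(frozen=True)
class SeqRecord:
    """One named sequence (scaffold, transcript, CDS, or protein)."""

    id: str
    seq: str
    kind: str = NUCLEOTIDE

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene's scaffold, strand and ordered exons (1-based inclusive).

    Introns and the gene span are derived from the exon list.
    """

    gene_id: str
    scaffold_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    is_coding: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if len(self.exons) < 1:
            raise ValueError(f"gene {self.gene_id}: no exons")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"gene {self.gene_id}: exon end < start")
            if s <= prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons unsorted or overlapping"
                )
            prev_end = e

    @property
    def span_start(self) -> int:
        return self.exons[0][0]

    @property
    def span_end(self) -> int:
        return self.exons[-1][1]

    @property
    def span_length(self) -> int:
        return self.span_end - self.span_start + 1

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps strictly between consecutive exons, 1-based inclusive."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 - e1 > 1:
                out.append((e1 + 1, s2 - 1))
        return tuple(out)

    @property
    def total_exon_bp(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def total_intron_bp(self) -> int:
        return sum(e - s + 1 for s, e in self.introns)

    def spliced_seq(self, scaffold_seq: str) -> str:
        """Exon sequence concatenated 5'->3' (reverse-complemented on '-')."""
        s = "".join(scaffold_seq[a - 1 : b] for a, b in self.exons)
        return revcomp(s) if self.strand == "-" else s


@dataclass(frozen=True)
class TabularHit:
    """One row of 12-column tabular similarity-search output.

    ``sstart > send`` is permitted and denotes a minus-strand subject
    alignment.
    """

    qid: str
    sid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise ValueError(f"hit {self.qid}/{self.sid}: qstart > qend")
        if self.evalue < 0:
            raise ValueError(f"hit {self.qid}/{self.sid}: negative E-value")

    @property
    def query_interval(self) -> Interval:
        return Interval(self.qid, self.qstart - 1, self.qend)


# ---------------------------------------------------------------------------
# sequence IO


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path: str | Path, kind: str = NUCLEOTIDE) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects (file order).

    Lowercase bases are uppercased; duplicated ids and empty records are
    rejected with the offending header named.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ParseError(f"duplicate sequence id {rec.id!r}")
            seq = str(rec.seq).upper()
            if not seq:
                raise ParseError(f"empty record for header {rec.id!r}")
            seen.add(rec.id)
            records.append(SeqRecord(rec.id, seq, kind))
    return records


def write_sequences(records: Iterable[SeqRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# feature IO


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def _read_gff3(path: str | Path) -> list[GeneModel]:
    gene_rows: dict[str, tuple] = {}
    gene_order: list[str] = []
    mrna_parent: dict[str, str] = {}
    mrna_order: dict[str, list[str]] = {}
    parts: dict[tuple[str, str], list[tuple[int, int]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ParseError(f"line {lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols[:9]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinate") from exc
            if end < start:
                raise ParseError(f"line {lineno}: end < start")
            attrs = _parse_gff3_attributes(attr_s)
            if ftype == "gene":
                gid = attrs.get("ID", f"gene_line{lineno}")
                gene_rows[gid] = (seqid, strand, start, end)
                gene_order.append(gid)
            elif ftype in ("mRNA", "transcript"):
                mid = attrs.get("ID", f"mRNA_line{lineno}")
                parent = attrs.get("Parent")
                if parent is None:
                    raise ParseError(f"line {lineno}: {ftype} without Parent")
                mrna_parent[mid] = parent
                mrna_order.setdefault(parent, []).append(mid)
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent")
                if parent is None:
                    raise ParseError(f"line {lineno}: {ftype} without Parent")
                parts.setdefault((parent, ftype), []).append((start, end))
    genes: list[GeneModel] = []
    for gid in gene_order:
        seqid, strand, gstart, gend = gene_rows[gid]
        # first mRNA per gene in file order; gene-level exons as fallback
        exons: list[tuple[int, int]] = []
        is_coding = True
        mrnas = mrna_order.get(gid, [])
        holders = ([mrnas[0]] if mrnas else []) + [gid]
        for holder in holders:
            exons = parts.get((holder, "exon"), []) or parts.get((holder, "CDS"), [])
            if exons:
                is_coding = (holder, "CDS") in parts or not mrnas
                break
        if not exons:
            exons = [(gstart, gend)]
        genes.append(
            GeneModel(gid, seqid, strand, tuple(sorted(exons)), is_coding=is_coding)
        )
    return genes


def _read_bed(path: str | Path) -> list[Interval]:
    out: list[Interval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 3:
                raise ParseError(f"line {lineno}: BED needs >= 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ParseError(f"line {lineno}: end <= start")
            out.append(Interval(cols[0], start, end))
    return out


def read_features(path: str | Path, dialect: str = "gff3"):
    """Read gene models (GFF3, 1-based kept) or intervals (BED, 0-based kept)."""
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "bed":
        return _read_bed(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_gff3(genes: Iterable[GeneModel], path: str | Path, source: str = "glacialis") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            base = f"{g.scaffold_id}\t{source}"
            fh.write(
                f"{base}\tgene\t{g.span_start}\t{g.span_end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mid = f"{g.gene_id}.mRNA1"
            fh.write(
                f"{base}\tmRNA\t{g.span_start}\t{g.span_end}\t.\t{g.strand}\t.\tID={mid};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{base}\texon\t{s}\t{e}\t.\t{g.strand}\t.\tID={mid}.exon{i};Parent={mid}\n"
                )
                if g.is_coding:
                    fh.write(
                        f"{base}\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\tID={mid}.cds;Parent={mid}\n"
                    )


def write_bed(intervals: Iterable[Interval], path: str | Path, names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = f"\t{names[i]}" if names else ""
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}{name}\n")


# ---------------------------------------------------------------------------
# tabular hits


def read_hits_tab(path: str | Path) -> list[TabularHit]:
    """Read 12-column tab-separated similarity hits (outfmt-6 semantics)."""
    hits: list[TabularHit] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ParseError(
                    f"line {lineno}: expected 12 columns, found {len(cols)}"
                )
            try:
                hits.append(
                    TabularHit(
                        qid=cols[0],
                        sid=cols[1],
                        pident=float(cols[2]),
                        length=int(cols[3]),
                        mismatch=int(cols[4]),
                        gapopen=int(cols[5]),
                        qstart=int(cols[6]),
                        qend=int(cols[7]),
                        sstart=int(cols[8]),
                        send=int(cols[9]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return hits


def write_hits_tab(hits: Iterable[TabularHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.qid, h.sid, h.pident, h.length, h.mismatch, h.gapopen,
                        h.qstart, h.qend, h.sstart, h.send, h.evalue, h.bitscore,
                    )
                )
                + "\n"
            )


def repeatmasker_to_bed(path: str | Path) -> list[Interval]:
    """Convert RepeatMasker-style .out tabular annotation to intervals."""
    out: list[Interval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            cols = line.split()
            if not cols or not cols[0].isdigit():
                continue  # header/blank lines
            if len(cols) < 7:
                raise ParseError(f"line {lineno}: truncated RepeatMasker row")
            out.append(Interval(cols[4], int(cols[5]) - 1, int(cols[6])))
    return out


# ---------------------------------------------------------------------------
# interval algebra


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals: sorted, pairwise-disjoint (per contig)."""
    by_contig: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    merged: list[Interval] = []
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(Interval(contig, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(Interval(contig, cur_s, cur_e))
    return merged


def interval_union_coverage(
    intervals: Sequence[Interval], domain_length: int
) -> tuple[list[Interval], int, float]:
    """Merge intervals on one contig and report covered bp and fraction."""
    if not intervals:
        return [], 0, 0.0
    contigs = {iv.contig for iv in intervals}
    if len(contigs) > 1:
        raise ValueError(f"intervals span multiple contigs: {sorted(contigs)}")
    max_end = max(iv.end for iv in intervals)
    if max_end > domain_length:
        raise ValueError(
            f"interval end {max_end} exceeds domain length {domain_length}"
        )
    merged = merge_intervals(intervals)
    covered = sum(len(iv) for iv in merged)
    return merged, covered, covered / domain_length


def overlap_bp(region: Interval, merged: Sequence[Interval]) -> int:
    """Total bp of ``region`` covered by a merged (disjoint) interval set."""
    total = 0
    for iv in merged:
        if iv.contig != region.contig:
            continue
        lo = max(region.start, iv.start)
        hi = min(region.end, iv.end)
        if hi > lo:
            total += hi - lo
    return total
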