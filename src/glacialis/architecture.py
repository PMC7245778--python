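"""Gene-organisation statistics: intergenic regions, gene clusters and their
unidirectionality, strand-change windows, single-exon and nested-gene
censuses, intergenic repeat partition, assembly/gene summary tables,
transcript support, and dark homologous-set classification.

A gene cluster is two or more genes separated by intergenic regions at most
5 kbp long; a cluster is unidirectional when all its members are encoded on
the same strand. Intergenic regions are strand-agnostic (between gene spans
in coordinate order); scaffold-terminal flanks are excluded.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_io import (
    GeneModel,
    Interval,
    SeqRecord,
    TabularHit,
    gc_percent,
    merge_intervals,
    overlap_bp,
)


def group_by_scaffold(genes: Iterable[GeneModel]) -> dict[str, list[GeneModel]]:
    """Genes per scaffold, sorted by span start (then end, then id)."""
    out: dict[str, list[GeneModel]] = {}
    for g in genes:
        out.setdefault(g.scaffold_id, []).append(g)
    for sid in out:
        out[sid].sort(key=lambda g: (g.span_start, g.span_end, g.gene_id))
    return out


@dataclass(frozen=True)
class IntergenicRegion:
    scaffold_id: str
    left_gene: str
    right_gene: str
    length: int
    interval: Interval | None  # None when genes overlap or abut


def intergenic_regions(genes: Iterable[GeneModel]) -> list[IntergenicRegion]:
    """One region per adjacent gene pair per scaffold (terminal flanks
    excluded); overlapping or abutting genes yield length 0."""
    out: list[IntergenicRegion] = []
    for sid, gs in sorted(group_by_scaffold(genes).items()):
        for a, b in zip(gs, gs[1:]):
            length = max(0, b.span_start - a.span_end - 1)
            iv = (
                Interval(sid, a.span_end, b.span_start - 1) if length > 0 else None
            )
            out.append(IntergenicRegion(sid, a.gene_id, b.gene_id, length, iv))
    return out


@dataclass(frozen=True)
class ClusterResult:
    scaffold_id: str
    gene_ids: tuple[str, ...]
    gaps: tuple[int, ...]
    unidirectional: bool

    @property
    def size(self) -> int:
        return len(self.gene_ids)


def cluster_genes(
    genes: Iterable[GeneModel], threshold: int = 5000
) -> tuple[list[ClusterResult], int]:
    """Maximal runs of adjacent genes whose successive intergenic lengths
    are all <= ``threshold``; singletons are not clusters."""
    clusters: list[ClusterResult] = []
    n_clustered = 0
    for sid, gs in sorted(group_by_scaffold(genes).items()):
        run: list[GeneModel] = [gs[0]] if gs else []
        gaps: list[int] = []
        for a, b in zip(gs, gs[1:]):
            gap = max(0, b.span_start - a.span_end - 1)
            if gap <= threshold:
                run.append(b)
                gaps.append(gap)
            else:
                if len(run) >= 2:
                    clusters.append(_make_cluster(sid, run, gaps))
                    n_clustered += len(run)
                run, gaps = [b], []
        if len(run) >= 2:
            clusters.append(_make_cluster(sid, run, gaps))
            n_clustered += len(run)
    return clusters, n_clustered


def _make_cluster(sid: str, run: Sequence[GeneModel], gaps: Sequence[int]) -> ClusterResult:
    strands = {g.strand for g in run}
    return ClusterResult(
        sid,
        tuple(g.gene_id for g in run),
        tuple(gaps),
        unidirectional=len(strands) == 1,
    )


def strand_change_histogram(
    genes: Iterable[GeneModel], window: int = 10, step: int = 1
) -> Counter:
    """Histogram of strand-orientation changes in sliding gene windows.

    A window of ``window`` consecutive genes (coordinate order, within one
    scaffold) contributes the number of adjacent pairs with unequal strand
    (0 .. window-1). Scaffolds with fewer genes than the window contribute
    nothing.
    """
    hist: Counter = Counter()
    for gs in group_by_scaffold(genes).values():
        strands = [g.strand for g in gs]
        for i in range(0, len(strands) - window + 1, step):
            w = strands[i : i + window]
            hist[sum(1 for a, b in zip(w, w[1:]) if a != b)] += 1
    return hist


def single_exon_census(genes: Iterable[GeneModel]) -> tuple[int, float | None]:
    """Count and fraction of genes with exactly one exon."""
    genes = list(genes)
    n_single = sum(1 for g in genes if g.n_exons == 1)
    return n_single, (n_single / len(genes)) if genes else None


@dataclass
class NestedReport:
    """Mapping host gene -> nested genes with their host intron index."""

    hosts: dict[str, list[tuple[str, int]]]

    @property
    def n_nested(self) -> int:
        return sum(len(v) for v in self.hosts.values())

    def introns_occupied(self, host_id: str) -> int:
        return len({i for _, i in self.hosts.get(host_id, [])})


def find_nested_genes(genes: Iterable[GeneModel]) -> NestedReport:
    """Genes whose full span lies within one intron of a multi-exon gene
    (either strand). Intron indices are 1-based in host coordinate order."""
    hosts: dict[str, list[tuple[str, int]]] = {}
    for gs in group_by_scaffold(genes).values():
        multi = [g for g in gs if g.n_exons >= 2]
        for host in multi:
            for idx, (istart, iend) in enumerate(host.introns, 1):
                for g in gs:
                    if g.gene_id == host.gene_id:
                        continue
                    if istart <= g.span_start and g.span_end <= iend:
                        hosts.setdefault(host.gene_id, []).append((g.gene_id, idx))
    return NestedReport(hosts=hosts)


def intergenic_repeat_partition(
    regions: Sequence[IntergenicRegion],
    repeats: Sequence[Interval],
    cutoff: int = 5000,
) -> dict[str, float | None]:
    """Repeat coverage of intergenic regions, split at ``cutoff`` length.

    Returns the covered fraction (sum of overlaps / sum of region lengths)
    for the <=cutoff and >cutoff classes; None for an empty class.
    """
    merged = merge_intervals(repeats) if repeats else []
    by_contig: dict[str, list[Interval]] = {}
    for iv in merged:
        by_contig.setdefault(iv.contig, []).append(iv)
    totals = {"le": 0, "gt": 0}
    covered = {"le": 0, "gt": 0}
    for r in regions:
        if r.length == 0 or r.interval is None:
            continue
        cls = "le" if r.length <= cutoff else "gt"
        totals[cls] += r.length
        covered[cls] += overlap_bp(r.interval, by_contig.get(r.scaffold_id, []))
    return {
        cls: (covered[cls] / totals[cls]) if totals[cls] else None
        for cls in ("le", "gt")
    }


@dataclass(frozen=True)
class AssemblyStats:
    n_scaffolds: int
    total_bp: int
    n50_bp: int
    max_scaffold_bp: int
    gc_percent: float | None


def assembly_stats(scaffolds: Sequence[SeqRecord]) -> AssemblyStats:
    """Scaffold count, total size, N50, maximum length and GC%.

    N50 is the length of the scaffold at which cumulative length (scaffolds
    sorted descending) first reaches half the assembly total. GC% is over
    unambiguous bases only (None if there are none).
    """
    if not scaffolds:
        raise ValueError("no scaffolds")
    lengths = sorted((len(s) for s in scaffolds), reverse=True)
    total = sum(lengths)
    cum = 0
    n50 = lengths[0]
    for L in lengths:
        cum += L
        if cum >= total / 2:
            n50 = L
            break
    return AssemblyStats(
        n_scaffolds=len(scaffolds),
        total_bp=total,
        n50_bp=n50,
        max_scaffold_bp=lengths[0],
        gc_percent=gc_percent("".join(s.seq for s in scaffolds)),
    )


@dataclass(frozen=True)
class GeneStats:
    n_genes: int
    mean_exons_per_gene: float
    mean_exon_length_bp: float
    total_exon_length_bp: int
    pct_genes_with_introns: float
    mean_intron_length_bp: float | None
    total_intron_length_bp: int
    mean_intergenic_length_bp: float | None
    cds_gc_percent: float | None
    pct_single_exon: float


def gene_stats(
    genes: Sequence[GeneModel], scaffolds: Sequence[SeqRecord]
) -> GeneStats:
    """Gene-model summary fields (exon/intron/intergenic metrics, CDS GC%)."""
    if not genes:
        raise ValueError("no genes")
    seqs = {s.id: s.seq for s in scaffolds}
    for g in genes:
        if g.scaffold_id not in seqs:
            raise ValueError(f"gene {g.gene_id}: unknown scaffold {g.scaffold_id}")
        if g.span_start < 1 or g.span_end > len(seqs[g.scaffold_id]):
            raise ValueError(
                f"gene {g.gene_id} exceeds bounds of scaffold {g.scaffold_id}"
            )
    n_genes = len(genes)
    n_exons = sum(g.n_exons for g in genes)
    total_exon = sum(g.total_exon_bp for g in genes)
    introns = [e - s + 1 for g in genes for s, e in g.introns]
    with_introns = sum(1 for g in genes if g.n_exons > 1)
    inter = [r.length for r in intergenic_regions(genes)]
    cds_concat = "".join(
        g.spliced_seq(seqs[g.scaffold_id]) for g in genes if g.is_coding
    )
    n_single, _frac = single_exon_census(genes)
    return GeneStats(
        n_genes=n_genes,
        mean_exons_per_gene=n_exons / n_genes,
        mean_exon_length_bp=total_exon / n_exons,
        total_exon_length_bp=total_exon,
        pct_genes_with_introns=100.0 * with_introns / n_genes,
        mean_intron_length_bp=(sum(introns) / len(introns)) if introns else None,
        total_intron_length_bp=sum(introns),
        mean_intergenic_length_bp=(sum(inter) / len(inter)) if inter else None,
        cds_gc_percent=gc_percent(cds_concat) if cds_concat else None,
        pct_single_exon=100.0 * n_single / n_genes,
    )


def transcript_support(
    genes: Sequence[GeneModel],
    hits: Iterable[TabularHit],
    min_ident: float = 90.0,
    min_cov: float = 50.0,
) -> tuple[dict[str, bool], float]:
    """Flag genes supported by transcript similarity.

    A gene is supported iff some hit (query = gene) has identity strictly
    above ``min_ident`` and alignment length strictly above ``min_cov``
    percent of the gene's spliced length. Hits whose query is not a known
    gene are skipped with a warning.
    """
    lengths = {g.gene_id: g.total_exon_bp for g in genes}
    supported = {gid: False for gid in lengths}
    for h in hits:
        if h.qid not in lengths:
            warnings.warn(f"hit query {h.qid!r} is not a known gene; skipped",
                          stacklevel=2)
            continue
        cov = 100.0 * h.length / lengths[h.qid]
        if h.pident > min_ident and cov > min_cov:
            supported[h.qid] = True
    pct = 100.0 * sum(supported.values()) / len(supported) if supported else 0.0
    return supported, pct


@dataclass
class DarkSetReport:
    dark: dict[str, bool]
    n_sets: int
    n_dark_sets: int
    dark_set_fraction: float | None
    dark_member_fraction: float | None


def classify_dark_sets(
    sets: Mapping[str, Sequence[str]],
    informative: Mapping[str, bool],
) -> DarkSetReport:
    """Classify homologous protein sets as dark.

    A set is dark iff no member has an informative similarity hit (hits
    described only as "uncharacterized" do not count as informative).
    Proteins missing from the annotation table are treated as having no
    hit, with a warning.
    """
    dark: dict[str, bool] = {}
    n_members = 0
    n_dark_members = 0
    for set_id, members in sets.items():
        is_dark = True
        for pid in members:
            if pid not in informative:
                warnings.warn(
                    f"protein {pid!r} has no annotation row; treated as no hit",
                    stacklevel=2,
                )
            elif informative[pid]:
                is_dark = False
        dark[set_id] = is_dark
        n_members += len(members)
        if is_dark:
            n_dark_members += len(members)
    n_sets = len(dark)
    n_dark = sum(dark.values())
    return DarkSetReport(
        dark=dark,
        n_sets=n_sets,
        n_dark_sets=n_dark,
        dark_set_fraction=(n_dark / n_sets) if n_sets else None,
        dark_member_fraction=(n_dark_members / n_members) if n_members else None,
    )
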