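"""Synthetic genomes, transcripts and k-mer histograms with planted truth.

The generator emulates the genome architecture this package analyses:
scaffolds carrying unidirectional tandem blocks of single-exon gene copies
(each block diverged from one ancestor CDS at per-site rate mu, with short
conserved intergenic spacers diverged at their own rate), genes nested inside
introns of multi-exon hosts, (TTG)n microsatellite tracts in intergenic
space, contaminant scaffolds of aberrant base composition, full-length
transcripts carrying a degenerate 22-nt spliced leader with 5' truncation
and 0-4 relic copies, and diploid bimodal k-mer depth histograms.

The mutation model is substitution-only, so identity expectations are
closed-form: two copies diverged at rate mu from a common ancestor share
expected identity (1-mu)^2 + mu^2/3 (~ 1 - 2*mu for small mu).

Every output is a pure function of the seed: a fixed seed yields
byte-identical files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .core_io import (
    GeneModel,
    Interval,
    SeqRecord,
    revcomp,
    write_bed,
    write_gff3,
    write_sequences,
)
from .leader import DINOSL_CONSENSUS
from .repeat_kmer import KmerHistogram

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T


class SimulationError(ValueError):
    """Requested content does not fit the configured scaffolds."""


@dataclass
class SynthConfig:
    """Study conditions for the synthetic genome/transcript generator.

    Defaults plant the structures at the scale the analyses expect: five
    tandem blocks whose internal gaps sit below the 5-kbp clustering
    threshold and whose between-block gaps sit above it, 15 nested genes
    packed three-introns-deep into one host, a 26% single-exon fraction,
    leader probability 0.3 with truncation mass concentrated at consensus
    positions 2 and 8, and CDS/spacer divergence 0.01/0.025 (expected
    identities ~98% and ~95%).
    """

    seed: int = 1
    n_scaffolds: int = 2
    scaffold_len_bp: int = 500_000
    n_gene_blocks: int = 5
    genes_per_block: tuple[int, int] = (3, 6)
    block_strand_mode: str = "unidirectional"  # or "random"
    intra_block_gap_bp: tuple[int, int] = (200, 4000)
    inter_block_gap_bp: tuple[int, int] = (6000, 30000)
    single_exon_fraction: float = 0.26
    n_nested_genes: int = 15
    n_singleton_genes: int = 20
    leader_consensus: str = DINOSL_CONSENSUS
    p_leader: float = 0.3
    relic_count_distribution: dict[int, float] = field(
        default_factory=lambda: {0: 0.6, 1: 0.2, 2: 0.1, 3: 0.05, 4: 0.05}
    )
    truncation_distribution: dict[int, float] = field(
        default_factory=lambda: {
            1: 0.14, 2: 0.42, 3: 0.03, 4: 0.03, 5: 0.03, 6: 0.02, 7: 0.03, 8: 0.30,
        }
    )
    per_base_error: float = 0.0
    ttg_tract_fraction: float = 0.25  # P(an intergenic gap carries a tract)
    block_divergence_mu: float = 0.01
    spacer_divergence_mu: float = 0.025
    n_contaminant_scaffolds: int = 1
    relic_unit: str | None = None  # default: consensus minus first base
    gc_content: float = 0.46

    def validate(self) -> None:
        for name, dist in (
            ("relic_count_distribution", self.relic_count_distribution),
            ("truncation_distribution", self.truncation_distribution),
        ):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, expected 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} has negative mass")
        for name in (
            "n_scaffolds", "scaffold_len_bp", "n_gene_blocks", "n_nested_genes",
            "n_singleton_genes", "n_contaminant_scaffolds",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_leader", "per_base_error", "single_exon_fraction",
                     "ttg_tract_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("genes_per_block", "intra_block_gap_bp", "inter_block_gap_bp"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} is not a valid range")
        if self.block_strand_mode not in ("unidirectional", "random"):
            raise ValueError(f"bad block_strand_mode {self.block_strand_mode!r}")

    @property
    def effective_relic_unit(self) -> str:
        return self.relic_unit or self.leader_consensus[1:]


@dataclass
class SyntheticTruth:
    """Planted ground truth, sufficient to recompute every downstream
    summary exactly when error rates are zero."""

    genes: dict[str, dict] = field(default_factory=dict)
    blocks: list[dict] = field(default_factory=list)
    nested: list[dict] = field(default_factory=list)
    repeats: list[dict] = field(default_factory=list)
    contaminant_scaffolds: list[str] = field(default_factory=list)
    transcripts: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def single_exon_ids(self) -> list[str]:
        return [g for g, info in self.genes.items() if info["n_exons"] == 1]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


class SimulatedGenome(NamedTuple):
    scaffolds: list[SeqRecord]
    genes: list[GeneModel]
    repeats: list[Interval]
    truth: SyntheticTruth


def random_sequence(rng: np.random.Generator, n: int, gc: float = 0.46) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitution-only mutation at per-site ``rate`` (non-ACGT untouched)."""
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = np.array([_BASE_INDEX.get(b, -1) for b in arr])
    hit = (rng.random(len(arr)) < rate) & (idx >= 0)
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit)
        arr[hit] = _BASES[(idx[hit] + shift) % 4]
    return arr.tobytes().decode()


def diverge_sequence(
    ancestor: SeqRecord, mu: float, n_copies: int, seed: int | np.random.Generator = 0
) -> list[SeqRecord]:
    """Independent substitution-mutated copies of an ancestor sequence."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [
        SeqRecord(f"{ancestor.id}_copy{i + 1}", mutate_sequence(ancestor.seq, mu, rng))
        for i in range(n_copies)
    ]


def _sample_from(dist: dict[int, float], rng: np.random.Generator) -> int:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return int(rng.choice(keys, p=probs))


def _random_cds(rng: np.random.Generator, lo: int, hi: int, gc: float) -> str:
    n = 3 * (int(rng.integers(lo, hi + 1)) // 3)
    return random_sequence(rng, max(n, 3), gc)


# ---------------------------------------------------------------------------
# genome


def _build_block(cfg, rng, block_idx: int):
    lo, hi = cfg.genes_per_block
    n = int(rng.integers(lo, hi + 1))
    ancestor_cds = _random_cds(rng, 300, 900, cfg.gc_content)
    glo, ghi = cfg.intra_block_gap_bp
    ancestor_spacer = random_sequence(
        rng, int(rng.integers(glo, ghi + 1)), cfg.gc_content
    )
    if cfg.block_strand_mode == "unidirectional":
        strands = [str(rng.choice(["+", "-"]))] * n
    else:
        strands = [str(rng.choice(["+", "-"])) for _ in range(n)]
    members = []
    for i in range(n):
        cds = mutate_sequence(ancestor_cds, cfg.block_divergence_mu, rng)
        spacer = (
            mutate_sequence(ancestor_spacer, cfg.spacer_divergence_mu, rng)
            if i < n - 1
            else None
        )
        members.append((cds, spacer, strands[i]))
    return {
        "family": f"fam{block_idx:03d}",
        "ancestor_cds": ancestor_cds,
        "ancestor_spacer": ancestor_spacer,
        "mu_cds": cfg.block_divergence_mu,
        "mu_spacer": cfg.spacer_divergence_mu,
        "members": members,
    }


def simulate_genome(cfg: SynthConfig) -> SimulatedGenome:
    """Generate scaffolds, gene models, repeat intervals and planted truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = SyntheticTruth(config={k: str(v) for k, v in asdict(cfg).items()})

    # plan items, round-robin over scaffolds
    n_hosts = -(-cfg.n_nested_genes // 15) if cfg.n_nested_genes else 0
    items: list[tuple[str, int]] = (
        [("block", i) for i in range(cfg.n_gene_blocks)]
        + [("host", i) for i in range(n_hosts)]
        + [("singleton", i) for i in range(cfg.n_singleton_genes)]
    )
    per_scaffold: list[list[tuple[str, int]]] = [[] for _ in range(cfg.n_scaffolds)]
    for j, item in enumerate(items):
        per_scaffold[j % cfg.n_scaffolds].append(item)

    nested_left = cfg.n_nested_genes
    gene_counter = 0
    scaffolds: list[SeqRecord] = []
    genes: list[GeneModel] = []
    repeats: list[Interval] = []

    def next_gid() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"g{gene_counter:05d}"

    for s_idx in range(cfg.n_scaffolds):
        sid = f"scaffold{s_idx + 1}"
        parts: list[str] = []
        cursor = 0

        def emit(seq: str) -> int:
            nonlocal cursor
            start = cursor
            parts.append(seq)
            cursor += len(seq)
            return start

        def emit_gap() -> None:
            lo, hi = cfg.inter_block_gap_bp
            gap = int(rng.integers(lo, hi + 1))
            if rng.random() < cfg.ttg_tract_fraction:
                copies = int(rng.integers(5, 31))
                tract = "TTG" * copies
                pad = max(gap - len(tract), 200)
                a = int(rng.integers(100, pad - 99)) if pad > 200 else pad // 2
                emit(random_sequence(rng, a, cfg.gc_content))
                t0 = emit(tract)
                repeats.append(Interval(sid, t0, t0 + len(tract)))
                truth.repeats.append(
                    {"scaffold": sid, "start": t0, "end": t0 + len(tract),
                     "copies": copies}
                )
                emit(random_sequence(rng, pad - a, cfg.gc_content))
            else:
                emit(random_sequence(rng, gap, cfg.gc_content))

        emit(random_sequence(rng, 1000, cfg.gc_content))
        for kind, idx in per_scaffold[s_idx]:
            if kind == "block":
                spec = _build_block(cfg, rng, idx)
                member_ids = []
                for cds, spacer, strand in spec["members"]:
                    gid = next_gid()
                    genomic = cds if strand == "+" else revcomp(cds)
                    start = emit(genomic)
                    gm = GeneModel(gid, sid, strand, ((start + 1, start + len(cds)),))
                    genes.append(gm)
                    member_ids.append(gid)
                    truth.genes[gid] = {
                        "scaffold": sid, "strand": strand, "role": "block",
                        "family": spec["family"], "n_exons": 1,
                        "exon_bp": len(cds), "intron_bp": 0, "cds": cds,
                    }
                    if spacer is not None:
                        emit(spacer)
                truth.blocks.append(
                    {"family": spec["family"], "scaffold": sid,
                     "members": member_ids, "ancestor_cds": spec["ancestor_cds"],
                     "ancestor_spacer": spec["ancestor_spacer"],
                     "mu_cds": spec["mu_cds"], "mu_spacer": spec["mu_spacer"]}
                )
            elif kind == "host":
                take = min(15, nested_left)
                nested_left -= take
                n_introns = min(3, take) or 1
                share = [take // n_introns] * n_introns
                for i in range(take % n_introns):
                    share[i] += 1
                host_id = next_gid()
                host_strand = str(rng.choice(["+", "-"]))
                exons: list[tuple[int, int]] = []
                nested_here: list[tuple[str, int, str, str]] = []
                exon_len = 200
                start = emit(random_sequence(rng, exon_len, cfg.gc_content))
                exons.append((start + 1, start + exon_len))
                for intron_idx in range(n_introns):
                    emit(random_sequence(rng, 300, cfg.gc_content))
                    for _ in range(share[intron_idx]):
                        gid = next_gid()
                        cds = _random_cds(rng, 300, 600, cfg.gc_content)
                        strand = str(rng.choice(["+", "-"]))
                        genomic = cds if strand == "+" else revcomp(cds)
                        g0 = emit(genomic)
                        genes.append(
                            GeneModel(gid, sid, strand, ((g0 + 1, g0 + len(cds)),))
                        )
                        truth.genes[gid] = {
                            "scaffold": sid, "strand": strand, "role": "nested",
                            "family": None, "n_exons": 1, "exon_bp": len(cds),
                            "intron_bp": 0, "cds": cds,
                        }
                        nested_here.append((gid, intron_idx + 1, strand, cds))
                        emit(random_sequence(rng, 300, cfg.gc_content))
                    e0 = emit(random_sequence(rng, exon_len, cfg.gc_content))
                    exons.append((e0 + 1, e0 + exon_len))
                host = GeneModel(host_id, sid, host_strand, tuple(exons))
                genes.append(host)
                truth.genes[host_id] = {
                    "scaffold": sid, "strand": host_strand, "role": "host",
                    "family": None, "n_exons": len(exons),
                    "exon_bp": host.total_exon_bp,
                    "intron_bp": host.total_intron_bp, "cds": None,
                }
                for gid, intron_idx, strand, _cds in nested_here:
                    truth.nested.append(
                        {"host": host_id, "nested": gid, "intron": intron_idx}
                    )
            else:  # singleton
                gid = next_gid()
                strand = str(rng.choice(["+", "-"]))
                if rng.random() < cfg.single_exon_fraction:
                    cds = _random_cds(rng, 300, 900, cfg.gc_content)
                    genomic = cds if strand == "+" else revcomp(cds)
                    g0 = emit(genomic)
                    gm = GeneModel(gid, sid, strand, ((g0 + 1, g0 + len(cds)),))
                else:
                    n_ex = int(rng.integers(2, 9))
                    exons = []
                    chunks = []
                    for i in range(n_ex):
                        ex_len = int(rng.integers(80, 301))
                        e0 = emit(random_sequence(rng, ex_len, cfg.gc_content))
                        exons.append((e0 + 1, e0 + ex_len))
                        chunks.append(parts[-1])
                        if i < n_ex - 1:
                            emit(random_sequence(rng, int(rng.integers(300, 1501)),
                                                 cfg.gc_content))
                    cds = "".join(chunks)
                    cds = cds if strand == "+" else revcomp(cds)
                    gm = GeneModel(gid, sid, strand, tuple(exons))
                genes.append(gm)
                truth.genes[gid] = {
                    "scaffold": sid, "strand": strand, "role": "singleton",
                    "family": None, "n_exons": gm.n_exons,
                    "exon_bp": gm.total_exon_bp, "intron_bp": gm.total_intron_bp,
                    "cds": cds,
                }
            emit_gap()

        if cursor > cfg.scaffold_len_bp:
            raise SimulationError(
                f"{sid}: planted content ({cursor} bp) exceeds scaffold length "
                f"({cfg.scaffold_len_bp} bp)"
            )
        if cursor < cfg.scaffold_len_bp:
            emit(random_sequence(rng, cfg.scaffold_len_bp - cursor, cfg.gc_content))
        seq = "".join(parts)
        # fill host spliced sequences now that the scaffold exists
        scaffolds.append(SeqRecord(sid, seq))

    for gm in genes:
        info = truth.genes[gm.gene_id]
        if info["cds"] is None:
            info["cds"] = gm.spliced_seq(scaffolds[int(gm.scaffold_id[8:]) - 1].seq)

    for c_idx in range(cfg.n_contaminant_scaffolds):
        sid = f"contam{c_idx + 1}"
        seq = random_sequence(rng, max(cfg.scaffold_len_bp // 5, 1000), 0.72)
        scaffolds.append(SeqRecord(sid, seq))
        truth.contaminant_scaffolds.append(sid)

    return SimulatedGenome(scaffolds, genes, repeats, truth)


def write_genome(sim: SimulatedGenome, out_dir: str | Path, prefix: str = "synthetic") -> dict[str, Path]:
    """Serialise a simulated genome as FASTA + GFF3 + BED + truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / f"{prefix}.fasta",
        "gff3": out_dir / f"{prefix}.gff3",
        "bed": out_dir / f"{prefix}.repeats.bed",
        "truth": out_dir / f"{prefix}.truth.json",
    }
    write_sequences(sim.scaffolds, paths["fasta"])
    write_gff3(sim.genes, paths["gff3"])
    write_bed(sim.repeats, paths["bed"])
    sim.truth.to_json(paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# transcripts


def simulate_transcripts(
    truth: SyntheticTruth,
    cfg: SynthConfig,
    n_transcripts: int | None = None,
    seed: int | None = None,
) -> list[SeqRecord]:
    """Full-length transcripts with planted leaders, relics and errors.

    Bodies are drawn (cyclically) from the coding genes in ``truth``. With
    probability ``p_leader`` a transcript is prefixed by the leader --
    5'-truncated per ``truncation_distribution``, degenerate D resolved
    uniformly to T/A/G -- followed by k relic units (k drawn from
    ``relic_count_distribution``). Per-base substitution errors are applied
    at ``per_base_error``. Labels are appended to ``truth.transcripts``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    bodies = [
        (gid, info["cds"])
        for gid, info in sorted(truth.genes.items())
        if info.get("cds")
    ]
    if not bodies:
        raise ValueError("truth contains no coding genes to transcribe")
    n = len(bodies) if n_transcripts is None else n_transcripts
    relic = cfg.effective_relic_unit
    out: list[SeqRecord] = []
    truth.transcripts.clear()
    for i in range(n):
        gid, body = bodies[i % len(bodies)]
        tid = f"t{i + 1:06d}"
        has_leader = bool(rng.random() < cfg.p_leader)
        l_start = 0
        k = 0
        d_base = ""
        if has_leader:
            l_start = _sample_from(cfg.truncation_distribution, rng)
            k = _sample_from(cfg.relic_count_distribution, rng)
            d_base = str(rng.choice(["T", "A", "G"]))
            resolved = d_base + cfg.leader_consensus[1:]
            prefix = resolved[l_start - 1 :] + relic * k
        else:
            prefix = ""
        seq = mutate_sequence(prefix + body, cfg.per_base_error, rng)
        out.append(SeqRecord(tid, seq))
        truth.transcripts.append(
            {"id": tid, "gene": gid, "has_leader": has_leader,
             "leader_start_position": l_start, "relic_count": k,
             "d_base": d_base}
        )
    return out


# ---------------------------------------------------------------------------
# k-mer histograms


def simulate_kmer_histogram(
    haploid_size_bp: int,
    het_peak_depth: float,
    error_rate: float = 0.0,
    seed: int = 0,
    het_fraction: float = 0.5,
    k: int = 21,
) -> KmerHistogram:
    """Diploid bimodal k-mer depth histogram with known haploid size.

    Heterozygous k-mers (haplotype-specific; ``2 * het_fraction *
    haploid_size_bp`` of them) draw Poisson depths around ``het_peak_depth``
    (c); homozygous k-mers draw around 2c. Total usable mass is then 2c *
    haploid_size_bp regardless of the heterozygous fraction, so the haploid
    size is recoverable as mass / (2c). ``error_rate`` adds a spike of
    depth-1/2 k-mers mimicking sequencing errors.
    """
    if het_peak_depth < 8:
        warnings.warn(
            f"het peak depth {het_peak_depth} < 8: peaks may not be resolvable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n_het = int(round(2 * het_fraction * haploid_size_bp))
    n_hom = int(round((1 - het_fraction) * haploid_size_bp))
    depths = np.concatenate(
        [
            rng.poisson(het_peak_depth, size=n_het),
            rng.poisson(2 * het_peak_depth, size=n_hom),
        ]
    )
    depths = depths[depths > 0]
    binc = np.bincount(depths)
    counts = {int(d): int(c) for d, c in enumerate(binc) if d > 0 and c > 0}
    if error_rate > 0:
        mass = int(depths.sum())
        n_err = int(round(mass * error_rate))
        counts[1] = counts.get(1, 0) + n_err
        counts[2] = counts.get(2, 0) + n_err // 4
    return KmerHistogram(counts=counts, k=k)
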