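"""Simple-repeat (motif-run) detection, k-mer profiling, and peak-based
genome-size estimation from k-mer depth histograms.

Genome size from k-mers: for a diploid genome the depth histogram of
distinct k-mers is bimodal, with haplotype-specific (heterozygous) k-mers
peaking at depth c and shared (homozygous) k-mers at 2c. With usable k-mer
mass M = sum(depth * count) above the error cutoff, M/c estimates the
diploid assembly size and M/(2c) the haploid size.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core_io import Interval, SeqRecord, merge_intervals, revcomp


@dataclass
class KmerHistogram:
    """Map depth -> count of distinct k-mers, for fixed k."""

    counts: dict[int, int]
    k: int = 21

    def __post_init__(self) -> None:
        self.counts = {int(d): int(c) for d, c in self.counts.items()}
        if any(d < 1 or c < 0 for d, c in self.counts.items()):
            raise ValueError("histogram depths must be >= 1 and counts >= 0")

    @property
    def total_mass(self) -> int:
        return sum(d * c for d, c in self.counts.items())

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for d in sorted(self.counts):
                fh.write(f"{d}\t{self.counts[d]}\n")

    @classmethod
    def read(cls, path: str | Path, k: int = 21) -> "KmerHistogram":
        counts: dict[int, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                d, c = line.split()[:2]
                counts[int(d)] = int(c)
        return cls(counts=counts, k=k)


@dataclass(frozen=True)
class GenomeSizeEstimate:
    """Peak-based size estimates; the first (heterozygous) peak gives the
    diploid size, the second (homozygous) peak the haploid size."""

    error_cutoff_depth: int
    het_peak_depth: int
    hom_peak_depth: int
    usable_kmer_mass: int
    size_from_first_peak: float  # diploid, bp
    size_from_second_peak: float  # haploid, bp

    def __post_init__(self) -> None:
        if not self.het_peak_depth < self.hom_peak_depth:
            raise ValueError("peak depths must satisfy c1 < c2")


class UnimodalHistogramError(ValueError):
    """The histogram has a single usable peak; a haploid interpretation
    (size = mass / peak depth) is attached as ``fallback_size``."""

    def __init__(self, message: str, fallback_size: float, peak_depth: int):
        super().__init__(message)
        self.fallback_size = fallback_size
        self.peak_depth = peak_depth


# ---------------------------------------------------------------------------
# motif runs


def _motif_forms(motif: str) -> list[str]:
    rotations = {motif[i:] + motif[:i] for i in range(len(motif))}
    return sorted(rotations | {revcomp(r) for r in rotations})


def find_motif_runs(
    seq: SeqRecord | str, motif: str = "TTG", min_copies: int = 3
) -> tuple[list[Interval], float]:
    """Locate tandem runs of a trinucleotide motif in all six forms.

    The motif's three rotations and their reverse complements (e.g. TTG,
    TGT, GTT, CAA, AAC, ACA) are interchangeable; runs of at least
    ``min_copies`` complete copies of any form are found, then overlapping
    or abutting runs are merged. Returns the merged intervals and the
    fraction of the sequence they cover. Ambiguous bases never match, so N
    breaks runs.
    """
    if len(motif) != 3:
        raise ValueError("motif must be a trinucleotide")
    if isinstance(seq, SeqRecord):
        contig, s = seq.id, seq.seq
    else:
        contig, s = "seq", seq
    s = s.upper()
    runs: list[Interval] = []
    for form in _motif_forms(motif):
        pattern = re.compile(f"(?:{form}){{{min_copies},}}")
        for m in pattern.finditer(s):
            runs.append(Interval(contig, m.start(), m.end()))
    if not runs:
        return [], 0.0
    # merge abutting as well as overlapping runs
    merged: list[Interval] = []
    for iv in sorted(runs, key=lambda i: (i.start, i.end)):
        if merged and iv.start <= merged[-1].end:
            last = merged.pop()
            iv = Interval(contig, last.start, max(last.end, iv.end))
        merged.append(iv)
    covered = sum(len(iv) for iv in merged)
    return merged, covered / len(s)


# ---------------------------------------------------------------------------
# k-mer profiling


def kmer_profile(
    seqs: Iterable[SeqRecord],
    k: int = 3,
    sample_rate: float = 1.0,
    seed: int = 0,
    top_n: int = 10,
) -> tuple[dict[str, float], list[tuple[str, float]]]:
    """Frequencies of overlapping k-mers on the given strand.

    Sequences are subsampled Bernoulli(``sample_rate``) with a fixed seed
    (mimicking read subsampling before counting); windows containing N are
    skipped. Frequencies sum to 1 over counted windows. Counting is
    strand-specific, not canonical, so e.g. TTG, TGT and GTT are reported
    separately.
    """
    if not 0.0 < sample_rate <= 1.0:
        raise ValueError("sample_rate must be in (0, 1]")
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    total = 0
    for rec in seqs:
        if sample_rate < 1.0 and rng.random() >= sample_rate:
            continue
        s = rec.seq.upper()
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if any(c not in "ACGT" for c in w):
                continue
            counts[w] = counts.get(w, 0) + 1
            total += 1
    if total == 0:
        return {}, []
    freqs = {w: c / total for w, c in sorted(counts.items())}
    top = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return freqs, top


def kmer_depth_histogram(
    reads: Iterable[SeqRecord], k: int, canonical: bool = True
) -> KmerHistogram:
    """Tally distinct k-mer multiplicities into a depth histogram.

    With ``canonical`` set, a k-mer and its reverse complement are counted
    as one (the lexicographic minimum), as standard k-mer counters do.
    """
    multiplicity: dict[str, int] = {}
    for rec in reads:
        s = rec.seq.upper()
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if any(c not in "ACGT" for c in w):
                continue
            if canonical:
                w = min(w, revcomp(w))
            multiplicity[w] = multiplicity.get(w, 0) + 1
    counts: dict[int, int] = {}
    for depth in multiplicity.values():
        counts[depth] = counts.get(depth, 0) + 1
    return KmerHistogram(counts=counts, k=k)


# ---------------------------------------------------------------------------
# genome-size estimation


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(float)
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="same")


def estimate_genome_size(
    hist: KmerHistogram, smoothing_window: int = 3
) -> GenomeSizeEstimate:
    """Bimodal-peak genome-size estimate from a k-mer depth histogram.

    The histogram is smoothed with a moving average; the error cutoff is
    the first local minimum (the depth at which the initial error-driven
    decline turns around; zero when the histogram rises from the start).
    The two largest smoothed local maxima above the cutoff give the
    heterozygous (c1) and homozygous (c2) peak depths; usable mass
    M = sum(d * count, d > cutoff) yields the diploid (M/c1) and haploid
    (M/c2) size estimates.
    """
    if not hist.counts:
        raise ValueError("empty histogram")
    max_depth = max(hist.counts)
    arr = np.zeros(max_depth + 2)
    for d, c in hist.counts.items():
        arr[d] = c
    s = _smooth(arr, smoothing_window)

    if s[2] > s[1]:
        cutoff = 0
    else:
        cutoff = 0
        for d in range(1, max_depth):
            if s[d + 1] > s[d]:
                cutoff = d
                break
    usable = [(d, c) for d, c in hist.counts.items() if d > cutoff]
    mass = sum(d * c for d, c in usable)

    maxima = [
        d
        for d in range(max(cutoff + 1, 1), max_depth + 1)
        if s[d] > s[d - 1] and s[d] >= s[d + 1]
    ]
    if len(maxima) < 2:
        peak = maxima[0] if maxima else max(usable, key=lambda dc: dc[1])[0]
        raise UnimodalHistogramError(
            "histogram is unimodal above the error cutoff; for a haploid "
            f"genome interpret size as mass/peak = {mass / peak:.0f} bp",
            fallback_size=mass / peak,
            peak_depth=peak,
        )
    top_two = sorted(sorted(maxima, key=lambda d: -s[d])[:2])
    c1, c2 = top_two
    return GenomeSizeEstimate(
        error_cutoff_depth=cutoff,
        het_peak_depth=c1,
        hom_peak_depth=c2,
        usable_kmer_mass=mass,
        size_from_first_peak=mass / c1,
        size_from_second_peak=mass / c2,
    )
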