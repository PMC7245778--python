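"""Scaffold screening rules for assemblies: contaminant flagging by hit
coverage, organelle flagging by single-hit reference coverage, and
GC/length outlier detection.

A scaffold is a putative contaminant when more than 10% of its length is
covered by the union of strong similarity hits (bit score > 1000,
E <= 1e-20) to a contaminant database. A scaffold is flagged as organelle
when a single hit against an organelle reference gene covers more than 75%
of the reference at E <= 1e-10. GC/length outliers are formalised as a
z-score rule on GC% and log10 length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import Interval, SeqRecord, TabularHit, gc_percent, merge_intervals

RETAIN = "retain"
CONTAMINANT = "contaminant"
PLASTID = "plastid"
MITOCHONDRIAL = "mitochondrial"
GC_OUTLIER = "gc_outlier"


@dataclass
class ScreenReport:
    """One verdict per scaffold plus the numbers supporting it."""

    verdicts: dict[str, str]
    details: dict[str, dict] = field(default_factory=dict)

    def flagged(self, verdict: str) -> list[str]:
        return sorted(s for s, v in self.verdicts.items() if v == verdict)


def flag_contaminants(
    scaffold_lengths: Mapping[str, int],
    hits: Iterable[TabularHit],
    min_bitscore: float = 1000.0,
    max_evalue: float = 1e-20,
    max_cov_pct: float = 10.0,
) -> ScreenReport:
    """Flag scaffolds whose qualifying-hit coverage exceeds the threshold.

    Query intervals of hits with bit score strictly above ``min_bitscore``
    and E-value at most ``max_evalue`` are unioned per scaffold; a scaffold
    is a contaminant iff the covered fraction exceeds ``max_cov_pct``/100.
    """
    per_scaffold: dict[str, list[Interval]] = {sid: [] for sid in scaffold_lengths}
    for h in hits:
        if h.qid not in scaffold_lengths:
            raise ValueError(f"hit query {h.qid!r} is not a known scaffold")
        if h.qend > scaffold_lengths[h.qid]:
            raise ValueError(
                f"hit on {h.qid} ends at {h.qend}, beyond scaffold length "
                f"{scaffold_lengths[h.qid]}"
            )
        if h.bitscore > min_bitscore and h.evalue <= max_evalue:
            per_scaffold[h.qid].append(h.query_interval)
    verdicts: dict[str, str] = {}
    details: dict[str, dict] = {}
    for sid, ivs in per_scaffold.items():
        covered = sum(len(iv) for iv in merge_intervals(ivs)) if ivs else 0
        frac = covered / scaffold_lengths[sid]
        verdicts[sid] = CONTAMINANT if frac > max_cov_pct / 100.0 else RETAIN
        details[sid] = {"covered_bp": covered, "covered_fraction": frac}
    return ScreenReport(verdicts=verdicts, details=details)


def flag_organelle(
    hits: Iterable[TabularHit],
    ref_lengths: Mapping[str, int],
    min_cov_pct: float = 75.0,
    max_evalue: float = 1e-10,
    label: str = PLASTID,
    cov_of: str = "reference",
    scaffold_lengths: Mapping[str, int] | None = None,
) -> ScreenReport:
    """Flag scaffolds with a strong single hit to an organelle reference.

    Hits are organelle-reference (query) vs scaffold (subject) comparisons.
    A scaffold is flagged iff some hit at E <= ``max_evalue`` covers more
    than ``min_cov_pct`` percent of the reference length by itself (no
    union over hits). ``cov_of='scaffold'`` switches the denominator to the
    scaffold length.
    """
    if label not in (PLASTID, MITOCHONDRIAL):
        raise ValueError(f"label must be {PLASTID!r} or {MITOCHONDRIAL!r}")
    if cov_of not in ("reference", "scaffold"):
        raise ValueError("cov_of must be 'reference' or 'scaffold'")
    verdicts: dict[str, str] = {}
    details: dict[str, dict] = {}
    for h in hits:
        if h.qid not in ref_lengths:
            raise ValueError(f"unknown organelle reference id {h.qid!r}")
        if cov_of == "reference":
            denom = ref_lengths[h.qid]
            aln_span = h.qend - h.qstart + 1
        else:
            if scaffold_lengths is None or h.sid not in scaffold_lengths:
                raise ValueError(f"no length for scaffold {h.sid!r}")
            denom = scaffold_lengths[h.sid]
            aln_span = abs(h.send - h.sstart) + 1
        cov = 100.0 * aln_span / denom
        best = details.setdefault(h.sid, {"best_cov_pct": 0.0, "best_ref": None})
        if cov > best["best_cov_pct"]:
            best["best_cov_pct"] = cov
            best["best_ref"] = h.qid
        if h.evalue <= max_evalue and cov > min_cov_pct:
            verdicts[h.sid] = label
        else:
            verdicts.setdefault(h.sid, RETAIN)
    return ScreenReport(verdicts=verdicts, details=details)


def gc_length_outliers(
    scaffolds: Sequence[SeqRecord], z: float = 3.0
) -> ScreenReport:
    """Flag scaffolds whose GC% or log10 length falls outside the fitted
    normal range (|z-score| > ``z`` on either axis).

    With fewer than 10 scaffolds no meaningful fit exists: a warning is
    issued and nothing is flagged.
    """
    verdicts = {s.id: RETAIN for s in scaffolds}
    details: dict[str, dict] = {}
    if len(scaffolds) < 10:
        warnings.warn(
            f"only {len(scaffolds)} scaffolds: too few for an outlier fit",
            stacklevel=2,
        )
        return ScreenReport(verdicts=verdicts, details=details)
    gc = np.array([gc_percent(s.seq) or 0.0 for s in scaffolds])
    loglen = np.log10([len(s) for s in scaffolds])
    gc_mu, gc_sd = gc.mean(), gc.std()
    ll_mu, ll_sd = loglen.mean(), loglen.std()
    for i, s in enumerate(scaffolds):
        z_gc = (gc[i] - gc_mu) / gc_sd if gc_sd > 0 else 0.0
        z_ll = (loglen[i] - ll_mu) / ll_sd if ll_sd > 0 else 0.0
        details[s.id] = {"z_gc": float(z_gc), "z_loglen": float(z_ll)}
        if not math.isinf(z) and (abs(z_gc) > z or abs(z_ll) > z):
            verdicts[s.id] = GC_OUTLIER
    return ScreenReport(verdicts=verdicts, details=details)
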