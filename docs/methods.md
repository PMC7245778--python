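# Methods

This note documents the models and rules implemented in `glacialis`, the
choices made where the underlying procedures were open, and what the
synthetic-data validation does and does not demonstrate.

## Coordinate conventions

All internal interval arithmetic is 0-based half-open. GFF3 gene models and
12-column hit tables keep their native 1-based inclusive coordinates in
`GeneModel`/`TabularHit`; BED stays 0-based half-open. Conversion happens
only at format boundaries, so no analysis stage ever reinterprets
coordinates. Ambiguity codes other than N are read but treated as N by the
k-mer and repeat scanners. When a gene has several mRNAs, the first in file
order is used (the intended inputs carry one model per gene).

## Spliced-leader detection

The leader model is the 22-nt DinoSL consensus `DCCGTAGCCATTTTGGCTCAAG`
with degenerate first base D = T/A/G, trans-spliced onto the mature mRNA
5′ end. Acceptance rules for a primary leader on a transcript:

- transcript-side alignment start ≤ `t_max_start` (default 5, 1-based);
- leader-side alignment end ≥ `min_leader_end` (default 20, on the 22-nt
  consensus, 1-based);
- no gaps, at most `max_mismatch` (default 1) mismatches.

Instead of a heuristic short-word search followed by filtering, the scan is
exhaustive and ungapped: at these query lengths exhaustive scanning is
exact, and the acceptance rules — not the search engine — define the
result. Two scanning choices deserve explanation:

**Candidate registers are 5′-flush.** A candidate either starts at the
transcript's first base with a 5′-truncated leader (`t_start = 1`,
`l_start ≥ 1`), or carries a complete leader after a few extra transcript
bases (`t_start ≥ 1`, `l_start = 1`). Each candidate extends ungapped to
the end of the consensus (or the transcript) and mismatches are counted
over the whole window. Allowing both sides to be trimmed simultaneously
would let a mismatching 5′ flank be discarded; the known non-canonical
leader variant `ATCGTAGCCATGTTGGCTCAAG`, which carries two in-register
mismatches to every consensus expansion, would then be accepted via a
doubly-trimmed register that hides one of them. Under the flush rule it is
rejected, as intended. Ties among accepted candidates are broken by longest
alignment, then fewest mismatches, then smallest transcript start, then
smallest leader start (the underlying procedure is silent on ties).

**The leader-side start is bounded** by `max_leader_start` (default 8, the
3′-most of the conserved CC dinucleotide positions). The acceptance rules
alone accept arbitrarily short consensus suffixes (down to 2–3 nt), at
which point essentially every transcript matches by chance; a short-word
similarity search imposes a comparable bound implicitly through its word
size and E-value. With the default bound, the chance-match probability for
a random transcript is ~1e-5, so recovery statistics on realistic sets are
effectively free of false positives. Transcripts truncated beyond position
8 are not distinguishable from chance under these rules and are not
reported; the bound is a parameter.

**Relic leaders.** Relic copies of the leader accumulate downstream of the
primary leader through cycles of transcript re-integration and
re-expression. For k = `max_relics` (8) down to 1, the query
`consensus + relic_unit^k` is aligned ungapped; k is accepted when a hit
starts within the first `relic_q_start_max` (11) bases of the query
(allowing transcript truncation) and the first `relic_t_start_max` (5)
bases of the transcript, and ends within `relic_end_slack` (5) bases of the
query end. Mismatches are budgeted per query segment: the consensus segment
inherits the primary match's mismatch count and each relic unit tolerates
at most `relic_max_mismatch_per_unit` (default 2). A pooled budget of
2k mismatches would be absorbed almost entirely by the trailing,
partially-aligned unit — only ~16 columns separate k from k+1 — and
over-count relics by one on a measurable fraction of transcripts; the
per-unit budget keeps planted counts exactly recoverable. The literal relic
unit sequence is not established in the literature; the default is the
consensus with the degenerate first base dropped
(`CCGTAGCCATTTTGGCTCAAG`), configurable via `LeaderParams.relic_unit`.

The start-position histogram reports the leader-side start (`l_start`) of
the accepted alignment, as a percentage of leader-bearing transcripts.

## Gene organisation

- **Intergenic regions** are strand-agnostic gaps between gene spans in
  coordinate order; overlapping or abutting genes contribute length 0, and
  scaffold-terminal flanks are excluded (also from the mean intergenic
  length in the summary table).
- **Clusters** are maximal runs of adjacent genes with successive
  intergenic lengths ≤ 5000 bp (the boundary is inclusive; the threshold is
  exposed). Singletons are not clusters. A cluster is unidirectional when
  all members share a strand.
- **Strand-change windows** slide with step 1 (exposed) within scaffolds;
  each window of 10 genes contributes its count of adjacent unequal-strand
  pairs.
- **Nested genes** must lie wholly inside a single intron of a multi-exon
  host; the nested gene's strand is unrestricted.
- **N50** is the length of the scaffold at which cumulative length
  (descending order) first reaches half the assembly total; GC% is computed
  over unambiguous bases and reported as undefined for all-N input.
- **Transcript support** requires a hit with identity strictly > 90%
  whose alignment length exceeds 50% of the gene's spliced (total-exon)
  length; the spliced length is used as the denominator because support
  comes from transcripts, which lack introns.
- **Dark sets** are homologous protein sets in which no member has an
  informative similarity hit; hits described only as "uncharacterized" are
  recorded as non-informative upstream of this classification.

## Tandem arrays and conservation

Families are connected components (single linkage) of the graph whose
edges are hits with E ≤ 1e-10 covering > 50% of query or subject. Tandem
blocks are maximal same-family runs in gene order allowing at most one
intervening gene of another family (exposed as `max_intervening`; this
mirrors the common `-b 1` block setting of synteny tools). The per-block
statistic x is the mean pairwise percent identity over all member pairs —
one optimal global alignment per pair, rather than a union of local hits —
computed separately for proteins, CDS, and the intergenic spacers between
consecutive members. Alignment scores are fixed (match +1, mismatch −1,
gap open −2, gap extend −1, the first gap column costing the open
penalty); identity is matches over aligned columns, counting internal gap
columns and excluding terminal gaps. Zero-length spacers are skipped with
a warning. Per family, x is aggregated over blocks as mean, sample
standard deviation (0 for a single block), minimum and maximum.

## Repeats and k-mers

(TTG)n detection treats the three rotations and their reverse complements
(TTG, TGT, GTT, CAA, ACA, AAC) as one pattern: runs of ≥ `min_copies`
(default 3) complete copies of any form are located and overlapping or
abutting runs merged; coverage is merged bp over sequence length. The
copy-number cutoff is a parameter because masking tools leave it implicit.
N never matches, so ambiguity breaks runs.

3-mer profiles count overlapping k-mers on the given strand only —
canonical counting would conflate TTG/TGT/GTT with their complements,
which the standard reports keep separate. Windows containing N are
skipped; read subsampling mimics the usual practice of profiling a few
percent of reads, implemented as Bernoulli-per-sequence with a fixed seed.

Genome-size estimation assumes a diploid k-mer depth histogram: a
heterozygous peak at depth c and a homozygous peak at 2c. The histogram is
smoothed with a moving average (window 3, exposed); the error cutoff is
the first local minimum of the smoothed curve (0 when the histogram rises
from the start); the two largest smoothed maxima above the cutoff give
c1 < c2; usable mass M = Σ d·count over d > cutoff yields the diploid
(M/c1) and haploid (M/c2) sizes. A unimodal histogram raises an error that
carries the haploid interpretation M/c as a fallback. Peak-position
discretisation limits accuracy to roughly one part in c, which is why the
recovery check uses a 5% band. Cross-k averaging of estimates (k = 17–31
is the usual sweep) is left to the caller, since it requires the read data
rather than a single histogram.

## Screening

The contaminant rule unions qualifying hit intervals per scaffold
(bit score strictly > 1000, E ≤ 1e-20) and flags scaffolds whose covered
fraction exceeds 10%. The organelle rule is deliberately per-hit, not a
union: a single hit must cover > 75% of the organelle reference at
E ≤ 1e-10 (the denominator can be switched to the scaffold). The GC/length
outlier rule formalises "outside the expected normal distribution" as
|z| > 3 on GC% or log10 length, fitted over all scaffolds; with fewer than
10 scaffolds no fit is attempted.

## Synthetic data generator

The generator plants, with byte-identical output for a fixed seed:

- tandem blocks of single-exon gene copies, each block diverged from one
  ancestor CDS at per-site substitution rate `block_divergence_mu`
  (default 0.01) with spacers from one ancestor spacer at
  `spacer_divergence_mu` (default 0.025) — the defaults reproduce the
  ~98% coding / ~95% spacer identity contrast typical of conserved tandem
  arrays. Substitution-only mutation keeps identity expectations in closed
  form: E[identity] = (1−μ)² + μ²/3 ≈ 1 − 2μ;
- within-block gaps of 200–4000 bp and between-item gaps of 6000–30000 bp,
  deliberately straddling the 5-kbp clustering threshold so both cluster
  classes exist;
- multi-exon host genes whose introns contain nested single-exon genes
  (15 nested genes pack into three introns of one host);
- filler genes that are single-exon with probability
  `single_exon_fraction` (default 0.26);
- (TTG)n tracts (5–30 copies) in intergenic gaps, each gap carrying one
  with probability `ttg_tract_fraction`;
- one or more contaminant scaffolds with aberrant GC (72%) and length;
- transcripts that carry a leader with probability `p_leader` (default
  0.3), truncated per `truncation_distribution` (default mass concentrated
  at consensus positions 2 and 8, ~72% combined, matching the observed
  preference for the double-cytosine start sites), with relic count drawn
  from `relic_count_distribution` and uniform per-base substitution errors;
- diploid k-mer histograms with Poisson depth components at c and 2c.
  Heterozygous k-mers number 2·f·G and homozygous (1−f)·G for haploid size
  G, so the usable mass is 2cG regardless of the heterozygous fraction f
  and the haploid size is recoverable as mass/(2c).

Truth labels (per-gene roles, block membership and ancestors, nested
pairs, repeat tracts, per-transcript leader/relic labels, contaminant ids)
are serialised as JSON alongside the FASTA/GFF3/BED outputs and suffice to
recompute every downstream summary exactly when error rates are zero.

What the generator does **not** emulate: indels and structural variation
(mutation is substitution-only), sequencing-read error profiles and
quality values, repeat families beyond microsatellite tracts, isoform
structure, GC heterogeneity along scaffolds, and genome-scale gene counts.
Passing recovery tests therefore demonstrates the correctness of the
decision rules and statistics on cleanly planted structure, not robustness
to assembly artefacts or alignment ambiguity in real data.

## Problem sizes used in validation

The recovery checks run on genomes of a few hundred kbp with tens of genes,
transcript sets of 1000–2000, and k-mer histograms equivalent to a 0.5-Mbp
haploid genome at 30× — sizes chosen so the full validation executes in
seconds while every statistic still has enough support to be meaningful
(binomial noise on a 2000-transcript leader fraction is ±1 point at one
standard deviation, and exact-recovery checks are noise-free by
construction).

## Known limitations

- The leader matcher's chance-match floor depends on `max_leader_start`;
  loosening it toward 22 re-admits trivial suffix matches.
- Family construction is single-linkage and will chain families through
  promiscuous members, exactly as the underlying graph rule implies.
- `estimate_genome_size` assumes two resolvable peaks; heterozygosity low
  enough to suppress the c peak, or coverage below ~8×, defeats it (a
  warning is raised by the simulator in that regime).
- The per-hit organelle rule cannot flag references covered only by
  several sub-75% fragments; switch `cov_of` or pre-merge hits if that
  behaviour is wanted.
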