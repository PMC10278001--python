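# Methods

omegakit implements the three bespoke computational procedures behind an
IS200/605-family TnpB ortholog survey — omegaRNA 5′ processing-site calling
from RACE reads, target-adjacent motif (TAM) discovery from an 8N randomized
cleavage screen, and guide–scaffold (RE) boundary detection from alignment
conservation — together with seeded generators that emulate each assay's
statistical structure. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
establish about real data.

## Coordinate and strand conventions

All coordinates are 0-based, half-open, on the plus strand of the supplied
template; BED output uses the identical convention so no conversion happens at
I/O boundaries, and 1-based positions appear only in log messages, flagged as
such. Loci are stored plus-strand: a minus-strand locus must be
reverse-complemented before annotation, which keeps the RACE and TAM logic
strand-free. Input sequences admit only A/C/G/T/N; the degenerate IUPAC
alphabet is reserved for motif output.

## 5′ RACE start-site calling

**Generator.** A RACE library is modelled as a mixture: with probability
`1 − background_rate` a read's 5′ end is `round(site + N(0, jitter_sd))`
clipped into the template (sites drawn by their weights), and with probability
`background_rate` it is uniform over the template (degradation and premature
RT stops). Reads extend 3′-ward to `read_length` (default 300, a standard
long single-end run) or the template end, carry a fixed 26-nt 5′ adaptor, and
accumulate independent per-base substitutions (default 0.1%, a
substitution-dominated short-read error model; indels are not modelled). The
discretized Gaussian is the simplest jitter law that exposes the caller's
aggregation behaviour; the discrete alternate start sites seen in real
libraries are represented by multiple weighted sites instead.

**Caller.** Adaptor trimming is a Hamming prefix match (default tolerance 1
substitution); untrimmed and post-trim-empty reads are excluded and counted.
Mapping anchors each read's first `min_anchor` bases (default 20) against
every template offset, ungapped; a read maps where the mismatch count is
lowest, ties to the leftmost offset, and only if the mismatch rate is at most
`max_mismatch_rate` (default 0.1). Ungapped anchoring is sufficient because
the assay captures contiguous 5′ sequence; splice- or gap-aware mapping is a
non-goal.

Start classification works on *peaks*, not single positions: the highest
remaining position absorbs all counts within `cluster_radius` (default 2)
positions, is scored as its cluster's fraction of mapped starts, and the
process repeats on the remainder. Clustering is essential, not cosmetic:
under ±1-position jitter a discretized Gaussian puts only ~38% of its mass on
the modal coordinate, so no single-position rule can recognise an
unambiguous site; a ±2 radius captures ~99% of a site's mass while keeping
well-separated sites distinct. The locus is `clear` when exactly one peak
holds ≥ `dominant_frac` (default 0.5) of mapped starts — the quantification
of "a substantial portion of reads at a single start site" — `multiple` when
at least two peaks each hold ≥ `secondary_frac` (default 0.2) with none
dominant, and `none` otherwise, including whenever fewer than `min_mapped`
(default 50) reads mapped. Peak ties break to the smaller (5′-most)
coordinate, consistent with the longest-species fallback. When no site can be
called, the 5′-most observed start — the longest RNA species — is used for
annotation.

The scaffold annotation runs from the called start to the locus's RE
boundary; a call at or past the boundary is an error. With a 20-nt guide this
reproduces the expected bookkeeping: a 126-nt processed species implies a
106-nt scaffold, and 59 nt of unprocessed 3′ padding yields a 185-nt species
without changing the call, because the caller only ever reads 5′ structure.

## 8N TAM screen

**Generator.** Each of `n_library` molecules (default 50,000) carries two
constant backbone anchors around eight uniform random bases. A molecule
enters the cleaved library with probability `cleave_rate_match` (default 0.9)
when its window matches the ground-truth motif (IUPAC-aware, anchored at a
configurable offset, default 0) and `cleave_rate_background` (default 0.001)
otherwise; all molecules enter the input library. Substitution errors are
applied per library after selection, so molecule identity (read id) is
conserved. These defaults place a 4-mer motif at roughly 225 cleaved windows
(~78% signal) and a 5-mer at roughly 95 (~47% signal) — a deliberately hard
operating point in which the 5-mer's motif-base frequency is only ~0.60
against the 0.133 of each other base.

**Analysis.** Window extraction requires both anchors (Hamming tolerance 1
each) separated by exactly eight bases, leftmost placement, N-free windows.
Enrichment is `log2((f_cleaved)/(f_input))` with Laplace pseudocount 1.0 on
every count cell, and per-position information content is the KL divergence
in bits of cleaved from input frequencies, floored at zero. Normalizing
against the *sequenced input library* rather than a uniform assumption
absorbs synthesis bias in real 8N pools; a uniform background remains
available (`input_table=None`). The model is position-independent — no
dinucleotide coupling — matching the short, low-degeneracy motifs the screen
is meant to detect.

Positions with information content ≥ `ic_call_threshold` are called; the
called span is the minimal contiguous interval covering them, and every
position inside the span contributes its bases with cleaved frequency ≥
`base_include_frac` (default 0.25) to the IUPAC consensus. Letting interior
span positions contribute even when individually below threshold makes
recovery of a 5-mer depend only on its two end positions, which materially
stabilises calls at low cleaved depth. `active` additionally requires at
least `min_total_windows` cleaved windows.

**Threshold calibration.** The defaults `ic_call_threshold = 0.15` bits and
`min_total_windows = 70` were fixed by an operating-characteristic analysis
on the generator at its default conditions, on a seed grid disjoint from the
test suite's seeds. The null distribution of the per-position KL statistic at
N cleaved windows is approximately χ²₃ / (2N ln 2) — about 0.04 bits in
expectation at N = 100 with upper tail near 0.2 — while the weakest true
signal (a 5-mer position at ~0.6 frequency) sits near 0.37 bits; 0.15 bits
splits these with the best joint recovery/specificity margin on the grid.
The window floor of 70 sits between the inactive-screen depth (≈ 50 ± 7
cleaved windows, pure background) and the weakest active depth (≈ 94 ± 10 for
a 5-mer), so inactive screens are gated out at ~3 standard deviations while
active screens pass at ~2.5. Both remain configuration-exposed; screens run
at different library sizes or cleavage rates should be recalibrated the same
way.

## Guide–scaffold boundary detection

**Generator.** An alignment of `n_seqs` ortholog 3′ ends: scaffold columns
are a shared sequence with independent substitutions at
`scaffold_subst_rate` (default 0.03); guide columns are uniform random per
sequence, since each locus targets a different genomic site. The true
boundary column equals the scaffold length; the generator emits gap-free
alignments (the caller handles gaps; the generator does not model indels).

**Caller.** Per-column conservation is the modal A/C/G/T frequency among
non-gap characters (N counts in the denominator only). For each candidate
column the mean conservation over the five columns upstream is compared with
the five downstream; a candidate qualifies when the upstream mean is ≥ 0.7,
the drop is ≥ 0.4, and the column is not gap-dominated (gap fraction ≤ 0.5,
excluding alignment-edge artifacts). Among qualifying candidates the
**downstream-most** (largest column) is returned; a null call is valid. The
three numeric values quantify a "sharp drop from a conserved region" and are
all configuration-exposed: with ~20 sequences, random guide columns sit near
0.4 conservation and scaffold columns near 0.97, so the planted drop of ~0.5
clears the threshold while internal scaffold variation does not. Because the
windowed rule keeps qualifying for one or two columns past the true boundary
(the upstream window still averages ≥ 0.7 with a guide column or two in it),
calls land within +2 columns of truth rather than exactly on it; recovery is
therefore assessed at ±2 columns. The call is reported in alignment-column
space with a projection to each sequence's ungapped coordinates.

## mRNA complementarity scan

Every fixed-length mRNA window (default 50 nt, matching the size of the
experimentally implicated inhibitory region) is scored by the maximal number
of contiguous, gap-free Watson–Crick pairings it can form with any scaffold
segment — the longest common substring between the window and the reverse
complement of the scaffold, computed by a run-length recurrence with
per-window truncation. G·T (G·U) wobble pairing is off by default and
flag-enabled. This is a deliberate sequence-level surrogate for RNA–RNA
co-folding: it ranks candidate cis-inhibitory windows and makes no
thermodynamic or mechanistic claim; MFE folding and covariance models are
non-goals.

## Determinism and problem sizes

Every generator draws all randomness from a single `numpy` generator seeded
by its `seed` field, so identical parameters give byte-identical FASTQ/FASTA
output; the truth sidecar records all parameters and derived ground truth.
Recovery and specificity are assessed over 100 seeded replicates per
condition at the defaults above (2,000 reads per RACE library, 50,000
molecules per screen, 20-sequence alignments), sizes at which each replicate
completes in well under a second and the statistical margins above are
comfortable.

## What the synthetic data do not show

The generators reproduce the *statistical structure* each caller assumes, not
the full messiness of the assays: no indels, no quality-score error
structure, no PCR duplicates or amplification bias, no ligation bias at the
5′ adaptor, no alignment gaps from true indel variation, and cleaved-library
depth tied to library size rather than set by sequencing. Passing recovery
tests therefore demonstrates that the callers invert their stated generative
models at realistic signal-to-noise — not that they are robust to every
artifact of real libraries. Headline real-data outcomes of the original
survey (fractions of orthologs with clear processing sites or TAM activity,
the 79–466-nt scaffold-length range) depend on the deposited sequencing data
and are out of scope here.

## Known limitations

* The start-site caller's thresholds formalize a qualitative rule; loci whose
  true dominant fraction sits near 0.5 will flip between `clear` and
  `multiple` across replicates by construction.
* The TAM caller assumes positional independence and a contiguous motif; a
  gapped or coupled motif would be reported as its contiguous hull.
* The boundary caller requires a conserved upstream shoulder; alignments in
  which fewer than ~10 sequences share the scaffold, or whose scaffold
  divergence exceeds ~10%, push the upstream mean below 0.7 and produce null
  calls.
* The complementarity scan scores only perfect contiguous runs; a single
  mismatch splits a long near-complementary stretch into two shorter runs.
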