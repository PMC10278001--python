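# omegakit

Analysis toolkit for characterizing TnpB nucleases and their omegaRNAs.
TnpB is the IS200/605-family, RNA-guided nuclease regarded as the ancestor of
Cas12; its noncoding omegaRNA consists of a conserved scaffold (inside the
transposon, ending at the right-end/RE boundary) followed by a locus-specific
guide. Characterizing a TnpB ortholog means answering three questions that
map onto three sequencing-based assays:

1. **Where is the omegaRNA 5′ processing site?** (5′ RACE sequencing of the
   in-vitro-expressed locus)
2. **What target-adjacent motif (TAM) does the nuclease require?** (cleavage
   screen of a plasmid library with eight fully randomized bases — an "8N
   library" — at the TAM position)
3. **Where does the scaffold end and the guide begin?** (conservation drop in
   an alignment of related locus 3′ ends)

omegakit implements one tested pipeline per question, plus seeded
synthetic-data generators that emulate each assay with known ground truth, so
every stage is verifiable end-to-end without any deposited sequencing data.

## Methods at a glance

* **RACE start-site calling** — adaptor trimming (Hamming prefix), ungapped
  anchor mapping of read 5′ ends, peak clustering of the start profile, and a
  three-way call: `clear` when one peak holds ≥ 50% of mapped starts
  (fraction *f*₁ ≥ 0.5), `multiple` when ≥ 2 peaks each hold ≥ 20% with none
  dominant, else `none` (with the 5′-most start — the longest species — as
  fallback). The scaffold annotation runs from the called start to the RE
  boundary.
* **TAM calling** — per-position enrichment
  log₂((f_cleaved + p)/(f_input + p)) and information content
  IC_j = Σ_b f_cleaved[j,b] · log₂(f_cleaved[j,b]/f_input[j,b]) (KL
  divergence in bits against the sequenced input library, Laplace pseudocount
  p = 1). Positions with IC ≥ 0.15 bits are called; the IUPAC consensus spans
  the minimal contiguous interval covering them, and `active` additionally
  requires ≥ 70 cleaved windows.
* **Boundary detection** — per-column modal-base conservation; a boundary is
  the **downstream-most** column where the mean over the 5 columns upstream
  is ≥ 0.7 and exceeds the 5-column downstream mean by ≥ 0.4.
* **Complementarity scan** — ranks fixed-length mRNA windows by the longest
  contiguous Watson–Crick pairing they can form with the scaffold (longest
  common substring with the scaffold's reverse complement), a sequence-level
  probe of the cis-inhibition hypothesis.

Model details, parameter defaults and calibration are in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate a RACE library from a 300-nt locus template with a processing site
planted at position 120 (0-based), then call it:

```bash
omegakit --seed 11 --out-dir demo simulate-race \
    --template demo/template.fasta --site 120:1.0 --n-reads 2000
omegakit --out-dir demo call-start \
    --reads demo/race_reads.fastq --template demo/template.fasta --guide-start 226
```

```
classification: clear; sites: [(120, 0.937374749498998)]
```

The call is `clear`: 93.7% of the 1,996 mapped read 5′ ends cluster at
position 120, exactly the planted site (the remainder is the 5% simulated
background). With the RE boundary at 226, the scaffold annotation
(`demo/scaffold.bed`) spans 120–226: a 106-nt scaffold, i.e. a 126-nt
processed species once its 20-nt guide is included.

Screen for the TAM of an ortholog whose true motif is 5′-TCAC:

```bash
omegakit --seed 11 --out-dir demo simulate-tam --true-tam TCAC
omegakit --out-dir demo tam-screen \
    --cleaved demo/tam_cleaved.fastq --input demo/tam_input.fastq \
    --anchor-up ACGGCTAGCTCAGT --anchor-down TGGAATTCTCGGGT
```

```
active: True; consensus: 'TCAC'
```

Out of 50,000 library molecules, 215 were cleaved; the four window positions
with information content above threshold read T-C-A-C, recovering the
planted motif with a called span of 4 (`demo/tam_call.json`; per-position
enrichment and a logo matrix are written alongside).

Find the RE boundary in a simulated 20-sequence ortholog alignment with a
120-nt scaffold:

```bash
omegakit --seed 11 --out-dir demo simulate-msa --n-seqs 20 --scaffold-len 120
omegakit --out-dir demo find-boundary --msa demo/msa.fasta
```

```
boundary column: 121
```

Conservation collapses from ~0.97 to ~0.4 where the guide begins; the
downstream-most qualifying drop is column 121, one column past the planted
boundary at 120 (the windowed rule can overshoot by up to two columns —
see docs/methods.md).

The same operations are available as library functions
(`omegakit.call_start_sites`, `omegakit.call_tam`, `omegakit.find_boundary`,
`omegakit.complementarity_scan`, …) on in-memory objects.

## Scope

omegakit consumes existing alignments and plain-text formats (FASTA, FASTQ,
BED, TSV, JSON). Building alignments, RNA secondary-structure or covariance
modelling, thermodynamic co-folding, phylogenetics, and HMM-based locus
discovery are out of scope.
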