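# macrna

Small-RNA sequencing analysis for ciliate macronuclear nanochromosomes.

Stichotrichous ciliates such as *Oxytricha trifallax* keep two genomes: a
silent germline micronucleus with conventional chromosomes, and a somatic
macronucleus whose DNA is processed into tens of thousands of gene-sized
"nanochromosomes" (~2.2 kb on average) with telomeres at both ends.  During
the formation of a new macronucleus after mating, internally eliminated
sequences (IESs) are excised and macronuclear-destined segments (MDSs) —
flanked in the germline by short duplicated "pointer" repeats, sometimes
permuted or strand-inverted ("scrambled") — are stitched together.  Soon
after mating, an abundant class of 27 nt small RNAs appears.  `macrna`
reimplements, as a tested and reusable library, the sequencing analysis that
characterizes this class: where the RNAs come from (parental macronucleus vs
germline), how they distribute over the two strands and along the
nanochromosome, and how the subtelomeric region is depleted of them.

The package is aimed at researchers analysing ciliate small-RNA libraries
(or anyone who wants a fully synthetic, ground-truth-labelled testbed for a
small-RNA pipeline).  Every stage is driven by a simulator of ciliate
nuclear dimorphism, so the whole analysis is testable without downloading
anything.

## Pipeline

1. **readprep** — 100 bp paired-end reads are adapter-trimmed and kept only
   when the two mates are exact complements ("bidirectional-identical"
   reads), then deduplicated into a distinct-read set with counts.
2. **ncfilter** — reads matching non-coding RNAs or a 40 nt telomeric decoy
   `(GGGGTTTT)5` are removed (≤3 substitutions, either strand).
3. **refbuild** — nanochromosomes are concatenated with 50-N spacers into
   `chr1` (complete, telomere-to-telomere records) and `chr2` (partial
   contigs), with exact offset maps and telomere annotations.
4. **aligncore** — complete enumeration of alignment sites on both strands
   with a bounded-mismatch policy (≤1 substitution by default, no indels),
   two-pass chr1(+chrM)→chr2 orchestration, SAM/bedGraph export.
5. **sizestats** — distinct-read length histograms with a mapped/unmapped
   split, per-position nucleotide frequency matrices (5′-U bias), abundant
   subsets, and the per-27mer count table for external differential tools.
6. **nucorigin** — Venn classification of 26–28 nt reads against trimmed
   micronuclear/macronuclear gene pairs: reads inside IESs can only match
   the germline version; reads spanning an MDS/MDS junction beyond both
   pointer copies can only match the somatic version.
7. **strandprofile** — per-nanochromosome strand balance.  With *p* and *m*
   reads on the two strands and a fair per-read coin, *p − m* has standard
   deviation √(p+m), so ~95 % of nanochromosomes should satisfy
   |p − m| ≤ 2√(p + m); the module computes this envelope, the Pearson
   correlation of (p, m), the empirical 95 % band, the per-position coverage
   coefficient of variation (population SD / mean of 5′-end counts), and
   end-anchored telomere-proximal density profiles (20 bins × 25 nt over 500
   positions) with a subtelomeric depletion-fold estimate.
8. **synthdata** — the generator: nanochromosomes with telomeric caps,
   micronuclear precursors with IESs/pointers/scrambling (exact round-trip
   reconstruction guaranteed), bidirectional small-RNA pools with length
   classes, 5′-U bias, gamma-distributed production hotspots, subtelomeric
   depletion, ncRNA contamination, and paired-end FASTQ emission with
   read-2 errors — all labelled with ground truth.
9. **pipeline / cli** — YAML-configured orchestration with seeded
   determinism, conservation checks, and a run manifest
   (`macrna simulate | prep | filter | build-ref | align | sizestats |
   venn | strandstats | run-all`).

## Worked example

Simulate a mating library over 50 nanochromosomes and run the whole
pipeline:

```python
from macrna.pipeline import RunConfig, run_pipeline, simulate
from macrna.synthdata import GeneratorConfig

cfg = GeneratorConfig(seed=42, n_nano=50, reads_per_nano_mean=400)
bundle = simulate(cfg, "demo_bundle")
manifest = run_pipeline(RunConfig(
    fastq1=str(bundle["fastq1"]), fastq2=str(bundle["fastq2"]),
    ncrna_fasta=str(bundle["ncrna"]), genome_fasta=str(bundle["genome"]),
    out_dir="demo_out", label="sim42", seed=42))
```

which prints (via the manifest):

```
pairs=20606  bidirectional-identical=16278 (79.0%)
ncRNA-matching=2387  surviving=13891
mapped=13891 (100.0%)  unique sites=5800
modal mapped length=27  5'-U fraction at 27 nt=0.911
strand Pearson r: total=0.992 distinct=0.962
envelope inside fraction=0.959  median coverage CV=7.28
telomere-proximal depletion fold=6.78
```

Reading these numbers: 79 % of read pairs were identical in both sequencing
directions (the high-confidence subset); after removing ncRNA matches, every
surviving read maps back to the synthetic macronuclear assembly; the modal
mapped length is 27 nt; production from the two strands is tightly
correlated (r ≈ 0.96–0.99) with ~95 % of nanochromosomes inside the binomial
envelope; coverage along each nanochromosome is highly non-uniform (median
CV ≈ 7); and the 30 nt interior to each telomere carries several-fold less
5′-end density than the rest of the molecule (the generator's setting here
was 8-fold).

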