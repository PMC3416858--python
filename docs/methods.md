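# Methods

This note documents the models, conventions and numerical choices behind
`macrna`, in the order the pipeline runs.

## Read preparation

Small-RNA inserts (15–45 nt) are shorter than the 100 bp paired-end reads,
so both mates sequence the entire insert.  Mate 2 is reverse-complemented
into template orientation, both mates are adapter-trimmed, and a pair is
kept only if the trimmed inserts are exact complements of equal length.
Adapter matching takes the *leftmost* occurrence of the 3′ adapter (full
match anywhere, or ≥6 exact bases running off the read end).  A
longest-insert rule was considered and rejected: a spurious adapter-like
hexamer in the downstream filler appears at the same template position in
both mates, so a longer-insert rule would let adapter-contaminated inserts
survive the identity collapse.  Pairs in which either mate shows no adapter
are rejected outright — without the adapter boundary the insert length is
unknown and the identity test is unreliable.  Length selection (16–45 nt)
is applied at this stage, before the ncRNA filter.  Distinctness is
strand-naive (exact string identity); strand is assigned at alignment.

## Alignment model

Classical short-read mappers score mismatches by base quality; `macrna`
replaces this with a deterministic, quality-free policy: at most *k*
substitutions anywhere, no indels, both strands, with *complete* site
enumeration.  The stringent genome policy is k=1; the lenient ncRNA-filter
policy is k=3.  Enumeration is pigeonhole seed-and-extend: the read is cut
into k+1 disjoint segments (segment length min(⌊L/(k+1)⌋, 12)); any valid
placement must contain one exact segment, so candidate sites are read off a
k-mer position table and verified by direct comparison.  Correctness is
checked in the test suite against an independent brute-force sliding-window
oracle on hundreds of randomized instances.  Windows containing N are
excluded, which also makes alignments across the 50-N spacers of the
concatenated reference impossible.

Two-pass orchestration maps reads first to the complete-nanochromosome
reference (plus the mitochondrial sequence when provided) and sends only the
leftovers to the partial contigs.  Mapping multiplicity (unique / 2–9 /
≥10 sites) is counted within the pass that captured the read.  For
statistics, one site per multi-mapping read is retained, drawn uniformly
from the (record, start, strand)-sorted hit list with a generator seeded
from the run seed, so reruns are byte-identical.  For track export (SAM,
per-strand bedGraph of 5′-end counts) all sites are retained.

## Reference construction

Records are concatenated with 50-N spacers; offsets satisfy
offset(k+1) = offset(k) + length(k) + 50 and are emitted as a TSV that
reconstructs the concatenated file byte-for-byte.  Coordinates are 0-based
half-open everywhere except SAM output (1-based POS).  Telomere annotation
measures maximal end-anchored runs of the telomere unit (reverse complement
at the 5′ end), allowing partial terminal repeats at any phase, with a
minimum run of 12 nt; records with runs at both ends form the "complete"
(chr1) class, the rest are partial contigs (chr2).  The paper-level
convention that the complete class required telomeres on *both* ends is
recomputed here from annotation rather than taken from an assembly.

## Strand-balance statistics

Under a fair per-read strand coin, the plus count of n reads is
Binomial(n, ½) with SD √n/2, so |p − m| ≤ 2√(p + m) is the ±2 SD locus and
should contain ~95 % of nanochromosomes.  Only records with ≥10 reads per
strand enter the table (both total and distinct counts are kept).  The
empirical band is the 95th percentile of |p − m|/√(p + m); overdispersion of
total counts relative to distinct counts (piles of identical reads) widens
it beyond the binomial 1.96.  The envelope's finite-n calibration (including
discreteness) is asserted at 0.94–0.97 over 10,000 simulated records.

## Coverage coefficient of variation

Per record, 5′-end counts are accumulated at each position (each read
counted once at its own-strand 5′ position, both strands pooled by default;
a per-strand mode exists), and CV = population SD / mean.  Telomeric
positions are included — their near-zero counts are part of the observed
non-uniformity.  Closed forms used as oracles: uniform coverage → 0; all
reads on one of L positions → √(L−1).

## Telomere-proximal profile and depletion fold

For every complete record ≥500 nt, 5′-end counts of one strand are taken
over the 500 positions anchored at each record end, normalized by the
record's own window mean, binned 20 × 25 nt, and averaged across records.
Geometry makes one end of each strand "shaded": a plus-strand read needs a
full read length between its 5′ end and the 3′ record end, so plus-strand
5′ density is structurally zero within ~27 nt of the 3′ interior edge
(mirrored for minus reads at the 5′ end).  Profiles of the two strands are
mirror images on strand-symmetric data, which the tests assert.

The depletion fold compares mean 5′-end density between a subtelomeric zone
and the undepleted remainder of the window.  Three choices matter and were
made for estimator calibration (validated against generator ground truth
across seeds and depletion settings):

* the zone is anchored at the *interior edge of the annotated telomere*
  (telomeric reads are removed by the ncRNA filter, so anchoring at the
  record end would dilute the zone with structurally empty positions);
* at the shaded end the zone is shifted past the read-length shade and
  trimmed to the positions that are depleted for, and reachable by, every
  read length in the 26–28 band (the raw zone there mixes structurally
  empty positions and full-rate edge positions, which biases the fold
  toward 1);
* records are pooled by depth (ratio of summed means rather than mean of
  per-record ratios).  Per-record ratios are heavy-tailed under the spiky
  hotspot landscape — a single production hotspot landing inside a shallow
  record's zone dominates an equal-weighted mean and biases the fold low by
  ~35 %; depth pooling keeps the estimate centred.

Folds are reported per end and pooled; profiles of both strands can be
pooled for the most stable estimate.

## Origin classification (Venn)

Distinct 26–28 nt reads are aligned to both strands of the micronuclear and
macronuclear versions of a gene pair (exact matching by default; the
mismatch cap is configurable) with all mappings retained.  Membership in
{both, micro-only, macro-only} follows from existence of any site.  Pairs
are assumed trimmed so the macronuclear sequence is contained in the
micronuclear clone: length differences are then exactly ΣIES + Σpointer,
which `validate_gene_pair` checks, along with exact round-trip reassembly
when an MDS decomposition is available.  Pooling across libraries defaults
to classifying each library separately and summing counts (a sequence seen
in k libraries contributes k); a distinct-union mode is provided.  Exact
matching was chosen for determinism; comparisons against published
accession-based tables are therefore approximate.

## The generator

What it emulates, per nanochromosome and strand:

| parameter | default | meaning |
|---|---|---|
| `n_nano` | 200 | nanochromosomes per fixture |
| `nano_len_mean/sd` | 2200 / 800 nt | record length, clipped ≥500 nt |
| `telomere_unit/len` | GGGGTTTT / 20 nt | caps; 5′ cap starts CCCCAAAA… |
| `reads_per_nano_mean` | 1000 | expected reads per record |
| `reads_per_nano_sigma` | 1.0 | lognormal spread of per-record depth |
| `class_weights` | 26:0.1, 27:0.8, 28:0.1 | mating length classes (vegetative: 20/21/22 at 0.3/0.4/0.3) |
| `strand_p` | 0.5 | per-read probability of the plus strand |
| `hotspot_shape` | 0.05 | gamma shape of per-position rates (smaller = spikier) |
| `u5_bias` | 0.97 | probability the 5′ base is U |
| `deplete_zone/factor` | 30 nt / 8 | subtelomeric thinning |
| `ncrna_contam_frac` | 0.15 | reads drawn from decoy ncRNAs |
| `pair_error_rate` | 0.005 | per-base read-2 disagreement |

The lognormal depth spread stands in for differential nanochromosome
amplification; without it every record would have the same expected total
and the plus/minus scatter would collapse onto a single binomial cloud with
no between-record correlation to recover.  The 5′-U bias is imposed by
reweighting candidate 5′ positions (U-start positions carry total weight
0.97), never by editing bases, so every read remains an exact genome
substring.  Subtelomeric depletion is applied per read: a sampled read that
overlaps the 30 nt interior to either telomere is kept with probability
1/deplete_factor and otherwise resampled — equivalent in distribution to
thinning the rates of every overlapping placement, and exact for all read
lengths at once.  Telomere-internal 5′ positions produce no reads (their
real-data counterparts are removed by the telomeric decoy).  Micronuclear
loci draw pointers from the actual junction sequence (2–20 nt) and IESs of
20–80 nt random sequence — generator conventions, since genome-wide pointer
and IES length distributions are not part of the published record used
here; IES border bases are re-drawn when they would extend a pointer match,
so the MDS/IES decomposition is unambiguous and reconstruction
(IES removal + pointer dedup + unscrambling) is exact by construction.

What it does not emulate: base-quality structure (constant Q), PCR
duplicates, the triphosphorylated ~25 nt class that real libraries cannot
ligate, sequence-composition biases of real genomes (interiors are i.i.d.
at the configured GC), chimeric reads, and indel errors.  Passing tests
therefore demonstrate the correctness of the computations and the internal
consistency of the statistics — not robustness to every artefact of real
libraries.

### 5′-U recovery: reads vs distinct sequences

The generator fixes the *read-level* 5′-U fraction.  Collapsing to distinct
sequences interacts with the hotspot landscape: U-start positions carry
~30-fold more weight per position, so they saturate (many duplicate reads
per position) while non-U positions are mostly singletons; the distinct-set
U fraction is therefore biased toward the base composition (e.g. ~0.91 when
the read-level fraction is 0.97 at default depth).  Parameter-recovery
checks accordingly use the count-weighted frequency matrix (a flag on
`position_freq`); the distinct-sequence matrix remains the default for
descriptive output.

## Problem sizes and seeds

The test suite runs fixtures of 10–200 nanochromosomes; the full
parameter-recovery checks use 200 nanochromosomes × ~200k reads per
depletion setting (2, 4, 8), completing in under a minute each on one CPU.
All randomness flows from `numpy.random.default_rng` seeded per fixture;
the recovery tests use the generator's default seed (0), and the
depletion-fold estimator above was calibrated on an independent seed range.
Hypothesis-based property tests run derandomized.

## Known limitations

* The mismatch-cap alignment policy is a deterministic surrogate for
  quality-weighted mappers; counts on real data will differ near the policy
  boundary.
* The Venn classifier performs no de-novo MDS/pointer annotation; it
  validates provided decompositions and otherwise reports anchor coverage
  only.
* Mitochondrial ncRNAs are not curated; chrM is only an optional extra
  reference target.
* `empirical_band` and the envelope assume per-record totals are
  independent across records; shared-hotspot effects between strands are
  not modelled in the null.
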