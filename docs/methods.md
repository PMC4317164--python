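# Methods

This note documents the models, conventions and numerical choices behind
`microx`, in the spirit of the methods documentation of mature scientific
packages: what each stage computes, under which assumptions, which
parameters matter, and what the synthetic-data tests do and do not
demonstrate.

## Coordinates, strand and sequence conventions

All internal coordinates are 0-based half-open genomic intervals; GTF I/O
converts from/to 1-based inclusive. Every sequence-level analysis operates
in *sense* (transcript) orientation: "upstream"/"5′" always means
transcript-orientation upstream, so on the minus strand the genomically
right-hand intron is the upstream one and its sequence is
reverse-complemented before use. A micro-exon's splice context is canonical
when the upstream intron ends `AG` and the downstream intron begins `GT`
(sense orientation). U and T are treated as equivalent on input; the
internal alphabet is ACGT.

A micro-exon is an *internal* exon (it has both neighbors within at least
one transcript) of length 3–51 nt. Discovery defaults to 3–51 nt; exons
shorter than 6 nt place ambiguously often enough that downstream analyses
conventionally use 6–51, and both bounds are parameters. When several
transcripts give an internal exon different neighbors, the flanking-intron
accessor uses the transcript minimizing total flanking-intron length, with
a lexicographic transcript-id tie-break, so results are deterministic.
Splice-site windows follow the MaxEntScan convention — 9-mer donor
(3 exonic + 6 intronic) and 23-mer acceptor (20 intronic + 3 exonic) — and
are configurable.

## Discovery from insertion alignments

Assumption: reads were aligned to cDNA references, so an unannotated
internal exon appears as an *insertion* at an exon–exon boundary of the
annotated transcript.

* Insertion filter: length 3–51 nt, aligned match ≥ 6 nt on both sides
  (`min_flank`). Substitutions are taken from the NM tag minus indel bases
  when present and capped at 2 (`max_mismatch`); without an NM tag the cap
  is not enforced. Only primary alignments are used.
* Boundary rule: the insertion offset must equal a junction offset exactly
  (tolerance 0 nt) — the conservative, testable reading. Groups are keyed
  by the *genomic* junction plus the inserted sequence, so transcripts
  sharing a junction pool their support; groups with < 10 reads are
  discarded.
* Intron search: exact string match in sense orientation only, requiring
  `AG` immediately 5′ and `GT` immediately 3′ of the occurrence. Multiple
  canonical occurrences ⇒ one is drawn uniformly with a caller-supplied
  seed (default 42) and the candidate is flagged ambiguous.
* Breadth rule: a placed candidate is *novel* if, in at least one tissue,
  ≥ 15 % of that tissue's samples show PSI ≥ 5 (missing PSI counts as
  not expressed), and the locus does not overlap an annotated internal
  exon. The candidate PSI matrix comes from the quantification stage run on
  an augmented transcriptome that includes the candidates.

## Augmented transcriptome and PSI

Micro-exons within a transcript are clustered by single linkage on genomic
gap ≤ 100 nt. The isoform set per transcript is: the all-included and
all-excluded backbones plus, for each cluster of size m, all 2^m local
combinations with out-of-cluster micro-exons included. Joint combinations
matter only for junctions a single read can span, so this bounds the
blow-up at Σ 2^{m_c} + 2 while keeping every junction a read can interrogate
representable; a hard cap of 12 exons per cluster guards against
pathological annotations. Novel micro-exons lying strictly inside an
annotated intron are insertable into the chain the same way.

Junction counting requires ≥ 6 nt (`min_anchor`) of the read on each side
of the junction, mirroring the discovery flank rule. A read counts at most
once per junction type even when it matches several isoforms. R_tot =
min(R_L, R_R) guards against alternative 5′/3′ splice sites inflating one
side. PSI = 100·R_tot/(R_tot+R_S), reported missing when R_tot+R_S ≤ 5
(`min_informative` = 6); the "informative" denominator is the
junction-read total, which is the reading under which the masking rule and
the estimator target coincide. Two read-assignment paths exist: SAM against
the augmented FASTA the module emits (NM ≤ 2, primary only), and an
internal exact-substring assigner for (read-id, sequence) pairs used by the
simulation path. Classification: CS iff median PSI ≥ 90 in the reference
tissue; AS iff the median is in [10, 90); below, not-expressed (boundary
values are inclusive on the CS and AS sides respectively). Brain-specific:
target median ≥ 25 and 80th percentile (linear interpolation) of pooled
non-target samples ≤ 10, pituitary excluded for its relatedness to brain.
ΔPSI uses condition medians and a strict |ΔPSI| > 15.

## Feature analytics

* **ESE density** = matching hexamer start positions / (L−5), counting
  overlaps; bounded in [0,1] and length-comparable, which is why the
  denominator is start positions rather than nucleotides. Undefined for
  L < 6.
* **Splice-site scoring** is a pluggable contract: the built-in scorer sums
  log2(p/0.25) over the window (a perfect 9-mer scores 18 bits); an adapter
  reads precomputed sequence→score tables, e.g. MaxEntScan output.
  Re-deriving the maximum-entropy model itself is out of scope.
* **PWM scans** use the natural log with zero-probability cells floored at
  1e-4, threshold = width·ln(0.6): a hit has geometric-mean per-position
  probability ≥ 0.6, a base-invariant statement as long as score and
  threshold share the log base — which the implementation enforces. Hits
  are distinct start positions (overlapping hits count separately; a
  motif-per-exon average counts each start once).
* **Upstream motif window** (a,b) = (10,20) selects hit starts at −20…−10
  relative to the exon start, the polypyrimidine/U2AF2 zone.
* **k-mer flank profiles** count k-mer starts per relative position within
  250-nt flanks clipped at the neighboring exon; densities are occurrences
  per scanned start position so classes with different intron lengths
  remain comparable.
* **Mann–Whitney U** is two-sided (scipy: exact for small tie-free samples,
  normal approximation with tie correction otherwise); a constant pooled
  sample returns p = 1.0 rather than the undefined tie-corrected statistic.
* **Set-overlap test**: exact hypergeometric upper tail. The default is the
  inclusive tail P(X ≥ k). The strictly-greater tail P(X > k) — the
  `1 − phyper(k, …)` idiom — is available via `inclusive=False`; for the
  reference RBFOX∩PTBP1 configuration (N=1480, A=159, B=113, k=25) the two
  give 1.86e-4 and 6.64e-5 respectively, and only the latter matches the
  previously reported bound, so comparisons against that number must use
  the exclusive tail.

The 607-hexamer ESE catalog and the 131-PWM RBP compendium are *inputs*;
the repository ships only small synthetic stand-ins inside tests.

## Conservation and coverage

Entropy of a gapless k-window over an alignment is Σ_columns −Σ_a f_a ln f_a
with f over all rows; any gap excludes the window entirely. Conserved
windows have entropy < 1.0 — low entropy means conservation; the threshold
is a parameter and only meaningful once the log base (natural) is fixed.
The empirical-distribution view of the threshold is computed globally, with
a per-region option. Region labels (5′-intron / exon / 3′-intron) are
assigned per alignment column by walking the reference (human) row.

Bootstrap profiles resample |S| score vectors with replacement, B = 1000
times; the band is the 5th–95th quantile (a 90 % interval — the
implementation labels the implied coverage) with type-7 linear
interpolation. Profile windows are 300 nt centered on the exon midpoint;
longer exons contribute their central 300 nt; minus-strand exons are
flipped to transcript orientation. Coverage metagenes average replicate
tracks first, then bootstrap. Percent identity counts gap columns as
mismatches. Score tracks are consumed from fixed-step wiggle or bedGraph
text.

## Coding impact

Phase bookkeeping follows the GFF convention operationally: the screen
`coding_potential(seq, phase)` takes the offset of the first complete codon
inside the insert (0/1/2) and checks only codons fully inside it — the fast
per-exon screen used for class summaries. `inclusion_consequence` performs
the exact spliced translation, junction-spanning codons included:
symmetric (length ≡ 0 mod 3) and stop-free ⇒ in-frame insertion with its
peptide; symmetric with a stop overlapping the insert ⇒ in-frame stop
(PTC offset = nt from insert start to the stop codon); non-symmetric ⇒
frameshift with the distance to the first stop of the shifted frame.
Stop codons are the standard nuclear set (TAA/TAG/TGA). Micro-exons
outside an annotated CDS are classified non-coding-region and excluded
from summaries. Reported class percentages round half-up to one decimal.

## The simulator: what it emulates, and what it does not

The generator's defaults define the test regime: 12 genes (three exons
each, alternating strands) on one contig, 8 samples over three tissues
(4 brain, 2 heart, 2 liver), 76-nt reads, 60 junction-informative reads
per exon and sample plus 30 background reads per gene. CS-type exons get
short introns (80–250 nt), ESE-hexamer-tiled bodies (planting probability
0.6 per 6-nt slot) and a 10-nt pyrimidine tract at −20…−11; AS/BS-type
exons get longer introns (350–900 nt) and `TGCATG` planted in 10-nt
downstream-flank slots at probability 0.12 (background) × 2 (AS/BS).
True PSI per kind: CS 97 everywhere; AS 55/45/35 (brain/heart/liver);
BS 60 in brain, 2 elsewhere — values chosen to sit comfortably inside the
CS/AS/brain-specific decision regions rather than on their boundaries.
All planted exons are verified canonical and uniquely placeable at
generation.

Reads are generated *junction-locally*: each junction-informative read is a
Bernoulli(PSI) draw — inclusion reads span the whole micro-exon with both
anchors (possible whenever read length ≥ exon + 2·anchor, i.e. all lengths
≤ 64 here), exclusion reads span the skip junction — so true PSI is exactly
the estimator's target and recovery can be judged against binomial
sampling error alone. Background reads start uniformly along the isoform.
The discovery SAM is written against the *annotated* cDNA, so inclusion
reads of withheld ("novel") exons appear as insertion alignments and
partial overlaps as soft-clips. The MSA simulator uses a 5-species star
phylogeny with per-site substitution (1 % inside planted conserved
windows, 35 % outside, no indels); the conservation track is a noisy
indicator of exonic/flank conservation; the CLIP track adds peaks over
planted `TGCATG` sites.

Consequences for interpretation: passing tests show the estimators and
scanners recover *planted* signal at the configured effect sizes under
uniform base composition, error-free reads (the error rate is configurable
but defaults to 0 because the exact-match assigner drops mismatched
reads), single-isoform backgrounds and star-phylogeny alignments. They do
not demonstrate robustness to alignment artifacts, indels in real MSAs,
expression-level confounding, multi-mapping, or non-uniform genomic
composition.

## Problem sizes and calibration checks

The test suite and acceptance script use desk-scale runs: estimator
calibration uses 5 exons × 40 samples at 200 informative reads per cell
(the ±2-binomial-SE interval covers ≈ 95.8 % of cells in expectation;
empirical mean over 20 generator seeds: 95.7 %); classification accuracy
uses 24 genes at default depth; discovery recall uses 20 withheld exons of
6–51 nt; motif detection uses 40 genes (20 CS / 20 AS); bootstrap scaling
compares |S| ∈ {25, 100, 400} at B = 1000. The whole suite runs in well
under a minute on one CPU.

## Known limitations

* No read alignment is performed; SAM input is taken as given, and the
  exact-match assigner ignores reads containing sequencing errors.
* Junction counting is per-exon; there is no EM/likelihood isoform
  abundance model and no multi-mapping rescue.
* The entropy scan assumes a trustworthy reference row and gapless windows;
  heavily gapped alignments yield few scorable windows.
* NMD is not modeled beyond reporting PTC offsets (no 50-nt rule).
* Cross-species coordinate projection, phastCons model fitting, and MSA
  construction are consumed as inputs, not computed.
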