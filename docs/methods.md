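# Methods

## Problem setting and assumptions

The pipeline analyses spliced long-read alignments of a single-gene PCR
amplicon on one reference contig and one strand. Three assumptions follow
from the amplicon design and are used throughout:

* every true transcript begins in one of the alternative first exons and
  ends in the terminal exon (the primers anneal there), so a read whose
  alignment reaches both termini traverses *all* exons of its source
  transcript;
* junctions arise only from gapped-intron (`N`) CIGAR operations; telling
  long deletions from introns is the spliced aligner's responsibility;
* one primary alignment per read; secondary and supplementary records are
  ignored, and each read contributes one vote per junction.

## Junction snapping

Nanopore indel noise displaces junction ends by a few nucleotides. Each
observed (donor, acceptor) pair is moved to the pair of annotated splice
sites that minimises the total shift, provided both ends lie within the
snap window `w` (default 12 nt, several times the typical indel-induced
displacement yet far below the ~150 nt minimum distance between annotated
sites in the locus). Ties are broken toward a pair that forms an annotated
junction, then toward GT..AG intron dinucleotides, then toward smaller
coordinates. Ends with no site within `w` are deliberately left untouched:
they are the raw material for cryptic-exon discovery.

## Junction table and support thresholds

A junction row is reported when its support reaches
`max(min_support, min_fraction × reads)` with defaults 5 reads and 0.01%.
The original study never states its own depth threshold (its least-supported
reported junction has 828 of ~200,000 reads, ≈0.4%); the defaults here are
engineering choices that admit every junction of the simulated catalogue
while suppressing singleton artefacts. Status is purely structural:
`annotated` pairs occur in an annotated transcript; `novel_combination`
pairs join two annotated sites not paired in any annotated transcript;
everything else is `cryptic`.

## Cryptic exons

A candidate observation is an internal aligned block (junction on both
sides) overlapping no annotated exon. Observations within `w` nt are
clustered; the call takes the per-cluster modal start and modal end (ties
toward the smaller coordinate), its flanking annotated exons, and the
cluster size as support. Modal boundaries are exact on error-free reads for
any support ≥ 1, and remain exact in expectation under the error model
because boundary displacements are a minority of observations per site.

## Isoform assembly

Full-length reads (both alignment ends within `t` = 30 nt of the amplicon
termini; the window absorbs terminal indels) are mapped block-by-block onto
the exon set — annotated exons plus registered cryptic calls. Reads with a
block spanning an intron (intron retention) or overlapping no exon are
excluded; retention is observable but deliberately outside the spliced
catalogue. Identical exon-id chains merge with summed support; chains below
`min_isoform_support` (default 3) or using a junction absent from the
filtered junction table are dropped. Since full-length amplicon reads are
unambiguous about their exon chain, support counting is exact and no
abundance deconvolution (EM over compatible reads) is needed or provided.

## ORF prediction and NMD

Initiation codons are found by anchor subsequences (±20 nt of sequence
context around each codon) rather than genome coordinates, so the caller
works identically on assembled variants and on bare cDNA records. Search is
exact-substring first, then one pass tolerating a single mismatch (edlib);
priority is annotated start (exon 2) > exon-3 alternative > exon-4
alternative > longest ATG-initiated ORF of ≥ `min_orf_aa` (default 50)
residues. A stop upstream of the located annotated termination codon is a
PTC; a PTC whose codon ends more than `d_nmd` = 50 nt (the standard
last-exon-junction rule, strict inequality) upstream of the final
exon–exon junction makes the transcript an NMD candidate, and a stop in the
final exon never does. Protein lengths count the initiator Met and exclude
the stop (371 aa for the annotated isoform).

## Domain presence

A domain is present iff its exact amino-acid subsequence on the annotated
protein occurs contiguously in the predicted isoform. This single rule
covers exon skips (the subsequence loses residues), internal insertions
(the subsequence is interrupted) and frameshifts (downstream residues
change), at the cost of being strict about single-residue variants — an
acceptable trade for isoform-level presence/absence tables.

## The synthetic locus

The built-in fixture emulates the ELF3 amplicon: ten annotated exons — two
alternative first exons of 120 and 234 nt, then E2–E9 — plus two reserved
intronic loci N1 (156 nt, inside the E7–E8 intron) and N2 (92 nt, inside
the E8–E9 intron) acting as cryptic exons. All introns are GT..AG. Exonic
sequence uses the alphabet {A, C, G}, with every T planted deliberately;
since ATG and all three stop codons contain T, start and stop codons exist
exactly where engineered, in every reading frame of every exon chain. The
planted features are the annotated ATG in E2 (after a 50-nt UTR stub),
in-frame alternative ATGs in E3 and E4, the annotated TGA in E9 (preceded
by a pinned C so no accidental A|TG start appears), a stop cassette in the
E9 3′ UTR with terminators in all three frames, and a TAA inside N1.

Coding spans per exon are multiples of three (150, 222, 93, 120, 90, 117,
180, 144 nt for E2–E9), chosen so that the locus reproduces the
text-determined protein lengths of the real variants: 371 aa reference,
341 aa for the exon-6 skip, 340 aa for the exon-4 skip, 297 aa for the
exon-3 skip, 310 aa and 262 aa for the double/triple skips, and — via the
stop-cassette placement — 476 aa for the N2 frameshift isoform. Every chain
of annotated exons therefore preserves frame; N2 (92 nt) is the single
frameshifting event, and N1 carries the premature stop. The five domains
map onto exons as PNT spanning E2/E3, TAD inside E4, SAR inside E6, AT-hook
inside E7 and ETS spanning E8/E9, which makes exon-chain edits correspond
one-to-one to domain-presence patterns.

The 27-chain reference catalogue encodes the two annotated variants and 25
novel ones. Chains that the variant descriptions fully determine are taken
as described; the remaining chains were completed so that each uses only
catalogued junctions, matches its reported domain pattern, and the
catalogue jointly exercises all 15 novel junctions between annotated exons.
Three of the four non-coding variants are realised as ORF-less (they lack
all three start-codon exons and the reduced alphabet plants no other ATG)
rather than PTC-bearing; the fourth (the N1 variant) carries a genuine
PTC/NMD configuration. Real deposited cDNAs contain incidental ATGs and
PTCs that this reduced-alphabet design intentionally omits.

## Read simulator

Reads are drawn i.i.d. from the weighted transcript mixture; each base is
deleted with probability `p_del` (default 0.03), surviving bases substituted
with probability `p_sub` (0.03), and a single random base inserted after any
position with probability `p_ins` (0.02) — uniform per base, no homopolymer
weighting, defaults chosen to mimic R9.4.1-era nanopore accuracy (~92%
identity). Optional truncation removes a uniform 5–45% terminal fraction
from a random end, which is what the full-length filter must reject. Every
error is logged, and the oracle SAM writer reconstructs each alignment with
introns at the true coordinates and error operations at their simulated
positions. Deletion runs touching an intron edge are merged into the gap,
reproducing the junction wobble of real spliced aligners (displacement
bounded by the run length, so well inside the snap window); this is what
makes the snap stage do real work on simulated data. The simulator does not
model signal-level artefacts, quality-score structure, chimeras or
strand-switching, so passing tests demonstrate the pipeline's logic and its
robustness to indel-type noise, not performance on every real-data failure
mode.

Default full-catalogue study conditions: the two annotated variants at 60%
and 10%, the 25 novel variants on a geometric ladder from 3% down to 0.3%
(mirroring the orders-of-magnitude support spread of the observed
junctions), 20,000 reads — the least abundant transcript then receives
~60 reads, comfortably above every threshold. Analyses and the acceptance
computation use this size; it completes in seconds while leaving every
count far from its decision boundary.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; GTF/SAM writers emit
  1-based. Minus-strand genes are handled by sequence reverse-complement
  only.
* The two alternative first exons are modelled as disjoint intervals with
  distinct donor sites (their junctions into exon 2 are counted
  separately); whether the real alternative first exons overlap genomically
  is not modelled.
* Snapping never produces empty or inverted blocks: a snap that would do so
  is declined.
* Empty inputs degrade gracefully: an alignment file with no primary
  records yields empty tables and a warning, not an error; an empty variant
  list reports every reference chain as missed.
* All randomness flows from a single integer seed per run; identical
  configurations give byte-identical FASTQ, truth-table, SAM and TSV
  outputs.

## Known limitations

Single-gene, single-contig scope; no base-level error correction or
re-alignment; no quantitative abundance modelling beyond read counts; the
domain rule is presence/absence of an exact subsequence, not a profile/HMM
match; NMD candidacy is the 50-nt heuristic, not a mechanistic model.
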