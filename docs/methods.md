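# Methods

## Split-read geometry

A long read that crosses a rearrangement junction is aligned as a chain
of local alignments: one primary record and supplementary records linked
by the SAM `SA` tag (`rname,pos,strand,CIGAR,mapQ,NM`). Each record is
placed on the read's own forward-orientation axis from its CIGAR clip
structure: the aligned window starts after the leading clip for a `+`
record and after the *trailing* clip for a `−` record (clips are stored
in alignment orientation). Hard clips are treated identically to soft
clips — either way the clipped bases exist on the read and shift the
window — which is required to order segments when an aligner hard-clips
supplementaries. Segments of one read are sorted by read offset;
consecutive segments overlapping on the read by more than a tolerance
(default 200 bp; long-read aligners routinely emit small overlaps at
split points) mark the read inconsistent and exclude it from junction
extraction. When a primary lies outside the queried region it is
synthesised from the first entry of a supplementary's `SA` tag, which by
convention describes the primary. True secondary records (flag 256) are
ignored throughout: the supported aligner invocation suppresses them,
and the chimeric partners of a split read are supplementary records.

Coordinates are 0-based half-open internally; all reported coordinates
are 1-based inclusive.

## Junctions, clustering, columns

Consecutive segments *i*, *i*+1 define a junction with two ends. Sides
encode which genomic boundary the end touches: `left_of_break` means the
position is a segment's reference *end* (aligned sequence lies 5′ of the
break), `right_of_break` a segment's reference *start*. A `+` segment
contributes its reference end as the read leaves it, a `−` segment its
reference start; symmetric rules hold where the next segment resumes.

Ends are clustered per (chromosome, side) by single linkage on sorted
positions, merging while the gap between consecutive members is at most
the window (default 250 nt); clusters need at least 2 supporting ends.
Single linkage is the simplest rule consistent with the
"two-or-more-within-250-nt" criterion, and the suite verifies it against
an exhaustive transitive-closure oracle. The cluster representative is
the median, ties resolved toward the lower coordinate, matching the
median consensus used everywhere else. Both junction ends are clustered
symmetrically; partner consistency is checked at classification, not
during detection, which keeps the detection stage mechanical and
auditable.

Clusters that co-locate on a chromosome (within the window) merge into
*columns* regardless of side — both flanks of an insertion point
co-terminate at one coordinate — and columns sharing at least one read
are paired. Column count is the complexity heuristic: 2 columns (or 3
with an insertion topology, i.e. one column carrying both sides and
paired with the other two) → simple; 3–4 otherwise → complex; more than
4 → complex with a manual-review warning, as multi-event loci need.

## Canonical signatures and the decision table

A junction is canonicalised by ordering its ends by reference coordinate
and, if the first end then maps to `−`, complementing both strands —
exactly what reading the molecule from the other direction does, so a
read and its reverse complement yield identical canonical junctions.
Junctions sharing shape (chromosomes, sides, strand relation) and
positions (within the window, single linkage) form a junction class; the
classes, their read proportions, and the number of distinct end loci
form the signature.

Classification is total over valid signatures (unknown patterns return
`unclassified`, never an exception). Classes need ≥ 2 reads and ≥ 10 %
of selected reads to enter the decision; these thresholds are our
choice, since the source workflow compares pattern proportions without
stating cutoffs. The table:

| classes | call |
|---|---|
| 1, same chrom, equal strands, `left→right`, forward gap | deletion |
| 1, same chrom, equal strands, `right←left` (span end joined to span start) | tandem duplication, alternative: ring chromosome |
| 2 mirrored opposite-strand classes at the same two loci | inversion |
| 2 reciprocal cross-chromosome classes | balanced translocation |
| 1 cross-chromosome class | unbalanced translocation |
| 2 classes, endpoint partition with site gap ≤ window | insertion (inverted when strands disagree) |
| 2 classes, partition with distinct site flanks | complex insertion-deletion |

The endpoint partition seeks an insertion-site pair — a `left` end from
one class and a `right` end from the other on a common chromosome, whose
gap is the loss at the site — with the remaining two ends delimiting the
origin span. For inverted same-chromosome events several partitions can
be geometrically consistent (this *is* the offset-inversion ambiguity);
the partition with the smallest loss is reported deterministically and
`inversion` is attached as an alternative. The duplication/ring pair
shares one canonical signature by construction, so the primary call is
the (far more common) tandem duplication with the ring chromosome always
attached; resolving either ambiguity needs karyotype or copy-number
evidence outside split-read scope. Both ambiguous pairs are asserted
byte-identical at the signature level in the tests.

The automated pipeline groups columns into connected components via
shared reads and merges a component pair when the joint evidence
classifies as one insertion event — the two flank columns of a complex
insertion-deletion are otherwise disconnected, and a single flank
misreads as a simple event (a translocation, when two chromosomes are
involved). The merge assumes one event per analysed region; co-located
independent events can legitimately combine into an insertion-deletion
reading and, like all multi-event loci, need manual review. The
CLI preserves the user-guided path: `call --mode complex` demands two
explicit column ids and refuses one.

## Consensus and reporting conventions

Per-read coordinates are reduced by the per-coordinate median with ties
toward the lower value; the median is stated for gapped-indel
aggregation in the source workflow and we unify split-read consensus on
it for robustness (one outlier against ≥ 3 concordant reads never moves
the call). Conventions, fixed because per-base bracketing cannot be
pinned from published exemplars alone (their few-bp offsets from Sanger
are confounded with alignment jitter):

- deletion/duplication/inversion of span `[s, e)` → `chrom:s+1_e` with
  suffix `del`/`dup`/`inv` (first through last affected base, 1-based
  inclusive);
- translocation → `t(chrA;chrB)(g.X;g.Y)` where each coordinate is the
  1-based last base 5′ of the junction on the `+` strand (numerically
  the 0-based junction offset);
- insertion → `chrom:p_p+1ins[origin]`;
- complex → `INS(origin=chrC:x-y;inverted=yes|no);LOSS(chrB:p-q)`, a
  fixed machine-parseable layout chosen because subjective HGVS naming
  of complex events shifts with geometry.

Exports: calls as TSV, BEDPE (0-based half-open, one line per breakpoint
pair), VCF 4.2 (symbolic ALTs for intra-chromosomal simple events, BND
mate pairs otherwise), supporting-read FASTA; cluster tables as TSV.

## Gapped-alignment path

Aligners that encode a rearrangement inside one CIGAR can only represent
insertions and deletions (the alignment must remain collinear), so this
path never emits other types. I/D operations strictly longer than 10 bp
are collected from primary alignments; deletions group by single-linkage
reference-span overlap, insertions — whose reference span is a point —
by position gap within the 250 nt window (a necessary refinement, since
point spans never mutually overlap). Groups under the support threshold
are reported flagged low-confidence rather than dropped. On error-free
data the split and gapped representations of one deletion agree to 0 bp.

## Simulator

`apply_rearrangement` edits the reference and records provenance as an
ordered list of `(chrom, start, end, orientation)` pieces whose
concatenation is the rearranged sequence; a ring chromosome is a single
circular piece with the distal sequence absent. Faux reads tile the
sequence: 10 kb windows every 1 kb, even indices forward, odd reverse-
complemented; tail windows are emitted truncated so coverage reaches
contig ends, and windows wrap the ring junction. `truth_alignments`
intersects each window with the piece map (merging reference-contiguous
neighbours, through which reads align straight), picks the longest
segment as primary and writes coordinate-sorted, indexed BAMs with
consistent SA tags — replacing a mandatory aligner dependency for
hermetic tests. MAPQ is fixed at 60 and NM at 0: the reads are exact
substrings. `add_read_noise` adds seeded substitutions (always changing
the base, so counts are exactly binomial) and short indels for
sequence-level robustness tests; truth records are unchanged.

The bundled reference is synthetic — two contigs, chrA 600 kb and chrB
450 kb, generated from a fixed internal seed with short dinucleotide
patches — because the genome is only the substrate of the method, not
part of it. The size keeps the full 68-scenario round trip at desk scale
(seconds) while every event (15–140 kb) is orders of magnitude larger
than the 250 nt clustering window and the 10 kb read length, so no
behaviour of interest is size-limited. What the faux data does *not*
emulate: realistic ONT/PacBio error profiles or read-length
distributions, diploid/heterozygous mixtures, multi-mapping in repeats.
Passing the round trip therefore demonstrates the geometric correctness
of detection, classification and annotation — not robustness to real
base-calling noise, which the noise generator probes only at the
sequence level.

The 68-scenario catalogue holds 32 simple events (6 deletions, 6
inversions, 5 duplications, 8 insertions spanning cross/same-chromosome
and inverted/forward, 4 translocation composites — balanced and both
unbalanced derivatives — and 3 rings; every kind in ≥ 2 size variants)
and 36 complex insertion-deletions (same-chromosome: inverted × origin
far/near/within the copied span × 3 sizes; cross-chromosome: inverted ×
3 loss sizes × 3 origin sizes). Exactly the duplication/ring and
same-chromosome-inverted-complex scenarios are expected ambiguous.

The jittered gapped-deletion generator shifts both endpoints of each
read's reported deletion together (up to ±186 bp) with a small
independent length wobble (±4 bp), emulating the documented structure of
real gapped reports, where endpoints wander by ~190 bp while lengths
agree within 8 bp.

## Known limitations

Events whose inserted sequence is absent from the reference cannot be
placed; only the two flanking sequences are used. Copy-number and
karyotype integration, CRAM input, realignment and base-quality use are
out of scope. The block limit (10 Mb) and the one-event-per-region
assumption of automated column merging reflect the targeted, user-guided
design rather than genome-wide scanning.
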