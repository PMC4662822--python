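# Methods

## Coordinates and formats

All internal coordinates are 0-based half-open intervals; RepeatMasker
`.out` and GFF3 (both 1-based inclusive) are converted once, on read, in
`io_formats`. RNA `U` is normalized to `T` at parse time so all sequence
comparisons are over DNA. Collapsed-read multiplicities are parsed from
`_xN` / `-N` identifier suffixes (the common small-RNA convention; the
`none` dialect treats every record as multiplicity 1). The 5′ end of a
minus-strand alignment is its rightmost base; every operation that talks
about read position (window binning, ping-pong overlaps, cluster
membership) is anchored on 5′ ends, the biologically defined piRNA
position.

## Library strata

Only genome-mapping reads enter analysis. NCNU keeps every mapper with its
multiplicity and all placements; NCU restricts to reads with exactly one
genomic placement; CU collapses NCU to distinct sequences (count 1,
ordered lexicographically, with the summed original multiplicity retained
in a side table). The RPM denominator for all stages is the NCNU total —
reads per million genome-mappers. Annotation precedence is
miRNA > rRNA > tRNA > snRNA > TE > gene > unannotated; structural-RNA
matches require zero mismatches, TE matches inherit the consensus method's
3-mismatch allowance. The precedence order is a package choice (it mirrors
the bona fide exclusion, which drops exactly the four structural classes)
and is configurable.

## Cluster calling

Windows are fixed, non-overlapping, anchored at coordinate 0 (the anchor
phase is a determinism choice; the window size defaults to 5 kb). A window *qualifies* with ≥ `min_per_window` (default 10) unique
piRNA 5′ ends. A cluster candidate is a maximal run beginning and ending
on qualifying windows in which every internal run of sub-threshold windows
is at most `max_gap_windows` (default 4, i.e. 20 kb) long; sub-threshold
counts inside the span still count toward the total. Candidates must reach
`min_total = ⌊fraction · N⌋` with `fraction = 0.0005` — flooring
reproduces both reference worked values (284 from 568,080; 101 from
202,533). Cluster intervals are trimmed to the qualifying end-windows so
empty gap windows never inflate spans, and single-window clusters are
allowed if they pass `min_total`.

Two deliberate consequences of the rule, found while testing against a
brute-force enumeration oracle:

* Raising `max_gap_windows` is monotone (can only merge runs) at the
  *candidate* level, but **not** after the `min_total` filter: a merge can
  lift two individually failing runs above the total threshold, so the
  post-filter cluster count may increase.
* Gaps may never sit at a cluster edge (runs start/end on qualifying
  windows); this is the stricter of the two readings of the gap rule.

Strand bias uses strict inequalities ("more than 75 %" / "more than
90 %"): dominant fraction > 0.90 is near-exclusive, > 0.75 strong,
otherwise unbiased; the dominant strand is undefined on an exact tie.
Chromatin classes are assigned by the largest bp overlap with the domain
BED, ties resolved toward the more heterochromatic class
(pericentromeric > intercalary-diffuse > intercalary-compact >
euchromatic); assigning whole clusters to regions has no single established rule, so majority-overlap is our explicit choice.
TE content is the bp fraction covered by the union of masked intervals
(overlaps merged first). Production shares attribute each unique piRNA to
the cluster containing its 5′ end (clusters are disjoint by construction)
or to `outside_clusters`, and sum to 1.

## TE attribution

The consensus method is an ungapped, end-to-end Hamming search of the read
and its reverse complement against every consensus (vectorized over
sliding windows), keeping the single best hit per read — fewest
mismatches, then TE name, then offset, then sense before antisense. A
gapped aligner in end-to-end mode would admit indels; the ungapped search
is deterministic, oracle-checkable, and faithful to the dominant
substitution case, so small divergences from aligner-based counts on real
data are expected. The one-hit-per-read policy mirrors single-alignment
reporting in common mappers but replaces their pseudo-random choice with
an explicit tie order. The overlap method requires exact full-length
containment of the read in a single masked interval's sequence
(boundary-straddling reads miss by construction), takes the first matching
interval in (chrom, start) order, and inherits that copy's identity;
orientation is sense when the read's genomic strand equals the copy's
strand. The two methods are never merged. On a genome whose TE copies are
identical to their consensus, the overlap method and the 0-mismatch
consensus method agree read-for-read; as copies diverge, the consensus hit
rate decays while the overlap method (which reads the genomic copy) is
unaffected — both properties are asserted in the test suite.

## Signatures

1U/10A fractions are computed at 1-based read positions over reads long
enough to have that position; the denominator choice (exclude shorter
reads) matters only for position 10 in libraries with < 10-nt reads. The
ping-pong histogram counts, for each offset k in 1..30, opposite-strand
5′-end pairs with q − p + 1 = k. Two weighting modes are provided because
the field uses both normalizations: `reads` (default)
counts distinct reads having ≥ 1 partner at k, `pairs` sums products of
multiplicities. The z-score of bin 10 uses offsets 1–30 excluding 10 as
background (sample standard deviation); it is reported as undefined when
the background has no spread. The histogram is invariant under viewing the
library on the opposite genome strand (coordinate mirror plus strand
flip), which the suite asserts; a strand relabeling that keeps intervals
fixed moves 5′ ends and is *not* a symmetry of the statistic. Overlap
composition tallies base frequencies at positions 1–10 from each partner's
own 5′ end over all k = 10 pairs.

## Genic piRNAs

Reads are matched exactly (zero mismatches, full length) against the
spliced transcript sequence or its reverse complement — there is no single
established mismatch setting for genic matching, and zero mismatches is the
conservative choice consistent with genome-unique input. Matches spanning
exon junctions are flagged rather than projected to a single genomic
interval. The 3′-UTR fraction requires entire containment in the UTR
(boundary-straddlers count outside). RPM groups are half-open upward:
[5,10) → 5–10, [10,50) → 10–50, [50,∞) → >50, resolving the ambiguity of
the conventional "5–10"/"10–50" labels at the joints. TE contamination is
flagged per transcript when TE-matching reads exceed 0.5 RPM; regardless
of flagging, every read mapping to both a transcript and a TE is dropped
from genic statistics (so flagging and cleaning commute). When a gene has
several transcripts, per-gene reporting keeps the transcript with the
highest unique RPM, ties broken by transcript id.

## The synthetic landscape

The generator emulates an ovarian small-RNA library over a small
mosquito-like genome. Two construction rules make the truth exact:

* **Reads are verbatim genome substrings.** Base biases are planted by 5′
  *site selection*: with probability `u1_bias` (default 0.791, a realistic
  ovarian bona fide 1U level) a primary's 5′ site is drawn from
  positions whose genomic base reads as U, otherwise from the complement
  set; sense TE reads get the analogous position-10 A selection
  (`a10_bias`, default 0.54). Reads are never edited, so exact mapping,
  the zero-mismatch overlap method, and coordinate truth hold by
  construction.
* **Ping-pong partners are cut from opposite strands at a 10-nt 5′
  overlap**, making the secondary's position-10 base the exact complement
  of the primary's position-1 base — the cleavage geometry, not a sampled
  bias.

Read lengths follow a 24–29 nt distribution with its apex at 27 nt
(0.08/0.13/0.20/0.26/0.20/0.13); miRNA contaminants are fixed at 22 nt.
The default landscape is three chromosomes (650 kb) partitioned into
chromatin domains; four clusters (6000/4000/3000/2000 reads; strand bias
0.95 and 0.85 for the two uni-directional ones) sized so each window far
exceeds the calling threshold; ten TE copies of five consensus families,
the read-producing ones placed inside clusters (as in real genomes, where
clusters are TE graveyards) at divergences 0.02–0.06 with an LTR-dominated
class mix (0.59/0.28/0.12/0.01) and 0.69 antisense bias; three genes
(sense fraction ≈ 0.81, 3′-UTR weight 0.58); 2000 miRNA reads over five
loci; and 200 background reads.

Ping-pong pairing runs in the bi-directional clusters and is off in the
strongly uni-directional ones — secondaries land on the opposite strand,
so pairing inside a near-exclusive cluster would contradict its planted
bias; biologically, uni-strand (flamenco-like) loci are primary-pathway
loci. Genic reads are emitted from a small set of distinct 5′ sites per
(orientation × UTR) category, with multiplicity carrying the planted
fractions: real genes show few discrete piRNA 5′ ends at high multiplicity
rather than dense unique coverage, and this keeps genic loci from
masquerading as read-dense cluster windows. Background reads are drawn
uniformly outside all planted features at a rate far below the
per-window threshold, so zero-false-positive cluster tests are meaningful.

All sampling consumes one NumPy generator seeded from `spec.seed` in
documented order (consensus library → chromosomes → copy mutations → reads
feature by feature); identical spec and seed give byte-identical outputs.

What the generator does **not** emulate: sequencing errors and adapter
artifacts; gapped/indel divergence of TE copies (substitutions only, so
the consensus method's ungapped model is exact here and its gapped-aligner
discrepancy is untested); multi-chromosome gene structures; realistic
multi-mapping landscapes (multi-mappers arise only from low-divergence
copy pairs); and genome-scale library sizes. Passing tests therefore
demonstrate algorithmic correctness and calibrated recovery under the
stated noise model, not concordance with any particular real library.

## Problem sizes and tolerances

The canonical run uses ~26,000 reads on 650 kb — large enough that
binomially planted fractions recover within the asserted bands (±2–3
percentage points at n ≥ 1000) while a full pipeline run stays within tens
of seconds. The acceptance computation uses 12,000 primary/secondary pairs
on a 400-kb chromosome. Recovery tolerances in the suite are simple
binomial bounds at the planted n, never fitted to observed runs. Fraction
comparisons use absolute tolerances; RPM values are reported to one
decimal in tables but compared at full precision in code.
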