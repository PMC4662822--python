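# pirnakit

Analysis pipeline for PIWI-interacting RNA (piRNA) populations in
small-RNA sequencing libraries: piRNA cluster identification, strand-bias
and chromatin classification, transposable-element (TE) attribution,
ping-pong signature statistics, and genic 3′-UTR piRNA profiling — together
with a synthetic-data generator that plants all of these structures in a
small genome with exact truth tables, so every stage is testable without
external downloads.

It is written for people studying germline small-RNA silencing in insects
(mosquito- and fly-like genomes in particular), and for anyone who needs a
transparent, oracle-checked reimplementation of the standard piRNA
analyses over FASTA/FASTQ reads, BED alignments, RepeatMasker annotation
and GFF3 gene models.

## The analyses

**Library strata.** Reads are analyzed in three strata: NCNU
(non-collapsed non-unique: all genome-mapping reads with multiplicity, for
TE and signature analysis), NCU (non-collapsed unique: genome-unique
mappers with duplicates, for gene profiling), and CU (collapsed unique:
distinct genome-unique sequences, for cluster calling). Bona fide piRNAs
are the 24–29 nt reads left after removing miRNA/rRNA/tRNA/snRNA matches.

**Cluster calling.** Unique piRNA 5′ ends are binned into non-overlapping
5-kb windows. A cluster is a maximal run of windows starting and ending on
windows with ≥ 10 piRNAs, in which gaps of up to 4 consecutive
sub-threshold windows (20 kb) may continue the run; a candidate is kept if
its total count reaches 0.05 % of the unique-mapper library
(⌊0.0005·N⌋, e.g. 284 of 568,080). Clusters with > 75 % of piRNAs on one
strand are *strongly* biased, > 90 % *near-exclusively* — the signature of
uni-directional transcription. Chromatin domains (pericentromeric,
intercalary, euchromatic) are assigned by majority bp overlap, TE content
as the repeat-masked fraction of cluster bp.

**TE attribution, two ways.** The *consensus* method places a read
end-to-end, ungapped, inside a TE consensus at Hamming distance ≤ 3; the
*overlap* method requires exact full-length containment in a repeat-masked
genomic copy. Each method reports at most one hit per read with
deterministic tie-breaking; hits aggregate into class/family fractions and
an antisense-bias estimate.

**Ping-pong signature.** For a plus-strand 5′ end at *p* and a
minus-strand 5′ end at *q*, the 5′–5′ overlap is *k = q − p + 1*; the
histogram of *k* over 1–30 peaks at 10 nt in a ping-pong-active library
(scored as a z-value of bin 10 against the other offsets), accompanied by
1U (uridine at position 1) and 10A (adenine at position 10) biases that
are Watson–Crick complements of each other across the overlap.

**Genic piRNAs.** Genome-unique reads are matched exactly against spliced
transcripts; abundance is normalized as RPM (reads per million
genome-mappers, e.g. 14,350 reads of 16,691,820 = 859.7 RPM). Transcripts
whose reads are shared with TEs above 0.5 RPM are flagged and dual-mapping
reads removed; profiles report sense fraction, the fraction of reads fully
inside the 3′ UTR, and the RPM group (5–10 / 10–50 / > 50).

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic landscape (tables land under `results/`, intermediate data under
`scratch/`):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_prepare_library.py
python analysis/03_call_clusters.py
python analysis/04_te_attribution.py
python analysis/05_signatures.py
python analysis/06_gene_pirnas.py
```

Step 03 prints (seed 1):

```
CU library: 20255 unique piRNAs -> min_total = 10
called 4 clusters (planted: 4):
 rank chrom  start    end  n_unique_pirnas  dominant_fraction bias_class ...
    1  chr1  10000  50000             7596              0.882     strong
    2  chr1 100000 130000             6247              0.509   unbiased
    3  chr2  10000  35000             3247              0.825     strong
    4  chr3 110000 130000             2953              0.504   unbiased
boundary recovery within one window: 4/4; false clusters: 0
```

All four planted clusters are recovered at their exact window boundaries
with no false calls; the two uni-directionally transcribed clusters come
back strand-biased, the two bi-directional ones unbiased. Step 04 reports
the planted LTR-dominated class mix (`LTR 0.588, non-LTR 0.264, DNA 0.129,
SINE 0.020` by the consensus method, vs the planted 0.59/0.28/0.12/0.01
plus cluster reads falling inside TE copies), and step 05 prints

```
ping-pong modal offset: 10 nt (z10 = 94.1, 4696 pairs at 10 nt)
```

— the 10-nt 5′ overlap planted by the simulator's cleavage rule. Step 06
recovers each gene's planted ~0.81 sense fraction and ~0.58 3′-UTR
fraction.

The same pipeline is available as subcommands
(`pirnakit simulate|prep|clusters|te|signatures|genes|run`) over a YAML
config whose defaults are the standard analysis parameters; every output
table carries the config hash that produced it.

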