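#!/usr/bin/env python
"""Size-select, annotate and stratify the small-RNA library.

Maps the simulated reads back to the genome (exact matching), annotates
each read (miRNA > rRNA > tRNA > snRNA > TE > gene > unannotated), keeps
the bona fide 24-29 nt piRNA pool, and builds the three strata: NCNU (all
genome-mappers), NCU (genome-unique), CU (collapsed unique).  The strata
feed cluster calling (CU), TE/signature analysis (NCNU) and gene profiling
(NCU).
"""

import argparse
from pathlib import Path

import pandas as pd

from pirnakit import gene_pirna as gp
from pirnakit import io_formats as io
from pirnakit import library_prep as lp
from pirnakit import te_attribution as te


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scratch", type=Path, default=Path("scratch/synthetic"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)
    prep_dir = args.scratch / "prep"
    prep_dir.mkdir(parents=True, exist_ok=True)

    reads = io.read_small_rna_fastq(args.scratch / "reads.fastq", "none")
    genome = io.read_genome_fasta(args.scratch / "genome.fa")
    te_library = io.read_te_consensus_fasta(args.scratch / "te_consensus.fa")
    mirna = [r.sequence for r in io.read_small_rna_fasta(args.scratch / "mirna_loci.fa", "none")]

    alignments = lp.map_reads_exact(reads, genome)

    def te_attributor(rs):
        return {h.read_id for h in te.consensus_map(rs, te_library)}

    transcripts = io.read_gff3_transcripts(args.scratch / "transcripts.gff3")
    tx_seqs = [gp.spliced_sequence(tx, genome) for tx in transcripts]
    annotations = lp.annotate_reads(reads, {"miRNA": mirna}, te_attributor, tx_seqs)
    summary = (
        pd.Series(list(annotations.values()))
        .value_counts()
        .rename_axis("category")
        .reset_index(name="reads")
    )
    summary["fraction"] = (summary.reads / summary.reads.sum()).round(4)
    summary.to_csv(args.results / "02_annotation_summary.tsv", sep="\t", index=False)

    pirna = lp.size_filter(reads, 24, 29)
    bona_fide = lp.bona_fide_filter(pirna, annotations)
    ids = {r.id for r in bona_fide}
    strata = lp.build_strata(bona_fide, [a for a in alignments if a.read_id in ids])

    rows = []
    for label, stratum in strata.items():
        rows.append(dict(stratum=label, reads=stratum.total_reads,
                         distinct=len({r.sequence for r in stratum.reads})))
    pd.DataFrame(rows).to_csv(
        args.results / "02_library_strata.tsv", sep="\t", index=False
    )

    io.write_alignments_bed(strata["CU"].alignments, prep_dir / "cu_alignments.bed")
    io.write_alignments_bed(strata["NCNU"].alignments, prep_dir / "ncnu_alignments.bed")
    with open(prep_dir / "ncnu_reads.fa", "w") as fh:
        for r in strata["NCNU"].reads:
            fh.write(f">{r.id}\n{r.sequence}\n")
    with open(prep_dir / "ncu_reads.fa", "w") as fh:
        for r in strata["NCU"].reads:
            fh.write(f">{r.id}\n{r.sequence}\n")

    print("annotation of the full library:")
    print(summary.to_string(index=False))
    print("\npiRNA-sized (24-29 nt) bona fide strata:")
    print(pd.DataFrame(rows).to_string(index=False))


if __name__ == "__main__":
    main()
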