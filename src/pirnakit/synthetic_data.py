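"""Synthetic genomes and small-RNA libraries with planted ground truth.

The generator emulates the structure of an ovarian small-RNA library from a
mosquito-like genome: piRNA clusters (uni- or bi-directionally
transcribed), TE copies diverged from their family consensus, ping-pong
primary/secondary pairs with 10-nt 5' overlaps, genic piRNAs concentrated
in 3'-UTRs, a 22-nt miRNA contaminant peak, and sparse background reads —
together with machine-readable truth tables so every pipeline stage can be
tested without external data.

Two construction rules keep the truth exact:

* **Reads are always verbatim genome substrings.**  Base biases (1U on
  primary piRNAs, 10A on sense TE piRNAs) are planted by *site selection* —
  with probability ``u1_bias`` a primary's 5' site is drawn from positions
  whose genomic base reads as U, otherwise from the complement set — never
  by editing the read.  Exact mapping, the zero-mismatch overlap method,
  and coordinate truth therefore hold by construction.
* **Ping-pong partners are cut from opposite genomic strands at a 10-nt
  5' overlap**, so the secondary's position-10 base is the Watson-Crick
  complement of the primary's position-1 base, exactly.

All sampling consumes a single NumPy generator seeded from ``spec.seed``
in documented order (consensus library, chromosome sequences, TE-copy
mutations, then reads feature-by-feature), so identical spec + seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AlignmentRecord,
    GenomicInterval,
    MaskedInterval,
    SmallRNARead,
    TEConsensus,
    TranscriptModel,
    revcomp,
    write_alignments_bed,
    write_domains_bed,
    write_genome_fasta,
    write_masked_bed,
    write_reads_fastq,
    write_te_consensus_fasta,
    write_transcripts_gff3,
)

__all__ = [
    "TEConsensusSpec",
    "PlantedTECopy",
    "PlantedCluster",
    "PlantedGene",
    "SimulationSpec",
    "SyntheticDataset",
    "default_spec",
    "build_genome",
    "simulate_reads",
    "generate",
    "write_outputs",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# default piRNA length distribution: broad 24-29 nt peak with its apex at 27
DEFAULT_LENGTHS: dict[int, float] = {
    24: 0.08,
    25: 0.13,
    26: 0.20,
    27: 0.26,
    28: 0.20,
    29: 0.13,
}


@dataclass(frozen=True)
class TEConsensusSpec:
    name: str
    te_class: str
    te_family: str
    length: int


@dataclass(frozen=True)
class PlantedTECopy:
    consensus_name: str
    interval: GenomicInterval  # strand = the copy's orientation
    divergence: float = 0.0
    n_reads: int = 0
    antisense_prob: float = 0.69  # fraction of reads opposing the TE


@dataclass(frozen=True)
class PlantedCluster:
    interval: GenomicInterval
    n_reads: int
    strand_bias: float = 0.5       # probability of the dominant strand
    directionality: str = "bi"     # uni | bi
    dominant_strand: str = "+"
    pingpong_fraction: Optional[float] = None  # None -> spec default


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    transcript_id: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    utr3: Optional[GenomicInterval]
    n_sense_reads: int
    n_antisense_reads: int
    utr3_weight: float = 0.58
    sirna_fraction: float = 0.2    # fraction of reads emitted at 21 nt
    sites_per_category: int = 1    # distinct source sites per orientation x location


@dataclass
class SimulationSpec:
    seed: int
    chrom_lengths: dict[str, int]
    te_library: list[TEConsensusSpec] = field(default_factory=list)
    te_copies: list[PlantedTECopy] = field(default_factory=list)
    planted_clusters: list[PlantedCluster] = field(default_factory=list)
    genes: list[PlantedGene] = field(default_factory=list)
    chromatin_domains: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    pingpong_fraction: float = 0.5
    u1_bias: float = 0.791
    a10_bias: float = 0.54
    length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTHS)
    )
    n_mirna_loci: int = 5
    n_mirna_reads: int = 2000
    mirna_length: int = 22
    n_background_reads: int = 200

    def validate(self) -> None:
        total = sum(self.length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"length distribution sums to {total}, not 1")
        max_len = max(self.length_distribution)
        for iv in self._all_feature_intervals():
            if iv.chrom not in self.chrom_lengths:
                raise ValueError(f"feature on undeclared chromosome {iv.chrom!r}")
            if iv.end > self.chrom_lengths[iv.chrom]:
                raise ValueError(
                    f"feature [{iv.start},{iv.end}) beyond {iv.chrom} length"
                )
        for c in self.planted_clusters:
            if not (0.5 <= c.strand_bias <= 1.0):
                raise ValueError("cluster strand_bias must be in [0.5, 1]")
            if len(c.interval) < max_len:
                raise ValueError("planted cluster shorter than max read length")
        for t in self.te_copies:
            if t.n_reads and len(t.interval) < max_len:
                raise ValueError("read-producing TE copy shorter than max read length")
            if not (0 <= t.divergence <= 0.2):
                raise ValueError("divergence must be in [0, 0.2]")
        self._check_disjoint()

    def _all_feature_intervals(self) -> list[GenomicInterval]:
        out = [c.interval for c in self.planted_clusters]
        out += [t.interval for t in self.te_copies]
        for g in self.genes:
            out += list(g.exons)
        return out

    def _check_disjoint(self) -> None:
        """TE copies may sit inside clusters; all other overlaps are errors."""
        clusters = [c.interval for c in self.planted_clusters]

        def in_cluster(iv: GenomicInterval) -> bool:
            return any(c.contains(iv) for c in clusters)

        independent: list[tuple[str, GenomicInterval]] = []
        for i, c in enumerate(clusters):
            independent.append((f"cluster{i}", c))
        for t in self.te_copies:
            if not in_cluster(t.interval):
                independent.append((t.consensus_name, t.interval))
        for g in self.genes:
            for e in g.exons:
                independent.append((g.gene_id, e))
        by_chrom: dict[str, list[tuple[str, GenomicInterval]]] = {}
        for name, iv in independent:
            by_chrom.setdefault(iv.chrom, []).append((name, iv))
        for items in by_chrom.values():
            items.sort(key=lambda t: t[1].start)
            for (na, a), (nb, b) in zip(items, items[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping planted features {na} and {nb} on {a.chrom}"
                    )


@dataclass
class SyntheticDataset:
    spec: SimulationSpec
    genome: dict[str, str]
    te_library: list[TEConsensus]
    masked_intervals: list[MaskedInterval]
    transcripts: list[TranscriptModel]
    mirna_loci: list[GenomicInterval]
    reads: list[SmallRNARead]
    alignments: list[AlignmentRecord]
    truth: pd.DataFrame

    @property
    def mirna_sequences(self) -> list[str]:
        return [
            self.genome[iv.chrom][iv.start : iv.end] for iv in self.mirna_loci
        ]


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Substitute each base independently with the given probability."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < divergence)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii")


def build_genome(
    spec: SimulationSpec, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, str], list[TEConsensus], list[MaskedInterval], list[TranscriptModel], list[GenomicInterval]]:
    """Materialize the genome and its planted annotation.

    Chromosomes are random sequence; each planted TE copy overwrites its
    interval with the consensus mutated at the stated divergence (reverse
    complemented for minus-strand copies); genes and miRNA loci simply
    adopt the background sequence under their annotation.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    consensus_seqs = {
        t.name: _random_seq(rng, t.length) for t in spec.te_library
    }
    te_library = [
        TEConsensus(t.name, t.te_class, t.te_family, consensus_seqs[t.name])
        for t in spec.te_library
    ]
    by_name = {t.name: t for t in te_library}

    genome = {
        chrom: bytearray(_random_seq(rng, n).encode("ascii"))
        for chrom, n in sorted(spec.chrom_lengths.items())
    }

    masked: list[MaskedInterval] = []
    for copy in spec.te_copies:
        te = by_name.get(copy.consensus_name)
        if te is None:
            raise ValueError(f"unknown consensus {copy.consensus_name!r}")
        span = len(copy.interval)
        if span > len(te.sequence):
            raise ValueError(
                f"copy of {te.name} longer than its consensus ({span} > "
                f"{len(te.sequence)})"
            )
        insert = _mutate(rng, te.sequence[:span], copy.divergence)
        if copy.interval.strand == "-":
            insert = revcomp(insert)
        genome[copy.interval.chrom][
            copy.interval.start : copy.interval.end
        ] = insert.encode("ascii")
        masked.append(
            MaskedInterval(
                interval=copy.interval,
                te_name=te.name,
                te_class=te.te_class,
                te_family=te.te_family,
            )
        )

    transcripts = [
        TranscriptModel(
            gene_id=g.gene_id,
            transcript_id=g.transcript_id,
            strand=g.strand,
            exons=g.exons,
            utr3=g.utr3,
        )
        for g in spec.genes
    ]

    # miRNA loci: fixed-length spans in feature-free territory
    mirna_loci = _place_mirna_loci(spec, rng)

    genome_str = {c: bytes(b).decode("ascii") for c, b in genome.items()}
    return genome_str, te_library, masked, transcripts, mirna_loci


def _feature_free_segments(spec: SimulationSpec) -> dict[str, list[tuple[int, int]]]:
    occupied: dict[str, list[tuple[int, int]]] = {
        c: [] for c in spec.chrom_lengths
    }
    for iv in spec._all_feature_intervals():
        occupied[iv.chrom].append((iv.start, iv.end))
    free: dict[str, list[tuple[int, int]]] = {}
    for chrom, spans in occupied.items():
        spans.sort()
        segments = []
        cursor = 0
        for s, e in spans:
            if s > cursor:
                segments.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < spec.chrom_lengths[chrom]:
            segments.append((cursor, spec.chrom_lengths[chrom]))
        free[chrom] = segments
    return free


def _place_mirna_loci(
    spec: SimulationSpec, rng: np.random.Generator
) -> list[GenomicInterval]:
    free = _feature_free_segments(spec)
    segments = [
        (chrom, s, e)
        for chrom in sorted(free)
        for (s, e) in free[chrom]
        if e - s >= spec.mirna_length + 2000
    ]
    loci = []
    for i in range(spec.n_mirna_loci):
        chrom, s, e = segments[i % len(segments)]
        # deterministic spread within the segment, away from its edges
        offset = s + 1000 + int(
            (e - s - 2000 - spec.mirna_length) * ((i // len(segments)) * 0.37 + 0.13)
        ) % max(e - s - 2000 - spec.mirna_length, 1)
        loci.append(
            GenomicInterval(chrom, offset, offset + spec.mirna_length, "+")
        )
    return loci


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

class _SiteSampler:
    """Draws biased 5'-end sites within one genomic interval.

    Keeps, per base, the sorted genomic positions carrying that base, so a
    constraint of the form "read position j must read as base B" can be
    sampled in O(log n) with exact fit bounds.
    """

    def __init__(self, genome: Mapping[str, str], interval: GenomicInterval):
        self.chrom = interval.chrom
        self.start = interval.start
        self.end = interval.end
        seq = np.frombuffer(
            genome[self.chrom][self.start : self.end].encode("ascii"), dtype=np.uint8
        )
        self.positions = {
            b: self.start + np.flatnonzero(seq == ord(b)) for b in "ACGT"
        }

    def _anchor_range(self, strand: str, length: int, j: int) -> tuple[int, int]:
        # genomic anchor g for read position j: '+' -> p = g-(j-1);
        # '-' -> q = g+(j-1); bounds keep the read inside the interval
        if strand == "+":
            return self.start + j - 1, self.end - length + j - 1
        return self.start + length - j, self.end - j

    def sample(
        self,
        rng: np.random.Generator,
        strand: str,
        length: int,
        j: int,
        read_base: str,
        want: bool,
    ) -> Optional[int]:
        """A 5' position whose read position ``j`` does/doesn't read ``read_base``.

        Returns None when no eligible site exists.
        """
        genomic_base = (
            read_base if strand == "+" else read_base.translate(str.maketrans("ACGT", "TGCA"))
        )
        lo, hi = self._anchor_range(strand, length, j)
        if want:
            bases = [genomic_base]
        else:
            bases = [b for b in "ACGT" if b != genomic_base]
        pools = []
        weights = []
        for b in bases:
            arr = self.positions[b]
            a = int(np.searchsorted(arr, lo, side="left"))
            z = int(np.searchsorted(arr, hi, side="right"))
            if z > a:
                pools.append((arr, a, z))
                weights.append(z - a)
        if not pools:
            return None
        total = sum(weights)
        pick = int(rng.integers(0, total))
        for (arr, a, z), w in zip(pools, weights):
            if pick < w:
                g = int(arr[a + pick])
                break
            pick -= w
        return g - (j - 1) if strand == "+" else g + (j - 1)

    def sample_any(
        self, rng: np.random.Generator, strand: str, length: int
    ) -> int:
        if strand == "+":
            return int(rng.integers(self.start, self.end - length + 1))
        return int(rng.integers(self.start + length - 1, self.end))


def _draw_length(rng: np.random.Generator, dist: dict[int, float]) -> int:
    lengths = sorted(dist)
    probs = np.array([dist[l] for l in lengths])
    return int(rng.choice(lengths, p=probs / probs.sum()))


def _extract(genome: Mapping[str, str], chrom: str, five: int, length: int, strand: str) -> tuple[int, int, str]:
    """(start, end, sequence) of a read with the given 5' end."""
    if strand == "+":
        start, end = five, five + length
    else:
        start, end = five - length + 1, five + 1
    if start < 0 or end > len(genome[chrom]):
        raise ValueError(f"read would leave {chrom}: [{start},{end})")
    seq = genome[chrom][start:end]
    return start, end, (seq if strand == "+" else revcomp(seq))


class _Emitter:
    def __init__(self) -> None:
        self.reads: list[SmallRNARead] = []
        self.alignments: list[AlignmentRecord] = []
        self.rows: list[dict] = []

    def emit(
        self,
        genome: Mapping[str, str],
        read_id: str,
        chrom: str,
        five: int,
        length: int,
        strand: str,
        source: str,
        feature_id: str,
        role: str = "na",
        partner_id: str = "",
        orientation: str = "na",
        in_utr3: Optional[bool] = None,
    ) -> None:
        start, end, seq = _extract(genome, chrom, five, length, strand)
        self.reads.append(SmallRNARead(id=read_id, sequence=seq, count=1))
        self.alignments.append(
            AlignmentRecord(
                read_id=read_id,
                interval=GenomicInterval(chrom, start, end, strand),
                n_genome_hits=1,
            )
        )
        self.rows.append(
            dict(
                read_id=read_id,
                source=source,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                feature_id=feature_id,
                role=role,
                partner_id=partner_id,
                orientation=orientation,
                in_utr3="" if in_utr3 is None else str(bool(in_utr3)),
                length=length,
            )
        )


def _simulate_cluster_reads(
    spec: SimulationSpec,
    genome: Mapping[str, str],
    rng: np.random.Generator,
    em: _Emitter,
) -> None:
    for ci, cluster in enumerate(spec.planted_clusters):
        cid = f"cluster{ci}"
        sampler = _SiteSampler(genome, cluster.interval)
        pp = (
            cluster.pingpong_fraction
            if cluster.pingpong_fraction is not None
            else spec.pingpong_fraction
        )
        for ri in range(cluster.n_reads):
            if cluster.directionality == "uni":
                on_dominant = rng.random() < cluster.strand_bias
                strand = (
                    cluster.dominant_strand
                    if on_dominant
                    else ("-" if cluster.dominant_strand == "+" else "+")
                )
            else:
                strand = "+" if rng.random() < 0.5 else "-"
            length = _draw_length(rng, spec.length_distribution)
            want_u = rng.random() < spec.u1_bias
            five = sampler.sample(rng, strand, length, j=1, read_base="T", want=want_u)
            if five is None:
                five = sampler.sample_any(rng, strand, length)
            rid = f"{cid}_p{ri:05d}"
            partner = ""
            if rng.random() < pp:
                partner = f"{cid}_s{ri:05d}"
            em.emit(
                genome, rid, cluster.interval.chrom, five, length, strand,
                source="cluster", feature_id=cid, role="primary",
                partner_id=partner,
            )
            if partner:
                l2 = _draw_length(rng, spec.length_distribution)
                if strand == "+":
                    s_strand, s_five = "-", five + 9
                else:
                    s_strand, s_five = "+", five - 9
                try:
                    em.emit(
                        genome, partner, cluster.interval.chrom, s_five, l2,
                        s_strand, source="cluster", feature_id=cid,
                        role="secondary", partner_id=rid,
                    )
                except ValueError:
                    em.rows[-1]["partner_id"] = ""  # partner did not fit


def _simulate_te_reads(
    spec: SimulationSpec,
    genome: Mapping[str, str],
    rng: np.random.Generator,
    em: _Emitter,
) -> None:
    for ti, copy in enumerate(spec.te_copies):
        if copy.n_reads == 0:
            continue
        tid = f"te{ti}_{copy.consensus_name}"
        sampler = _SiteSampler(genome, copy.interval)
        copy_strand = copy.interval.strand if copy.interval.strand in "+-" else "+"
        for ri in range(copy.n_reads):
            antisense = rng.random() < copy.antisense_prob
            strand = (
                ("-" if copy_strand == "+" else "+") if antisense else copy_strand
            )
            length = _draw_length(rng, spec.length_distribution)
            if antisense:
                # primary-like: 1U bias at the 5' end
                want = rng.random() < spec.u1_bias
                five = sampler.sample(rng, strand, length, j=1, read_base="T", want=want)
            else:
                # secondary-like: 10A bias
                want = rng.random() < spec.a10_bias
                five = sampler.sample(rng, strand, length, j=10, read_base="A", want=want)
            if five is None:
                five = sampler.sample_any(rng, strand, length)
            em.emit(
                genome, f"{tid}_r{ri:05d}", copy.interval.chrom, five, length,
                strand, source="TE", feature_id=copy.consensus_name,
                orientation="antisense" if antisense else "sense",
            )


def _gene_sites(
    spec: SimulationSpec,
    gene: PlantedGene,
    genome: Mapping[str, str],
    rng: np.random.Generator,
) -> dict[tuple[str, bool], list[tuple[int, int, str]]]:
    """Pre-drawn source sites per (orientation, in_utr3) category.

    Each site is (5' position, length, genomic strand).  Keeping the number
    of distinct sites small while multiplicity carries the planted
    fractions mirrors the few discrete piRNA 5' ends real genes show, and
    keeps genic loci below the per-window distinct-read threshold of the
    cluster caller.  Within a category, site lengths follow the siRNA/piRNA
    mixture by largest-remainder allocation.
    """
    utr = gene.utr3
    exonic: list[GenomicInterval] = list(gene.exons)
    sites: dict[tuple[str, bool], list[tuple[int, int, str]]] = {}
    n_sites = gene.sites_per_category

    def site_lengths() -> list[int]:
        n21 = int(round(gene.sirna_fraction * n_sites))
        lens = [21] * n21
        while len(lens) < n_sites:
            lens.append(_draw_length(rng, spec.length_distribution))
        return lens

    for orientation in ("sense", "antisense"):
        genomic_strand = (
            gene.strand
            if orientation == "sense"
            else ("-" if gene.strand == "+" else "+")
        )
        for in_utr in (True, False):
            chosen: list[tuple[int, int, str]] = []
            for length in site_lengths():
                regions = []
                for e in exonic:
                    lo, hi = e.start, e.end
                    if utr is not None:
                        if in_utr:
                            lo, hi = max(lo, utr.start), min(hi, utr.end)
                        else:
                            # entirely outside the UTR, no straddling
                            if utr.start <= lo < utr.end or utr.start < hi <= utr.end:
                                if lo >= utr.start and hi <= utr.end:
                                    continue
                            if lo < utr.start:
                                hi = min(hi, utr.start)
                            elif hi > utr.end:
                                lo = max(lo, utr.end)
                    elif in_utr:
                        continue
                    if hi - lo >= length:
                        regions.append((lo, hi))
                if not regions:
                    continue
                lo, hi = regions[int(rng.integers(0, len(regions)))]
                if genomic_strand == "+":
                    five = int(rng.integers(lo, hi - length + 1))
                else:
                    five = int(rng.integers(lo + length - 1, hi))
                chosen.append((five, length, genomic_strand))
            if chosen:
                sites[(orientation, in_utr)] = chosen
    return sites


def _simulate_gene_reads(
    spec: SimulationSpec,
    genome: Mapping[str, str],
    rng: np.random.Generator,
    em: _Emitter,
) -> None:
    for gene in spec.genes:
        sites = _gene_sites(spec, gene, genome, rng)
        n_total = gene.n_sense_reads + gene.n_antisense_reads
        p_sense = gene.n_sense_reads / n_total if n_total else 0.0
        for ri in range(n_total):
            orientation = "sense" if rng.random() < p_sense else "antisense"
            in_utr = gene.utr3 is not None and rng.random() < gene.utr3_weight
            pool = sites.get((orientation, in_utr)) or sites.get(
                (orientation, not in_utr)
            )
            if not pool:
                continue
            five, length, strand = pool[int(rng.integers(0, len(pool)))]
            em.emit(
                genome, f"{gene.gene_id}_r{ri:05d}", gene.exons[0].chrom,
                five, length, strand, source="gene",
                feature_id=gene.gene_id, orientation=orientation,
                in_utr3=in_utr,
            )


def _simulate_mirna_reads(
    spec: SimulationSpec,
    genome: Mapping[str, str],
    mirna_loci: Sequence[GenomicInterval],
    rng: np.random.Generator,
    em: _Emitter,
) -> None:
    if not mirna_loci:
        return
    for ri in range(spec.n_mirna_reads):
        li = int(rng.integers(0, len(mirna_loci)))
        iv = mirna_loci[li]
        em.emit(
            genome, f"mir{li}_r{ri:05d}", iv.chrom, iv.start,
            spec.mirna_length, "+", source="miRNA", feature_id=f"mir{li}",
        )


def _simulate_background_reads(
    spec: SimulationSpec,
    genome: Mapping[str, str],
    mirna_loci: Sequence[GenomicInterval],
    rng: np.random.Generator,
    em: _Emitter,
) -> None:
    free = _feature_free_segments(spec)
    max_len = max(spec.length_distribution)
    mirna_spans = {(iv.chrom, iv.start, iv.end) for iv in mirna_loci}
    segments = []
    for chrom in sorted(free):
        for s, e in free[chrom]:
            # carve out miRNA loci, which were placed in free space
            spans = [(s, e)]
            for mc, ms, me in sorted(mirna_spans):
                if mc != chrom:
                    continue
                spans = [
                    piece
                    for a, b in spans
                    for piece in (((a, min(b, ms)),) if a < ms else ())
                    + (((max(a, me), b),) if b > me else ())
                    if piece[0] < piece[1]
                ]
            for a, b in spans:
                if b - a > max_len:
                    segments.append((chrom, a, b))
    if not segments:
        return
    weights = np.array([b - a for _, a, b in segments], dtype=float)
    weights /= weights.sum()
    for ri in range(spec.n_background_reads):
        si = int(rng.choice(len(segments), p=weights))
        chrom, a, b = segments[si]
        strand = "+" if rng.random() < 0.5 else "-"
        length = _draw_length(rng, spec.length_distribution)
        if strand == "+":
            five = int(rng.integers(a, b - length + 1))
        else:
            five = int(rng.integers(a + length - 1, b))
        em.emit(
            genome, f"bg_r{ri:05d}", chrom, five, length, strand,
            source="background", feature_id="background",
        )


def simulate_reads(
    spec: SimulationSpec,
    genome: Mapping[str, str],
    mirna_loci: Sequence[GenomicInterval],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[SmallRNARead], list[AlignmentRecord], pd.DataFrame]:
    """Emit the synthetic library with its truth placements and labels."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    em = _Emitter()
    _simulate_cluster_reads(spec, genome, rng, em)
    _simulate_te_reads(spec, genome, rng, em)
    _simulate_gene_reads(spec, genome, rng, em)
    _simulate_mirna_reads(spec, genome, mirna_loci, rng, em)
    _simulate_background_reads(spec, genome, mirna_loci, rng, em)
    truth = pd.DataFrame(em.rows)
    return em.reads, em.alignments, truth


def generate(spec: SimulationSpec) -> SyntheticDataset:
    """Build genome and library from one seeded stream (the canonical entry)."""
    rng = np.random.default_rng(spec.seed)
    genome, te_library, masked, transcripts, mirna_loci = build_genome(spec, rng)
    reads, alignments, truth = simulate_reads(spec, genome, mirna_loci, rng)
    return SyntheticDataset(
        spec=spec,
        genome=genome,
        te_library=te_library,
        masked_intervals=masked,
        transcripts=transcripts,
        mirna_loci=mirna_loci,
        reads=reads,
        alignments=alignments,
        truth=truth,
    )


def write_outputs(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write the dataset as plain-text files; returns {artifact: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "reads": outdir / "reads.fastq",
        "alignments": outdir / "alignments.bed",
        "truth": outdir / "truth.tsv",
        "te_consensus": outdir / "te_consensus.fa",
        "masked": outdir / "te_masked.bed",
        "transcripts": outdir / "transcripts.gff3",
        "domains": outdir / "domains.bed",
        "clusters_truth": outdir / "clusters_truth.bed",
        "mirna": outdir / "mirna_loci.fa",
    }
    write_genome_fasta(dataset.genome, paths["genome"])
    write_reads_fastq(dataset.reads, paths["reads"])
    write_alignments_bed(dataset.alignments, paths["alignments"])
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    write_te_consensus_fasta(dataset.te_library, paths["te_consensus"])
    write_masked_bed(dataset.masked_intervals, paths["masked"])
    write_transcripts_gff3(dataset.transcripts, paths["transcripts"])
    write_domains_bed(dataset.spec.chromatin_domains, paths["domains"])
    with open(paths["clusters_truth"], "wt") as fh:
        for i, c in enumerate(dataset.spec.planted_clusters):
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t"
                f"cluster{i}\t{c.n_reads}\t"
                f"{c.dominant_strand if c.directionality == 'uni' else '.'}\n"
            )
    with open(paths["mirna"], "wt") as fh:
        for i, seq in enumerate(dataset.mirna_sequences):
            fh.write(f">mir{i}\n{seq}\n")
    return paths


# ---------------------------------------------------------------------------
# the default study landscape
# ---------------------------------------------------------------------------

def default_spec(seed: int = 0) -> SimulationSpec:
    """The canonical synthetic landscape the pipeline is exercised on.

    Three chromosomes (650 kb total) partitioned into chromatin domains;
    four planted clusters — near-exclusive and strong uni-directional,
    plus two bi-directional — holding diverged TE copies whose reads
    follow the antisense-biased, LTR-dominated class mix; three genes with
    3'-UTR-concentrated, sense-biased piRNAs; a 22-nt miRNA contaminant
    peak; and sparse background far below the cluster-calling threshold.
    """
    L = GenomicInterval
    clusters = [
        PlantedCluster(L("chr1", 10_000, 50_000), 6000, 0.95, "uni", "+"),
        PlantedCluster(L("chr1", 100_000, 130_000), 4000, 0.5, "bi"),
        PlantedCluster(L("chr2", 10_000, 35_000), 3000, 0.85, "uni", "-"),
        PlantedCluster(L("chr3", 110_000, 130_000), 2000, 0.5, "bi"),
    ]
    te_library = [
        TEConsensusSpec("Gypsy1", "LTR", "Gypsy", 1500),
        TEConsensusSpec("Bel1", "LTR", "BEL", 1200),
        TEConsensusSpec("Juan1", "non-LTR", "Jockey", 1100),
        TEConsensusSpec("Mar1", "DNA", "Mariner", 800),
        TEConsensusSpec("Sine1", "SINE", "SINEX", 300),
    ]
    # read-producing copies sit inside clusters (strands chosen so the
    # antisense-dominant reads reinforce the cluster's planted strand);
    # silent higher-divergence copies populate the genomic TE landscape
    te_copies = [
        PlantedTECopy("Gypsy1", L("chr1", 12_000, 13_500, "-"), 0.03, 700),
        PlantedTECopy("Gypsy1", L("chr1", 30_000, 31_500, "-"), 0.05, 570),
        PlantedTECopy("Bel1", L("chr1", 40_000, 41_200, "-"), 0.04, 500),
        PlantedTECopy("Juan1", L("chr1", 20_000, 21_100, "-"), 0.04, 500),
        PlantedTECopy("Juan1", L("chr2", 15_000, 16_100, "+"), 0.06, 340),
        PlantedTECopy("Mar1", L("chr1", 108_000, 108_800, "+"), 0.03, 360),
        PlantedTECopy("Sine1", L("chr1", 45_000, 45_300, "-"), 0.02, 30),
        PlantedTECopy("Gypsy1", L("chr1", 200_000, 201_500, "+"), 0.15),
        PlantedTECopy("Mar1", L("chr3", 50_000, 50_800, "-"), 0.12),
        PlantedTECopy("Bel1", L("chr2", 120_000, 121_200, "+"), 0.10),
    ]
    genes = [
        PlantedGene(
            "gene1", "gene1-RA", "+",
            (L("chr2", 60_000, 61_200), L("chr2", 61_800, 63_000)),
            L("chr2", 62_400, 63_000),
            n_sense_reads=1200, n_antisense_reads=280,
        ),
        PlantedGene(
            "gene2", "gene2-RA", "-",
            (L("chr3", 20_000, 22_000),),
            L("chr3", 20_000, 20_600),
            n_sense_reads=800, n_antisense_reads=190,
        ),
        PlantedGene(
            "gene3", "gene3-RA", "+",
            (L("chr2", 150_000, 151_500),),
            L("chr2", 151_000, 151_500),
            n_sense_reads=500, n_antisense_reads=120,
        ),
    ]
    domains = [
        (L("chr1", 0, 60_000), "pericentromeric"),
        (L("chr1", 60_000, 300_000), "euchromatic"),
        (L("chr2", 0, 50_000), "intercalary_diffuse"),
        (L("chr2", 50_000, 200_000), "euchromatic"),
        (L("chr3", 0, 100_000), "euchromatic"),
        (L("chr3", 100_000, 150_000), "intercalary_compact"),
    ]
    return SimulationSpec(
        seed=seed,
        chrom_lengths={"chr1": 300_000, "chr2": 200_000, "chr3": 150_000},
        te_library=te_library,
        te_copies=te_copies,
        planted_clusters=[
            # ping-pong runs in the bi-directional clusters; strongly
            # uni-directional loci are primary-only
            PlantedCluster(
                c.interval, c.n_reads, c.strand_bias, c.directionality,
                c.dominant_strand,
                pingpong_fraction=0.0 if c.directionality == "uni" else None,
            )
            for c in clusters
        ],
        genes=genes,
        chromatin_domains=domains,
    )
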