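"""Consensus and overlap TE attribution, checked against string oracles."""

import random

import pytest

from pirnakit import synthetic_data as sd
from pirnakit import te_attribution as te
from pirnakit.io_formats import (
    GenomicInterval as GI,
    MaskedInterval,
    SmallRNARead,
    TEConsensus,
    revcomp,
)


def _read(rid, seq):
    return SmallRNARead(id=rid, sequence=seq, count=1)


def _hamming_oracle(read, library, max_mm):
    """Exhaustive all-offsets, both-strand Hamming search."""
    best = None
    for cons in sorted(library, key=lambda t: t.name):
        for orient, query in ((0, read), (1, revcomp(read))):
            for off in range(len(cons.sequence) - len(query) + 1):
                window = cons.sequence[off : off + len(query)]
                mm = sum(a != b for a, b in zip(window, query))
                cand = (mm, cons.name, off, orient)
                if best is None or cand < best:
                    best = cand
    if best is None or best[0] > max_mm:
        return None
    return best


@pytest.fixture(scope="module")
def library():
    rng = random.Random(42)
    return [
        TEConsensus(
            name, klass, family, "".join(rng.choice("ACGT") for _ in range(400))
        )
        for name, klass, family in [
            ("Alpha", "LTR", "Gypsy"),
            ("Beta", "non-LTR", "Jockey"),
            ("Gamma", "DNA", "Mariner"),
        ]
    ]


class TestConsensusMap:
    def test_exact_substring_is_sense_zero_mismatch(self, library):
        seq = library[0].sequence[100:127]
        (hit,) = te.consensus_map([_read("r", seq)], library)
        assert (hit.te_name, hit.n_mismatches, hit.orientation) == (
            "Alpha", 0, "sense",
        )
        assert hit.method == "consensus"

    def test_revcomp_is_antisense(self, library):
        seq = revcomp(library[1].sequence[50:77])
        (hit,) = te.consensus_map([_read("r", seq)], library)
        assert (hit.te_name, hit.orientation) == ("Beta", "antisense")

    def test_three_mismatches_accepted(self, library):
        seq = list(library[2].sequence[10:37])
        for i in (2, 11, 20):
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        (hit,) = te.consensus_map([_read("r", "".join(seq))], library)
        assert (hit.te_name, hit.n_mismatches) == ("Gamma", 3)

    def test_matches_exhaustive_oracle_on_random_reads(self, library):
        rng = random.Random(99)
        reads = []
        # mix of planted (0-5 mutations) and fully random reads
        for i in range(40):
            cons = library[i % 3]
            off = rng.randrange(len(cons.sequence) - 27)
            seq = list(cons.sequence[off : off + 27])
            for _ in range(rng.randint(0, 5)):
                j = rng.randrange(27)
                seq[j] = rng.choice([b for b in "ACGT" if b != seq[j]])
            if rng.random() < 0.5:
                seq = list(revcomp("".join(seq)))
            reads.append(_read(f"p{i}", "".join(seq)))
        for i in range(10):
            reads.append(
                _read(f"n{i}", "".join(rng.choice("ACGT") for _ in range(27)))
            )
        hits = {h.read_id: h for h in te.consensus_map(reads, library)}
        for read in reads:
            expected = _hamming_oracle(read.sequence, library, 3)
            if expected is None:
                assert read.id not in hits
            else:
                hit = hits[read.id]
                assert hit.n_mismatches == expected[0]
                assert hit.te_name == expected[1]
                assert hit.orientation == ("sense", "antisense")[expected[3]]

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            te.consensus_map([_read("r", "ACGT" * 7)], [])


class TestOverlapMap:
    @pytest.fixture()
    def genome(self):
        rng = random.Random(17)
        return {"chr1": "".join(rng.choice("ACGT") for _ in range(2000))}

    @pytest.fixture()
    def masked(self):
        return [
            MaskedInterval(GI("chr1", 500, 800, "+"), "Alpha", "LTR", "Gypsy"),
            MaskedInterval(GI("chr1", 1200, 1500, "-"), "Gamma", "DNA", "Mariner"),
        ]

    def test_verbatim_containment_hits(self, genome, masked):
        seq = genome["chr1"][520:547]
        (hit,) = te.overlap_map([_read("r", seq)], masked, genome)
        assert (hit.te_name, hit.n_mismatches, hit.method) == ("Alpha", 0, "overlap")
        assert hit.orientation == "sense"  # plus-strand read, plus-strand copy

    def test_orientation_relative_to_copy_strand(self, genome, masked):
        # a plus-strand read inside a minus-strand copy opposes the TE
        seq = genome["chr1"][1250:1277]
        (hit,) = te.overlap_map([_read("r", seq)], masked, genome)
        assert hit.orientation == "antisense"
        # its reverse complement runs with the TE
        (hit_rc,) = te.overlap_map([_read("r2", revcomp(seq))], masked, genome)
        assert hit_rc.orientation == "sense"

    def test_single_substitution_misses(self, genome, masked):
        seq = list(genome["chr1"][520:547])
        seq[13] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[13]]
        assert te.overlap_map([_read("r", "".join(seq))], masked, genome) == []

    def test_boundary_straddling_read_misses(self, genome, masked):
        # half inside the masked copy, half outside: no full-length containment
        seq = genome["chr1"][790:817]
        assert te.overlap_map([_read("r", seq)], masked, genome) == []

    def test_out_of_bounds_interval_rejected(self, genome):
        masked = [MaskedInterval(GI("chr1", 1990, 2100, "+"), "X")]
        with pytest.raises(ValueError, match="outside genome"):
            te.overlap_map([_read("r", "A" * 27)], masked, genome)


class TestAggregation:
    def _hits(self, spec):
        return [
            te.TEHit(f"r{i}", name, klass, fam, "sense", 0, "consensus")
            for i, (name, klass, fam) in enumerate(spec)
        ]

    def test_hand_tally(self):
        hits = self._hits(
            [("G", "LTR", "Gypsy")] * 6
            + [("J", "non-LTR", "Jockey")] * 3
            + [("M", "DNA", "Mariner")]
        )
        by_class, by_family = te.aggregate_by_te(hits)
        assert by_class == pytest.approx(
            {"LTR": 0.6, "non-LTR": 0.3, "DNA": 0.1}
        )
        assert by_family["Gypsy"] == pytest.approx(0.6)

    def test_multiplicity_weighting(self):
        hits = self._hits([("G", "LTR", "Gypsy"), ("M", "DNA", "Mariner")])
        by_class, _ = te.aggregate_by_te(hits, read_counts={"r0": 9, "r1": 1})
        assert by_class == pytest.approx({"LTR": 0.9, "DNA": 0.1})

    def test_empty(self):
        assert te.aggregate_by_te([]) == ({}, {})

    def test_antisense_fraction(self):
        hits = [
            te.TEHit(f"r{i}", "G", "LTR", "Gypsy",
                     "antisense" if i < 69 else "sense", 0, "overlap")
            for i in range(100)
        ]
        assert te.antisense_fraction(hits) == pytest.approx(0.69)
        with pytest.raises(ValueError):
            te.antisense_fraction([])


class TestGenomeLandscape:
    def test_simple_and_union_coverage(self):
        masked = [
            MaskedInterval(GI("chr1", 100, 200, "+"), "A", "LTR", "Gypsy"),
        ]
        result = te.genome_te_landscape(masked, {"chr1": 1000})
        assert result["total"] == pytest.approx(0.10)
        overlapping = masked + [
            MaskedInterval(GI("chr1", 150, 250, "+"), "A", "LTR", "Gypsy")
        ]
        result = te.genome_te_landscape(overlapping, {"chr1": 1000})
        assert result["total"] == pytest.approx(0.15)  # union, not sum

    def test_empty_mask(self):
        result = te.genome_te_landscape([], {"chr1": 1000})
        assert result["total"] == 0.0

    def test_per_domain_coverage(self):
        masked = [MaskedInterval(GI("chr1", 0, 300, "+"), "A", "LTR", "Gypsy")]
        domains = [
            (GI("chr1", 0, 400), "pericentromeric"),
            (GI("chr1", 400, 1000), "euchromatic"),
        ]
        result = te.genome_te_landscape(masked, {"chr1": 1000}, domains)
        assert result["domain"]["pericentromeric"] == pytest.approx(0.75)
        assert result["domain"]["euchromatic"] == 0.0


def _te_only_spec(seed, divergence, n_reads, antisense_prob=0.69):
    """A genome holding only read-producing TE copies."""
    half = n_reads // 2
    return sd.SimulationSpec(
        seed=seed,
        chrom_lengths={"chrT": 60_000},
        te_library=[
            sd.TEConsensusSpec("GypsyT", "LTR", "Gypsy", 1200),
            sd.TEConsensusSpec("MarT", "DNA", "Mariner", 800),
        ],
        te_copies=[
            sd.PlantedTECopy(
                "GypsyT", GI("chrT", 5_000, 6_200, "+"), divergence, half,
                antisense_prob,
            ),
            sd.PlantedTECopy(
                "MarT", GI("chrT", 20_000, 20_800, "-"), divergence,
                n_reads - half, antisense_prob,
            ),
        ],
        n_mirna_loci=0,
        n_mirna_reads=0,
        n_background_reads=0,
    )


class TestMethodConsistency:
    def test_antisense_probability_recovered(self):
        ds = sd.generate(_te_only_spec(seed=5, divergence=0.0, n_reads=10_000,
                                       antisense_prob=0.7))
        hits = te.overlap_map(ds.reads, ds.masked_intervals, ds.genome)
        assert len(hits) == len(ds.reads)
        assert te.antisense_fraction(hits) == pytest.approx(0.7, abs=0.02)

    def test_zero_divergence_methods_agree_read_for_read(self):
        ds = sd.generate(_te_only_spec(seed=6, divergence=0.0, n_reads=600))
        overlap = {h.read_id: h for h in
                   te.overlap_map(ds.reads, ds.masked_intervals, ds.genome)}
        consensus = {h.read_id: h for h in
                     te.consensus_map(ds.reads, ds.te_library, max_mismatches=0)}
        assert set(overlap) == set(consensus)
        for rid in overlap:
            assert overlap[rid].te_name == consensus[rid].te_name
            assert overlap[rid].orientation == consensus[rid].orientation

    def test_consensus_hit_rate_decreases_with_divergence(self):
        rates = []
        for divergence in (0.0, 0.05, 0.10):
            ds = sd.generate(
                _te_only_spec(seed=7, divergence=divergence, n_reads=600)
            )
            hits = te.consensus_map(ds.reads, ds.te_library)
            rates.append(len(hits) / len(ds.reads))
            # the overlap method reads the genomic copy: divergence-invariant
            overlap = te.overlap_map(ds.reads, ds.masked_intervals, ds.genome)
            assert len(overlap) == len(ds.reads)
        assert rates[0] > rates[1] > rates[2]

    def test_hits_reverify_by_direct_comparison(self):
        ds = sd.generate(_te_only_spec(seed=8, divergence=0.05, n_reads=200))
        by_name = {t.name: t for t in ds.te_library}
        reads = {r.id: r for r in ds.reads}
        for hit in te.consensus_map(ds.reads, ds.te_library):
            oracle = _hamming_oracle(
                reads[hit.read_id].sequence, [by_name[hit.te_name]], 3
            )
            assert oracle is not None and oracle[0] == hit.n_mismatches
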