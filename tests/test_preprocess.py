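"""Read cleaning, collapsing, mapping and annotation."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sitamir import preprocess as pp

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


class TestTrimAndFilter:
    def test_insert_plus_adapter_recovers_insert(self):
        insert = "ACGTACGTACGTACGTACGTACGTAC"   # 26 nt
        out = pp.trim_and_filter([insert + ADAPTER[:10]], ADAPTER)
        assert out == [insert]

    def test_short_insert_discarded(self):
        out = pp.trim_and_filter(["ACGTACGTACGTACG" + ADAPTER], ADAPTER)  # 15 nt
        assert out == []

    def test_boundary_lengths_kept(self):
        r30 = "ACGTACGTAC" * 3
        assert pp.trim_and_filter([r30], ADAPTER) == [r30]
        r16 = "ACGTACGTACGTACGT"
        assert pp.trim_and_filter([r16 + ADAPTER], ADAPTER) == [r16]

    def test_n_and_quality_filters(self):
        assert pp.trim_and_filter(["ACGTNCGTACGTACGTACGT"], ADAPTER) == []
        # read must not end in an adapter prefix, or it would be trimmed
        read = ("ACGTACGTACGTACGTACGC", [30] * 19 + [2])
        assert pp.trim_and_filter([read], ADAPTER, min_qual=20) == []
        assert pp.trim_and_filter([read], ADAPTER, min_qual=0) == ["ACGTACGTACGTACGTACGC"]

    def test_short_adapter_rejected(self):
        with pytest.raises(ValueError):
            pp.trim_and_filter([], "ACGT")


class TestCollapse:
    def test_counts_aggregate(self):
        lib = pp.collapse(["A" * 20, "A" * 20, "C" * 22], "CL")
        assert lib.unique_reads == 2
        assert lib.total_reads == 3
        assert lib.entries["A" * 20] == 2

    def test_empty(self):
        lib = pp.collapse([])
        assert lib.total_reads == 0 and lib.unique_reads == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGT", min_size=16, max_size=30), max_size=50))
    def test_totals_conserved(self, reads):
        lib = pp.collapse(reads)
        assert lib.total_reads == len(reads)
        assert lib.unique_reads == len(set(reads))

    def test_out_of_bounds_length_rejected(self):
        with pytest.raises(ValueError):
            pp.collapse(["ACGT"])


class TestLengthDistribution:
    def test_single_bin(self):
        lib = pp.collapse(["A" * 24, "C" * 24])
        hist = pp.length_distribution(lib)
        assert set(hist) == {24}
        assert hist[24] == (2, 2)

    def test_totals_conserved(self, small_libraries, small_config):
        cl, _ = small_libraries
        # build a clean library from the generated raw reads
        trimmed = {}
        for raw, count in cl:
            kept = pp.trim_and_filter([raw], small_config.adapter)
            for k in kept:
                trimmed[k] = trimmed.get(k, 0) + count
        lib = pp.CollapsedLibrary(trimmed, "CL")
        hist = pp.length_distribution(lib)
        assert sum(t for _, t in hist.values()) == lib.total_reads
        assert sum(u for u, _ in hist.values()) == lib.unique_reads
        assert all(16 <= length <= 30 for length in hist)
        # the simulated background has the canonical 24-nt mode
        assert max(hist, key=lambda k: hist[k][0]) == 24

    def test_empty(self):
        assert pp.length_distribution(pp.collapse([])) == {}


class TestPercentage:
    @pytest.mark.parametrize("count,total,expected", [
        (12839242, 24498926, 52.41),
        (363399, 3067712, 11.85),
        (117589, 14124084, 0.83),
        (104080, 10374842, 1.00),
        (2026243, 10374842, 19.53),
        (1, 3, 33.33),
        (0, 100, 0.0),
    ])
    def test_published_table_arithmetic(self, count, total, expected):
        assert pp.percentage(count, total) == expected

    def test_round_half_up(self):
        assert pp.percentage(125, 100000) == 0.13   # 0.125 rounds up


class TestOverlapStats:
    def test_disjoint_libraries(self):
        a = pp.collapse(["A" * 20] * 3, "CL")
        b = pp.collapse(["C" * 20] * 2, "DT")
        t = pp.overlap_stats(a, b)
        assert t["shared"]["unique"] == 0
        assert t["shared"]["total_pct"] == 0.0
        assert t["CL_specific"]["total"] == 3
        assert t["DT_specific"]["total"] == 2

    def test_shared_totals_count_both_libraries(self):
        a = pp.collapse(["A" * 20] * 4 + ["G" * 21], "CL")
        b = pp.collapse(["A" * 20] * 6, "DT")
        t = pp.overlap_stats(a, b)
        assert t["shared"]["total"] == 10
        assert t["grand"]["total"] == 11
        assert t["grand"]["unique"] == 3   # published convention: sum of libraries

    def test_symmetry(self):
        a = pp.collapse(["A" * 20, "C" * 20, "G" * 20], "CL")
        b = pp.collapse(["A" * 20, "T" * 20], "DT")
        t1 = pp.overlap_stats(a, b)
        t2 = pp.overlap_stats(b, a)
        assert t1["shared"] == t2["shared"]
        assert t1["CL_specific"] == t2["CL_specific"]
        assert t1["DT_specific"] == t2["DT_specific"]


def naive_scan(read, genome):
    hits = []
    for name, seq in genome.items():
        for strand, probe in (("+", read), ("-", pp.revcomp_dna(read))):
            start = seq.find(probe)
            while start != -1:
                hits.append((name, start, start + len(read), strand))
                start = seq.find(probe, start + 1)
    return sorted(hits)


class TestMapPerfect:
    def test_plus_minus_and_unmapped(self):
        genome = {"s1": "TTTT" + "ACGTACGTACGTACGTACGT" + "TTTT"}
        read = "ACGTACGTACGTACGTACGT"
        rc = pp.revcomp_dna(read)
        lib = pp.collapse([read, rc, "G" * 20])
        loci = pp.map_perfect(lib, genome)
        assert any(l.strand == "+" for l in loci[read])
        assert any(l.strand == "-" for l in loci[rc])
        assert loci["G" * 20] == []

    def test_agrees_with_naive_scan(self):
        rng = random.Random(3)
        genome = {"s1": "".join(rng.choice("ACGT") for _ in range(5000)),
                  "s2": "".join(rng.choice("ACGT") for _ in range(3000))}
        reads = []
        for _ in range(30):
            L = rng.randint(16, 30)
            i = rng.randint(0, 4900)
            reads.append(genome["s1"][i:i + L])
        reads += ["".join(rng.choice("ACGT") for _ in range(25)) for _ in range(10)]
        lib = pp.collapse([r for r in reads if 16 <= len(r) <= 30])
        loci = pp.map_perfect(lib, genome)
        for read in lib.entries:
            got = sorted((l.scaffold, l.start, l.end, l.strand) for l in loci[read])
            assert got == naive_scan(read, genome)


class TestClassifyReads:
    def _setup(self):
        rng = random.Random(11)
        rrna = "".join(rng.choice("ACGT") for _ in range(120))
        genome = {"s1": "".join(rng.choice("ACGT") for _ in range(400))
                        + rrna + "".join(rng.choice("ACGT") for _ in range(400))}
        return genome, rrna

    def test_rrna_exact_match(self):
        genome, rrna = self._setup()
        read = rrna[10:34]
        lib = pp.collapse([read])
        loci = pp.map_perfect(lib, genome)
        table, assign = pp.classify_reads(
            lib, loci, {"rRNA": [rrna]}, {}, [], [])
        assert assign[read] == "rRNA"

    def test_repeat_beats_exon(self):
        genome, _ = self._setup()
        read = genome["s1"][50:74]
        lib = pp.collapse([read])
        loci = pp.map_perfect(lib, genome)
        gene = pp.GeneModel("g1", "s1", "+", exons=[(0, 200)], cds=[(0, 200)])
        table, assign = pp.classify_reads(
            lib, loci, {}, {"s1": [(40, 90)]}, [gene], [])
        assert assign[read] == "repeat"

    def test_exon_sense_vs_antisense_and_intron(self):
        genome, _ = self._setup()
        gene = pp.GeneModel("g1", "s1", "-", exons=[(0, 100), (200, 300)], cds=[])
        exon_read = genome["s1"][10:34]
        intron_read = genome["s1"][120:144]
        lib = pp.collapse([exon_read, intron_read])
        loci = pp.map_perfect(lib, genome)
        _, assign = pp.classify_reads(lib, loci, {}, {}, [gene], [])
        assert assign[exon_read] == "exon_antisense"    # read '+', gene '-'
        assert assign[intron_read] == "intron_antisense"

    def test_known_mirna_with_mismatches(self):
        genome, _ = self._setup()
        read = genome["s1"][300:321]
        ref = list(read)
        ref[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref[5]]
        lib = pp.collapse([read])
        loci = pp.map_perfect(lib, genome)
        _, assign = pp.classify_reads(lib, loci, {}, {}, [], ["".join(ref)])
        assert assign[read] == "miRNA"

    def test_unmapped_goes_to_others(self):
        genome, _ = self._setup()
        read = "A" * 25
        lib = pp.collapse([read])
        loci = pp.map_perfect(lib, genome)
        _, assign = pp.classify_reads(lib, loci, {}, {}, [], [])
        assert assign[read] == "others"

    def test_category_totals_conserved(self, small_bundle):
        for lab in ("CL", "DT"):
            table = small_bundle["annotation"][lab]
            lib = small_bundle["lib_cl" if lab == "CL" else "lib_dt"]
            assert sum(table.total.values()) == lib.total_reads
            assert sum(table.unique.values()) == lib.unique_reads
            df = table.as_dataframe()
            assert df[df.category == "Total"].iloc[0]["total"] == lib.total_reads
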