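"""Known/novel miRNA identification, criteria, families and context."""

import numpy as np
import pytest

from sitamir import discovery as dc
from sitamir import preprocess as pp
from sitamir import rnastruct as rs
from sitamir import synthio as sy


def mutate(seq, positions):
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    s = list(seq)
    for p in positions:
        s[p] = flip[s[p]]
    return "".join(s)


class TestMatchKnown:
    REF = {"sit-miR156a": "TGACAGAAGAGAGTGAGCACA"}

    def test_exact_and_boundary_mismatches(self):
        base = self.REF["sit-miR156a"]
        lib = pp.collapse([base, mutate(base, [0, 5]), mutate(base, [0, 5, 9])])
        hits = dc.match_known(lib, self.REF)
        assert hits[base] == ("sit-miR156a", 0)
        assert hits[mutate(base, [0, 5])] == ("sit-miR156a", 2)
        assert mutate(base, [0, 5, 9]) not in hits     # 3 mismatches: rejected

    def test_length_must_match(self):
        base = self.REF["sit-miR156a"]
        lib = pp.collapse([base[:-1]])
        assert dc.match_known(lib, self.REF) == {}

    def test_best_hit_fewest_mismatches_then_id(self):
        base = self.REF["sit-miR156a"]
        ref = {"b-ref": base, "a-ref": mutate(base, [3])}
        lib = pp.collapse([base])
        assert dc.match_known(lib, ref)[base] == ("b-ref", 0)
        tie = {"b-ref": base, "a-ref": base}
        assert dc.match_known(lib, tie)[base] == ("a-ref", 0)


class TestExtractPrecursors:
    GENOME = {"s1": "ACGT" * 500}

    def test_three_windows_contain_mature(self):
        locus = pp.Locus("s1", 1000, 1021, "+")
        wins = dc.extract_precursors(self.GENOME, locus)
        assert len(wins) == 3
        mat = self.GENOME["s1"][1000:1021]
        for s, e, seq in wins:
            assert s <= 1000 and e >= 1021
            assert mat in seq

    def test_clipped_at_scaffold_start(self):
        locus = pp.Locus("s1", 10, 31, "+")
        wins = dc.extract_precursors(self.GENOME, locus)
        assert all(s == 0 or s > 0 for s, e, _ in wins)
        assert min(s for s, _, _ in wins) == 0

    def test_locus_outside_scaffold(self):
        with pytest.raises(ValueError):
            dc.extract_precursors(self.GENOME, pp.Locus("s1", 1990, 2011, "+"))


class TestApplyCriteria:
    def _candidate(self, mfe=-30.0):
        rng = np.random.default_rng(8)
        hp = sy.build_hairpin(rng, 120)
        st = rs.fold_mfe(rs.to_rna(hp.precursor))
        cand = dc.MiRNACandidate(mature=hp.mature, star=hp.star, structure=st,
                                 n_genomic_loci=1)
        return cand, st

    def test_planted_candidate_passes_all(self):
        cand, _ = self._candidate()
        verdicts = dc.apply_criteria(cand)
        assert cand.passed, verdicts

    def test_mfe_boundary_inclusive(self):
        cand, st = self._candidate()
        assert dc.apply_criteria(cand, mfe_max=st.mfe)["mfe"][0]
        assert not dc.apply_criteria(cand, mfe_max=st.mfe - 0.1)["mfe"][0]

    def test_excess_duplex_mismatches_fail(self):
        cand, _ = self._candidate()
        cand.duplex = rs.DuplexReport(5, 0, 0, (2, 2))
        v = dc.apply_criteria(cand)
        assert not v["duplex_mismatches"][0]
        cand.duplex = rs.DuplexReport(4, 3, 0, (2, 2))
        v = dc.apply_criteria(cand)
        assert v["duplex_mismatches"][0] and not v["duplex_bulge"][0]

    def test_locus_count_bound(self):
        cand, _ = self._candidate()
        cand.n_genomic_loci = 25
        assert not dc.apply_criteria(cand)["locus_count"][0]
        cand.n_genomic_loci = 24
        assert dc.apply_criteria(cand)["locus_count"][0]

    def test_sirna_exclusion(self):
        cand, _ = self._candidate()
        assert not dc.apply_criteria(cand, is_sirna=True)["not_sirna"][0]

    def test_require_star_mode(self):
        cand, _ = self._candidate()
        cand.star = None
        cand.duplex = None
        v = dc.apply_criteria(cand, require_star=True)
        assert not v["duplex_mismatches"][0]


class TestFindStar:
    def test_planted_star_found(self):
        rng = np.random.default_rng(9)
        hp = sy.build_hairpin(rng, 140)
        st = rs.fold_mfe(rs.to_rna(hp.precursor))
        lib = pp.collapse([hp.mature, hp.star, hp.star])
        star = dc.find_star(lib, rs.to_rna(hp.precursor), rs.to_rna(hp.mature), st)
        assert star == hp.star

    def test_no_opposite_arm_reads(self):
        rng = np.random.default_rng(9)
        hp = sy.build_hairpin(rng, 140)
        st = rs.fold_mfe(rs.to_rna(hp.precursor))
        lib = pp.collapse([hp.mature])
        assert dc.find_star(lib, rs.to_rna(hp.precursor), rs.to_rna(hp.mature), st) is None

    def test_higher_count_wins(self):
        rng = np.random.default_rng(9)
        hp = sy.build_hairpin(rng, 140)
        st = rs.fold_mfe(rs.to_rna(hp.precursor))
        # shift the star by one: still valid geometry within tolerance
        shifted = hp.precursor[hp.star_off - 1: hp.star_off + 20]
        lib = pp.collapse([hp.star] + [shifted] * 3)
        got = dc.find_star(lib, rs.to_rna(hp.precursor), rs.to_rna(hp.mature), st)
        assert got == shifted


class TestPredictedStar:
    def test_matches_planted_geometry(self):
        rng = np.random.default_rng(10)
        hp = sy.build_hairpin(rng, 130)
        st = rs.fold_mfe(rs.to_rna(hp.precursor))
        sp = dc.predicted_star(st, rs.to_rna(hp.precursor), rs.to_rna(hp.mature))
        assert sp is not None
        rep = rs.duplex_stats(rs.to_rna(hp.mature), sp, st)
        assert rep.mismatches <= 4 and rep.max_bulge <= 2

    def test_none_for_unpaired_mature(self):
        st = rs.fold_mfe("A" * 60)
        assert dc.predicted_star(st, "A" * 60, "A" * 21) is None


class TestClusterLoci:
    def test_gap_merging_same_strand_only(self):
        loci = {
            "A" * 21: [pp.Locus("s1", 100, 121, "+")],
            "C" * 21: [pp.Locus("s1", 250, 271, "+")],   # within 200 of first
            "G" * 21: [pp.Locus("s1", 600, 621, "+")],   # beyond the gap
            "T" * 21: [pp.Locus("s1", 110, 131, "-")],   # other strand
        }
        counts = {k: 1 for k in loci}
        clusters = dc.cluster_loci(loci, counts, gap=200)
        sizes = sorted(len(c) for c in clusters)
        assert sizes == [1, 1, 2]


class TestRecoveryOnFixture:
    def test_planted_recovery_and_decoy_rejection(self, small_bundle, small_fixture_dir):
        outdir, _ = small_fixture_dir
        truth = sy.load_truth(outdir)
        known = small_bundle["known_candidates"]
        novel = small_bundle["novel_candidates"]
        planted = {m.mature for m in truth.mirnas}
        found = {c.mature for c in known if c.passed} | {c.mature for c in novel}
        assert len(planted & found) >= 0.9 * len(planted)
        decoys = [s for *_, s in truth.decoy_loci]
        assert not any(any(c.mature in d for d in decoys) for c in novel)

    def test_known_novel_disjoint(self, small_bundle):
        known = {c.mature for c in small_bundle["known_candidates"]}
        novel = {c.mature for c in small_bundle["novel_candidates"]}
        assert not (known & novel)

    def test_repeat_read_fails_locus_bound(self, small_world, small_bundle):
        genome, truth, ann = small_world
        # a read from the high-copy repeat family maps to > 24 loci
        sc, (s, e) = next((scf, iv) for scf, ivs in ann.repeats.items()
                          for iv in ivs)
        read = genome[sc][s + 10: s + 34]
        lib = pp.collapse([read] * 6)
        locus_map = pp.map_perfect(lib, genome)
        assert len(locus_map[read]) > 24
        cand = dc.evaluate_candidate(read, locus_map[read], genome, lib, (6, 0))
        assert not cand.criteria_verdicts["locus_count"][0]

    def test_relaxing_mfe_never_shrinks_candidate_set(self, small_world, small_bundle):
        genome, truth, ann = small_world
        locus_map = small_bundle["locus_map"]
        merged = small_bundle["merged"]
        unannot = {
            seq: count for seq, count in merged.entries.items()
            if locus_map.get(seq) and 20 <= len(seq) <= 24
        }
        lib = pp.CollapsedLibrary(unannot, "u")
        strict = dc.predict_novel(lib, genome, locus_map, mfe_max=-18.0)
        relaxed = dc.predict_novel(lib, genome, locus_map, mfe_max=-10.0)
        assert {c.mature for c in strict} <= {c.mature for c in relaxed}


class TestFamilies:
    def _cand(self, mature, status="novel", mirna_id=""):
        return dc.MiRNACandidate(mature=mature, status=status, mirna_id=mirna_id)

    def test_identical_matures_same_family(self):
        a, b = self._cand("A" * 21), self._cand("A" * 21)
        dc.cluster_families([a, b])
        assert a.family == b.family

    def test_distant_matures_split(self):
        a = self._cand("TGACAGAAGAGAGTGAGCACA")
        b = self._cand(mutate("TGACAGAAGAGAGTGAGCACA", [0, 4, 8, 12]))
        dc.cluster_families([a, b])
        assert a.family != b.family

    def test_two_mismatches_merge(self):
        a = self._cand("TGACAGAAGAGAGTGAGCACA")
        b = self._cand(mutate("TGACAGAAGAGAGTGAGCACA", [0, 4]))
        dc.cluster_families([a, b])
        assert a.family == b.family

    def test_known_inherits_reference_family(self):
        k = self._cand("TGACAGAAGAGAGTGAGCACA", status="known",
                       mirna_id="sit-miR156a-5p")
        dc.cluster_families([k])
        assert k.family == "miR156"


class TestGenomicContext:
    GENES = [pp.GeneModel("g", "s1", "+", exons=[(100, 200), (300, 400)],
                          cds=[(100, 200)])]

    def test_cds(self):
        assert dc.classify_genomic_context(("s1", 120, 180), self.GENES) == "CDS"

    def test_intron(self):
        assert dc.classify_genomic_context(("s1", 220, 280), self.GENES) == "intron"

    def test_intergenic(self):
        assert dc.classify_genomic_context(("s1", 500, 560), self.GENES) == "intergenic"
        assert dc.classify_genomic_context(("s2", 120, 180), self.GENES) == "intergenic"
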