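"""Synthetic-data generator: determinism, containment, planted truth."""

import dataclasses

import numpy as np
import pytest

from sitamir import rnastruct as rs
from sitamir import synthio as sy


def tiny_config(**kw):
    base = dict(seed=1, read_depth=30_000, degradome_depth=4_000,
                n_mirna_loci=8, n_transcripts=10, n_targets=5)
    base.update(kw)
    return sy.SyntheticConfig(**base)


class TestConfigValidation:
    def test_precursor_range_bounds(self):
        with pytest.raises(ValueError):
            tiny_config(precursor_len_range=(40, 222)).validate()
        with pytest.raises(ValueError):
            tiny_config(precursor_len_range=(61, 400)).validate()

    def test_de_fraction_must_give_integer_count(self):
        with pytest.raises(ValueError):
            tiny_config(de_fraction=0.3, n_mirna_loci=8).validate()

    def test_peak_fraction_range(self):
        with pytest.raises(ValueError):
            tiny_config(cleavage_peak_fraction=0.0).validate()

    def test_positive_lengths(self):
        with pytest.raises(ValueError):
            tiny_config(scaffold_len=0).validate()


class TestGenGenome:
    def test_truth_count_and_unique_containment(self):
        cfg = tiny_config()
        genome, truth, ann = sy.gen_genome(cfg)
        assert len(truth.mirnas) == cfg.n_mirna_loci
        blob = "#".join(genome.values())
        blob_rc = "#".join(sy.revcomp_dna(g) for g in genome.values())
        for m in truth.mirnas:
            assert genome[m.scaffold][m.mature_start:m.mature_end] == m.mature
            prec = genome[m.scaffold][m.precursor_start:m.precursor_end]
            assert m.mature in prec and m.star in prec
            assert blob.count(m.mature) + blob_rc.count(m.mature) == 1

    def test_determinism_and_seed_sensitivity(self):
        g1, t1, _ = sy.gen_genome(tiny_config())
        g2, t2, _ = sy.gen_genome(tiny_config())
        assert g1 == g2 and t1 == t2
        g3, _, _ = sy.gen_genome(tiny_config(seed=2))
        assert g3 != g1

    def test_planted_hairpins_satisfy_model_criteria(self):
        genome, truth, _ = sy.gen_genome(tiny_config())
        for m in truth.mirnas:
            prec = rs.to_rna(genome[m.scaffold][m.precursor_start:m.precursor_end])
            st = rs.fold_mfe(prec)
            assert rs.is_stemloop(st, min_stem=15)
            assert st.mfe <= -18.0
            rep = rs.duplex_stats(rs.to_rna(m.mature), rs.to_rna(m.star), st)
            assert rep.mismatches <= 4
            assert rep.max_bulge <= 2

    def test_decoys_fail_hairpin_criteria(self):
        _, truth, _ = sy.gen_genome(tiny_config())
        assert len(truth.decoy_loci) == len(truth.mirnas)
        for *_, seq in truth.decoy_loci:
            assert sy._decoy_is_negative(seq)

    def test_sizing_error_when_scaffolds_too_small(self):
        with pytest.raises((sy.SizingError, ValueError)):
            sy.gen_genome(tiny_config(scaffold_len=900, n_mirna_loci=8))

    def test_target_cleavage_geometry(self):
        _, truth, _ = sy.gen_genome(tiny_config())
        assert len(truth.targets) == 5
        for t in truth.targets:
            mir = next(m for m in truth.mirnas if m.mirna_id == t.mirna_id)
            site = sy.revcomp_dna(mir.mature)
            tseq = truth.transcripts[t.transcript_id]
            s0 = t.site_start - 1
            assert tseq[s0:s0 + len(site)] == site
            # tag 5' end opposite miRNA position 10
            assert t.cleavage_position == t.site_start + len(site) - 10


class TestLibraries:
    def test_depth_and_adapters(self):
        cfg = tiny_config()
        genome, truth, ann = sy.gen_genome(cfg)
        cl, dt = sy.gen_srna_libraries(truth, cfg, genome, ann)
        for lib in (cl, dt):
            assert sum(c for _, c in lib) == cfg.read_depth
            assert all(seq.endswith(cfg.adapter) for seq, _ in lib[:50])

    def test_zero_depth_rejected(self):
        cfg = tiny_config()
        genome, truth, ann = sy.gen_genome(cfg)
        cfg2 = dataclasses.replace(cfg, read_depth=0)
        with pytest.raises(ValueError):
            sy.gen_srna_libraries(truth, cfg2, genome, ann)

    def test_no_de_when_fraction_zero(self):
        cfg = tiny_config(de_fraction=0.0)
        _, truth, _ = sy.gen_genome(cfg)
        assert all(m.log2fc == 0.0 for m in truth.mirnas)
        assert all(m.cl_mean == m.dt_mean for m in truth.mirnas)

    def test_nb_degenerates_to_mean(self):
        rng = np.random.default_rng(0)
        assert sy._nb_draw(rng, 37.4, 0.0) == 37
        assert sy._nb_draw(rng, 0.0, 0.1) == 0

    def test_planted_fold_change_recovered_at_deep_counts(self):
        # deep planted counts (~100x) make the two-unit log2FC tight
        cfg = tiny_config(read_depth=200_000, expression_scale=100.0,
                          n_mirna_loci=20, de_fraction=0.5)
        _, truth, _ = sy.gen_genome(cfg)
        cl, dt = sy.gen_srna_libraries(truth, cfg)
        cl_d, dt_d = dict(cl), dict(dt)
        n_cl = sum(cl_d.values())
        n_dt = sum(dt_d.values())
        ok = 0
        de_mirnas = [m for m in truth.mirnas if m.log2fc != 0]
        for m in de_mirnas:
            raw = m.mature + cfg.adapter
            x = cl_d.get(raw, 0)
            y = dt_d.get(raw, 0)
            obs = np.log2((y / n_dt) / (x / n_cl))
            if abs(obs - m.log2fc) <= 0.5:
                ok += 1
        assert ok >= 0.9 * len(de_mirnas)


class TestDegradome:
    def test_all_tags_at_site_when_peak_is_one(self):
        cfg = tiny_config(cleavage_peak_fraction=1.0)
        _, truth, _ = sy.gen_genome(cfg)
        tags = sy.gen_degradome(truth, cfg)
        target_tids = {t.transcript_id for t in truth.targets}
        planted_starts = {
            truth.transcripts[t.transcript_id][t.cleavage_position - 1:
                                               t.cleavage_position + 19]
            for t in truth.targets}
        for seq, count in tags:
            for tid in target_tids:
                tr = truth.transcripts[tid]
                if seq in tr:
                    assert seq in planted_starts

    def test_peak_is_modal_at_default_fraction(self):
        cfg = tiny_config(cleavage_peak_fraction=0.8, degradome_depth=10_000)
        _, truth, _ = sy.gen_genome(cfg)
        tags = dict(sy.gen_degradome(truth, cfg))
        t = truth.targets[0]
        tr = truth.transcripts[t.transcript_id]
        counts = {}
        for seq, c in tags.items():
            start = tr.find(seq)
            while start != -1:
                counts[start + 1] = counts.get(start + 1, 0) + c
                start = tr.find(seq, start + 1)
        assert max(counts, key=counts.get) == t.cleavage_position

    def test_background_transcript_has_no_dominant_position(self):
        cfg = tiny_config(degradome_depth=10_000)
        _, truth, _ = sy.gen_genome(cfg)
        tags = dict(sy.gen_degradome(truth, cfg))
        target_tids = {t.transcript_id for t in truth.targets}
        bg = next(tid for tid in sorted(truth.transcripts) if tid not in target_tids)
        tr = truth.transcripts[bg]
        counts = {}
        for seq, c in tags.items():
            i = tr.find(seq)
            if i != -1:
                counts[i + 1] = counts.get(i + 1, 0) + c
        total = sum(counts.values())
        assert total > 100
        assert max(counts.values()) / total < 0.15

    def test_tags_are_transcript_substrings(self):
        cfg = tiny_config()
        _, truth, _ = sy.gen_genome(cfg)
        tags = sy.gen_degradome(truth, cfg)
        blob = "#".join(truth.transcripts.values())
        assert all(seq in blob for seq, _ in tags)

    def test_zero_depth_rejected(self):
        cfg = tiny_config()
        _, truth, _ = sy.gen_genome(cfg)
        bad = dataclasses.replace(cfg, degradome_depth=0)
        with pytest.raises(ValueError):
            sy.gen_degradome(truth, bad)


class TestTruthRoundTrip:
    def test_write_then_load_identical(self, tmp_path):
        cfg = tiny_config()
        _, truth, _ = sy.gen_genome(cfg)
        sy.write_truth(truth, tmp_path)
        again = sy.load_truth(tmp_path)
        assert again == truth

    def test_fixture_truth_deterministic(self, tmp_path):
        from sitamir import pipeline
        cfg = tiny_config()
        pipeline.make_fixture(cfg, tmp_path / "a")
        pipeline.make_fixture(cfg, tmp_path / "b")
        for name in ("truth_mirnas.tsv", "truth_targets.tsv", "genome.fa",
                     "reads_cl.fa", "degradome.fa"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
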