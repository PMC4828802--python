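"""End-to-end pipeline orchestration and fixture generation.

``make_fixture`` materializes a complete synthetic input set (genome,
collapsed read libraries with adapters, degradome tags, references,
annotations, truth tables) and ``run_pipeline`` executes the full
analysis: preprocess → known/novel miRNA discovery → differential
expression → degradome target calling, writing published-style report
tables, a run manifest and a log.  Re-running with the same config and
inputs reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import yaml
from Bio import SeqIO

from . import __version__, degradome, diff_expr, discovery, preprocess, synthio
from .preprocess import CollapsedLibrary
from .rnastruct import to_rna

log = logging.getLogger("sitamir")


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run."""

    # inputs
    reads_cl: str = ""
    reads_dt: str = ""
    genome: str = ""
    ncrna: str = ""
    repeats: str = ""
    gff: str = ""
    known_mirnas: str = ""
    transcripts: str = ""
    degradome_tags: str = ""
    outdir: str = "results"
    # preprocessing
    adapter: str = synthio.DEFAULT_ADAPTER
    min_len: int = 16
    max_len: int = 30
    min_qual: int = 0
    # discovery
    max_mm: int = 2
    flank: int = 250
    mfe_max: float = -18.0
    max_duplex_mm: int = 4
    max_bulge: int = 2
    max_loci: int = 24
    min_stem: int = 15
    min_locus_count: int = 5
    cluster_gap: int = 200
    require_star: bool = False
    # differential expression
    min_count: int = 10
    lfc_min: float = 1.0
    alpha: float = 0.01
    # degradome
    max_score: float = 4.5
    predict_score: float = 3.0
    tag_len: int = 20
    cleavage_window: int = 1
    seed: int = 42

    def validate(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")
        if not (16 <= self.min_len and self.max_len <= 50):
            raise ValueError("read length bounds out of range")
        if self.mfe_max > 0:
            raise ValueError("mfe_max must be ≤ 0 kcal/mol")
        if len(self.adapter) < 5:
            raise ValueError("adapter must be at least 5 nt")
        for name in ("max_mm", "max_duplex_mm", "max_bulge", "max_loci",
                     "min_stem", "min_count", "tag_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def make_fixture(config: synthio.SyntheticConfig, outdir) -> PipelineConfig:
    """Write a complete, self-contained synthetic input set.

    Returns a PipelineConfig pointing at the written files; truth tables
    are written alongside for recovery checks.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth, ann = synthio.gen_genome(config)
    cl, dt = synthio.gen_srna_libraries(truth, config, genome, ann)
    tags = synthio.gen_degradome(truth, config)

    synthio.write_fasta(genome, outdir / "genome.fa")
    synthio.write_reads_collapsed(cl, outdir / "reads_cl.fa")
    synthio.write_reads_collapsed(dt, outdir / "reads_dt.fa")
    synthio.write_reads_collapsed(tags, outdir / "degradome.fa")
    ncrna = {f"{cls}_{i + 1} class={cls}": seq
             for cls, seqs in ann.ncrna_ref.items() for i, seq in enumerate(seqs)}
    synthio.write_fasta(ncrna, outdir / "ncrna.fa")
    synthio.write_fasta(ann.known_mirna_ref, outdir / "known_mirnas.fa")
    synthio.write_fasta(truth.transcripts, outdir / "transcripts.fa")
    synthio.write_gff3(ann.genes, outdir / "genes.gff3")
    synthio.write_bed(ann.repeats, outdir / "repeats.bed")
    synthio.write_truth(truth, outdir)

    pc = PipelineConfig(
        reads_cl=str(outdir / "reads_cl.fa"),
        reads_dt=str(outdir / "reads_dt.fa"),
        genome=str(outdir / "genome.fa"),
        ncrna=str(outdir / "ncrna.fa"),
        repeats=str(outdir / "repeats.bed"),
        gff=str(outdir / "genes.gff3"),
        known_mirnas=str(outdir / "known_mirnas.fa"),
        transcripts=str(outdir / "transcripts.fa"),
        degradome_tags=str(outdir / "degradome.fa"),
        outdir=str(outdir / "results"),
        adapter=config.adapter,
        seed=config.seed,
    )
    pc.to_yaml(outdir / "pipeline.yaml")
    return pc


def _read_fasta_dict(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _load_ncrna(path) -> Dict[str, List[str]]:
    out: Dict[str, List[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        cls = None
        for tok in rec.description.split():
            if tok.startswith("class="):
                cls = tok.split("=", 1)[1]
        cls = cls or rec.id.split("_")[0]
        out.setdefault(cls, []).append(str(rec.seq).upper())
    return out


def load_and_clean(path, label: str, cfg: PipelineConfig) -> CollapsedLibrary:
    """Load a read file (raw FASTQ or collapsed FASTA), trim and filter."""
    path = str(path)
    if path.endswith((".fq", ".fastq")):
        raw = preprocess.read_sequences(path)
        clean = preprocess.trim_and_filter(
            raw, cfg.adapter, cfg.min_len, cfg.max_len, cfg.min_qual)
        return preprocess.collapse(clean, label)
    # collapsed raw reads: trim each unique read once, carry its count
    raw_lib = preprocess.load_collapsed(path, label)
    entries: Dict[str, int] = {}
    for seq, count in raw_lib.entries.items():
        kept = preprocess.trim_and_filter([(seq, None)], cfg.adapter,
                                          cfg.min_len, cfg.max_len, cfg.min_qual)
        for insert in kept:
            entries[insert] = entries.get(insert, 0) + count
    lib = CollapsedLibrary(entries, label)
    lib.validate(cfg.min_len, cfg.max_len)
    return lib


def _require(path, what: str) -> None:
    if not path or not Path(path).exists():
        raise FileNotFoundError(f"missing input for {what}: {path!r}")


def run_pipeline(config: PipelineConfig, stages: Optional[Set[str]] = None) -> dict:
    """Execute the analysis and write the report bundle.

    ``stages`` limits execution: any of {"preprocess", "discover", "de",
    "degradome"}; later stages pull in their prerequisites.  Returns a
    dict of in-memory results (libraries, tables, candidate lists).
    """
    config.validate()
    stages = stages or {"preprocess", "discover", "de", "degradome"}
    if "de" in stages or "degradome" in stages:
        stages = stages | {"discover"}
    if "discover" in stages:
        stages = stages | {"preprocess"}
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}

    # ---- preprocess --------------------------------------------------------
    _require(config.reads_cl, "CL reads")
    _require(config.reads_dt, "DT reads")
    _require(config.genome, "genome")
    lib_cl = load_and_clean(config.reads_cl, "CL", config)
    lib_dt = load_and_clean(config.reads_dt, "DT", config)
    for lib in (lib_cl, lib_dt):
        log.info("%s: %d clean reads, %d unique after trimming (thresholds %d-%d nt)",
                 lib.label, lib.total_reads, lib.unique_reads, config.min_len, config.max_len)
        if lib.total_reads == 0:
            log.warning("%s library empty after filtering; outputs will be partial", lib.label)
    genome = _read_fasta_dict(config.genome)
    ncrna = _load_ncrna(config.ncrna) if config.ncrna else {}
    repeats = synthio.read_bed(config.repeats) if config.repeats else {}
    genes = synthio.read_gff3(config.gff) if config.gff else []
    known_ref = _read_fasta_dict(config.known_mirnas) if config.known_mirnas else {}

    merged = CollapsedLibrary(dict(lib_cl.entries), "CL+DT")
    for seq, c in lib_dt.entries.items():
        merged.entries[seq] = merged.entries.get(seq, 0) + c
    locus_map = preprocess.map_perfect(merged, genome)
    n_mapped = sum(1 for v in locus_map.values() if v)
    log.info("perfect-match mapping: %d/%d unique sequences mapped", n_mapped, merged.unique_reads)

    overlap = preprocess.overlap_stats(lib_cl, lib_dt)
    hist = {lab: preprocess.length_distribution(lib)
            for lab, lib in (("CL", lib_cl), ("DT", lib_dt))}
    tables = {}
    assignments = {}
    for lib in (lib_cl, lib_dt):
        table, assign = preprocess.classify_reads(
            lib, locus_map, ncrna, repeats, genes,
            list(known_ref.values()), max_mirna_mm=config.max_mm)
        tables[lib.label] = table
        assignments[lib.label] = assign

    bundle.update(lib_cl=lib_cl, lib_dt=lib_dt, merged=merged, locus_map=locus_map,
                  overlap=overlap, length_hist=hist, annotation=tables)
    _write_preprocess_reports(outdir, overlap, hist, tables)
    if stages == {"preprocess"}:
        _write_manifest(outdir, config)
        return bundle

    # ---- discovery ---------------------------------------------------------
    known_hits = discovery.match_known(merged, known_ref, max_mm=config.max_mm)
    by_ref: Dict[str, List[str]] = {}
    for seq, (rid, mm) in known_hits.items():
        by_ref.setdefault(rid, []).append(seq)
    known_cands: List[discovery.MiRNACandidate] = []
    known_loci: List[Tuple[str, int, int]] = []
    for rid in sorted(by_ref):
        mature = max(by_ref[rid], key=lambda s: (merged.entries[s], s))
        cand = discovery.evaluate_candidate(
            mature, locus_map[mature], genome, merged,
            counts=(lib_cl.entries.get(mature, 0), lib_dt.entries.get(mature, 0)),
            flank=config.flank, mfe_max=config.mfe_max, min_stem=config.min_stem,
            require_star=config.require_star, status="known")
        cand.mirna_id = rid.removesuffix("-ref")
        cand.family = discovery.family_of(rid)
        known_cands.append(cand)
        if cand.passed:
            known_loci.append((cand.scaffold, cand.precursor_start, cand.precursor_end))

    # unannotated = mapped reads not matching any reference class
    unannot_entries = {
        seq: count for seq, count in merged.entries.items()
        if locus_map.get(seq)
        and assignments["CL"].get(seq, assignments["DT"].get(seq)) == "others"
        and 20 <= len(seq) <= 24
    }
    unannotated = CollapsedLibrary(unannot_entries, "unannotated")
    novel_cands = discovery.predict_novel(
        unannotated, genome, locus_map, known_loci=known_loci,
        min_count=config.min_locus_count, gap=config.cluster_gap,
        flank=config.flank, mfe_max=config.mfe_max, max_loci=config.max_loci,
        min_stem=config.min_stem, require_star=config.require_star)
    for i, cand in enumerate(sorted(novel_cands, key=lambda c: (c.scaffold, c.precursor_start))):
        cand.mirna_id = f"sit-novel-mir{i + 1:03d}"
        cand.counts = (lib_cl.entries.get(cand.mature, 0), lib_dt.entries.get(cand.mature, 0))
    discovery.cluster_families(known_cands + novel_cands)
    for cand in known_cands + novel_cands:
        if cand.scaffold:
            cand.context = discovery.classify_genomic_context(
                (cand.scaffold, cand.precursor_start, cand.precursor_end), genes)
    passed_known = [c for c in known_cands if c.passed]
    log.info("discovery: %d known (of %d references hit), %d novel candidates pass criteria",
             len(passed_known), len(by_ref), len(novel_cands))
    bundle.update(known_candidates=known_cands, novel_candidates=novel_cands)
    discovery.candidate_table(known_cands).to_csv(outdir / "known_mirnas.tsv", sep="\t", index=False)
    discovery.candidate_table(novel_cands).to_csv(outdir / "novel_mirnas.tsv", sep="\t", index=False)

    all_passed = passed_known + novel_cands

    # ---- differential expression ------------------------------------------
    if "de" in stages:
        de_records = diff_expr.call_de(
            [(c.mirna_id, c.counts[0], c.counts[1]) for c in all_passed],
            N1=lib_cl.total_reads, N2=lib_dt.total_reads,
            min_count=config.min_count, lfc_min=config.lfc_min, alpha=config.alpha)
        n_up = sum(r.de_call == "up" for r in de_records)
        n_down = sum(r.de_call == "down" for r in de_records)
        log.info("differential expression: %d up, %d down of %d tested (|log2FC| ≥ %.1f, p ≤ %.2g)",
                 n_up, n_down, len(de_records), config.lfc_min, config.alpha)
        bundle["de_records"] = de_records
        diff_expr.de_table(de_records).to_csv(outdir / "de_table.tsv", sep="\t", index=False)

    # ---- degradome ---------------------------------------------------------
    if "degradome" in stages and config.transcripts and config.degradome_tags:
        _require(config.transcripts, "transcripts")
        _require(config.degradome_tags, "degradome tags")
        transcripts = _read_fasta_dict(config.transcripts)
        tag_lib = preprocess.load_collapsed(config.degradome_tags, "degradome")
        tplots = degradome.map_tags(tag_lib.entries.items(), transcripts, config.tag_len)
        mir_seqs = {c.mirna_id: to_rna(c.mature) for c in all_passed}
        hits = degradome.call_targets(mir_seqs, tplots, transcripts,
                                      max_score=config.max_score, window=config.cleavage_window)
        predicted = degradome.predict_targets_insilico(mir_seqs, transcripts,
                                                       max_score=config.predict_score)
        log.info("degradome: %d validated target hits, %d in-silico predictions",
                 len(hits), len(predicted))
        bundle.update(tplots=tplots, target_hits=hits, predicted_targets=predicted)
        degradome.target_table(hits).to_csv(outdir / "targets_validated.tsv", sep="\t", index=False)
        import pandas as pd

        pd.DataFrame(predicted, columns=["mirna_id", "transcript_id", "cleavage_position",
                                         "score"]).to_csv(
            outdir / "targets_predicted.tsv", sep="\t", index=False)
        with open(outdir / "tplots.tsv", "w") as fh:
            fh.write("transcript\tposition\tcount\n")
            for tid in sorted(tplots):
                for p, c in sorted(tplots[tid].abundance.items()):
                    fh.write(f"{tid}\t{p}\t{c}\n")

    _write_manifest(outdir, config)
    return bundle


def _write_preprocess_reports(outdir: Path, overlap, hist, tables) -> None:
    with open(outdir / "table1_overlap.tsv", "w") as fh:
        fh.write("type\tunique\tunique_pct\ttotal\ttotal_pct\n")
        for key, row in overlap.items():
            fh.write(f"{key}\t{row['unique']}\t{row['unique_pct']}"
                     f"\t{row['total']}\t{row['total_pct']}\n")
    with open(outdir / "length_histogram.tsv", "w") as fh:
        fh.write("library\tlength\tunique\ttotal\n")
        for lab, h in hist.items():
            for length, (u, t) in h.items():
                fh.write(f"{lab}\t{length}\t{u}\t{t}\n")
    for lab, table in tables.items():
        table.as_dataframe().to_csv(outdir / f"table2_annotation_{lab.lower()}.tsv",
                                    sep="\t", index=False)


def _write_manifest(outdir: Path, config: PipelineConfig) -> None:
    manifest = {
        "package": "sitamir",
        "version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.suffix == ".tsv"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
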