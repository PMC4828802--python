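"""Cleaning, collapsing, mapping and annotating small-RNA libraries.

The stage mirrors a standard sRNA-seq funnel: 3' adapter trimming and
quality/length filtering (16–30 nt retained), collapsing exact
duplicates into a counted library, perfect-match genome mapping on both
strands, and single-category annotation of every read against ncRNA
references (rRNA/tRNA/snRNA/snoRNA), known miRNAs, repeats and gene
models, with fixed precedence.  Summaries mirror the published
shared/specific overlap table, annotation-category table and read
length distribution.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO

#: annotation categories in precedence order (highest first); a
#: multi-locus read is classified by its highest-precedence hit.
CATEGORY_PRECEDENCE = (
    "rRNA", "tRNA", "snRNA", "snoRNA", "miRNA", "repeat",
    "exon_sense", "exon_antisense", "intron_sense", "intron_antisense",
    "others",
)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp_dna(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


def percentage(count: int, total: int) -> float:
    """count/total × 100, rounded to 2 decimals, half-up (table style)."""
    if total == 0:
        return 0.0
    return float((Decimal(count) * 100 / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class CollapsedLibrary:
    """Unique small-RNA sequences with per-library counts."""

    entries: Dict[str, int] = field(default_factory=dict)
    label: str = ""

    @property
    def total_reads(self) -> int:
        return sum(self.entries.values())

    @property
    def unique_reads(self) -> int:
        return len(self.entries)

    def validate(self, min_len: int = 16, max_len: int = 30) -> None:
        for seq, count in self.entries.items():
            if count < 0:
                raise ValueError(f"negative count for {seq}")
            if not (min_len <= len(seq) <= max_len):
                raise ValueError(f"sequence length {len(seq)} outside [{min_len}, {max_len}]")


def read_sequences(path: str) -> List[Tuple[str, Optional[list]]]:
    """Load raw reads from FASTQ or FASTA as (sequence, phred qualities
    or None).  For collapsed ``seq_N x<count>`` FASTA use
    :func:`load_collapsed` instead."""
    fmt = "fastq" if str(path).endswith((".fq", ".fastq")) else "fasta"
    out = []
    for rec in SeqIO.parse(str(path), fmt):
        quals = rec.letter_annotations.get("phred_quality") if fmt == "fastq" else None
        out.append((str(rec.seq).upper(), quals))
    return out


def load_collapsed(path: str, label: str = "") -> CollapsedLibrary:
    """Read a collapsed FASTA with ``seq_N x<count>`` headers."""
    entries: Dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        count = 1
        for tok in desc.split():
            if tok.startswith("x") and tok[1:].isdigit():
                count = int(tok[1:])
        entries[str(rec.seq).upper()] = entries.get(str(rec.seq).upper(), 0) + count
    return CollapsedLibrary(entries, label)


def write_collapsed(lib: CollapsedLibrary, path: str) -> None:
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(sorted(lib.entries.items(), key=lambda kv: (-kv[1], kv[0]))):
            fh.write(f">seq_{i + 1} x{count}\n{seq}\n")


def trim_and_filter(
    reads: Iterable[Tuple[str, Optional[list]]],
    adapter: str,
    min_len: int = 16,
    max_len: int = 30,
    min_qual: int = 0,
) -> List[str]:
    """Remove 3' adapters and discard low-quality / off-length reads.

    The adapter is removed by the longest-prefix rule: the leftmost
    position in the read from which the remaining suffix equals a
    prefix of the adapter marks the insert end.  After trimming, reads
    shorter than ``min_len`` or longer than ``max_len`` are discarded,
    as are reads containing N or any base with quality below
    ``min_qual``.
    """
    adapter = adapter.upper()
    if len(adapter) < 5:
        raise ValueError("adapter must be at least 5 nt")
    clean: List[str] = []
    for item in reads:
        seq, quals = (item, None) if isinstance(item, str) else item
        seq = seq.upper()
        if "N" in seq:
            continue
        if quals is not None and min_qual > 0 and any(q < min_qual for q in quals):
            continue
        insert = seq
        for i in range(len(seq)):
            if adapter.startswith(seq[i:]):
                insert = seq[:i]
                break
        if min_len <= len(insert) <= max_len:
            clean.append(insert)
    return clean


def collapse(reads: Iterable[str], label: str = "") -> CollapsedLibrary:
    """Aggregate exact duplicate reads into a counted library."""
    lib = CollapsedLibrary(dict(Counter(reads)), label)
    lib.validate()
    return lib


def length_distribution(lib: CollapsedLibrary) -> Dict[int, Tuple[int, int]]:
    """Histogram: read length → (unique sequences, total reads)."""
    uniq: Counter = Counter()
    tot: Counter = Counter()
    for seq, count in lib.entries.items():
        uniq[len(seq)] += 1
        tot[len(seq)] += count
    return {length: (uniq[length], tot[length]) for length in sorted(uniq)}


def overlap_stats(lib_a: CollapsedLibrary, lib_b: CollapsedLibrary) -> dict:
    """Shared/specific composition of two libraries (published-table layout).

    Denominators follow the published convention: the grand unique
    total is the *sum* of the two libraries' unique counts (a shared
    sequence is present in both libraries), and the grand read total is
    the sum of library sizes.  Shared totals sum reads of shared
    sequences from both libraries; specific rows are self-consistent
    (library minus shared), so at the unique level the three category
    rows sum to the denominator minus the shared count.
    """
    set_a, set_b = set(lib_a.entries), set(lib_b.entries)
    shared = set_a & set_b
    a_only, b_only = set_a - shared, set_b - shared
    grand_unique = lib_a.unique_reads + lib_b.unique_reads
    grand_total = lib_a.total_reads + lib_b.total_reads
    shared_total = sum(lib_a.entries[s] + lib_b.entries[s] for s in shared)
    a_total = sum(lib_a.entries[s] for s in a_only)
    b_total = sum(lib_b.entries[s] for s in b_only)

    def row(u, t):
        return {
            "unique": u, "unique_pct": percentage(u, grand_unique),
            "total": t, "total_pct": percentage(t, grand_total),
        }

    return {
        "grand": row(grand_unique, grand_total),
        "shared": row(len(shared), shared_total),
        f"{lib_a.label or 'A'}_specific": row(len(a_only), a_total),
        f"{lib_b.label or 'B'}_specific": row(len(b_only), b_total),
    }


# ---------------------------------------------------------------------------
# perfect-match genome mapping


@dataclass(frozen=True)
class Locus:
    scaffold: str
    start: int      # 0-based, half-open
    end: int
    strand: str     # '+' or '-'


def map_perfect(lib: CollapsedLibrary, genome: Dict[str, str]) -> Dict[str, List[Locus]]:
    """Exact-substring mapping of every library sequence, both strands.

    Returns sequence → list of loci (possibly empty = unmapped).  The
    genome is indexed once per distinct read length, so mapping is
    linear in genome size × number of distinct lengths.
    """
    lengths = sorted({len(s) for s in lib.entries})
    genome = {k: v.upper() for k, v in genome.items()}
    index: Dict[int, Dict[str, List[Tuple[str, int]]]] = {}
    for L in lengths:
        idx: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
        for name, seq in genome.items():
            for i in range(len(seq) - L + 1):
                idx[seq[i:i + L]].append((name, i))
        index[L] = idx
    out: Dict[str, List[Locus]] = {}
    for read in lib.entries:
        L = len(read)
        loci = [Locus(sc, i, i + L, "+") for sc, i in index[L].get(read, ())]
        rc = revcomp_dna(read)
        loci += [Locus(sc, i, i + L, "-") for sc, i in index[L].get(rc, ())]
        out[read] = sorted(loci, key=lambda l: (l.scaffold, l.start, l.strand))
    return out


# ---------------------------------------------------------------------------
# annotation


@dataclass
class GeneModel:
    """Minimal gene model: exon intervals (0-based half-open) on one strand."""

    gene_id: str
    scaffold: str
    strand: str
    exons: List[Tuple[int, int]]
    cds: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def introns(self) -> List[Tuple[int, int]]:
        ex = sorted(self.exons)
        return [(a_end, b_start) for (_, a_end), (b_start, _) in zip(ex, ex[1:]) if b_start > a_end]

    @property
    def span(self) -> Tuple[int, int]:
        ex = sorted(self.exons)
        return ex[0][0], ex[-1][1]


def _hamming_le(a: str, b: str, limit: int) -> bool:
    if len(a) != len(b):
        return False
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return False
    return True


class AnnotationTable:
    """Per-category unique/total counts and percentages for one library."""

    def __init__(self, label: str):
        self.label = label
        self.unique: Counter = Counter()
        self.total: Counter = Counter()

    def add(self, category: str, count: int) -> None:
        self.unique[category] += 1
        self.total[category] += count

    def as_dataframe(self):
        import pandas as pd

        uniq_sum = sum(self.unique.values())
        tot_sum = sum(self.total.values())
        rows = []
        for cat in CATEGORY_PRECEDENCE:
            rows.append({
                "category": cat,
                "unique": self.unique[cat],
                "unique_pct": percentage(self.unique[cat], uniq_sum),
                "total": self.total[cat],
                "total_pct": percentage(self.total[cat], tot_sum),
            })
        rows.append({
            "category": "Total", "unique": uniq_sum, "unique_pct": 100.0,
            "total": tot_sum, "total_pct": 100.0,
        })
        return pd.DataFrame(rows)


def classify_reads(
    lib: CollapsedLibrary,
    locus_map: Dict[str, List[Locus]],
    ncrna_ref: Dict[str, Sequence[str]],
    repeat_intervals: Dict[str, List[Tuple[int, int]]],
    gene_models: Sequence[GeneModel],
    known_mirnas: Sequence[str],
    max_mirna_mm: int = 2,
) -> Tuple[AnnotationTable, Dict[str, str]]:
    """Assign every library sequence exactly one annotation category.

    Precedence (highest first): rRNA > tRNA > snRNA > snoRNA > known
    miRNA > repeat > exon_sense > exon_antisense > intron_sense >
    intron_antisense > others.  ncRNA membership requires the read to be
    an exact substring of a reference sequence of that class; known
    miRNA membership an equal-length match with at most
    ``max_mirna_mm`` substitutions; repeat/exon/intron membership full
    containment of a mapped locus in the interval.  Unmapped reads fall
    through to "others".  Returns the summary table and the
    per-sequence category map.
    """
    # concatenated reference blobs allow O(1)-ish substring membership
    blobs = {cls: "#".join(s.upper() for s in seqs) for cls, seqs in ncrna_ref.items()}
    mir_by_len: Dict[int, List[str]] = defaultdict(list)
    for m in known_mirnas:
        mir_by_len[len(m)].append(m.upper())

    genes_by_scaffold: Dict[str, List[GeneModel]] = defaultdict(list)
    for g in gene_models:
        genes_by_scaffold[g.scaffold].append(g)

    def categorize(seq: str, loci: List[Locus]) -> str:
        if not loci:
            return "others"
        for cls in ("rRNA", "tRNA", "snRNA", "snoRNA"):
            if cls in blobs and seq in blobs[cls]:
                return cls
        if any(_hamming_le(seq, ref, max_mirna_mm) for ref in mir_by_len.get(len(seq), ())):
            return "miRNA"
        hits = set()
        for locus in loci:
            for (rs, re) in repeat_intervals.get(locus.scaffold, ()):
                if rs <= locus.start and locus.end <= re:
                    hits.add("repeat")
            for gene in genes_by_scaffold.get(locus.scaffold, ()):
                sense = "sense" if locus.strand == gene.strand else "antisense"
                if any(es <= locus.start and locus.end <= ee for es, ee in gene.exons):
                    hits.add(f"exon_{sense}")
                elif any(is_ <= locus.start and locus.end <= ie for is_, ie in gene.introns):
                    hits.add(f"intron_{sense}")
        for cat in CATEGORY_PRECEDENCE:
            if cat in hits:
                return cat
        return "others"

    table = AnnotationTable(lib.label)
    assignment: Dict[str, str] = {}
    for seq, count in lib.entries.items():
        cat = categorize(seq, locus_map.get(seq, []))
        assignment[seq] = cat
        table.add(cat, count)
    return table, assignment
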