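"""Known and novel miRNA identification.

Known miRNAs are library sequences matching a reference mature set
(miRBase-like) at equal length with at most two substitutions.  Novel
candidates come from clustering unannotated mapped reads into loci,
taking the most abundant read per locus as the mature, extracting
candidate precursor windows from the genome, folding them, and applying
the four identification criteria:

1. the precursor folds into a single marked stem-loop hairpin;
2. ≤ 4 mismatches between miRNA and miRNA*;
3. asymmetric bulges ≤ 2 nt;
4. precursor MFE ≤ −18 kcal/mol (inclusive, under the package's
   pair-energy model);

plus two siRNA-exclusion rules: loci whose abundant read pair shows the
siRNA 2-nt-3'-overhang duplex signature are dropped, as are sequences
with more than 24 perfect genomic loci (repeat-derived).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import rnastruct
from .preprocess import CollapsedLibrary, GeneModel, Locus, revcomp_dna
from .rnastruct import DuplexReport, HairpinStructure, to_rna


@dataclass
class MiRNACandidate:
    mature: str                      # DNA, genome sense
    arm: str = ""                    # 5p | 3p
    star: Optional[str] = None
    scaffold: str = ""
    precursor_start: int = 0         # 0-based half-open
    precursor_end: int = 0
    strand: str = "+"
    precursor_seq: str = ""          # DNA
    structure: Optional[HairpinStructure] = None
    duplex: Optional[DuplexReport] = None
    n_genomic_loci: int = 0
    counts: Tuple[int, int] = (0, 0)     # (CL, DT)
    family: str = ""
    context: str = ""
    status: str = "novel"            # known | novel
    mirna_id: str = ""
    criteria_verdicts: Dict[str, Tuple[bool, str]] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return bool(self.criteria_verdicts) and all(
            ok for ok, _ in self.criteria_verdicts.values())


def family_of(ref_id: str) -> str:
    """Family label from a reference name: sit-miR156a-5p → miR156."""
    m = re.search(r"(miR\d+)", ref_id, flags=re.IGNORECASE)
    return m.group(1) if m else ref_id


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def match_known(
    lib: CollapsedLibrary,
    mature_ref: Dict[str, str],
    max_mm: int = 2,
) -> Dict[str, Tuple[str, int]]:
    """Match library sequences against reference matures.

    A hit requires equal length and Hamming distance ≤ ``max_mm``
    (substitutions only, no indels).  The best hit per sequence (fewest
    mismatches, ties by lexicographic reference id) is retained.
    Returns sequence → (reference id, mismatches).
    """
    by_len: Dict[int, List[Tuple[str, str]]] = {}
    for rid in sorted(mature_ref):
        seq = mature_ref[rid].upper()
        by_len.setdefault(len(seq), []).append((rid, seq))
    hits: Dict[str, Tuple[str, int]] = {}
    for seq in lib.entries:
        best: Optional[Tuple[int, str]] = None
        for rid, ref in by_len.get(len(seq), ()):
            mm = _hamming(seq, ref)
            if mm <= max_mm and (best is None or (mm, rid) < best):
                best = (mm, rid)
        if best is not None:
            hits[seq] = (best[1], best[0])
    return hits


def extract_precursors(
    genome: Dict[str, str],
    locus: Locus,
    flank: int = 250,
) -> List[Tuple[int, int, str]]:
    """Candidate precursor windows around a mature locus.

    Three windows — long 5' flank, long 3' flank, and symmetric — each
    clipped to scaffold bounds; every window contains the mature.
    Returns (start, end, sequence) with genome-sense sequence; minus
    strand loci are reverse-complemented downstream.
    """
    seq = genome[locus.scaffold]
    if not (0 <= locus.start < locus.end <= len(seq)):
        raise ValueError("locus outside scaffold")
    shapes = [(flank, 20), (20, flank), (flank // 2, flank // 2)]
    out = []
    for f, g in shapes:
        s = max(0, locus.start - f)
        e = min(len(seq), locus.end + g)
        out.append((s, e, seq[s:e]))
    return out


def find_star(
    lib: CollapsedLibrary,
    precursor_seq: str,
    mature: str,
    structure: HairpinStructure,
    tolerance: int = 1,
) -> Optional[str]:
    """Detect an expressed miRNA* on the arm opposite the mature.

    Candidates are library sequences (DNA) occurring in the precursor
    (RNA) on the opposite side of the terminal loop whose duplex with
    the mature has ~2-nt 3' overhangs on both strands (± ``tolerance``).
    The highest-count qualifying sequence wins; ties resolve 5'-most.
    Returns the star in library (DNA) alphabet.
    """
    if structure.arms is None and not rnastruct.is_stemloop(structure, min_stem=1):
        return None
    loop_lo, loop_hi = structure.arms["loop"]
    mature = to_rna(mature)
    m_off = precursor_seq.find(mature)
    if m_off < 0:
        return None
    mature_5p = m_off + len(mature) - 1 < loop_lo
    # enumerate opposite-arm windows and look them up in the library
    if mature_5p:
        lo, hi = loop_hi + 1, len(precursor_seq)
    else:
        lo, hi = 0, loop_lo
    best: Optional[Tuple[int, int, str]] = None   # (-count, offset, seq)
    for L in range(19, 25):
        for off in range(lo, hi - L + 1):
            sub = precursor_seq[off:off + L]
            dna = sub.replace("U", "T")
            count = lib.entries.get(dna, 0)
            if count == 0 or sub == mature:
                continue
            rep = rnastruct.duplex_stats(mature, sub, structure)
            if all(abs(o - 2) <= tolerance for o in rep.overhang_3p) and rep.mismatches <= 4:
                key = (-count, off, dna)
                if best is None or key < best:
                    best = key
    return best[2] if best else None


def predicted_star(
    structure: HairpinStructure,
    precursor_seq: str,
    mature: str,
) -> Optional[str]:
    """The opposite-arm segment the structure pairs with the mature.

    Spans the partners of the mature's paired bases plus a canonical
    2-nt 3' extension — the Dicer-product geometry.  Used to evaluate
    the duplex criteria when no expressed miRNA* is in the library.
    Returns None when the mature is essentially unpaired.
    """
    mature = to_rna(mature)
    m0 = precursor_seq.find(mature)
    if m0 < 0:
        return None
    partner = structure.partner()
    qs = [partner[p] for p in range(m0, m0 + len(mature)) if p in partner]
    qs = [q for q in qs if q < m0 or q >= m0 + len(mature)]
    if len(qs) < 5:
        return None
    q_min, q_max = min(qs), max(qs)
    return precursor_seq[max(0, q_min): min(len(precursor_seq), q_max + 3)]


def apply_criteria(
    candidate: MiRNACandidate,
    mfe_max: float = -18.0,
    max_duplex_mm: int = 4,
    max_bulge: int = 2,
    max_loci: int = 24,
    min_stem: int = 15,
    is_sirna: bool = False,
    require_star: bool = False,
) -> Dict[str, Tuple[bool, str]]:
    """Evaluate the four identification criteria plus siRNA exclusions.

    Stores and returns per-criterion (verdict, reason).  Duplex criteria
    are evaluated only when a star is present; without one they pass
    vacuously unless ``require_star``.
    """
    st = candidate.structure
    v: Dict[str, Tuple[bool, str]] = {}
    if st is None:
        v["stemloop"] = (False, "no structure computed")
    else:
        ok = rnastruct.is_stemloop(st, min_stem=min_stem)
        v["stemloop"] = (ok, f"{st.n_pairs} pairs; single terminal loop: {ok}")
    dup = candidate.duplex
    if dup is None and candidate.star is not None and st is not None:
        dup = rnastruct.duplex_stats(to_rna(candidate.mature), to_rna(candidate.star), st)
        candidate.duplex = dup
    if require_star and candidate.star is None:
        v["duplex_mismatches"] = (False, "no miRNA* detected (star required)")
        v["duplex_bulge"] = (False, "no miRNA* detected (star required)")
    elif dup is None:
        # no expressed star and no evaluable pairing geometry
        v["duplex_mismatches"] = (False, "mature unpaired in hairpin; no duplex")
        v["duplex_bulge"] = (False, "mature unpaired in hairpin; no duplex")
    else:
        src = "" if candidate.star is not None else " (structure-predicted star)"
        v["duplex_mismatches"] = (dup.mismatches <= max_duplex_mm,
                                  f"{dup.mismatches} mismatches (max {max_duplex_mm}){src}")
        v["duplex_bulge"] = (dup.max_bulge <= max_bulge,
                             f"max bulge {dup.max_bulge} nt (max {max_bulge}){src}")
    if st is None:
        v["mfe"] = (False, "no structure computed")
    else:
        v["mfe"] = (st.mfe <= mfe_max, f"MFE {st.mfe:.1f} kcal/mol (max {mfe_max})")
    v["locus_count"] = (candidate.n_genomic_loci <= max_loci,
                        f"{candidate.n_genomic_loci} genomic loci (max {max_loci})")
    v["not_sirna"] = (not is_sirna, "siRNA duplex signature" if is_sirna else "no siRNA signature")
    candidate.criteria_verdicts = v
    return v


def _fold_best_window(
    genome: Dict[str, str],
    locus: Locus,
    mature: str,
    flank: int,
    mfe_max: float,
    min_stem: int,
) -> Optional[Tuple[int, int, str, HairpinStructure]]:
    """Excise and fold the best candidate precursor around a mature locus.

    Each flanking window is folded coarsely; the outermost stem pair
    enclosing the mature with a single terminal loop marks the
    precursor, which is refolded on its own.  Among windows whose
    excised precursor is a stem-loop within the stability bound, the
    lowest-MFE one wins.  Returned coordinates are window-genome based
    (0-based half-open on the plus strand).
    """
    best = None
    for s, e, seq in extract_precursors(genome, locus, flank):
        if locus.strand == "-":
            seq = revcomp_dna(seq)
        if len(seq) > 400:
            seq = seq[:400]
        m0 = seq.find(mature)
        if m0 < 0:
            continue
        try:
            coarse = rnastruct.fold_mfe(to_rna(seq))
        except ValueError:
            continue
        region = rnastruct.hairpin_region(coarse, m0, m0 + len(mature) - 1)
        if region is None:
            continue
        i, j = region
        sub = seq[i: j + 1]
        if len(sub) < 40:
            continue
        st = rnastruct.fold_mfe(to_rna(sub))
        if rnastruct.is_stemloop(st, min_stem=min_stem) and st.mfe <= mfe_max:
            # the mature must sit on one arm, not across the terminal loop
            sm = sub.find(mature)
            loop_lo, loop_hi = st.arms["loop"]
            on_5p = sm + len(mature) - 1 <= loop_lo + 3
            on_3p = sm >= loop_hi - 3
            if sm < 0 or not (on_5p or on_3p):
                continue
            if locus.strand == "+":
                gs, ge = s + i, s + j + 1
            else:
                ge, gs = e - i, e - j - 1
            if best is None or st.mfe < best[3].mfe:
                best = (gs, ge, sub, st)
    return best


def evaluate_candidate(
    mature: str,
    loci: List[Locus],
    genome: Dict[str, str],
    lib: CollapsedLibrary,
    counts: Tuple[int, int],
    locus_reads: Optional[Sequence[Tuple[str, int, int, int]]] = None,
    flank: int = 250,
    mfe_max: float = -18.0,
    min_stem: int = 15,
    max_duplex_mm: int = 4,
    max_bulge: int = 2,
    max_loci: int = 24,
    require_star: bool = False,
    status: str = "novel",
) -> MiRNACandidate:
    """Build and judge one candidate from a mature sequence and its loci."""
    cand = MiRNACandidate(mature=mature, counts=counts, status=status,
                          n_genomic_loci=len(loci))
    if not loci:
        apply_criteria(cand, mfe_max=mfe_max, min_stem=min_stem, require_star=require_star)
        cand.criteria_verdicts["stemloop"] = (False, "unmapped mature")
        return cand
    locus = loci[0]
    cand.scaffold, cand.strand = locus.scaffold, locus.strand
    best = _fold_best_window(genome, locus, mature, flank, mfe_max, min_stem)
    if best is not None:
        s, e, seq, st = best
        cand.precursor_start, cand.precursor_end = s, e
        cand.precursor_seq = seq
        cand.structure = st
        rna_pre = st.sequence
        m_off = rna_pre.find(to_rna(mature))
        loop_lo, _ = st.arms["loop"]
        cand.arm = "5p" if (m_off >= 0 and m_off + len(mature) - 1 < loop_lo) else "3p"
        star = find_star(lib, rna_pre, to_rna(mature), st)
        if star is not None:
            cand.star = star
            cand.duplex = rnastruct.duplex_stats(to_rna(mature), to_rna(star), st)
        else:
            sp = predicted_star(st, rna_pre, to_rna(mature))
            if sp is not None:
                cand.duplex = rnastruct.duplex_stats(to_rna(mature), sp, st)
    else:
        # keep the symmetric window for reporting even when nothing passes
        s, e, seq = extract_precursors(genome, locus, flank)[2]
        if locus.strand == "-":
            seq = revcomp_dna(seq)
        cand.precursor_start, cand.precursor_end = s, e
        cand.precursor_seq = seq[:400]
        try:
            cand.structure = rnastruct.fold_mfe(to_rna(cand.precursor_seq))
        except ValueError:
            cand.structure = None
    is_sirna = rnastruct.sirna_duplex_check(locus_reads or [])
    apply_criteria(cand, mfe_max=mfe_max, max_duplex_mm=max_duplex_mm,
                   max_bulge=max_bulge, max_loci=max_loci, min_stem=min_stem,
                   require_star=require_star, is_sirna=is_sirna)
    return cand


def cluster_loci(
    locus_map: Dict[str, List[Locus]],
    counts: Dict[str, int],
    gap: int = 200,
) -> List[List[Tuple[str, Locus]]]:
    """Single-linkage clustering of mapped reads into genomic loci.

    Reads on the same scaffold and strand whose intervals are within
    ``gap`` nt are merged into one locus cluster.  Returns clusters of
    (sequence, locus) pairs, deterministic in ordering.
    """
    placed = []
    for seq, loci in locus_map.items():
        for locus in loci:
            placed.append((locus.scaffold, locus.strand, locus.start, locus.end, seq, locus))
    placed.sort(key=lambda t: (t[0], t[1], t[2], t[3], t[4]))
    clusters: List[List[Tuple[str, Locus]]] = []
    cur: List = []
    cur_key = None
    cur_end = -1
    for sc, strand, start, end, seq, locus in placed:
        if cur_key == (sc, strand) and start <= cur_end + gap:
            cur.append((seq, locus))
            cur_end = max(cur_end, end)
        else:
            if cur:
                clusters.append(cur)
            cur = [(seq, locus)]
            cur_key = (sc, strand)
            cur_end = end
    if cur:
        clusters.append(cur)
    return clusters


def predict_novel(
    unannotated: CollapsedLibrary,
    genome: Dict[str, str],
    locus_map: Dict[str, List[Locus]],
    known_loci: Sequence[Tuple[str, int, int]] = (),
    min_count: int = 5,
    gap: int = 200,
    flank: int = 250,
    mfe_max: float = -18.0,
    max_loci: int = 24,
    min_stem: int = 15,
    require_star: bool = False,
) -> List[MiRNACandidate]:
    """Predict novel miRNAs from unannotated mapped reads.

    Reads are clustered into loci (same strand, gap ≤ ``gap``); per
    cluster the most abundant read is the mature candidate, judged by
    the full criteria set; clusters overlapping a known miRNA locus are
    dropped.
    """
    mapped = {s: l for s, l in locus_map.items() if s in unannotated.entries}
    clusters = cluster_loci(mapped, unannotated.entries, gap=gap)
    # strand-agnostic read index so the siRNA duplex check sees both strands
    by_scaffold: Dict[str, List[Tuple[str, int, int, int]]] = {}
    for seq, loci in mapped.items():
        for l in loci:
            by_scaffold.setdefault(l.scaffold, []).append(
                (l.strand, l.start, l.end, unannotated.entries[seq]))
    out: List[MiRNACandidate] = []
    seen_mature = set()
    for cluster in clusters:
        total = sum(unannotated.entries[seq] for seq, _ in cluster)
        if total < min_count:
            continue
        sc = cluster[0][1].scaffold
        lo = min(l.start for _, l in cluster)
        hi = max(l.end for _, l in cluster)
        if any(ksc == sc and ks < hi and lo < ke for ksc, ks, ke in known_loci):
            continue
        mature, locus = max(cluster, key=lambda t: (unannotated.entries[t[0]], t[0]))
        if mature in seen_mature:
            continue
        seen_mature.add(mature)
        locus_reads = [r for r in by_scaffold.get(sc, ())
                       if r[1] < hi + 2 and lo - 2 < r[2]]
        cand = evaluate_candidate(
            mature, locus_map[mature], genome, unannotated,
            counts=(unannotated.entries[mature], 0),
            locus_reads=locus_reads, flank=flank, mfe_max=mfe_max,
            max_loci=max_loci, min_stem=min_stem, require_star=require_star,
            status="novel",
        )
        if cand.passed:
            out.append(cand)
    # a hairpin is discoverable from both strands (the arms are near
    # reverse complements): collapse candidates whose precursor
    # intervals overlap, keeping the more abundant mature
    out.sort(key=lambda c: (-c.counts[0], c.mature))
    kept: List[MiRNACandidate] = []
    for cand in out:
        clash = any(
            k.scaffold == cand.scaffold
            and k.precursor_start < cand.precursor_end
            and cand.precursor_start < k.precursor_end
            for k in kept)
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda c: (c.scaffold, c.precursor_start, c.mature))
    return kept


def cluster_families(candidates: Sequence[MiRNACandidate], max_mm: int = 2,
                     prefix: str = "sit_novel_fam") -> None:
    """Assign family labels in place.

    Known candidates inherit the family embedded in their id/reference;
    novel matures are single-linkage clustered at equal length and
    Hamming distance ≤ ``max_mm``; family ids are stable (ordered by
    the lexicographically smallest member mature).
    """
    novel = [c for c in candidates if c.status == "novel"]
    matures = sorted({c.mature for c in novel})
    parent = {m: m for m in matures}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(matures):
        for b in matures[i + 1:]:
            if len(a) == len(b) and _hamming(a, b) <= max_mm:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    roots = sorted({find(m) for m in matures})
    fam_id = {root: f"{prefix}{i + 1}" for i, root in enumerate(roots)}
    for c in novel:
        c.family = fam_id[find(c.mature)]
    for c in candidates:
        if c.status == "known" and not c.family:
            c.family = family_of(c.mirna_id or c.family)


def classify_genomic_context(
    locus: Tuple[str, int, int],
    gene_models: Sequence[GeneModel],
) -> str:
    """Genomic context of a precursor locus: CDS > intron > intergenic.

    Decided by the precursor midpoint: inside an annotated CDS interval
    → CDS; inside an intron → intron; otherwise intergenic.
    """
    sc, start, end = locus
    mid = (start + end) // 2
    in_intron = False
    for g in gene_models:
        if g.scaffold != sc:
            continue
        if any(cs <= mid < ce for cs, ce in g.cds):
            return "CDS"
        if any(is_ <= mid < ie for is_, ie in g.introns):
            in_intron = True
    return "intron" if in_intron else "intergenic"


def candidate_table(candidates: Sequence[MiRNACandidate]):
    """Published-style candidate table (DataFrame)."""
    import pandas as pd

    rows = [{
        "miRNA": c.mirna_id or c.family,
        "mature_sequence": c.mature,
        "arm": c.arm,
        "length": len(c.mature),
        "star_sequence": c.star or "",
        "precursor_location": f"{c.scaffold}:{c.precursor_start + 1}..{c.precursor_end}:{c.strand}",
        "MFE": round(c.structure.mfe, 1) if c.structure else float("nan"),
        "family": c.family,
        "context": c.context,
        "count_cl": c.counts[0],
        "count_dt": c.counts[1],
        "status": c.status,
        "passed": c.passed,
    } for c in candidates]
    return pd.DataFrame(rows)
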