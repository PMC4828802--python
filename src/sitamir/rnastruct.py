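"""RNA secondary structure prediction and miRNA:miRNA* duplex analysis.

Folding uses a base-pair-counting energy model (a weighted Nussinov
dynamic program): each admissible pair contributes a fixed stacking-free
energy — G:C −3.0, A:U −2.0, G:U −1.0 kcal/mol — with a minimum hairpin
loop of 3 nt and no loop penalties.  This deliberately simple model is
*not* a nearest-neighbour (Turner) model: its minima are comparable only
within the model, and the −18 kcal/mol precursor stability criterion
used downstream is interpreted under it.  A plug-in hook
(``fold_mfe(engine=...)``) accepts an external folding callable for
parity with thermodynamic folders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from numba import njit

# Per-pair energies, kcal/mol.  Integer-valued so the DP is exact.
PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}

_RNA_ALPHABET = frozenset("ACGU")
_ENC = {"A": 0, "C": 1, "G": 2, "U": 3}
# energy lookup by encoded base pair; 1 (positive) marks "cannot pair"
_EMAT = np.ones((4, 4), dtype=np.int64)
for (_a, _b), _e in PAIR_ENERGY.items():
    _EMAT[_ENC[_a], _ENC[_b]] = int(_e)


def to_rna(seq: str) -> str:
    """Transliterate a DNA string to RNA (T→U, uppercased)."""
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    comp = {"A": "U", "U": "A", "G": "C", "C": "G", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq.upper().replace("T", "U")))


@dataclass
class HairpinStructure:
    """A nested (pseudoknot-free) secondary structure.

    ``pairs`` holds 0-based (i, j) index pairs with i < j; ``mfe`` is the
    total energy of the structure under the package's pair-energy model,
    in kcal/mol.  ``arms`` is populated by :func:`is_stemloop` for
    single-hairpin structures: 0-based inclusive intervals for the 5'
    arm, 3' arm and terminal loop.
    """

    sequence: str
    pairs: frozenset
    dot_bracket: str
    mfe: float
    arms: Optional[dict] = field(default=None)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def partner(self) -> dict:
        """Map every paired index to its partner."""
        d = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d


@njit(cache=True)
def _nussinov_fill(enc: np.ndarray, min_loop: int):
    """Fill energy (W) and minimum-pair-count (C) tables.

    Recurrence over [i, j]: either i is unpaired, or i pairs with some k
    (k − i > min_loop), splitting the interval.  Every nested structure
    has exactly one such decomposition, which keeps traceback canonical.
    Ties on energy are broken toward fewer pairs.
    """
    n = enc.shape[0]
    W = np.zeros((n + 2, n + 2), dtype=np.int64)
    C = np.zeros((n + 2, n + 2), dtype=np.int64)
    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            best_e = W[i + 1, j]
            best_c = C[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                e = _EMAT_G[enc[i], enc[k]]
                if e < 0:
                    te = e + W[i + 1, k - 1] + W[k + 1, j]
                    tc = 1 + C[i + 1, k - 1] + C[k + 1, j]
                    if te < best_e or (te == best_e and tc < best_c):
                        best_e = te
                        best_c = tc
            W[i, j] = best_e
            C[i, j] = best_c
    return W, C


# numba closes over module globals at compile time; expose the table
# under the name used inside the kernel.
_EMAT_G = _EMAT


def _traceback(enc: np.ndarray, W: np.ndarray, C: np.ndarray, min_loop: int):
    """Recover one optimal structure deterministically.

    At each interval the leftmost base is paired to its smallest
    admissible partner achieving the optimal (energy, pair count), else
    left unpaired — a fixed canonical choice among co-optimal structures.
    """
    n = enc.shape[0]
    pairs = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        while i < j:
            target_e, target_c = W[i, j], C[i, j]
            paired = False
            for k in range(i + min_loop + 1, j + 1):
                e = _EMAT[enc[i], enc[k]]
                if e < 0:
                    te = e + W[i + 1, k - 1] + W[k + 1, j]
                    tc = 1 + C[i + 1, k - 1] + C[k + 1, j]
                    if te == target_e and tc == target_c:
                        pairs.append((i, k))
                        if k + 1 <= j:
                            stack.append((k + 1, j))
                        i, j = i + 1, k - 1
                        paired = True
                        break
            if not paired:
                i += 1
    return pairs


def fold_mfe(
    seq: str,
    min_loop: int = 3,
    engine: Optional[Callable[[str], tuple]] = None,
) -> HairpinStructure:
    """Fold an RNA sequence into its minimum-energy nested structure.

    Parameters
    ----------
    seq
        RNA string over {A, C, G, U}, length 10–400.
    min_loop
        Minimum number of unpaired bases in a hairpin loop.
    engine
        Optional external folding engine: a callable mapping the
        sequence to ``(dot_bracket, mfe)``.  When given, its structure
        is adopted verbatim (e.g. for parity with thermodynamic
        folders); otherwise the built-in pair-energy DP is used.
    """
    seq = seq.upper()
    if not (5 <= len(seq) <= 400):
        raise ValueError(f"sequence length {len(seq)} outside [5, 400]")
    if not set(seq) <= _RNA_ALPHABET:
        bad = sorted(set(seq) - _RNA_ALPHABET)
        raise ValueError(f"invalid RNA characters {bad}; DNA input must be transliterated (to_rna)")

    if engine is not None:
        db, mfe = engine(seq)
        return HairpinStructure(seq, frozenset(pairs_from_dot_bracket(db)), db, float(mfe))

    enc = np.array([_ENC[c] for c in seq], dtype=np.int64)
    W, C = _nussinov_fill(enc, min_loop)
    pairs = _traceback(enc, W, C, min_loop)
    db = dot_bracket_from_pairs(len(seq), pairs)
    return HairpinStructure(seq, frozenset(pairs), db, float(W[0, len(seq) - 1]))


def dot_bracket_from_pairs(n: int, pairs: Sequence[tuple]) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def pairs_from_dot_bracket(db: str) -> list:
    stack, pairs = [], []
    for idx, c in enumerate(db):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            pairs.append((stack.pop(), idx))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pairs


def structure_energy(seq: str, pairs) -> float:
    """Energy of an explicit structure under the pair-energy model."""
    return float(sum(PAIR_ENERGY[(seq[i], seq[j])] for i, j in pairs))


def enumerate_structures(seq: str, min_loop: int = 3):
    """Exhaustively enumerate every nested structure of a short sequence.

    Yields lists of (i, j) pairs.  Exponential — intended as an
    independent oracle for sequences of ~18 nt and below.
    """
    n = len(seq)

    def rec(i, j):
        if i >= j:
            yield []
            return
        # position i unpaired
        for rest in rec(i + 1, j):
            yield rest
        # position i paired with k
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in PAIR_ENERGY:
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        yield [(i, k)] + inner + outer

    yield from rec(0, n - 1)


def is_stemloop(structure: HairpinStructure, min_stem: int = 15) -> bool:
    """Decide whether a folded structure is a single stem-loop hairpin.

    True iff the structure contains exactly one terminal (hairpin) loop
    — which excludes multiloops and multi-hairpin concatemers — and at
    least ``min_stem`` base pairs in total.  On success the structure's
    ``arms`` field is populated with 0-based inclusive intervals.
    """
    pairs = sorted(structure.pairs)
    if len(pairs) < min_stem:
        return False
    # hairpin loops: pairs enclosing no other pair
    hairpin_closers = []
    for (i, j) in pairs:
        if not any(i < a and b < j for a, b in pairs if (a, b) != (i, j)):
            hairpin_closers.append((i, j))
    if len(hairpin_closers) != 1:
        return False
    inner_i, inner_j = hairpin_closers[0]
    outer_i = min(i for i, _ in pairs)
    outer_j = max(j for _, j in pairs)
    structure.arms = {
        "5p": (outer_i, inner_i),
        "3p": (inner_j, outer_j),
        "loop": (inner_i + 1, inner_j - 1),
    }
    return True


def hairpin_region(structure: HairpinStructure, lo: int, hi: int,
                   slop: int = 8) -> Optional[tuple]:
    """Single-hairpin region of a larger fold covering [lo, hi].

    Finds the widest pair (i, j) whose interior contains exactly one
    terminal loop and which covers [lo, hi] up to ``slop`` nt of
    overhang on either side (duplex 3' overhangs legitimately stick out
    of the stem).  Returns the region extended to include [lo, hi], or
    None.  Used to excise a candidate precursor from a genomic window
    whose flanks fold independently.
    """
    pairs = sorted(structure.pairs)
    closers = [(a, b) for (a, b) in pairs
               if not any(a < x and y < b for x, y in pairs if (x, y) != (a, b))]
    best = None
    for i, j in pairs:
        if i - slop <= lo and hi <= j + slop:
            inside = sum(1 for a, b in closers if i <= a and b <= j)
            if inside == 1 and (best is None or j - i > best[1] - best[0]):
                best = (i, j)
    if best is None:
        return None
    return min(best[0], lo), max(best[1], hi)


@dataclass
class DuplexReport:
    """Geometry of one miRNA:miRNA* duplex under a fixed alignment."""

    mismatches: int
    max_bulge: int
    gu_pairs: int
    overhang_3p: tuple  # (mature-strand 3' overhang, star-strand 3' overhang), nt


def _is_pair(a: str, b: str) -> bool:
    return (a, b) in PAIR_ENERGY


def _is_gu(a: str, b: str) -> bool:
    return (a, b) in (("G", "U"), ("U", "G"))


def _duplex_from_structure(mature: str, star: str, structure: HairpinStructure):
    """Derive duplex geometry from the folded precursor, if coherent."""
    seq = structure.sequence
    m0 = seq.find(mature)
    s0 = seq.find(star)
    if m0 < 0 or s0 < 0:
        raise ValueError("mature/star not substrings of the precursor")
    if not is_stemloop(structure, min_stem=1):
        return None
    if m0 > s0:  # orient: first interval 5', second 3'
        m0, s0 = s0, m0
        first, second = star, mature
    else:
        first, second = mature, star
    m1, s1 = m0 + len(first) - 1, s0 + len(second) - 1
    loop_lo, loop_hi = structure.arms["loop"]
    if m1 >= loop_lo or s0 <= loop_hi:
        return None  # arms straddle the loop; fall back to alignment
    partner = structure.partner()
    cols = [(p, partner[p]) for p in range(m0, m1 + 1)
            if p in partner and s0 <= partner[p] <= s1]
    if len(cols) < 5:
        return None
    mismatches = 0
    max_bulge = 0
    gu = sum(1 for p, q in cols if _is_gu(seq[p], seq[q]))
    for (p1, q1), (p2, q2) in zip(cols, cols[1:]):
        gap_m = p2 - p1 - 1
        gap_s = q1 - q2 - 1
        mismatches += min(gap_m, gap_s)
        max_bulge = max(max_bulge, abs(gap_m - gap_s))
    # unopposed 5'-side tails inside the duplex region
    first_p, first_q = cols[0]
    last_p, last_q = cols[-1]
    over_first = m1 - last_p       # 3' overhang of the 5'-arm strand
    over_second = s1 - first_q     # 3' overhang of the 3'-arm strand
    if first is mature:
        overhangs = (over_first, over_second)
    else:
        overhangs = (over_second, over_first)
    return DuplexReport(mismatches, max_bulge, gu, overhangs)


def _needleman_wunsch_duplex(mature: str, star: str):
    """Align mature against the star read antiparallel.

    Complementary columns (Watson–Crick or G:U) score +1, mismatches 0,
    internal gaps −1; terminal gaps are free (duplex overhangs are not
    bulges).  Ties prefer the diagonal, i.e. fewer gaps.  Returns the
    aligned column list as (mature_index or None, star_index or None).
    """
    a = mature
    b = star[::-1]  # antiparallel
    n, m = len(a), len(b)
    S = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = S[i - 1, j - 1] + (1.0 if _is_pair(a[i - 1], b[j - 1]) else 0.0)
            S[i, j] = max(diag, S[i - 1, j] - 1.0, S[i, j - 1] - 1.0)
    # free end gaps: start traceback at the best cell on the last row/col
    ends = [(S[n, j], n, j) for j in range(m + 1)] + [(S[i, m], i, m) for i in range(n + 1)]
    _, i, j = max(ends, key=lambda t: (t[0], t[1] + t[2]))
    cols = []
    for jj in range(m - 1, j - 1, -1):
        cols.append((None, jj))
    for ii in range(n - 1, i - 1, -1):
        cols.append((ii, None))
    while i > 0 and j > 0:
        diag = S[i - 1, j - 1] + (1.0 if _is_pair(a[i - 1], b[j - 1]) else 0.0)
        if S[i, j] == diag:
            cols.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif S[i, j] == S[i - 1, j] - 1.0:
            cols.append((i - 1, None))
            i -= 1
        else:
            cols.append((None, j - 1))
            j -= 1
    while i > 0:
        cols.append((i - 1, None))
        i -= 1
    while j > 0:
        cols.append((None, j - 1))
        j -= 1
    cols.reverse()
    return cols


def duplex_stats(mature: str, star: str, structure: Optional[HairpinStructure] = None) -> DuplexReport:
    """Mismatch/bulge/overhang statistics of a miRNA:miRNA* duplex.

    When a folded precursor is supplied and both strands lie on opposite
    arms of its single stem, the geometry is read off the structure;
    otherwise the two strands are globally aligned antiparallel (match
    1, mismatch 0, gap −1).  Mismatches are opposed non-complementary
    columns; a bulge is a run of unopposed bases on one strand.
    """
    mature, star = to_rna(mature), to_rna(star)
    if structure is not None:
        rep = _duplex_from_structure(mature, star, structure)
        if rep is not None:
            return rep
    # canonical strand order: co-optimal alignments can differ in
    # mismatch count, so tie-breaking must not depend on argument order
    swapped = star < mature
    if swapped:
        mature, star = star, mature
    cols = _needleman_wunsch_duplex(mature, star)
    b = star[::-1]
    mismatches = 0
    gu = 0
    max_bulge = 0
    run = 0
    # trim terminal gap runs: they are overhangs, not bulges
    first_al = next(k for k, (x, y) in enumerate(cols) if x is not None and y is not None)
    last_al = len(cols) - 1 - next(
        k for k, (x, y) in enumerate(reversed(cols)) if x is not None and y is not None
    )
    for x, y in cols[first_al: last_al + 1]:
        if x is not None and y is not None:
            run = 0
            if _is_pair(mature[x], b[y]):
                if _is_gu(mature[x], b[y]):
                    gu += 1
            else:
                mismatches += 1
        else:
            run += 1
            max_bulge = max(max_bulge, run)
    # 3' overhangs: mature 3' end is the right end; star 3' end is the left
    # end of the reversed star, i.e. leading star-only columns.
    over_m = sum(1 for x, y in cols[last_al + 1:] if x is not None)
    over_s = sum(1 for x, y in cols[:first_al] if y is not None)
    if swapped:
        over_m, over_s = over_s, over_m
    return DuplexReport(mismatches, max_bulge, gu, (over_m, over_s))


def sirna_duplex_check(locus_reads) -> bool:
    """Detect the siRNA duplex signature at a genomic locus.

    ``locus_reads`` is an iterable of (strand, start, end, count) with
    0-based half-open genome coordinates.  Returns True iff the most
    abundant plus-strand and minus-strand reads form a double-stranded
    duplex in which each strand carries a 2-nt 3' overhang — the
    Dicer-typical siRNA geometry used to exclude siRNA loci from miRNA
    calls.
    """
    plus = [r for r in locus_reads if r[0] == "+"]
    minus = [r for r in locus_reads if r[0] == "-"]
    if not plus or not minus:
        return False
    sp = max(plus, key=lambda r: r[3])
    sm = max(minus, key=lambda r: r[3])
    # plus 3' end extends 2 nt past the minus 5' end, and vice versa
    return (sp[2] - sm[2] == 2) and (sp[1] - sm[1] == 2)
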