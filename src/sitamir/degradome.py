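"""Degradome (PARE) target identification and categorization.

Degradome tags are 5'-anchored fragments of cleaved mRNAs; the 5' end
of a tag marks a cleavage position.  Tags are mapped exactly to
transcripts to build T-plots (per-position tag-abundance profiles),
candidate miRNA binding sites are scored with an Allen-type
complementarity penalty, and each validated cleavage site is assigned
one of five categories ranked by how dominant its tag pile is relative
to the rest of the transcript:

* 0 — site abundance is the unique maximum on the transcript,
* 1 — maximum but tied with another position,
* 2 — above the median of occupied positions but not the maximum,
* 3 — at or below the median,
* 4 — exactly one raw read at the site.

The single-read rule (category 4) is tested first, so a transcript
whose only tag sits at the site is 4, not 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from statistics import median
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass
class TPlot:
    """Per-transcript degradome profile: 1-based 5'-end position → count."""

    transcript_id: str
    length: int
    abundance: Dict[int, int] = field(default_factory=dict)

    @property
    def total_tags(self) -> int:
        return sum(self.abundance.values())

    def validate(self) -> None:
        for pos in self.abundance:
            if not (1 <= pos <= self.length):
                raise ValueError(f"position {pos} outside [1, {self.length}]")


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    cleavage_position: int     # 1-based transcript coordinate
    site_abundance: int
    score: float
    category: int
    alternates: Tuple[int, ...] = ()   # categories at other in-window piles


def map_tags(
    tags: Iterable[Tuple[str, int]],
    transcripts: Dict[str, str],
    tag_len: int = 20,
) -> Dict[str, TPlot]:
    """Build T-plots from degradome tags.

    ``tags`` yields (sequence, count); each tag is truncated to its
    5'-most ``tag_len`` nt and matched exactly (sense strand) against
    every transcript; each perfect match adds the tag count at the
    1-based position of the tag 5' end.  Multi-transcript tags count at
    every match.
    """
    transcripts = {k: _rna(v) for k, v in transcripts.items()}
    collapsed: Counter = Counter()
    for seq, count in tags:
        collapsed[_rna(seq)[:tag_len]] += count
    tplots = {tid: TPlot(tid, len(seq)) for tid, seq in transcripts.items()}
    for tag, count in collapsed.items():
        if not tag:
            continue
        for tid, seq in transcripts.items():
            start = seq.find(tag)
            while start != -1:
                pos = start + 1
                tplots[tid].abundance[pos] = tplots[tid].abundance.get(pos, 0) + count
                start = seq.find(tag, start + 1)
    return tplots


def allen_score(mirna: str, site: str) -> float:
    """Allen-type complementarity penalty of a miRNA against a target site.

    The site is the transcript window (sense, 5'→3', same length as the
    miRNA); the miRNA binds it antiparallel, so miRNA position i
    (1-based from the miRNA 5' end) pairs the site base at position
    L−i+1.  Penalties: mismatch 1.0, G:U wobble 0.5, doubled at miRNA
    positions 2–13 (the seed-to-cleavage core); perfect pairs 0.
    """
    mirna, site = _rna(mirna), _rna(site)
    if len(mirna) != len(site):
        raise ValueError("site window must equal miRNA length in ungapped mode")
    L = len(mirna)
    score = 0.0
    for i in range(1, L + 1):
        m = mirna[i - 1]
        t = site[L - i]
        if (m, t) in _PAIRS:
            pen = 0.0
        elif (m, t) in _GU:
            pen = 0.5
        else:
            pen = 1.0
        if 2 <= i <= 13:
            pen *= 2.0
        score += pen
    return score


def expected_cleavage(window_start_1based: int, mirna_len: int) -> int:
    """Transcript coordinate paired with miRNA position 10.

    Cleavage of the target occurs between the bases paired to miRNA
    positions 10 and 11; the degradome tag 5' end sits at the base
    paired to position 10: window_start + L − 10 (1-based).
    """
    return window_start_1based + mirna_len - 10


def find_sites(
    mirna: str,
    transcript: str,
    max_score: float = 4.5,
) -> List[Tuple[int, int, float]]:
    """All binding sites of a miRNA on a transcript at the score cutoff.

    Returns (window_start, expected_cleavage_position, score), 1-based,
    for every window with Allen penalty ≤ ``max_score`` (inclusive).
    """
    mirna, transcript = _rna(mirna), _rna(transcript)
    L = len(mirna)
    if len(transcript) < L:
        return []
    out = []
    for s0 in range(len(transcript) - L + 1):
        window = transcript[s0:s0 + L]
        sc = allen_score(mirna, window)
        if sc <= max_score:
            start = s0 + 1
            out.append((start, expected_cleavage(start, L), sc))
    return out


def categorize(tplot: TPlot, position: int) -> int:
    """Assign the five-way cleavage category for one T-plot position.

    Cascade: a single raw read at the site → 4; unique transcript-wide
    maximum → 0; tied maximum → 1; above the median of occupied
    positions → 2; otherwise → 3.
    """
    ab = tplot.abundance.get(position, 0)
    if ab <= 0:
        raise ValueError(f"no degradome signal at position {position}")
    if ab == 1:
        return 4
    values = list(tplot.abundance.values())
    mx = max(values)
    if ab == mx:
        return 0 if values.count(mx) == 1 else 1
    return 2 if ab > median(values) else 3


def call_targets(
    mirnas: Dict[str, str],
    tplots: Dict[str, TPlot],
    transcripts: Dict[str, str],
    max_score: float = 4.5,
    window: int = 1,
) -> List[TargetHit]:
    """Degradome-validated target calling.

    For every (miRNA, transcript) pair, candidate sites within the
    complementarity cutoff are checked for tag signal within ±``window``
    nt of the expected cleavage coordinate; a hit is recorded at the
    in-window coordinate of maximal abundance (ties resolve to the
    expected coordinate, then 5'-most) with the category of that exact
    coordinate.  Categories of other occupied in-window coordinates are
    listed as alternates.  Output is sorted by miRNA id then transcript.
    """
    hits: List[TargetHit] = []
    for mid, mseq in sorted(mirnas.items()):
        for tid in sorted(transcripts):
            tp = tplots.get(tid)
            if tp is None or not tp.abundance:
                continue
            for _, cleave, score in find_sites(mseq, transcripts[tid], max_score):
                occupied = [
                    (tp.abundance[p], p) for p in range(cleave - window, cleave + window + 1)
                    if tp.abundance.get(p, 0) > 0
                ]
                if not occupied:
                    continue
                best_ab = max(a for a, _ in occupied)
                at_best = [p for a, p in occupied if a == best_ab]
                pos = cleave if cleave in at_best else min(at_best)
                alternates = tuple(
                    categorize(tp, p) for _, p in sorted(occupied, key=lambda t: t[1])
                    if p != pos
                )
                hits.append(TargetHit(
                    mid, tid, pos, tp.abundance[pos],
                    score, categorize(tp, pos), alternates,
                ))
    return hits


def predict_targets_insilico(
    mirnas: Dict[str, str],
    transcripts: Dict[str, str],
    max_score: float = 3.0,
) -> List[Tuple[str, str, int, float]]:
    """Complementarity-only target prediction (no degradome evidence).

    A simplified stand-in for web-based plant target predictors: every
    (miRNA, transcript, site) whose Allen penalty is ≤ ``max_score`` is
    reported as (mirna_id, transcript_id, expected_cleavage, score),
    flagged "predicted" by provenance (distinct from validated hits).
    """
    out = []
    for mid, mseq in sorted(mirnas.items()):
        for tid in sorted(transcripts):
            for _, cleave, score in find_sites(mseq, transcripts[tid], max_score):
                out.append((mid, tid, cleave, score))
    return out


def target_table(hits: Sequence[TargetHit], annotations: Optional[Dict[str, str]] = None):
    """Render target hits as a published-style table (DataFrame)."""
    import pandas as pd

    rows = [{
        "family": h.mirna_id,
        "target_gene": h.transcript_id,
        "cleave_position": h.cleavage_position,
        "category": h.category,
        "alt_categories": "/".join(map(str, h.alternates)),
        "alignment_score": h.score,
        "site_abundance": h.site_abundance,
        "annotation": (annotations or {}).get(h.transcript_id, ""),
    } for h in hits]
    return pd.DataFrame(rows)


def tplot_table(tp: TPlot):
    import pandas as pd

    return pd.DataFrame(
        [{"transcript": tp.transcript_id, "position": p, "count": c}
         for p, c in sorted(tp.abundance.items())]
    )
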