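"""TPM normalization and two-library differential expression tests.

Expression is normalized as tags per million (TPM): count / library
total × 10⁶.  Differential expression between the control (CL) and
drought (DT) libraries is assessed with three classical tests for a
count difference between two tag libraries:

* the Audic–Claverie exact test, based on the conditional distribution
  of one library's count given the other,

      p(y | x) = (N2/N1)^y · (x+y)! / (x!·y!) · (1 + N2/N1)^−(x+y+1),

  which is the negative-binomial pmf NB(y; r = x+1, p = N1/(N1+N2)) —
  the identity used to evaluate the tail sums stably;
* Fisher's exact test on the 2×2 table [[x, N1−x], [y, N2−y]];
* Pearson's chi-square on the same table, df = 1, no continuity
  correction.

The Audic–Claverie p-value is primary for DE calls: a miRNA is called
up (down) when log2 fold-change DT/CL on the TPM scale is ≥ 1 (≤ −1)
and p ≤ 0.01; miRNAs sequenced fewer than 10 times in both libraries
are filtered from testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Tuple

import numpy as np
from scipy import stats


def tpm(count: int, total: int) -> float:
    """Tags-per-million normalization: count / total × 10⁶."""
    if total <= 0:
        raise ZeroDivisionError("library total must be positive")
    if not (0 <= count <= total):
        raise ValueError("count must lie in [0, total]")
    return count / total * 1_000_000


def audic_claverie(x: int, y: int, N1: int, N2: int) -> float:
    """Two-sided Audic–Claverie p-value for counts x (CL) and y (DT).

    The conditional law of y given x is negative binomial with x+1
    successes and success probability N1/(N1+N2); the two-sided p is
    twice the smaller tail (capped at 1), with the observed y included
    in both tails.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    p = N1 / (N1 + N2)
    lower = stats.nbinom.cdf(y, x + 1, p)         # Σ_{k ≤ y} p(k|x)
    upper = stats.nbinom.sf(y - 1, x + 1, p)      # Σ_{k ≥ y} p(k|x)
    return float(min(1.0, 2.0 * min(lower, upper)))


def audic_claverie_batch(x: np.ndarray, y: np.ndarray, N1: int, N2: int) -> np.ndarray:
    """Vectorized :func:`audic_claverie` over count arrays."""
    x = np.asarray(x)
    y = np.asarray(y)
    p = N1 / (N1 + N2)
    lower = stats.nbinom.cdf(y, x + 1, p)
    upper = stats.nbinom.sf(y - 1, x + 1, p)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def fisher_2x2(x: int, y: int, N1: int, N2: int) -> float:
    """Two-sided Fisher exact test on [[x, N1−x], [y, N2−y]]."""
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if x > N1 or y > N2:
        raise ValueError("count exceeds its library total")
    _, p = stats.fisher_exact([[x, N1 - x], [y, N2 - y]], alternative="two-sided")
    return float(min(1.0, p))


def chisq_2x2(x: int, y: int, N1: int, N2: int) -> Tuple[float, bool]:
    """Pearson chi-square (df=1, no continuity correction) on the 2×2 table.

    Returns (p, degenerate); an expected cell of zero makes the
    statistic undefined, reported as p = 1.0 with the degenerate flag.
    """
    obs = np.array([[x, N1 - x], [y, N2 - y]], dtype=float)
    total = obs.sum()
    if total == 0:
        return 1.0, True
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if np.any(expected == 0):
        return 1.0, True
    stat = float(((obs - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(stat, df=1)), False


@dataclass
class DiffExprRecord:
    """Per-miRNA differential-expression summary between CL and DT."""

    mirna_id: str
    x: int           # CL count
    y: int           # DT count
    N1: int          # CL library total
    N2: int          # DT library total
    tpm_cl: float = 0.0
    tpm_dt: float = 0.0
    log2fc: float = 0.0
    p_ac: float = 1.0
    p_fisher: float = 1.0
    p_chisq: float = 1.0
    p_ac_bh: float = 1.0     # Benjamini–Hochberg adjusted AC p, informational
    de_call: str = "ns"      # up | down | ns | filtered


def _log2fc(x: int, y: int, N1: int, N2: int, pseudo: float = 0.5) -> float:
    """log2(TPM_DT / TPM_CL) with a 0.5-read pseudo-TPM for zero counts."""
    t_cl = tpm(x, N1) if x > 0 else pseudo / N1 * 1e6
    t_dt = tpm(y, N2) if y > 0 else pseudo / N2 * 1e6
    return math.log2(t_dt / t_cl)


def call_de(
    records: Iterable[Tuple[str, int, int]],
    N1: int,
    N2: int,
    min_count: int = 10,
    lfc_min: float = 1.0,
    alpha: float = 0.01,
    strict_filter: bool = False,
) -> List[DiffExprRecord]:
    """Run the three tests and call differential expression.

    ``records`` yields (mirna_id, CL count, DT count).  A record is
    "filtered" when its count is below ``min_count`` in both libraries
    (in either library when ``strict_filter``); otherwise it is called
    up / down when |log2FC| ≥ ``lfc_min`` and the Audic–Claverie p
    ≤ ``alpha``; Fisher and chi-square p-values are reported alongside.
    """
    out: List[DiffExprRecord] = []
    for mirna_id, x, y in records:
        rec = DiffExprRecord(mirna_id, int(x), int(y), N1, N2)
        rec.tpm_cl = tpm(rec.x, N1)
        rec.tpm_dt = tpm(rec.y, N2)
        keep = (rec.x >= min_count and rec.y >= min_count) if strict_filter \
            else (rec.x >= min_count or rec.y >= min_count)
        if not keep:
            rec.de_call = "filtered"
            out.append(rec)
            continue
        rec.log2fc = _log2fc(rec.x, rec.y, N1, N2)
        rec.p_ac = audic_claverie(rec.x, rec.y, N1, N2)
        rec.p_fisher = fisher_2x2(rec.x, rec.y, N1, N2)
        rec.p_chisq, _ = chisq_2x2(rec.x, rec.y, N1, N2)
        if rec.log2fc >= lfc_min and rec.p_ac <= alpha:
            rec.de_call = "up"
        elif rec.log2fc <= -lfc_min and rec.p_ac <= alpha:
            rec.de_call = "down"
        else:
            rec.de_call = "ns"
        out.append(rec)
    # BH adjustment over tested records, reported for information only
    tested = [r for r in out if r.de_call != "filtered"]
    if tested:
        ps = np.array([r.p_ac for r in tested])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            idx = order[rank]
            running = min(running, ps[idx] * m / (rank + 1))
            adj[idx] = running
        for r, a in zip(tested, adj):
            r.p_ac_bh = float(a)
    return out


def de_table(records: List[DiffExprRecord]):
    """Render DE records as a DataFrame with the report's column styles."""
    import pandas as pd

    rows = [{
        "mirna_id": r.mirna_id,
        "count_cl": r.x,
        "count_dt": r.y,
        "tpm_cl": round(r.tpm_cl, 1),
        "tpm_dt": round(r.tpm_dt, 1),
        "log2fc": round(r.log2fc, 2),
        "p_ac": f"{r.p_ac:.3e}",
        "p_fisher": f"{r.p_fisher:.3e}",
        "p_chisq": f"{r.p_chisq:.3e}",
        "p_ac_bh": f"{r.p_ac_bh:.3e}",
        "de_call": r.de_call,
    } for r in records]
    return pd.DataFrame(rows)
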