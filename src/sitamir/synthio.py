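"""Seeded synthetic-data generator with known planted truth.

Emulates the statistical structure of a two-condition (control CL vs
drought DT) small-RNA sequencing experiment plus a degradome library:

* a multi-scaffold genome carrying planted miRNA hairpin loci (perfectly
  complementary stems with a 2-nt 3'-overhang miRNA:miRNA* duplex),
  dinucleotide-shuffled decoy hairpins, ncRNA decoys
  (rRNA/tRNA/snRNA/snoRNA), a high-copy repeat family, siRNA duplex
  loci, and gene models placing some precursors in CDS or introns;
* two read libraries with negative-binomial counts around planted
  means, a planted log2 fold-change on a chosen DE subset, a 24-nt
  length mode, and a fixed 3' adapter on every raw read;
* degradome tag piles peaking at planted cleavage sites on synthetic
  transcripts.

Everything is driven by one numpy Generator seeded from the config, so
identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import rnastruct
from .preprocess import GeneModel, revcomp_dna

_BASES = np.array(list("ACGT"))

#: Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class SyntheticConfig:
    """Study-condition knobs for the generator (defaults = test fixture)."""

    seed: int = 42
    n_scaffolds: int = 4
    scaffold_len: int = 60_000
    n_mirna_loci: int = 20
    precursor_len_range: Tuple[int, int] = (61, 222)
    n_sirna_loci: int = 5
    n_ncrna_decoys: int = 4          # per class
    n_genes: int = 20
    read_depth: int = 2_000_000      # total reads per library
    dispersion: float = 0.01         # NB overdispersion (var = μ + αμ²)
    de_fraction: float = 0.25
    planted_log2fc: float = 2.0
    degradome_depth: int = 20_000
    cleavage_peak_fraction: float = 0.9
    n_targets: int = 10
    n_transcripts: int = 20
    transcript_len: int = 500
    expression_scale: float = 1.0    # extra multiplier on planted miRNA means
    known_fraction: float = 0.5      # planted miRNAs present in the reference set
    mature_len: int = 21
    adapter: str = DEFAULT_ADAPTER
    repeat_copies: int = 30

    def validate(self) -> None:
        lo, hi = self.precursor_len_range
        if not (50 <= lo <= hi <= 300):
            raise ValueError("precursor_len_range must lie within [50, 300]")
        for name in ("n_scaffolds", "scaffold_len", "n_mirna_loci", "n_transcripts",
                     "transcript_len", "mature_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        n_de = self.de_fraction * self.n_mirna_loci
        if abs(n_de - round(n_de)) > 1e-9:
            raise ValueError("de_fraction × n_mirna_loci must be an integer")
        if not (0.0 < self.cleavage_peak_fraction <= 1.0):
            raise ValueError("cleavage_peak_fraction must lie in (0, 1]")
        if len(self.adapter) < 5:
            raise ValueError("adapter must be at least 5 nt")

    @property
    def n_de(self) -> int:
        return round(self.de_fraction * self.n_mirna_loci)


@dataclass
class PlantedMirna:
    mirna_id: str
    mature: str          # DNA, genome strand
    star: str
    arm: str             # 5p | 3p
    scaffold: str
    mature_start: int    # 0-based half-open, + strand
    mature_end: int
    precursor_start: int
    precursor_end: int
    known: bool
    context: str         # intergenic | CDS | intron
    cl_mean: float
    dt_mean: float
    log2fc: float


@dataclass
class PlantedTarget:
    mirna_id: str
    transcript_id: str
    site_start: int          # 1-based window start on transcript
    cleavage_position: int   # 1-based


@dataclass
class PlantedTruth:
    mirnas: List[PlantedMirna] = field(default_factory=list)
    sirna_loci: List[Tuple[str, int, int]] = field(default_factory=list)
    decoy_loci: List[Tuple[str, int, int, str]] = field(default_factory=list)  # + precursor seq
    targets: List[PlantedTarget] = field(default_factory=list)
    transcripts: Dict[str, str] = field(default_factory=dict)


@dataclass
class Annotations:
    genes: List[GeneModel]
    repeats: Dict[str, List[Tuple[int, int]]]
    ncrna_ref: Dict[str, List[str]]          # class → reference sequences
    known_mirna_ref: Dict[str, str]          # reference id → mature (DNA)
    background_windows: List[Tuple[str, int, int]] = field(default_factory=list)


class SizingError(ValueError):
    """Requested features do not fit on the configured scaffolds."""


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _dinucleotide_shuffle(rng: np.random.Generator, seq: str) -> str:
    """Composition-preserving shuffle destroying long-range pairing.

    Shuffles non-overlapping dinucleotide blocks; preserves approximate
    dinucleotide composition while breaking the planted stem.
    """
    blocks = [seq[i:i + 2] for i in range(0, len(seq) - 1, 2)]
    tail = seq[len(blocks) * 2:]
    order = rng.permutation(len(blocks))
    return "".join(blocks[i] for i in order) + tail


def _mutate_away(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


#: decoy expressed-read offset within the shuffled locus (see
#: gen_srna_libraries); the negativity check excises a hairpin around it
DECOY_READ_OFFSET = 5


def _decoy_is_negative(seq_dna: str, read_len: int = 21) -> bool:
    """True when a shuffled decoy fails the miRNA identification chain.

    Mirrors the discovery evaluation on the decoy locus itself: fold,
    excise the single-hairpin region around the expressed read, refold,
    and test stem-loop size, stability and the predicted-star duplex.
    """
    from . import discovery  # deferred: avoid import-order coupling

    rna = rnastruct.to_rna(seq_dna)
    lo = DECOY_READ_OFFSET
    hi = lo + read_len - 1
    st = rnastruct.fold_mfe(rna)
    region = rnastruct.hairpin_region(st, lo, hi)
    if region is None:
        return True
    sub = rna[region[0]: region[1] + 1]
    if len(sub) < 40:
        return True
    st2 = rnastruct.fold_mfe(sub)
    if not (rnastruct.is_stemloop(st2, min_stem=15) and st2.mfe <= -18.0):
        return True
    mature = rna[lo: hi + 1]
    sm = sub.find(mature)
    loop_lo, loop_hi = st2.arms["loop"]
    if sm < 0 or not (sm + len(mature) - 1 <= loop_lo + 3 or sm >= loop_hi - 3):
        return True  # read crosses the terminal loop: rejected downstream
    sp = discovery.predicted_star(st2, sub, mature)
    if sp is None:
        return True
    rep = rnastruct.duplex_stats(mature, sp, st2)
    return rep.mismatches > 4 or rep.max_bulge > 2


@dataclass
class _Hairpin:
    precursor: str
    mature: str
    star: str
    arm: str
    mature_off: int   # offset of mature within precursor
    star_off: int


def build_hairpin(rng: np.random.Generator, total_len: int, mature_len: int = 21,
                  arm: str = "5p") -> _Hairpin:
    """Construct a precursor whose MFE structure is a single long stem.

    The 3' arm is the exact reverse complement of the 5' arm except at
    the two bases opposite the duplex 3' overhang, which are mutated so
    that the full-length reverse complement of the mature does not occur
    in the genome.  The mature sits on the requested arm; its star is
    the opposite-arm read with canonical 2-nt 3' overhangs.
    """
    loop_len = 8
    arm_len = (total_len - loop_len) // 2
    if arm_len < mature_len + 3:
        raise SizingError(f"precursor length {total_len} too short for a {mature_len}-nt mature")
    u_len = int(rng.integers(2, arm_len - mature_len))
    v_len = arm_len - mature_len - u_len
    guide = _random_dna(rng, mature_len)
    # the loop-proximal stem end is clamped to C:G pairs and the loop to
    # poly-A, so no fold can trade loop-adjacent stem pairs for
    # cross-pairs into the loop: the planted stem is the unique optimum.
    # With the mature arm 5', the loop-adjacent end is v's tail; with it
    # 3', it is u's head (the precursor is other + loop + arm_m).
    u = _random_dna(rng, u_len)
    v = _random_dna(rng, v_len)
    if arm == "5p":
        v = v[: max(0, v_len - 4)] + "C" * min(4, v_len)
    else:
        u = "G" * min(4, u_len) + u[min(4, u_len):]
    arm_m = u + guide + v
    other = list(revcomp_dna(arm_m))
    p = v_len  # start of revcomp(guide) within the opposite arm
    for k in (p, p + 1):  # opposite the guide's 3' overhang; duplex untouched
        other[k] = _mutate_away(rng, other[k])
    # one mismatch inside the duplex (real miRNA:miRNA* duplexes are
    # imperfect; it also stops the star read cross-mapping to the
    # opposite strand of the mature arm)
    k = p + 2 + int(rng.integers(4, mature_len - 4))
    other[k] = _mutate_away(rng, other[k])
    other = "".join(other)
    star = other[p + 2: p + 2 + mature_len]
    loop = "A" * loop_len
    if arm == "5p":
        precursor = arm_m + loop + other
        mature_off = u_len
        star_off = len(arm_m) + loop_len + p + 2
    else:
        precursor = other + loop + arm_m
        mature_off = len(other) + loop_len + u_len
        star_off = p + 2
    return _Hairpin(precursor, guide, star, arm, mature_off, star_off)


class _Placer:
    """Non-overlapping feature placement on one scaffold."""

    def __init__(self, rng: np.random.Generator, length: int, margin: int = 250):
        self.rng = rng
        self.length = length
        self.margin = margin
        self.taken: List[Tuple[int, int]] = []

    def place(self, size: int, max_tries: int = 500) -> int:
        if size + 2 * self.margin >= self.length:
            raise SizingError(f"feature of {size} nt cannot fit on a {self.length}-nt scaffold")
        for _ in range(max_tries):
            start = int(self.rng.integers(self.margin, self.length - size - self.margin))
            if all(start + size + self.margin <= s or e + self.margin <= start
                   for s, e in self.taken):
                self.taken.append((start, start + size))
                return start
        raise SizingError("scaffold too crowded to host the requested loci")


def gen_genome(config: SyntheticConfig):
    """Generate the genome, planted truth and annotation sets.

    Returns (genome: dict scaffold → DNA, truth: PlantedTruth,
    annotations: Annotations).  Identical configs give identical output.
    """
    config.validate()
    for salt in range(5):
        out = _gen_genome_once(config, salt)
        if out is not None:
            return out
    raise RuntimeError("could not generate a collision-free genome")  # pragma: no cover


def _gen_genome_once(config: SyntheticConfig, salt: int):
    rng = np.random.default_rng((config.seed, salt))
    names = [f"scaffold_{i + 1}" for i in range(config.n_scaffolds)]
    scaffolds = {n: list(_random_dna(rng, config.scaffold_len)) for n in names}
    placers = {n: _Placer(rng, config.scaffold_len) for n in names}
    truth = PlantedTruth()
    repeats: Dict[str, List[Tuple[int, int]]] = {n: [] for n in names}
    ncrna_ref: Dict[str, List[str]] = {}
    genes: List[GeneModel] = []

    def insert(name: str, seq: str) -> int:
        start = placers[name].place(len(seq))
        scaffolds[name][start:start + len(seq)] = list(seq)
        return start

    lo, hi = config.precursor_len_range
    n_de = config.n_de
    contexts = (["CDS"] * max(1, round(0.1 * config.n_mirna_loci))
                + ["intron"] * max(1, round(0.1 * config.n_mirna_loci)))
    contexts += ["intergenic"] * (config.n_mirna_loci - len(contexts))
    known_ids = set(range(int(round(config.known_fraction * config.n_mirna_loci))))

    # --- miRNA hairpin loci -------------------------------------------------
    # expression means scale with sequencing depth (tag counts are
    # depth-proportional); the log-uniform range matches moderately to
    # highly expressed plant miRNAs at the default two-million-read depth
    depth_scale = config.read_depth / 2_000_000 * config.expression_scale
    base_means = np.exp(rng.uniform(np.log(80), np.log(800), config.n_mirna_loci)) * depth_scale
    for i in range(config.n_mirna_loci):
        total_len = int(rng.integers(lo, hi + 1))
        arm = "5p" if rng.random() < 0.5 else "3p"
        # the generator's contract: every planted precursor satisfies the
        # stem-loop and stability criteria under the package's own energy
        # model; rare constructions where the mutated overhang-opposite
        # bases seed a side-hairpin are redrawn
        for _ in range(20):
            hp = build_hairpin(rng, total_len, config.mature_len, arm)
            st = rnastruct.fold_mfe(rnastruct.to_rna(hp.precursor))
            if rnastruct.is_stemloop(st, min_stem=15) and st.mfe <= -18.0:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not construct a conforming hairpin")
        name = names[i % len(names)]
        start = insert(name, hp.precursor)
        lfc = 0.0
        if i < n_de:
            lfc = config.planted_log2fc * (1 if i % 2 == 0 else -1)
        known = i in known_ids
        prefix = "sit-miR" if known else "sit-novel-miR"
        truth.mirnas.append(PlantedMirna(
            mirna_id=f"{prefix}{i + 1:03d}",
            mature=hp.mature, star=hp.star, arm=hp.arm, scaffold=name,
            mature_start=start + hp.mature_off,
            mature_end=start + hp.mature_off + len(hp.mature),
            precursor_start=start, precursor_end=start + len(hp.precursor),
            known=known, context=contexts[i],
            cl_mean=float(base_means[i]),
            dt_mean=float(base_means[i] * 2.0 ** lfc),
            log2fc=lfc,
        ))

    # --- decoys: dinucleotide-shuffled precursors ---------------------------
    for i, mir in enumerate(list(truth.mirnas)):
        name = names[(i + 1) % len(names)]
        prec = "".join(scaffolds[mir.scaffold][mir.precursor_start:mir.precursor_end])
        # decoys are the discovery negative set: reshuffle until the
        # shuffled locus genuinely fails the hairpin criteria, also when
        # a candidate hairpin is excised around its expressed read
        for _ in range(50):
            shuf = _dinucleotide_shuffle(rng, prec)
            if _decoy_is_negative(shuf):
                break
        else:  # pragma: no cover
            raise RuntimeError("could not construct a failing decoy")
        start = insert(name, shuf)
        truth.decoy_loci.append((name, start, start + len(shuf), shuf))

    # --- ncRNA decoys -------------------------------------------------------
    for cls in ("rRNA", "tRNA", "snRNA", "snoRNA"):
        ncrna_ref[cls] = []
        for _ in range(config.n_ncrna_decoys):
            seq = _random_dna(rng, int(rng.integers(90, 160)))
            name = names[int(rng.integers(0, len(names)))]
            insert(name, seq)
            ncrna_ref[cls].append(seq)

    # --- repeat family: one unit, many copies -------------------------------
    unit = _random_dna(rng, 100)
    for _ in range(config.repeat_copies):
        name = names[int(rng.integers(0, len(names)))]
        start = insert(name, unit)
        repeats[name].append((start, start + len(unit)))

    # --- siRNA duplex loci --------------------------------------------------
    for _ in range(config.n_sirna_loci):
        name = names[int(rng.integers(0, len(names)))]
        start = placers[name].place(25)
        truth.sirna_loci.append((name, start, start + 25))

    # --- gene models --------------------------------------------------------
    gid = 0
    for mir in truth.mirnas:
        s, e = mir.precursor_start, mir.precursor_end
        if mir.context == "CDS":
            gid += 1
            genes.append(GeneModel(f"gene_{gid:03d}", mir.scaffold, "+",
                                   exons=[(s - 50, e + 50)], cds=[(s - 50, e + 50)]))
        elif mir.context == "intron":
            gid += 1
            genes.append(GeneModel(f"gene_{gid:03d}", mir.scaffold, "+",
                                   exons=[(s - 80, s - 20), (e + 20, e + 80)],
                                   cds=[(s - 80, s - 20)]))
    for _ in range(config.n_genes):
        gid += 1
        name = names[int(rng.integers(0, len(names)))]
        start = placers[name].place(600)
        genes.append(GeneModel(
            f"gene_{gid:03d}", name, "+" if rng.random() < 0.5 else "-",
            exons=[(start, start + 220), (start + 380, start + 600)],
            cds=[(start, start + 220)],
        ))

    # --- discrete background sRNA-producing windows -------------------------
    # real intergenic sRNA background is patchy, not uniform: reads come
    # from scattered producing loci, which also keeps locus clustering at
    # a 200-nt gap from fusing the whole scaffold
    background_windows: List[Tuple[str, int, int]] = []
    for _ in range(10 * config.n_scaffolds):
        name = names[int(rng.integers(0, len(names)))]
        try:
            start = placers[name].place(250)
        except SizingError:
            continue
        background_windows.append((name, start, start + 250))

    genome = {n: "".join(chars) for n, chars in scaffolds.items()}

    # uniqueness check: every planted mature occurs exactly once genome-wide
    blob = "#".join(genome.values())
    blob_rc = "#".join(revcomp_dna(g) for g in genome.values())
    for mir in truth.mirnas:
        occ = blob.count(mir.mature) + blob_rc.count(mir.mature)
        if occ != 1:
            return None  # rebuild with a new salt

    # --- transcripts + planted cleavage targets -----------------------------
    for t in range(config.n_transcripts):
        truth.transcripts[f"Si{t + 1:06d}m"] = _random_dna(rng, config.transcript_len)
    tids = sorted(truth.transcripts)
    for k in range(config.n_targets):
        mir = truth.mirnas[k % len(truth.mirnas)]
        tid = tids[k % len(tids)]
        site = revcomp_dna(mir.mature)
        L = len(site)
        pos0 = int(rng.integers(30, config.transcript_len - L - 30))
        seq = truth.transcripts[tid]
        truth.transcripts[tid] = seq[:pos0] + site + seq[pos0 + L:]
        site_start = pos0 + 1
        cleavage = site_start + L - 10
        if not (1 <= cleavage <= config.transcript_len):
            raise ValueError("cleavage position outside transcript")  # pragma: no cover
        truth.targets.append(PlantedTarget(mir.mirna_id, tid, site_start, cleavage))

    known_ref = {f"{m.mirna_id}-ref": m.mature for m in truth.mirnas if m.known}
    ann = Annotations(genes=genes, repeats=repeats, ncrna_ref=ncrna_ref,
                      known_mirna_ref=known_ref,
                      background_windows=background_windows)
    return genome, truth, ann


# ---------------------------------------------------------------------------
# read libraries


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial with mean/dispersion parameterization.

    var = μ + α·μ²; the α → 0 limit degenerates to the rounded mean.
    """
    if mean <= 0:
        return 0
    if dispersion <= 1e-12:
        return int(round(mean))
    n = 1.0 / dispersion
    p = n / (n + mean)
    return int(rng.negative_binomial(n, p))


def _nb_draws(rng: np.random.Generator, mean: float, dispersion: float,
              size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 1e-12:
        return np.full(size, int(round(mean)), dtype=np.int64)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size).astype(np.int64)


#: read-length law on [16, 30]: canonical plant 24-nt mode plus a
#: secondary 21-nt miRNA-length shoulder
_LEN_SUPPORT = np.arange(16, 31)
_LEN_WEIGHTS = np.exp(-0.5 * ((_LEN_SUPPORT - 24) / 2.2) ** 2)
_LEN_WEIGHTS[_LEN_SUPPORT == 21] *= 1.8
_LEN_WEIGHTS /= _LEN_WEIGHTS.sum()


def _weighted_lens(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(_LEN_SUPPORT, size=n, p=_LEN_WEIGHTS)


def gen_srna_libraries(truth: PlantedTruth, config: SyntheticConfig,
                       genome: Optional[Dict[str, str]] = None,
                       annotations: Optional[Annotations] = None):
    """Simulate the CL and DT raw-read libraries.

    Returns two lists of (raw_read, count): planted miRNA/star reads
    with NB counts around their true means (DT means carry the planted
    fold-change), siRNA duplex reads, ncRNA/repeat/exon fragments, and
    random background, every read suffixed with the 3' adapter.
    """
    config.validate()
    if config.read_depth <= 0:
        raise ValueError("read_depth must be positive")
    rng = np.random.default_rng((config.seed, 101))
    adapter = config.adapter

    def raw(insert: str) -> str:
        return insert + adapter

    libs = {"CL": {}, "DT": {}}

    def add(label: str, insert: str, count: int) -> None:
        if count > 0:
            r = raw(insert)
            libs[label][r] = libs[label].get(r, 0) + count

    planted_total = {"CL": 0, "DT": 0}
    for mir in truth.mirnas:
        for label, mean in (("CL", mir.cl_mean), ("DT", mir.dt_mean)):
            c = _nb_draw(rng, mean, config.dispersion)
            add(label, mir.mature, c)
            add(label, mir.star, _nb_draw(rng, 0.08 * mean, config.dispersion))
            planted_total[label] += c

    # decoy loci are expressed too, so discovery specificity is exercised
    for name, s, e, seq in truth.decoy_loci:
        frag = seq[DECOY_READ_OFFSET: DECOY_READ_OFFSET + 21]
        for label in ("CL", "DT"):
            add(label, frag, _nb_draw(rng, 40, config.dispersion))

    # siRNA duplex loci: complementary 21-mers with 2-nt 3' overhangs
    if genome is not None:
        for name, s, e in truth.sirna_loci:
            plus = genome[name][s + 2: s + 23]
            minus = revcomp_dna(genome[name][s: s + 21])
            for label in ("CL", "DT"):
                add(label, plus, _nb_draw(rng, 60, config.dispersion))
                add(label, minus, _nb_draw(rng, 55, config.dispersion))

    # background composition (fractions of the remaining depth)
    remaining = {lab: max(0, config.read_depth - sum(libs[lab].values()))
                 for lab in ("CL", "DT")}

    def fragments(source_seqs: List[str], share: float, mean_count: float,
                  antisense: bool = False) -> None:
        source_seqs = [s for s in source_seqs if len(s) > 30]
        if not source_seqs:
            return
        budget = {lab: share * remaining[lab] for lab in ("CL", "DT")}
        produced = {"CL": 0, "DT": 0}
        src_lens = np.array([len(s) for s in source_seqs])
        while any(produced[lab] < budget[lab] for lab in ("CL", "DT")):
            n = 2000
            idx = rng.integers(0, len(source_seqs), n)
            Ls = _weighted_lens(rng, n)
            starts = (rng.random(n) * (src_lens[idx] - Ls)).astype(np.int64)
            flip = rng.random(n) < 0.5 if antisense else np.zeros(n, bool)
            counts = {lab: _nb_draws(rng, mean_count, config.dispersion, n)
                      for lab in ("CL", "DT")}
            for k in range(n):
                frag = source_seqs[int(idx[k])][int(starts[k]): int(starts[k] + Ls[k])]
                if flip[k]:
                    frag = revcomp_dna(frag)
                done = True
                for lab in ("CL", "DT"):
                    if produced[lab] < budget[lab]:
                        add(lab, frag, int(counts[lab][k]))
                        produced[lab] += int(counts[lab][k])
                        done = False
                if done:
                    break

    ann = annotations
    if ann is not None:
        all_ncrna = [s for seqs in ann.ncrna_ref.values() for s in seqs]
        fragments(all_ncrna, 0.22, 40)
        if genome is not None:
            rep_seqs = [genome[n][s:e] for n, ivs in ann.repeats.items() for s, e in ivs]
            fragments(rep_seqs, 0.02, 25)
            exon_seqs = [genome[g.scaffold][s:e] for g in ann.genes for s, e in g.exons]
            fragments(exon_seqs, 0.01, 12, antisense=True)
    if genome is not None and ann is not None and ann.background_windows:
        bg_seqs = [genome[n][s:e] for n, s, e in ann.background_windows]
        fragments(bg_seqs, 0.25, 4)

    # unmappable random singletons fill the rest (high unique diversity)
    for lab in ("CL", "DT"):
        gap = config.read_depth - sum(libs[lab].values())
        while gap > 0:
            n = max(1, min(50_000, gap // 2))
            Ls = _weighted_lens(rng, n)
            counts = 1 + rng.integers(0, 3, n)
            mat = rng.integers(0, 4, (n, 30))
            for k in range(n):
                if gap <= 0:
                    break
                c = min(gap, int(counts[k]))
                seq = "".join(_BASES[mat[k, : Ls[k]]])
                add(lab, seq, c)
                gap -= c

    cl = sorted(libs["CL"].items())
    dt = sorted(libs["DT"].items())
    return cl, dt


def gen_degradome(truth: PlantedTruth, config: SyntheticConfig,
                  tag_len: int = 20) -> List[Tuple[str, int]]:
    """Simulate degradome tags over the synthetic transcripts.

    For every transcript, a share of ``cleavage_peak_fraction`` of its
    tags starts exactly at each planted cleavage position; the rest are
    uniform over valid 5' positions.  Tags are 5'-anchored exact
    substrings of the transcript.
    """
    config.validate()
    if config.degradome_depth <= 0:
        raise ValueError("degradome_depth must be positive")
    rng = np.random.default_rng((config.seed, 202))
    targets_by_tid: Dict[str, List[PlantedTarget]] = {}
    for t in truth.targets:
        if t.transcript_id not in truth.transcripts:
            raise ValueError(f"no transcript {t.transcript_id} for planted target")
        seq = truth.transcripts[t.transcript_id]
        if not (1 <= t.cleavage_position <= len(seq) - tag_len + 1):
            raise ValueError("cleavage position outside transcript")
        targets_by_tid.setdefault(t.transcript_id, []).append(t)

    per_transcript = max(1, config.degradome_depth // max(1, len(truth.transcripts)))
    tags: Dict[str, int] = {}

    def add(tag: str, count: int) -> None:
        if count > 0 and tag:
            tags[tag] = tags.get(tag, 0) + count

    for tid in sorted(truth.transcripts):
        seq = truth.transcripts[tid]
        n_pos = len(seq) - tag_len + 1
        planted = targets_by_tid.get(tid, [])
        peak = int(round(config.cleavage_peak_fraction * per_transcript))
        if planted:
            for t in planted:
                add(seq[t.cleavage_position - 1: t.cleavage_position - 1 + tag_len],
                    peak // len(planted))
            n_bg = per_transcript - peak
        else:
            n_bg = per_transcript
        if n_bg > 0:
            positions = rng.integers(0, n_pos, n_bg)
            for p, c in zip(*np.unique(positions, return_counts=True)):
                add(seq[int(p): int(p) + tag_len], int(c))
    return sorted(tags.items())


# ---------------------------------------------------------------------------
# writers / truth round-trip


def write_fasta(seqs: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), 70):
                fh.write(s[i:i + 70] + "\n")


def write_reads_fastq(reads: List[Tuple[str, int]], path, max_expand: int = 10 ** 7) -> None:
    """Expand (read, count) pairs to FASTQ with constant phred-40 quality."""
    total = sum(c for _, c in reads)
    if total > max_expand:
        raise ValueError(f"refusing to expand {total} reads; write collapsed FASTA instead")
    with open(path, "w") as fh:
        i = 0
        for seq, count in reads:
            for _ in range(count):
                i += 1
                fh.write(f"@read_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_reads_collapsed(reads: List[Tuple[str, int]], path) -> None:
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(reads):
            fh.write(f">seq_{i + 1} x{count}\n{seq}\n")


def write_gff3(genes: List[GeneModel], path) -> None:
    """Gene models as GFF3 (1-based inclusive coordinates on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(f"{g.scaffold}\t.\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            for i, (es, ee) in enumerate(sorted(g.exons)):
                fh.write(f"{g.scaffold}\t.\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}.exon{i + 1};Parent={g.gene_id}\n")
            for i, (cs, ce) in enumerate(sorted(g.cds)):
                fh.write(f"{g.scaffold}\t.\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}.cds{i + 1};Parent={g.gene_id}\n")


def read_gff3(path) -> List[GeneModel]:
    by_gene: Dict[str, GeneModel] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            sc, _, kind, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if kind == "gene":
                by_gene[fields["ID"]] = GeneModel(fields["ID"], sc, strand, exons=[], cds=[])
            elif kind in ("exon", "CDS"):
                g = by_gene[fields["Parent"]]
                iv = (int(start) - 1, int(end))
                (g.exons if kind == "exon" else g.cds).append(iv)
    return list(by_gene.values())


def write_bed(intervals: Dict[str, List[Tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(intervals):
            for s, e in sorted(intervals[name]):
                fh.write(f"{name}\t{s}\t{e}\n")


def read_bed(path) -> Dict[str, List[Tuple[int, int]]]:
    out: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, s, e = line.split()[:3]
            out.setdefault(name, []).append((int(s), int(e)))
    return out


_MIRNA_COLS = [f.name for f in dataclasses.fields(PlantedMirna)]
_TARGET_COLS = [f.name for f in dataclasses.fields(PlantedTarget)]


def write_truth(truth: PlantedTruth, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "truth_mirnas.tsv", "w") as fh:
        fh.write("\t".join(_MIRNA_COLS) + "\n")
        for m in truth.mirnas:
            fh.write("\t".join(str(getattr(m, c)) for c in _MIRNA_COLS) + "\n")
    with open(outdir / "truth_targets.tsv", "w") as fh:
        fh.write("\t".join(_TARGET_COLS) + "\n")
        for t in truth.targets:
            fh.write("\t".join(str(getattr(t, c)) for c in _TARGET_COLS) + "\n")
    with open(outdir / "truth_sirna_loci.tsv", "w") as fh:
        fh.write("scaffold\tstart\tend\n")
        for name, s, e in truth.sirna_loci:
            fh.write(f"{name}\t{s}\t{e}\n")
    with open(outdir / "truth_decoys.tsv", "w") as fh:
        fh.write("scaffold\tstart\tend\tsequence\n")
        for name, s, e, seq in truth.decoy_loci:
            fh.write(f"{name}\t{s}\t{e}\t{seq}\n")
    write_fasta(truth.transcripts, outdir / "transcripts.fa")


def load_truth(outdir) -> PlantedTruth:
    from Bio import SeqIO

    outdir = Path(outdir)
    truth = PlantedTruth()
    conv = {"mature_start": int, "mature_end": int, "precursor_start": int,
            "precursor_end": int, "known": lambda v: v == "True",
            "cl_mean": float, "dt_mean": float, "log2fc": float,
            "site_start": int, "cleavage_position": int}
    with open(outdir / "truth_mirnas.tsv") as fh:
        header = fh.readline().split()
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            kw = {c: conv.get(c, str)(v) for c, v in zip(header, vals)}
            truth.mirnas.append(PlantedMirna(**kw))
    with open(outdir / "truth_targets.tsv") as fh:
        header = fh.readline().split()
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            kw = {c: conv.get(c, str)(v) for c, v in zip(header, vals)}
            truth.targets.append(PlantedTarget(**kw))
    with open(outdir / "truth_sirna_loci.tsv") as fh:
        fh.readline()
        for line in fh:
            name, s, e = line.split()
            truth.sirna_loci.append((name, int(s), int(e)))
    with open(outdir / "truth_decoys.tsv") as fh:
        fh.readline()
        for line in fh:
            name, s, e, seq = line.split()
            truth.decoy_loci.append((name, int(s), int(e), seq))
    for rec in SeqIO.parse(str(outdir / "transcripts.fa"), "fasta"):
        truth.transcripts[rec.id] = str(rec.seq)
    return truth
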