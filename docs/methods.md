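# Methods

This note records the models behind each stage, the defaults and why,
what the synthetic generator does and does not emulate, and the
numerical and design choices made where the field leaves them open.

## RNA secondary structure

Folding is a weighted Nussinov dynamic program: the energy of a nested
structure is the sum of per-pair terms — G:C −3.0, A:U −2.0, G:U −1.0
kcal/mol — with a minimum hairpin loop of 3 nt and no loop or stacking
terms.  The recurrence decomposes every interval as "leftmost base
unpaired, or paired with k", which gives each structure a unique
decomposition and a canonical traceback; ties on energy are broken
toward fewer pairs, then by a fixed traceback order (pair the leftmost
base to its nearest admissible partner).  The DP table is filled by a
numba kernel in integer arithmetic, so energy comparisons are exact;
sequences up to 400 nt fold in tens of milliseconds.

This is deliberately *not* a nearest-neighbour (Turner) model.  Its
minima are meaningful only within the model, and the −18 kcal/mol
precursor-stability criterion is interpreted under it; published MFE
values from thermodynamic folders (spanning roughly −18 to −112
kcal/mol for plant pre-miRNAs) are not numerically reproducible here
and are not asserted anywhere.  `fold_mfe(engine=...)` accepts an
external folding callable returning (dot-bracket, MFE) for parity work
with such folders.

A stem-loop is a structure with exactly one terminal loop (which rules
out multiloops and concatemers) and at least `min_stem` = 15 base
pairs — a typical lower bound for plant pre-miRNA stems; the value is
a parameter.  Candidate precursors are excised from genomic windows by
`hairpin_region`: fold the window, take the widest pair enclosing the
mature whose interior holds a single terminal loop (allowing the
mature to overhang the stem by ≤ 8 nt, since duplex 3' overhangs
legitimately stick out), and refold the excised subsequence on its
own.  The mature must lie on one arm; candidates whose mature crosses
the terminal loop are rejected in every window.

Duplex geometry (miRNA vs miRNA*) is read from the folded precursor
when both strands sit on opposite arms of one stem; otherwise the two
strands are aligned antiparallel with match +1 (Watson–Crick or G:U),
mismatch 0, internal gap −1 and free terminal gaps, ties toward the
diagonal.  Mismatches are opposed non-complementary columns; a bulge
is a run of unopposed bases on one strand; terminal overhangs are not
bulges.  When no expressed miRNA* is in the library, the duplex
criteria are evaluated against the *structure-predicted* star — the
opposite-arm segment pairing the mature plus a 2-nt 3' extension (the
Dicer-product geometry).  Without this, the duplex criteria would be
vacuous for star-less candidates and any random stem-loop would pass.

## Identification criteria and siRNA exclusion

A candidate passes when all of: single stem-loop with ≥ 15 pairs;
duplex mismatches ≤ 4; largest asymmetric bulge ≤ 2 nt; precursor MFE
≤ −18.0 kcal/mol (inclusive — "maximum free energy allowed" reads as a
bound attained); ≤ 24 perfect genomic loci; and no siRNA duplex
signature at the locus.  The siRNA signature is two abundant reads on
opposite strands forming a duplex in which each strand carries a 2-nt
3' overhang; the check uses the most abundant read per strand over the
locus, both strands gathered regardless of the clustering strand.
Known-miRNA matching requires equal length and ≤ 2 substitutions (no
indels — "mismatches" is read as substitutions), best hit by fewest
mismatches then lexicographic reference id.

Novel discovery clusters unannotated mapped reads per scaffold and
strand at a 200-nt gap with a 5-read minimum locus count (stand-ins
for unpublished tool defaults; both configurable), takes the most
abundant read per locus as the mature (20–24 nt), and evaluates the
criteria over three flanking windows (250/20, 20/250, 125/125 nt),
keeping the passing window with the lowest MFE.  Since a planted
hairpin is discoverable from either strand (the arms are near reverse
complements), passing candidates whose precursor intervals overlap are
collapsed to the more abundant mature.  Novel candidates do not
require an expressed star (plant studies routinely report most novel
miRNAs without one); `require_star=True` enables the stricter mode.
Families: known candidates inherit the `miRNA###` token of their
reference name; novel matures are single-linkage clustered at equal
length and Hamming distance ≤ 2.  Genomic context is decided by the
precursor midpoint: CDS, else intron, else intergenic.

## Differential expression

Expression is TPM: count / library total × 10⁶ (totals are clean-read
counts).  The primary test is Audic–Claverie; the conditional law of
the second count given the first is negative binomial,
NB(y; r = x+1, p = N1/(N1+N2)), and the two-sided p is twice the
smaller tail with the observed count included in both tails, capped at
1.  Fisher's exact test and Pearson's chi-square (df 1, no continuity
correction; degenerate tables report p = 1 with a flag) are computed
on [[x, N1−x], [y, N2−y]] and reported alongside — the AC p drives
calls because it is the canonical test for two-library tag counts.
A record is filtered when its count is < 10 in *both* libraries (the
strict either-library reading would discard strongly induced miRNAs
absent in one library; it is available behind a flag).  Zero counts
enter log2 fold-changes as a 0.5-read pseudo-TPM, keeping them finite
and symmetric.  No multiple-testing correction is applied to calls; a
Benjamini–Hochberg column is emitted for information.

## Degradome analysis

Tags are truncated to their 5'-most 20 nt (PARE signatures are
conventionally 20–21 nt of a 50-nt read; configurable) and mapped
exactly, sense strand, every match counting at the 1-based coordinate
of the tag 5' end.  Binding sites are scored ungapped with the
Allen-type penalty — mismatch 1.0, G:U 0.5, doubled at miRNA positions
2–13 — and kept at ≤ 4.5 (inclusive); this scheme is an
interpretation chosen because it produces the half-point score range
published for such tables.  The expected cleavage coordinate is the
base paired to miRNA position 10; validation accepts tag signal within
±1 nt (whether the original analyses allowed a window is unstated).
Categories follow the cascade: single raw read → 4 (tested first, so a
transcript whose only tag sits at the site is 4, not 0); unique
maximum → 0; tied maximum → 1; above the median of *occupied*
positions → 2; else 3.  One category is reported per hit; categories
of other tag piles inside the validation window are listed in a
secondary column.  Fractional or dual categories seen in published
tables have no stated definition and are not reproduced.  The
in-silico predictor is the same complementarity score at cutoff 3.0
with no degradome evidence — a deliberate simplification of web-based
plant target predictors, flagged as predictions.

## Synthetic data

The generator plants, on 4 × 60-kb scaffolds: 20 miRNA hairpins
(precursor lengths 61–222 nt, matching the published pre-miRNA range),
dinucleotide-shuffled decoy hairpins at separate loci, 4 ncRNA decoys
per class, a 100-nt repeat unit at 30 copies (exceeding the 24-locus
bound), 5 siRNA duplex loci, gene models that put ~10% of precursors
in CDS and ~10% in introns, and 40 discrete background sRNA-producing
windows (real intergenic background is patchy; uniform background
would also fuse locus clustering).  Hairpin construction makes the 3'
arm the reverse complement of the 5' arm except: two substitutions
opposite the mature's 3' overhang (so the full-length mature occurs
exactly once in the genome across both strands) and one substitution
inside the duplex (real duplexes are imperfect; it also stops the star
read cross-mapping to the opposite strand).  The loop-adjacent stem
end is clamped to C:G pairs against a poly-A loop so no fold can trade
stem pairs for cross-pairs into the loop.  Every planted precursor is
verified at build time to satisfy the stem-loop/stability criteria
under the package's own energy model, and every decoy to fail the
identification chain; violating draws are redrawn deterministically.

Counts are negative binomial with (mean, dispersion) parameterization,
var = μ + αμ², independent across miRNAs; α defaults to 0.01 —
technical (same-sample) tag libraries are nearly Poisson, which is
also the regime the Audic–Claverie test assumes.  Planted means are
log-uniform 80–800 at the default 2 × 10⁶-read depth and scale
proportionally with depth; DE miRNAs (25% of loci) alternate sign at
|log2FC| = 2.  Star reads are generated at 8% of mature abundance.
Reads carry the Illumina sRNA 3' adapter so trimming is non-trivial;
background lengths have the canonical plant 24-nt mode.  Degradome
tags place `cleavage_peak_fraction` (default 0.9) of each target
transcript's tags exactly at the planted cleavage position, the rest
uniform.

What this does **not** emulate: sequencing errors beyond the absence
thereof, quality-score structure, isomiR 5'/3' heterogeneity,
RNA-editing, multi-hairpin MIR clusters, cross-mapping between near
paralogs, and thermodynamically realistic (imperfect, bulged) hairpin
precursors.  Passing the recovery tests therefore shows the pipeline's
logic is correct under its own model assumptions, not that its
sensitivity/specificity transfer quantitatively to real libraries.

## Report conventions

Coordinates are 0-based half-open internally, 1-based inclusive in all
written reports.  Table percentages are rounded half-up to 2 decimals;
the shared/specific overlap table follows the published convention of
using the *sum* of library unique counts as denominator (a shared
sequence is in both libraries), with self-consistent specific rows —
the corresponding published table's DT-specific row equals the whole
DT library and is internally inconsistent, so it is documented rather
than reproduced.  TPMs print at 1 decimal, fold-changes at 2,
p-values in scientific notation.  Multi-mapping reads contribute their
full count once, classified by their highest-precedence locus.

## Problem sizes

Tests run the pipeline at 1.2–2 × 10⁵ reads per library (about 15 s
end to end); the acceptance script and the acceptance tests use the
full default conditions, 2 × 10⁶ reads per library with 20 planted
miRNAs and 10 cleavage targets, which completes in a few minutes on
one CPU.  Folding-oracle checks enumerate all nested structures for
sequences ≤ 18 nt; Audic–Claverie is checked against direct summation
on a 9 × 9 count grid at two library depths and calibrated on 10⁴
Poisson null replicates.
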