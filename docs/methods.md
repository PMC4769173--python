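# Methods

## Problem and model

In a species where males are XY and females XX, genome scaffolds derived
from the sex chromosomes leave a quantitative fingerprint in resequencing
depth: an X-derived scaffold is present in one copy in a male and two in a
female, so after library-size normalization its male/female coverage ratio
centres on 1/2 (log2 = −1); a Y-derived scaffold receives male reads only,
except that repeats shared between the Y, the X and the autosomes attract
some female reads ("cross-mapping"), so Y scaffolds are strongly — but not
infinitely — male-biased. `sexscaff` turns these observations into a
classification and validation pipeline:

1. **Coverage.** Per scaffold and sample, fold-coverage is
   `reads_mapped × read_length / scaffold_length`, then divided by the
   unweighted mean over all scaffolds of that sample (mean of the
   normalized profile is 1 by construction). Precomputed coverages can be
   ingested directly in place of counts.
2. **Ratios.** Pairwise per-scaffold `log2((m + p)/(f + p))` of normalized
   coverage, with pseudocount `p` for zero protection. A female/female
   ratio is computed as a negative (specificity) control but never used
   for classification.
3. **Classification.** Scaffolds shorter than 10 kb are left uncalled
   (their ratios are too noisy); X candidates satisfy
   −1.25 ≤ log2(M/F) ≤ −0.75 (closed interval bracketing the one-copy
   expectation); Y candidates show a linear fold of at least 7 (closed
   bound). The X interval is negative and the Y bound positive, so the
   calls are mutually exclusive by construction.
4. **Uniqueness.** Y (or X) candidates are tiled with sliding windows
   (1 kb at 0.5 kb offsets for PCR targets; 10 kb for FISH probe design)
   and each window is asked whether it shares sequence with any *other*
   scaffold; windows whose only hits are to their own scaffold are unique,
   and overlapping unique windows merge into regions from which assay
   targets are selected. Unique sequence is what makes a male-specific PCR
   or an X-paint probe interpretable.
5. **qPCR validation.** Crossing points (C_T) are called by the
   second-derivative-maximum method; per-primer-pair efficiency E comes
   from the slope of a dilution-series calibration (E = 10^(−1/slope));
   assays with either efficiency outside [1.8, 2.1] are excluded; the
   efficiency-corrected relative quantity Q = E_t^(−C_T,t) / E_r^(−C_T,r)
   against an autosomal reference is compared between sexes with a
   pooled-variance Student's t test (Welch optional), reporting group
   means, SEM = sd/√n, and significance at 0.05 / 0.001. An X-linked
   target is expected at twice the relative quantity in females. The plain
   C_T ratio (mean C_T target / mean C_T reference) is also reported for
   comparability with the common plotting convention, but Q is the
   inferential statistic.

## Key parameters

| parameter | default | units | why |
|---|---|---|---|
| `min_length_bp` | 10 000 | bp | below this, Poisson noise on depth makes calls unreliable |
| `x_log2_low..high` | −1.25..−0.75 | log2 | symmetric band around the one-copy expectation −1 |
| `y_fold_min` | 7 | fold | male-bias bound high enough to exclude autosomal noise yet tolerant of female cross-mapping |
| `min_male_normcov` | 0.1 | normalized | guard: a huge fold from near-zero/near-zero coverage is noise, not Y linkage |
| pseudocount `p` | 0.01 | normalized | keeps male-only scaffolds finite and ranks female-zero scaffolds highest; see below |
| `min_shared_exact_match_bp` | 50 | bp | cross-scaffold hit = exact shared run of ≥ 50 bp, either strand |
| window / offset | 1000 / 500 (PCR), 10 000 (probe) | bp | window geometry of the two scan modes |
| efficiency gate | [1.8, 2.1] | per cycle | chemistry quality bounds for inclusion |
| SDM smoothing halfwidth | 1 | cycles | Savitzky–Golay window 2h+1 (see numerical choices) |

**Pseudocount.** The pseudocount exists only to protect against division
by zero, so it must sit well below genuinely meaningful low coverage.
Repeat-driven female leakage onto a Y scaffold is on the order of 5% of
genome-average depth (normalized ≈ 0.05); a pseudocount of the same
magnitude would drag a true 10-fold male bias below the 7-fold bound and
misclassify exactly the scaffolds the threshold is designed to catch.
0.01 leaves a saturated, leaky Y scaffold at ≈ 8.7-fold while still
ranking female-zero scaffolds highest. `p = 0` is supported, with +inf
sentinels flagged per scaffold.

**Normalization set.** The mean is taken over *all* scaffolds by default
(the simplest reading of mean-coverage normalization); a flag restricts it
to scaffolds ≥ `min_length_bp` for sensitivity analyses, and a
length-weighted mean is available. Normalization is idempotent, and
scaling a sample's counts by any constant leaves its normalized profile
unchanged.

## Match engine

A shared contiguous exact match of length ≥ L exists between two sequences
iff they share a substring of length exactly L, so the default engine
indexes every L-mer of the assembly (forward strand, N-free; lowercase
treated as uppercase, N never matches) and queries each window's forward
and reverse-complement L-mers — an exact decision procedure, not a
heuristic. Own-scaffold hits at any locus are ignored: a window duplicated
elsewhere on its own scaffold is still unique for assay purposes. The
L = 50 default is a conservative proxy for a default nucleotide BLAST
search; an import path for standard 12-column BLAST tabular output
(query ids `scaffold:start-end`) lets an external BLAST self-search stand
in for the built-in engine, since real-data region counts can be sensitive
to the search tool and its settings.

Window tiling starts at 0 and steps by the offset; a truncated terminal
window is emitted iff it is at least one offset long (a scaffold shorter
than the offset yields one whole-scaffold window). This keeps scaffold
ends in play while keeping windows statistically comparable; a terminal
tail shorter than the offset is deliberately dropped.

## Numerical choices

**SDM C_T.** The crossing point is the argmax of the second derivative of
the fluorescence curve. Two obvious discretizations fail: a plain moving
average biases the asymmetric second-derivative peak by ~0.35 cycles (box
kernels shift skewed peaks), and quadratic interpolation of the
cycle-resolution second difference errs by ~0.5 cycles at realistic curve
steepness. The implementation therefore smooths with a Savitzky–Golay
filter (window 2h+1, polynomial order ≤ 3 — exact on locally polynomial
signal), locates the peak cycle by discrete second difference, and
refines by evaluating the second derivative of a quintic interpolating
spline on a 0.001-cycle grid within ±2 cycles of that peak. Against a
dense-grid oracle on a noiseless logistic curve this lands within 0.01
cycles; the estimate is exactly invariant to positive scaling of
fluorescence and equivariant under cycle shifts. Curves whose dynamic
range is below 10× the baseline noise (first five cycles) return a
"no amplification" sentinel rather than a number.

**Efficiency fit.** Ordinary least squares of C_T on log10(input); a
non-negative slope (C_T not decreasing with template) is an invalid
calibration, not a number. Noiseless series generated from any efficiency
invert exactly (measured max |Ê − E| < 1e−12 across the gate range).

**t test.** Pooled-variance Student's t by default because that is the
named test of the validation design; Welch is a flag. Identical constant
groups return t = 0, p = 1 rather than NaN. Replicate sets with C_T
standard deviation > 0.5 cycles are flagged as QC warnings but not
dropped.

**Tie-breaks.** Candidate rankings (X by length, Y by fold then length)
and assay-region selection (by length, then start coordinate) break all
remaining ties lexicographically / by coordinate, so outputs are
deterministic under input permutation.

## Synthetic data: what it emulates, what it does not

The generator builds an assembly of autosomal, X and Y scaffolds
(defaults: 30/6/6, log-uniform lengths 5–200 kb, GC 0.4) with three shared
repeat families (X↔Y, autosome↔Y, genome-wide; units 400–1200 bp). Half
the Y scaffolds are *repeat-saturated* — tiled end to end with shared
units, so no window of them is unique — mirroring the empirical situation
where most Y candidates carry repeats in every window; the rest keep
private sequence between scattered copies. Coverage is Poisson:
count ~ Poisson(depth × length × ploidy / read_length) with ploidy 1 for
autosomes, 1 (F) / 0.5 (M) for X, 0.5 (M) / 0 (F) for Y plus a female
cross-mapping mass of depth × repeat_bp × 0.05 / read_length. The default
sampling design is one male (125 bp reads) and two females (95 bp reads)
at 40× autosomal depth. qPCR simulation draws replicate C_T values
`base_ct − log_E(copy_factor) + N(0, 0.1)` with copy factor 2 for X
targets in females, and can emit logistic amplification curves whose SDM
crossing point equals the drawn C_T. Everything is reproducible from one
integer seed.

Deliberately not modelled: read-level sequencing (errors, fragment-length
effects, mappability), repeat divergence between copies (available as an
option set to 0%), assembly artefacts such as chimeric scaffolds, and
overdispersion beyond Poisson (real depth data are usually somewhat
overdispersed; an overdispersed run would mainly widen the ratio spread
on short scaffolds). Passing synthetic tests therefore demonstrates the
correctness of the computations and thresholds under the stated
generative model — not that the thresholds are optimal for any particular
real dataset, where mapping bias and repeat structure can shift both the
X ratio band and the achievable Y fold.

## Problem sizes

Test and acceptance runs use the default synthetic assembly (42 scaffolds,
~2 Mb), 50 random toy genomes (≤ ~15 kb each) for the engine-vs-oracle
equivalence, 200 simulated X-target qPCR experiments plus 1,000 autosomal
(null) experiments, and dilution series of 5 points. These sizes give
stable statistics while keeping any single check to seconds.

## Known limitations

- The uniqueness engine is exact for *exact* repeats; diverged repeat
  copies below the match length are invisible to it (as they would be to
  a word-size-limited search only approximately). Real-data region counts
  depend on engine settings; the BLAST import path exists for exactly
  this reason.
- Classification consumes the male vs *one* female ratio; with several
  females, per-female ratio columns are all reported but the first female
  anchors the calls.
- Short scaffolds are intentionally unclassified, so genuinely X-linked
  short scaffolds are systematically missed — total X-candidate length is
  an underestimate of X content.
- The Y-fold bound cannot distinguish Y linkage from male-specific
  insertions or severe female mapping dropouts; validation (unique-region
  PCR) is part of the design, not an optional extra.
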