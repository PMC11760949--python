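# Methods

## The measurement model

SMRT sequencing reports, for every incorporated base, an inter-pulse
duration (IPD) ratio: observed polymerase pause over the expected
unmodified pause. N6-methyladenine slows incorporation, so adenine IPD
ratios pool into a bimodal distribution — an unmethylated mode near 1 and
a methylated mode several-fold higher. In *Tetrahymena* the methylated
motif is ApT, which is symmetric across the duplex: the Watson adenine at
position p pairs with a Crick adenine at p+1. With circular-consensus
(CCS) reads, each molecule yields per-position IPD ratios on both
strands, so each molecule's view of each ApT duplex can be classified
Full / Hemi-W / Hemi-C / Un by thresholding the two adenine IPDs.

Downstream statistics are defined on these calls:

* penetrance of an adenine site = methylated molecules / covering
  molecules; sites supported by ≥ 3 methylated molecules are
  high-confidence 6mA sites;
* ΣP of a gene = sum of penetrance over all ApT adenine sites whose
  duplex (Watson-A) position lies in [start, end) — both adenines of a
  duplex count, since penetrance is defined per adenine;
* genome-wide 6mApT/ApT = high-confidence methylated fraction of covered
  ApT adenine sites;
* full/hemi ratio = Full observations / (Hemi-W + Hemi-C) observations,
  counted per molecule-duplex observation.

## Quality control

Three per-molecule filters, each independent, a molecule being retained
iff it passes all:

1. consensus passes ≥ 20 (boundary inclusive);
2. global dispersion: per strand, the sample SD (n−1 denominator) of IPD
   ratios over unmethylated adenines (IPD < 2.8); SD ≥ 0.35 on either
   strand removes the molecule. Strands with fewer than two qualifying
   adenines contribute no SD and cannot trigger removal — removing on
   undefined evidence would bias against short molecules.
3. local N\* artifacts: per strand, non-A positions with IPD ≥ 2.8 are
   chained while successive gaps are ≤ 25 bp; a chain of ≥ 4 removes the
   molecule. Chaining by successive gaps (rather than bounding the whole
   cluster span at 25 bp) is the adopted reading; the alternative is a
   one-line change in `local_artifact_filter`.

## Threshold deconvolution

The 6mA cutoff is fitted per sample: a 2-component Gaussian mixture (EM,
k-means initialisation, fixed seed; pools above 100k values are
subsampled) on ln IPD of all pooled adenines, with the cutoff at the
equal-posterior crossing between the component means (closed-form
quadratic). The fit is accepted as bimodal only if the minor weight is
≥ 1% and Ashman's D = |m1 − m0| / sqrt((s0² + s1²)/2) ≥ 2 — the standard
condition for a two-Gaussian mixture to be bimodal. Otherwise the
conservative working cutoff 2.8 is used. The D criterion matters: on
genome-scale pools where methylated adenines are < 1% of observations, EM
happily splits the unmethylated mode into two overlapping halves whose
separation can exceed one pooled SD; a weaker gate would accept that
split and put the cutoff inside the unmethylated mode. Ties at the
cutoff (IPD == cutoff) are called methylated, consistent with the
inclusive conventions of the QC rules.

One global cutoff is used for both strands; the genome-wide fraction uses
covered sites in its denominator. Both choices are isolated behind
function arguments.

## The synthetic-data generator

The generator emulates the statistical structure the estimators assume,
with exported ground truth; it does not model raw polymerase kinetics,
base-calling error or alignment.

**Genome.** AT-rich random sequence (A=T=0.375, C=G=0.125) in which every
ApT dinucleotide is placed deliberately: background ApTs are removed
(each accidental T after an A is flipped to C/G, which cannot create new
ApTs) and a requested density of ApT sites (default 140/kb, matching an
AT-rich macronuclear genome) is inserted uniformly at random with ≥ 2 bp
spacing. The exported site list is therefore exhaustive. Genes are
non-overlapping random intervals with random strands.

**Methylation.** Per-site penetrance in ciliate 6mA data is strongly
bimodal: methylated ApT sites carry high penetrance, the rest of the
genome is clean. The generator therefore designates a configured fraction
of ApT duplexes as methylated — an exact rounded count with random
placement, so the realized genome-wide 6mApT/ApT equals the configured
value up to rounding — and draws duplex states i.i.d. per molecule from
the preset's conditional state probabilities at designated sites
(always Un elsewhere). A homogeneous i.i.d. model cannot do this job: if
every duplex had per-molecule methylation probability 0.02, the
high-confidence site fraction at 20× coverage would be
P(Binom(20, 0.02) ≥ 3) ≈ 0.8%, not 2%.

The conditional state vector is parametrized by the configured full/hemi
ratio r and a methylation intensity m (probability a designated duplex
shows any methylation on a given molecule): P_full = m·r/(1+r),
P_hemi-W = P_hemi-C = m/(2(1+r)), P_un = 1−m. Presets are calibrated to
the published strain estimates:

| preset | 6mApT/ApT | full/hemi | m |
|--------|-----------|-----------|------|
| WT | 2.03% | 7.58 | 0.962 |
| APPA (catalytically dead) | 0.50% | 0.02 | 0.918 |
| dAMT1 (knockout) | 0.53% | 0.02 | 0.918 |
| RNAi (knockdown) | 1.02% | 2.0 | 0.95 |

The RNAi full/hemi value is reported only as "lower than WT"; 2.0 is a
plausible intermediate and is not an acceptance quantity. Per-gene
overrides support (a) a target ΣP, realized as a block of sites at
penetrance 0.95 (plus one remainder site) so the true ΣP is exact —
concentrating penetrance also matches WT-like methylated sites and keeps
the estimator variance ∝ Σ p(1−p)/coverage small; and (b) a target
fraction of methylated sites (used for the gene-body enrichment
experiment: one gene at 11.71%, background genes at 3.07%).

**IPD emissions.** Log-normal: unmethylated adenines and non-A bases at
location ln 1.0, scale 0.25; methylated adenines at location ln 5.0,
scale 0.18. The locations reproduce the bimodal separation around the
2.8 working cutoff. The methylated scale is chosen so per-strand
misclassification at that cutoff (~0.06%) stays negligible relative to
the rare hemi class: with a scale of 0.30 the miss rate is 2.7% and
Full→Hemi leakage alone (2 × 0.027 × P_full) would inflate the WT hemi
mass by ~40% — an emission artifact, not an estimator property; real
methylated IPD ratios separate essentially completely at the working
cutoff. The distributional family is a stand-in (the decision statistic,
not the generative law, is what the analysis fixes) and lives behind
`EmissionModel` so it can be swapped.

**Artifacts.** A configurable fraction of molecules (default 2%) receives
extra per-molecule multiplicative noise (log-scale SD 0.30, pushing the
unmethylated-A IPD SD past the 0.35 exclusion rule), and another 2% an
inserted run of 4–6 consecutive non-A positions drawn from the methylated
emission on one strand (an N\* cluster). Passes are discrete uniform
10–40 so both sides of the ≥ 20 filter are exercised. Molecule intervals
are uniform; lengths uniform in [0.8, 1.2] × mean.

**Fragments.** MNase-like fragment midpoints are a mixture of uniform
draws over the tight (±25 bp, 51 integer positions) and loose (±75 bp,
151 positions) dyad windows. Uniform placement already yields a degree of
51/151, so the tight-component weight is w = (p − 51/151)/(1 − 51/151),
making the expected measured degree equal the requested p; requests below
the floor clamp to it. Lengths are uniform in 120–260 bp.

**Counts.** Negative-binomial gene counts (var = μ + αμ²) with means
baseline × 2^(log2FC × treated) × factor, and Poisson spike-in totals
proportional to the per-sample factor. The experiments use α = 0.01
(CV 10%), technical-replicate-grade noise consistent with
spike-in-controlled cultures of an isogenic strain.

What passing tests on these data do **not** show: robustness to
sequence-context-dependent kinetics, mapping error, non-ApT 6mA, copy
number variation of the genome, or count overdispersion beyond NB — none
of which the generator produces.

## Differential expression stand-in

The study-specific computation is the spike-in size factor
(z_i / exp(mean ln z), so factors multiply to exactly 1); the test behind
it is deliberately a replaceable adapter: Welch's t-test on
log2(normalized + 0.5) with Benjamini–Hochberg correction, using the
boundary-inclusive thresholds log2FC ≤ −1, adjusted p < 0.05. With 3 vs 3
samples Welch's effective degrees of freedom (2–4) floor the attainable
p-values, so after BH over thousands of genes a minority of genuinely
2-fold-down genes always sits above 0.05 — the power checks are
therefore phrased for the typical injected gene (mean estimate, median
adjusted p), not per-gene universally. The fold-change pseudocount is
0.5.

## Chromatin metrics

"Fragments within k bp of the dyad" is read as fragment midpoint within a
closed ±k window (the midpoint approximates the fragment's own dyad);
whole-fragment overlap is the noted alternative. Gene-level positioning
averages the nearest up to three dyads downstream of the TSS inside the
gene body, requiring at least two defined degrees. ChIP enrichment
normalizes per total fragment count (CPM-equivalent), fragments assigned
to genes by midpoint.

## Numerical and degenerate-input conventions

Coordinates 0-based half-open throughout; the ApT duplex addressed by its
Watson-A position. Undefined ratios return NaN sentinels (full/hemi with
zero full and hemi; positioning with an empty outer window; gene ratio
with zero ApT; enrichment with zero input counts), except full/hemi with
Full observations but no hemi, which returns +inf. Zero-variance DE genes
get p = 1. All generators and fits are pure functions of their seed;
experiment-level seeds are split with `numpy.random.SeedSequence`.

## Problem sizes

Genome-wide experiments use a 50-kb genome at 140 ApT duplexes/kb with
9,000 molecules of mean length 500 bp (~60× retained coverage after the
passes and artifact filters), sizes at which the Monte-Carlo error of the
rare hemi class is ~3%. Gene-level ΣP experiments use a single ~4-kb gene
at ~20× retained coverage, matching the study's sequencing depth; the
gene-body experiment uses nine genes on the 50-kb genome at ~25×.

## Known limitations

The IPD emission family and artifact models are stand-ins calibrated to
reproduce the published summary statistics, not fitted to kinetic data;
recovery results certify the estimators, not the biology. The DE adapter
has no dispersion shrinkage and should be swapped for a count-based model
when real replicate counts are analysed. Nucleosome dyads are consumed,
not called. Non-ApT adenines are never summarized.
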