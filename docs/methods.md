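# Methods

`cernet` infers competing-endogenous-RNA (ceRNA) relationships from a
two-group, three-class transcriptome experiment: mRNA, lncRNA and miRNA
count matrices over the same samples, here a high- versus low-intramuscular-fat
(IMF) contrast with six animals per group. The pipeline chains five stages —
class-wise differential expression, miRNA target prediction, lncRNA target
assignment, trend-model triplet assembly, and weighted co-expression module
analysis — and ships a synthetic-data generator with planted ground truth so
that every stage, and the pipeline end to end, is testable without any
sequencing data.

## Differential expression

Counts for each RNA class are modelled as negative binomial with variance
`mu + alpha * mu^2`. Normalization is median-of-ratios: per-feature
geometric means over samples form the reference (features containing a zero
are excluded; a "poscounts"-style fallback over positive entries is
available behind `pseudo_reference=True`), and the resulting factors are
rescaled to geometric mean 1.

The per-feature dispersion `alpha` is a pooled method-of-moments estimate
from the two within-group sample variances, floored at 1e-8. The log2 fold
change is `log2((mean_high + 0.5) / (mean_low + 0.5))`; the pseudocount of
0.5 keeps the estimate finite for all-zero groups. The Wald statistic uses
the delta-method standard error of a log2 mean of NB draws,
`var = (1/mu + alpha) / (n * ln(2)^2)` per group. P-values are two-sided
normal and Benjamini–Hochberg adjusted **within each RNA class** (the three
classes are separate experiments with separate library preparations).

Significance calls are per-class: mRNA requires `padj < 0.05` **and**
`|log2FC| > 1`; lncRNA and miRNA require `padj < 0.05` only. Both gates are
configurable. There is no dispersion shrinkage, no outlier replacement and
no covariate adjustment; on clean simulated data the calls and fold changes
agree closely with DESeq2 (checked in the test suite via pydeseq2 on a small
fixture), but individual p-values will differ on real data with few counts.

The variance-stabilizing transform used upstream of all correlation-based
steps is the proxy `log2(count/size_factor + 1)`, tagged `vst-proxy` in the
container so provenance is explicit. It is not a fitted mean-variance
transform; for soft-thresholded correlation networks the difference is
immaterial at the expression levels simulated here.

Two screening filters mirror the upstream conventions of this analysis:
lncRNA candidates must satisfy transcript length >= 200 nt, exon count >= 2,
best-sample FPKM strictly > 0.5, and best-sample read coverage >= 3
(coverage is approximated as `count * read_length / transcript_length`,
read length 150 by default); genes enter the co-expression stage only with
row sum strictly > 10.

## miRNA target prediction

Canonical seed sites are found by scanning the host 5'->3' for the
Watson–Crick reverse complement of miRNA positions 2–7. Context upgrades
the site: a match to position 8 on the 5' flank and/or an adenosine on the
3' flank give 7mer-m8, 7mer-A1 or 8mer; all occurrences are reported,
overlaps included. Default accepted classes are {8mer, 7mer-m8, 7mer-A1};
6mer sites can be enabled.

Duplex stability is scored by a simplified additive model: G:C pairs -3.0,
A:U -2.0, G:U wobble -1.0 kcal/mol, +4.0 per unpaired or bulged base. A
dynamic program aligns the miRNA against the reverse-complemented site
window (the site plus enough upstream sequence for 3'-end pairing). The
miRNA is consumed end to end — every unpaired miRNA base pays the +4
penalty — while target overhangs outside the duplex are free. This makes a
bare seed match on an otherwise random window score poorly; extensive
pairing is needed to reach the default cutoff of -20.0 kcal/mol. The
numbers are not nearest-neighbor free energies and are comparable only
within this package.

A target pair is called conjunctively: at least one site of an accepted
class **and** minimal duplex energy <= cutoff. The same engine runs against
mRNA 3'UTRs (silencing arm) and full lncRNA transcripts (sponge arm).

## lncRNA targets and the overlap gene set

cis targets: gene and lncRNA transcript spans on the same chromosome with a
gap of at most 100 kb between closest ends (inclusive; overlap counts as
distance 0; strand is ignored — no strand rule is defined for this
proximity criterion). trans targets: |Pearson r| >= 0.95 (inclusive)
between the two features' VST-proxy profiles across all samples;
zero-variance features are excluded with a warning.

The candidate gene set for sponge triplets is the triple intersection of
(i) DE mRNAs, (ii) targets of DE miRNAs, and (iii) cis-or-trans targets of
DE lncRNAs. A union-style `either` mode exists for sensitivity analyses.

## Triplet assembly

A triplet (lncRNA, miRNA, mRNA) is emitted iff the miRNA has a predicted
site on both the lncRNA and the mRNA, the mRNA is in the overlap set, and
the three DE calls follow one of the two sponge trend models:
`lncRNA+|miRNA-|mRNA+` or `lncRNA-|miRNA+|mRNA-` (lncRNA and mRNA
co-directional, miRNA opposite — the expression signature expected when a
lncRNA sequesters a repressive miRNA). Multiple sites between a pair
collapse onto one edge carrying the best (lowest-energy) evidence.
Co-location/co-expression evidence for the lncRNA–mRNA pair is attached
when available and can be made mandatory (`require_lnc_target=True`); it is
not required by default, since proximity is one mechanism among several for
a functional sponge pair. Output order is sorted by ids, and exports
(node/edge/triplet TSVs plus a summary) are byte-deterministic.

An optional post-filter keeps only triplets whose mRNA is a hub gene
(|kME| >= 0.8) of a co-expression module whose trait association has
p < 0.05. The synthetic default dataset plants no modules, so this stage is
validated on its own constructed inputs rather than in the end-to-end run.

## Co-expression modules (WGCNA-style, compact)

Unsigned adjacency `|cor|^beta`; the soft power is the smallest
`beta in 1..30` whose connectivity distribution reaches a signed scale-free
fit R^2 of 0.85, computed by regressing log10 bin frequency on log10 mean
connectivity over 10 equal-width connectivity bins and negating the R^2
when the slope is positive. When no power qualifies — common for small
sample counts and homogeneous networks — the documented fallback power 21
is used with a warning.

Topological overlap follows the standard unsigned formula
`TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)`, clipped to
[0,1] (pre-clip excursions are warned above 1e-9). Genes are clustered by
average linkage on `1 - TOM` with a **static** cut (default height 0.995),
clusters below 30 genes go to "grey", and modules are labelled by
decreasing size with the classical color names. Dynamic tree cut and
module merging are deliberately out of scope: the static cut is simpler,
fully reproducible, and adequate for the planted-block designs this package
is validated on.

Module eigengenes are first principal components of the standardized module
submatrix, unit-norm, sign-aligned so correlation with the module mean
profile is non-negative. Module–trait association is a Pearson correlation
with the per-sample trait (continuous IMF % by default; the binary group
works too) with a two-sided Student-t p-value,
`t = r sqrt(n-2)/sqrt(1-r^2)`, df `n-2`. One combined 12-sample network is
the default; per-group networks are a caller-side option (subset the
samples) rather than a separate code path.

## Validation statistics

Relative qPCR expression uses `2^-ddCt` with the reference-gene dCt and the
arithmetic mean control dCt as calibrator (amplification efficiency fixed at
2); the geometric mean of control folds is 1 by construction. Group
comparisons use the pooled Student t-test by default (Welch behind a flag)
with the usual star bands (* <0.05, ** <0.01, *** <0.001). Phenotype
summaries report n/max/min/mean/SD with the sample (n-1) SD.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *design* of the motivating experiment: 12
samples in two IMF groups of 6, NB counts with `var = mu + alpha mu^2`
(default dispersion 0.05, base means log-uniform on [50, 500]), a fraction
of features carrying a +/- `lfc_planted` (default 2.0) group effect, and
IMF percentages uniform on the selection windows 5.8–6.6 % (high) and
1.4–2.2 % (low). The default DE background is 5 % of features
(`frac_null = 0.95`), matching the scale of the motivating study's DE yield
(roughly 4–5 % of expressed genes).

Planted sponge triplets are the ground truth for recovery testing. Each
triplet's three members get trend-consistent group effects plus a shared
per-sample lognormal factor (sigma 0.3 in log2; inverted for the miRNA)
emulating the co-fluctuation a sponge induces. The triplet's miRNA gets a
fully complementary binding site — which contains the canonical 8mer seed
site, since planted miRNAs start with U — inserted at a random,
non-overlapping offset in both the mRNA 3'UTR (500 nt) and the lncRNA body
(1000 nt). Seed-only sites would not represent a validated strong
interaction and would not pass the energy gate; full complementarity models
a high-affinity site. Sites are recorded in the truth manifest at their
8mer offsets.

Genomic layout: one synthetic chromosome; features are spaced > 1 Mb apart
so that no non-planted pair is cis, then each planted lncRNA is relocated
next to its mRNA with a gap uniform on [0, 100 kb] (`cis_fraction`
controls how many planted pairs are co-located; default 1.0, so planted
pairs always carry co-location evidence — trans detection is exercised by
dedicated tests on constructed profiles). Exon structure is synthetic
(contiguous blocks with 100-bp introns) and round-trips exactly through the
GTF writer/reader.

Not emulated: read-level artifacts and FASTQ simulation, batch/sex
covariates, isoform structure, realistic library-size variation, genome-wide
background site frequency, and conservation signal. Consequently, passing
recovery tests demonstrates the pipeline's logic and thresholds are
implemented correctly — not that the thresholds have the same operating
characteristics on real tissue data, where biological variance and
sequence composition are far less benign.

## Numerical choices and degenerate inputs

- Same seed => bit-identical datasets, results and exports; one
  `numpy.random.default_rng` drives each simulation.
- BH adjustment is vectorized step-up, capped at 1; inputs outside [0,1]
  are rejected.
- Dispersion floor 1e-8; fold-change pseudocount 0.5.
- Zero-variance genes abort adjacency with the offending ids; zero-variance
  trans profiles are skipped with a warning; a constant trait is an error.
- Single-gene modules use the standardized profile as eigengene; singleton
  phenotype summaries report SD 0 with a `degenerate` flag.
- A t-test on two zero-variance groups returns p=1 when means agree and is
  an error otherwise.
- GTF is 1-based inclusive at the file boundary, 0-based half-open
  internally; readers reject rather than coerce malformed input, with the
  offending line number.

## Problem sizes

The validation suite and the reproduction script use: 10 replicate default
datasets (500/200/100 features) for triplet recovery; 2000 features x 10
seeds for null calibration and 200 planted features on an 1800-feature null
background for power; 150-gene 3-block designs (10 seeds) for module
recovery and a 300-gene uneven-tightness design for soft-threshold
selection; 1000 random pairs/vectors for the seed-scan and BH oracle
equivalences and n <= 30 matrices for the TOM oracle. These sizes give
stable averages while keeping the whole suite under a minute on one CPU.

## Known limitations

- The DE test is asymptotic (normal Wald); at very low counts it is
  anti-conservative relative to exact NB tests.
- The duplex-energy scale is internal; cutoffs cannot be transferred to
  RNAhybrid/miRanda scores.
- The static tree cut can split a loose module into core + grey rather
  than recovering it whole; Rand-index checks on planted blocks quantify
  this.
- With 12 samples, a trans threshold of |r| >= 0.95 still admits chance
  correlations between strongly differential features; the triple overlap
  and trend gates, not the correlation alone, keep the false triplet rate
  near zero in the validated conditions.
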