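# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot show.

## Scientific setting

The package targets a semi-captive elephant population managed across
timber camps: wild-captured founders and captive-born descendants, with
births, deaths and *maternity* recorded in log books but paternity
unknown because mating is unsupervised and often involves wild bulls.
Genotype data (RADseq-scale, ~13,000 biallelic SNPs on 261 individuals)
are used to (1) quantify per-individual diversity and inbreeding, (2)
estimate pairwise relatedness and enhance the matrilineal pedigree with
inferred father–offspring links, (3) partition each genome into
age-resolved identity-by-descent classes, and (4) design reduced marker
panels for cost-effective relatedness monitoring.

## Genotype representation and QC

Genotypes are alt-allele dosages {0, 1, 2} with a distinct missing code,
never imputed. Coordinates are 1-based, intervals closed. Markers on
chromosomes flagged non-autosomal in the genome layout are dropped on
load. The standard QC retains markers with MAF strictly above 0.05 and
missingness at most 10% (boundary conventions: MAF exactly at the cutoff
fails; missingness exactly at the cutoff passes). LD pruning removes one
marker from every same-chromosome pair within a 50 kb window whose
squared dosage correlation (composite LD over pairwise-complete samples
— genotypes are unphased) exceeds the threshold. The removal rule is
deterministic: drop the member with the higher missing rate, then the
lower MAF, then the larger position. Because every within-window pair is
examined, the survivor set does not depend on a sweep step size; the
`step_snps` parameter exists for interface familiarity and is inert.

## KING-robust kinship and degree classes

For a pair (a, b), over markers non-missing in both:

    phi = (N_both_het − 2·N_opposite_hom) / (N_het_a + N_het_b)

This moment estimator conditions on the pair's own heterozygosity and is
therefore robust to allele-frequency misspecification and population
structure. Relatedness is r = 2·phi (parent–offspring r ≈ 0.5). Two
scales coexist in practice and the package fixes the convention: degree
classification operates on r (r > 0.45 first degree; 0.25 ≤ r ≤ 0.45
second; 0.125 ≤ r < 0.25 third/fourth; below that unrelated — the
second-degree bin is closed at the top so classification is total),
while unrelated-subset pruning operates on phi with the conventional
0.08 cutoff (second degree or closer). Pairs with a zero denominator are
flagged undefined and excluded from classification. The all-pairs
computation is four 0/1 matrix products in float32 (exact, since every
count is far below 2^24).

The unrelated subset is selected greedily: repeatedly remove the sample
in the most surviving pairs at phi ≥ cutoff, breaking ties toward the
sample whose camp is most represented among current survivors (rare
camps are preserved), then lexicographically. The output is exhaustively
re-checked pair-free on every run.

Father–offspring inference emits (sire, offspring) for every
first-degree pair whose older member is male, whose birth-year gap
strictly exceeds 18 years, and for which the recorded (matrilineal)
pedigree shows no relation — no shared recorded dam and no recorded
maternal ancestor in common. Age uses whole birth years; approximate
birth years propagate a flag onto emitted pairs. Pairs lacking birth
years are skipped and reported.

## Runs of homozygosity and F_ROH

A ROH is a maximal marker run with (i) no heterozygous call and (ii) at
most one missing call — maximal meaning extension in either direction
would violate (i) or (ii) — that additionally has (iii) at least 20
SNPs, (iv) SNP density (markers/span) at least the dataset-wide density
(total markers / total autosomal length), and (v) span at least 100 kb.
Exact maximal-run semantics replace the windowed heuristics of common
tools: the behaviour is deterministic and testable against exhaustive
sub-interval enumeration, at the price of small count differences versus
window-based callers. Segment endpoints are the first and last marker
positions (no extension into flanking gaps). F_ROH is the merged segment
span divided by total autosomal length. A `WGS_PRESET` parameter set
(50 SNPs, 500 kb) ships for dense callsets; its values are this
package's documented defaults for dense data, not a citation.

The density criterion has a subtle consequence worth knowing: with
markers placed uniformly at random, a genuine autozygous run's realized
density fluctuates symmetrically around the dataset-wide threshold, so
roughly half of marginal segments fail criterion (iv). With evenly
spaced markers the run density always sits just above the dataset ratio
and the criterion only rejects sparse artifacts. Validation experiments
that measure autozygosity recovery therefore use even spacing
(`marker_placement="even"`).

Group comparisons use the two-sided Wilcoxon rank-sum test (normal
approximation with tie correction, via the Mann–Whitney U
implementation, no continuity correction) and one-way fixed-effects
ANOVA. Note the rank-sum test cannot reach p < 0.01 with 3 observations
per group regardless of separation; calibration is verified by
simulation (type-I error 0.05 ± 0.02 at α = 0.05).

## Multi-class homozygosity-by-descent HMM

Each genome is modelled as an alternating sequence of segments from nine
HBD classes with rates R = 2, 4, …, 512 per Morgan plus a non-HBD class
whose rate ties to the largest HBD rate. Class-k segment lengths are
exponential with rate R_k, so R_k/2 indexes the generations back to the
common ancestor: small rates = long segments = recent inbreeding.
Between markers at genetic distance d (bp × 1 cM/Mb) the chain stays on
its segment with probability exp(−R_k·d); otherwise a new segment starts
in class j with mixing probability M_j. Emissions: non-HBD sites are
Hardy–Weinberg in the population alt frequency q; HBD sites are
homozygous (p, 0, q) up to an error mass ε (default 0.001) spread as
Hardy–Weinberg — the concrete emission law is this package's choice.
Missing genotypes emit 1 (skipped).

Inference is exact scaled forward–backward per chromosome
(chromosomes are independent chains; posteriors sum to 1 to 1e-10, and
the forward likelihood matches full path enumeration to 1e-8 on small
instances). The mixing vector is estimated per individual by L-BFGS-B
over softmax logits (the single-sample forward pass is numba-compiled);
rates and ε stay fixed. Per-class genome fractions are the unweighted
marker average of the posteriors (not span-weighted; documented and
easily swapped).

Identifiability is the binding constraint at desk scale, and two facts
shape the validation design. First, genome occupancy of class k scales
as M_k/R_k, so mixing mass on slow classes dominates the genome;
saturating the genome with HBD destroys the length signal because
adjacent same-class segments merge invisibly. Second, adjacent doubling
classes differ only two-fold in segment length, so resolving the fast
classes needs sub-0.2 cM marker spacing while counting enough
slow-class segments needs tens of Morgans of map — incompatible at one
uniform spacing with 5,000 markers. The recovery experiment therefore
plants one dominant HBD class at 40% genome occupancy against a non-HBD
background, on a graded ladder of four evenly spaced chromosomes
(1.6 Mb, 800 kb, 200 kb and 100 kb spacing × 1,250 markers) with
informative markers (alt freq U(0.2, 0.5)), and judges the partition
output: per-class genome fractions against realized path occupancy
(mean error ≤ 0.03 per class) and the dominant HBD class by genome
fraction (identified in ~90–93% of samples; every observed miss is an
adjacent-class confusion with the fitted likelihood above the
likelihood at the planted truth, i.e. a property of the maximum
likelihood surface, not of the optimizer).

## RIM panels and the resampling null

Panels are built from the post-QC set by dropping markers above 5%
missingness ("call rate below 5%" is read as call rate ≥ 95%; the
literal reading would be a no-op after QC), LD-pruning at r² > 0.2 with
the same 50 kb window machinery, then keeping markers with MAF ≥ 0.35,
0.40 or 0.45 (inclusive, so a threshold can retain markers exactly at
it). Increasing thresholds give nested panels. Each panel's kinships are
compared with the full-set reference by Pearson correlation on phi
(scale-invariant, so the phi-vs-r choice is cosmetic), and benchmarked
against 100 random panels of matched size drawn without replacement from
the same post-QC set. High-MAF markers maximise heterozygosity and hence
information per marker for the counting estimator, which is why the RIM
panel consistently beats its matched null.

## The simulator and what it does (not) show

`SimConfig` defaults mirror the study shape: 261 genotyped individuals —
54 wild-captured founders (34 females, 20 bulls) plus 207 captive-born —
typed at 13,000 markers on 10 × 120 Mb autosomes; 14 additional wild
bulls sire but are never sampled; founder alt frequencies U(0.05, 0.5)
in Hardy–Weinberg and linkage equilibrium; Mendelian transmission with
Poisson crossovers at 1 cM/Mb; symmetric uniform genotype miscalls at
rate 0.005 and missingness 0.02. Captive births draw dams uniformly from
females of reproductive age (15–50) and sires from age-eligible males
(20–60, hence every true sire is >18 years older than its offspring)
with probability proportional to a per-male weight raised to the
`sire_skew` exponent. With the age-eligibility dynamics an exponent of 1
already concentrates paternity so that the top bulls sire ~9–13 sampled
offspring, matching the observed reproductive skew; exponent 0 gives
uniform paternity for null experiments. Mating avoids close kin (no
shared matriline, no shared true ancestor within two generations),
reflecting documented behavioural inbreeding avoidance and chemosensory
kin recognition in elephants; it also keeps the paternity-recovery
experiment well-posed, because the inference rule deliberately discards
pairs with a recorded maternal relation. Dams are recorded in the
visible pedigree; true sires live only in a hidden truth table that the
metadata writer never emits.

What the synthetic data do not emulate: a realistic site-frequency
spectrum (founder MAFs are uniform, so RIM panel sizes are larger than
on real RADseq data), linkage disequilibrium among founders (LD arises
only from pedigree structure), allelic-dropout-shaped genotyping error
(miscalls are symmetric), camp-level population structure (founders are
one panmictic pool), and deep demographic history (no coalescent past,
so HBD class profiles of preset individuals are dominated by the non-HBD
class). Passing tests demonstrate correctness and calibration of the
estimators and inference machinery under the stated models, not
robustness to every artifact of real reduced-representation data.

## Problem sizes used in validation

Chosen to give tight Monte-Carlo error while the full suite stays at
desk scale: estimator calibration with ≥50 pairs per relationship at
5,000 error-free markers; paternity recovery aggregated over 10
replicate preset pedigrees at 2,000 markers with error 0.005 and no
missingness (~150 recoverable pairs each; the expected per-pair
classification margin puts aggregate sensitivity at ~0.95, so this
check is intrinsically near its threshold); F_ROH recovery over 200
full-sib replicates at 5,000 evenly spaced markers on 4 × 100 Mb
chromosomes; HBD recovery over 100 samples of 5,000 markers on the
ladder geometry; RIM-vs-null over 20 replicate presets with 100-draw
nulls; test calibration over 1,000 null replicates; end-to-end
determinism on a 100 × 3,000 preset. `scripts/acceptance.py` re-runs the
same experiments (RIM with 10 replicates) from a command-line seed.

## Known limitations

- The ROH caller's exact-run semantics can differ from windowed tools by
  a few marginal segments on identical input.
- The paternity rule is threshold-based, as specified; no
  genotyping-error-aware likelihood parentage assignment is attempted.
- HBD class rates are fixed, not estimated, and adjacent doubling
  classes are only ~two-fold apart, which bounds dominant-class
  identification around 90% at 5,000 markers.
- The pipeline is single-machine and in-memory; the preset scale
  (hundreds of samples, tens of thousands of markers) is the intended
  operating point.
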