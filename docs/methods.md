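# Methods

## Phenotype model and tolerance evaluation

Each entry (two parents, n F1 lines) carries a latent tolerance multiplier
w: under control conditions a trait's replicate values are
`baseline × noise`, under stress `baseline × w × noise`.  Noise is
multiplicative log-normal with unit mean and coefficient of variation
`noise_cv`; positive-valued multiplicative noise is the simplest model
consistent with traits that are masses and lengths and with a CV
parameterization.  The replicate-level CV default (0.15) is a free choice —
typical of greenhouse biomass replicates — exposed in the config; the
design defaults (140 lines, 7 traits, 10 treatment and 6 control replicates,
maternal/paternal tolerance 0.65/0.25, line effects ~ Normal(0.46, 0.15)
truncated to (0.02, 1.5)) reproduce a wide, transgressively segregating
population whose composite scores bracket both parents.

The tolerance index WI = treatment mean / control mean recovers w exactly as
noise → 0, which is what the exact-recovery tests exploit (`noise_cv = 0` is
explicitly allowed for this reason).  The morphological score is recorded
under stress only; since an index needs a control denominator, the score's
treatment value enters the membership function directly.  Membership values
are min–max rescalings per trait across **all** entries (parents included);
a trait whose index is constant across the population has no scale and is
dropped from the composite with a logged warning.  The composite MFVW is
the unweighted mean of membership values.  Grading uses the mean and SD of
MFVW over the F1 lines only (parents are graded against the same
thresholds for reference): HWT at x ≥ m + 1.64s, then WT, MWT, WS, HWS in
1.64/1.0 SD bands, each interval closed on its lower bound, so m + 1.64s is
HWT and m − 1.64s is WS.  The multipliers (1.0, 1.64) are configurable.

Population heterosis treats each line's index as one observation; per-line
heterosis uses replicate values.  MPH/HPH significance is the classical
two-sided one-sample t-test against MPV/HPV, starred at P < 0.05 / P < 0.01.
Display rounding is half-away-from-zero at 2 decimals; all internal
computation is full precision.  Mid-parent values quoted from printed
parental means can disagree with printed heterosis percentages by up to
about a percentage point, because published tables round their inputs.

## Count model

Per-gene trio means (maternal, paternal, hybrid) are set by the gene's true
class; replicate counts are negative-binomial with var = μ + φμ², the
standard RNA-seq dispersion parameterization (φ → 0 degenerates to
Poisson).  Baseline means are log-uniform over `mean_log_range`
(default 10² – 10^3.5).  Per-sample library factors drawn uniformly from
[0.7, 1.3] scale the means so that normalization is non-trivial.

Class construction, with S = `effect_size` (default 4):

| class | maternal | paternal | hybrid |
|---|---|---|---|
| null | b | b | b |
| P1 / P6 (maternal dominance) | b / Sb | Sb / b | = maternal |
| P3 / P4 (paternal dominance) | Sb / b | b / Sb | = paternal |
| P5 / P2 (transgressive up/down) | b / Sb | b / Sb | S·max / min/S |
| P0 / P7 (additive) | b / S²b | S²b / b | (maternal+paternal)/2 |

For the additive classes the hybrid is pinned at the *arithmetic*
mid-parent, which caps its fold separation from the high parent at 2
regardless of how far apart the parents are; the parents are therefore
spread S²-fold so that both hybrid–parent contrasts stay near that ceiling
and every pair of groups meant to differ remains detectable.  The default
class mix is 60 % null and 5 % per profile: median-of-ratios normalization
(like real RNA-seq) assumes most genes are not differential, and a
signal-dominated matrix would bias the size factors (the bias is visible if
the null fraction is pushed low, which the config permits).  Both
conditions (control/stress) share a gene's class and means, so
stress-vs-control contrasts in synthetic data are null by construction.

What the generator does **not** emulate: gene-specific dispersions, GC or
length biases, correlated genes, outlier replicates, and condition-dependent
class switching.  Passing recovery tests therefore demonstrate correctness
of the statistical machinery under the stated model, not performance on any
real dataset.

## Differential expression

Size factors are median-of-ratios against the geometric-mean reference over
genes nonzero in every sample, falling back to total-count scaling (logged)
when no such gene exists.  The default test operates on
log₂(normalized + 1): per-gene pooled variances are squeezed toward an
empirical-Bayes prior fitted by matching the moments of log s² (trigamma
inversion by Newton), and the prior follows a lowess trend in average log
expression because count variance depends on expression level — with a flat
prior, genes above the trend are systematically over-called (measured as
~14 % vs ~6 % type-I error at nominal 5 % on mixed simulated data).  The
statistic gains the prior degrees of freedom, which at 3 replicates per
group is what makes modest fold changes (the additive hybrid sits only
~1.9-fold from its high parent) detectable at all.  A plain Welch engine is
available behind the same interface (`engine="welch"`).  The pseudocount
(1.0) guards zeros and is recorded in config.  Fold change is computed on
normalized group means — not log-space means — so "fold change ≥ 2" is
|log₂FC| ≥ 1, symmetric for up and down.  FDR is Benjamini–Hochberg within
one contrast; all-zero genes get p = 1.

The hybrid-vs-mid-parent contrast treats the mid-parent as an *estimated*
reference: the test statistic is the log₂ ratio of the hybrid mean to the
arithmetic mid-parent with a delta-method standard error that includes the
parental group-mean variances (Var(mid) = (Var(m̄)+Var(p̄))/4) and
Welch–Satterthwaite degrees of freedom.  Ignoring the reference's sampling
error roughly doubles the false-positive rate on additive genes, because
the mid-parent inherits half the (larger) high parent's variance.

## Profile classification

The decision tree evaluates transgressive (both hybrid–parent contrasts
significant, same direction), then dominance (one contrast null, the other
significant), then additive (parents significantly differ, hybrid not
different from the mid-parent); first match wins, so a gene satisfying
several clauses gets the stronger claim only when both of its defining
contrasts are significant.  "Significant" is BH q ≤ α (default 0.05) on
that contrast.  The numeric profile IDs follow the anchored convention —
P5 transgressive-up, P1/P6 maternal dominance (low/high parent matched),
P3 paternal dominance — with P2 (transgressive-down), P4 (second paternal
dominance) and the P0/P7 additive orientation (maternal below/above
paternal) fixed by symmetry: exchanging the parental labels flips P0↔P7,
P1↔P3, P6↔P4 and leaves P2, P5, unclassified unchanged, a property tested
exactly.  The default classification universe is genes that are DEGs in at
least one hybrid-vs-parent contrast (the set trend analysis runs on);
`universe="all"` classifies everything.  The mid-parent comparison uses
replicate-level hybrid values (not only the group mean), which gives the
test its degrees of freedom.

Expected failure modes, visible in the recovery confusion matrix: additive
genes whose hybrid-vs-high-parent contrast (capped below 2-fold) goes
undetected are mislabelled as dominance toward that parent; these dominate
the few-percent error at the default settings (~98 % profile recovery at
5,000 genes, 3 replicates, S = 4, φ = 0.05).

## Enrichment

Over-representation only (upper-tail hypergeometric); the multiple-testing
"Q value" is read as Benjamini–Hochberg.  The background universe defaults
to annotated genes (union of term members), configurable to a custom set;
list members outside the universe are dropped with a warning, emptied terms
likewise.  Output ordering is by q, then p, then term ID, for determinism.

## Pipeline

One YAML config with CLI overrides; every output table carries a comment
header with tool version, config hash (output paths excluded, so identical
analyses hash identically) and seed; `manifest.json` records per-stage row
counts and timings.  The pipeline's enrichment stage, lacking a real
annotation database offline, builds a synthetic GMT whose first terms are
biased toward the transgressive-up gene set, so the stage exercises a
positive control end to end.

## Problem sizes

Defaults used by the test suite and the reproduction script — 5,000 genes ×
3 replicates for recovery and calibration runs, 100,000 random triples for
the grade-partition property, exhaustive hypergeometric enumeration to
N = 25 — are sized to give stable Monte-Carlo estimates (binomial SE ≤ 0.5
percentage points on recovery rates) while keeping any single check in the
seconds range.
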