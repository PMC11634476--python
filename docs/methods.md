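# Methods

This note documents the statistical model, the conventions the estimators
follow, what the synthetic-data generator does and does not emulate, and the
design choices made where the field's practice is not unique.

## Two-sample MR model

All estimators consume harmonized summary data: per instrument $j$, the
SNP–exposure effect $\hat\gamma_j$ with SE $\sigma_{\gamma j}$ and the
SNP–outcome effect $\hat\Gamma_j$ with SE $\sigma_{\Gamma j}$, aligned to a
common effect allele. The identifying assumptions are the usual
instrumental-variable ones: instruments associate with the exposure, share
no confounder with the outcome, and affect the outcome only through the
exposure (no horizontal pleiotropy). The estimators weight by the inverse
outcome variance $w_j = \sigma_{\Gamma j}^{-2}$ only; exposure-side
sampling error is ignored (the "no measurement error" convention). This
first-order treatment is accurate for strong instruments (mean F of order
100 or more) and is the regime the defaults target; with weak instruments
the IVW estimate attenuates by roughly a factor $1 + 1/\bar F$, which is
why the F > 10 screen is on by default.

Conventions, fixed rather than configurable:

- Normal (z) quantiles everywhere: 95% CIs are $\pm z_{0.975}\,\mathrm{SE}$
  with $z_{0.975} = 1.959964$, p-values two-sided normal tails.
- Random-effects IVW multiplies the fixed-effect SE by
  $\max(1, \sqrt{Q/\mathrm{df}})$ — multiplicative overdispersion floored
  at 1, never shrinking below the fixed-effect SE. `mode="random"` is the
  default because trait GWAS outcomes routinely carry residual
  heterogeneity.
- MR-Egger orients instruments so $\hat\gamma_j \ge 0$ (negating both
  coordinates where needed) before fitting the intercept model; the fit is
  not invariant to per-instrument allele re-coding without such a
  convention. Both coefficient SEs carry the same $\max(1,\sqrt{Q/\mathrm{df}})$
  factor, df = J − 2.
- Cochran's Q uses df = J − 1 for IVW and J − 2 for Egger, with a
  chi-square upper-tail p-value.

## Harmonization

The outcome's effects are aligned to the exposure's effect allele: matching
pairs are kept, swapped pairs negate the outcome beta and complement its
EAF, and non-palindromic pairs are additionally matched across strands by
base complement. Palindromic (A/T, C/G) variants cannot be strand-resolved
from alleles alone; the default policy (`drop_ambiguous`, band 0.08) drops
those with missing EAF or EAF within 0.42–0.58 in either study and aligns
the remainder by minor/major-allele orientation. This is standard
two-sample MR practice rather than a property of any particular dataset.
Within a file, duplicated variant ids keep the lowest-p row,
deterministically.

## Instrument selection

Defaults mirror common drug-target MR practice: association threshold
p < 1e-4 (strict inequality), greedy best-p-first clumping removing
neighbours with r² > 0.8 within 250 kb (center-to-center, same chromosome;
ties broken by variant id for determinism), and per-variant
F = (beta/SE)² with F > 10 required. The clumping algorithm is PLINK-style
greedy; its output is independent of input row order because candidates are
canonically ordered by (p, id).

## MR-PRESSO

The observed statistic is the leave-one-out weighted residual sum of
squares; its null distribution is a parametric bootstrap
($\gamma^*_j \sim N(\hat\gamma_j, \sigma_{\gamma j}^2)$,
$\Gamma^*_j \sim N(\hat\beta_{-j}\hat\gamma_j, \sigma_{\Gamma j}^2)$, K =
2000 draws by default), with fixed-effect leave-one-out slopes throughout
for speed and determinism. Monte-Carlo p-values are floored at 1/(K+1) and
never exactly zero. Outliers are instruments whose per-SNP residual
p-value falls below 0.05/J (Bonferroni); the corrected estimate is plain
IVW on the remaining set. The distortion test compares the raw-vs-corrected
percentage shift against removing random same-size subsets of the
non-outliers (1000 draws). Draw order is fixed (all $\gamma^*$ then all
$\Gamma^*$, instrument-major) and the distortion bootstrap uses a separate
seeded stream, so a given seed reproduces results bit-for-bit.

## Mediation

The indirect effect is the product of coefficients
$\hat\beta_1\hat\beta_2$; its SE assumes the two stages come from
independent samples (zero covariance), which is the two-sample design. The
mediation proportion divides by the total effect. Two delta-method
variants for the proportion SE are offered: `fixed` (default) treats the
total effect as known, giving $\mathrm{SE}_\mathrm{ind}/|\hat\beta_\mathrm{total}|$;
`propagated` adds the total effect's relative variance. `fixed` is the
default because, on the package's reference three-estimate chain with
stage SEs back-derived from its CIs, it reproduces that
interval's half-width to within a few hundredths of a percentage point,
whereas full propagation gives a visibly wider interval. Proportions
outside [0, 1] are reported with a warning, not clipped.

Mediator instruments always exclude any variant in the exposure's
instrument set: the mediator→outcome stage must not be instrumented by
variants acting through the exposure's direct path. The screen runs
mediator→outcome MR for every candidate first (multiplicity adjustment
across candidates: none by default, Bonferroni and BH-FDR available — the
raw-p default reflects how such proteome/metabolome screens are commonly
reported), then exposure→mediator MR for the survivors, and by default
requires sign($\hat\beta_1\hat\beta_2$) to match the total effect before a
candidate counts as a mediator.

## Synthetic data generator

`simulate_chain` emulates a biobank-scale two-sample design at the
summary level: exposure, mediator and outcome GWAS of 200 000 samples each
(independent noise — no sample overlap), 30 exposure instruments and 30
mediator instruments, MAF uniform on (0.05, 0.5), and per-trait SEs from
the standardized-trait approximation $1/\sqrt{2f(1-f)n}$. True effects:
$\gamma_j \sim N(0, 0.15^2)$ per allele copy, chosen to mimic strong cis
molecular-QTL instruments (mean F on the order of 10³), the regime where
the no-measurement-error convention is benign; chain coefficients
$\alpha = -0.2$ (exposure→mediator), $\theta = 0.3$ (mediator→outcome),
$\delta = -0.24$ (direct), so the total effect is −0.30 with a true
mediation proportion of 0.20 — the magnitude of the package's reference
chain. Horizontal pleiotropy adds $N(\mu_p, \sigma_p^2)$ offsets to the
outcome truth for a configurable fraction of instruments (zero by
default). LD is block-diagonal with constant within-block r², and blocks
are placed far apart genomically so the clump window behaves as intended.

`plant_outliers` adds `offset_in_se` outcome SEs to k instruments. By
default the offset is applied on each instrument's exposure-increasing
orientation (directional pleiotropy); applied instead in the table's
arbitrary allele coding (`orient="coded"`), the offsets have random sign
relative to the instruments and act like balanced pleiotropy — detection
is unaffected, but removing such outliers improves the point estimate far
less often, since their biases partially cancel.

What the generator does *not* emulate: marginal-effect inflation through
LD (effects are drawn at the causal variant; the LD matrix only describes
the clumping structure), binary outcomes on the log-odds scale (effects
stay on the linear scale throughout), sample overlap, population
stratification, winner's-curse selection of instruments from the same
sample, and INDEL/multi-allelic variants. Passing recovery and calibration
tests on this generator therefore demonstrates correctness of the
estimators under the two-sample model's assumptions, not robustness to
those real-data complications.

## Simulation-study sizes and numerical notes

The bundled studies (`mrlink.benchmarks`) use 200 replicates for recovery,
500 for null calibration of Q and the IVW/Egger tests, 200 (K = 500) for
the MR-PRESSO global null, and 100 (K = 2000) for outlier power — sizes at
which Monte-Carlo error is small relative to the quantities measured while
a full run stays in the tens of seconds on one CPU. P-values are clipped
into (1e-300, 1] to keep logs finite; harmonized rows are sorted by
variant id so every downstream computation is order-stable; `NA` is the
canonical missing value on disk, and floats are written at 17 significant
digits so a write→read round trip is bit-exact.

## Known limitations

- No exposure-side measurement-error correction in the Wald/IVW SEs;
  estimates attenuate when instruments are weak.
- No weighted-median/mode estimators, multivariable MR, or Steiger
  filtering.
- No liftover or reference-genome normalization of variants; matching is
  purely by id and alleles.
- The distortion-test null (random subsets of non-outliers) is a
  resampling convention; other implementations of the same idea may differ
  in detail.
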