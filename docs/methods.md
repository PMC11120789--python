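# Methods

## Model and estimator

A subject's profile `M_s` in p dimensions is modelled as a drift–diffusion
random walk: the displacement over an interval `t` is Gaussian with mean
`α t W` (drift magnitude `α ≥ 0`, unit direction `W`) and covariance `Ξ`.
Writing the squared Euclidean interpoint distance as a Gaussian quadratic
form and splitting it into its drift, diffusion, and cross terms gives

    E[d²] = α² t² + c·t,        Var[d²] = O(t²),

where `c·t` collects the diffusion eigenvalue sum over the interval (for
`Ξ = I` per unit time, `c = p`). For large effective dimension the
diffusion term is approximately Gaussian, so the squared distance behaves
like a linear regression response. The distribution of distances does not
depend on the drift direction (distances are invariant to orthonormal basis
changes), which is why only the magnitude is identifiable from distances —
and why that is all this framework estimates.

Two models and two response scalings are implemented:

| model     | scaling       | response | regressor | slope estimates |
|-----------|---------------|----------|-----------|-----------------|
| linear2   | time_scaled (default) | d²/t | t      | β = α²          |
| linear2   | literal       | d²       | t²        | —               |
| linear    | time_scaled   | d/√t     | √t        | α               |
| linear    | literal       | d        | t         | —               |

**Why time-scaling is the default.** Under diffusion the `c·t` term grows
with the interval. In the literal `d² ~ t²` regression that term loads on
the slope (t and t² are positively correlated for positive intervals), so
the literal form rejects far too often under the null and is biased; the
time-scaled form turns the diffusion term into a free intercept, leaving
the null slope exactly zero. Concretely, for the pre/post generator below,
`d²/s | s ~ χ²_p(α²s)` with mean `p + α²s` — independent of `s` when
`α = 0`, which is what makes the coefficient t-test calibrated. The literal
forms are retained behind a flag because the unsquared literal fit
(`d ~ t`) is a natural naive comparator whose dimension-dependent bias the
bias grids demonstrate.

Fits are ordinary least squares with an intercept; the drift test is the
conventional two-sided coefficient t-test on the slope. A one-sided test
would be defensible (β = α² ≥ 0 under the model) but the two-sided
convention is kept. Negative slope estimates are reported as-is, while
`alpha_hat` is clipped at zero — a magnitude cannot be negative. At least
3 pairs are required (slope + intercept + one residual degree of freedom);
a zero-variance regressor (all intervals equal) is an error rather than a
silent NaN.

Pairs are built per subject after sorting by time. The default mode is
**baseline** (each later sample against the subject's first, intervals
measured from the start of the walk); `consecutive` and `all_pairs` are
available. Within-subject dependence among pairs is deliberately ignored
in the OLS — the estimator is a pooled regression, not a mixed model — so
pooled p-values should be read as approximate when subjects contribute
many overlapping pairs. Per-subject fits (`fit_per_subject`) avoid the
issue entirely and feed the two-group comparison, a pooled-variance
Student t-test on per-subject `alpha_hat` values.

## Synthetic-data generator

`simulate_prepost` emulates the canonical two-timepoint longitudinal
design: per subject, a follow-up time `s ~ Exponential(rate)` (rate 1 by
default, i.e. mean interval 1 study-time unit; the rate only sets the time
unit and cancels out of the null slope test), with the baseline observation
at the origin and displacement `X | s ~ N(α s · v, s I)` for unit drift
direction `v = 1_p/√p`. The mean-vector norm is then `α s` and
`E[‖X‖² | s] = α² s² + p s`. The per-coordinate drift mean is `α s/√p` —
the `1/√p` (not `1/p`) scaling is forced by requiring `‖v‖ = 1` and a
squared mean distance of `(αs)²`. `simulate_trajectory` generates full
walks with increments `N(α·dt·v, dt·I)` on a regular grid.

What the generator does **not** emulate: compositionality (simulated
coordinates are unconstrained reals, not relative abundances),
feature correlation (`Σ = s·I` only), non-Gaussian jumps, missing values,
and irregular within-subject sampling beyond the exponential follow-up.
Passing tests therefore show calibration and recovery under the idealized
Gaussian drift–diffusion regime; on real microbiome data the CLR transform
brings compositions closer to this regime but heavy tails and correlated
taxa remain untested territory.

Randomness: every replicate draws from
`SeedSequence(seed, spawn_key=(n, d, round(1e4·α), round(1e4·rate), r))`,
so grid results are independent of cell ordering, method list, and worker
count, and any cell can be reproduced in isolation.

## Comparison methods

Five min-p alternatives are implemented exactly in their usual form: PCo1,
PCo2 and PCoA regress the first 1, first 2, or all retained principal
coordinates on time and take the **raw minimum** p-value across axes (no
multiplicity adjustment — that is how these ad-hoc procedures are used, and
"fixing" them would destroy the comparison being made); uFDR and uHolm
regress every feature on time and take the minimum Benjamini–Hochberg or
Holm-adjusted p-value. For simulated pre/post data the methods see the
follow-up displacement vectors at their observation times; the constant
baseline rows are excluded by default (they are degenerate regression rows)
but can be included via a flag. Under the null these methods are strongly
anticonservative at high dimension — both because min-p selection
capitalizes on chance and because diffusion makes the per-feature
regression errors heteroscedastic (variance ∝ time), which the per-feature
t-tests do not account for.

## Transforms and PCoA

CLR uses the natural log with a configurable pseudocount; the default
(`'auto'`) is half the smallest positive value in the table, applied only
when zeros are present — standard compositional practice that keeps the
choice scale-free. Aitchison distance is defined as Euclidean∘CLR and is
computed that way. PCoA double-centres `−D²/2` (Gower), eigendecomposes,
and keeps axes with eigenvalue above `max(n,1)·eps·λ_max`; negative-
eigenvalue axes (non-Euclidean dissimilarities) are dropped with a warning
and counted, with no Cailliez/Lingoes correction, so baseline behaviour on
such inputs is transparent rather than silently altered. Axis signs follow
the largest-magnitude-loading-positive convention for reproducible output;
eigenvalue ties keep input order.

## Evaluation grids and problem sizes

The study runner evaluates rejection fractions (type I error at `α = 0`,
power otherwise) and slope bias (`slope − α²` for linear2, `slope − α` for
linear) over cells of (n, d, α). Two dimension presets ship, `dmax-1000`
(`{1, 10, 100, 1000}`) and `dmax-400` (`{1, 10, 100, 400}`), with
n ∈ {10, 20, 50, 100}
and α ∈ {0, 0.5, 1, 2, 3}. The default replicate count is 2000 per cell —
enough for a binomial 99% interval of ±0.013 around 0.05 — chosen so a
full grid runs in minutes on a single core; larger counts are a parameter,
not a code change. The acceptance script uses 2000 replicates for the null
calibration, 500 for the bias cell, and 1000 trajectories for drift
recovery, with Monte-Carlo standard errors reported against in the tests.

## Data handling choices

Feature tables are validated as finite with unique ids; non-negativity is
enforced for raw abundance input but relaxed (explicitly, via
`allow_negative`) for derived tables such as CLR output and simulated
displacement coordinates, which are real-valued by nature. The sample-sum
filter is a plain row-sum threshold on the table as given — no rescaling —
matching how incompletely profiled relative-abundance samples are screened
in practice. Distance matrices must be symmetric within 1e-9 (tiny
floating-point asymmetry is averaged away), hollow, and non-negative.
Duplicate (subject, time) records are an error by default; `dedupe='first'`
keeps the first occurrence. Subjects with too few timepoints are skipped
with a warning in pair construction and reported (not raised) in
per-subject fitting.

## Known limitations

- Pooled fits ignore within-subject correlation between pairs; standard
  errors are approximate whenever one subject contributes many pairs.
- `alpha_hat = √max(slope, 0)` is slightly biased downward near small α
  (Jensen) and upward at α = 0 (clipping); the slope itself is unbiased
  under the time-scaled linear2 model and is what the bias grids assess.
- The group comparison assumes equal variances (Student, not Welch).
- The Gaussian approximation of the diffusion term weakens at very small
  dimension; empirically the slope test stays near nominal even at d = 1
  for the sample sizes studied, but small-n/d = 1 corners are the closest
  to the band edge.
- No missing-value handling: distances must be computable for every pair.
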