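# Methods

## Screening model

FHP level is a deterministic function of FNTA via three cutoffs
(default 12°, 25°, 40°), each level interval closed on the left and open on
the right, so an FNTA equal to a cutoff belongs to the higher level. The
cutoffs live in the constants bank rather than in code; everything
downstream (candidate generation, voting, evaluation) takes them from the
bank, so alternative screening protocols are a configuration change.

## Boundary-line models

Each of the eight radiographic parameters has a diagnostic model of three
lines `0 = K + L1·X + L2·Y` in the (parameter, FNTA) plane, separating
levels 0/1 ("blue"), 1/2 ("pink") and 2/3 ("red"). The representation is
normalised to `L2 < 0`, which orients every line so that larger FNTA lies
on the higher-level side and makes the closed form
`Y(X) = −(K + L1·X)/L2` well defined. A model must satisfy the stacking
invariant blue < pink < red (checked at the midpoint of the common span);
a fitted model violating it raises an error rather than being silently
reordered, because a crossed stack means the training data do not support
a monotone level geometry for that parameter.

The packaged default bank transcribes the published constants for all 24
lines verbatim, together with each line's parameter-axis span (LE/RE). All
24 boundary FNTA values at the span endpoints reproduce the published
initial/end angles to the printed 0.1° precision (checked in the test
suite).

### Candidate generation from FNTA alone

At diagnosis time the parameter value is unknown, so a line is summarised
by its FNTA range over its span (the line is affine in X, hence the range
is attained at the endpoints). Comparison is exact floating point; values
are rounded to 0.1° only in rendered reports. Tie rule: FNTA equal to the
range minimum is unambiguously the lower level, equal to the maximum
unambiguously the upper level; strictly inside is ambiguous and both
levels become candidates. Level `l` is a candidate when every lower
boundary is above-or-ambiguous and every boundary from `l` up is
below-or-ambiguous; the resulting set is provably nonempty and contiguous
for stacked lines, and is cross-checked in the tests against a brute-force
oracle that sweeps the parameter axis on a fine grid and classifies each
(X, FNTA) point by the sign of `K + L1·X + L2·Y`, for every packaged model
and every FNTA from 0° to 70° in 0.1° steps.

Two documented departures from the published evaluation sheet, neither of
which changes any final voted diagnosis there:

* **CL effective range.** Several printed CL cells are unambiguous although
  the boundary's FNTA range over the full printed span contains the FNTA
  (consistent with the original analysis clipping CL to its observed,
  unpublished data range). The default is the printed span; a per-line
  `eff_LE`/`eff_RE` override exists for users who know a narrower range.
* **Rounding at the margin.** The published sheet occasionally compares
  FNTA against endpoint angles rounded to 0.1° (e.g. an FNTA of 10 against
  a rounded minimum of 10.0, exact value 9.96). Exact evaluation can flip
  such borderline ambiguity flags; final diagnoses are unaffected.

### Voting

Each model casts one vote per candidate level; the diagnosis is the argmax
of the vote counts. Ties (impossible on the packaged bank over the
published evaluation sheet, but possible for refitted banks) resolve to
the highest tied level and set a flag — conservative in the referral
direction, since over-referring to radiography is the safer error.

### Fitting

The fitting method behind the published constants is not fully specified,
so the package adopts the canonical two-class linear boundary: Fisher's
linear discriminant with equal priors and pooled covariance, whose
boundary passes through the midpoint of the class means, solved directly
on the 2×2 pooled covariance. Degenerate inputs (fewer than two points per
class, singular covariance, coincident means, a vertical boundary, a
single shared X value) are errors. Each line's span is the pooled X range
of the four-level training sample so that the three lines of a model share
one axis.

With within-level spread shrunk toward zero the fitted boundary FNTA
approaches the midpoint of the adjacent levels' truncated FNTA means —
12.93°, 24.25° and 42.98° under the default distributions. Note the third
midpoint sits ~3° above the 40° screening cutoff: the default level-2 and
level-3 FNTA means (31.24°, 54.71°) are asymmetric about the cutoff, so a
refitted red boundary systematically lands near 43°, much as the published
red lines run 40.3°–50.6°. Tests check fitted boundaries against these
closed-form midpoints (and against the 12°/25° cutoffs, which the first
two midpoints fall within 2° of).

## Synthetic cohorts

The generator emulates the structure the pipeline needs: within each FHP
level, FNTA is normal with the published level mean/SD, optionally
truncated to the level's screening interval (default on, so the generating
label is consistent with threshold screening; off reproduces plain
normals), and each radiographic parameter is normal with the published
level mean/SD. Per-level counts are unpublished; the default (38, 55, 36,
16) sums to the study's 145 and is an explicit placeholder. An optional
per-parameter FNTA correlation (default 0, matching the near-zero published
correlations) is imposed via a Gaussian copula: one latent standard normal
drives the truncated-normal FNTA quantile and mixes into the parameter with
weight r, so the latent correlation is exactly r and survives the monotone
truncation map in rank terms. One `numpy.random.Generator` seeded from the
spec drives the whole cohort in a fixed level/parameter order, making
cohorts byte-reproducible.

What the generator does **not** model — and therefore what green tests do
not establish about real data: measurement error of the depth sensor or of
manual radiographic angle reading, inter-rater variability, age/sex
structure, any true joint dependence among the eight parameters beyond the
optional pairwise FNTA correlation, and non-normal tails. Synthetic
validation shows the machinery is correct, not that the published
constants generalise.

`split_cohort` reserves `floor((1 − train_fraction) · n)` records for
evaluation (0.70 on 145 gives the published 102/43 allocation); stratified
splitting allocates evaluation slots per level by largest-remainder
rounding, emulating a level-balanced random draw, with ties broken toward
lower levels for determinism.

## Evaluation statistics

Percent agreement is `100 · matches / n` reported to two decimals. The
confusion chart is 4×4 (rows: threshold classification; columns: voted
diagnosis) with TPR/FNR per row and PPV/FDR per column; rates on empty
rows or columns are reported as missing, never zero. Sample SDs use the
n−1 denominator. Normality is Shapiro–Wilk; associations are Spearman's
rho (average ranks on ties; the level treated as an integer 0–3 score) and
Pearson's r, two-sided p-values via the standard approximations with an
exact permutation method below n = 20. A constant-valued parameter yields
a flagged row with missing statistics. The published correlation table's
numeric values require the unpublished raw cohort; the package reproduces
the table's structure and validates the statistics on synthetic data.

## Problem sizes and numerical choices

Test and validation workloads are sized for tight, stable statistical
bands: distributional recovery uses 5,000–10,000 records per level
(tolerance 3 standard errors), the truncated-normal mean check 10,000
records against the closed-form mean (0.2° band), low-noise fitting 300
records per level with SDs scaled by 0.1, and the discriminant symmetry
check 8,000 points per group so the 0.05° midline band sits beyond two
sigma of the slope's sampling noise. The candidate-generation oracle runs
exhaustively (8 models × 701 FNTA values × a 2,001-point parameter grid).
All file outputs embed provenance comments (command, seed, bank digest);
angles are serialised at full precision.
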