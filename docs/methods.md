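# Methods

`equipoise` analyzes agreement studies of patient-management decisions: the
same portfolio of standardized cases is submitted to many clinicians (and
optionally to the same clinicians twice), and the reproducibility of their
categorical management choices is used as an empirical measure of clinical
uncertainty — the precondition for randomizing patients between rival
options. This note documents the statistical procedures, the generative
model behind the synthetic data, the numerical conventions, and the
limitations.

## Data model

A study is a long-format table of decisions: rater x case x session x
question -> choice, with optional per-decision confidence and
trial-proposal fields. Validation enforces one record per (rater, case,
session, question), sessions in {1, 2}, and non-empty choice labels. The
category set Y defaults to the observed choices but can be declared
explicitly; declared-but-unobserved options are retained because the
questionnaire's option list, not the observed answers, defines the space
over which chance agreement operates. Identifiers are opaque strings. A
study may carry several questions; every analysis operates on one
(question, session) slice.

## Agreement statistics

For case *i* with *n_i* raters and *n_ij* votes in category *j*, pairwise
agreement is

    P_i = (sum_j n_ij^2 - n_i) / (n_i (n_i - 1)),

the probability that two randomly chosen raters of that case agree.
Percent agreement is the unweighted mean of the P_i. Fleiss' kappa uses

    P-bar = mean_i P_i,   p_j = sum_i n_ij / sum_i n_i,
    P-bar_e = sum_j p_j^2,   kappa = (P-bar - P-bar_e) / (1 - P-bar_e).

The implementation generalizes the classical equal-*n* formula to variable
raters per case, since real surveys have missing responses: P_i is computed
per case from whatever raters responded, and the pooled p_j weight each
case by its number of assignments. Cases with fewer than two raters carry
no pairwise information and are excluded with a logged count. Missing
responses are excluded, never imputed. With equal *n_i* the statistic is
exactly the textbook Fleiss kappa (verified against
`statsmodels.stats.inter_rater.fleiss_kappa` in the test suite); with two
raters and complete data it coincides with Scott's pi.

Cohen's kappa compares two raters over the intersection of their cases,
with chance agreement from the product of their marginal category
proportions. The same routine, applied to one rater's two sessions, is the
intra-rater self-kappa. PABAK (2 p_o - 1, binary questions only) is
provided because kappa-type statistics are sensitive to decision
prevalence and a deliberately balanced portfolio changes prevalence by
construction.

Kappa is undefined when chance agreement reaches 1 (all assignments in one
category); this is detected with a tolerance of 1e-12 and raised as a
degeneracy error rather than returning 0/0 noise.

### Confidence intervals

Percentile bootstrap, resampling cases with replacement (raters fixed),
default B = 2000 at the 95% level, seeded and fully deterministic. Cases
are the exchangeable sampling unit here: the portfolio is a sample from a
conceptual spectrum of presentations, while the rater panel is treated as
the fixed population of interest. Percentile rather than BCa: transparent,
adequate at portfolio scale, and free of the jackknife machinery BCa needs
on small Z. Bootstrap replicates whose resampled table is degenerate are
dropped and counted (warned above 1%).

### Interpretation

Landis-Koch verbal bands with upper ends closed: below 0 poor, [0, 0.20]
slight, (0.20, 0.40] fair, (0.40, 0.60] moderate, (0.60, 0.80]
substantial, (0.80, 1] almost perfect. The package treats 0.6 as the lower
bound of substantial agreement, so `below_substantial` is true at
kappa = 0.6 exactly: a study sitting on the boundary has not demonstrated
substantial agreement. The uncertainty index inverts the scale into a
trial-recruitment-potential label (poor/slight -> high, fair/moderate ->
intermediate, substantial/almost perfect -> low). This three-level mapping
is a convention of this package — the direction (less agreement, more
recruitment potential) is principled; the cut points are configurable and
reports label them as such.

### Subgroups

Subgroup analyses partition raters by a roster field (specialty,
experience, center) or cases by a portfolio field (control class or any
covariate); each subgroup is re-analyzed in isolation, including its own
pooled p_j. Subgroups too small to estimate are returned with an explicit
`insufficient` status. Estimable subgroups with fewer than 30 analyzed
cases — the lower end of the recommended portfolio size — carry a wide-CI
caution flag, since subgrouping reduces the observations and the intervals
are irremediably wide at that scale.

## Intra-rater analysis

Two-session records are paired per (rater, case); unpaired observations
are excluded and counted. Per rater: the fraction of cases with a changed
decision and the self-kappa. Per case: the fraction of paired raters who
changed. The case-level summary counts cases where that fraction reaches a
threshold (default 25%) and renders the sentence "at least k/n clinicians
(p%) changed their own decision in q% (m/Z) of cases", where k is the
ceiling of threshold x n — the minimum rater count implied by "at least".
Percentages are rounded to one decimal, halves away from zero (so 7/41
renders as 17.1%). Cases with fewer than 2 paired raters are excluded from
the case-level count with a log message.

## Disagreement profiles

The per-case disagreement measure is the minority share, 1 minus the modal
vote proportion: 0 when unanimous, bounded by (|Y|-1)/|Y|, equal to 0.5 at
an even binary split. An exact modal tie is reported as a tie with the
majority undefined — maximal disagreement, not an arbitrary winner. The
portfolio-level summary counts cases whose minority share reaches a
threshold (default 1/3, so the standard sentence reads "at least 1/3 of
physicians disagreed in ... of cases"). Equipoise candidates are the cases
passing the minority-share threshold and, when a trial-proposal question
exists, a minimum trial-vote proportion; they are ranked by descending
minority share. The vote-bar ordering (descending target-category
proportion, ties by case id) produces the stacked-bar table with
near-unanimous "for" cases at the top and "against" at the bottom.

The trial-concordance analysis is deliberately minimal and flagged as
exploratory in reports: Spearman rank correlation between per-case
minority share and per-case trial-vote proportion, with a seeded
permutation p-value (default 999 permutations, two-sided on |rho|) rather
than a parametric test — Z is small and no distributional claim is
warranted. Zero variance in either variable is reported as "undefined",
not as rho = 0.

## Generative model (synthetic studies)

No generative model is implied by the agreement statistics themselves; the
simulator exists to test the pipeline and to plan studies, and is the
minimal structure producing the phenomena such studies exhibit:

- case propensity theta_z ~ Beta(a_c, b_c) per control class; defaults
  Beta(14, 2) for positive controls (mean 0.875, occasionally contested),
  Beta(2, 2) for the grey zone (centered on 1/2, wide), Beta(2, 14) for
  negative controls;
- rater bias b_x ~ Normal(0, sigma^2) on the log-odds scale, default
  sigma = 0.6, spreading individual decision rates widely around the case
  propensity while keeping group-level rates similar;
- decision ~ Bernoulli(inverse-logit(logit(theta_z) + b_x));
- session 2 copies session 1 with probability 1 - rho, else is redrawn
  from the same Bernoulli; rho is the per-decision instability (default
  0.35 in the standard fixture — substantial but not majority instability
  on contested cases, negligible on near-unanimous ones, since a redraw
  only changes the answer with probability 2p(1-p));
- trial votes ~ Bernoulli(inverse-logit(logit(0.1) + 4.5 u_z)) with
  u_z = 4 theta_z (1 - theta_z): about 10% support at zero case
  uncertainty rising to roughly 90% at maximal uncertainty.

Portfolio composition uses largest-remainder rounding with the
deterministic tie order positive > grey > negative, so 41 cases at equal
thirds give (14, 14, 13).

The standard fixture emulates a thrombectomy-style study: 41 cases, 86
raters in two specialty blocks (60 + 26), both a binary intervention
question and a trial-proposal question, and a 20-rater subset rated twice.
Because overall uncertainty is the fixture's defining property, generation
verifies that global Fleiss kappa is below 0.6 and redraws from a derived
seed (with a warning) in the rare case it is not. At these parameters the
fixture's kappa lands around 0.35-0.50 across seeds.

What the simulator does not emulate: covariate-driven decision rules (case
difficulty is a single latent propensity), order and fatigue effects
between sessions (independence is assumed, as a shuffled re-presentation
is designed to achieve), non-response patterns correlated with difficulty,
and multi-category option sets (the binary pathway is the tested default).
Passing tests on synthetic data therefore validate the statistical
machinery and its wiring, not the realism of any clinical scenario.

The simulator is never fitted to observed data; it is for design and
testing only.

## Study design tools

The informativeness rule of thumb requires at least 10 raters and a 30-50
case portfolio; larger portfolios pass with a respondent-burden warning
rather than failing. The power tool replaces closed-form kappa sample-size
formulas with simulation: for each (raters, cases) grid point it draws
replicate studies from a specified generative truth and reports the
kappa-estimate distribution, the mean percentile-bootstrap CI half-width
(at a reduced B, recorded in the output), and the probability that the CI
upper bound stays below 0.6 — the operational version of "precise enough
to demonstrate the lack of substantial agreement". Raw Monte-Carlo values
are reported without smoothing. Default problem sizes (100-200 replicates,
B = 200 inside the grid) keep a desk-scale laptop run under a minute;
both are parameters.

## Reporting

`build_report` runs the full stack and emits a 13-item GRRAS-adapted
checklist (items unfillable from config metadata or computed results are
marked `missing`, never dropped), the results block, plain-language
sentences, and provenance (package version, seed, config). JSON is the
machine contract; Markdown is derived from it. Figure-ready exports are
tidy CSVs (per-rater rates, ordered vote-bar proportions, kappa bars with
CIs) rather than rendered images. All analyses are seed-deterministic end
to end: rerunning `analyze` on the same inputs reproduces byte-identical
outputs.

## Numerical conventions

- Degeneracy tolerance 1e-12 throughout (chance agreement, proportion
  sums, threshold comparisons `>= t - 1e-12` so exact boundary cases
  qualify).
- Percent rounding: one decimal, half away from zero.
- Deterministic orderings everywhere a sequence is emitted: CSV rows by
  (case, rater, session, question); candidates by (-minority share,
  case id); subgroup levels lexicographic.
- Seeds: a single user seed; internal child seeds derived via
  `numpy.random.SeedSequence`, kept below 2^31.

## Known limitations

- No weighted kappa for ordinal options, no Krippendorff's alpha, no
  latent-class agreement models; decisions are treated as nominal.
- Non-responses are absent records, not a "cannot decide" category, unless
  the user declares such a category explicitly.
- The bootstrap resamples cases only; rater-level resampling (two-way
  uncertainty) is not implemented.
- Confidence ratings are carried through I/O but not yet analyzed.
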