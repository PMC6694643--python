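# Methods

## The liability-threshold model

All estimators in `famline` assume Falconer's threshold model: each person
carries an unobserved liability L ~ N(0, 1); the trait is expressed iff
L > t, where the threshold t is fixed by the population prevalence K
through Φ(t) = 1 − K. Two summaries of a group with trait prevalence q
recur throughout:

* the **threshold deviate** x = Φ⁻¹(1 − q), computed via the upper-tail
  quantile (`scipy.stats.norm.isf`), and
* the **mean deviate of the affected** a = φ(x)/q, the mean of the upper
  truncated standard normal.

Exact computation is the default. A second, verbatim table-lookup path
exists because historical analyses read (x, a) from coarse printed
"simplified Falconer tables"; those entries can be off by what corresponds
to one or two percentage points of prevalence (e.g. a printed x = 0.681 at
q = 26.43 % actually corresponds to q ≈ 24.8 %). The lookup path
reproduces published arithmetic bit-for-bit and deliberately refuses to
interpolate, so that table-vs-theory discrepancies stay visible instead of
being smoothed away.

## Falconer heritability

For a relative class with genetic similarity coefficient r (½, ¼, ⅛ for
first/second/third degree), the liability of a relative of a proband
regresses on the proband's liability with slope b = r·h². Estimating b
from the case-relative and control-relative prevalences gives

    b = p₀ (x₀ − x₁) / a₀,   p₀ = 1 − q₀.

Using the *control relatives* (rather than the population) as the baseline
matches a screened-control design: control probands are sampled as
unaffected, so q₀ < K and the formula self-corrects for that by taking
(x₀, a₀) at q₀.

Two multiplier conventions convert b to h²:

* `one_over_r` (default): h² = b/r, the formula as stated;
* `paper_fixed_2`: h² = 2b at every degree. Published analyses sometimes
  apply the first-degree doubling to all degrees; both conventions coincide
  at r = ½, and at r = ¼ (⅛) the literal 1/r multiplier gives 2× (4×) the
  fixed-doubling value.

The standard error is the classical approximation
SE = (1/r)·√(p₁/(A·a₁²)·(p₀/a₀)²) with A the number of case probands, and
the CI is the symmetric normal interval h² ± 1.96·SE. A is user-settable
(its defining count is ambiguous in older texts); defaults use the proband
count. Estimates outside [0, 1] are *flagged, never clamped*: truncation
would hide model misfit.

Deterministic accuracy of the estimator under the exact conditional model
was checked by quadrature: for K = 0.2322 and true h² ∈ {0.2, 0.5, 0.8}
the population-level estimate differs from the truth by at most ≈ 0.011
(largest at high h², where the linear regression approximation of the
threshold model is weakest).

## Modified-Weinberg segregation ratio

Families enter a study through affected probands, which inflates
within-sibship case counts. The modified-Weinberg estimator removes
single-case households (which can only have entered through their proband):

    p = (R − J) / (T − J).

Two SE conventions are implemented because the classical formula circulates
with two different exponents of (T − J) in its first term:

* `as_computed` (default): (R−J)(T−R)/(T−J)³ + 2Q(T−R)²/(T−J)⁴ — the
  binomial-variance-style form that published worked examples actually
  evaluate;
* `as_printed_formula`: (R−J)(T−R)/(T−J)² + 2Q(T−R)²/(T−J)⁴ — the form as
  it is usually typeset. On realistic counts this term dominates and gives
  an SE more than an order of magnitude larger; it is retained so users can
  see exactly what the printed formula implies.

Classification compares the CI with the single-gene expectations 0.50
(dominant) and 0.25 (recessive): a call is made only when exactly one of
{dominant in CI, recessive in CI, CI entirely below 0.25} matches;
anything else is `inconclusive`.

## The bundled reference study

The package ships the aggregate counts of a published 1:1 matched
case-control family study of essential hypertension (342 probands per arm,
8599 relatives): class-level prevalence counts, sibship totals
T = 2013, R = 891, J = 580 over 684 households with the published
two-case count Q = 163, and the per-prevalence (x, a) lookups used in the
original analysis. Three integrity notes:

* the published Q = 163 is inconsistent with J = 580 over 684 households
  (J + Q exceeds the household count) and equals the count of size-2
  households; it is carried verbatim as a table-level override rather than
  re-derived, since the SE arithmetic it feeds is otherwise reproduced
  exactly;
* the per-size sibship breakdown is only partially legible in the source;
  rows for sizes 1 and 2 are as published and the remaining rows are
  synthetic fillers that preserve the published totals (all estimators
  consume totals only);
* the published per-degree heritability SEs (≈ 0.0004) are not derivable
  from the stated SE formula under any plausible A and are treated as a
  printing error; the formula value (≈ 0.049 at the first degree) is
  reported instead. Likewise the published per-stratum chi-square
  statistics are not reproducible from the printed 2×2 counts by any
  standard test, so a standard Pearson chi-square is shipped and the
  printed values are not asserted anywhere.

## The synthetic-data generator

`simulate_study` emulates the matched design the estimators assume:
case probands drawn from the liability distribution truncated above t,
control probands truncated below t (screened unaffected, mirroring typical
control definitions), and relatives correlated with the proband through
ρ = r·h². Defaults are the reference study's conditions: K = 0.2322, 342
families per arm, and a 12-relative family (2 parents, 2 siblings,
1 offspring, 4 second-degree, 3 third-degree — matching the surveyed mean
family sizes of ≈ 4.95/4.54/3.08 by degree).

Two dependence models:

* `conditional_on_proband` (default) — relatives independent given the
  proband, each N(ρ·L_p, 1 − ρ²). This is exactly the model under which
  the Falconer regression is unbiased, so recovery tests are sharp.
* `full_mvn` — one joint draw per family with correlation r_ij·h², where
  r_ij = 2·(kinship) comes from a pedigree expanded from the class counts
  with latent founders (grandparents, spouses, cousins' parents), kinship
  computed by the standard recursion. Siblings are then mutually
  correlated, not just correlated with the proband.

One root `SeedSequence` spawns an independent substream per family, so
changing the structure or family counts never shifts another family's
draws; output is byte-identical for equal configs.

`expected_relative_prevalence` is the closed-form companion: 1-D
quadrature of Φ((ρl − t)/√(1 − ρ²)) against the truncated proband density.
It cross-checks the simulator in the tests and handles the ρ ∈ {0, 1}
boundaries exactly.

`simulate_sibships` draws exchangeably-correlated sibships (pairwise
liability correlation h²/2) and applies either *complete* ascertainment
(each affected sibling independently detected with probability π; the
sibship enters iff at least one is detected) or *single* ascertainment (the
π → 0 limit: entry probability proportional to the number of affected,
implemented by acceptance sampling with probability k/size).

What the generator does **not** model: shared-environment variance,
assortative mating, age/sex structure and age-of-onset, variable family
sizes, and misdiagnosis. Passing recovery tests therefore show correctness
of the estimators *under the liability-threshold sampling model*, not
robustness to these real-data features; in particular shared environment
would inflate h² in real data exactly as it does in the classical method.

## Problem sizes and numerical choices

* Parameter-recovery tests use 2×10⁴ families per arm (first-degree
  structure), where the Monte-Carlo SE of ĥ² is ≈ 0.01 and the ±0.05
  recovery band is comfortably testable; enumeration and quadrature
  cross-checks use 4 Monte-Carlo SDs as tolerance.
* Prevalences are exact `Fraction`s internally; rounding (2 dp for
  percentages, 3 dp for ratios) happens only at the presentation layer.
* Table lookups key prevalences rounded to 9 dp; the pipeline rounds
  observed prevalences to 4 dp before a table lookup, matching how printed
  tables are keyed.
* The deviate oracle in the tests is the standard library's
  `statistics.NormalDist` — an inverse-CDF implementation independent of
  the scipy routine the package uses — with agreement required to 1e-10.
* Degenerate inputs fail loudly: empty strata carry `q = None` (never a
  silent 0/0), T = J makes the segregation ratio undefined, zero-margin
  2×2 tables raise, and q ∉ (0, 1) is a domain error everywhere.
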