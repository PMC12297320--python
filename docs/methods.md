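# Methods

## Rule-based genetic subtyping

The classifier assigns one of seven subtypes from a streamlined targeted
panel — 35 genes across six defining feature sets plus three FISH
rearrangements (BCL2, BCL6, MYC):

| subtype  | defining mutations | FISH |
|----------|--------------------|------|
| MCD-like | BTG1, CD79B, IRF4, MYD88, MPEG1, PIM1, PRDM1, TBL1XR1 | — |
| BN2-like | BTG2, CD70, CCND3, DTX1, NOTCH2, TNFAIP3 | BCL6 rearrangement |
| N1-like  | NOTCH1 | — |
| TP53-mutant | TP53 | — |
| EZB-like | ARID1A, B2M, CIITA, CREBBP, EZH2, EP300, FAS, GNA13, KMT2D, STAT6, TNFRSF14 | BCL2 rearrangement |
| ST2-like | DDX3X, DUSP2, IRF8, SGK1, SOCS1, STAT3, TET2, ZFP36L1 | — |

Decision procedure: (1) any retained nonsynonymous TP53 call forces
TP53-mutant, regardless of all other evidence (mirroring how TP53 calls
are excluded before cross-algorithm concordance comparisons); (2)
otherwise the remaining five rules are scored by matched-feature count
and the largest count wins; (3) equal counts break by a fixed,
configurable priority order, default `TP53 > N1 > MCD > BN2 > EZB > ST2`
(an aggressiveness ordering: the poorer-prognosis classes outrank the
more indolent ones); (4) no match at all is NOS. Every rule needs one
matched feature by default — the source scheme publishes no per-subtype
count threshold, so the count-then-priority scheme here is a documented
stand-in for the original (unpublished) decision hierarchy, and the tie
order is configurable precisely because it is a design choice, not an
established fact. Ties are rare in practice (most profiles match a
single rule) but every multi-candidate call records all candidates.

Missing FISH is tri-valued (`True`/`False`/`None`) and a rule requiring a
rearrangement can never fire on `None` — conservative, because an
unassayed translocation should not create evidence. MYC rearrangement is
carried in the data model but participates in no default rule; the
strict-EZB variant (off by default) additionally demands the BCL2
rearrangement for an EZB-like call. "Pathogenic TP53 variant" is
operationalized as any retained nonsynonymous TP53 call — no
pathogenicity database is consulted. Gene aliasing is a non-goal:
symbols are uppercased verbatim (HIST1H1E stays HIST1H1E).

## Simon two-stage design

Exact enumeration over all `(r1, n1, r, n)` with `n ≤ n_max` (default
120). For each `(n1, r1, n)` the rejection probability is a decreasing
function of `r`, so the smallest `r` meeting the one-sided α constraint
is selected and the candidate kept when its power clears `1 − β`;
feasible candidates are ranked by expected sample size under `H0`
(optimal) or by `n` (minimax), with deterministic tie-breaks (smaller
`n`, then `n1`, then `r1`). Stage-1 stopping is futility-only — the
standard Simon formulation. The convention throughout is *stop iff
responses ≤ r1*, *reject iff total responses > r*.

The enumeration is validated against classic published design tables
(optimal and minimax) at several `(p0, p1)` pairs, and every returned
design re-verifies against a brute-force enumeration of all `(x1, x2)`
outcome pairs.

For the trial scenario built into the demo and acceptance script —
`H0: CR = 36%` vs `H1: CR = 56%`, one-sided α = 0.05 — the package uses
power 0.90 as the operative design parameter: the enumeration then
yields `r1/n1 = 9/23` and `r/n = 30/68`, i.e. exactly the published
stage-1 size (23) and evaluable total (68, inflated to 76 enrollment at
the 10% anticipated dropout rate via `⌈68/0.9⌉`). No 80%-power design
reproduces those sample sizes (the α = 0.05, β = 0.20 optimal design is
`6/15, 23/51`), so the package treats 90% as the trial's actual powering
and documents the choice here. Under the stop-if-≤9 convention the
smallest stage-1 response count that continues to stage 2 is 10.

## Endpoint statistics

* **Response rates**: exact fractions over the intent-to-treat
  denominator (patients with missing assessments stay in the
  denominator). Intervals default to Clopper–Pearson (exact beta
  quantiles, via `statsmodels`), with Wald as an option. Published
  trial intervals in this setting often match no textbook method at the
  printed precision, so downstream comparisons should rely on the point
  estimates.
* **Kaplan–Meier**: product-limit with Greenwood variance; curves step
  only at observed event times and are right-continuous, so a "2-year
  rate" is the step value at t = 24 months. When the curve reaches zero
  the Greenwood term degenerates and the standard error is reported
  as 0.
* **Log-rank**: the two-sample score with hypergeometric variance; with
  zero pooled events the statistic is 0 and p = 1 by convention. At a
  single shared event time the statistic equals `(N−1)/N` times the
  Pearson 2×2 chi-square — checked numerically in the tests.
* **Cox (univariate, binary covariate)**: Newton–Raphson on the Breslow
  partial likelihood (score tolerance 1e-8, damped first steps).
  Breslow is the simplest tie-handling consistent with the exact
  likelihood; Efron is deferred, and the test suite compares against an
  independent fitter only on tie-free data where the two coincide.
  Monotone likelihoods (all events on one covariate arm) are detected
  when the estimate escapes |β| > 15; a bounded estimate is returned
  with `converged=False` and a runtime warning rather than an exception.
* **Safety**: per-event any-grade and grade≥3 counts and rates, per arm
  and overall, counting each patient once per event label at their worst
  grade. Efficacy percentages are conventionally read at 1 decimal
  place and safety at 0, matching trial-report practice.

## Synthetic cohort generator

The generator emulates the published cohort's statistical structure so
every pipeline stage can be exercised without access to the deposited
patient-level data.

* **Gene frequencies** (marginal mode): the 25 recurrently mutated genes
  with their printed frequencies (PIM1 0.43, MYD88 0.36, KMT2D 0.26,
  BTG2 0.25, CD79B 0.24, TMSB4X 0.24, BTG1 0.21, … CD58 0.11); all other
  panel genes at a 0.05 background. Genes mutate independently.
* **Subtype prevalences** (subtype-first mode): MCD-like 25%, BN2-like
  20%, N1-like 5%, NOS 34%, TP53-mutant 12%, EZB-like 3%, ST2-like 1%.
  The strict variant guarantees classifier recovery: each patient gets
  ≥1 uniformly chosen defining feature of the drawn subtype, extra
  features only from the *same* rule (at their marginal frequencies),
  passenger mutations only from genes outside every defining set, TP53
  excluded unless the label is TP53-mutant, and BCL2/BCL6 flags never
  raised for a competing rule (they may still be missing rather than
  negative). Label recovery is therefore exact by construction, and the
  round-trip is asserted at cohort scale in the tests.
* **Responses**: drawn per assigned regimen from the printed per-arm
  counts — zanubrutinib 18 CR / 9 PR of 34, lenalidomide 17 CR / 6 PR of
  30, decitabine 6 CR of 9, chidamide 2/2 in remission, tofacitinib 1
  PD. Cells the source tables leave unreported (the SD/PD split within
  arms; two protocol deviators with unassessed responses) are folded
  into PD so each arm's distribution sums to 1; the choice is recorded
  in every generated manifest.
* **Survival**: PFS is exponential with rate `λ1 = −ln(0.693)/24`
  (anchored to the 69.3% 2-year PFS landmark); OS = PFS plus an
  independent exponential tail whose rate is solved numerically so the
  hypoexponential marginal hits the 88.3% 2-year OS anchor. This
  enforces OS ≥ PFS pathwise. Administrative censoring is uniform over
  (6, 33) months — median 19.5, matching the reported median follow-up
  under a ~27-month accrual window. Responses and survival times are
  drawn independently given the arm; the response–progression coupling
  of real data is deliberately not modeled.
* **Covariates**: age ~ round(N(58, 12²)) clipped to 18–75, refractory
  51%, IPI low/intermediate/high 16/55/29%, bulky disease 16% — the
  published baseline table's margins, independent of genotype.
* **Determinism**: one root seed feeds fixed-index named substreams
  (labels, genes, FISH, variant classes, covariates, response, survival,
  censoring), so regenerating one table never perturbs another, and
  identical configs produce byte-identical files.

What passing tests on these cohorts shows: the pipeline's logic
(classification, arithmetic, estimators) is correct at the study's
frequencies and scale. What it does not show: robustness to co-mutation
correlation (marginal independence is an acknowledged simplification of
the real oncoprint), to genotype-dependent survival, or to the
response-conditional censoring patterns of real trials.

## Problem sizes and numerical choices

Calibration checks run at n = 10,000 patients (frequencies, prevalences;
3-sigma binomial bands) and n = 20,000 for the survival-anchor check
(±1.5 percentage points); the classifier round-trip is asserted at
n = 1,000 and the full-suite versions at a few hundred. Binomial tail
probabilities go through scipy's stable implementations; the design
search prunes on the incumbent's expected sample size (`EN0 ≥ n1`) and,
for minimax, on the incumbent's `n` — both prunings are exact, not
heuristic. Dropout inflation uses the smallest integer `m` with
`m(1 − d) ≥ n`, guarded against floating-point edge cases.

## Known limitations

* The true subtyping hierarchy and per-class thresholds of the original
  algorithm are unpublished; the count-then-priority scheme is this
  package's documented surrogate, and concordance with other labelings
  should be assessed with `compare_labelings` (which, like published
  concordance analyses, drops NOS and excluded classes from the
  denominator).
* Only univariate Cox with a single binary covariate is implemented —
  the package's prognostic-factor interface — not multivariable
  modeling or proportional-hazards diagnostics.
* Exponential survival is single-parameter by design (identifiable from
  one landmark anchor); Weibull shape is deferred.
* VCF/full-MAF parsing, variant annotation, and pathogenicity scoring
  are out of scope; inputs are pre-called, pre-annotated MAF-lite rows.
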