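# lymphtrial

Analytics for genetic-subtype-guided salvage immunochemotherapy trials in
relapsed/refractory diffuse large B-cell lymphoma (R/R DLBCL), aimed at
trial statisticians and computational hematopathologists.

Modern DLBCL trials stratify patients by *genetic subtype*: a targeted
mutation panel plus BCL2/BCL6/MYC FISH assigns each tumor to one of seven
classes (MCD-like, BN2-like, N1-like, TP53-mutant, EZB-like, ST2-like, or
NOS), and each class maps to an R-ICE backbone plus a subtype-matched
targeted agent (zanubrutinib, lenalidomide, decitabine, chidamide, or
tofacitinib). This package implements that pipeline end to end:

* **`lymphtrial.io`** — validated TSV readers/writers for mutation calls
  (MAF-lite), tri-valued FISH flags, and clinical outcome tables.
* **`lymphtrial.lymphplex`** — the rule-based seven-subtype classifier
  (TP53 precedence, count-then-priority resolution, conservative handling
  of missing FISH) and the fixed subtype→regimen map.
* **`lymphtrial.design`** — Simon two-stage phase-II designs by exact
  binomial enumeration (optimal and minimax), operating characteristics,
  stage-1 futility decisions, and dropout inflation.
* **`lymphtrial.endpoints`** — response rates with exact
  (Clopper–Pearson) intervals, Kaplan–Meier with Greenwood variance,
  two-sample log-rank, univariate Cox regression (Breslow partial
  likelihood, Newton–Raphson), and CTCAE safety tabulation.
* **`lymphtrial.simulate`** — a seeded synthetic-cohort generator
  calibrated to the published cohort (gene frequencies, subtype
  prevalences, per-arm response distributions, exponential survival
  anchored at 2-year PFS/OS landmarks).

## The statistics at the core

**Simon two-stage design.** Enroll `n1` patients; stop for futility if
responses `X1 ≤ r1`; otherwise accrue to `n` and reject `H0: p = p0` when
total responses exceed `r`. The type-I error and power are exact binomial
sums,

    α  = Σ_{x1 > r1} b(x1; n1, p0) · P(X2 > r − x1; n − n1, p0)
    1−β = same expression at p1,

and the search enumerates all `(r1, n1, r, n)` with `n ≤ n_max`, keeping
the feasible design minimizing the expected sample size under `H0`
(optimal) or the maximum sample size (minimax). The enumeration reproduces
the classic published design tables exactly.

**Endpoints.** CR rate and ORR are exact fractions of the intent-to-treat
denominator with Clopper–Pearson intervals; survival uses the product-limit
estimator `S(t) = Π (1 − d_j/n_j)` with Greenwood standard errors, the
log-rank score with hypergeometric variance, and a one-covariate Cox model
`h(t|x) = h0(t) e^{βx}` maximized by Newton–Raphson on the Breslow partial
likelihood.

## Worked example

```python
from lymphtrial import (DesignSpec, simon_search, classify_patient,
                        response_rates)
from lymphtrial.io import FishStatus

design = simon_search(DesignSpec(p0=0.36, p1=0.56, alpha=0.05, beta=0.10))
print(design.n1, design.r1, design.n, design.r)
# 23 9 68 30   -> stage 1: 23 patients, stop if <=9 CRs; total 68, reject if >30

call = classify_patient({"MYD88", "PIM1", "NOTCH2"},
                        FishStatus("P1", False, False, False))
print(call.subtype, call.regimen)
# MCD_like R_ICE_zanubrutinib   (2 MCD features outvote 1 BN2 feature)
```

The command-line pipeline runs the same machinery:

```bash
lymphtrial demo --seed 1 --n 76 --out run/
```

which simulates a 76-patient cohort, classifies it, computes the trial
design, and writes `subtype_calls.tsv`, `design.json` and
`endpoints.json` (response rates plus 24-month PFS/OS read-outs, overall
and per arm).

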