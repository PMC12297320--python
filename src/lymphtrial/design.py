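"""Simon two-stage phase-II designs by exact binomial enumeration.

A Simon two-stage design enrolls ``n1`` evaluable patients, stops for
futility if at most ``r1`` respond, otherwise accrues to ``n`` total and
rejects the null response rate ``p0`` in favour of the alternative ``p1``
when the total number of responders exceeds ``r``.  The *optimal* design
minimises the expected sample size under the null; the *minimax* design
minimises the maximum sample size.  Both are found here by exhaustive
enumeration of ``(r1, n1, r, n)`` with exact binomial probabilities, the
same computation phase-II sample-size software performs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

__all__ = [
    "DesignSpec",
    "TwoStageDesign",
    "InfeasibleDesignError",
    "binomial_tail",
    "design_oc",
    "simon_search",
    "stage1_decision",
    "inflate_for_dropout",
]


class InfeasibleDesignError(ValueError):
    """No design within the search bound satisfies both error constraints."""


@dataclass(frozen=True)
class DesignSpec:
    """Hypotheses and error bounds for a single-arm binary-endpoint design.

    Parameters
    ----------
    p0
        Null (uninteresting) response probability.
    p1
        Alternative response probability the trial should detect; ``p1 > p0``.
    alpha
        One-sided type-I error bound.
    beta
        Type-II error bound (power target is ``1 - beta``).
    n_max
        Largest total sample size enumerated.
    """

    p0: float
    p1: float
    alpha: float = 0.05
    beta: float = 0.20
    n_max: int = 120

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 < self.p1 < 1.0):
            raise ValueError(
                f"require 0 < p0 < p1 < 1, got p0={self.p0}, p1={self.p1}"
            )
        if not (0.0 < self.alpha < 0.5 and 0.0 < self.beta < 0.5):
            raise ValueError(
                f"require alpha, beta in (0, 0.5), got alpha={self.alpha}, beta={self.beta}"
            )
        if self.n_max < 2:
            raise ValueError("n_max must be at least 2")


@dataclass(frozen=True)
class TwoStageDesign:
    """A concrete two-stage design with its attained operating characteristics.

    ``r1`` is the stage-1 futility bound (stop if responses <= r1) and ``r``
    the final bound (reject H0 if total responses > r).
    """

    n1: int
    r1: int
    n: int
    r: int
    attained_alpha: float
    attained_power: float
    pet0: float
    en0: float
    criterion: str = "optimal"

    def __post_init__(self) -> None:
        if not (0 <= self.r1 < self.n1 <= self.n):
            raise ValueError(f"require 0 <= r1 < n1 <= n, got r1={self.r1}, n1={self.n1}, n={self.n}")
        if not (self.r1 <= self.r <= self.n):
            raise ValueError(f"require r1 <= r <= n, got r={self.r}")

    def to_dict(self) -> dict:
        return {
            "n1": self.n1,
            "r1": self.r1,
            "n": self.n,
            "r": self.r,
            "attained_alpha": self.attained_alpha,
            "attained_power": self.attained_power,
            "pet0": self.pet0,
            "en0": self.en0,
            "criterion": self.criterion,
        }


def binomial_tail(k: int, n: int, p: float) -> float:
    """Exact lower binomial tail ``P(X <= k)`` for ``X ~ Binomial(n, p)``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    return float(binom.cdf(k, n, p))


def design_oc(design: TwoStageDesign, p: float) -> dict:
    """Operating characteristics of ``design`` at true response probability ``p``.

    Returns ``pet`` (probability of early termination after stage 1),
    ``reject_prob`` (probability of declaring efficacy) and ``expected_n``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    n1, r1, n, r = design.n1, design.r1, design.n, design.r
    n2 = n - n1
    pet = float(binom.cdf(r1, n1, p))
    x1 = np.arange(r1 + 1, n1 + 1)
    pmf1 = binom.pmf(x1, n1, p)
    # stage-2 survival: P(X2 > r - x1); degenerate n2 = 0 handled by sf at k<0 -> 1
    if n2 == 0:
        tail2 = (x1 > r).astype(float)
    else:
        tail2 = binom.sf(r - x1, n2, p)
    reject = float(np.sum(pmf1 * tail2))
    expected_n = n1 + (1.0 - pet) * n2
    return {"pet": pet, "reject_prob": reject, "expected_n": expected_n}


def _stage2_sf(n2: int, p: float, lo: int, hi: int) -> np.ndarray:
    """P(X2 > k) for k = lo..hi with out-of-range k clipped exactly."""
    ks = np.arange(lo, hi + 1)
    if n2 == 0:
        return (ks < 0).astype(float)
    out = binom.sf(np.clip(ks, -1, n2), n2, p)
    out[ks < 0] = 1.0
    out[ks >= n2] = 0.0
    return out


def simon_search(spec: DesignSpec, criterion: str = "optimal") -> TwoStageDesign:
    """Find the Simon two-stage design for ``spec`` by exhaustive enumeration.

    For every admissible ``(n1, r1, n)`` the smallest final bound ``r``
    meeting the type-I constraint is located (rejection probability is
    decreasing in ``r``), and the candidate is kept when its power clears
    ``1 - beta``.  ``criterion='optimal'`` minimises the expected sample
    size under ``p0``; ``'minimax'`` minimises ``n`` first.  Ties break
    deterministically toward smaller ``n``, then ``n1``, then ``r1``.
    """
    if criterion not in ("optimal", "minimax"):
        raise ValueError(f"criterion must be 'optimal' or 'minimax', got {criterion!r}")
    p0, p1, alpha, beta = spec.p0, spec.p1, spec.alpha, spec.beta

    best: tuple | None = None  # sort key -> design params
    # per-n1 stage-1 pmfs/cdfs, cached across n
    pmf0_c: dict[int, np.ndarray] = {}
    pmf1_c: dict[int, np.ndarray] = {}
    cdf0_c: dict[int, np.ndarray] = {}
    cdf1_c: dict[int, np.ndarray] = {}

    for n in range(2, spec.n_max + 1):
        # the minimax key is ordered by n first: once any feasible design
        # exists, larger totals cannot improve it
        if criterion == "minimax" and best is not None and n > best[0][0]:
            break
        for n1 in range(1, n):
            # en0 >= n1 always, so no design with n1 beyond the incumbent's
            # en0 can improve the optimal criterion
            if criterion == "optimal" and best is not None and n1 > best[0][0]:
                break
            n2 = n - n1
            if n1 not in pmf0_c:
                xs = np.arange(n1 + 1)
                pmf0_c[n1] = binom.pmf(xs, n1, p0)
                pmf1_c[n1] = binom.pmf(xs, n1, p1)
                cdf0_c[n1] = np.cumsum(pmf0_c[n1])
                cdf1_c[n1] = np.cumsum(pmf1_c[n1])
            pmf0, pmf1 = pmf0_c[n1], pmf1_c[n1]
            cdf0, cdf1 = cdf0_c[n1], cdf1_c[n1]
            for r1 in range(0, n1):
                # power can never exceed P(continue | p1); prune the rest of
                # the r1 loop once even that upper bound is too small
                if 1.0 - cdf1[r1] < 1.0 - beta:
                    break
                x1 = np.arange(r1 + 1, n1 + 1)
                sf0 = _stage2_sf(n2, p0, r1 + 1 - n1, n - (r1 + 1))
                sf1 = _stage2_sf(n2, p1, r1 + 1 - n1, n - (r1 + 1))
                # reject(r) = sum_{x1>r1} pmf[x1] * P(X2 > r - x1), r = r1..n
                rs = np.arange(r1, n + 1)
                idx = rs[:, None] - x1[None, :] - (r1 + 1 - n1)
                w0 = pmf0[x1]
                reject0 = sf0[idx] @ w0
                # smallest r with attained alpha <= spec alpha (reject0 decreasing)
                ok = np.nonzero(reject0 <= alpha)[0]
                if ok.size == 0:
                    continue
                j = int(ok[0])
                power = float(sf1[idx[j]] @ pmf1[x1])
                if power < 1.0 - beta:
                    continue
                r = int(rs[j])
                pet0 = float(cdf0[r1])
                en0 = n1 + (1.0 - pet0) * n2
                if criterion == "optimal":
                    key = (en0, n, n1, r1)
                else:
                    key = (n, en0, n1, r1)
                if best is None or key < best[0]:
                    best = (key, (n1, r1, n, r, float(reject0[j]), power, pet0, en0))
    if best is None:
        raise InfeasibleDesignError(
            f"no two-stage design with n <= {spec.n_max} attains "
            f"alpha <= {alpha} and power >= {1 - beta} for p0={p0}, p1={p1}"
        )
    n1, r1, n, r, a, pw, pet0, en0 = best[1]
    return TwoStageDesign(
        n1=n1, r1=r1, n=n, r=r,
        attained_alpha=a, attained_power=pw, pet0=pet0, en0=en0,
        criterion=criterion,
    )


def stage1_decision(design: TwoStageDesign, responses: int) -> str:
    """Futility rule after stage 1: ``'continue'`` iff responses exceed ``r1``."""
    if not 0 <= responses <= design.n1:
        raise ValueError(
            f"stage-1 responses must lie in [0, n1={design.n1}], got {responses}"
        )
    return "continue" if responses > design.r1 else "stop_futility"


def inflate_for_dropout(n_evaluable: int, dropout_rate: float) -> int:
    """Smallest enrollment ``m`` with ``m * (1 - dropout_rate) >= n_evaluable``."""
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError(f"dropout_rate must lie in [0, 1), got {dropout_rate}")
    if n_evaluable < 0:
        raise ValueError("n_evaluable must be nonnegative")
    m = math.ceil(n_evaluable / (1.0 - dropout_rate) - 1e-9)
    while m * (1.0 - dropout_rate) < n_evaluable - 1e-9:
        m += 1
    return m
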