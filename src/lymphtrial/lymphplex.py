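"""Rule-based genetic subtyping of DLBCL mutation + FISH profiles.

The classifier assigns each patient one of seven genetic subtypes from a
streamlined targeted panel (35 genes) plus three FISH rearrangements
(BCL2, BCL6, MYC), in the style of the simplified LymphPlex scheme:

* ``TP53_mut`` — any retained nonsynonymous TP53 call, taking precedence
  over every other feature;
* ``MCD_like``, ``BN2_like``, ``N1_like``, ``EZB_like``, ``ST2_like`` —
  assigned to the rule with the most matched defining features, with a
  fixed, configurable priority order breaking ties;
* ``NOS`` — not otherwise specified, when no defining feature matches.

Each subtype maps totally onto its trial regimen (R-ICE plus a
subtype-matched targeted agent).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import Cohort, FishStatus

logger = logging.getLogger(__name__)

__all__ = [
    "SUBTYPES",
    "FISH_MARKERS",
    "REGIMEN_MAP",
    "SubtypeRule",
    "SubtypeCall",
    "ClassifierConfig",
    "ConcordanceSummary",
    "default_ruleset",
    "evaluate_features",
    "classify_patient",
    "assign_regimen",
    "classify_cohort",
    "compare_labelings",
    "ruleset_to_json",
    "ruleset_from_json",
]

SUBTYPES = (
    "MCD_like",
    "BN2_like",
    "N1_like",
    "TP53_mut",
    "EZB_like",
    "ST2_like",
    "NOS",
)

#: FISH feature tokens usable in rules
FISH_MARKERS = ("BCL2_R", "BCL6_R", "MYC_R")

_FISH_ATTR = {
    "BCL2_R": "bcl2_rearranged",
    "BCL6_R": "bcl6_rearranged",
    "MYC_R": "myc_rearranged",
}

#: fixed, total subtype -> regimen map
REGIMEN_MAP: Mapping[str, str] = {
    "MCD_like": "R_ICE_zanubrutinib",
    "BN2_like": "R_ICE_zanubrutinib",
    "N1_like": "R_ICE_lenalidomide",
    "NOS": "R_ICE_lenalidomide",
    "TP53_mut": "R_ICE_decitabine",
    "EZB_like": "R_ICE_chidamide",
    "ST2_like": "R_ICE_tofacitinib",
}

MCD_GENES = frozenset(
    {"BTG1", "CD79B", "IRF4", "MYD88", "MPEG1", "PIM1", "PRDM1", "TBL1XR1"}
)
BN2_GENES = frozenset({"BTG2", "CD70", "CCND3", "DTX1", "NOTCH2", "TNFAIP3"})
N1_GENES = frozenset({"NOTCH1"})
TP53_GENES = frozenset({"TP53"})
EZB_GENES = frozenset(
    {
        "ARID1A", "B2M", "CIITA", "CREBBP", "EZH2", "EP300",
        "FAS", "GNA13", "KMT2D", "STAT6", "TNFRSF14",
    }
)
ST2_GENES = frozenset(
    {"DDX3X", "DUSP2", "IRF8", "SGK1", "SOCS1", "STAT3", "TET2", "ZFP36L1"}
)

#: the 35 panel genes carried by defining feature sets
PANEL_GENES = MCD_GENES | BN2_GENES | N1_GENES | TP53_GENES | EZB_GENES | ST2_GENES

#: default tie-break priority, highest risk first
DEFAULT_PRIORITY = ("TP53_mut", "N1_like", "MCD_like", "BN2_like", "EZB_like", "ST2_like")


@dataclass(frozen=True)
class SubtypeRule:
    """Defining mutation and FISH features of one non-NOS subtype."""

    subtype: str
    mutation_features: frozenset
    fish_features: frozenset
    priority_rank: int

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES or self.subtype == "NOS":
            raise ValueError(f"invalid rule subtype {self.subtype!r}")
        if not (self.mutation_features or self.fish_features):
            raise ValueError(f"{self.subtype}: rule must carry at least one feature")
        bad = set(self.fish_features) - set(FISH_MARKERS)
        if bad:
            raise ValueError(f"{self.subtype}: unknown FISH markers {sorted(bad)}")


@dataclass(frozen=True)
class SubtypeCall:
    """Assigned subtype with the feature evidence and mapped regimen."""

    sample_id: str
    subtype: str
    matched_features: frozenset
    candidate_subtypes: tuple  # (subtype, n_matched) for every rule with a match
    regimen: str


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable classification behaviour.

    ``priority`` breaks ties between rules matching with equal feature
    counts (earlier wins); ``min_matches`` is the smallest matched-feature
    count that qualifies a rule; ``strict_ezb`` additionally requires the
    BCL2 rearrangement for an EZB-like call.
    """

    priority: tuple = DEFAULT_PRIORITY
    min_matches: int = 1
    strict_ezb: bool = False

    def __post_init__(self) -> None:
        if set(self.priority) != set(DEFAULT_PRIORITY):
            raise ValueError(
                "priority must be a permutation of the six non-NOS subtypes"
            )
        if self.min_matches < 1:
            raise ValueError("min_matches must be >= 1")


def default_ruleset() -> tuple:
    """The six non-NOS rules with their defining gene / FISH feature sets."""
    prio = {s: i for i, s in enumerate(DEFAULT_PRIORITY)}
    return (
        SubtypeRule("TP53_mut", TP53_GENES, frozenset(), prio["TP53_mut"]),
        SubtypeRule("N1_like", N1_GENES, frozenset(), prio["N1_like"]),
        SubtypeRule("MCD_like", MCD_GENES, frozenset(), prio["MCD_like"]),
        SubtypeRule("BN2_like", BN2_GENES, frozenset({"BCL6_R"}), prio["BN2_like"]),
        SubtypeRule("EZB_like", EZB_GENES, frozenset({"BCL2_R"}), prio["EZB_like"]),
        SubtypeRule("ST2_like", ST2_GENES, frozenset(), prio["ST2_like"]),
    )


_ALL_FALSE_FISH = FishStatus("", False, False, False)


def evaluate_features(
    profile: Iterable[str], fish: FishStatus | None, rule: SubtypeRule
) -> frozenset:
    """Features of ``rule`` present in the patient's profile.

    A FISH feature matches only when the corresponding flag is ``True``;
    a missing (``None``) assay never matches — conservative by design.
    """
    genes = frozenset(profile)
    matched = genes & rule.mutation_features
    if fish is not None:
        for marker in rule.fish_features:
            if getattr(fish, _FISH_ATTR[marker]) is True:
                matched |= {marker}
    return frozenset(matched)


def assign_regimen(subtype: str) -> str:
    """Trial regimen for a subtype label (total, fixed map)."""
    try:
        return REGIMEN_MAP[subtype]
    except KeyError:
        raise ValueError(f"unknown subtype label {subtype!r}")


def classify_patient(
    profile: Iterable[str],
    fish: FishStatus | None,
    ruleset: Sequence[SubtypeRule] | None = None,
    config: ClassifierConfig | None = None,
    sample_id: str = "",
) -> SubtypeCall:
    """Classify a single patient.

    A retained TP53 mutation forces ``TP53_mut`` regardless of any other
    feature.  Otherwise the rule with the largest matched-feature count
    wins; ties break by the configured priority order; with no qualifying
    rule the patient is ``NOS``.
    """
    ruleset = default_ruleset() if ruleset is None else ruleset
    config = ClassifierConfig() if config is None else config
    genes = frozenset(g.upper() for g in profile)
    prio = {s: i for i, s in enumerate(config.priority)}

    if "TP53" in genes:
        return SubtypeCall(
            sample_id=sample_id,
            subtype="TP53_mut",
            matched_features=frozenset({"TP53"}),
            candidate_subtypes=(("TP53_mut", 1),),
            regimen=assign_regimen("TP53_mut"),
        )

    candidates: list[tuple[str, frozenset]] = []
    for rule in ruleset:
        if rule.subtype == "TP53_mut":
            continue
        matched = evaluate_features(genes, fish, rule)
        if len(matched) < config.min_matches:
            continue
        if (
            config.strict_ezb
            and rule.subtype == "EZB_like"
            and "BCL2_R" not in matched
        ):
            continue
        candidates.append((rule.subtype, matched))

    if not candidates:
        return SubtypeCall(
            sample_id=sample_id,
            subtype="NOS",
            matched_features=frozenset(),
            candidate_subtypes=(),
            regimen=assign_regimen("NOS"),
        )

    candidates.sort(key=lambda c: (-len(c[1]), prio[c[0]]))
    winner, matched = candidates[0]
    if len(candidates) > 1 and len(candidates[1][1]) == len(matched):
        logger.debug(
            "%s: tie between %s broken by priority",
            sample_id,
            [c[0] for c in candidates if len(c[1]) == len(matched)],
        )
    return SubtypeCall(
        sample_id=sample_id,
        subtype=winner,
        matched_features=matched,
        candidate_subtypes=tuple((s, len(m)) for s, m in candidates),
        regimen=assign_regimen(winner),
    )


def classify_cohort(
    cohort: Cohort,
    ruleset: Sequence[SubtypeRule] | None = None,
    config: ClassifierConfig | None = None,
) -> tuple[list[SubtypeCall], dict[str, float]]:
    """Classify every patient; return the calls and subtype proportions."""
    calls = [
        classify_patient(
            cohort.mutations.get(p.sample_id, frozenset()),
            cohort.fish.get(p.sample_id),
            ruleset=ruleset,
            config=config,
            sample_id=p.sample_id,
        )
        for p in cohort.patients
    ]
    n = len(calls)
    freq = {s: 0 for s in SUBTYPES}
    for c in calls:
        freq[c.subtype] += 1
    table = {s: (freq[s] / n if n else 0.0) for s in SUBTYPES}
    return calls, table


@dataclass(frozen=True)
class ConcordanceSummary:
    n_compared: int
    n_agreeing: int

    @property
    def proportion(self) -> float:
        return self.n_agreeing / self.n_compared if self.n_compared else float("nan")


def _as_label_map(calls) -> dict[str, str]:
    if isinstance(calls, Mapping):
        return dict(calls)
    return {c.sample_id: c.subtype for c in calls}


def compare_labelings(
    calls_a, calls_b, exclude: Iterable[str] = ()
) -> ConcordanceSummary:
    """Pairwise label concordance over samples classified by both schemes.

    Pairs whose label in either input is NOS (unclassified) or in
    ``exclude`` drop out of the denominator, mirroring how cross-algorithm
    concordance is reported for genetic subtyping schemes.
    """
    a = _as_label_map(calls_a)
    b = _as_label_map(calls_b)
    if set(a) != set(b):
        raise ValueError("labelings cover different sample sets")
    skip = set(exclude) | {"NOS"}
    compared = agreeing = 0
    for sid in a:
        if a[sid] in skip or b[sid] in skip:
            continue
        compared += 1
        if a[sid] == b[sid]:
            agreeing += 1
    return ConcordanceSummary(n_compared=compared, n_agreeing=agreeing)


# ---------------------------------------------------------------------------
# ruleset (de)serialisation


def ruleset_to_json(ruleset: Sequence[SubtypeRule], path: str | Path) -> None:
    doc = [
        {
            "subtype": r.subtype,
            "mutation_features": sorted(r.mutation_features),
            "fish_features": sorted(r.fish_features),
            "priority_rank": r.priority_rank,
        }
        for r in ruleset
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def ruleset_from_json(path: str | Path) -> tuple:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return tuple(
        SubtypeRule(
            subtype=d["subtype"],
            mutation_features=frozenset(d["mutation_features"]),
            fish_features=frozenset(d["fish_features"]),
            priority_rank=int(d["priority_rank"]),
        )
        for d in doc
    )
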