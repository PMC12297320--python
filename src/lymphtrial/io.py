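"""Tabular I/O for the three cohort inputs: mutations, FISH, and clinical data.

All three inputs are tab-separated UTF-8 text with a header row; ``#``-prefixed
lines are comments and ``NA`` is the sole missing-value token.  Readers
validate aggressively and raise :class:`CohortFormatError` (structural
problems: missing columns, bad tokens) or :class:`CohortValidationError`
(semantically impossible records, e.g. overall survival shorter than
progression-free survival).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantCall",
    "FishStatus",
    "PatientRecord",
    "Cohort",
    "CohortFormatError",
    "CohortValidationError",
    "VARIANT_CLASSES",
    "NONSYNONYMOUS_CLASSES",
    "read_mutation_table",
    "read_fish_table",
    "read_clinical_table",
    "assemble_cohort",
    "write_mutation_table",
    "write_fish_table",
    "write_clinical_table",
    "write_results",
]

#: every variant-effect class the mutation table may carry
VARIANT_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "splice_site", "inframe_indel", "silent", "other"}
)

#: default whitelist: protein-altering (nonsynonymous) classes only
NONSYNONYMOUS_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "splice_site", "inframe_indel"}
)

DISEASE_STATUS = frozenset({"refractory", "relapsed"})
IPI_RISK = frozenset({"low", "intermediate", "high"})
RESPONSES = frozenset({"CR", "PR", "SD", "PD"})


class CohortFormatError(ValueError):
    """The file does not conform to the documented TSV layout."""


class CohortValidationError(ValueError):
    """A parsed record violates a domain invariant."""


@dataclass(frozen=True)
class VariantCall:
    """One retained somatic variant call for one sample."""

    sample_id: str
    gene: str
    variant_class: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise CohortValidationError("sample_id must be nonempty")
        if not self.gene:
            raise CohortValidationError("gene must be nonempty")
        if self.variant_class not in VARIANT_CLASSES:
            raise CohortValidationError(
                f"unknown variant_class {self.variant_class!r} for {self.sample_id}"
            )


@dataclass(frozen=True)
class FishStatus:
    """Tri-valued rearrangement flags (True / False / None=missing).

    A missing flag is preserved as ``None`` and never coerced to False:
    a subtyping rule that requires a rearrangement cannot fire on a
    missing assay.
    """

    sample_id: str
    bcl2_rearranged: bool | None
    bcl6_rearranged: bool | None
    myc_rearranged: bool | None


@dataclass(frozen=True)
class PatientRecord:
    """Clinical covariates and trial outcomes for one patient."""

    sample_id: str
    age_years: int
    disease_status: str
    ipi_risk: str
    bulky_disease: bool
    response: str | None = None
    pfs_months: float | None = None
    pfs_event: bool | None = None
    os_months: float | None = None
    os_event: bool | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise CohortValidationError("sample_id must be nonempty")
        if self.disease_status not in DISEASE_STATUS:
            raise CohortValidationError(
                f"{self.sample_id}: disease_status {self.disease_status!r} "
                f"not in {sorted(DISEASE_STATUS)}"
            )
        if self.ipi_risk not in IPI_RISK:
            raise CohortValidationError(
                f"{self.sample_id}: ipi_risk {self.ipi_risk!r} not in {sorted(IPI_RISK)}"
            )
        if self.response is not None and self.response not in RESPONSES:
            raise CohortValidationError(
                f"{self.sample_id}: response {self.response!r} not in {sorted(RESPONSES)}"
            )
        for name in ("pfs", "os"):
            t = getattr(self, f"{name}_months")
            e = getattr(self, f"{name}_event")
            if t is not None and t < 0:
                raise CohortValidationError(f"{self.sample_id}: negative {name}_months")
            if e is not None and t is None:
                raise CohortValidationError(
                    f"{self.sample_id}: {name}_event defined without {name}_months"
                )
        if (
            self.pfs_months is not None
            and self.os_months is not None
            and self.pfs_months > self.os_months + 1e-9
        ):
            raise CohortValidationError(
                f"{self.sample_id}: pfs_months ({self.pfs_months}) exceeds "
                f"os_months ({self.os_months})"
            )


@dataclass
class Cohort:
    """Assembled per-patient view of the three input tables.

    ``mutations`` maps every clinical sample to the *set* of mutated genes
    after variant-class filtering; samples absent from the mutation table
    get an empty profile.  Genomic records without a clinical row are kept
    out of the cohort but reported in ``reconciliation``.
    """

    patients: list[PatientRecord]
    mutations: dict[str, frozenset[str]]
    fish: dict[str, FishStatus]
    reconciliation: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.patients]

    def __len__(self) -> int:
        return len(self.patients)


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            dtype=str,
            na_values=["NA"],
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError:
        raise CohortFormatError(f"{path}: file is empty (expected a header row)")
    for col in required:
        if col not in df.columns:
            raise CohortFormatError(f"{path}: missing required column {col!r}")
    return df


def read_mutation_table(
    path: str | Path, allowed_classes: Iterable[str] | None = None
) -> list[VariantCall]:
    """Read a MAF-lite mutation TSV, retaining only whitelisted variant classes.

    The default whitelist keeps the protein-altering classes and drops
    ``silent`` and ``other``; the number of excluded rows is logged.
    Gene symbols are uppercased on ingest.
    """
    allowed = (
        NONSYNONYMOUS_CLASSES if allowed_classes is None else frozenset(allowed_classes)
    )
    bad = allowed - VARIANT_CLASSES
    if bad:
        raise ValueError(f"unknown variant classes in whitelist: {sorted(bad)}")
    df = _read_tsv(path, ["sample_id", "gene", "variant_class"])
    calls: list[VariantCall] = []
    n_excluded = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        sid, gene, vclass = row.sample_id, row.gene, row.variant_class
        if pd.isna(sid) or pd.isna(gene) or pd.isna(vclass):
            raise CohortFormatError(f"{path}: data row {i}: empty field")
        if vclass not in VARIANT_CLASSES:
            raise CohortFormatError(
                f"{path}: data row {i}: unknown variant_class {vclass!r}"
            )
        if vclass not in allowed:
            n_excluded += 1
            continue
        calls.append(VariantCall(sample_id=sid, gene=gene.upper(), variant_class=vclass))
    if n_excluded:
        logger.info("%s: excluded %d variant rows outside the whitelist", path, n_excluded)
    return calls


_FLAG_TOKENS = {"0": False, "1": True}


def read_fish_table(path: str | Path) -> list[FishStatus]:
    """Read per-sample BCL2/BCL6/MYC rearrangement flags (0 / 1 / NA)."""
    cols = ["bcl2_rearranged", "bcl6_rearranged", "myc_rearranged"]
    df = _read_tsv(path, ["sample_id"] + cols)
    records: list[FishStatus] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        sid = row.sample_id
        if pd.isna(sid) or not sid:
            raise CohortFormatError(f"{path}: data row {i}: empty sample_id")
        if sid in seen:
            raise CohortFormatError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        flags = {}
        for col in cols:
            tok = getattr(row, col)
            if pd.isna(tok):
                flags[col] = None
            elif tok in _FLAG_TOKENS:
                flags[col] = _FLAG_TOKENS[tok]
            else:
                raise CohortFormatError(
                    f"{path}: data row {i}: flag value {tok!r} in {col} "
                    "(expected 0, 1 or NA)"
                )
        records.append(FishStatus(sample_id=sid, **flags))
    return records


def _opt_float(tok, path, i, col) -> float | None:
    if pd.isna(tok):
        return None
    try:
        return float(tok)
    except ValueError:
        raise CohortFormatError(f"{path}: data row {i}: unparseable {col} {tok!r}")


def _opt_flag(tok, path, i, col) -> bool | None:
    if pd.isna(tok):
        return None
    if tok in _FLAG_TOKENS:
        return _FLAG_TOKENS[tok]
    raise CohortFormatError(f"{path}: data row {i}: flag value {tok!r} in {col}")


CLINICAL_COLUMNS = [
    "sample_id",
    "age_years",
    "disease_status",
    "ipi_risk",
    "bulky_disease",
    "response",
    "pfs_months",
    "pfs_event",
    "os_months",
    "os_event",
]


def read_clinical_table(path: str | Path) -> list[PatientRecord]:
    """Read the clinical covariate/outcome table into validated records.

    Enumerated fields are matched case-insensitively; survival invariants
    (PFS never exceeding OS, event flags only with times) are enforced per
    row and reported with the offending sample_id.
    """
    df = _read_tsv(path, CLINICAL_COLUMNS)
    records: list[PatientRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        sid = row.sample_id
        if pd.isna(sid) or not sid:
            raise CohortFormatError(f"{path}: data row {i}: empty sample_id")
        try:
            age = int(row.age_years)
        except (ValueError, TypeError):
            raise CohortFormatError(
                f"{path}: data row {i}: unparseable age_years {row.age_years!r}"
            )
        resp = None if pd.isna(row.response) else str(row.response).upper()
        rec = PatientRecord(
            sample_id=sid,
            age_years=age,
            disease_status=str(row.disease_status).lower(),
            ipi_risk=str(row.ipi_risk).lower(),
            bulky_disease=bool(_opt_flag(row.bulky_disease, path, i, "bulky_disease")),
            response=resp,
            pfs_months=_opt_float(row.pfs_months, path, i, "pfs_months"),
            pfs_event=_opt_flag(row.pfs_event, path, i, "pfs_event"),
            os_months=_opt_float(row.os_months, path, i, "os_months"),
            os_event=_opt_flag(row.os_event, path, i, "os_event"),
        )
        records.append(rec)
    return records


def assemble_cohort(
    variants: Sequence[VariantCall],
    fish: Sequence[FishStatus],
    clinical: Sequence[PatientRecord],
) -> Cohort:
    """Merge parsed tables into a :class:`Cohort` keyed by clinical sample_id.

    Mutation profiles use set semantics (repeat calls for the same gene
    collapse); clinical samples without any genomic record get an empty
    profile.  Orphan genomic records are reported, never silently dropped.
    """
    seen: set[str] = set()
    for p in clinical:
        if p.sample_id in seen:
            raise CohortValidationError(f"duplicate clinical sample_id {p.sample_id!r}")
        seen.add(p.sample_id)
    profiles: dict[str, set[str]] = {p.sample_id: set() for p in clinical}
    reconciliation: list[str] = []
    for v in variants:
        if v.sample_id in profiles:
            profiles[v.sample_id].add(v.gene)
        else:
            reconciliation.append(f"mutation record for unknown sample {v.sample_id!r}")
    fish_map: dict[str, FishStatus] = {}
    for f in fish:
        if f.sample_id not in profiles:
            reconciliation.append(f"FISH record for unknown sample {f.sample_id!r}")
            continue
        fish_map[f.sample_id] = f
    for msg in reconciliation:
        logger.warning("reconciliation: %s", msg)
    return Cohort(
        patients=list(clinical),
        mutations={sid: frozenset(genes) for sid, genes in profiles.items()},
        fish=fish_map,
        reconciliation=reconciliation,
    )


# ---------------------------------------------------------------------------
# writers


def _na(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)


def write_mutation_table(calls: Sequence[VariantCall], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tgene\tvariant_class\n")
        for c in calls:
            fh.write(f"{c.sample_id}\t{c.gene}\t{c.variant_class}\n")


def write_fish_table(records: Sequence[FishStatus], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tbcl2_rearranged\tbcl6_rearranged\tmyc_rearranged\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{_na(r.bcl2_rearranged)}\t"
                f"{_na(r.bcl6_rearranged)}\t{_na(r.myc_rearranged)}\n"
            )


def write_clinical_table(records: Sequence[PatientRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(CLINICAL_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    _na(getattr(r, col)) for col in CLINICAL_COLUMNS
                )
                + "\n"
            )


def write_results(
    out_dir: str | Path,
    subtype_calls=None,
    design: Mapping | None = None,
    endpoints: Mapping | None = None,
) -> dict[str, Path]:
    """Write pipeline outputs with deterministic column order and formatting.

    Per-patient subtype calls go to TSV; the design and endpoint summaries
    to pretty-printed JSON with sorted keys so identical analyses produce
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if subtype_calls is not None:
        p = out_dir / "subtype_calls.tsv"
        with open(p, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("sample_id\tsubtype\tregimen\tmatched_features\tn_candidates\n")
            for c in subtype_calls:
                feats = ";".join(sorted(c.matched_features))
                fh.write(
                    f"{c.sample_id}\t{c.subtype}\t{c.regimen}\t{feats}\t"
                    f"{len(c.candidate_subtypes)}\n"
                )
        written["subtype_calls"] = p
    for name, obj in (("design", design), ("endpoints", endpoints)):
        if obj is not None:
            p = out_dir / f"{name}.json"
            with open(p, "w", encoding="utf-8", newline="\n") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True)
                fh.write("\n")
            written[name] = p
    return written
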