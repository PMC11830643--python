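"""Specimen trait table: records, substratum-use classification, CSV IO.

The study system is two heterodont bivalve clades: the asiphonate
Archiheterodonta (families Astartidae, Carditidae, Crassatellidae) and the
siphonate family Veneridae.  Each specimen carries its family, siphonate
condition, optional habit annotation (borer / nestler / epifaunal /
infaunal), an optional pallial-sinus depth expressed as a fraction of shell
length, and the measured morphometric variables.

Substratum-use categories follow a burial-depth rule set: explicit habit
annotations (borer, nestler, epifaunal) take precedence because those modes
are defined by the substrate occupied, not by depth; asiphonate infauna are
``infaunal_asiphonate``; siphonate species shorter than 50 mm are assumed
shallow-burrowing; longer siphonate species are classified by estimated
siphon length (sinus-depth fraction x SL), with estimates deeper than 30 mm
counted as ``deep_siphonate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

__all__ = [
    "SpecimenRecord",
    "FAMILIES",
    "FAMILY_CLADE",
    "SUBSTRATUM_CATEGORIES",
    "SchemaError",
    "RecordValidationError",
    "UnclassifiableError",
    "classify_substratum",
    "classify_all",
    "read_trait_table",
    "write_trait_table",
    "records_to_frame",
]

FAMILY_CLADE = {
    "Astartidae": "Archiheterodonta",
    "Carditidae": "Archiheterodonta",
    "Crassatellidae": "Archiheterodonta",
    "Veneridae": "Veneridae",
}
FAMILIES = tuple(FAMILY_CLADE)

ARCHIHETERODONT_FAMILIES = ("Astartidae", "Carditidae", "Crassatellidae")

SUBSTRATUM_CATEGORIES = (
    "infaunal_asiphonate",
    "shallow_siphonate",
    "deep_siphonate",
    "borer",
    "nestler",
    "epifaunal",
)

HABIT_ANNOTATIONS = ("borer", "nestler", "epifaunal", "infaunal")

#: Siphonate species shorter than this adult shell length (mm) are assumed
#: shallow-burrowing without checking the pallial sinus.
SHALLOW_SL_CUTOFF_MM = 50.0

#: Estimated posterior burial depth (mm) beyond which a taxon counts as deep.
DEEP_BURIAL_CUTOFF_MM = 30.0


class SchemaError(ValueError):
    """Trait-table CSV is missing a required column."""


class RecordValidationError(ValueError):
    """A specimen row violates the family/clade/siphonate invariants."""


class UnclassifiableError(ValueError):
    """Record cannot be assigned a substratum category (missing sinus data)."""


@dataclass
class SpecimenRecord:
    """One specimen: identity, biology flags, and measured metrics."""

    taxon: str
    family: str
    siphonate: bool
    habit_annotation: Optional[str] = None
    sinus_depth_fraction: Optional[float] = None
    metrics: dict = field(default_factory=dict)
    substratum: Optional[str] = None

    def __post_init__(self):
        self.validate()

    @property
    def clade(self) -> str:
        return FAMILY_CLADE.get(self.family, self.family)

    @property
    def SL(self) -> Optional[float]:
        return self.metrics.get("SL")

    def validate(self) -> None:
        """Enforce the clade/siphonate invariants for the study families.

        Families outside the study set are tolerated here; the table reader
        rejects them unless explicitly allowed.
        """
        if self.family in ARCHIHETERODONT_FAMILIES and self.siphonate:
            raise RecordValidationError(
                f"{self.taxon}: archiheterodont family {self.family} must be "
                "asiphonate")
        elif self.family == "Veneridae" and not self.siphonate:
            raise RecordValidationError(
                f"{self.taxon}: Veneridae must be siphonate")
        if (self.habit_annotation is not None
                and self.habit_annotation not in HABIT_ANNOTATIONS):
            raise RecordValidationError(
                f"{self.taxon}: unknown habit annotation "
                f"{self.habit_annotation!r}")
        if self.sinus_depth_fraction is not None and not (
                0.0 <= self.sinus_depth_fraction <= 1.0):
            raise RecordValidationError(
                f"{self.taxon}: sinus_depth_fraction must lie in [0, 1]")


def classify_substratum(record: SpecimenRecord) -> str:
    """Assign one of the six substratum-use categories.

    Precedence: explicit borer/nestler/epifaunal annotation wins; otherwise
    asiphonate infauna are ``infaunal_asiphonate``; siphonate species with
    SL < 50 mm are ``shallow_siphonate``; otherwise the estimated siphon
    length (sinus-depth fraction x SL) decides: > 30 mm -> ``deep_siphonate``,
    else ``shallow_siphonate``.  Deterministic and total on valid records.
    """
    if record.habit_annotation in ("borer", "nestler", "epifaunal"):
        return record.habit_annotation
    if not record.siphonate:
        return "infaunal_asiphonate"
    sl = record.SL
    if sl is None:
        raise UnclassifiableError(f"{record.taxon}: siphonate record has no SL")
    if sl < SHALLOW_SL_CUTOFF_MM:
        return "shallow_siphonate"
    if record.sinus_depth_fraction is None:
        raise UnclassifiableError(
            f"{record.taxon}: siphonate, SL = {sl:g} mm >= "
            f"{SHALLOW_SL_CUTOFF_MM:g} mm but sinus_depth_fraction missing")
    siphon_mm = record.sinus_depth_fraction * sl
    if siphon_mm > DEEP_BURIAL_CUTOFF_MM:
        return "deep_siphonate"
    return "shallow_siphonate"


def classify_all(records) -> list:
    """Classify every record in place; returns the list."""
    for rec in records:
        rec.substratum = classify_substratum(rec)
    return list(records)


_REQUIRED = ("taxon", "family", "siphonate")
_METRIC_COLUMNS = ("TSV", "TIV", "pSV", "SL", "height", "width", "XS",
                   "logSL", "internal_mode")


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "yes", "t"):
        return True
    if text in ("false", "0", "no", "f"):
        return False
    raise RecordValidationError(f"cannot parse boolean from {value!r}")


def read_trait_table(path, allow_extra_families: bool = False) -> list:
    """Read specimen records from a headed CSV.

    Required columns: ``taxon``, ``family``, ``siphonate``.  Optional:
    ``habit_annotation``, ``sinus_depth_fraction``, ``substratum`` and any
    metric columns (``pSV``, ``SL``, ``logSL``, ``XS``, ...).  Rows are
    validated against the clade/siphonate invariants.
    """
    df = pd.read_csv(path)
    for col in _REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"trait table is missing required column {col!r}")
    records = []
    for _, row in df.iterrows():
        family = str(row["family"])
        if family not in FAMILY_CLADE and not allow_extra_families:
            raise RecordValidationError(
                f"{row['taxon']}: unknown family {family!r} "
                "(pass allow_extra_families to accept)")
        habit = row.get("habit_annotation")
        if pd.isna(habit) or habit == "":
            habit = None
        sinus = row.get("sinus_depth_fraction")
        sinus = None if sinus is None or pd.isna(sinus) else float(sinus)
        metrics = {col: float(row[col]) if col != "internal_mode" else row[col]
                   for col in _METRIC_COLUMNS
                   if col in df.columns and not pd.isna(row[col])}
        substratum = (None if "substratum" not in df.columns
                      or pd.isna(row["substratum"]) else str(row["substratum"]))
        records.append(SpecimenRecord(
            taxon=str(row["taxon"]), family=family,
            siphonate=_parse_bool(row["siphonate"]),
            habit_annotation=habit, sinus_depth_fraction=sinus,
            metrics=metrics, substratum=substratum))
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Flatten records (identity + metrics + substratum) into a DataFrame."""
    rows = []
    for rec in records:
        row = {"taxon": rec.taxon, "family": rec.family,
               "clade": FAMILY_CLADE.get(rec.family, ""),
               "siphonate": rec.siphonate,
               "habit_annotation": rec.habit_annotation,
               "sinus_depth_fraction": rec.sinus_depth_fraction}
        row.update(rec.metrics)
        row["substratum"] = rec.substratum
        rows.append(row)
    return pd.DataFrame(rows)


def write_trait_table(records, path) -> None:
    records_to_frame(records).to_csv(path, index=False)
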