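"""Inclusion rules for the disease-causing variant set.

The analysis keeps missense substitutions only — splice, stop-gain,
frameshift, intronic, non-coding and synonymous variants are excluded
because the disease mechanism is misfolding of the full-length protein,
not loss of function — and then retains the variants curated as ACMG
pathogenic or likely pathogenic ("disease-causing"). Classification is a
curated input; no ACMG evidence combining happens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .cohort_io import (
    ALL,
    AcmgCategory,
    ClassificationTable,
    CohortRow,
    CohortTable,
    CountUnit,
    DISEASE_CAUSING,
    FormatError,
    PopulationCounts,
)
from .variants import Consequence, VariantRecord, infer_consequence

logger = logging.getLogger(__name__)


@dataclass
class FilterResult:
    """A filtered table plus a log of every excluded row with its reason.

    No row is silently dropped: len(input) == len(table) + len(excluded).
    """

    table: CohortTable
    excluded: list[tuple[CohortRow, str]] = field(default_factory=list)

    def log_tsv(self) -> str:
        lines = ["variant\treason"]
        lines += [f"{row.record.label}\t{reason}" for row, reason in self.excluded]
        return "\n".join(lines) + "\n"


@dataclass
class ClassifiedVariant:
    """A variant row with its curated ACMG category attached."""

    record: VariantRecord
    counts: dict[str, PopulationCounts]
    category: AcmgCategory
    unit: CountUnit = CountUnit.ALLELES

    @property
    def disease_causing(self) -> bool:
        return self.category in DISEASE_CAUSING


def filter_missense(table: CohortTable, splice_window: int = 2) -> FilterResult:
    """Keep exactly the missense rows of a cohort table.

    Consequences are inferred where absent. Every excluded row is recorded
    with its consequence class as the reason; filtering twice is a no-op.
    """
    kept: list[CohortRow] = []
    excluded: list[tuple[CohortRow, str]] = []
    for row in table.rows:
        csq = row.record.consequence
        if csq is None:
            csq = infer_consequence(row.record, splice_window=splice_window)
            row.record.consequence = csq
        if csq is Consequence.MISSENSE:
            kept.append(row)
        else:
            excluded.append((row, f"excluded: consequence={csq.value}"))
    logger.info("%s: %d/%d rows are missense (%d excluded)",
                table.database_name, len(kept), len(table.rows), len(excluded))
    return FilterResult(
        table=CohortTable(database_name=table.database_name, unit=table.unit, rows=kept),
        excluded=excluded)


def join_classification(table: CohortTable, cls: ClassificationTable,
                        unmatched_policy: str = "uncertain") -> list[ClassifiedVariant]:
    """Attach curated ACMG categories to every row of a cohort table.

    Rows are matched by genomic key, falling back to cDNA notation.
    Unmatched rows follow ``unmatched_policy``: ``uncertain`` (default)
    assigns uncertain_significance with a warning — conservative, since
    VUS are excluded downstream; ``drop`` removes them with a log entry;
    ``strict`` raises.
    """
    if unmatched_policy not in ("uncertain", "drop", "strict"):
        raise ValueError(f"unknown unmatched_policy {unmatched_policy!r}")
    out: list[ClassifiedVariant] = []
    for row in table.rows:
        category = cls.lookup(row.record)
        if category is None:
            if unmatched_policy == "strict":
                raise FormatError(f"no classification for {row.record.label}")
            if unmatched_policy == "drop":
                logger.info("dropped unclassified variant %s", row.record.label)
                continue
            logger.warning("no classification for %s; defaulting to uncertain_significance",
                           row.record.label)
            category = AcmgCategory.UNCERTAIN_SIGNIFICANCE
        out.append(ClassifiedVariant(record=row.record, counts=row.counts,
                                     category=category, unit=table.unit))
    return out


def select_disease_causing(classified: list[ClassifiedVariant]) -> list[ClassifiedVariant]:
    """Retain exactly the pathogenic + likely-pathogenic variants."""
    selected = [v for v in classified if v.disease_causing]
    logger.info("%d of %d classified variants are disease-causing",
                len(selected), len(classified))
    return selected
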