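"""Readers and writers for variant-summary and cohort-metadata formats.

Three table dialects — gnomAD-style and ChinaMAP-style (counts are
alleles) and clinical-exome-style (counts are individuals, as commercial
diagnostic labs report) — are normalized into one internal
:class:`CohortTable`. An annotated VCF with AC/AN/nhomalt INFO fields
(optionally population-suffixed, gnomAD convention ``AC_afr``) is read into
the same representation.
"""

from __future__ import annotations

import enum
import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .variants import (
    Consequence,
    GenomicLocation,
    HgvsParseError,
    VariantRecord,
    infer_consequence,
    parse_hgvs_c,
    parse_hgvs_p,
)

logger = logging.getLogger(__name__)

#: Pooled-population label used when no stratification applies.
ALL = "ALL"

#: Packaged data directory (bundled summary-table fixtures + cohort metadata).
DATA_DIR = Path(__file__).parent / "data"


class FormatError(ValueError):
    """A summary table or VCF violates its dialect's format contract."""


class AcmgCategory(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN_SIGNIFICANCE = "uncertain_significance"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"

    @classmethod
    def parse(cls, label: str) -> "AcmgCategory":
        norm = re.sub(r"[\s_-]+", "_", str(label).strip().lower())
        try:
            return cls(norm)
        except ValueError:
            allowed = ", ".join(c.value for c in cls)
            raise FormatError(
                f"unknown ACMG category {label!r}; allowed: {allowed}") from None


#: Categories the analysis treats as disease-causing.
DISEASE_CAUSING = frozenset({AcmgCategory.PATHOGENIC, AcmgCategory.LIKELY_PATHOGENIC})


@dataclass
class PopulationCounts:
    """Per-variant, per-population observed counts.

    ``allele_count`` holds the count column of the source table: alternate
    alleles for allele-unit databases, carrier individuals for
    individual-unit databases (the table's ``unit`` flag disambiguates).
    ``allele_number`` is the per-site number of genotyped alleles when the
    source provides it; ``cohort_individuals`` the number of sequenced
    individuals in the cohort.
    """

    population: str
    allele_count: int
    homozygote_count: int = 0
    allele_number: Optional[int] = None
    cohort_individuals: Optional[int] = None

    def __post_init__(self) -> None:
        if self.allele_count < 0 or self.homozygote_count < 0:
            raise FormatError(
                f"{self.population}: negative count "
                f"(AC={self.allele_count}, hom={self.homozygote_count})")
        if self.homozygote_count > self.allele_count // 2:
            raise FormatError(
                f"{self.population}: homozygote count {self.homozygote_count} "
                f"exceeds AC/2 for AC={self.allele_count}")
        if self.allele_number is not None:
            if self.allele_number <= 0:
                raise FormatError(f"{self.population}: allele_number must be positive")
            if self.allele_count > self.allele_number:
                raise FormatError(
                    f"{self.population}: AC={self.allele_count} exceeds AN={self.allele_number}")
        if self.cohort_individuals is not None:
            if self.cohort_individuals <= 0:
                raise FormatError(f"{self.population}: cohort_individuals must be positive")
            if self.allele_number is not None and self.allele_number > 2 * self.cohort_individuals:
                raise FormatError(
                    f"{self.population}: AN={self.allele_number} exceeds "
                    f"2 x {self.cohort_individuals} individuals")


@dataclass
class CohortRow:
    record: VariantRecord
    counts: dict[str, PopulationCounts] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop, c in self.counts.items():
            if c.population != pop:
                raise FormatError(f"counts keyed {pop!r} labelled {c.population!r}")


class CountUnit(str, enum.Enum):
    ALLELES = "alleles"
    INDIVIDUALS = "individuals"


@dataclass
class CohortTable:
    """One database's variant summary in the internal representation."""

    database_name: str
    unit: CountUnit = CountUnit.ALLELES
    rows: list[CohortRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.unit = CountUnit(self.unit)
        for row in self.rows:
            # Disjoint subpopulations must not exceed the pooled count; they
            # may undershoot it when only some populations were extracted.
            subtotal = sum(c.allele_count for p, c in row.counts.items() if p != ALL)
            if ALL in row.counts and len(row.counts) > 1:
                if subtotal > row.counts[ALL].allele_count:
                    raise FormatError(
                        f"{row.record.label}: subpopulation counts sum to {subtotal}, "
                        f"exceeding the pooled count {row.counts[ALL].allele_count}")

    @property
    def populations(self) -> set[str]:
        return {p for row in self.rows for p in row.counts}

    def __len__(self) -> int:
        return len(self.rows)

    def total_count(self, population: str = ALL) -> int:
        return sum(r.counts[population].allele_count for r in self.rows
                   if population in r.counts)


@dataclass
class ClassificationTable:
    """Curated variant -> ACMG category mapping.

    Lookups try the genomic key first, then the cDNA notation, matching
    the join-key convention of the summary tables.
    """

    by_genomic: dict[tuple, AcmgCategory] = field(default_factory=dict)
    by_cdna: dict[str, AcmgCategory] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def add(self, key_genomic: Optional[tuple], cdna: Optional[str],
            category: AcmgCategory, note: str = "") -> None:
        for mapping, key in ((self.by_genomic, key_genomic), (self.by_cdna, cdna)):
            if key is None:
                continue
            if key in mapping and mapping[key] != category:
                raise FormatError(f"duplicate classification for {key!r} with "
                                  f"conflicting categories")
            mapping[key] = category
        if cdna is not None and note:
            self.notes[cdna] = note

    def lookup(self, record: VariantRecord) -> Optional[AcmgCategory]:
        if record.location is not None:
            cat = self.by_genomic.get(record.location.key)
            if cat is not None:
                return cat
        if record.cdna is not None:
            return self.by_cdna.get(record.cdna.canonical)
        return None

    def __len__(self) -> int:
        return len(self.by_cdna) or len(self.by_genomic)


# ---------------------------------------------------------------------------
# Summary-table dialects
# ---------------------------------------------------------------------------

# canonical column -> accepted header spellings (lowercased)
_COLUMN_ALIASES = {
    "location": ["genomic location (grch37)", "genomic_location", "location"],
    "transcript": ["transcript"],
    "protein_id": ["protein id", "protein_id"],
    "cdna": ["variant", "cdna", "hgvs_c"],
    "protein": ["protein change", "protein_change", "hgvs_p"],
    "count": ["allele count", "allele_count", "individual count", "individual_count"],
    "homozygotes": ["homozygote count", "homozygote_count", "number of homozygotes"],
    "frequency": ["allele frequency", "allele_frequency"],
    "category": ["variants categories", "variant_category", "category",
                 "acmg_category", "classification"],
    "population": ["population"],
}

_DIALECTS = {
    "gnomad_like": {
        "unit": CountUnit.ALLELES,
        "required": ["location", "transcript", "cdna", "count", "homozygotes"],
    },
    "chinamap_like": {
        "unit": CountUnit.ALLELES,
        "required": ["location", "transcript", "cdna", "count"],
    },
    "clinical_exome_like": {
        "unit": CountUnit.INDIVIDUALS,
        "required": ["location", "transcript", "cdna", "count"],
    },
}

_LOCATION_RE = re.compile(r"^(?P<contig>chr[\w]+)\s*:\s*(?P<pos>[\d,]+)$")


def _resolve_columns(header: list[str]) -> dict[str, str]:
    lowered = {h.strip().lower(): h for h in header}
    out = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                out[canon] = lowered[alias]
                break
    return out


def _parse_location(text: str, cdna) -> Optional[GenomicLocation]:
    """Build a genomic key from a 'chr18: 29172937' cell plus the cDNA alleles.

    Summary tables print contig:position only; for substitutions on a
    plus-strand gene (TTR is one) the genomic ref/alt equal the cDNA bases.
    Returns None when alleles cannot be determined.
    """
    m = _LOCATION_RE.match(str(text).strip())
    if m is None:
        raise FormatError(f"unparseable genomic location {text!r}")
    if cdna is None or cdna.ref is None:
        return None
    return GenomicLocation(contig=m["contig"], position=int(m["pos"].replace(",", "")),
                           ref=cdna.ref, alt=cdna.alt)


def read_summary_tsv(path: Union[str, Path], dialect: str,
                     database_name: Optional[str] = None,
                     cohort_individuals: Optional[int] = None) -> CohortTable:
    """Read a variant-summary TSV in one of the three database dialects.

    All dialects share the internal model; they differ in required columns
    and in whether the count column is alleles (gnomad_like,
    chinamap_like) or individuals (clinical_exome_like). Malformed rows
    are reported together with their line numbers.
    """
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    spec = _DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(list(df.columns))
    missing = [c for c in spec["required"] if c not in cols]
    if missing:
        raise FormatError(f"{path}: dialect {dialect!r} requires columns {missing}; "
                          f"found {list(df.columns)}")

    rows: list[CohortRow] = []
    errors: list[str] = []
    for i, r in df.iterrows():
        lineno = i + 2  # 1-based, after header
        try:
            cdna = parse_hgvs_c(r[cols["cdna"]])
            protein = None
            if "protein" in cols and pd.notna(r.get(cols["protein"])):
                protein = parse_hgvs_p(r[cols["protein"]])
            rec = VariantRecord(
                location=_parse_location(r[cols["location"]], cdna),
                transcript=str(r[cols["transcript"]]).strip(),
                protein_id=str(r[cols["protein_id"]]).strip() if "protein_id" in cols else None,
                cdna=cdna,
                protein=protein,
            )
            rec.consequence = infer_consequence(rec)
            count = int(r[cols["count"]])
            hom = int(r[cols["homozygotes"]]) if "homozygotes" in cols and pd.notna(
                r.get(cols["homozygotes"])) else 0
            pop = str(r[cols["population"]]).strip() if "population" in cols and pd.notna(
                r.get(cols["population"])) else ALL
            counts = PopulationCounts(population=pop, allele_count=count,
                                      homozygote_count=hom,
                                      cohort_individuals=cohort_individuals)
            rows.append(CohortRow(record=rec, counts={pop: counts}))
        except (HgvsParseError, FormatError, ValueError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise FormatError(f"{path}: {len(errors)} malformed row(s):\n  " + "\n  ".join(errors))
    name = database_name or Path(path).stem
    logger.info("read %d variants (%s dialect) from %s", len(rows), dialect, path)
    return CohortTable(database_name=name, unit=spec["unit"], rows=rows)


def read_classification_table(path: Union[str, Path]) -> ClassificationTable:
    """Read a curated classification table (variant key -> ACMG category).

    Accepts either a minimal two-column delimited file (cDNA notation,
    category) or a full summary TSV carrying a category column; category
    labels are validated case-insensitively against the five ACMG tiers.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = _resolve_columns(list(df.columns))
    if "category" not in cols:
        raise FormatError(f"{path}: no recognizable category column")
    if "cdna" not in cols:
        raise FormatError(f"{path}: no recognizable variant column")
    table = ClassificationTable()
    for _, r in df.iterrows():
        cdna = parse_hgvs_c(r[cols["cdna"]])
        category = AcmgCategory.parse(r[cols["category"]])
        key = None
        if "location" in cols and pd.notna(r.get(cols["location"])):
            loc = _parse_location(r[cols["location"]], cdna)
            key = loc.key if loc is not None else None
        note = str(r[cols["note"]]) if "note" in cols else ""
        table.add(key, cdna.canonical, category, note)
    return table


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def read_vcf_counts(path: Union[str, Path],
                    population_field_map: Optional[dict[str, str]] = None,
                    database_name: Optional[str] = None,
                    cohort_individuals: Optional[dict[str, int]] = None,
                    require_pass: bool = False) -> CohortTable:
    """Read per-population AC/AN/homozygote counts from an annotated VCF.

    ``population_field_map`` maps population labels to INFO-key suffixes
    (gnomAD convention: ``{"African/African-American": "afr"}`` reads
    ``AC_afr``/``AN_afr``/``nhomalt_afr``); with no map the plain
    AC/AN/nhomalt fields populate the ``ALL`` population. Multi-allelic
    sites are decomposed into one row per ALT allele. ``require_pass``
    applies an optional FILTER=PASS gate (off by default).
    """
    import pysam

    def _info_list(rec, key):
        if key not in rec.info:
            return None
        v = rec.info[key]
        return list(v) if isinstance(v, tuple) else [v]

    field_map = population_field_map or {ALL: ""}
    rows: list[CohortRow] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if require_pass and rec.filter.keys() not in ([], ["PASS"]):
                continue
            for ai, alt in enumerate(rec.alts or ()):
                if set(alt) - set("ACGT") or set(rec.ref) - set("ACGT"):
                    continue  # symbolic / spanning-deletion alleles
                vrec = VariantRecord(location=GenomicLocation(
                    contig=rec.chrom, position=rec.pos, ref=rec.ref, alt=alt))
                counts: dict[str, PopulationCounts] = {}
                for label, suffix in field_map.items():
                    sfx = f"_{suffix}" if suffix else ""
                    ac = _info_list(rec, f"AC{sfx}")
                    if ac is None:
                        continue
                    an = _info_list(rec, f"AN{sfx}")
                    if an is None:
                        raise FormatError(
                            f"{rec.chrom}:{rec.pos}: AC{sfx} present without AN{sfx}")
                    hom = _info_list(rec, f"nhomalt{sfx}")
                    an_val = int(an[0])
                    if an_val % 2:
                        warnings.warn(
                            f"{rec.chrom}:{rec.pos}: AN{sfx}={an_val} is odd "
                            "(non-diploid parity)", stacklevel=2)
                    n_ind = (cohort_individuals or {}).get(label)
                    counts[label] = PopulationCounts(
                        population=label,
                        allele_count=int(ac[ai]),
                        allele_number=an_val,
                        homozygote_count=int(hom[ai]) if hom is not None else 0,
                        cohort_individuals=n_ind)
                if counts:
                    rows.append(CohortRow(record=vrec, counts=counts))
    return CohortTable(database_name=database_name or Path(path).stem,
                       unit=CountUnit.ALLELES, rows=rows)


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

REPORT_VERSION = 1

_REPORT_COLUMNS = [
    "database", "population", "method", "n_variants", "carriers",
    "carrier_frequency", "maf", "prevalence_per_100k", "ci_low", "ci_high",
    "penetrance", "prevalence_display", "maf_display",
]


def write_report(estimates, path: Union[str, Path], format: str = "tsv",
                 provenance: Optional[dict] = None) -> None:
    """Write prevalence estimates as TSV or JSON.

    Columns come in a fixed order; full-precision values are accompanied
    by display-rounded strings (prevalence to 1 decimal, frequencies to 3
    significant figures). The JSON form carries a schema version and
    provenance and round-trips at full float precision.
    """
    if not estimates:
        raise ValueError("no estimates to report")
    records = [e.as_dict() for e in estimates]
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(records)
        for col in _REPORT_COLUMNS:
            if col not in df.columns:
                df[col] = None
        df[_REPORT_COLUMNS].to_csv(path, sep="\t", index=False)
    elif format == "json":
        payload = {"report_version": REPORT_VERSION,
                   "provenance": provenance or {},
                   "estimates": records}
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report_json(path: Union[str, Path]) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("report_version") != REPORT_VERSION:
        raise FormatError(f"unsupported report_version {payload.get('report_version')}")
    return payload


def load_cohort_metadata(path: Union[str, Path, None] = None) -> dict:
    """Load database metadata (sequenced individuals per population).

    Defaults to the bundled metadata for the three reference databases
    (gnomAD v2.1.1 exomes, ChinaMAP, and a clinical exome laboratory).
    """
    p = Path(path) if path is not None else DATA_DIR / "cohorts.json"
    return json.loads(p.read_text())
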