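"""End-to-end pipeline: filter -> classify -> estimate -> interval.

:func:`reproduce_reference_analysis` runs the whole analysis over the
bundled summary tables of the three reference databases (gnomAD v2.1.1
exomes, ChinaMAP, and a clinical referral-exome laboratory) and returns
every headline quantity: the pooled gnomAD estimate, the African /
non-African stratification, the two Chinese-database estimates and the
cross-database prevalence interval.

:class:`RunConfig`/:func:`run_pipeline` expose the same flow for
user-supplied inputs (the CLI's ``run`` subcommand).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import cohort_io, filtering, prevalence
from .cohort_io import ALL, CountUnit, DATA_DIR
from .prevalence import AggregateCounts, PrevalenceEstimate, PrevalenceInterval

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run over one or more databases.

    Each database entry needs: ``summary`` (TSV path), ``dialect``,
    ``n_individuals``, and optionally ``classification`` (separate curated
    table; defaults to the category column of the summary itself).
    """

    databases: dict[str, dict]
    output_dir: Optional[Path] = None
    penetrance: float = 1.0
    ci_level: float = 0.95
    unmatched_policy: str = "uncertain"

    def validate(self) -> None:
        for name, db in self.databases.items():
            for key in ("summary", "dialect", "n_individuals"):
                if key not in db:
                    raise ValueError(f"database {name!r}: missing config key {key!r}")
            if not Path(db["summary"]).exists():
                raise FileNotFoundError(f"database {name!r}: {db['summary']} not found")


def estimate_database(summary_path, dialect: str, n_individuals: int,
                      database_name: str, classification_path=None,
                      penetrance: float = 1.0, ci_level: float = 0.95,
                      unmatched_policy: str = "uncertain") -> tuple[PrevalenceEstimate, dict]:
    """Run filter -> classify -> aggregate -> estimate for one database.

    Returns the pooled-population estimate and a log dict with the row
    counts in and out of every stage.
    """
    table = cohort_io.read_summary_tsv(summary_path, dialect,
                                       database_name=database_name,
                                       cohort_individuals=n_individuals)
    cls = cohort_io.read_classification_table(classification_path or summary_path)
    missense = filtering.filter_missense(table)
    classified = filtering.join_classification(missense.table, cls,
                                               unmatched_policy=unmatched_policy)
    selected = filtering.select_disease_causing(classified)
    agg = prevalence.aggregate(selected, ALL, cohort_individuals=n_individuals)
    est = prevalence.prevalence_carrier_method(agg, penetrance=penetrance,
                                               ci_level=ci_level, database=database_name)
    log = {
        "database": database_name,
        "rows_in": len(table),
        "missense": len(missense.table),
        "excluded_non_missense": len(missense.excluded),
        "classified": len(classified),
        "disease_causing": len(selected),
        "total_count": agg.total_allele_count,
        "homozygotes": agg.total_homozygotes,
        "unit": agg.unit.value,
    }
    logger.info("%s: %d rows -> %d disease-causing, count %d %s",
                database_name, log["rows_in"], log["disease_causing"],
                log["total_count"], log["unit"])
    return est, log


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline for every configured database.

    Writes TSV + JSON reports into ``config.output_dir`` when set and
    returns {"estimates": ..., "interval": ..., "logs": ...}.
    """
    config.validate()
    estimates: list[tuple[str, PrevalenceEstimate]] = []
    logs = []
    for name, db in config.databases.items():
        est, log = estimate_database(
            db["summary"], db["dialect"], int(db["n_individuals"]),
            database_name=name, classification_path=db.get("classification"),
            penetrance=config.penetrance, ci_level=config.ci_level,
            unmatched_policy=config.unmatched_policy)
        estimates.append((name, est))
        logs.append(log)
    interval = prevalence.prevalence_interval(estimates)
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        ests = [e for _, e in estimates]
        cohort_io.write_report(ests, outdir / "prevalence_report.tsv", "tsv")
        cohort_io.write_report(ests, outdir / "prevalence_report.json", "json",
                               provenance={"interval": interval.as_dict(), "logs": logs})
    return {"estimates": estimates, "interval": interval, "logs": logs}


def reproduce_reference_analysis(output_dir: Optional[Path] = None,
                                 metadata_path=None) -> dict:
    """Reproduce the published TTR prevalence analysis from the bundled tables.

    Returns a flat dict of the headline quantities:

    - gnomAD pooled: variant/allele/homozygote totals, aggregate MAF and
      prevalence per 100,000 (N = 125,780 exomes on average at the locus);
    - African / non-African stratification: the African allele frequency
      (402 alleles in 12,487 exomes) and the non-African prevalence (65
      alleles in 113,261 exomes), plus the exactly-derived complement of
      the subtraction (which differs from the reported 65 — flagged);
    - ChinaMAP and clinical-exome estimates and the cross-database
      prevalence interval for mainland China.
    """
    meta = cohort_io.load_cohort_metadata(metadata_path)

    # --- gnomAD pooled ----------------------------------------------------
    g = meta["gnomAD"]
    est_gnomad, log_gnomad = estimate_database(
        DATA_DIR / g["summary_table"], g["dialect"], g["n_average_exomes"],
        database_name="gnomAD")
    agg_gnomad = AggregateCounts(
        population=ALL, n_variants=log_gnomad["disease_causing"],
        total_allele_count=log_gnomad["total_count"],
        total_homozygotes=log_gnomad["homozygotes"],
        cohort_individuals=g["n_average_exomes"], unit=CountUnit.ALLELES)
    maf_gnomad = prevalence.aggregate_maf(agg_gnomad)

    # --- African / non-African stratification -----------------------------
    strat = g["stratification"]
    afr = strat["African/African-American"]
    non_afr = strat["non-African"]
    afr_af = afr["allele_count"] / (2 * afr["n_individuals"])
    agg_non_afr = AggregateCounts(
        population="non-African", n_variants=agg_gnomad.n_variants,
        total_allele_count=non_afr["allele_count"],
        total_homozygotes=non_afr["homozygote_count"],
        cohort_individuals=non_afr["n_individuals"], unit=CountUnit.ALLELES)
    est_non_afr = prevalence.prevalence_carrier_method(agg_non_afr, database="gnomAD")

    # Exact complement of the African split within the sequenced cohort; the
    # reported non-African allele count differs (undocumented exclusions in
    # the source), so the reported counts above drive the headline number.
    agg_total_seq = dataclasses.replace(agg_gnomad, cohort_individuals=g["n_sequenced"])
    agg_afr = AggregateCounts(
        population="African/African-American", n_variants=1,
        total_allele_count=afr["allele_count"],
        total_homozygotes=afr["homozygote_count"],
        cohort_individuals=afr["n_individuals"], unit=CountUnit.ALLELES)
    derived = prevalence.stratify_complement(agg_total_seq, agg_afr)
    if derived.total_allele_count != non_afr["allele_count"]:
        logger.warning(
            "derived non-African complement (%d alleles) differs from the "
            "reported count (%d); using the reported numbers",
            derived.total_allele_count, non_afr["allele_count"])

    # --- ChinaMAP ----------------------------------------------------------
    c = meta["ChinaMAP"]
    est_chinamap, log_chinamap = estimate_database(
        DATA_DIR / c["summary_table"], c["dialect"], c["n_individuals"],
        database_name="ChinaMAP")

    # --- clinical referral exomes ------------------------------------------
    a = meta["Amcarelab"]
    est_amcare, log_amcare = estimate_database(
        DATA_DIR / a["summary_table"], a["dialect"], a["n_individuals"],
        database_name="Amcarelab")

    # --- cross-database interval for mainland China ------------------------
    interval = prevalence.prevalence_interval(
        [("ChinaMAP", est_chinamap), ("Amcarelab", est_amcare)])

    results = {
        "gnomad": est_gnomad,
        "gnomad_aggregate": agg_gnomad,
        "gnomad_maf": maf_gnomad,
        "african_allele_frequency": afr_af,
        "non_african": est_non_afr,
        "derived_non_african_complement": derived,
        "chinamap": est_chinamap,
        "amcarelab": est_amcare,
        "china_interval": interval,
        "logs": [log_gnomad, log_chinamap, log_amcare],
    }
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        ests = [est_gnomad, est_non_afr, est_chinamap, est_amcare]
        cohort_io.write_report(ests, outdir / "prevalence_report.tsv", "tsv")
        cohort_io.write_report(
            ests, outdir / "prevalence_report.json", "json",
            provenance={"interval": interval.as_dict(),
                        "african_allele_frequency": afr_af,
                        "logs": results["logs"]})
    return results
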