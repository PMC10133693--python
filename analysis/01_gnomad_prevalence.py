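#!/usr/bin/env python
"""Pooled prevalence of hereditary TTR amyloidosis from the gnomAD summary.

Reads the bundled gnomAD v2.1.1 TTR disease-causing variant table, runs the
missense + ACMG pathogenic/likely-pathogenic filter, aggregates allele and
homozygote counts and estimates carrier-frequency prevalence per 100,000
(N = 125,780 exomes on average at the locus).

Writes results/gnomad_prevalence.{tsv,json}.
"""

from pathlib import Path

from varprev.cohort_io import DATA_DIR, load_cohort_metadata, write_report
from varprev.pipeline import estimate_database
from varprev.prevalence import display_frequency, display_prevalence

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    meta = load_cohort_metadata()["gnomAD"]
    est, log = estimate_database(
        DATA_DIR / meta["summary_table"], meta["dialect"],
        meta["n_average_exomes"], database_name="gnomAD")

    print(f"{log['rows_in']} variants read; {log['missense']} missense; "
          f"{log['disease_causing']} disease-causing "
          f"({log['total_count']} alleles, {log['homozygotes']} homozygotes)")
    print(f"carriers: {est.carriers} of {meta['n_average_exomes']} individuals")
    print(f"aggregate disease-allele frequency: {display_frequency(est.maf)}")
    print(f"prevalence: {display_prevalence(est.prevalence_per_100k)}/100,000 "
          f"(95% CI {display_prevalence(est.ci_low)}-{display_prevalence(est.ci_high)})")

    RESULTS.mkdir(exist_ok=True)
    write_report([est], RESULTS / "gnomad_prevalence.tsv", "tsv")
    write_report([est], RESULTS / "gnomad_prevalence.json", "json",
                 provenance={"stage_log": log})
    print(f"wrote {RESULTS / 'gnomad_prevalence.tsv'}")


if __name__ == "__main__":
    main()
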