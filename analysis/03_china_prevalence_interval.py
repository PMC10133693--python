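#!/usr/bin/env python
"""Mainland-China prevalence interval from the two Chinese databases.

ChinaMAP (population cohort, N = 10,588, allele counts) and the clinical
referral-exome cohort (N = 45,392, carrier-individual counts) each yield a
carrier-frequency prevalence; the cross-database interval is the min-max
envelope of the two point estimates.

Writes results/china_interval.{tsv,json}.
"""

from pathlib import Path

from varprev.cohort_io import DATA_DIR, load_cohort_metadata, write_report
from varprev.pipeline import estimate_database
from varprev.prevalence import display_prevalence, prevalence_interval

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    meta = load_cohort_metadata()
    estimates = []
    for name in ("ChinaMAP", "Amcarelab"):
        db = meta[name]
        est, log = estimate_database(DATA_DIR / db["summary_table"], db["dialect"],
                                     db["n_individuals"], database_name=name)
        unit = "alleles" if name == "ChinaMAP" else "individuals"
        print(f"{name}: {log['disease_causing']} disease-causing variants, "
              f"{log['total_count']} {unit} -> "
              f"{display_prevalence(est.prevalence_per_100k)}/100,000")
        estimates.append((name, est))

    iv = prevalence_interval(estimates)
    print(f"estimated prevalence interval for mainland China: "
          f"{display_prevalence(iv.low)}-{display_prevalence(iv.high)}/100,000")

    RESULTS.mkdir(exist_ok=True)
    write_report([e for _, e in estimates], RESULTS / "china_interval.tsv", "tsv")
    write_report([e for _, e in estimates], RESULTS / "china_interval.json", "json",
                 provenance={"interval": iv.as_dict()})
    print(f"wrote {RESULTS / 'china_interval.tsv'}")


if __name__ == "__main__":
    main()
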