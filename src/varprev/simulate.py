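"""Synthetic population sequencing cohorts with known truth.

Diploid genotypes are sampled per individual and variant under
Hardy-Weinberg equilibrium at specified per-population allele frequencies:
P(dosage 2) = p^2, P(1) = 2p(1-p), P(0) = (1-p)^2, variants unlinked.
The genotype matrix supports an exact carrier oracle (individuals with
dosage >= 1 at any disease-causing variant, each counted once), which
validates the summary-level carrier rule AC - hom and quantifies its
compound-heterozygote overcount.

Randomness is reproducible: a single global seed expands into independent
substreams per (population, variant) via stable hashing, so adding a
variant to a spec does not perturb the draws of the others.

Bundled spec factories emulate the three reference database shapes: a
gnomAD-like multi-ancestry exome cohort (125,748 individuals, 8
populations, allele frequencies spanning ~4e-6 to 2e-2 with one
African-enriched variant), a ChinaMAP-like population cohort (10,588) and
a clinical-exome-like cohort (45,392).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort_io import (
    ALL,
    AcmgCategory,
    CohortRow,
    CohortTable,
    CountUnit,
    PopulationCounts,
)
from .variants import (
    Consequence,
    GenomicLocation,
    VariantRecord,
    infer_consequence,
    parse_hgvs_c,
    parse_hgvs_p,
)


@dataclass
class SimVariant:
    """A simulated variant: record, true per-population allele frequency, category."""

    record: VariantRecord
    freqs: dict[str, float]
    category: AcmgCategory = AcmgCategory.UNCERTAIN_SIGNIFICANCE

    def __post_init__(self) -> None:
        bad = {p: f for p, f in self.freqs.items() if not 0.0 <= f <= 1.0}
        if bad:
            raise ValueError(f"allele frequencies outside [0, 1]: {bad}")


@dataclass
class CohortSimSpec:
    """Specification of a synthetic cohort: populations, variants, seed."""

    populations: list[tuple[str, int]]
    variants: list[SimVariant]
    seed: int
    linkage: str = "independent"
    database_name: str = "simulated"

    def __post_init__(self) -> None:
        if self.linkage != "independent":
            raise ValueError("only independent (unlinked) variants are supported")
        for label, n in self.populations:
            if n < 1:
                raise ValueError(f"population {label!r} needs n_individuals >= 1")

    @property
    def n_individuals(self) -> int:
        return sum(n for _, n in self.populations)


@dataclass
class GenotypeMatrix:
    """Individuals x variants alternate-allele dosages (0/1/2)."""

    genotypes: np.ndarray  # shape (N, V), int8
    variants: list[SimVariant]
    population_labels: np.ndarray  # shape (N,), str
    database_name: str = "simulated"

    def __post_init__(self) -> None:
        n, v = self.genotypes.shape
        if len(self.population_labels) != n or len(self.variants) != v:
            raise ValueError("genotype matrix dimensions disagree with labels/variants")


def _substream(seed: int, population: str, variant: SimVariant) -> np.random.Generator:
    """Independent RNG stream keyed by (seed, population, variant identity)."""
    key = variant.record.cdna.canonical if variant.record.cdna else str(variant.record.key)
    digest = hashlib.sha256(f"{population}|{key}".encode()).digest()
    return np.random.default_rng(
        np.random.SeedSequence([seed, int.from_bytes(digest[:8], "big")]))


def simulate(spec: CohortSimSpec) -> GenotypeMatrix:
    """Draw the diploid genotype matrix of a synthetic cohort under HWE."""
    n_total = spec.n_individuals
    gm = np.zeros((n_total, len(spec.variants)), dtype=np.int8)
    labels = np.empty(n_total, dtype=object)
    start = 0
    for pop, n in spec.populations:
        stop = start + n
        labels[start:stop] = pop
        for j, variant in enumerate(spec.variants):
            p = variant.freqs.get(pop, 0.0)
            if p == 0.0:
                continue
            u = _substream(spec.seed, pop, variant).random(n)
            # cumulative HWE genotype probabilities: [p^2, p^2 + 2p(1-p), 1]
            gm[start:stop, j] = np.where(u < p * p, 2,
                                         np.where(u < p * p + 2 * p * (1 - p), 1, 0))
        start = stop
    return GenotypeMatrix(genotypes=gm, variants=list(spec.variants),
                          population_labels=labels, database_name=spec.database_name)


def summarize(gm: GenotypeMatrix) -> CohortTable:
    """Collapse a genotype matrix to per-population + pooled summary counts.

    AC is the dosage column sum, the homozygote count the number of 2s,
    AN = 2 x individuals; allele conservation is exact by construction.
    """
    pops = list(dict.fromkeys(gm.population_labels))  # stable order
    masks = {pop: gm.population_labels == pop for pop in pops}
    rows: list[CohortRow] = []
    n_total = gm.genotypes.shape[0]
    for j, variant in enumerate(gm.variants):
        col = gm.genotypes[:, j]
        counts: dict[str, PopulationCounts] = {}
        for pop in pops:
            sub = col[masks[pop]]
            n = int(masks[pop].sum())
            counts[pop] = PopulationCounts(
                population=pop, allele_count=int(sub.sum()),
                homozygote_count=int((sub == 2).sum()),
                allele_number=2 * n, cohort_individuals=n)
        if ALL not in counts:
            counts[ALL] = PopulationCounts(
                population=ALL, allele_count=int(col.sum()),
                homozygote_count=int((col == 2).sum()),
                allele_number=2 * n_total, cohort_individuals=n_total)
        rows.append(CohortRow(record=variant.record, counts=counts))
    return CohortTable(database_name=gm.database_name, unit=CountUnit.ALLELES, rows=rows)


def classification_of(spec_or_gm) -> dict[str, AcmgCategory]:
    """True categories of the simulated variants, keyed by cDNA notation."""
    variants = spec_or_gm.variants
    return {v.record.cdna.canonical: v.category for v in variants if v.record.cdna}


def oracle_carrier_count(gm: GenotypeMatrix,
                         disease_causing: Optional[Sequence[int]] = None) -> int:
    """Exact number of carrier individuals in the genotype matrix.

    An individual with dosage >= 1 at ANY disease-causing variant counts
    once, however many such alleles they carry — unlike the summary-level
    rule AC - hom, which counts a compound heterozygote once per variant.
    Hence oracle <= AC - hom always, with equality iff nobody carries
    pathogenic alleles at more than one variant.
    """
    if disease_causing is None:
        disease_causing = [j for j, v in enumerate(gm.variants)
                           if v.category in (AcmgCategory.PATHOGENIC,
                                             AcmgCategory.LIKELY_PATHOGENIC)]
    idx = list(disease_causing)
    if not idx:
        return 0
    return int((gm.genotypes[:, idx] >= 1).any(axis=1).sum())


# ---------------------------------------------------------------------------
# Bundled spec factories emulating the reference database shapes
# ---------------------------------------------------------------------------

def _variant(cdna: str, protein: str, pos: int,
             category: AcmgCategory, freqs: dict[str, float]) -> SimVariant:
    c = parse_hgvs_c(cdna)
    p = parse_hgvs_p(protein)
    rec = VariantRecord(
        location=GenomicLocation("chr18", pos, c.ref, c.alt) if c.ref else None,
        transcript="NM_000371.4", protein_id="NP_000362.1", cdna=c, protein=p)
    rec.consequence = infer_consequence(rec)
    return SimVariant(record=rec, freqs=freqs, category=category)


#: gnomAD v2.1.1-like exome population sizes. African/African-American is
#: fixed at the reported 12,487; the remaining seven are realistic relative
#: sizes chosen to total 125,748.
GNOMAD_LIKE_POPULATIONS: list[tuple[str, int]] = [
    ("non-Finnish European", 54596),
    ("African/African-American", 12487),
    ("Latino", 17296),
    ("South Asian", 15308),
    ("East Asian", 9197),
    ("Finnish", 10824),
    ("Ashkenazi Jewish", 5040),
    ("other", 1000),
]


def gnomad_like_spec(seed: int) -> CohortSimSpec:
    """Multi-ancestry exome cohort: six TTR disease-causing variants whose
    pooled frequencies ladder from 4e-6 to 1.7e-3, with the V142I variant
    African-enriched (0.016 in African/African-American, rare elsewhere),
    plus a synonymous and a benign missense variant to exercise filtering.
    """
    pops = [p for p, _ in GNOMAD_LIKE_POPULATIONS]
    afr = "African/African-American"
    non_afr = [p for p in pops if p != afr]

    def uniform(f: float) -> dict[str, float]:
        return {p: f for p in pops}

    # V142I: 0.016 in African ancestry; elsewhere set so the pooled
    # expectation matches an overall frequency of 0.00174.
    n_afr = dict(GNOMAD_LIKE_POPULATIONS)[afr]
    n_tot = sum(n for _, n in GNOMAD_LIKE_POPULATIONS)
    f_rest = (0.00174 * n_tot - 0.016 * n_afr) / (n_tot - n_afr)
    v142i_freqs = {p: f_rest for p in non_afr}
    v142i_freqs[afr] = 0.016

    lp = AcmgCategory.LIKELY_PATHOGENIC
    pa = AcmgCategory.PATHOGENIC
    variants = [
        _variant("c.148G>A", "p.V50M", 29172937, pa, uniform(0.000103)),
        _variant("c.238A>G", "p.T80A", 29175120, pa, uniform(0.00000398)),
        _variant("c.250T>C", "p.F84L", 29175132, pa, uniform(0.00000398)),
        _variant("c.262A>T", "p.I88L", 29175144, lp, uniform(0.0000199)),
        _variant("c.349G>T", "p.A117S", 29178543, lp, uniform(0.00000795)),
        _variant("c.424G>A", "p.V142I", 29178618, lp, v142i_freqs),
        # non-disease-causing context rows
        _variant("c.57G>A", "p.G19G", 29172846, AcmgCategory.BENIGN, uniform(0.002)),
        _variant("c.76G>A", "p.G26S", 29172865, AcmgCategory.BENIGN, uniform(0.06)),
    ]
    return CohortSimSpec(populations=list(GNOMAD_LIKE_POPULATIONS), variants=variants,
                         seed=seed, database_name="gnomad_like_sim")


def chinamap_like_spec(seed: int) -> CohortSimSpec:
    """Single-population cohort of 10,588 with two rare disease-causing
    variants (one expected allele each) and a common benign variant."""
    pop = [("Chinese", 10588)]
    f1 = 1 / (2 * 10588)
    variants = [
        _variant("c.148G>A", "p.V50M", 29172937, AcmgCategory.PATHOGENIC, {"Chinese": f1}),
        _variant("c.424G>A", "p.V142I", 29178618, AcmgCategory.LIKELY_PATHOGENIC, {"Chinese": f1}),
        _variant("c.76G>A", "p.G26S", 29172865, AcmgCategory.BENIGN, {"Chinese": 0.04}),
    ]
    return CohortSimSpec(populations=pop, variants=variants, seed=seed,
                         database_name="chinamap_like_sim")


def clinical_exome_like_spec(seed: int) -> CohortSimSpec:
    """Referral-exome cohort of 45,392 with a broader ladder of rare
    disease-causing variants (expected ~34 carrier individuals total)."""
    n = 45392
    pop = [("referral", n)]
    lp = AcmgCategory.LIKELY_PATHOGENIC
    # frequencies chosen so expected total alleles ~ 34 over the set
    per_allele = 1 / (2 * n)
    freq_ladder = [8, 5, 4, 3, 3, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1]
    cdnas = ["c.148G>A", "c.349G>T", "c.113A>G", "c.241G>A", "c.325G>A",
             "c.424G>A", "c.165G>T", "c.199G>A", "c.210T>A", "c.214T>C",
             "c.221A>C", "c.224T>G", "c.290C>T", "c.311T>A", "c.401A>G"]
    proteins = ["p.V50M", "p.A117S", "p.D38G", "p.E81K", "p.E109K",
                "p.V142I", "p.K55N", "p.G67R", "p.S70R", "p.S72P",
                "p.E74A", "p.L75R", "p.S97F", "p.I104N", "p.Y134C"]
    positions = [29172937, 29178543, 29172902, 29175123, 29175207,
                 29178618, 29172954, 29172988, 29175092, 29175096,
                 29175103, 29175106, 29175172, 29175193, 29178595]
    variants = [
        _variant(c, p, pos,
                 AcmgCategory.PATHOGENIC if c == "c.148G>A" else lp,
                 {"referral": k * per_allele})
        for c, p, pos, k in zip(cdnas, proteins, positions, freq_ladder)
    ]
    return CohortSimSpec(populations=pop, variants=variants, seed=seed,
                         database_name="clinical_exome_like_sim")
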