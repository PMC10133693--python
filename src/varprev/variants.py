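"""Core variant domain model: genomic locations, HGVS c./p. notation, and
consequence-class inference for single-gene variant records.

The HGVS support here is deliberately minimal: single-nucleotide
substitutions at the cDNA level (including intronic offsets and UTR
positions) and simple protein changes (substitution, identity, stop gain,
frameshift marker). That covers every variant shape occurring in gene-level
summary tables for a missense-driven disease like hereditary transthyretin
amyloidosis; delins/dup/repeat syntax is out of scope.

Protein positions for TTR appear in two historical numbering schemes: the
mature protein (legacy "V30M") and the full precursor including the
20-residue signal peptide ("V50M"). :class:`NumberingScheme` and
:func:`convert_numbering` reconcile the two.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Optional

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicLocation",
    "HgvsC",
    "HgvsP",
    "VariantRecord",
    "NumberingScheme",
    "Consequence",
    "HgvsParseError",
    "parse_hgvs_c",
    "parse_hgvs_p",
    "infer_consequence",
    "convert_numbering",
    "TTR_SIGNAL_PEPTIDE_LENGTH",
    "MATURE_PROTEIN",
    "FULL_PRECURSOR",
]

#: Signal-peptide length of the TTR preproprotein (residues 1-20); the
#: offset between legacy mature-protein numbering (V30M) and precursor
#: numbering (V50M).
TTR_SIGNAL_PEPTIDE_LENGTH = 20

AA_3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}
AA_1 = set(AA_3TO1.values()) - {"*"}

_NUCS = frozenset("ACGT")

_TRANSCRIPT_RE = re.compile(r"^(NM_|NR_|XM_|ENST)\d+(\.\d+)?$")


class HgvsParseError(ValueError):
    """Raised when an HGVS string cannot be parsed; names the bad token."""


class Consequence(str, enum.Enum):
    """Coarse molecular consequence classes used by the inclusion filter."""

    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    INTRONIC = "intronic"
    NONCODING = "noncoding"
    OTHER = "other"


@dataclass(frozen=True)
class GenomicLocation:
    """A 1-based GRCh37 point substitution: contig, position, ref, alt."""

    contig: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"position must be positive, got {self.position}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _NUCS:
                raise ValueError(f"{name} allele {allele!r} is not a non-empty A/C/G/T string")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref!r})")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref, self.alt)


@dataclass(frozen=True)
class HgvsC:
    """A parsed cDNA substitution.

    ``region`` is ``cds`` for ordinary coding positions, ``utr5``/``utr3``
    for positions written with the ``-``/``*`` prefixes. ``offset`` is the
    intronic offset (0 for exonic positions). ``ref`` may be None: gene
    summary tables occasionally print the alt-only form ``c.148>A``.
    """

    position: int
    alt: str
    ref: Optional[str] = None
    offset: int = 0
    region: str = "cds"
    raw: str = ""

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"cDNA position must be positive, got {self.position}")
        if self.region not in ("cds", "utr5", "utr3"):
            raise ValueError(f"unknown region {self.region!r}")

    @property
    def intronic(self) -> bool:
        return self.offset != 0

    @property
    def canonical(self) -> str:
        prefix = {"cds": "", "utr5": "-", "utr3": "*"}[self.region]
        off = f"{self.offset:+d}" if self.offset else ""
        ref = self.ref or ""
        return f"c.{prefix}{self.position}{off}{ref}>{self.alt}"


@dataclass(frozen=True)
class HgvsP:
    """A parsed protein change in canonical 1-letter form.

    ``alt_aa`` is a 1-letter amino acid, ``*`` for a stop gain, or ``=``
    for identity (synonymous). A frameshift is flagged separately; its
    ``alt_aa`` is the first changed residue when given, else None.
    """

    ref_aa: str
    codon: int
    alt_aa: Optional[str]
    frameshift: bool = False
    raw: str = ""

    def __post_init__(self) -> None:
        if self.codon < 1:
            raise ValueError(f"codon must be >= 1, got {self.codon}")

    @property
    def is_synonymous(self) -> bool:
        return self.alt_aa == "="

    @property
    def is_stop_gain(self) -> bool:
        return self.alt_aa == "*"

    @property
    def canonical(self) -> str:
        if self.frameshift:
            return f"p.{self.ref_aa}{self.codon}{self.alt_aa or ''}fs"
        return f"p.{self.ref_aa}{self.codon}{self.alt_aa}"


@dataclass(frozen=True)
class NumberingScheme:
    """Protein residue numbering: mature chain vs full precursor.

    Mature-protein numbering omits the signal peptide, so precursor codon =
    mature codon + signal_peptide_length. For TTR the offset is 20
    (V30M mature == V50M precursor).
    """

    scheme: str  # "mature_protein" | "full_precursor"
    signal_peptide_length: int = TTR_SIGNAL_PEPTIDE_LENGTH

    def __post_init__(self) -> None:
        if self.scheme not in ("mature_protein", "full_precursor"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.signal_peptide_length < 0:
            raise ValueError("signal_peptide_length must be non-negative")


MATURE_PROTEIN = NumberingScheme("mature_protein")
FULL_PRECURSOR = NumberingScheme("full_precursor")


@dataclass
class VariantRecord:
    """One gene variant as a summary table or VCF row describes it."""

    location: Optional[GenomicLocation] = None
    transcript: Optional[str] = None
    protein_id: Optional[str] = None
    cdna: Optional[HgvsC] = None
    protein: Optional[HgvsP] = None
    consequence: Optional[Consequence] = None

    def __post_init__(self) -> None:
        if self.transcript is not None and not _TRANSCRIPT_RE.match(self.transcript):
            raise ValueError(f"transcript {self.transcript!r} is not a versioned RefSeq/Ensembl accession")

    @property
    def key(self):
        """Join key: genomic tuple when known, else (transcript, cDNA)."""
        if self.location is not None:
            return self.location.key
        if self.cdna is not None:
            return (self.transcript, self.cdna.canonical)
        raise ValueError("variant has neither genomic location nor cDNA notation")

    @property
    def label(self) -> str:
        if self.cdna is not None:
            p = f" ({self.protein.canonical})" if self.protein else ""
            return f"{self.cdna.canonical}{p}"
        if self.location is not None:
            c = self.location
            return f"{c.contig}:{c.position}{c.ref}>{c.alt}"
        return "<unlocated variant>"


_HGVS_C_RE = re.compile(
    r"^c\.(?P<utr3>\*)?(?P<utr5>-)?(?P<pos>\d+)(?P<off>[+-]\d+)?"
    r"(?P<ref>[ACGT])?>(?P<alt>[ACGT])$"
)


def _strip(raw: str) -> str:
    return re.sub(r"\s+", "", raw)


def parse_hgvs_c(raw: str) -> HgvsC:
    """Parse a cDNA substitution like ``c.148G>A`` or ``c.100+1G>T``.

    Whitespace anywhere in the string is tolerated (summary tables print
    forms like ``c.148 > A``). UTR positions (``c.-12A>G``, ``c.*34A>G``)
    and intronic offsets are recognized.
    """
    s = _strip(raw)
    if not s.startswith("c."):
        raise HgvsParseError(f"{raw!r}: expected 'c.' prefix")
    m = _HGVS_C_RE.match(s)
    if m is None:
        raise HgvsParseError(f"{raw!r}: not a recognized cDNA substitution")
    region = "utr3" if m["utr3"] else ("utr5" if m["utr5"] else "cds")
    return HgvsC(
        position=int(m["pos"]),
        offset=int(m["off"]) if m["off"] else 0,
        ref=m["ref"],
        alt=m["alt"],
        region=region,
        raw=raw,
    )


_AA_TOKEN_RE = re.compile(r"([A-Z][a-z]{2}|[A-Z*=])")


def _parse_aa(token: str, raw: str) -> str:
    if len(token) == 3:
        try:
            return AA_3TO1[token.capitalize()]
        except KeyError:
            raise HgvsParseError(f"{raw!r}: unknown amino-acid code {token!r}") from None
    if token in ("*", "X"):
        return "*"
    if token == "=":
        return "="
    if token in AA_1:
        return token
    raise HgvsParseError(f"{raw!r}: unknown amino-acid code {token!r}")


_HGVS_P_RE = re.compile(
    r"^(?P<ref>[A-Z][a-z]{2}|[A-Z])(?P<codon>\d+)"
    r"(?P<alt>[A-Z][a-z]{2}|[A-Z*=])?$"
)


def parse_hgvs_p(raw: str) -> HgvsP:
    """Parse a protein change like ``p.V50M``, ``p.(Val142Ile)``, ``p.Y116Ter``.

    3-letter and 1-letter codes normalize to the same canonical 1-letter
    form; predicted-change parentheses are stripped; identity written
    either ``p.V50=`` or ``p.V50V`` normalizes to the ``=`` marker.
    """
    s = _strip(raw)
    if not s.startswith("p."):
        raise HgvsParseError(f"{raw!r}: expected 'p.' prefix")
    body = s[2:]
    if body.startswith("(") and body.endswith(")"):
        body = body[1:-1]
    # frameshift marker: everything from "fs" on (e.g. "fs", "fs*12") is a flag,
    # not part of the amino-acid tokens ("fs" occurs in no 3-letter code)
    fs_idx = body.find("fs")
    frameshift = fs_idx != -1
    if frameshift:
        body = body[:fs_idx]
    m = _HGVS_P_RE.match(body)
    if m is None:
        raise HgvsParseError(f"{raw!r}: not a recognized protein change")
    ref = _parse_aa(m["ref"], raw)
    if ref == "=":
        raise HgvsParseError(f"{raw!r}: reference amino acid missing")
    alt = _parse_aa(m["alt"], raw) if m["alt"] else None
    if not frameshift:
        if alt is None:
            raise HgvsParseError(f"{raw!r}: missing alternate amino acid")
        if alt == ref:
            alt = "="  # p.V50V -> identity marker
    return HgvsP(ref_aa=ref, codon=int(m["codon"]), alt_aa=alt,
                 frameshift=frameshift, raw=raw)


def infer_consequence(record: VariantRecord, splice_window: int = 2) -> Consequence:
    """Assign a single consequence class to a variant record.

    Priority: frameshift and stop-gain from the protein notation; UTR and
    intronic/splice calls from the cDNA notation (positions within
    ``splice_window`` intronic bases of an exon boundary are ``splice``,
    deeper ones ``intronic``); then synonymous/missense from the amino
    acids. Start-loss (codon 1 Met substituted) is not a folding-change
    missense and falls through to ``other``. A record with neither an
    informative cDNA nor protein gets ``other`` with a warning rather than
    being dropped.
    """
    p = record.protein
    if p is not None and p.frameshift:
        return Consequence.FRAMESHIFT
    if p is not None and p.is_stop_gain:
        return Consequence.NONSENSE
    c = record.cdna
    if c is not None and c.region in ("utr5", "utr3"):
        return Consequence.NONCODING
    if c is not None and c.intronic:
        return Consequence.SPLICE if abs(c.offset) <= splice_window else Consequence.INTRONIC
    if p is not None:
        if p.is_synonymous:
            return Consequence.SYNONYMOUS
        if p.codon == 1 and p.ref_aa == "M":
            return Consequence.OTHER  # start-loss: not a substitution of the folded chain
        if p.ref_aa in AA_1 and p.alt_aa in AA_1 and p.ref_aa != p.alt_aa:
            return Consequence.MISSENSE
        return Consequence.OTHER
    logger.warning("variant %s has no informative cDNA or protein notation; classed 'other'",
                   record.label)
    return Consequence.OTHER


def annotate_consequence(record: VariantRecord, splice_window: int = 2) -> VariantRecord:
    """Return the record with its consequence field filled in."""
    record.consequence = infer_consequence(record, splice_window=splice_window)
    return record


def convert_numbering(p: HgvsP, from_scheme: NumberingScheme,
                      to_scheme: NumberingScheme) -> HgvsP:
    """Shift a protein change between mature and precursor numbering.

    Mature -> precursor adds the signal-peptide length to the codon;
    the reverse subtracts it. Amino acids are untouched. Converting to
    mature numbering fails for codons inside the signal peptide.
    """
    if from_scheme.signal_peptide_length != to_scheme.signal_peptide_length:
        raise ValueError("schemes disagree on signal_peptide_length")
    if from_scheme.scheme == to_scheme.scheme:
        return p
    shift = from_scheme.signal_peptide_length
    if from_scheme.scheme == "mature_protein":
        codon = p.codon + shift
    else:
        codon = p.codon - shift
        if codon <= 0:
            raise ValueError(
                f"codon {p.codon} lies within the {shift}-residue signal peptide; "
                "no mature-protein number exists")
    return replace(p, codon=codon, raw="")
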