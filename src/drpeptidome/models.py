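"""Core domain types for HLA-DRB1 immunopeptidome analysis.

The unit of analysis is an eluted peptide observed in one sample
(a monocyte-derived dendritic-cell preparation, either lysate-pulsed or
control). Each sample carries a pair of four-digit HLA-DRB1 alleles;
peptide-allele binding strength is expressed as a NetMHCIIpan-style
percentile rank (lower = stronger) and discretised into strong binder
(SB), weak binder (WB) and non-binder (NB) classes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

#: The 20 canonical amino-acid one-letter codes. Ambiguity codes (B, Z, X)
#: and non-residue characters are rejected on input.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(CANONICAL_AA)

#: Subcellular compartments used for peptide-generating-protein annotation.
COMPARTMENTS = ("CM", "S/EM", "C", "N", "Lys/End", "ER", "GA", "Mit", "other")

_ALLELE_RE = re.compile(
    r"^(?:HLA-)?DRB1[*_](?P<group>\d{1,3}):(?P<protein>\d{1,3})$"
)


class BindingClass(str, Enum):
    SB = "SB"
    WB = "WB"
    NB = "NB"


class Group(str, Enum):
    CONTROL = "control"
    PULSED = "pulsed"


class AssignmentMode(str, Enum):
    FILTERED = "filtered"
    NONFILTERED = "nonfiltered"


class SharingCategory(str, Enum):
    """Sharing status of a (peptide, allele-unit) association.

    unique            exclusive to one allele in a single sample
    dual              on both alleles of one sample, nowhere else
    multiple          present in units spanning different alleles/samples
    allele_exclusive  in more than one sample but always on the same allele
    """

    UNIQUE = "unique"
    DUAL = "dual"
    MULTIPLE = "multiple"
    ALLELE_EXCLUSIVE = "allele_exclusive"


def canonical_allele(name: str) -> str:
    """Normalise an HLA-DRB1 allele name to ``DRB1*dd:dd`` form.

    Accepts the ``HLA-`` prefixed variant, colon-less four-digit form
    (``DRB1*0101``) and unpadded fields. Only the DRB1 locus is supported;
    secondary DRB loci (DRB3/4/5) and other class II genes are out of scope.
    """
    s = name.strip()
    m = _ALLELE_RE.match(s)
    if m is None:
        m2 = re.match(r"^(?:HLA-)?DRB1[*_](\d{4})$", s)
        if m2:
            d = m2.group(1)
            return f"DRB1*{d[:2]}:{d[2:]}"
        raise ValueError(f"not a valid HLA-DRB1 allele name: {name!r}")
    grp = int(m.group("group"))
    prot = int(m.group("protein"))
    return f"DRB1*{grp:02d}:{prot:02d}"


def validate_sequence(seq: str) -> str:
    """Return ``seq`` uppercased, or raise ValueError for non-canonical residues."""
    s = seq.strip().upper()
    if not s:
        raise ValueError("empty peptide sequence")
    bad = set(s) - _AA_SET
    if bad:
        raise ValueError(
            f"non-canonical residue(s) {sorted(bad)} in peptide {seq!r}"
        )
    return s


@dataclass
class PeptideRecord:
    """One eluted peptide observed in one sample."""

    sequence: str
    sample_id: str
    source_accessions: frozenset[str] = frozenset()
    intensity: float | None = None

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence)
        self.source_accessions = frozenset(self.source_accessions)
        if self.intensity is not None and self.intensity < 0:
            raise ValueError("intensity must be non-negative")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SampleInfo:
    """Sample identity, experimental group and ordered DRB1 typing.

    ``allele_a <= allele_b`` lexicographically (canonical order); a
    homozygous sample has ``allele_a == allele_b``.
    """

    sample_id: str
    group: Group
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        a = canonical_allele(self.allele_a)
        b = canonical_allele(self.allele_b)
        if a > b:
            a, b = b, a
        object.__setattr__(self, "allele_a", a)
        object.__setattr__(self, "allele_b", b)
        object.__setattr__(self, "group", Group(self.group))

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_a, self.allele_b)

    @property
    def is_homozygous(self) -> bool:
        return self.allele_a == self.allele_b


@dataclass(frozen=True)
class Thresholds:
    """Percent-rank cut-offs for SB/WB classification.

    SB: rank in [0, sb_max); WB: [sb_max, wb_max]; NB: (wb_max, 100].
    The half-open convention closes the gap the strict inequalities of the
    usual "SB < 1, 1 < WB < 5" phrasing leave at exactly 1 and 5 without
    reclassifying any interior value.
    """

    sb_max: float = 1.0
    wb_max: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.sb_max < self.wb_max <= 100):
            raise ValueError(
                f"require 0 < sb_max < wb_max <= 100, got {self.sb_max}, {self.wb_max}"
            )


@dataclass(frozen=True)
class BindingCall:
    """Predicted percent-rank of one (peptide, allele) pair plus its class."""

    peptide: str
    allele: str
    percent_rank: float
    binding_class: BindingClass

    def __post_init__(self) -> None:
        object.__setattr__(self, "allele", canonical_allele(self.allele))
        if not (0.0 <= self.percent_rank <= 100.0):
            raise ValueError(
                f"percent rank {self.percent_rank} outside [0, 100] "
                f"for {self.peptide}/{self.allele}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """A peptide-generating protein with optional subcellular localisations.

    Multi-compartment proteins keep every annotated localisation and are
    counted once per compartment in enrichment analyses.
    """

    accession: str
    localizations: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "localizations", frozenset(self.localizations))
        bad = set(self.localizations) - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartment(s) {sorted(bad)}")


@dataclass
class AssignmentTable:
    """Per-sample mapping peptide -> allele set.

    In filtered mode every peptide maps to exactly one allele (its
    best-ranked binder); in non-filtered mode dual peptides map to both
    co-expressed alleles.
    """

    sample_id: str
    mode: AssignmentMode
    entries: dict[str, frozenset[str]] = field(default_factory=dict)
    alleles: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.mode = AssignmentMode(self.mode)
        self.entries = {p: frozenset(a) for p, a in self.entries.items()}
        for pep, al in self.entries.items():
            if self.mode is AssignmentMode.FILTERED and len(al) != 1:
                raise ValueError(
                    f"filtered assignment for {pep} must name exactly one allele"
                )
            if not 1 <= len(al) <= 2:
                raise ValueError(f"assignment for {pep} must name 1 or 2 alleles")
            if self.alleles is not None and not al <= set(self.alleles):
                raise ValueError(
                    f"assignment for {pep} uses alleles outside the sample typing"
                )

    @property
    def peptides(self) -> list[str]:
        return list(self.entries)

    def dual_peptides(self) -> list[str]:
        return [p for p, a in self.entries.items() if len(a) == 2]

    def peptides_of(self, allele: str) -> list[str]:
        allele = canonical_allele(allele)
        return [p for p, a in self.entries.items() if allele in a]

    def exclusive_peptides_of(self, allele: str) -> list[str]:
        allele = canonical_allele(allele)
        return [p for p, a in self.entries.items() if a == {allele}]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssignmentTable):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.mode == other.mode
            and self.entries == other.entries
        )


def index_calls(calls: Iterable[BindingCall]) -> dict[tuple[str, str], BindingCall]:
    """Index binding calls by (peptide, allele); duplicate keys are an error."""
    out: dict[tuple[str, str], BindingCall] = {}
    for c in calls:
        key = (c.peptide, c.allele)
        if key in out and out[key].percent_rank != c.percent_rank:
            raise ValueError(f"conflicting duplicate binding call for {key}")
        out[key] = c
    return out
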