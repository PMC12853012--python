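"""Dominance ratios, SB/WB fractions, overlap matrices and sharing classes.

The unit of comparison is an *allele unit*: one (sample, DRB1 allele)
pair. The same allele carried by two donors yields two distinct units, so
inter-donor reproducibility of an allele's repertoire is itself measurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    AssignmentMode,
    AssignmentTable,
    BindingCall,
    BindingClass,
    PeptideRecord,
    SampleInfo,
    SharingCategory,
    index_calls,
)


@dataclass(frozen=True, order=True)
class AlleleUnit:
    sample_id: str
    allele: str

    def __str__(self) -> str:
        return f"{self.sample_id}:{self.allele}"


@dataclass
class DominanceResult:
    """Exclusive-peptide count ratio between the two alleles of a sample.

    ``ratio = n_x / n_y`` (allele_x is the canonically first allele);
    ratio > 1 means allele X dominates presentation. The ratio is +inf
    when only X has exclusive peptides and NaN when neither does, or when
    the sample is homozygous (``applicable`` is False).
    """

    sample_id: str
    allele_x: str
    allele_y: str
    n_x: int
    n_y: int
    ratio: float
    inverse_ratio: float
    applicable: bool = True


def dominance_ratio(table: AssignmentTable, sample: SampleInfo) -> DominanceResult:
    """Ratio of peptide counts exclusively assigned to allele X vs allele Y.

    Normally computed on a filtered assignment (where every peptide is
    exclusive to one allele); on a non-filtered table, dual peptides are
    excluded and only exclusive counts enter the ratio.
    """
    if table.sample_id != sample.sample_id:
        raise ValueError("assignment table does not belong to this sample")
    x, y = sample.alleles
    if sample.is_homozygous:
        n = len(table.entries)
        return DominanceResult(
            sample.sample_id, x, y, n, n, math.nan, math.nan, applicable=False
        )
    n_x = len(table.exclusive_peptides_of(x))
    n_y = len(table.exclusive_peptides_of(y))
    if n_y > 0:
        ratio = n_x / n_y
    elif n_x > 0:
        ratio = math.inf
    else:
        ratio = math.nan
    if n_x > 0:
        inverse = n_y / n_x
    elif n_y > 0:
        inverse = math.inf
    else:
        inverse = math.nan
    return DominanceResult(sample.sample_id, x, y, n_x, n_y, ratio, inverse)


def sbwb_fractions(
    calls: Iterable[BindingCall] | Mapping[tuple[str, str], BindingCall],
    table: AssignmentTable,
    sample: SampleInfo,
) -> dict[str, tuple[float, float]]:
    """Normalised (SB fraction, WB fraction) per allele unit of a sample.

    For each allele, the fractions of its assigned binder peptides that
    are strong vs weak binders for that allele; SB + WB == 1. Alleles with
    no assigned peptides are omitted.
    """
    idx = calls if isinstance(calls, Mapping) else index_calls(calls)
    out: dict[str, tuple[float, float]] = {}
    for allele in dict.fromkeys(sample.alleles):
        peps = table.peptides_of(allele)
        n_sb = n_wb = 0
        for pep in peps:
            call = idx.get((pep, allele))
            if call is None:
                raise ValueError(f"no binding call for ({pep}, {allele})")
            if call.binding_class is BindingClass.SB:
                n_sb += 1
            elif call.binding_class is BindingClass.WB:
                n_wb += 1
            else:
                raise ValueError(
                    f"non-binder ({pep}, {allele}) present in assignment table"
                )
        total = n_sb + n_wb
        if total:
            out[allele] = (n_sb / total, n_wb / total)
    return out


@dataclass
class OverlapMatrix:
    """Row-normalised sharing fractions between allele units.

    Off-diagonal (i, j) is the fraction of unit i's items also seen in
    unit j — symmetric in support but not in value, since rows are
    normalised by each unit's own repertoire size. The diagonal holds the
    exclusivity fraction: items of unit i found in no other unit.
    """

    units: list[AlleleUnit]
    values: np.ndarray
    level: str

    def to_dataframe(self) -> pd.DataFrame:
        labels = [str(u) for u in self.units]
        return pd.DataFrame(self.values, index=labels, columns=labels)


def _unit_items(
    tables: Sequence[AssignmentTable],
    samples: Mapping[str, SampleInfo],
    level: str,
    peptides: Sequence[PeptideRecord] | None,
) -> dict[AlleleUnit, frozenset[str]]:
    acc_of: dict[tuple[str, str], frozenset[str]] = {}
    if level == "protein":
        if peptides is None:
            raise ValueError("protein-level overlap needs peptide records")
        for rec in peptides:
            key = (rec.sample_id, rec.sequence)
            acc_of[key] = acc_of.get(key, frozenset()) | rec.source_accessions
    items: dict[AlleleUnit, frozenset[str]] = {}
    for t in tables:
        sample = samples[t.sample_id]
        for allele in dict.fromkeys(sample.alleles):
            unit = AlleleUnit(t.sample_id, allele)
            peps = t.peptides_of(allele)
            if level == "peptide":
                items[unit] = frozenset(peps)
            else:
                accs: set[str] = set()
                for p in peps:
                    accs |= acc_of.get((t.sample_id, p), frozenset())
                items[unit] = frozenset(accs)
    return items


def overlap_matrix(
    tables: Sequence[AssignmentTable],
    samples: Iterable[SampleInfo],
    level: str = "peptide",
    peptides: Sequence[PeptideRecord] | None = None,
) -> OverlapMatrix:
    """Pairwise repertoire overlap between all allele units.

    ``level='peptide'`` compares peptide sets; ``level='protein'``
    compares peptide-generating-protein (PGP) accession sets. Units with
    an empty repertoire yield a row of NaN.
    """
    if level not in ("peptide", "protein"):
        raise ValueError(f"unknown overlap level {level!r}")
    sample_map = {s.sample_id: s for s in samples}
    items = _unit_items(tables, sample_map, level, peptides)
    units = sorted(items)
    n = len(units)
    values = np.zeros((n, n))
    sets = [items[u] for u in units]
    for i in range(n):
        if not sets[i]:
            values[i, :] = np.nan
            continue
        others: set[str] = set()
        for j in range(n):
            if j == i:
                continue
            values[i, j] = len(sets[i] & sets[j]) / len(sets[i])
            others |= sets[j]
        values[i, i] = len(sets[i] - others) / len(sets[i])
    return OverlapMatrix(units=units, values=values, level=level)


def _occurrences(
    tables: Sequence[AssignmentTable],
) -> dict[str, set[AlleleUnit]]:
    occ: dict[str, set[AlleleUnit]] = {}
    for t in tables:
        for pep, alleles in t.entries.items():
            for a in alleles:
                occ.setdefault(pep, set()).add(AlleleUnit(t.sample_id, a))
    return occ


def classify_sharing(
    peptide: str,
    unit: AlleleUnit,
    tables: Sequence[AssignmentTable],
) -> SharingCategory:
    """Four-way sharing class of one (peptide, allele-unit) association.

    unique — the peptide occurs in exactly one unit across the whole
    analysis set; dual — in both alleles of one sample and nowhere else;
    allele_exclusive — in two or more samples but always on the same
    allele; multiple — anything spanning several alleles across samples
    (cross-sample presence dominates over within-sample duality).
    """
    occ = _occurrences(tables).get(peptide, set())
    if unit not in occ:
        raise ValueError(f"peptide {peptide} is not assigned to unit {unit}")
    return _categorise(occ)


def _categorise(occ: set[AlleleUnit]) -> SharingCategory:
    samples = {u.sample_id for u in occ}
    alleles = {u.allele for u in occ}
    if len(occ) == 1:
        return SharingCategory.UNIQUE
    if len(samples) == 1 and len(alleles) == 2:
        return SharingCategory.DUAL
    if len(alleles) == 1:
        return SharingCategory.ALLELE_EXCLUSIVE
    return SharingCategory.MULTIPLE


def classify_all_sharing(
    tables: Sequence[AssignmentTable],
) -> dict[tuple[str, AlleleUnit], SharingCategory]:
    """Sharing class for every (peptide, unit) association in the set."""
    occ = _occurrences(tables)
    out: dict[tuple[str, AlleleUnit], SharingCategory] = {}
    for pep, units in occ.items():
        cat = _categorise(units)
        for u in units:
            out[(pep, u)] = cat
    return out


def sharing_summary(
    tables: Sequence[AssignmentTable],
) -> pd.DataFrame:
    """Per-unit counts of each sharing category (long format)."""
    rows = []
    for (pep, unit), cat in classify_all_sharing(tables).items():
        rows.append(
            {
                "sample_id": unit.sample_id,
                "allele": unit.allele,
                "peptide": pep,
                "category": cat.value,
            }
        )
    return pd.DataFrame(rows)
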