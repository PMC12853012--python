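"""Binding-rank classification and dual-peptide allele assignment.

A peptide eluted from a heterozygous sample may be predicted to bind one
or both of the co-expressed HLA-DRB1 alleles ("dual peptides"). Two
assignment conditions are supported:

* **non-filtered** — every dual peptide is credited to both alleles;
* **filtered** — every peptide is credited only to the allele with the
  stronger predicted binding (lower percent rank).

Peptides that bind neither allele (non-binders on both) are excluded from
the assignment altogether.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

from .models import (
    AssignmentMode,
    AssignmentTable,
    BindingCall,
    BindingClass,
    SampleInfo,
    Thresholds,
    index_calls,
)

log = logging.getLogger(__name__)


def classify_binding(
    percent_rank: float, thresholds: Thresholds = Thresholds()
) -> BindingClass:
    """Discretise a percent rank into SB / WB / NB.

    SB: rank < sb_max; WB: sb_max <= rank <= wb_max; NB: rank > wb_max.
    """
    if not (0.0 <= percent_rank <= 100.0):
        raise ValueError(f"percent rank {percent_rank} outside [0, 100]")
    if percent_rank < thresholds.sb_max:
        return BindingClass.SB
    if percent_rank <= thresholds.wb_max:
        return BindingClass.WB
    return BindingClass.NB


def _sample_ranks(
    sample: SampleInfo,
    calls: Iterable[BindingCall] | Mapping[tuple[str, str], BindingCall],
) -> dict[str, dict[str, float]]:
    """Collect percent ranks per peptide for the sample's alleles.

    Raises if any peptide lacks a call for one of the sample's alleles.
    """
    idx = calls if isinstance(calls, Mapping) else index_calls(calls)
    alleles = set(sample.alleles)
    per_pep: dict[str, dict[str, float]] = {}
    for (pep, allele), call in idx.items():
        if allele in alleles:
            per_pep.setdefault(pep, {})[allele] = call.percent_rank
    for pep, ranks in per_pep.items():
        missing = alleles - set(ranks)
        if missing:
            raise ValueError(
                f"peptide {pep} in sample {sample.sample_id} lacks a binding "
                f"call for {sorted(missing)}"
            )
    return per_pep


def assign_nonfiltered(
    sample: SampleInfo,
    calls: Iterable[BindingCall] | Mapping[tuple[str, str], BindingCall],
    thresholds: Thresholds = Thresholds(),
) -> AssignmentTable:
    """Assign each binder peptide to every allele it binds (SB or WB).

    Peptides with no affinity for either allele are dropped. In a
    heterozygous sample, entries carrying both alleles are dual peptides.
    """
    per_pep = _sample_ranks(sample, calls)
    entries: dict[str, frozenset[str]] = {}
    for pep, ranks in per_pep.items():
        binders = frozenset(
            a for a, r in ranks.items() if classify_binding(r, thresholds) != BindingClass.NB
        )
        if binders:
            entries[pep] = binders
    return AssignmentTable(
        sample_id=sample.sample_id,
        mode=AssignmentMode.NONFILTERED,
        entries=entries,
        alleles=sample.alleles,
    )


def assign_filtered(
    sample: SampleInfo,
    calls: Iterable[BindingCall] | Mapping[tuple[str, str], BindingCall],
    thresholds: Thresholds = Thresholds(),
) -> AssignmentTable:
    """Assign each binder peptide exclusively to its best-ranked allele.

    Rank ties are broken to the canonically first allele, with a warning,
    so repeated runs are reproducible. In a homozygous sample every binder
    goes to the single allele.
    """
    per_pep = _sample_ranks(sample, calls)
    entries: dict[str, frozenset[str]] = {}
    for pep, ranks in per_pep.items():
        binders = {
            a: r for a, r in ranks.items() if classify_binding(r, thresholds) != BindingClass.NB
        }
        if not binders:
            continue
        best_rank = min(binders.values())
        best = sorted(a for a, r in binders.items() if r == best_rank)
        if len(best) > 1:
            log.warning(
                "sample %s peptide %s: rank tie between %s; assigned to %s",
                sample.sample_id,
                pep,
                best,
                best[0],
            )
        entries[pep] = frozenset({best[0]})
    return AssignmentTable(
        sample_id=sample.sample_id,
        mode=AssignmentMode.FILTERED,
        entries=entries,
        alleles=sample.alleles,
    )


def dual_fraction(table: AssignmentTable) -> float:
    """Fraction of binder peptides assigned to both co-expressed alleles.

    Defined on a non-filtered assignment; NaN when the sample has no
    binder peptides at all.
    """
    if table.mode is not AssignmentMode.NONFILTERED:
        raise ValueError("dual fraction is defined on non-filtered assignments")
    n = len(table.entries)
    if n == 0:
        return math.nan
    return len(table.dual_peptides()) / n
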