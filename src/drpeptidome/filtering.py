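"""Repertoire cleaning and nested-set grouping.

Eluted-peptide lists are cleaned by provenance (handling contaminants such
as keratins, bovine serum proteins from culture medium) and by length
(class II ligands are kept in the 9-25 residue range). Cleaned repertoires
are then grouped into nested sets: peptides from one source protein that
share a common binding core and differ only in their flanking residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .models import PeptideRecord

log = logging.getLogger(__name__)

REASON_CONTAMINANT = "contaminant"
REASON_LENGTH = "length"


@dataclass
class FilterReport:
    """Accounting of a repertoire-cleaning pass.

    Every removed record carries exactly one reason, the first matching
    rule (contaminant before length), and
    ``n_input == n_removed_contaminant + n_removed_length + n_kept``.
    """

    n_input: int = 0
    n_removed_contaminant: int = 0
    n_removed_length: int = 0
    n_kept: int = 0
    removed: list[tuple[PeptideRecord, str]] = field(default_factory=list)


@dataclass
class NestedSet:
    """Peptides from one protein sharing a common contiguous core."""

    core: str
    members: list[str]
    source_accession: str


def filter_repertoire(
    peptides: Sequence[PeptideRecord],
    contaminant_accessions: Iterable[str] = (),
    min_len: int = 9,
    max_len: int = 25,
) -> tuple[list[PeptideRecord], FilterReport]:
    """Remove contaminant-derived and out-of-length peptides.

    A peptide is flagged as a contaminant when any of its source
    accessions is in ``contaminant_accessions`` (provenance-driven
    removal). Input order is preserved among kept peptides.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    contaminants = set(contaminant_accessions)
    report = FilterReport(n_input=len(peptides))
    kept: list[PeptideRecord] = []
    for rec in peptides:
        if rec.source_accessions & contaminants:
            report.n_removed_contaminant += 1
            report.removed.append((rec, REASON_CONTAMINANT))
        elif not (min_len <= len(rec.sequence) <= max_len):
            report.n_removed_length += 1
            report.removed.append((rec, REASON_LENGTH))
        else:
            kept.append(rec)
    report.n_kept = len(kept)
    return kept, report


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def shares_core(a: str, b: str, core_len: int) -> bool:
    """True when two sequences share a contiguous substring of length >= core_len."""
    if len(a) < core_len or len(b) < core_len:
        return False
    return bool(_kmers(a, core_len) & _kmers(b, core_len))


def longest_common_core(members: Sequence[str]) -> str:
    """Longest substring common to all members.

    Ties at the maximal length are broken by leftmost occurrence in the
    longest member.
    """
    if not members:
        raise ValueError("no members")
    shortest = min(members, key=len)
    longest = max(members, key=len)
    others = [m for m in members if m is not shortest]
    for length in range(len(shortest), 0, -1):
        common = _kmers(shortest, length)
        for m in others:
            common &= _kmers(m, length)
            if not common:
                break
        if common:
            for i in range(len(longest) - length + 1):
                cand = longest[i : i + length]
                if cand in common:
                    return cand
    return ""


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def group_nested_sets(
    peptides: Sequence[PeptideRecord], core_len: int = 9
) -> list[NestedSet]:
    """Partition each protein's peptides into nested sets.

    Two peptides of the same source protein are related when they share a
    contiguous substring of at least ``core_len`` residues (the typical
    class II 9-mer binding core); the relation is closed transitively, so
    a set is a connected group around one or more overlapping cores. The
    reported core is the longest substring common to all members, which in
    long transitive chains may fall below ``core_len`` (logged).

    Peptides mapping to several proteins participate in the grouping of
    every accession they carry.
    """
    by_acc: dict[str, list[str]] = {}
    for rec in peptides:
        for acc in sorted(rec.source_accessions):
            by_acc.setdefault(acc, []).append(rec.sequence)

    out: list[NestedSet] = []
    for acc in sorted(by_acc):
        seqs = sorted(set(by_acc[acc]))
        uf = _UnionFind(len(seqs))
        kmer_owner: dict[str, int] = {}
        for i, s in enumerate(seqs):
            if len(s) < core_len:
                continue
            for kmer in _kmers(s, core_len):
                if kmer in kmer_owner:
                    uf.union(kmer_owner[kmer], i)
                else:
                    kmer_owner[kmer] = i
        groups: dict[int, list[str]] = {}
        for i, s in enumerate(seqs):
            groups.setdefault(uf.find(i), []).append(s)
        for root in sorted(groups):
            members = groups[root]
            core = longest_common_core(members)
            if len(core) < core_len and len(members) > 1:
                log.warning(
                    "nested set in %s has all-member core %r shorter than %d",
                    acc,
                    core,
                    core_len,
                )
            out.append(NestedSet(core=core, members=members, source_accession=acc))
    return out
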