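"""Readers and writers for the tabular and sequence formats the pipeline touches.

Formats
-------
* peptide tables: TSV/CSV with at least ``sample_id`` and ``sequence``
  columns, optional semicolon-joined ``accessions`` and ``intensity``;
* binding predictions: tab-separated NetMHCIIpan-style tables with
  peptide, allele and percent-rank columns;
* proteomes: FASTA with UniProt (``sp|P07355|ANXA2_HUMAN``) or bare
  accession headers;
* sample typings and protein localisation annotations as TSV.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .binding import classify_binding
from .models import (
    AssignmentMode,
    AssignmentTable,
    BindingCall,
    PeptideRecord,
    ProteinRecord,
    SampleInfo,
    Thresholds,
    canonical_allele,
    validate_sequence,
    COMPARTMENTS,
)

log = logging.getLogger(__name__)

DEFAULT_PEPTIDE_COLUMNS = {
    "sample_id": "sample_id",
    "sequence": "sequence",
    "accessions": "accessions",
    "intensity": "intensity",
}

_RANK_COLUMN_ALIASES = ("percent_rank", "%rank", "%rank_el", "rank", "%rank_ba")
_PEPTIDE_COLUMN_ALIASES = ("peptide", "sequence")
_ALLELE_COLUMN_ALIASES = ("allele", "mhc")


def read_peptide_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[PeptideRecord]:
    """Read a per-sample eluted-peptide table.

    Rows with non-canonical residues are rejected (logged, not fatal).
    Duplicate (sample, sequence) rows are collapsed and their accession
    sets unioned; the first non-missing intensity is kept.
    """
    cols = dict(DEFAULT_PEPTIDE_COLUMNS)
    if dialect:
        cols.update(dialect)
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.empty:
        raise ValueError(f"empty peptide table: {path}")
    for required in ("sample_id", "sequence"):
        if cols[required] not in df.columns:
            raise ValueError(f"peptide table missing column {cols[required]!r}")

    merged: dict[tuple[str, str], PeptideRecord] = {}
    for _, row in df.iterrows():
        raw_seq = row[cols["sequence"]]
        sample = str(row[cols["sample_id"]])
        try:
            seq = validate_sequence(str(raw_seq))
        except ValueError as exc:
            log.warning("rejected peptide row (%s): %s", sample, exc)
            continue
        accs: set[str] = set()
        if cols["accessions"] in df.columns and pd.notna(row.get(cols["accessions"])):
            accs = {a for a in str(row[cols["accessions"]]).split(";") if a}
        intensity = None
        if cols["intensity"] in df.columns and pd.notna(row.get(cols["intensity"])):
            intensity = float(row[cols["intensity"]])
        key = (sample, seq)
        if key in merged:
            prev = merged[key]
            merged[key] = PeptideRecord(
                sequence=seq,
                sample_id=sample,
                source_accessions=prev.source_accessions | accs,
                intensity=prev.intensity if prev.intensity is not None else intensity,
            )
        else:
            merged[key] = PeptideRecord(
                sequence=seq,
                sample_id=sample,
                source_accessions=frozenset(accs),
                intensity=intensity,
            )
    if not merged:
        raise ValueError(f"no valid peptide rows in {path}")
    return list(merged.values())


def write_peptide_table(records: Iterable[PeptideRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "sequence": r.sequence,
            "accessions": ";".join(sorted(r.source_accessions)),
            "intensity": "" if r.intensity is None else r.intensity,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_netmhciipan_output(
    path: str | Path,
    thresholds: Thresholds = Thresholds(),
) -> list[BindingCall]:
    """Read a NetMHCIIpan-4.1-style tab-separated prediction table.

    The reader locates the peptide, allele and percent-rank columns by
    name (case-insensitive; ``%Rank_EL`` and plain ``%Rank`` dialects are
    both accepted). Binding classes are re-derived from the rank so that
    every returned call satisfies
    ``binding_class == classify_binding(percent_rank)``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.empty:
        raise ValueError(f"empty binding prediction table: {path}")
    lower = {c.lower().strip(): c for c in df.columns}

    def find(aliases: Sequence[str], what: str) -> str:
        for a in aliases:
            if a in lower:
                return lower[a]
        raise ValueError(f"cannot find {what} column in {path} (have {list(df.columns)})")

    pep_col = find(_PEPTIDE_COLUMN_ALIASES, "peptide")
    allele_col = find(_ALLELE_COLUMN_ALIASES, "allele")
    rank_col = find(_RANK_COLUMN_ALIASES, "percent-rank")

    calls: list[BindingCall] = []
    seen: dict[tuple[str, str], float] = {}
    for _, row in df.iterrows():
        pep = validate_sequence(str(row[pep_col]))
        allele = canonical_allele(str(row[allele_col]))
        rank = float(row[rank_col])
        key = (pep, allele)
        if key in seen:
            if seen[key] != rank:
                raise ValueError(
                    f"ambiguous duplicate prediction for {key}: "
                    f"{seen[key]} vs {rank}"
                )
            continue
        seen[key] = rank
        calls.append(
            BindingCall(
                peptide=pep,
                allele=allele,
                percent_rank=rank,
                binding_class=classify_binding(rank, thresholds),
            )
        )
    return calls


def write_binding_calls(calls: Iterable[BindingCall], path: str | Path) -> None:
    rows = [
        {
            "peptide": c.peptide,
            "allele": c.allele,
            "percent_rank": c.percent_rank,
            "binding_class": c.binding_class.value,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def parse_fasta_accession(header: str) -> str:
    """Extract the accession from a UniProt-style or bare FASTA header."""
    first = header.split()[0]
    if "|" in first:
        parts = first.split("|")
        if len(parts) >= 2 and parts[1]:
            return parts[1]
    return first


def read_fasta_proteome(path: str | Path) -> set[ProteinRecord]:
    """Read a proteome FASTA into a deduplicated accession set."""
    path = Path(path)
    accessions: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accessions.add(parse_fasta_accession(rec.id))
    if not accessions:
        raise ValueError(f"empty FASTA proteome: {path}")
    return {ProteinRecord(accession=a) for a in accessions}


def read_sample_table(path: str | Path) -> list[SampleInfo]:
    """Read sample typings: columns sample_id, group, allele_a, allele_b."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "allele_a", "allele_b"}
    if not required <= set(df.columns):
        raise ValueError(f"sample table must have columns {sorted(required)}")
    return [
        SampleInfo(
            sample_id=str(r.sample_id),
            group=str(r.group),
            allele_a=str(r.allele_a),
            allele_b=str(r.allele_b),
        )
        for r in df.itertuples()
    ]


def write_sample_table(samples: Iterable[SampleInfo], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "group": s.group.value,
            "allele_a": s.allele_a,
            "allele_b": s.allele_b,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_localization_table(path: str | Path) -> dict[str, ProteinRecord]:
    """Read accession -> comma-joined compartment annotations."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"accession", "localizations"} <= set(df.columns):
        raise ValueError("localisation table needs accession, localizations columns")
    out: dict[str, ProteinRecord] = {}
    for r in df.itertuples():
        locs = frozenset(
            x.strip() for x in str(r.localizations).split(",") if x.strip()
        )
        out[str(r.accession)] = ProteinRecord(str(r.accession), locs)
    return out


def write_localization_table(
    proteins: Iterable[ProteinRecord], path: str | Path
) -> None:
    rows = [
        {"accession": p.accession, "localizations": ",".join(sorted(p.localizations))}
        for p in proteins
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_assignment_table(
    tables: Iterable[AssignmentTable], path: str | Path
) -> None:
    """Write assignment tables as long-format TSV (one row per peptide)."""
    rows = []
    for t in tables:
        for pep, alleles in t.entries.items():
            rows.append(
                {
                    "sample_id": t.sample_id,
                    "mode": t.mode.value,
                    "peptide": pep,
                    "alleles": ";".join(sorted(alleles)),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_assignment_table(path: str | Path) -> list[AssignmentTable]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "mode", "peptide", "alleles"}
    if not required <= set(df.columns):
        raise ValueError(f"assignment table must have columns {sorted(required)}")
    tables: dict[tuple[str, str], dict[str, frozenset[str]]] = {}
    for r in df.itertuples():
        key = (str(r.sample_id), str(r.mode))
        tables.setdefault(key, {})[str(r.peptide)] = frozenset(
            str(r.alleles).split(";")
        )
    return [
        AssignmentTable(sample_id=sid, mode=AssignmentMode(mode), entries=entries)
        for (sid, mode), entries in tables.items()
    ]
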