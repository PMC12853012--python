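"""Identification of pulse-induced proteins and enrichment comparisons.

A protein is *pulse-induced* when it is a source of peptides eluted from
lysate-pulsed dendritic cells, is present in the tumour-lysate proteome,
and is absent from the control-cell immunopeptidomes — set logic on three
accession sets. Downstream comparisons: the induced set's share of the
lysate proteome and of the pulsed immunopeptidome, the rank correlation
between lysate protein abundance and peptide representation, and per-
compartment Welch t-tests with Holm-Sidak correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .models import PeptideRecord, ProteinRecord, COMPARTMENTS


@dataclass
class PulseSets:
    """Accession/peptide sets entering and leaving the pulse-induction logic.

    ``induced_proteins == (p_proteins & lysate_proteins) - c_proteins``.
    A peptide from a pulsed sample counts as induced when at least one of
    its source accessions is induced (flagged in outputs, since such a
    peptide may also map to a non-induced protein).
    """

    p_proteins: frozenset[str]
    c_proteins: frozenset[str]
    lysate_proteins: frozenset[str]
    induced_proteins: frozenset[str] = frozenset()
    induced_peptides: frozenset[str] = frozenset()


def identify_pulse_induced(
    p_proteins: Iterable[str],
    c_proteins: Iterable[str],
    lysate_proteins: Iterable[str],
    pulsed_peptides: Sequence[PeptideRecord] = (),
) -> PulseSets:
    """Set logic for pulse-induced proteins and the peptides they yield."""
    p = frozenset(p_proteins)
    c = frozenset(c_proteins)
    lys = frozenset(lysate_proteins)
    if not lys:
        raise ValueError("empty lysate proteome: nothing can be pulse-induced")
    induced = (p & lys) - c
    peptides = frozenset(
        rec.sequence for rec in pulsed_peptides if rec.source_accessions & induced
    )
    return PulseSets(
        p_proteins=p,
        c_proteins=c,
        lysate_proteins=lys,
        induced_proteins=induced,
        induced_peptides=peptides,
    )


def immunopeptidome_shares(
    sets: PulseSets, n_pulsed_binder_peptides: int
) -> tuple[float, float]:
    """Induced share of the lysate proteome and of the pulsed immunopeptidome.

    Returns percentages: ``|induced proteins| / |lysate proteins|`` and
    ``|induced peptides| / n_pulsed_binder_peptides``.
    """
    if not sets.lysate_proteins or n_pulsed_binder_peptides <= 0:
        raise ValueError("zero denominator in immunopeptidome shares")
    proteome_pct = 100.0 * len(sets.induced_proteins) / len(sets.lysate_proteins)
    peptidome_pct = 100.0 * len(sets.induced_peptides) / n_pulsed_binder_peptides
    return proteome_pct, peptidome_pct


def peptide_representation(
    sets: PulseSets, pulsed_peptides: Sequence[PeptideRecord]
) -> dict[str, int]:
    """Distinct induced-peptide count per induced protein.

    Nested-set members are counted individually; a peptide mapping to
    several induced proteins contributes to each of them.
    """
    counts = dict.fromkeys(sets.induced_proteins, 0)
    seen: set[tuple[str, str]] = set()
    for rec in pulsed_peptides:
        if rec.sequence not in sets.induced_peptides:
            continue
        for acc in rec.source_accessions & sets.induced_proteins:
            key = (acc, rec.sequence)
            if key not in seen:
                seen.add(key)
                counts[acc] += 1
    return counts


def abundance_representation_corr(
    abundance: Mapping[str, float],
    representation: Mapping[str, int],
) -> tuple[float, float]:
    """Spearman correlation between lysate abundance and peptide yield.

    Only proteins present in both mappings enter; NaN is returned for
    constant vectors (correlation undefined).
    """
    shared = sorted(set(abundance) & set(representation))
    if len(shared) < 3:
        raise ValueError("need at least 3 proteins with abundance and representation")
    x = np.array([abundance[a] for a in shared], dtype=float)
    y = np.array([representation[a] for a in shared], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class CompartmentComparison:
    """One compartment's Welch t-test between two sample groups."""

    compartment: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    p_raw: float
    p_adjusted: float = math.nan
    significant: bool = False


def holm_sidak(p_values: Sequence[float]) -> list[float]:
    """Step-down Sidak adjustment.

    Sort p-values ascending; the i-th smallest of m is adjusted to
    ``1 - (1 - p_i)^(m - i)`` (0-based i), then running maxima enforce
    monotonicity.
    """
    m = len(p_values)
    order = np.argsort(p_values)
    adjusted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        adj = 1.0 - (1.0 - p_values[idx]) ** (m - i)
        running = max(running, min(1.0, adj))
        adjusted[idx] = running
    return adjusted.tolist()


def compartment_percentages(
    peptides: Sequence[PeptideRecord],
    localizations: Mapping[str, ProteinRecord],
) -> dict[str, dict[str, float]]:
    """Per-sample percentage of PGPs annotated to each compartment.

    Multi-localised proteins are counted once in every compartment they
    carry, so percentages within a sample may sum to more than 100.
    """
    per_sample_accs: dict[str, set[str]] = {}
    for rec in peptides:
        per_sample_accs.setdefault(rec.sample_id, set()).update(
            rec.source_accessions
        )
    out: dict[str, dict[str, float]] = {}
    for sample, accs in per_sample_accs.items():
        annotated = [localizations[a] for a in accs if a in localizations]
        n = len(annotated)
        pct = dict.fromkeys(COMPARTMENTS, 0.0)
        if n:
            for prot in annotated:
                for comp in prot.localizations:
                    pct[comp] += 100.0 / n
        out[sample] = pct
    return out


def compartment_enrichment(
    group_a: Mapping[str, Mapping[str, float]],
    group_b: Mapping[str, Mapping[str, float]],
    alpha: float = 0.05,
    compartments: Sequence[str] = COMPARTMENTS,
) -> list[CompartmentComparison]:
    """Welch t-tests per compartment between two groups of samples.

    Inputs are per-sample compartment-percentage mappings (one inner
    mapping per sample). Each compartment is analysed independently and
    p-values are Holm-Sidak adjusted across compartments at level alpha.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples for a Welch test")
    results: list[CompartmentComparison] = []
    for comp in compartments:
        a = np.array([s.get(comp, 0.0) for s in group_a.values()])
        b = np.array([s.get(comp, 0.0) for s in group_b.values()])
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and math.isclose(
            a[0], b[0]
        ):
            p_raw = 1.0
        else:
            p_raw = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            if math.isnan(p_raw):
                p_raw = 1.0
        results.append(
            CompartmentComparison(
                compartment=comp,
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                sd_a=float(a.std(ddof=1)),
                sd_b=float(b.std(ddof=1)),
                p_raw=p_raw,
            )
        )
    adjusted = holm_sidak([r.p_raw for r in results])
    for r, adj in zip(results, adjusted):
        r.p_adjusted = adj
        r.significant = adj < alpha
    return results
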