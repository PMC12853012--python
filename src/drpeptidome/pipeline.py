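"""End-to-end orchestration: simulate/load -> filter -> assign -> analyse.

A single :class:`RunConfig` drives every stage; each stage's outputs are
written as TSV/JSON under the output directory and a manifest (config
hash, seed, package version, output list) is written last, so a directory
with no manifest is never mistaken for a complete run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from . import io as dio
from .binding import assign_filtered, assign_nonfiltered, dual_fraction
from .filtering import filter_repertoire, group_nested_sets
from .mds import compare_conditions, mds_analysis
from .models import (
    AssignmentTable,
    Group,
    PeptideRecord,
    SampleInfo,
    Thresholds,
    index_calls,
)
from .pulse import (
    abundance_representation_corr,
    compartment_enrichment,
    compartment_percentages,
    identify_pulse_induced,
    immunopeptidome_shares,
    peptide_representation,
)
from .repertoire import dominance_ratio, overlap_matrix, sbwb_fractions, sharing_summary
from .simulate import CONTAMINANT_ACCESSIONS, Cohort, CohortConfig, generate_cohort

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One structured configuration for a whole pipeline run.

    Exactly one of ``simulate`` (cohort-generation parameters) or
    ``inputs`` (paths to peptide/sample/binding tables and the lysate
    proteome) must be provided.
    """

    outdir: str | Path = "results"
    seed: int = 0
    simulate: Mapping[str, Any] | None = None
    inputs: Mapping[str, str] | None = None
    sb_max: float = 1.0
    wb_max: float = 5.0
    min_len: int = 9
    max_len: int = 25
    mds_max_peptides: int = 600
    mds_k_max: int = 50
    gap_open: float = 11.0
    gap_extend: float = 1.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of a simulate block or real input paths is required"
            )
        # validate every stage's options before any stage runs
        Thresholds(self.sb_max, self.wb_max)
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if self.mds_max_peptides < 3 or self.mds_k_max < 2:
            raise ValueError("invalid MDS options")

    def thresholds(self) -> Thresholds:
        return Thresholds(self.sb_max, self.wb_max)

    def config_hash(self) -> str:
        # the hash captures analysis-relevant options, not where results land
        payload = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in self.__dict__.items()
            if k not in ("outdir", "log_level")
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def _load_inputs(cfg: RunConfig):
    paths = dict(cfg.inputs or {})
    peptides = dio.read_peptide_table(paths["peptides"])
    samples = dio.read_sample_table(paths["samples"])
    calls = dio.read_netmhciipan_output(paths["binding"], cfg.thresholds())
    contaminants: set[str] = set()
    if "contaminants" in paths:
        contaminants = {
            line.strip()
            for line in Path(paths["contaminants"]).read_text().splitlines()
            if line.strip()
        }
    lysate = None
    if "lysate" in paths:
        lysate = {p.accession for p in dio.read_fasta_proteome(paths["lysate"])}
    localizations = (
        dio.read_localization_table(paths["localizations"])
        if "localizations" in paths
        else None
    )
    abundance = None
    if "abundance" in paths:
        df = pd.read_csv(paths["abundance"], sep="\t")
        abundance = dict(zip(df["accession"], df["abundance"].astype(float)))
    return peptides, samples, calls, contaminants, lysate, localizations, abundance


def _simulated_inputs(cfg: RunConfig):
    block = dict(cfg.simulate or {})
    block.setdefault("seed", cfg.seed)
    block.setdefault("thresholds", cfg.thresholds())
    cohort = generate_cohort(CohortConfig(**block))
    lysate = set(cohort.lysate_sequences)
    return (
        cohort.peptides,
        cohort.samples,
        cohort.calls,
        set(CONTAMINANT_ACCESSIONS),
        lysate,
        cohort.localizations,
        cohort.lysate_abundance,
        cohort,
    )


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute filter -> assign -> dominance/overlap/sharing -> pulse -> MDS.

    Returns a report dictionary with the headline numbers of each stage;
    all tables are written under ``cfg.outdir`` and listed in the manifest.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    report: dict[str, Any] = {"seed": cfg.seed}

    cohort: Cohort | None = None
    if cfg.simulate is not None:
        (
            peptides,
            samples,
            calls,
            contaminants,
            lysate,
            localizations,
            abundance,
            cohort,
        ) = _simulated_inputs(cfg)
    else:
        peptides, samples, calls, contaminants, lysate, localizations, abundance = (
            _load_inputs(cfg)
        )

    sample_map = {s.sample_id: s for s in samples}
    missing = sorted({p.sample_id for p in peptides} - set(sample_map))
    if missing:
        raise ValueError(
            f"stage assign: no HLA typing for sample(s) {missing}; "
            "every sample in the peptide table needs a typing row"
        )

    # ---- stage: filter -------------------------------------------------
    kept, filt_report = filter_repertoire(
        peptides, contaminants, cfg.min_len, cfg.max_len
    )
    report["n_peptide_observations"] = filt_report.n_input
    report["n_after_cleaning"] = filt_report.n_kept
    report["n_removed_contaminant"] = filt_report.n_removed_contaminant
    report["n_removed_length"] = filt_report.n_removed_length
    dio.write_peptide_table(kept, outdir / "peptides_clean.tsv")
    written.append("peptides_clean.tsv")
    (outdir / "filter_report.json").write_text(
        json.dumps(
            {
                "n_input": filt_report.n_input,
                "n_removed_contaminant": filt_report.n_removed_contaminant,
                "n_removed_length": filt_report.n_removed_length,
                "n_kept": filt_report.n_kept,
            },
            indent=1,
        )
    )
    written.append("filter_report.json")

    nested = group_nested_sets(kept)
    report["n_nested_sets"] = sum(1 for s in nested if len(s.members) > 1)

    # ---- stage: assign (both modes) ------------------------------------
    idx = index_calls(calls)
    by_sample: dict[str, list[PeptideRecord]] = {}
    for rec in kept:
        by_sample.setdefault(rec.sample_id, []).append(rec)

    tables_nf: list[AssignmentTable] = []
    tables_f: list[AssignmentTable] = []
    dual_fracs: dict[str, float] = {}
    thresholds = cfg.thresholds()
    for sid in sorted(by_sample):
        sample = sample_map[sid]
        sub_idx = {
            (p.sequence, a): idx[(p.sequence, a)]
            for p in by_sample[sid]
            for a in dict.fromkeys(sample.alleles)
            if (p.sequence, a) in idx
        }
        for p in by_sample[sid]:
            for a in dict.fromkeys(sample.alleles):
                if (p.sequence, a) not in idx:
                    raise ValueError(
                        f"stage assign: sample {sid} peptide {p.sequence} has "
                        f"no binding call for {a}"
                    )
        nf = assign_nonfiltered(sample, sub_idx, thresholds)
        f = assign_filtered(sample, sub_idx, thresholds)
        tables_nf.append(nf)
        tables_f.append(f)
        if not sample.is_homozygous:
            dual_fracs[sid] = dual_fraction(nf)
    dio.write_assignment_table(tables_nf + tables_f, outdir / "assignments.tsv")
    written.append("assignments.tsv")
    report["n_binder_peptides"] = sum(len(t.entries) for t in tables_nf)
    report["dual_fraction"] = dual_fracs

    # ---- stage: dominance / overlap / sharing --------------------------
    dom_rows = []
    for t in tables_f:
        res = dominance_ratio(t, sample_map[t.sample_id])
        dom_rows.append(
            {
                "sample_id": res.sample_id,
                "allele_x": res.allele_x,
                "allele_y": res.allele_y,
                "n_x": res.n_x,
                "n_y": res.n_y,
                "ratio": res.ratio,
                "inverse_ratio": res.inverse_ratio,
                "applicable": res.applicable,
            }
        )
    pd.DataFrame(dom_rows).to_csv(outdir / "dominance.tsv", sep="\t", index=False)
    written.append("dominance.tsv")
    report["dominance"] = {
        r["sample_id"]: r["ratio"] for r in dom_rows if r["applicable"]
    }

    sbwb_rows = []
    for t in tables_nf:
        sample = sample_map[t.sample_id]
        for allele, (sb, wb) in sbwb_fractions(idx, t, sample).items():
            sbwb_rows.append(
                {"sample_id": t.sample_id, "allele": allele, "sb": sb, "wb": wb}
            )
    pd.DataFrame(sbwb_rows).to_csv(outdir / "sbwb_fractions.tsv", sep="\t", index=False)
    written.append("sbwb_fractions.tsv")

    for level in ("peptide", "protein"):
        om = overlap_matrix(tables_nf, samples, level=level, peptides=kept)
        om.to_dataframe().to_csv(outdir / f"overlap_{level}.tsv", sep="\t")
        written.append(f"overlap_{level}.tsv")

    sharing = sharing_summary(tables_nf)
    sharing.to_csv(outdir / "sharing.tsv", sep="\t", index=False)
    written.append("sharing.tsv")
    report["sharing_counts"] = (
        sharing["category"].value_counts().to_dict() if len(sharing) else {}
    )

    # ---- stage: pulse ---------------------------------------------------
    groups = {s.group for s in samples}
    if lysate and groups == {Group.CONTROL, Group.PULSED}:
        binder_seqs = {
            t.sample_id: set(t.entries) for t in tables_nf
        }
        pulsed_peps = [
            p
            for p in kept
            if sample_map[p.sample_id].group is Group.PULSED
            and p.sequence in binder_seqs.get(p.sample_id, set())
        ]
        control_peps = [
            p for p in kept if sample_map[p.sample_id].group is Group.CONTROL
        ]
        p_prot = {a for p in pulsed_peps for a in p.source_accessions}
        c_prot = {a for p in control_peps for a in p.source_accessions}
        sets = identify_pulse_induced(p_prot, c_prot, lysate, pulsed_peps)
        n_pulsed_binders = len({p.sequence for p in pulsed_peps})
        proteome_pct, peptidome_pct = immunopeptidome_shares(sets, n_pulsed_binders)
        report["n_induced_proteins"] = len(sets.induced_proteins)
        report["n_induced_peptides"] = len(sets.induced_peptides)
        report["induced_pct_of_lysate"] = proteome_pct
        report["induced_pct_of_peptidome"] = peptidome_pct
        pd.DataFrame(
            {"accession": sorted(sets.induced_proteins)}
        ).to_csv(outdir / "induced_proteins.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"peptide": sorted(sets.induced_peptides)}
        ).to_csv(outdir / "induced_peptides.tsv", sep="\t", index=False)
        written += ["induced_proteins.tsv", "induced_peptides.tsv"]

        if abundance is not None:
            repr_counts = peptide_representation(sets, pulsed_peps)
            try:
                rho, pval = abundance_representation_corr(abundance, repr_counts)
                report["abundance_representation_spearman"] = rho
                report["abundance_representation_p"] = pval
            except ValueError:
                log.warning("too few induced proteins for a rank correlation")

        if localizations is not None:
            pct = compartment_percentages(kept, localizations)
            grp_a = {
                sid: v
                for sid, v in pct.items()
                if sample_map[sid].group is Group.PULSED
            }
            grp_b = {
                sid: v
                for sid, v in pct.items()
                if sample_map[sid].group is Group.CONTROL
            }
            if len(grp_a) >= 2 and len(grp_b) >= 2:
                comps = compartment_enrichment(grp_a, grp_b)
                pd.DataFrame(
                    [
                        {
                            "compartment": c.compartment,
                            "mean_pulsed": c.mean_a,
                            "mean_control": c.mean_b,
                            "p_raw": c.p_raw,
                            "p_adjusted": c.p_adjusted,
                            "significant": c.significant,
                        }
                        for c in comps
                    ]
                ).to_csv(outdir / "compartment_enrichment.tsv", sep="\t", index=False)
                written.append("compartment_enrichment.tsv")

    # ---- stage: MDS ------------------------------------------------------
    pooled = sorted({p for t in tables_nf for p in t.entries})
    if len(pooled) > cfg.mds_max_peptides:
        sel_rng = np.random.default_rng(cfg.seed)
        pooled = sorted(
            sel_rng.choice(pooled, size=cfg.mds_max_peptides, replace=False)
        )
    pool_set = set(pooled)

    def restrict(tables: list[AssignmentTable]) -> list[AssignmentTable]:
        return [
            AssignmentTable(
                sample_id=t.sample_id,
                mode=t.mode,
                entries={p: a for p, a in t.entries.items() if p in pool_set},
            )
            for t in tables
        ]

    k_grid = range(2, min(cfg.mds_k_max, len(pooled) - 1) + 1)
    _, _, emb_nf = mds_analysis(
        restrict(tables_nf),
        sample_map,
        k_grid=k_grid,
        gap_open=cfg.gap_open,
        gap_extend=cfg.gap_extend,
    )
    _, _, emb_f = mds_analysis(
        restrict(tables_f),
        sample_map,
        k_grid=k_grid,
        gap_open=cfg.gap_open,
        gap_extend=cfg.gap_extend,
    )
    coords_rows = [
        {
            "sample_id": e.unit.sample_id,
            "allele": e.unit.allele,
            "mode": e.mode.value,
            "x": float(e.xy[0]),
            "y": float(e.xy[1]),
        }
        for e in emb_f + emb_nf
    ]
    pd.DataFrame(coords_rows).to_csv(outdir / "mds_coordinates.tsv", sep="\t", index=False)
    written.append("mds_coordinates.tsv")

    deltas = compare_conditions(emb_f, emb_nf, sample_map)
    pd.DataFrame(
        [
            {
                "sample_id": d.sample_id,
                "allele_a": d.unit_a.allele,
                "allele_b": d.unit_b.allele,
                "dist_filtered": d.dist_filtered,
                "dist_nonfiltered": d.dist_nonfiltered,
                "delta": d.delta,
            }
            for d in deltas
        ]
    ).to_csv(outdir / "mds_distance_changes.tsv", sep="\t", index=False)
    written.append("mds_distance_changes.tsv")
    finite = [d.delta for d in deltas if math.isfinite(d.delta)]
    report["mean_mds_delta"] = float(np.mean(finite)) if finite else math.nan

    if cohort is not None:
        report["ground_truth_induced"] = len(cohort.ground_truth.induced_proteins)

    # manifest written last: its presence marks a complete run
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "outputs": written,
        "report": {
            k: v for k, v in report.items() if isinstance(v, (int, float, str))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return report
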