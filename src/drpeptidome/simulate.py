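"""Synthetic immunopeptidome cohorts with full ground truth.

The generator emulates the statistical structure of an HLA-DR eluted-
ligand study on monocyte-derived dendritic cells from heterozygous
donors:

* each DRB1 allele carries a 9-mer position-weight-matrix motif with
  anchor positions P1/P4/P6/P9, the positions that dominate class II
  binding specificity;
* peptide-allele percent ranks are emulated against a fixed seeded
  background of random peptides, mirroring percentile-rank semantics of
  neural binding predictors (lower = stronger);
* per sample, binder peptides are planted as allele-exclusive or dual
  (binding both co-expressed alleles) with configurable dual fraction and
  exclusive-count dominance ratio, lengths follow a truncated normal
  around 15 residues within 9-25, and a configurable fraction of binders
  expands into nested sets sharing a common core;
* lysate-pulsed samples additionally present peptides from designated
  "induced" proteins of a tumour-lysate proteome that never appear in
  control samples, so downstream set logic can recover them exactly;
* handling contaminants (keratin/bovine accessions) and out-of-range
  lengths are planted at low rates to exercise repertoire cleaning.

Everything is reproducible from the configuration seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .binding import classify_binding
from .models import (
    BindingCall,
    Group,
    PeptideRecord,
    ProteinRecord,
    SampleInfo,
    Thresholds,
    CANONICAL_AA,
    COMPARTMENTS,
)

AA = CANONICAL_AA
_AA_INDEX = {a: i for i, a in enumerate(AA)}
CORE_LEN = 9
#: Anchor positions of the class II 9-mer binding core (0-based P1, P4, P6, P9).
ANCHOR_POSITIONS = (0, 3, 5, 8)

#: Keratin and bovine-serum accessions used as the planted handling-contaminant
#: pool (matching the provenance-driven removal rule of the cleaning step).
CONTAMINANT_ACCESSIONS = (
    "P04264",  # keratin K1
    "P13645",  # keratin K10
    "P35908",  # keratin K2
    "P02769",  # bovine serum albumin
    "P02662",  # bovine alpha-S1 casein
)

#: Built-in anchor residues per allele. Pairs that co-occur in the default
#: cohort share anchors in proportion to how promiscuous/overlapping their
#: real-world motifs are (e.g., the two Asp-at-P4 alleles).
DEFAULT_ANCHORS: dict[str, dict[int, str]] = {
    "DRB1*01:01": {0: "Y", 3: "L", 5: "A", 8: "L"},
    "DRB1*01:02": {0: "Y", 3: "L", 5: "G", 8: "M"},
    "DRB1*03:01": {0: "L", 3: "D", 5: "K", 8: "Y"},
    "DRB1*04:04": {0: "F", 3: "D", 5: "N", 8: "S"},
    "DRB1*07:01": {0: "Y", 3: "I", 5: "A", 8: "L"},
    "DRB1*11:01": {0: "W", 3: "E", 5: "Q", 8: "M"},
    "DRB1*11:04": {0: "W", 3: "M", 5: "T", 8: "V"},
    "DRB1*12:01": {0: "V", 3: "Q", 5: "H", 8: "W"},
    "DRB1*13:01": {0: "I", 3: "S", 5: "N", 8: "F"},
    "DRB1*13:02": {0: "I", 3: "S", 5: "K", 8: "F"},
    "DRB1*13:03": {0: "L", 3: "D", 5: "R", 8: "Y"},
    "DRB1*13:05": {0: "M", 3: "N", 5: "S", 8: "T"},
    "DRB1*15:01": {0: "F", 3: "V", 5: "P", 8: "A"},
}

#: Per-allele anchor stringency: stronger motifs present more strong binders.
DEFAULT_STRENGTHS: dict[str, float] = {
    "DRB1*01:01": 5.0,
    "DRB1*01:02": 5.0,
    "DRB1*03:01": 5.0,
    "DRB1*04:04": 5.0,
    "DRB1*07:01": 4.0,
    "DRB1*11:01": 3.5,
    "DRB1*11:04": 3.5,
    "DRB1*12:01": 3.5,
    "DRB1*13:01": 3.5,
    "DRB1*13:02": 3.5,
    "DRB1*13:03": 4.0,
    "DRB1*13:05": 3.5,
    "DRB1*15:01": 4.0,
}


@dataclass
class AlleleMotif:
    """A 9x20 log-odds matrix with designated anchor positions."""

    allele: str
    pwm: np.ndarray
    anchor_positions: tuple[int, ...]
    strength: float

    def __post_init__(self) -> None:
        if self.pwm.shape != (CORE_LEN, len(AA)):
            raise ValueError("PWM must be 9 x 20")
        if not np.all(np.isfinite(self.pwm)):
            raise ValueError("PWM must be finite")


def make_motif(
    allele: str,
    anchors: Mapping[int, str] | None = None,
    strength: float | None = None,
    rng: np.random.Generator | None = None,
    noise: float = 0.05,
) -> AlleleMotif:
    """Build an allele motif from anchor residues and a stringency scalar.

    Anchor columns put weight ``strength`` on the anchor residue;
    non-anchor columns are near-uniform (small reproducible noise scaled
    by strength). ``strength == 0`` yields exactly uniform columns.
    """
    if anchors is None:
        anchors = DEFAULT_ANCHORS[allele]
    if strength is None:
        strength = DEFAULT_STRENGTHS.get(allele, 4.0)
    if strength < 0:
        raise ValueError("strength must be non-negative")
    rng = rng or np.random.default_rng(0)
    pwm = np.zeros((CORE_LEN, len(AA)))
    if strength > 0:
        pwm += rng.normal(0.0, noise * strength, size=pwm.shape)
        for pos, aa in anchors.items():
            pwm[pos, :] = 0.0
            pwm[pos, _AA_INDEX[aa]] = strength
    return AlleleMotif(
        allele=allele,
        pwm=pwm,
        anchor_positions=tuple(sorted(anchors)),
        strength=strength,
    )


def _sequence_uniform(seq: str) -> float:
    """Deterministic pseudo-uniform draw in [0, 1) from a peptide sequence."""
    digest = hashlib.blake2b(seq.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") / 2**64


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX[a] for a in seq), dtype=np.int64, count=len(seq))


def _decode(codes: np.ndarray) -> str:
    return "".join(AA[int(c)] for c in codes)


def _max_window_scores(codes: np.ndarray, pwm: np.ndarray) -> np.ndarray:
    """Best 9-mer-window PWM score for each row of equal-length code arrays."""
    n, length = codes.shape
    if length < CORE_LEN:
        raise ValueError(f"peptides shorter than the {CORE_LEN}-mer core")
    windows = np.lib.stride_tricks.sliding_window_view(codes, CORE_LEN, axis=1)
    # windows: (n, length-8, 9); look up pwm[pos, residue] per window position
    scores = pwm[np.arange(CORE_LEN), windows].sum(axis=2)
    return scores.max(axis=1)


class RankPredictor:
    """Percent-rank emulation against a fixed seeded random background.

    The background (``background_size`` random 15-mers) is shared across
    alleles, so ranks are comparable between co-expressed alleles. The
    percent rank of a peptide is the percentage of background peptides
    scoring strictly higher under the allele's motif.
    """

    def __init__(
        self,
        motifs: Mapping[str, AlleleMotif],
        background_size: int = 10000,
        seed: int = 0,
    ) -> None:
        self.motifs = dict(motifs)
        rng = np.random.default_rng(seed)
        self._background = rng.integers(0, len(AA), size=(background_size, 15))
        self._bg_sorted: dict[str, np.ndarray] = {}

    def _background_scores(self, allele: str) -> np.ndarray:
        if allele not in self._bg_sorted:
            pwm = self.motifs[allele].pwm
            self._bg_sorted[allele] = np.sort(
                _max_window_scores(self._background, pwm)
            )
        return self._bg_sorted[allele]

    def percent_ranks(self, peptides: Sequence[str], allele: str) -> np.ndarray:
        """Vectorised percent ranks for peptides of arbitrary length >= 9.

        Background ties are broken by a deterministic per-peptide uniform
        draw (a sequence hash), so ranks stay continuous even for flat
        motifs while remaining reproducible across runs.
        """
        bg = self._background_scores(allele)
        pwm = self.motifs[allele].pwm
        n_bg = bg.size
        out = np.empty(len(peptides))
        by_len: dict[int, list[int]] = {}
        for i, p in enumerate(peptides):
            by_len.setdefault(len(p), []).append(i)
        for length, idxs in by_len.items():
            codes = np.vstack([_encode(peptides[i]) for i in idxs])
            scores = _max_window_scores(codes, pwm)
            hi = np.searchsorted(bg, scores, side="right")
            lo = np.searchsorted(bg, scores, side="left")
            higher = n_bg - hi
            ties = hi - lo
            u = np.array([_sequence_uniform(peptides[i]) for i in idxs])
            out[idxs] = 100.0 * (higher + u * ties) / n_bg
        return out

    def percent_rank(self, peptide: str, allele: str) -> float:
        return float(self.percent_ranks([peptide], allele)[0])


def emulate_percent_rank(
    peptide: str,
    motif: AlleleMotif,
    background_size: int = 10000,
    seed: int = 0,
) -> float:
    """Convenience single-peptide rank emulation (deterministic in seed)."""
    predictor = RankPredictor({motif.allele: motif}, background_size, seed)
    return predictor.percent_rank(peptide, motif.allele)


def default_study_samples() -> list[SampleInfo]:
    """The default cohort: 8 control and 6 pulsed samples, 13 DRB1 alleles.

    One sample is homozygous; two allele combinations recur in two samples
    each, enabling cross-donor comparisons of the same pairing.
    """
    rows = [
        ("C-1921", Group.CONTROL, "DRB1*13:01", "DRB1*13:02"),
        ("C-1922", Group.CONTROL, "DRB1*07:01", "DRB1*07:01"),
        ("C-2102", Group.CONTROL, "DRB1*01:01", "DRB1*11:01"),
        ("C-2103", Group.CONTROL, "DRB1*11:04", "DRB1*12:01"),
        ("C-2104", Group.CONTROL, "DRB1*03:01", "DRB1*13:03"),
        ("C-2105", Group.CONTROL, "DRB1*01:01", "DRB1*07:01"),
        ("C-2106", Group.CONTROL, "DRB1*01:01", "DRB1*07:01"),
        ("C-2107", Group.CONTROL, "DRB1*03:01", "DRB1*13:02"),
        ("P-1901", Group.PULSED, "DRB1*03:01", "DRB1*13:01"),
        ("P-1902", Group.PULSED, "DRB1*13:05", "DRB1*15:01"),
        ("P-1903", Group.PULSED, "DRB1*04:04", "DRB1*13:02"),
        ("P-1907", Group.PULSED, "DRB1*07:01", "DRB1*13:02"),
        ("P-1912", Group.PULSED, "DRB1*03:01", "DRB1*13:03"),
        ("P-1914", Group.PULSED, "DRB1*01:02", "DRB1*13:02"),
    ]
    return [SampleInfo(s, g, a, b) for s, g, a, b in rows]


#: Default planted dominance (exclusive-count ratio of the canonically
#: first allele over the second) and dual fraction per default sample,
#: spanning the strong-dominance and balanced regimes seen across real
#: heterozygous DRB1 combinations.
DEFAULT_DOMINANCE: dict[str, float] = {
    "C-1921": 0.1,   # 13:01 vs 13:02 — 13:02 dominates (1/ratio = 10)
    "C-2102": 20.25,  # 01:01 strongly dominant over 11:01
    "C-2103": 1.0,
    "C-2104": 0.7,
    "C-2105": 1.9,
    "C-2106": 1.9,
    "C-2107": 1.4,
    "P-1901": 10.7,  # 03:01 over 13:01
    "P-1902": 0.5,
    "P-1903": 3.0,   # 04:04 over 13:02
    "P-1907": 1.0,
    "P-1912": 0.7,
    "P-1914": 3.0,
}

#: Default eluted-peptide totals per sample: right-skewed counts summing to
#: 2899 with a median of 195, the regime of a 14-donor MoDC elution study.
DEFAULT_PEPTIDE_COUNTS: dict[str, int] = {
    "C-1921": 200,
    "C-1922": 150,
    "C-2102": 215,
    "C-2103": 137,
    "C-2104": 235,
    "C-2105": 190,
    "C-2106": 165,
    "C-2107": 130,
    "P-1901": 255,
    "P-1902": 95,
    "P-1903": 366,
    "P-1907": 115,
    "P-1912": 280,
    "P-1914": 366,
}

DEFAULT_DUAL_FRACTION: dict[str, float] = {
    "C-1921": 0.15,
    "C-1922": 0.0,
    "C-2102": 0.20,
    "C-2103": 0.14,
    "C-2104": 0.55,
    "C-2105": 0.45,
    "C-2106": 0.45,
    "C-2107": 0.40,
    "P-1901": 0.20,
    "P-1902": 0.25,
    "P-1903": 0.50,
    "P-1907": 0.30,
    "P-1912": 0.62,
    "P-1914": 0.50,
}


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror a 14-sample dendritic-cell study: 2899 eluted peptides
    in total (median 195 per sample, about two thirds of them binders),
    15-mer average length within 9-25, per-sample dual fractions spanning
    14-62%, and a 1292-protein lysate proteome with 58 designated induced
    proteins yielding 120 peptides in the pulsed group.
    """

    samples: list[SampleInfo] = field(default_factory=default_study_samples)
    peptides_per_sample: int | Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PEPTIDE_COUNTS)
    )
    length_mean: float = 15.0
    length_sd: float = 2.5
    length_bounds: tuple[int, int] = (9, 25)
    dual_overlap: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DUAL_FRACTION)
    )
    dominance: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DOMINANCE)
    )
    nonbinder_rate: float = 0.315
    contaminant_rate: float = 0.008
    length_outlier_rate: float = 0.005
    nested_set_rate: float = 0.25
    shared_peptide_rate: float = 0.15
    n_lysate_proteins: int = 1292
    n_induced: int = 58
    n_induced_peptides: int = 120
    n_self_proteins: int = 600
    lysate_shared_fraction: float = 0.15
    anchors: Mapping[str, Mapping[int, str]] | None = None
    strengths: Mapping[str, float] | None = None
    background_size: int = 10000
    thresholds: Thresholds = field(default_factory=Thresholds)
    max_reject_batches: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_bounds
        if not (9 <= lo <= hi <= 25):
            raise ValueError("length bounds must lie within 9-25")
        for sid, f in self._per_sample(self.dual_overlap).items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"dual fraction for {sid} outside [0, 1]")
        if self.n_induced > self.n_lysate_proteins:
            raise ValueError("more induced proteins than lysate proteins")
        if self.n_induced_peptides < self.n_induced:
            raise ValueError("need at least one induced peptide per induced protein")

    def _per_sample(self, value, default=None) -> dict[str, float]:
        if isinstance(value, Mapping):
            out = {}
            for s in self.samples:
                if s.sample_id in value:
                    out[s.sample_id] = value[s.sample_id]
                elif default is not None:
                    out[s.sample_id] = default
                else:
                    raise KeyError(f"no value for sample {s.sample_id}")
            return out
        return {s.sample_id: value for s in self.samples}

    def dual_of(self, sample_id: str) -> float:
        return self._per_sample(self.dual_overlap, default=0.35)[sample_id]

    def dominance_of(self, sample_id: str) -> float:
        return self._per_sample(self.dominance, default=1.0)[sample_id]

    def n_peptides_of(self, sample_id: str) -> int:
        return int(
            self._per_sample(self.peptides_per_sample, default=207)[sample_id]
        )


@dataclass
class GroundTruth:
    """Generator-side truth for every planted quantity."""

    peptide_origin: dict[tuple[str, str], str] = field(default_factory=dict)
    true_dominance: dict[str, float] = field(default_factory=dict)
    true_dual_fraction: dict[str, float] = field(default_factory=dict)
    induced_proteins: frozenset[str] = frozenset()
    induced_peptides: frozenset[str] = frozenset()
    family_of: dict[str, str] = field(default_factory=dict)


@dataclass
class Cohort:
    """A generated cohort: every table the pipeline readers consume."""

    config: CohortConfig
    samples: list[SampleInfo]
    peptides: list[PeptideRecord]
    calls: list[BindingCall]
    lysate_sequences: dict[str, str]
    lysate_abundance: dict[str, float]
    localizations: dict[str, ProteinRecord]
    ground_truth: GroundTruth


class _SampleBuilder:
    """Rejection-sampling machinery for one sample's peptide categories."""

    def __init__(
        self,
        sample: SampleInfo,
        predictor: RankPredictor,
        config: CohortConfig,
        rng: np.random.Generator,
    ) -> None:
        self.sample = sample
        self.predictor = predictor
        self.config = config
        self.rng = rng
        self.wb_max = config.thresholds.wb_max
        self.seen: set[str] = set()
        a, b = sample.alleles
        self.probs = {
            a: _softmax_probs(predictor.motifs[a].pwm),
            b: _softmax_probs(predictor.motifs[b].pwm),
        }
        blended = (predictor.motifs[a].pwm + predictor.motifs[b].pwm) / 2.0
        self.blended_probs = _softmax_probs(blended)

    def _lengths(self, n: int) -> np.ndarray:
        lo, hi = self.config.length_bounds
        out = np.empty(n, dtype=int)
        filled = 0
        while filled < n:
            draw = np.rint(
                self.rng.normal(
                    self.config.length_mean, self.config.length_sd, size=2 * (n - filled)
                )
            ).astype(int)
            ok = draw[(draw >= lo) & (draw <= hi)][: n - filled]
            out[filled : filled + ok.size] = ok
            filled += ok.size
        return out

    def _candidates(self, n: int, probs: np.ndarray | None) -> list[str]:
        """Random peptides: a motif-sampled core with uniform flanks."""
        lengths = self._lengths(n)
        if probs is None:
            cores = self.rng.integers(0, len(AA), size=(n, CORE_LEN))
        else:
            cum = probs.cumsum(axis=1)  # (9, 20) per-position CDF
            u = self.rng.random((n, CORE_LEN))
            cores = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
        out = []
        for i in range(n):
            extra = lengths[i] - CORE_LEN
            left = int(self.rng.integers(0, extra + 1)) if extra else 0
            lf = self.rng.integers(0, len(AA), size=left)
            rf = self.rng.integers(0, len(AA), size=extra - left)
            out.append(_decode(np.concatenate([lf, cores[i], rf])))
        return out

    def _ranks(self, peptides: list[str]) -> dict[str, np.ndarray]:
        return {
            al: self.predictor.percent_ranks(peptides, al)
            for al in dict.fromkeys(self.sample.alleles)
        }

    def draw(
        self,
        n: int,
        accept,
        probs: np.ndarray | None,
        what: str,
        batch: int = 256,
    ) -> list[str]:
        """Draw n unique peptides satisfying ``accept(rank_by_allele, i)``."""
        out: list[str] = []
        for _ in range(self.config.max_reject_batches):
            if len(out) >= n:
                break
            cands = self._candidates(batch, probs)
            ranks = self._ranks(cands)
            for i, pep in enumerate(cands):
                if len(out) >= n:
                    break
                if pep in self.seen:
                    continue
                if accept(ranks, i):
                    out.append(pep)
                    self.seen.add(pep)
        if len(out) < n:
            hint = (
                " (dual peptides for disjoint motifs are rare; share anchor "
                "residues between the co-expressed alleles)"
                if what == "dual"
                else ""
            )
            raise RuntimeError(
                f"sample {self.sample.sample_id}: could not draw {n} {what} "
                f"peptides within the rejection budget{hint}"
            )
        return out

    def exclusive(self, allele: str, other: str, n: int) -> list[str]:
        def accept(ranks, i):
            return ranks[allele][i] <= self.wb_max and (
                allele == other or ranks[other][i] > self.wb_max
            )

        return self.draw(n, accept, self.probs[allele], f"{allele}-exclusive")

    def dual(self, n_win_a: int, n_win_b: int) -> tuple[list[str], list[str]]:
        """Dual binders (WB or better on both alleles) split by which allele wins."""
        a, b = self.sample.alleles
        win_a: list[str] = []
        win_b: list[str] = []
        out_total = n_win_a + n_win_b
        for _ in range(self.config.max_reject_batches):
            if len(win_a) >= n_win_a and len(win_b) >= n_win_b:
                break
            cands = self._candidates(256, self.blended_probs)
            ranks = self._ranks(cands)
            for i, pep in enumerate(cands):
                if pep in self.seen:
                    continue
                ra, rb = ranks[a][i], ranks[b][i]
                if ra > self.wb_max or rb > self.wb_max or ra == rb:
                    continue
                if ra < rb and len(win_a) < n_win_a:
                    win_a.append(pep)
                    self.seen.add(pep)
                elif rb < ra and len(win_b) < n_win_b:
                    win_b.append(pep)
                    self.seen.add(pep)
        if len(win_a) < n_win_a or len(win_b) < n_win_b:
            raise RuntimeError(
                f"sample {self.sample.sample_id}: could not draw "
                f"{out_total} dual peptides within the rejection budget "
                "(dual peptides for disjoint motifs are rare; share anchor "
                "residues between the co-expressed alleles)"
            )
        return win_a, win_b

    def nonbinders(self, n: int) -> list[str]:
        def accept(ranks, i):
            return all(r[i] > self.wb_max for r in ranks.values())

        return self.draw(n, accept, None, "non-binder")

    def nested_variants(self, peptide: str, accept, n: int = 2) -> list[str]:
        """Same-core peptides with fresh flanks, kept only if class-preserving."""
        lo, hi = self.config.length_bounds
        # use the central 9-mer as the shared core
        start = (len(peptide) - CORE_LEN) // 2
        core = _encode(peptide[start : start + CORE_LEN])
        variants: list[str] = []
        for _ in range(8 * n):
            if len(variants) >= n:
                break
            length = int(self._lengths(1)[0])
            extra = length - CORE_LEN
            left = int(self.rng.integers(0, extra + 1)) if extra else 0
            lf = self.rng.integers(0, len(AA), size=left)
            rf = self.rng.integers(0, len(AA), size=extra - left)
            cand = _decode(np.concatenate([lf, core, rf]))
            if cand in self.seen or cand == peptide:
                continue
            ranks = self._ranks([cand])
            if accept(ranks, 0):
                variants.append(cand)
                self.seen.add(cand)
        return variants


def _softmax_probs(pwm: np.ndarray) -> np.ndarray:
    e = np.exp(pwm - pwm.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def generate_peptide_families(
    n_families: int = 3,
    members_per_family: int = 10,
    length_bounds: tuple[int, int] = (12, 18),
    seed: int = 0,
) -> tuple[list[str], dict[str, int]]:
    """Nested-set-like sequence families for cluster-recovery experiments.

    Each family shares one random 9-mer core embedded in random flanks;
    families are well separated because independent random cores rarely
    align. Returns the pooled peptides and their true family labels.
    """
    rng = np.random.default_rng(seed)
    peptides: list[str] = []
    labels: dict[str, int] = {}
    seen: set[str] = set()
    for fam in range(n_families):
        core = rng.integers(0, len(AA), size=CORE_LEN)
        made = 0
        while made < members_per_family:
            length = int(rng.integers(length_bounds[0], length_bounds[1] + 1))
            extra = length - CORE_LEN
            left = int(rng.integers(0, extra + 1)) if extra else 0
            lf = rng.integers(0, len(AA), size=left)
            rf = rng.integers(0, len(AA), size=extra - left)
            pep = _decode(np.concatenate([lf, core, rf]))
            if pep in seen:
                continue
            seen.add(pep)
            peptides.append(pep)
            labels[pep] = fam
            made += 1
    return peptides, labels


def _make_accessions(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort with ground truth.

    Control samples are generated first so that the accession pools of
    pulsed samples can be restricted to proteins that cannot confound the
    pulse-induction set logic: a pulsed peptide's source is either a
    designated induced lysate protein, a self protein absent from the
    lysate, or a lysate protein already seen in controls.
    """
    rng = np.random.default_rng(config.seed)
    alleles = sorted({a for s in config.samples for a in s.alleles})
    motifs = {
        a: make_motif(
            a,
            anchors=(config.anchors or {}).get(a),
            strength=(config.strengths or {}).get(a),
            rng=np.random.default_rng([config.seed % (2**31), i]),
        )
        for i, a in enumerate(alleles)
    }
    predictor = RankPredictor(
        motifs, background_size=config.background_size, seed=config.seed % (2**31)
    )

    lysate_accs = _make_accessions("LYSP", config.n_lysate_proteins)
    self_accs = _make_accessions("SELF", config.n_self_proteins)
    induced_accs = list(
        rng.choice(lysate_accs, size=config.n_induced, replace=False)
    )
    non_induced_lysate = [a for a in lysate_accs if a not in set(induced_accs)]
    n_shared = int(round(config.lysate_shared_fraction * len(non_induced_lysate)))
    shared_lysate = list(
        rng.choice(non_induced_lysate, size=n_shared, replace=False)
    )
    control_pool = self_accs + shared_lysate

    # induced peptide allocation: each induced protein yields >= 1 peptide
    induced_alloc = induced_accs + list(
        rng.choice(induced_accs, size=config.n_induced_peptides - config.n_induced)
    )
    rng.shuffle(induced_alloc)
    pulsed_ids = [s.sample_id for s in config.samples if s.group is Group.PULSED]
    induced_per_sample: dict[str, list[str]] = {sid: [] for sid in pulsed_ids}
    if pulsed_ids:
        owners = rng.integers(0, len(pulsed_ids), size=len(induced_alloc))
        for acc, who in zip(induced_alloc, owners):
            induced_per_sample[pulsed_ids[who]].append(acc)

    truth = GroundTruth(
        induced_proteins=frozenset(induced_accs),
    )
    peptides: list[PeptideRecord] = []
    call_ranks: dict[tuple[str, str], float] = {}
    reuse_pool: dict[str, list[str]] = {a: [] for a in alleles}
    control_used_lysate: set[str] = set()
    induced_peptides: set[str] = set()

    ordered = sorted(config.samples, key=lambda s: (s.group is Group.PULSED, s.sample_id))
    for s_index, sample in enumerate(ordered):
        srng = np.random.default_rng(
            [config.seed % (2**31), 1000 + s_index]
        )
        builder = _SampleBuilder(sample, predictor, config, srng)
        a, b = sample.alleles
        n_total = config.n_peptides_of(sample.sample_id)
        n_contam = int(round(config.contaminant_rate * n_total))
        n_lenout = int(round(config.length_outlier_rate * n_total))
        n_clean = n_total - n_contam - n_lenout
        n_nonbind = int(round(config.nonbinder_rate * n_total))
        n_binders = n_clean - n_nonbind
        induced_list = list(induced_per_sample.get(sample.sample_id, []))
        r = config.dominance_of(sample.sample_id)

        if sample.is_homozygous:
            n_dual = 0
            n_x, n_y = n_binders, 0
            dw_x = dw_y = 0
        else:
            f_dual = config.dual_of(sample.sample_id)
            n_dual = int(round(f_dual * n_binders))
            n_excl = n_binders - n_dual
            n_x = int(round(n_excl * r / (1.0 + r)))
            n_y = n_excl - n_x
            # split dual winners so the filtered-count ratio matches r
            dw_x = int(round((r * n_y + r * n_dual - n_x) / (1.0 + r)))
            dw_x = min(max(dw_x, 0), n_dual)
            dw_y = n_dual - dw_x

        # reuse previously generated exclusive peptides of the same allele
        sample_reused: set[str] = set()
        cat_peptides: dict[str, list[str]] = {}
        for allele, other, quota in ((a, b, n_x), (b, a, n_y)):
            if quota == 0:
                cat_peptides.setdefault(allele, [])
                continue
            reused: list[str] = []
            n_reuse = int(round(config.shared_peptide_rate * quota))
            pool = [p for p in reuse_pool[allele] if p not in builder.seen]
            srng.shuffle(pool)
            for pep in pool:
                if len(reused) >= n_reuse:
                    break
                ranks = builder._ranks([pep])
                ok = ranks[allele][0] <= builder.wb_max and (
                    allele == other or ranks[other][0] > builder.wb_max
                )
                if ok:
                    reused.append(pep)
                    builder.seen.add(pep)
                    sample_reused.add(pep)
            fresh = builder.exclusive(allele, other, quota - len(reused))
            cat_peptides[allele] = reused + fresh
            if allele == other:
                break
        if not sample.is_homozygous:
            win_a, win_b = builder.dual(dw_x, dw_y)
            dual_peps = win_a + win_b
        else:
            dual_peps = []
        nonbind = builder.nonbinders(n_nonbind)

        # pool all binders with their category; the induced ones are picked
        # first (kept as singletons so the planted induced-peptide count is
        # exact), the rest may expand into nested-set families
        binder_pool: list[tuple[str, str]] = []
        for allele in dict.fromkeys((a, b)):
            binder_pool += [
                (pep, f"exclusive:{allele}") for pep in cat_peptides.get(allele, [])
            ]
        binder_pool += [(pep, "dual") for pep in dual_peps]
        if len(induced_list) > len(binder_pool):
            raise RuntimeError(
                f"sample {sample.sample_id}: {len(induced_list)} induced peptides "
                f"allocated but only {len(binder_pool)} binders; increase "
                "peptides_per_sample or lower n_induced_peptides"
            )
        order = np.arange(len(binder_pool))
        srng.shuffle(order)
        # induced peptides are fresh sequences (never cross-sample reused),
        # so the planted distinct induced-peptide count is exact
        fresh = [i for i in order if binder_pool[i][0] not in sample_reused]
        shared = [i for i in order if binder_pool[i][0] in sample_reused]
        if len(induced_list) > len(fresh):
            raise RuntimeError(
                f"sample {sample.sample_id}: not enough fresh binders for "
                f"{len(induced_list)} induced peptides"
            )
        induced_members = [binder_pool[i] for i in fresh[: len(induced_list)]]
        plain_members = [
            binder_pool[i] for i in fresh[len(induced_list) :] + shared
        ]

        def excl_accept(allele, other):
            def accept(ranks, i):
                return ranks[allele][i] <= builder.wb_max and (
                    allele == other or ranks[other][i] > builder.wb_max
                )

            return accept

        # nested-set expansion: a seed binder spawns same-core, same-protein
        # variants that replace later peptides of the same category, so the
        # per-category quota is preserved
        families: list[tuple[list[str], str]] = []  # (members, origin)
        by_cat: dict[str, list[str]] = {}
        for pep, origin in plain_members:
            by_cat.setdefault(origin, []).append(pep)
        for origin, peps in by_cat.items():
            if origin == "dual":
                families += [([p], origin) for p in peps]
                continue
            allele = origin.split(":", 1)[1]
            other = b if allele == a else a
            accept = excl_accept(allele, other)
            out = list(peps)
            i = 0
            while i < len(out):
                fam = [out[i]]
                if i < len(out) - 1 and srng.random() < config.nested_set_rate:
                    room = len(out) - i - 1
                    fs = min(int(srng.integers(1, 3)), room)
                    variants = builder.nested_variants(out[i], accept, n=fs)
                    for v in variants:
                        out.pop()
                        fam.append(v)
                families.append((fam, origin))
                i += 1

        if sample.group is Group.PULSED:
            safe_lysate = sorted(control_used_lysate)
            noninduced_pool = self_accs + safe_lysate
        else:
            noninduced_pool = control_pool

        recs: list[PeptideRecord] = []

        def emit(pep: str, origin: str, acc: str) -> None:
            recs.append(
                PeptideRecord(
                    sequence=pep,
                    sample_id=sample.sample_id,
                    source_accessions=frozenset({acc}),
                )
            )
            truth.peptide_origin[(sample.sample_id, pep)] = origin
            base = origin.split(";")[0]
            if base.startswith("exclusive:"):
                reuse_pool[base.split(":", 1)[1]].append(pep)
            elif base == "dual":
                reuse_pool[a].append(pep)
                reuse_pool[b].append(pep)

        for (pep, origin), acc in zip(induced_members, induced_list):
            induced_peptides.add(pep)
            emit(pep, origin + ";induced", acc)
        for fam_i, (fam, origin) in enumerate(families):
            acc = noninduced_pool[int(srng.integers(0, len(noninduced_pool)))]
            if sample.group is Group.CONTROL and acc.startswith("LYSP"):
                control_used_lysate.add(acc)
            for pep in fam:
                emit(pep, origin, acc)
            if len(fam) > 1:
                for pep in fam:
                    truth.family_of[pep] = f"{sample.sample_id}:{fam_i}"
        for pep in nonbind:
            acc = noninduced_pool[int(srng.integers(0, len(noninduced_pool)))]
            if sample.group is Group.CONTROL and acc.startswith("LYSP"):
                control_used_lysate.add(acc)
            emit(pep, "nonbinder", acc)

        # planted contaminants and length outliers
        for _ in range(n_contam):
            pep = _decode(srng.integers(0, len(AA), size=int(builder._lengths(1)[0])))
            if pep in builder.seen:
                continue
            builder.seen.add(pep)
            acc = CONTAMINANT_ACCESSIONS[
                int(srng.integers(0, len(CONTAMINANT_ACCESSIONS)))
            ]
            recs.append(
                PeptideRecord(pep, sample.sample_id, frozenset({acc}))
            )
            truth.peptide_origin[(sample.sample_id, pep)] = "contaminant"
        for _ in range(n_lenout):
            length = int(srng.integers(26, 33))
            pep = _decode(srng.integers(0, len(AA), size=length))
            if pep in builder.seen:
                continue
            builder.seen.add(pep)
            acc = noninduced_pool[int(srng.integers(0, len(noninduced_pool)))]
            recs.append(PeptideRecord(pep, sample.sample_id, frozenset({acc})))
            truth.peptide_origin[(sample.sample_id, pep)] = "length_outlier"

        # binding calls for every peptide long enough to score
        scorable = [r.sequence for r in recs if len(r.sequence) >= CORE_LEN]
        for allele in dict.fromkeys((a, b)):
            ranks = predictor.percent_ranks(scorable, allele)
            for pep, rank in zip(scorable, ranks):
                call_ranks[(pep, allele)] = float(rank)

        peptides.extend(recs)
        truth.true_dominance[sample.sample_id] = (
            float("nan") if sample.is_homozygous else r
        )
        truth.true_dual_fraction[sample.sample_id] = (
            0.0 if sample.is_homozygous else config.dual_of(sample.sample_id)
        )

    truth.induced_peptides = frozenset(induced_peptides)

    calls = [
        BindingCall(
            peptide=pep,
            allele=allele,
            percent_rank=rank,
            binding_class=classify_binding(rank, config.thresholds),
        )
        for (pep, allele), rank in sorted(call_ranks.items())
    ]

    # lysate proteome: induced proteins embed the peptides they yielded
    peptides_by_acc: dict[str, list[str]] = {}
    for rec in peptides:
        for acc in rec.source_accessions:
            peptides_by_acc.setdefault(acc, []).append(rec.sequence)
    lysate_sequences: dict[str, str] = {}
    for acc in lysate_accs:
        body = "".join(sorted(set(peptides_by_acc.get(acc, []))))
        pad = max(0, 100 - len(body))
        tail = _decode(rng.integers(0, len(AA), size=pad))
        lysate_sequences[acc] = body + tail
    lysate_abundance = {
        acc: float(x)
        for acc, x in zip(lysate_accs, rng.lognormal(10.0, 1.5, len(lysate_accs)))
    }

    # subcellular localisations: induced proteins lean cytosolic
    localizations: dict[str, ProteinRecord] = {}
    base_probs = np.array([0.22, 0.20, 0.20, 0.12, 0.08, 0.06, 0.04, 0.04, 0.04])
    induced_probs = np.array([0.08, 0.05, 0.45, 0.12, 0.08, 0.06, 0.06, 0.06, 0.04])
    for acc in lysate_accs + self_accs + list(CONTAMINANT_ACCESSIONS):
        probs = induced_probs if acc in truth.induced_proteins else base_probs
        n_loc = 1 + int(rng.random() < 0.15)
        locs = rng.choice(COMPARTMENTS, size=n_loc, replace=False, p=probs)
        localizations[acc] = ProteinRecord(acc, frozenset(locs.tolist()))

    return Cohort(
        config=config,
        samples=list(config.samples),
        peptides=peptides,
        calls=calls,
        lysate_sequences=lysate_sequences,
        lysate_abundance=lysate_abundance,
        localizations=localizations,
        ground_truth=truth,
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort in the file dialects the pipeline readers consume."""
    from . import io as dio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "peptides": outdir / "peptides.tsv",
        "samples": outdir / "samples.tsv",
        "binding": outdir / "binding_calls.tsv",
        "lysate": outdir / "lysate_proteome.fasta",
        "abundance": outdir / "lysate_abundance.tsv",
        "localizations": outdir / "localizations.tsv",
        "contaminants": outdir / "contaminants.txt",
        "ground_truth": outdir / "ground_truth.json",
    }
    dio.write_peptide_table(cohort.peptides, paths["peptides"])
    dio.write_sample_table(cohort.samples, paths["samples"])
    dio.write_binding_calls(cohort.calls, paths["binding"])
    with open(paths["lysate"], "w") as fh:
        for acc, seq in cohort.lysate_sequences.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(paths["abundance"], "w") as fh:
        fh.write("accession\tabundance\n")
        for acc, x in cohort.lysate_abundance.items():
            fh.write(f"{acc}\t{x:.6g}\n")
    dio.write_localization_table(cohort.localizations.values(), paths["localizations"])
    paths["contaminants"].write_text("\n".join(CONTAMINANT_ACCESSIONS) + "\n")
    truth = cohort.ground_truth
    with open(paths["ground_truth"], "w") as fh:
        json.dump(
            {
                "peptide_origin": {
                    f"{sid}\t{pep}": origin
                    for (sid, pep), origin in truth.peptide_origin.items()
                },
                "true_dominance": truth.true_dominance,
                "true_dual_fraction": truth.true_dual_fraction,
                "induced_proteins": sorted(truth.induced_proteins),
                "induced_peptides": sorted(truth.induced_peptides),
            },
            fh,
            indent=1,
            allow_nan=True,
        )
    return paths
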