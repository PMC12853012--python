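"""Alignment-based peptide clustering and 2D MDS embedding of allele units.

The method positions each (sample, allele) unit by the peptide repertoire
it presents:

1. all peptides are pairwise globally aligned (Needleman-Wunsch, BLOSUM62,
   affine gaps) and alignment scores are turned into a normalised
   dissimilarity;
2. average-linkage hierarchical clustering groups homologous peptides and
   nested sets, with the cluster count chosen by mean silhouette width;
3. each allele unit becomes a relative-frequency vector over the peptide
   clusters (dual peptides feed both co-expressed units in non-filtered
   mode);
4. classical (Torgerson) metric MDS projects inter-unit Euclidean
   distances to 2D;
5. the filtered and non-filtered configurations are Procrustes-aligned and
   per-sample co-expressed-pair distance changes are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .models import AssignmentMode, AssignmentTable, SampleInfo, validate_sequence
from .repertoire import AlleleUnit

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric normalised alignment dissimilarities between peptides.

    Values lie in [0, 1] with zero diagonal. The triangle inequality is
    not guaranteed: normalised alignment distances are a dissimilarity,
    not a metric.
    """

    items: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.items)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match item count")


@dataclass
class AlleleEmbedding:
    """One allele unit's cluster-frequency vector and 2D MDS coordinates."""

    unit: AlleleUnit
    feature: np.ndarray
    xy: np.ndarray | None
    mode: AssignmentMode


@dataclass
class DistanceChange:
    """Filtered-vs-non-filtered MDS distance between co-expressed alleles."""

    sample_id: str
    unit_a: AlleleUnit
    unit_b: AlleleUnit
    dist_filtered: float
    dist_nonfiltered: float

    @property
    def delta(self) -> float:
        return self.dist_filtered - self.dist_nonfiltered


def make_aligner(
    matrix_name: str = "BLOSUM62", gap_open: float = 11.0, gap_extend: float = 1.0
) -> Align.PairwiseAligner:
    """Global pairwise aligner; a gap of length L costs gap_open + L*gap_extend."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def self_score(seq: str, aligner: Align.PairwiseAligner) -> float:
    """Gapless self-alignment score: sum of diagonal substitution entries."""
    m = aligner.substitution_matrix
    return float(sum(m[a, a] for a in seq))


def pairwise_peptide_distances(
    peptides: Sequence[str],
    matrix_name: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    normalisation: str = "min_self",
) -> DistanceMatrix:
    """Normalised global-alignment dissimilarities between all peptide pairs.

    ``d(a, b) = 1 - S(a, b) / norm`` where ``norm`` is the smaller
    (``min_self``, default) or larger (``max_self``) of the two
    self-alignment scores, clipped to [0, 1]. Identical sequences get 0.
    """
    items = [validate_sequence(p) for p in peptides]
    if len(items) < 2:
        raise ValueError("need at least 2 peptides")
    if normalisation not in ("min_self", "max_self"):
        raise ValueError(f"unknown normalisation {normalisation!r}")
    aligner = make_aligner(matrix_name, gap_open, gap_extend)
    self_scores = np.array([self_score(p, aligner) for p in items])
    n = len(items)
    d = np.zeros((n, n))
    pick = min if normalisation == "min_self" else max
    for i, j in combinations(range(n), 2):
        if items[i] == items[j]:
            continue
        s = aligner.score(items[i], items[j])
        norm = pick(self_scores[i], self_scores[j])
        dist = 1.0 - s / norm
        d[i, j] = d[j, i] = min(1.0, max(0.0, dist))
    return DistanceMatrix(items=items, d=d)


def cluster_peptides(dm: DistanceMatrix, k: int) -> np.ndarray:
    """Average-linkage hierarchical clustering cut into k groups (labels 1..k)."""
    condensed = squareform(dm.d, checks=False)
    Z = linkage(condensed, method="average")
    return fcluster(Z, t=k, criterion="maxclust")


def choose_cluster_count(
    dm: DistanceMatrix, k_grid: Sequence[int] | None = None
) -> int:
    """Cluster count maximising mean silhouette width over ``k_grid``.

    Ties go to the smallest k. Degenerate inputs (all peptides identical)
    fall back to the grid's lower bound with a warning.
    """
    n = len(dm.items)
    if n < 3:
        raise ValueError("need at least 3 peptides to choose a cluster count")
    if k_grid is None:
        k_grid = range(2, min(50, n - 1) + 1)
    k_grid = [k for k in k_grid if 2 <= k <= n - 1]
    if not k_grid:
        raise ValueError("empty cluster-count grid")
    if not np.any(dm.d > 0):
        log.warning("all peptides identical; forcing k to the grid lower bound")
        return min(k_grid)
    best_k, best_score = None, -np.inf
    for k in sorted(k_grid):
        labels = cluster_peptides(dm, k)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(dm.d, labels, metric="precomputed")
        if score > best_score + 1e-12:
            best_k, best_score = k, score
    if best_k is None:
        log.warning("no valid clustering on the grid; using the lower bound")
        return min(k_grid)
    return best_k


def allele_feature_vectors(
    dm_items: Sequence[str],
    labels: np.ndarray,
    tables: Sequence[AssignmentTable],
    samples: Mapping[str, SampleInfo],
) -> list[AlleleEmbedding]:
    """Relative cluster-frequency vector per allele unit.

    In non-filtered tables, dual peptides contribute to both co-expressed
    units. Units with no assigned peptides get a zero vector (warned).
    """
    label_of = dict(zip(dm_items, labels))
    k = int(labels.max())
    out: list[AlleleEmbedding] = []
    for t in tables:
        sample = samples[t.sample_id]
        for allele in dict.fromkeys(sample.alleles):
            unit = AlleleUnit(t.sample_id, allele)
            feat = np.zeros(k)
            peps = t.peptides_of(allele)
            for pep in peps:
                if pep not in label_of:
                    raise ValueError(f"peptide {pep} has no cluster label")
                feat[label_of[pep] - 1] += 1.0
            if peps:
                feat /= feat.sum()
            else:
                log.warning("allele unit %s has no peptides; zero feature vector", unit)
            out.append(AlleleEmbedding(unit=unit, feature=feat, xy=None, mode=t.mode))
    return out


def classical_mds(d: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) metric MDS of a square distance matrix.

    Double-centres the squared distances, eigendecomposes, and keeps the
    top eigendimensions with positive eigenvalues. If fewer than
    ``n_components`` positive eigenvalues exist, remaining axes are
    zero-padded (warned). Axis signs follow a deterministic convention:
    the first nonzero loading of each axis is positive.
    """
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    B = (B + B.T) / 2
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    coords = np.zeros((n, n_components))
    n_pos = 0
    for axis in range(min(n_components, n)):
        if eigval[axis] > 1e-10:
            coords[:, axis] = eigvec[:, axis] * np.sqrt(eigval[axis])
            n_pos += 1
    if n_pos < n_components:
        log.warning(
            "distance matrix supports only %d positive eigendimensions; "
            "remaining axes zero-padded",
            n_pos,
        )
    for axis in range(n_components):
        col = coords[:, axis]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    return coords


def mds_project(embeddings: Sequence[AlleleEmbedding]) -> list[AlleleEmbedding]:
    """Project allele units to 2D from inter-unit Euclidean feature distances."""
    if len(embeddings) < 3:
        raise ValueError("need at least 3 allele units for an MDS projection")
    X = np.vstack([e.feature for e in embeddings])
    d = squareform(pdist(X, metric="euclidean"))
    coords = classical_mds(d, n_components=2)
    for e, xy in zip(embeddings, coords):
        e.xy = xy
    return list(embeddings)


def procrustes_align(
    reference: np.ndarray, moving: np.ndarray
) -> np.ndarray:
    """Align ``moving`` onto ``reference`` by translation and rotation/reflection.

    No rescaling is applied, so aligned inter-point distances are those of
    the original moving configuration.
    """
    ref_c = reference - reference.mean(axis=0)
    mov_c = moving - moving.mean(axis=0)
    R, _ = orthogonal_procrustes(mov_c, ref_c)
    return mov_c @ R + reference.mean(axis=0)


def compare_conditions(
    filtered: Sequence[AlleleEmbedding],
    nonfiltered: Sequence[AlleleEmbedding],
    samples: Mapping[str, SampleInfo],
) -> list[DistanceChange]:
    """Per-sample co-expressed-pair distance change between the two modes.

    The non-filtered configuration is Procrustes-aligned to the filtered
    one (common frame) before distances are measured; positive delta means
    the pair sits farther apart under filtered assignment, i.e. dual
    peptides pull the co-expressed alleles together.
    """
    f_by_unit = {e.unit: e for e in filtered}
    n_by_unit = {e.unit: e for e in nonfiltered}
    if set(f_by_unit) != set(n_by_unit):
        raise ValueError("filtered and non-filtered embeddings cover different units")
    units = sorted(f_by_unit)
    F = np.vstack([f_by_unit[u].xy for u in units])
    N = np.vstack([n_by_unit[u].xy for u in units])
    N_aligned = procrustes_align(F, N)
    pos_f = {u: F[i] for i, u in enumerate(units)}
    pos_n = {u: N_aligned[i] for i, u in enumerate(units)}
    out: list[DistanceChange] = []
    for sid in sorted({u.sample_id for u in units}):
        sample = samples[sid]
        if sample.is_homozygous:
            continue
        ua = AlleleUnit(sid, sample.allele_a)
        ub = AlleleUnit(sid, sample.allele_b)
        if ua not in pos_f or ub not in pos_f:
            continue
        out.append(
            DistanceChange(
                sample_id=sid,
                unit_a=ua,
                unit_b=ub,
                dist_filtered=float(np.linalg.norm(pos_f[ua] - pos_f[ub])),
                dist_nonfiltered=float(np.linalg.norm(pos_n[ua] - pos_n[ub])),
            )
        )
    return out


def mds_analysis(
    tables: Sequence[AssignmentTable],
    samples: Mapping[str, SampleInfo],
    k_grid: Sequence[int] | None = None,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[DistanceMatrix, np.ndarray, list[AlleleEmbedding]]:
    """Full embedding pass for one assignment mode.

    Pools all assigned peptides, computes the distance matrix, picks the
    cluster count by silhouette, builds feature vectors and projects the
    units to 2D.
    """
    pooled = sorted({p for t in tables for p in t.entries})
    dm = pairwise_peptide_distances(
        pooled, matrix_name=matrix_name, gap_open=gap_open, gap_extend=gap_extend
    )
    k = choose_cluster_count(dm, k_grid)
    labels = cluster_peptides(dm, k)
    embeddings = allele_feature_vectors(dm.items, labels, tables, samples)
    mds_project(embeddings)
    return dm, labels, embeddings
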