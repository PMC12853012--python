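import numpy as np
import pytest

from drpeptidome import (
    SampleInfo,
    choose_cluster_count,
    classical_mds,
    compare_conditions,
    mds_project,
    pairwise_peptide_distances,
)
from drpeptidome.mds import (
    AlleleEmbedding,
    allele_feature_vectors,
    cluster_peptides,
    make_aligner,
    procrustes_align,
    self_score,
)
from drpeptidome.models import AssignmentMode, AssignmentTable, Group
from drpeptidome.repertoire import AlleleUnit
from drpeptidome.simulate import generate_peptide_families

AA = "ACDEFGHIKLMNPQRSTVWY"
A, B = "DRB1*03:01", "DRB1*13:01"


def _nw_affine_oracle(a, b, matrix, gap_open=11.0, gap_extend=1.0):
    """Independent Gotoh global alignment; gap of length L costs open + L*extend."""
    n, m = len(a), len(b)
    NEG = -1e9
    first = gap_open + gap_extend  # cost of opening a gap of length 1
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a aligned to gap)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - first, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - first, Y[i, j - 1] - gap_extend)
    return max(M[n, m], X[n, m], Y[n, m])


class TestPeptideDistances:
    def test_zero_diagonal_symmetry_and_range(self, rng):
        peps = ["".join(rng.choice(list(AA), 15)) for _ in range(12)]
        dm = pairwise_peptide_distances(peps)
        assert np.allclose(np.diag(dm.d), 0.0)
        assert np.allclose(dm.d, dm.d.T)
        assert dm.d.min() >= 0.0 and dm.d.max() <= 1.0

    def test_self_score_is_blosum_diagonal_sum(self):
        # BLOSUM62 diagonal: A=4 C=9 D=6 E=5 F=6 G=6 H=8 I=4 K=5 -> 53
        aligner = make_aligner()
        assert self_score("ACDEFGHIK", aligner) == pytest.approx(53.0)
        assert aligner.score("ACDEFGHIK", "ACDEFGHIK") == pytest.approx(53.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_alignment_scores_match_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        aligner = make_aligner()
        matrix = aligner.substitution_matrix
        a = "".join(rng.choice(list(AA), int(rng.integers(9, 16))))
        b = "".join(rng.choice(list(AA), int(rng.integers(9, 16))))
        assert aligner.score(a, b) == pytest.approx(
            _nw_affine_oracle(a, b, matrix)
        )

    def test_family_members_closer_than_strangers(self):
        peps, labels = generate_peptide_families(2, 6, seed=3)
        dm = pairwise_peptide_distances(peps)
        lab = np.array([labels[p] for p in dm.items])
        within = dm.d[np.ix_(lab == 0, lab == 0)]
        between = dm.d[np.ix_(lab == 0, lab == 1)]
        assert within[np.triu_indices_from(within, 1)].mean() < between.mean()

    def test_identical_sequences_distance_zero(self):
        dm = pairwise_peptide_distances(["IQQDTKGDY", "IQQDTKGDY", "WWWWWWWWW"])
        assert dm.d[0, 1] == 0.0

    def test_rejects_non_canonical(self):
        with pytest.raises(ValueError):
            pairwise_peptide_distances(["AAAAAAAAX", "CCCCCCCCC"])


class TestClusterCount:
    @pytest.mark.parametrize("k_true", [2, 3])
    def test_recovers_planted_families(self, k_true):
        peps, _ = generate_peptide_families(k_true, 10, seed=5)
        dm = pairwise_peptide_distances(peps)
        assert choose_cluster_count(dm, range(2, 8)) == k_true

    def test_too_few_peptides_errors(self):
        dm = pairwise_peptide_distances(["AAAAAAAAA", "CCCCCCCCC"])
        with pytest.raises(ValueError):
            choose_cluster_count(dm)

    def test_degenerate_identical_peptides_fall_back(self):
        dm = pairwise_peptide_distances(["IQQDTKGDY"] * 5)
        assert choose_cluster_count(dm, range(2, 4)) == 2


class TestFeatureVectors:
    def _embed(self, entries_nf):
        samples = {"s1": SampleInfo("s1", Group.CONTROL, A, B)}
        table = AssignmentTable("s1", AssignmentMode.NONFILTERED, entries_nf)
        items = sorted(entries_nf)
        labels = np.array([1 + (i % 2) for i in range(len(items))])
        return items, labels, table, samples

    def test_one_hot_for_single_cluster_unit(self):
        samples = {"s1": SampleInfo("s1", Group.CONTROL, A, B)}
        table = AssignmentTable(
            "s1",
            AssignmentMode.NONFILTERED,
            {"AAAAAAAAA": {A}, "CCCCCCCCC": {A}},
        )
        emb = allele_feature_vectors(
            ["AAAAAAAAA", "CCCCCCCCC"], np.array([1, 1]), [table], samples
        )
        by_unit = {e.unit: e for e in emb}
        assert np.allclose(by_unit[AlleleUnit("s1", A)].feature, [1.0])
        assert np.allclose(by_unit[AlleleUnit("s1", B)].feature, [0.0])

    def test_dual_peptides_count_for_both_units(self):
        items, labels, table, samples = self._embed(
            {"AAAAAAAAA": {A, B}, "CCCCCCCCC": {A}}
        )
        emb = {e.unit: e for e in allele_feature_vectors(items, labels, [table], samples)}
        # dual peptide AAAAAAAAA (cluster 1) feeds both units
        assert emb[AlleleUnit("s1", A)].feature.sum() == pytest.approx(1.0)
        assert emb[AlleleUnit("s1", B)].feature[0] == pytest.approx(1.0)

    def test_missing_cluster_label_errors(self):
        items, labels, table, samples = self._embed({"AAAAAAAAA": {A}})
        table.entries["CCCCCCCCC"] = frozenset({A})
        with pytest.raises(ValueError):
            allele_feature_vectors(items, labels, [table], samples)


class TestClassicalMds:
    def test_collinear_three_points_exact(self):
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        coords = classical_mds(d)
        got = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.allclose(got, d, atol=1e-10)

    @pytest.mark.parametrize("n", [4, 7, 10])
    def test_recovers_euclidean_configurations(self, n, rng):
        """2D-embeddable matrices are reproduced to within 1e-8."""
        pts = rng.normal(size=(n, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords = classical_mds(d)
        got = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.allclose(got, d, atol=1e-8)

    def test_sign_convention_deterministic(self, rng):
        pts = rng.normal(size=(5, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        c1 = classical_mds(d)
        c2 = classical_mds(d.copy())
        assert np.array_equal(c1, c2)
        for axis in range(2):
            nz = np.nonzero(np.abs(c1[:, axis]) > 1e-12)[0]
            if nz.size:
                assert c1[nz[0], axis] > 0

    def test_identical_features_coincide(self):
        feats = [np.array([0.5, 0.5]), np.array([0.5, 0.5]), np.array([1.0, 0.0])]
        emb = [
            AlleleEmbedding(AlleleUnit(f"s{i}", A), f, None, AssignmentMode.FILTERED)
            for i, f in enumerate(feats)
        ]
        mds_project(emb)
        assert np.allclose(emb[0].xy, emb[1].xy)

    def test_rank_deficient_zero_pads(self):
        # 1D configuration: 3 collinear points embed with a zero second axis
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        coords = classical_mds(d)
        assert np.allclose(coords[:, 1], 0.0)


class TestCompareConditions:
    def _embeddings(self, coords, mode):
        return [
            AlleleEmbedding(
                AlleleUnit(sid, allele), np.zeros(2), np.asarray(xy, float), mode
            )
            for (sid, allele), xy in coords.items()
        ]

    def test_identical_configurations_zero_deltas(self):
        coords = {
            ("s1", A): (0.0, 0.0),
            ("s1", B): (1.0, 0.0),
            ("s2", A): (0.0, 2.0),
            ("s2", B): (3.0, 2.0),
        }
        samples = {
            "s1": SampleInfo("s1", Group.CONTROL, A, B),
            "s2": SampleInfo("s2", Group.CONTROL, A, B),
        }
        f = self._embeddings(coords, AssignmentMode.FILTERED)
        nf = self._embeddings(coords, AssignmentMode.NONFILTERED)
        deltas = compare_conditions(f, nf, samples)
        assert len(deltas) == 2
        assert all(abs(d.delta) < 1e-10 for d in deltas)

    def test_rotated_configuration_aligns_back(self, rng):
        pts = rng.normal(size=(6, 2))
        theta = 1.1
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = pts @ R.T + np.array([5.0, -2.0])
        aligned = procrustes_align(pts, moved)
        assert np.allclose(aligned, pts, atol=1e-10)

    def test_unit_mismatch_errors(self):
        samples = {"s1": SampleInfo("s1", Group.CONTROL, A, B)}
        f = self._embeddings(
            {("s1", A): (0, 0), ("s1", B): (1, 0)}, AssignmentMode.FILTERED
        )
        nf = self._embeddings({("s1", A): (0, 0)}, AssignmentMode.NONFILTERED)
        with pytest.raises(ValueError):
            compare_conditions(f, nf, samples)


def test_cluster_labels_partition_items():
    peps, _ = generate_peptide_families(3, 6, seed=2)
    dm = pairwise_peptide_distances(peps)
    labels = cluster_peptides(dm, 3)
    assert len(labels) == len(peps)
    assert set(labels) == {1, 2, 3}
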