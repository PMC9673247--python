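import numpy as np
import pandas as pd
import pytest

from conftest import make_metadata
from fruitcore.clustering import (
    DianaClustering,
    correlation_dissimilarity,
    cut_tree,
    diana_tree,
    pca_summary,
    profile_matrix,
)


# ---------------------------------------------------------------------------
# independent straight-from-pseudocode DIANA reference (plain loops, no numpy
# vectorization; shares no code with the implementation under test)


def reference_diana(d):
    n = len(d)
    splits = []
    active = [list(range(n))]
    while active:
        best, best_diam = None, -1.0
        for c in active:
            diam = 0.0
            for i in c:
                for j in c:
                    diam = max(diam, d[i][j])
            if diam > best_diam or (diam == best_diam and c[0] < active[best][0]):
                best_diam, best = diam, active.index(c)
        c = active.pop(best)
        # splinter seed: max average dissimilarity to the others
        seed, seed_avg = None, -1.0
        for i in c:
            avg = sum(d[i][j] for j in c if j != i) / (len(c) - 1)
            if avg > seed_avg:
                seed_avg, seed = avg, i
        a = [i for i in c if i != seed]
        b = [seed]
        while len(a) > 1:
            cand, cand_diff = None, 0.0
            for i in a:
                da = sum(d[i][j] for j in a if j != i) / (len(a) - 1)
                db = sum(d[i][j] for j in b) / len(b)
                diff = da - db
                if cand is None or diff > cand_diff:
                    cand, cand_diff = i, diff
            if cand_diff > 0:
                a.remove(cand)
                b.append(cand)
            else:
                break
        splits.append((tuple(sorted(c)), tuple(sorted(a)), tuple(sorted(b)), best_diam))
        for child in (a, b):
            if len(child) > 1:
                active.append(list(child))
    return splits


def as_partition(splits, n, k):
    clusters = [set(range(n))]
    for members, left, right, _ in splits[: k - 1]:
        for i, c in enumerate(clusters):
            if c == set(members):
                clusters[i] = set(left)
                clusters.append(set(right))
                break
    return sorted((frozenset(c) for c in clusters), key=min)


class TestDianaTree:
    def test_two_tight_pairs_split_first(self):
        d = np.array(
            [[0, 0.1, 5, 5], [0.1, 0, 5, 5], [5, 5, 0, 0.1], [5, 5, 0.1, 0]]
        )
        tree = diana_tree(d)
        s = tree.splits[0]
        assert {frozenset(s.left), frozenset(s.right)} == {
            frozenset({0, 1}),
            frozenset({2, 3}),
        }
        assert s.height == 5.0

    def test_single_object_no_splits(self):
        tree = diana_tree(np.zeros((1, 1)))
        assert tree.splits == []

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            diana_tree(np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError, match="non-negative"):
            diana_tree(np.array([[0, -1], [-1, 0]]))

    def test_heights_non_increasing_along_paths(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        tree = diana_tree(d)
        parent_height = {}
        for s in tree.splits:
            h = parent_height.get(s.members, np.inf)
            assert s.height <= h + 1e-12
            parent_height[s.left] = s.height
            parent_height[s.right] = s.height

    def test_matches_reference_on_random_matrices(self):
        """Partitions equal an independent reference on 100 random 8x8 inputs."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.uniform(0, 1, size=(8, 8))
            d = (x + x.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = diana_tree(d)
            ref = reference_diana(d.tolist())
            for k in (2, 3, 4, 8):
                mine = sorted(
                    (
                        frozenset(c)
                        for c in _partition_from_tree(tree, k)
                    ),
                    key=min,
                )
                assert mine == as_partition(ref, 8, k)

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(size=(10, 10))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        t1, t2 = diana_tree(d), diana_tree(d)
        assert [(s.members, s.left, s.right, s.height) for s in t1.splits] == [
            (s.members, s.left, s.right, s.height) for s in t2.splits
        ]


def _partition_from_tree(tree, k):
    labels = cut_tree(tree, k=k, min_size=1).to_numpy()
    return [
        set(np.nonzero(labels == lab)[0].tolist()) for lab in sorted(set(labels))
    ]


class TestCutTree:
    @pytest.fixture
    def blob_tree(self):
        d = np.array(
            [[0, 0.1, 5, 5], [0.1, 0, 5, 5], [5, 5, 0, 0.1], [5, 5, 0.1, 0]]
        )
        return diana_tree(d)

    def test_k2_recovers_blobs(self, blob_tree):
        labels = cut_tree(blob_tree, k=2, min_size=1)
        assert labels.tolist() == [1, 1, 2, 2]

    def test_k_equals_n_all_unassigned_with_min_size(self, blob_tree):
        labels = cut_tree(blob_tree, k=4, min_size=2)
        assert labels.tolist() == [0, 0, 0, 0]

    def test_min_size_one_assigns_everything(self, blob_tree):
        labels = cut_tree(blob_tree, k=2, min_size=1)
        assert (labels > 0).all()

    def test_height_cut(self, blob_tree):
        labels = cut_tree(blob_tree, height=1.0, min_size=1)
        assert labels.tolist() == [1, 1, 2, 2]

    def test_k_out_of_range(self, blob_tree):
        with pytest.raises(ValueError, match="out of range"):
            cut_tree(blob_tree, k=9)
        with pytest.raises(ValueError, match="exactly one"):
            cut_tree(blob_tree, k=2, height=1.0)


class TestProfileMatrix:
    def test_hand_zscore_example(self):
        # one gene, cell means (0, 3, 15) -> log2(x+1) = (0, 2, 4) -> z = (-1, 0, 1)
        meta = make_metadata(replicates=1)
        counts = np.array([[0, 3, 15]])
        prof = profile_matrix(counts, np.ones(3), meta, grouping="species")
        np.testing.assert_allclose(prof.values[0], [-1.0, 0.0, 1.0], atol=1e-10)

    def test_replicates_averaged(self):
        meta = make_metadata(stages=(("2", 2.0), ("3", 3.0)), replicates=2)
        counts = np.array([[4, 6, 0, 0]])
        prof = profile_matrix(counts, np.ones(4), meta, grouping="species")
        # cell means (5, 0) -> log2 (log2(6), 0)
        assert prof.cell_labels == [("sp", "2"), ("sp", "3")]
        m = np.log2(np.array([6.0, 1.0]))
        z = (m - m.mean()) / m.std(ddof=1)
        np.testing.assert_allclose(prof.values[0], z, atol=1e-12)

    def test_constant_gene_flagged_zero_row(self):
        meta = make_metadata(replicates=1)
        counts = np.array([[7, 7, 7]])
        prof = profile_matrix(counts, np.ones(3), meta, grouping="species")
        assert prof.constant[0]
        np.testing.assert_array_equal(prof.values[0], 0.0)

    def test_rows_standardized(self):
        rng = np.random.default_rng(3)
        meta = make_metadata(species=("a", "b"), fruit_types=("dry", "fleshy"))
        counts = rng.poisson(50, size=(40, len(meta)))
        prof = profile_matrix(counts, np.ones(len(meta)), meta, grouping="fruit_type")
        ok = ~prof.constant
        assert np.abs(prof.values[ok].mean(axis=1)).max() < 1e-10
        assert np.abs(prof.values[ok].std(axis=1, ddof=1) - 1).max() < 1e-10


class TestPca:
    def test_collinear_data_pc1_explains_all(self):
        t = np.linspace(0, 1, 6)
        X = np.column_stack([t, 2 * t, -t])
        out = pca_summary(X)
        assert out["percent_variance"][0] == pytest.approx(100.0)

    def test_percentages_monotone_and_bounded(self):
        rng = np.random.default_rng(4)
        out = pca_summary(rng.normal(size=(20, 5)))
        pv = out["percent_variance"]
        assert np.all(np.diff(pv) <= 1e-9)
        assert pv.sum() <= 100 + 1e-9

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 4))
        out = pca_summary(X)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        scores = Xc @ evecs
        for j in range(4):
            assert (
                np.allclose(out["scores"][:, j], scores[:, j], atol=1e-8)
                or np.allclose(out["scores"][:, j], -scores[:, j], atol=1e-8)
            )
        np.testing.assert_allclose(
            out["percent_variance"], 100 * evals / evals.sum(), atol=1e-8
        )

    def test_constant_matrix_flagged(self):
        out = pca_summary(np.ones((4, 3)))
        assert out["degenerate"]
        assert np.all(out["percent_variance"] == 0)


class TestDianaClustering:
    def test_recovers_inverted_archetypes(self):
        """Two planted profile archetypes (a trajectory and its mirror)."""
        rng = np.random.default_rng(6)
        base = np.array([-1.0, 0.0, 1.0, 0.5, -0.5])
        profiles = np.vstack(
            [base + rng.normal(0, 0.15, 5) for _ in range(30)]
            + [-base + rng.normal(0, 0.15, 5) for _ in range(30)]
        )
        est = DianaClustering(k=2, min_size=1, metric="correlation")
        labels = est.fit_predict(profiles)
        truth = np.repeat([0, 1], 30)
        # Rand index
        same_pred = labels[:, None] == labels[None, :]
        same_true = truth[:, None] == truth[None, :]
        iu = np.triu_indices(60, 1)
        rand = (same_pred == same_true)[iu].mean()
        assert rand >= 0.95

    def test_sklearn_get_set_params(self):
        est = DianaClustering(k=3)
        assert est.get_params()["k"] == 3
        est.set_params(min_size=5)
        assert est.min_size == 5

    def test_constant_row_rejected_for_correlation(self):
        X = np.vstack([np.ones(4), np.arange(4.0)])
        with pytest.raises(ValueError, match="constant"):
            DianaClustering(metric="correlation").fit(X)
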