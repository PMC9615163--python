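"""Binarization, binary distance, Ward clustering, enrichment, correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from sctam.matrix import CountMatrix
from sctam.methylation import (
    BinaryMethylationMatrix,
    binarize,
    binary_distance,
    binary_distance_matrix,
    cluster_cells,
    cluster_cpgs,
    cluster_mean_methylation,
    fisher_state_enrichment,
    meth_expression_correlation,
    ward_cluster,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def ward_d2_oracle(dist: np.ndarray):
    """Exhaustive Ward (ward.D2) agglomeration via the Lance-Williams
    recurrence on squared dissimilarities.

    Returns (merge list [(i, j, height, size)], per-step membership sets,
    had_tie).  ``had_tie`` reports whether any merge decision was ambiguous
    (two candidate pairs at the same minimum cost) — on such inputs the Ward
    tree is not unique and tie-breaking is implementation-defined.
    """
    n = dist.shape[0]
    d2 = dist.astype(float) ** 2
    active = {i: {i} for i in range(n)}
    d2 = {(i, j): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    partitions = [frozenset(frozenset(s) for s in active.values())]
    next_id = n
    had_tie = False
    while len(active) > 1:
        (i, j), best = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        runners = sorted(v for v in d2.values() if v > best)
        if (sum(1 for v in d2.values() if abs(v - best) < 1e-12) > 1
                or (runners and runners[0] - best < 1e-12)):
            had_tie = True
        ni, nj = len(active[i]), len(active[j])
        merges.append((i, j, math.sqrt(best), ni + nj))
        merged = active.pop(i) | active.pop(j)
        for k in list(active):
            nk = len(active[k])
            dik = d2.pop((min(i, k), max(i, k)))
            djk = d2.pop((min(j, k), max(j, k)))
            dij = best
            new = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
            d2[(min(k, next_id), max(k, next_id))] = new
        del d2[(i, j)]
        active[next_id] = merged
        next_id += 1
        partitions.append(frozenset(frozenset(s) for s in active.values()))
    return merges, partitions, had_tie


def random_binary_matrix(rng, n_rows, n_cols):
    x = rng.random((n_rows, n_cols)) < rng.uniform(0.2, 0.8)
    while not x.any(axis=1).all():
        x = rng.random((n_rows, n_cols)) < rng.uniform(0.2, 0.8)
    return x.astype(np.int8)


def decision_tie_free_case(rng, n_rows, n_cols):
    """Random binary matrix on which the Ward tree is unique (no tied merge
    decision in the exhaustive agglomeration); regenerated otherwise."""
    for _ in range(500):
        x = random_binary_matrix(rng, n_rows, n_cols)
        d = squareform(pdist(x, metric="jaccard"))
        merges, partitions, had_tie = ward_d2_oracle(d)
        if not had_tie:
            return x, d, merges, partitions
    raise RuntimeError("could not build a decision-tie-free instance")


def hypergeom_fisher_oracle(table):
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

class TestBinarize:
    def test_threshold_at_one_read(self, toy_counts):
        b = binarize(toy_counts)
        assert b.calls.loc["b1"].tolist() == [1, 0, 1]
        assert b.calls.loc["b2"].tolist() == [0, 0, 0]

    def test_unknown_amplicon_rejected(self, toy_counts):
        with pytest.raises(ValueError):
            binarize(toy_counts, ["nope"])

    def test_matches_truth_when_noise_free(self, small_panel):
        """With zero dropout and zero digestion failure, binarized digested
        counts equal the true methylation states exactly."""
        from sctam.simulate import SimConfig, simulate_experiment

        profiles, classes = small_panel
        cfg = SimConfig(n_cells={"typeA": 50, "typeB": 50, "typeC": 0},
                        cell_type_profiles=profiles, amplicon_classes=classes,
                        dropout=pd.Series(0.0, index=profiles.index),
                        digestion_fpr=0.0, seed=50)
        dig, _, truth = simulate_experiment(cfg)
        b = binarize(dig)
        hha = classes.index[classes != "non_hha"]
        assert b.calls[hha].equals(truth.methylation[hha].astype(np.int8))

    def test_nonbinary_matrix_rejected(self):
        with pytest.raises(ValueError):
            BinaryMethylationMatrix(pd.DataFrame([[0, 2]]))


# ---------------------------------------------------------------------------
# binary distance
# ---------------------------------------------------------------------------

class TestBinaryDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ([1, 0, 1], [1, 0, 1], 0.0),
        ([1, 0, 0], [0, 1, 0], 1.0),      # 2 discordant / 2 in union
        ([1, 1, 0], [1, 0, 0], 0.5),      # 1 discordant / 2 in union
        ([0, 0, 0], [0, 0, 0], 0.0),      # empty union -> 0 by convention
    ])
    def test_examples(self, a, b, expected):
        assert binary_distance(a, b) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            binary_distance([1, 0], [1, 0, 1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(1, 30), st.integers(0, 2 ** 30 - 1), st.integers(0, 2 ** 30 - 1))
    def test_properties(self, n, abits, bbits):
        a = [(abits >> i) & 1 for i in range(n)]
        b = [(bbits >> i) & 1 for i in range(n)]
        d = binary_distance(a, b)
        assert 0.0 <= d <= 1.0
        assert d == binary_distance(b, a)
        joint = [i for i in range(n) if a[i] or b[i]]
        agrees = all(a[i] == b[i] for i in joint)
        assert (d == 0.0) == agrees

    def test_matrix_matches_scipy_jaccard(self):
        rng = np.random.default_rng(51)
        x = (rng.random((20, 15)) < 0.5).astype(np.int8)
        x[0] = 0  # include an all-zero row to exercise the 0/0 convention
        m = BinaryMethylationMatrix(pd.DataFrame(x))
        ours = binary_distance_matrix(m)
        ref = pdist(x.astype(bool), metric="jaccard")
        assert np.allclose(ours, ref)


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

class TestWardCluster:
    def test_k_equals_n_singletons(self):
        rng = np.random.default_rng(52)
        x = random_binary_matrix(rng, 6, 25)
        d = squareform(pdist(x, metric="jaccard"))
        assign = ward_cluster(d, k=6)
        assert sorted(assign.labels) == [1, 2, 3, 4, 5, 6]

    def test_two_block_structure(self):
        block_a = np.tile([1, 1, 1, 1, 0, 0, 0, 0], (5, 1))
        block_b = np.tile([0, 0, 0, 0, 1, 1, 1, 1], (5, 1))
        rng = np.random.default_rng(53)
        x = np.vstack([block_a, block_b])
        flip = rng.random(x.shape) < 0.05
        x = np.where(flip, 1 - x, x)
        assign = ward_cluster(squareform(pdist(x.astype(bool), "jaccard")), k=2)
        labels = assign.labels.to_numpy()
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[-1]

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(54)
        x = random_binary_matrix(rng, 9, 30)
        assign = ward_cluster(squareform(pdist(x.astype(bool), "jaccard")), k=3)
        heights = assign.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ward_cluster(np.array([[0.0, 1.0], [0.5, 0.0]]), 1)  # asymmetric
        with pytest.raises(ValueError):
            ward_cluster(np.array([[0.0, 1.0], [1.0, 0.0]]), 3)  # k > n

    def test_agrees_with_exhaustive_oracle(self):
        """Heights and all k-partitions match brute-force ward.D2 agglomeration
        on tie-free random binary matrices, n <= 10."""
        rng = np.random.default_rng(55)
        for _ in range(30):
            n = int(rng.integers(4, 11))
            x, d, merges, partitions = decision_tie_free_case(rng, n, 32)
            oracle_heights = [m[2] for m in merges]
            for k in range(1, n + 1):
                assign = ward_cluster(d, k)
                got = frozenset(
                    frozenset(assign.labels.index[assign.labels == c])
                    for c in range(1, k + 1) if (assign.labels == c).any()
                )
                assert got == partitions[n - k], f"partition mismatch at n={n}, k={k}"
            assert np.allclose(np.sort(assign.linkage[:, 2]), np.sort(oracle_heights))


class TestClusterCpgs:
    def test_transpose_symmetry(self, small_experiment):
        _, dig, _, _ = small_experiment
        b = binarize(dig.subset_barcodes(dig.barcodes[:40]))
        assign = cluster_cpgs(b, k=3)
        t = BinaryMethylationMatrix(b.calls.T)
        direct = ward_cluster(binary_distance_matrix(t), 3)
        assert list(assign.labels) == list(direct.labels)

    def test_planted_amplicon_blocks(self):
        rng = np.random.default_rng(56)
        cells = 60
        col_a = rng.random((cells, 1)) < 0.9
        col_b = rng.random((cells, 1)) < 0.1
        x = np.hstack([np.tile(col_a, (1, 6)), np.tile(col_b, (1, 6))])
        flip = rng.random(x.shape) < 0.03
        x = np.where(flip, ~x, x).astype(np.int8)
        m = BinaryMethylationMatrix(
            pd.DataFrame(x, columns=[f"amp{i}" for i in range(12)]))
        labels = cluster_cpgs(m, 2).labels
        assert labels.iloc[:6].nunique() == 1 and labels.iloc[6:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_k1_single_cluster(self):
        m = BinaryMethylationMatrix(pd.DataFrame(np.eye(4, dtype=int)))
        assert set(cluster_cpgs(m, 1).labels) == {1}


class TestClusterMeans:
    def _toy(self):
        calls = pd.DataFrame(
            [[1, 1, 0], [1, 0, 0], [0, 1, 1], [0, 0, 1]],
            index=list("wxyz"), columns=["p", "q", "r"])
        m = BinaryMethylationMatrix(calls)
        cells = cluster_cells(m, 1)
        cells.labels[:] = [1, 1, 2, 2]
        cells.k = 2
        cpgs = cluster_cpgs(m, 1)
        cpgs.labels[:] = [1, 1, 2]
        cpgs.k = 2
        return m, cells, cpgs

    def test_block_means_by_hand(self):
        m, cells, cpgs = self._toy()
        out = cluster_mean_methylation(m, cells, cpgs).set_index(
            ["cell_cluster", "cpg_cluster"])
        # block (1, 1): cells w,x on p,q -> 3 of 4 ones
        assert out.loc[(1, 1), "mean"] == pytest.approx(0.75)
        # SE uses the number of cells (2), not calls (4)
        assert out.loc[(1, 1), "se"] == pytest.approx(math.sqrt(0.75 * 0.25 / 2))
        assert out.loc[(2, 2), "mean"] == pytest.approx(1.0)
        assert out.loc[(2, 2), "se"] == 0.0

    def test_permutation_invariance(self):
        m, cells, cpgs = self._toy()
        base = cluster_mean_methylation(m, cells, cpgs)
        perm = BinaryMethylationMatrix(m.calls.iloc[::-1, ::-1])
        out = cluster_mean_methylation(perm, cells, cpgs)
        merged = base.merge(out, on=["cell_cluster", "cpg_cluster"])
        assert np.allclose(merged["mean_x"], merged["mean_y"])


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

class TestFisherEnrichment:
    def _run(self, a, b, c, d):
        cluster = [f"i{k}" for k in range(a)] + [f"j{k}" for k in range(b)]
        rest = [f"k{k}" for k in range(c)] + [f"l{k}" for k in range(d)]
        states = pd.Series(
            {**{f"i{k}": "S" for k in range(a)}, **{f"j{k}": "O" for k in range(b)},
             **{f"k{k}": "S" for k in range(c)}, **{f"l{k}": "O" for k in range(d)}})
        return fisher_state_enrichment(cluster, cluster + rest, states, "S")

    def test_worked_table_3113(self):
        res = self._run(3, 1, 1, 3)
        assert res["p_value"] == pytest.approx(34 / 70)
        assert res["odds_ratio"] == pytest.approx(9.0)

    def test_perfect_separation(self):
        res = self._run(10, 0, 0, 10)
        assert res["p_value"] == pytest.approx(2 / math.comb(20, 10))

    def test_cluster_equals_background(self):
        states = pd.Series({"a": "S", "b": "O"})
        res = fisher_state_enrichment(["a", "b"], ["a", "b"], states, "S")
        assert res["p_value"] == 1.0 and res["degenerate"]

    def test_cluster_not_subset_rejected(self):
        with pytest.raises(ValueError):
            fisher_state_enrichment(["a"], ["b"], pd.Series({"a": "S", "b": "S"}), "S")

    def test_matches_enumeration_for_random_tables(self):
        rng = np.random.default_rng(57)
        for _ in range(60):
            a, b, c, d = (int(v) for v in rng.integers(0, 16, 4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            res = self._run(a, b, c, d)
            assert res["p_value"] == pytest.approx(
                hypergeom_fisher_oracle([[a, b], [c, d]]), rel=1e-9)


# ---------------------------------------------------------------------------
# methylation-expression correlation
# ---------------------------------------------------------------------------

class TestMethExpressionCorrelation:
    def _coords(self):
        gene_coords = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr2"], "start": [10_000, 60_000, 5_000],
             "end": [12_000, 62_000, 6_000]}, index=["near", "far", "other_chrom"])
        cpg_coords = pd.DataFrame({"chrom": ["chr1"], "pos": [20_000]}, index=["cpgA"])
        return gene_coords, cpg_coords

    def test_perfect_anticorrelation_and_window(self):
        gene_coords, cpg_coords = self._coords()
        meth = pd.DataFrame([[0.1, 0.5, 0.9]], index=["cpgA"], columns=list("abc"))
        expr = pd.DataFrame([[0.9, 0.5, 0.1], [1, 2, 3], [5, 5, 6]],
                            index=["near", "far", "other_chrom"], columns=list("abc"))
        out = meth_expression_correlation(meth, expr, gene_coords, cpg_coords)
        # "far" (40 kb) and "other_chrom" excluded by the 25-kb same-chromosome rule
        assert out["gene"].tolist() == ["near"]
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_r_matches_closed_form(self):
        gene_coords, cpg_coords = self._coords()
        m = np.array([0.1, 0.3, 0.2, 0.8, 0.6])
        e = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        meth = pd.DataFrame([m], index=["cpgA"], columns=list("abcde"))
        expr = pd.DataFrame([e], index=["near"], columns=list("abcde"))
        out = meth_expression_correlation(meth, expr, gene_coords, cpg_coords)
        expect = np.cov(m, e, ddof=1)[0, 1] / (np.std(m, ddof=1) * np.std(e, ddof=1))
        assert out["r"].iloc[0] == pytest.approx(expect)

    def test_too_few_clusters_rejected(self):
        gene_coords, cpg_coords = self._coords()
        meth = pd.DataFrame([[0.1, 0.9]], index=["cpgA"], columns=list("ab"))
        expr = pd.DataFrame([[1.0, 2.0]], index=["near"], columns=list("ab"))
        with pytest.raises(ValueError):
            meth_expression_correlation(meth, expr, gene_coords, cpg_coords)


# ---------------------------------------------------------------------------
# end-to-end cluster recovery
# ---------------------------------------------------------------------------

def test_cluster_recovery_on_simulated_cells(small_experiment):
    """Standard path: restrict to high-performance (FNR < 0.25) amplicons from
    the undigested control, binarize the digested counts, Ward-cluster."""
    from sklearn.metrics import adjusted_rand_score

    from sctam.error_model import estimate_fnr, select_high_performance

    cfg, dig, undig, truth = small_experiment
    real = truth.barcode_table.index[~truth.barcode_table["is_empty"]
                                     & ~truth.barcode_table["is_doublet"]]
    fnr = estimate_fnr(undig.subset_barcodes(list(real)), cfg.amplicon_classes)
    keep = select_high_performance(fnr, max_fnr=0.25)
    binary = binarize(dig.subset_barcodes(list(real)), keep)
    assign = cluster_cells(binary, 3)
    ari = adjusted_rand_score(truth.barcode_table.loc[real, "cell_type"],
                              assign.labels)
    assert ari >= 0.9
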