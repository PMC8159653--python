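import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from netprox.comodules import (
    ModuleConfig,
    adjacency_matrix,
    assemble_gw,
    detect_modules,
    module_eigengene,
    module_trait_correlation,
    select_soft_threshold,
    tom_similarity,
)
from netprox.diffexpr import ExpressionMatrix
from netprox.genesets import GeneSet
from netprox.synthdata import SynthConfig, gen_coexpression, gen_expression


def expr_from_array(x: np.ndarray, n_normal: int) -> ExpressionMatrix:
    genes = [f"G{i:03d}" for i in range(x.shape[0])]
    samples = [f"S{j}" for j in range(x.shape[1])]
    phen = pd.Series(
        ["normal"] * n_normal + ["disease"] * (x.shape[1] - n_normal),
        index=samples,
    )
    return ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples), phen)


def block_matrix(n_blocks, block_size, n_samples, rng, corr=1.0, noise=0.0):
    """Planted blocks sharing a latent factor; corr=1 means identical rows."""
    rows = []
    for _ in range(n_blocks):
        latent = rng.standard_normal(n_samples)
        for _ in range(block_size):
            eps = rng.standard_normal(n_samples)
            rows.append(np.sqrt(corr) * latent + np.sqrt(1 - corr) * eps
                        + noise * rng.standard_normal(n_samples))
    return np.asarray(rows) + 8.0


class TestTOM:
    def test_two_genes_full_adjacency(self):
        adj = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=list("ab"),
                           columns=list("ab"))
        tom = tom_similarity(adj)
        assert tom.loc["a", "b"] == pytest.approx(1.0)

    def test_disconnected_pair_zero(self):
        adj = pd.DataFrame(np.zeros((3, 3)), index=list("abc"),
                           columns=list("abc"))
        assert tom_similarity(adj).loc["a", "b"] == 0.0

    def test_uniform_triangle_by_hand(self):
        # (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        adj = pd.DataFrame(0.5 * (1 - np.eye(3)), index=list("abc"),
                           columns=list("abc"))
        assert tom_similarity(adj).loc["a", "b"] == pytest.approx(0.5)

    def test_asymmetric_input_rejected(self):
        adj = pd.DataFrame([[0.0, 0.4], [0.5, 0.0]], index=list("ab"),
                           columns=list("ab"))
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(adj)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        a = rng.random((n, n)) * 0.9
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        labels = [f"g{i}" for i in range(n)]
        adj = pd.DataFrame(a, index=labels, columns=labels)
        tom = tom_similarity(adj).to_numpy()
        k = a.sum(axis=1)
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(n))
                expect = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expect)
        assert tom.min() >= 0 and tom.max() <= 1


class TestDetectModules:
    def test_two_perfect_blocks_two_modules(self):
        rng = np.random.default_rng(0)
        mat = expr_from_array(block_matrix(2, 60, 40, rng, corr=1.0), 20)
        tom = tom_similarity(adjacency_matrix(mat, 6))
        assign = detect_modules(tom, ModuleConfig(beta=6), mat=mat)
        sizes = assign.labels.value_counts()
        assert sorted(sizes[sizes.index != "grey"]) == [60, 60]

    def test_small_block_goes_grey(self):
        rng = np.random.default_rng(1)
        mat = expr_from_array(block_matrix(1, 10, 40, rng, corr=1.0), 20)
        tom = tom_similarity(adjacency_matrix(mat, 6))
        assign = detect_modules(tom, ModuleConfig(beta=6, min_module_size=50))
        assert (assign.labels == "grey").all()
        assert assign.modules() == {}

    def test_single_latent_factor_single_module(self):
        rng = np.random.default_rng(2)
        mat = expr_from_array(block_matrix(1, 60, 40, rng, corr=0.95), 20)
        tom = tom_similarity(adjacency_matrix(mat, 6))
        assign = detect_modules(tom, ModuleConfig(beta=6), mat=mat)
        assert set(assign.labels.unique()) == {"module1"}

    def test_planted_block_recovery_ari(self):
        cfg = SynthConfig(seed=1, n_samples_per_group=50)
        mat, truth = gen_expression(cfg)
        beta = select_soft_threshold(mat)
        tom = tom_similarity(adjacency_matrix(mat, beta))
        assign = detect_modules(tom, ModuleConfig(beta=beta), mat=mat)
        planted = truth["module_membership"].set_index("gene")["module"]
        ari = adjusted_rand_score(
            planted.values, assign.labels.loc[planted.index].values
        )
        assert ari >= 0.9


class TestSoftThreshold:
    def test_vacuous_target_returns_smallest(self):
        mat, _ = gen_expression(SynthConfig(seed=3, n_genes=200))
        assert select_soft_threshold(mat, candidates=[3, 5, 7],
                                     rsq_target=0.0) == 3

    def test_single_candidate_returned(self):
        mat, _ = gen_expression(SynthConfig(seed=3, n_genes=200))
        assert select_soft_threshold(mat, candidates=[6]) == 6

    def test_constant_matrix_is_error(self):
        x = np.full((20, 10), 3.0)
        mat = expr_from_array(x, 5)
        with pytest.raises(ValueError):
            select_soft_threshold(mat)

    def test_scale_free_benchmark_crossing(self):
        # generator built so the fit crosses 0.85 at a known power (seed 1)
        cmat, _ = gen_coexpression(SynthConfig(seed=1))
        assert select_soft_threshold(cmat) == 4


class TestEigengeneAndTrait:
    def test_eigengene_tracks_phenotype_perfectly(self):
        phen01 = np.array([0.0] * 10 + [1.0] * 10)
        x = np.tile(phen01, (60, 1)) + 8.0
        # tiny jitter so per-gene variance is nonzero but structure is exact
        rng = np.random.default_rng(0)
        x = x + 1e-6 * rng.standard_normal(x.shape)
        mat = expr_from_array(x, 10)
        assign = detect_modules(
            tom_similarity(adjacency_matrix(mat, 2)), ModuleConfig(beta=2),
            mat=mat,
        )
        trait = module_trait_correlation(assign, mat)
        assert abs(trait.loc[0, "r"]) == pytest.approx(1.0, abs=1e-6)

    def test_planted_trait_module_positive_and_significant(self):
        mat, truth = gen_expression(SynthConfig(seed=1, n_samples_per_group=50))
        beta = select_soft_threshold(mat)
        assign = detect_modules(
            tom_similarity(adjacency_matrix(mat, beta)),
            ModuleConfig(beta=beta), mat=mat,
        )
        trait = module_trait_correlation(assign, mat)
        linked_genes = set(
            truth["module_membership"]
            .query("trait_linked")["gene"]
        )
        # find the detected module carrying the planted trait-linked block
        overlaps = {
            m: len(genes.members & linked_genes)
            for m, genes in assign.modules().items()
        }
        linked_module = max(overlaps, key=overlaps.get)
        row = trait.set_index("module").loc[linked_module]
        assert row["r"] > 0 and row["p"] < 0.01

    def test_null_module_correlation_stays_moderate(self):
        # independent-noise modules: |r| < 0.5 in at least 95% of replicates
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            eig = rng.standard_normal(40)
            phen = np.array([0.0] * 20 + [1.0] * 20)
            r = np.corrcoef(eig, phen)[0, 1]
            hits += abs(r) < 0.5
        assert hits / n_rep >= 0.95

    def test_eigengene_variance_optimality(self):
        rng = np.random.default_rng(9)
        mat = expr_from_array(block_matrix(1, 30, 50, rng, corr=0.7), 25)
        genes = GeneSet.from_symbols("m", mat.values.index)
        eig = module_eigengene(mat, genes).to_numpy()
        x = mat.values.to_numpy()
        xs = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        var_eig = float(((xs @ eig) ** 2).sum())
        for row in xs:  # projection onto any single gene profile explains less
            u = row / np.linalg.norm(row)
            assert var_eig >= float(((xs @ u) ** 2).sum()) - 1e-8

    def test_undersized_module_is_error(self):
        mat, _ = gen_expression(SynthConfig(seed=3, n_genes=300))
        with pytest.raises(ValueError):
            module_eigengene(mat, GeneSet.from_symbols("m", ["G0000"]))


class TestAssembleGW:
    def test_positive_and_negative_intersections(self):
        got = assemble_gw(
            GeneSet.from_symbols("p1", ["A", "B"]),
            GeneSet.from_symbols("p2", ["B", "C"]),
            GeneSet.from_symbols("n1", ["D"]),
            GeneSet.from_symbols("n2", ["D", "E"]),
        )
        assert got.members == frozenset({"B", "D"})
        assert got.provenance == "G_W"

    def test_all_empty(self):
        e = GeneSet.from_symbols("e", [])
        assert assemble_gw(e, e, e, e).members == frozenset()

    def test_overlap_deduplicated(self):
        s = GeneSet.from_symbols("s", ["X"])
        assert assemble_gw(s, s, s, s).members == frozenset({"X"})
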