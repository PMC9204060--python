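import numpy as np
import pandas as pd
import pytest

import cernaforge as cf
from cernaforge.coexpr_modules import (
    GREY,
    detect_modules,
    eigengene,
    module_trait,
    soft_adjacency,
    tom_similarity,
    variance_prefilter,
)
from cernaforge.synthetic_data import design_metadata
from oracles import naive_tom


def expr_matrix(values, gene_ids=None, meta=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i:03d}" for i in range(values.shape[0])]
    meta = meta if meta is not None else design_metadata()
    frame = pd.DataFrame(values, index=gene_ids, columns=meta.index[: values.shape[1]])
    return cf.ExpressionMatrix(
        values=frame, metadata=meta, unit="FPKM"
    )


def two_block_matrix(seed=0, n_noise=20, block=60, loading=0.5, sd=0.15):
    """Two orthogonal 60-gene blocks plus a few unstructured genes."""
    rng = np.random.default_rng(seed)
    meta = design_metadata()
    n_s = len(meta)
    f1 = rng.normal(size=n_s)
    f2 = rng.normal(size=n_s)
    f2 -= f2 @ f1 / (f1 @ f1) * f1
    f1 /= f1.std()
    f2 /= f2.std()
    rows, ids, truth = [], [], {}
    for b, f in (("block1", f1), ("block2", f2)):
        for i in range(block):
            gid = f"{b}_{i:02d}"
            rows.append(5.0 + loading * f + rng.normal(0, sd, n_s))
            ids.append(gid)
            truth[gid] = b
    for i in range(n_noise):
        rows.append(5.0 + rng.normal(0, sd, n_s))
        ids.append(f"noise_{i:02d}")
    values = 2.0 ** np.array(rows)
    return expr_matrix(values, ids, meta), truth


class TestPrefilter:
    def test_zero_drop_is_identity(self, small_study):
        out = variance_prefilter(small_study.mrna_expr, 0.0)
        pd.testing.assert_frame_equal(out.values, small_study.mrna_expr.values)

    def test_drop_fraction_counts(self):
        rng = np.random.default_rng(1)
        m = expr_matrix(rng.uniform(1, 100, size=(100, 18)))
        assert variance_prefilter(m, 0.45).values.shape[0] == 55

    def test_retained_set_matches_variance_ranking(self):
        rng = np.random.default_rng(2)
        m = expr_matrix(rng.uniform(1, 100, size=(40, 18)))
        kept = set(variance_prefilter(m, 0.3).values.index)
        var = np.log2(m.values + 1.0).var(axis=1, ddof=1)
        expected = set(var.sort_values(kind="stable").index[12:])
        # deterministic tie-break by gene id; continuous data has no ties
        assert kept == expected

    def test_constant_matrix_rejected(self):
        m = expr_matrix(np.ones((5, 18)))
        with pytest.raises(ValueError):
            variance_prefilter(m, 0.5)


class TestAdjacency:
    def test_power_of_correlation(self):
        # adjacency is |r|^beta for whatever r the pair has
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])  # r = 0.8 with x
        meta = design_metadata().iloc[:4]
        m = expr_matrix(np.vstack([x, y]), ["a", "b"], meta)
        r = cf.pearson(x, y)
        adj = soft_adjacency(m, beta=8)
        assert adj.loc["a", "b"] == pytest.approx(abs(r) ** 8)

    def test_perfect_pair_stays_one(self):
        meta = design_metadata().iloc[:5]
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = expr_matrix(np.vstack([x, 3 * x]), ["a", "b"], meta)
        for beta in (1, 8, 20):
            assert soft_adjacency(m, beta).loc["a", "b"] == pytest.approx(1.0)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(3)
        m = expr_matrix(rng.uniform(1, 50, size=(50, 18)))
        adj = soft_adjacency(m, beta=8).to_numpy()
        assert np.allclose(adj, adj.T)
        assert ((adj >= 0) & (adj <= 1)).all()
        assert np.allclose(np.diag(adj), 1.0)


class TestTom:
    def test_two_gene_network(self):
        adj = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=list("ab"), columns=list("ab"))
        assert tom_similarity(adj).loc["a", "b"] == pytest.approx(1.0)

    def test_three_gene_hand_value(self):
        adj = pd.DataFrame(
            0.5 * (np.ones((3, 3)) - np.eye(3)) + np.eye(3),
            index=list("abc"), columns=list("abc"),
        )
        assert tom_similarity(adj).loc["a", "b"] == pytest.approx(0.75 / 1.5)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 1, size=(30, 30))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=[f"g{i}" for i in range(30)],
                           columns=[f"g{i}" for i in range(30)])
        expected = np.array(naive_tom(a.tolist()))
        assert np.allclose(tom_similarity(adj).to_numpy(), expected, atol=1e-9)

    def test_identical_indicator_profiles_give_unit_overlap(self):
        # holds when the shared profiles are 0/1-valued (a^2 = a)
        for shared in (0.0, 1.0):
            a = np.array([
                [1.0, 1.0, shared],
                [1.0, 1.0, shared],
                [shared, shared, 1.0],
            ])
            adj = pd.DataFrame(a, index=list("abc"), columns=list("abc"))
            assert tom_similarity(adj).loc["a", "b"] == pytest.approx(1.0)


class TestModules:
    def test_two_planted_blocks_recovered(self):
        m, truth = two_block_matrix(seed=5)
        tom = tom_similarity(soft_adjacency(m, beta=8))
        mods = detect_modules(tom, m, min_size=50, merge_cut=0.85)
        non_grey = [x for x in mods if x.label != GREY]
        assert len(non_grey) == 2
        for block in ("block1", "block2"):
            members = {g for g in truth if truth[g] == block}
            best = max(len(members & set(x.genes)) for x in non_grey)
            assert best >= 0.95 * len(members)

    def test_min_size_larger_than_clusters_gives_grey(self):
        m, _ = two_block_matrix(seed=6)
        tom = tom_similarity(soft_adjacency(m, beta=8))
        mods = detect_modules(tom, m, min_size=200, merge_cut=0.85)
        assert [x.label for x in mods] == [GREY]
        assert sum(len(x.genes) for x in mods) == 140

    def test_gene_order_permutation_invariant(self):
        m, _ = two_block_matrix(seed=7)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.values.index)
        m2 = cf.ExpressionMatrix(
            values=m.values.loc[perm], metadata=m.metadata, unit=m.unit
        )
        mods1 = detect_modules(tom_similarity(soft_adjacency(m, 8)), m, 50, 0.85)
        mods2 = detect_modules(tom_similarity(soft_adjacency(m2, 8)), m2, 50, 0.85)
        sets1 = sorted((frozenset(x.genes) for x in mods1), key=sorted)
        sets2 = sorted((frozenset(x.genes) for x in mods2), key=sorted)
        assert sets1 == sets2


class TestEigengene:
    def test_perfectly_correlated_module(self):
        meta = design_metadata().iloc[:6]
        x = np.array([1.0, 4.0, 2.0, 6.0, 3.0, 5.0])
        m = expr_matrix(np.vstack([x, 2 * x, 0.5 * x]), ["a", "b", "c"], meta)
        eg = eigengene(m, ("a", "b", "c"))
        assert abs(cf.pearson(eg.to_numpy(), x)) == pytest.approx(1.0)

    def test_sign_follows_mean_profile(self):
        m, _ = two_block_matrix(seed=8)
        genes = tuple(g for g in m.values.index if g.startswith("block1"))
        eg = eigengene(m, genes)
        profile = np.log2(m.values.loc[list(genes)]).mean(axis=0)
        assert cf.pearson(eg.to_numpy(), profile.to_numpy()) > 0


class TestModuleTrait:
    def test_planted_trait_association_recovered(self, small_result):
        table = small_result.module_trait
        # block 1 follows the senescence score: highest in mutant 2nd/3rd leaf
        row = table[table["module"] == small_result.senescence_module]
        best = row.loc[row["r"].idxmax(), "trait"]
        assert best in ("mutant_second", "mutant_third")

    def test_entries_bounded(self, small_result):
        r = small_result.module_trait["r"].dropna()
        assert ((r >= -1) & (r <= 1)).all()

    def test_null_eigengene_weak_association(self):
        rng = np.random.default_rng(9)
        meta = design_metadata()
        rs = []
        for _ in range(30):
            module = cf.CoexprModule(
                label="x", genes=("g",),
                eigengene=pd.Series(rng.normal(size=18), index=meta.index),
            )
            tab = module_trait([module], meta)
            rs.append(tab["r"].abs().mean())
        assert np.mean(rs) < 0.35
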