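import numpy as np
import pandas as pd
import pytest

import cernaforge as cf
from cernaforge.cerna_network import (
    assemble_triplets,
    build_graph,
    export_network,
    filter_pairs,
    triplet_table,
)
from cernaforge.pipeline import recovery_report
from cernaforge.synthetic_data import design_metadata
from oracles import naive_triplets


def toy_matrices(seed=0, n_lnc=20, n_mir=5, n_mrna=20):
    """Random expression for a brute-force comparison instance."""
    rng = np.random.default_rng(seed)
    meta = design_metadata()
    z = np.repeat([0.0, 0.5, 1.0, 0.5, 2.5, 3.5], 3)

    def mk(prefix, n, sign):
        ids = [f"{prefix}{i}" for i in range(n)]
        vals = 2.0 ** (
            5.0 + sign * z[None, :] * rng.integers(0, 2, n)[:, None]
            + rng.normal(0, 0.3, (n, 18))
        )
        return cf.ExpressionMatrix(
            values=pd.DataFrame(vals, index=ids, columns=meta.index),
            metadata=meta, unit="FPKM",
        )

    return mk("l", n_lnc, +1), mk("m", n_mir, -1), mk("g", n_mrna, +1)


class TestFilterPairs:
    def _setup(self, scc_values):
        """One miRNA against targets with prescribed Spearman values."""
        meta = design_metadata()
        n = len(meta)
        base = np.arange(n, dtype=float)
        mir = cf.ExpressionMatrix(
            values=pd.DataFrame([base + 1], index=["m0"], columns=meta.index),
            metadata=meta, unit="TPM",
        )
        rows, ids = [], []
        for i, rho in enumerate(scc_values):
            ids.append(f"g{i}")
            if rho == -1.0:
                rows.append(n - base)
            elif rho == 1.0:
                rows.append(base + 2)
            else:  # partial anticorrelation via partial reversal
                k = int(round((1 - abs(rho)) * n))
                v = (n - base).copy()
                v[:k] = v[:k][::-1]
                rows.append(v)
        target = cf.ExpressionMatrix(
            values=pd.DataFrame(np.array(rows) + 1, index=ids, columns=meta.index),
            metadata=meta, unit="FPKM",
        )
        hits = pd.DataFrame({"mirna": ["m0"] * len(ids), "transcript": ids})
        return hits, mir, target, set(ids)

    def test_anticorrelation_threshold(self):
        hits, mir, target, de = self._setup([-1.0, 1.0])
        out = filter_pairs(hits, mir, target, {"m0"}, de, scc_threshold=-0.7)
        assert list(out["target"]) == ["g0"]

    def test_threshold_is_strict(self):
        """A pair sitting exactly on the cutoff is dropped, not kept."""
        hits, mir, target, de = self._setup([-0.8])
        rho = cf.spearman(
            mir.values.loc["m0"].to_numpy(), target.values.loc["g0"].to_numpy()
        )
        at_cutoff = filter_pairs(hits, mir, target, {"m0"}, de, scc_threshold=rho)
        assert at_cutoff.empty
        just_above = filter_pairs(
            hits, mir, target, {"m0"}, de, scc_threshold=rho + 1e-9
        )
        assert list(just_above["target"]) == ["g0"]

    def test_non_de_members_excluded(self):
        hits, mir, target, de = self._setup([-1.0, -1.0])
        out = filter_pairs(hits, mir, target, {"m0"}, {"g1"}, scc_threshold=-0.7)
        assert list(out["target"]) == ["g1"]
        out2 = filter_pairs(hits, mir, target, set(), de, scc_threshold=-0.7)
        assert out2.empty

    def test_constant_profile_dropped(self):
        meta = design_metadata()
        mir = cf.ExpressionMatrix(
            values=pd.DataFrame(
                [np.arange(18, dtype=float)], index=["m0"], columns=meta.index
            ),
            metadata=meta, unit="TPM",
        )
        target = cf.ExpressionMatrix(
            values=pd.DataFrame([np.ones(18)], index=["g0"], columns=meta.index),
            metadata=meta, unit="FPKM",
        )
        hits = pd.DataFrame({"mirna": ["m0"], "transcript": ["g0"]})
        out = filter_pairs(hits, mir, target, {"m0"}, {"g0"})
        assert out.empty

    def test_sample_mismatch_rejected(self):
        hits, mir, target, de = self._setup([-1.0])
        shuffled = cf.ExpressionMatrix(
            values=target.values.iloc[:, ::-1],
            metadata=target.metadata, unit="FPKM",
        )
        with pytest.raises(ValueError, match="sample"):
            filter_pairs(hits, mir, shuffled, {"m0"}, de)


class TestAssembleTriplets:
    def test_shared_mirna_required(self):
        lnc, mir, mrna = toy_matrices(1)
        mm = pd.DataFrame({"mirna": ["m0"], "target": ["g0"], "scc": [-0.9]})
        ml = pd.DataFrame({"mirna": ["m1"], "target": ["l0"], "scc": [-0.9]})
        assert assemble_triplets(mm, ml, lnc, mrna, pcc_threshold=-1.0) == []

    def test_matches_bruteforce_triple_loop(self):
        lnc, mir, mrna = toy_matrices(2)
        rng = np.random.default_rng(3)
        mm = pd.DataFrame(
            {
                "mirna": [f"m{rng.integers(0, 5)}" for _ in range(15)],
                "target": [f"g{rng.integers(0, 20)}" for _ in range(15)],
                "scc": -0.9,
            }
        ).drop_duplicates(["mirna", "target"])
        ml = pd.DataFrame(
            {
                "mirna": [f"m{rng.integers(0, 5)}" for _ in range(15)],
                "target": [f"l{rng.integers(0, 20)}" for _ in range(15)],
                "scc": -0.9,
            }
        ).drop_duplicates(["mirna", "target"])
        got = assemble_triplets(mm, ml, lnc, mrna, pcc_threshold=0.9)
        pcc = {
            (l, g): cf.pearson(lnc.values.loc[l], mrna.values.loc[g])
            for l in lnc.values.index
            for g in mrna.values.index
        }
        expected = naive_triplets(
            list(mm[["mirna", "target"]].itertuples(index=False, name=None)),
            list(ml[["mirna", "target"]].itertuples(index=False, name=None)),
            pcc, 0.9,
        )
        assert {(t.lncrna, t.mirna, t.mrna) for t in got} == expected
        assert len(got) > 0

    def test_module_filter_applies_to_mrna(self):
        lnc, mir, mrna = toy_matrices(4)
        mm = pd.DataFrame({"mirna": ["m0", "m0"], "target": ["g0", "g1"], "scc": -0.9})
        ml = pd.DataFrame({"mirna": ["m0"], "target": ["l0"], "scc": -0.9})
        all_t = assemble_triplets(mm, ml, lnc, mrna, pcc_threshold=-1.0)
        only_g0 = assemble_triplets(
            mm, ml, lnc, mrna, pcc_threshold=-1.0, module_genes={"g0"}
        )
        assert {t.mrna for t in all_t} == {"g0", "g1"}
        assert {t.mrna for t in only_g0} == {"g0"}

    def test_relaxing_thresholds_is_monotone(self):
        lnc, mir, mrna = toy_matrices(5)
        mm = pd.DataFrame(
            {"mirna": ["m0"] * 5, "target": [f"g{i}" for i in range(5)], "scc": -0.9}
        )
        ml = pd.DataFrame(
            {"mirna": ["m0"] * 5, "target": [f"l{i}" for i in range(5)], "scc": -0.9}
        )
        strict = assemble_triplets(mm, ml, lnc, mrna, pcc_threshold=0.9)
        loose = assemble_triplets(mm, ml, lnc, mrna, pcc_threshold=0.5)
        assert {(t.lncrna, t.mirna, t.mrna) for t in strict} <= {
            (t.lncrna, t.mirna, t.mrna) for t in loose
        }

    def test_emitted_triplets_satisfy_all_constraints(self, small_result):
        for t in small_result.triplets:
            assert t.scc_mirna_mrna < -0.7
            assert t.scc_mirna_lnc < -0.7
            assert t.pcc_lnc_mrna > 0.9


class TestExport:
    def test_single_triplet_graph_shape(self, tmp_path):
        t = cf.CeRNATriplet("l0", "m0", "g0", -0.9, -0.9, 0.95)
        g = export_network([t], str(tmp_path / "n.sif"), str(tmp_path / "n.graphml"))
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
        sif = (tmp_path / "n.sif").read_text().strip().splitlines()
        assert len(sif) == 2
        assert (tmp_path / "n.graphml").exists()

    def test_empty_network_files_valid(self, tmp_path):
        g = export_network([], str(tmp_path / "e.sif"), str(tmp_path / "e.graphml"))
        assert g.number_of_nodes() == 0
        assert (tmp_path / "e.sif").read_text() == ""

    def test_counts_match_set_arithmetic(self, small_result):
        triplets = small_result.triplets
        g = build_graph(triplets)
        table = triplet_table(triplets)
        assert g.number_of_nodes() == (
            table["lncrna"].nunique() + table["mirna"].nunique()
            + table["mrna"].nunique()
        )
        types = {d["type"] for _, d in g.nodes(data=True)}
        assert types <= {"lncRNA", "miRNA", "mRNA"}


class TestEndToEndRecovery:
    def test_planted_triplets_recovered_no_decoys(self, small_result):
        rec = recovery_report(small_result)
        assert rec["n_recovered"] == rec["n_planted"] > 0
        assert rec["n_spurious"] == 0

    def test_planted_mrnas_inside_senescence_module(self, small_result):
        rec = {t.mrna for t in small_result.triplets_in_module}
        planted = set(small_result.study.truth.triplets["mrna"])
        assert rec == planted
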