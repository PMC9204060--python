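"""ceRNA triplet assembly: lncRNA-miRNA-mRNA under correlation constraints.

A competing-endogenous-RNA triplet requires (i) the miRNA to have a
predicted binding site on both the mRNA and the lncRNA, (ii) all three
members to be differentially expressed, (iii) the miRNA to be anticorrelated
with each target (Spearman rho < -0.7, strict), and (iv) the lncRNA and mRNA
to be positively co-expressed (Pearson r > 0.9, strict).  Pairs whose
correlation is undefined (constant profiles) are dropped, never passed.

The Spearman filter applies to miRNA-vs-target pairs for both target classes
(mRNA and lncRNA); the Pearson filter then ties together lncRNA and mRNA
that share at least one common miRNA.  An optional module gene set restricts
triplets to mRNAs inside a co-expression module (lncRNA membership is a
separate switch, off by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .expression_de import ExpressionMatrix
from .io_formats import logger
from .stats_core import pearson, spearman


@dataclass(frozen=True)
class CeRNATriplet:
    lncrna: str
    mirna: str
    mrna: str
    scc_mirna_mrna: float
    scc_mirna_lnc: float
    pcc_lnc_mrna: float


def _check_samples(*matrices: ExpressionMatrix) -> list[str]:
    samples = list(matrices[0].values.columns)
    for m in matrices[1:]:
        if list(m.values.columns) != samples:
            raise ValueError("expression matrices disagree on sample columns")
    return samples


def filter_pairs(
    hits: pd.DataFrame,
    mirna_expr: ExpressionMatrix,
    target_expr: ExpressionMatrix,
    de_mirnas: set[str],
    de_targets: set[str],
    scc_threshold: float = -0.7,
) -> pd.DataFrame:
    """miRNA-target pairs surviving prediction + DE + anticorrelation gates.

    ``hits`` is a target-prediction table with ``mirna`` and ``transcript``
    columns.  A pair is retained iff both members are differentially
    expressed and spearman(miRNA, target) < ``scc_threshold`` (strict);
    undefined correlations drop the pair.  Returns columns mirna, target,
    scc.
    """
    _check_samples(mirna_expr, target_expr)
    pairs = (
        hits[["mirna", "transcript"]].drop_duplicates().itertuples(index=False)
        if len(hits)
        else []
    )
    rows = []
    for mirna, target in pairs:
        if mirna not in de_mirnas or target not in de_targets:
            continue
        if mirna not in mirna_expr.values.index or target not in target_expr.values.index:
            continue
        rho = spearman(
            mirna_expr.values.loc[mirna].to_numpy(),
            target_expr.values.loc[target].to_numpy(),
        )
        if not np.isnan(rho) and rho < scc_threshold:
            rows.append({"mirna": mirna, "target": target, "scc": rho})
    out = pd.DataFrame(rows, columns=["mirna", "target", "scc"])
    logger.info(
        "filter_pairs: %d of %d predicted pairs pass DE + SCC < %s",
        len(out), hits[["mirna", "transcript"]].drop_duplicates().shape[0]
        if len(hits) else 0,
        scc_threshold,
    )
    return out


def assemble_triplets(
    mirna_mrna_pairs: pd.DataFrame,
    mirna_lnc_pairs: pd.DataFrame,
    lnc_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    pcc_threshold: float = 0.9,
    module_genes: set[str] | None = None,
    require_lnc_in_module: bool = False,
) -> list[CeRNATriplet]:
    """Join the two pair lists on common miRNAs and apply the Pearson gate.

    One triplet is emitted per (lncRNA, shared miRNA, mRNA) with
    pearson(lncRNA, mRNA) > ``pcc_threshold`` (strict).  Every emitted
    triplet is re-audited against its three correlation constraints.
    Output is deduplicated and sorted by (lncrna, mirna, mrna).
    """
    _check_samples(lnc_expr, mrna_expr)
    by_mirna_mrna: dict[str, dict[str, float]] = {}
    for row in mirna_mrna_pairs.itertuples(index=False):
        by_mirna_mrna.setdefault(row.mirna, {})[row.target] = row.scc
    by_mirna_lnc: dict[str, dict[str, float]] = {}
    for row in mirna_lnc_pairs.itertuples(index=False):
        by_mirna_lnc.setdefault(row.mirna, {})[row.target] = row.scc

    pcc_cache: dict[tuple[str, str], float] = {}

    def pcc(lnc: str, mrna: str) -> float:
        key = (lnc, mrna)
        if key not in pcc_cache:
            pcc_cache[key] = pearson(
                lnc_expr.values.loc[lnc].to_numpy(),
                mrna_expr.values.loc[mrna].to_numpy(),
            )
        return pcc_cache[key]

    triplets: set[CeRNATriplet] = set()
    for mirna in sorted(set(by_mirna_mrna) & set(by_mirna_lnc)):
        for mrna, lnc in product(
            sorted(by_mirna_mrna[mirna]), sorted(by_mirna_lnc[mirna])
        ):
            if module_genes is not None:
                if mrna not in module_genes:
                    continue
                if require_lnc_in_module and lnc not in module_genes:
                    continue
            r = pcc(lnc, mrna)
            if not np.isnan(r) and r > pcc_threshold:
                triplets.add(
                    CeRNATriplet(
                        lncrna=lnc,
                        mirna=mirna,
                        mrna=mrna,
                        scc_mirna_mrna=by_mirna_mrna[mirna][mrna],
                        scc_mirna_lnc=by_mirna_lnc[mirna][lnc],
                        pcc_lnc_mrna=r,
                    )
                )
    out = sorted(triplets, key=lambda t: (t.lncrna, t.mirna, t.mrna))
    _audit_triplets(out, lnc_expr, mrna_expr, pcc_threshold)
    logger.info("assemble_triplets: %d triplets", len(out))
    return out


def _audit_triplets(
    triplets: Sequence[CeRNATriplet],
    lnc_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    pcc_threshold: float,
) -> None:
    """Recompute the Pearson constraint for every emitted triplet."""
    for t in triplets:
        r = pearson(
            lnc_expr.values.loc[t.lncrna].to_numpy(),
            mrna_expr.values.loc[t.mrna].to_numpy(),
        )
        if not (r > pcc_threshold) or not np.isclose(r, t.pcc_lnc_mrna):
            raise AssertionError(
                f"triplet audit failed for {t.lncrna}/{t.mirna}/{t.mrna}"
            )


def triplet_table(triplets: Sequence[CeRNATriplet]) -> pd.DataFrame:
    return pd.DataFrame(
        [t.__dict__ for t in triplets],
        columns=[
            "lncrna", "mirna", "mrna",
            "scc_mirna_mrna", "scc_mirna_lnc", "pcc_lnc_mrna",
        ],
    )


def build_graph(triplets: Sequence[CeRNATriplet]) -> nx.Graph:
    """Bipartite-style graph: lncRNA-miRNA and miRNA-mRNA edges."""
    graph = nx.Graph()
    for t in triplets:
        graph.add_node(t.lncrna, type="lncRNA")
        graph.add_node(t.mirna, type="miRNA")
        graph.add_node(t.mrna, type="mRNA")
        graph.add_edge(t.lncrna, t.mirna, interaction="lncRNA-miRNA")
        graph.add_edge(t.mirna, t.mrna, interaction="miRNA-mRNA")
    return graph


def export_network(
    triplets: Sequence[CeRNATriplet],
    sif_path: str,
    graphml_path: str | None = None,
) -> nx.Graph:
    """Write a SIF edge list (and optionally GraphML) for network viewers."""
    graph = build_graph(triplets)
    with open(sif_path, "w") as fh:
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{data['interaction']}\t{b}\n")
    if graphml_path is not None:
        nx.write_graphml(graph, graphml_path)
    counts = {"lncRNA": 0, "miRNA": 0, "mRNA": 0}
    for _, data in graph.nodes(data=True):
        counts[data["type"]] += 1
    logger.info(
        "export_network: %d edges, nodes by type %s", graph.number_of_edges(), counts
    )
    return graph
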