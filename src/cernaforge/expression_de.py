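"""Abundance normalization (FPKM, TPM) and differential-expression calling.

The DE caller is a deliberately simple, fully documented surrogate for
count-model tools: Welch's two-sample t-test on log2(abundance + pseudocount)
with Benjamini-Hochberg correction within each contrast.  Thresholds follow
the analysis conventions: mRNA and lncRNA are called at q < 0.05 with
|log2FC| >= 1 (fold change >= 2), miRNA at a raw p-value cutoff (default
0.05; a 0.07 preset exists) with the same fold-change rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io_formats import logger
from .stats_core import bh_fdr

GENOTYPES = ("wild", "mutant")
LEAVES = ("flag", "second", "third")


@dataclass
class ExpressionMatrix:
    """Nonnegative feature x sample abundance table with sample metadata.

    ``values``: DataFrame, rows = feature ids, columns = sample ids.
    ``metadata``: DataFrame indexed by sample id with columns ``genotype``
    (wild/mutant), ``leaf`` (flag/second/third) and ``replicate``.
    ``unit``: one of count, FPKM, TPM, log2.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    unit: str = "count"

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative entries")
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        for col in ("genotype", "leaf", "replicate"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks required column {col!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def subset(self, features: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[list(features)],
            metadata=self.metadata,
            unit=self.unit,
        )

    def group_samples(self, genotype: str, leaf: str) -> list[str]:
        m = self.metadata
        mask = (m["genotype"] == genotype) & (m["leaf"] == leaf)
        return [s for s in self.values.columns if s in m.index[mask]]


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + c) transform; the co-expression stage runs on this scale."""
    if matrix.unit == "log2":
        return matrix
    return ExpressionMatrix(
        values=np.log2(matrix.values + pseudocount),
        metadata=matrix.metadata,
        unit="log2",
    )


def fpkm(counts: ExpressionMatrix, lengths: Mapping[str, int]) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM_i = count_i / ((length_i / 1e3) * (library_total / 1e6)); the
    identity sum_i FPKM_i * L_kb_i * total_M = library_total holds exactly.
    """
    vals = counts.values
    length_vec = pd.Series({g: lengths[g] for g in vals.index}, dtype=float)
    if (length_vec <= 0).any():
        raise ValueError("transcript lengths must be positive")
    totals = vals.sum(axis=0)
    if (totals <= 0).any():
        zero = totals.index[totals <= 0][0]
        raise ValueError(f"zero library size in sample {zero!r}")
    out = vals.div(length_vec / 1e3, axis=0).div(totals / 1e6, axis=1)
    return ExpressionMatrix(values=out, metadata=counts.metadata, unit="FPKM")


def tpm_small(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Tags-per-million scaling for small-RNA counts; columns sum to 1e6."""
    totals = counts.values.sum(axis=0)
    if (totals <= 0).any():
        zero = totals.index[totals <= 0][0]
        raise ValueError(f"zero library size in sample {zero!r}")
    out = counts.values.div(totals, axis=1) * 1e6
    return ExpressionMatrix(values=out, metadata=counts.metadata, unit="TPM")


@dataclass(frozen=True)
class DEThresholds:
    fdr_alpha: float = 0.05
    log2fc_min: float = 1.0
    p_mirna: float = 0.05
    pseudocount: float = 1.0


def call_de(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    feature_class: str = "mRNA",
    thresholds: DEThresholds | None = None,
    contrast: str = "A_vs_B",
) -> pd.DataFrame:
    """Differential expression of group B relative to group A.

    Returns a DataFrame with columns feature, contrast, log2fc, p, q, status.
    log2FC = log2((mean_B + c) / (mean_A + c)); p from Welch's t on
    log2(x + c); q = BH within the contrast.  Status is up/down/ns by the
    class rule: mRNA and lncRNA use q, miRNA uses raw p.
    """
    if feature_class not in ("mRNA", "lncRNA", "miRNA"):
        raise ValueError(f"unknown feature class {feature_class!r}")
    th = thresholds or DEThresholds()
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("sample groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    c = th.pseudocount
    a = np.log2(matrix.values[group_a].to_numpy() + c)
    b = np.log2(matrix.values[group_b].to_numpy() + c)
    log2fc = np.log2(matrix.values[group_b].mean(axis=1).to_numpy() + c) - np.log2(
        matrix.values[group_a].mean(axis=1).to_numpy() + c
    )
    tres = _sps.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.asarray(tres.pvalue, dtype=float)
    # Welch's t is undefined when both groups are exactly constant and equal;
    # those features are trivially non-differential.
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_fdr(p)
    sig = p < th.p_mirna if feature_class == "miRNA" else q < th.fdr_alpha
    status = np.where(
        sig & (log2fc >= th.log2fc_min),
        "up",
        np.where(sig & (log2fc <= -th.log2fc_min), "down", "ns"),
    )
    out = pd.DataFrame(
        {
            "feature": matrix.values.index,
            "contrast": contrast,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "status": status,
        }
    ).reset_index(drop=True)
    logger.info(
        "call_de[%s %s]: %d features, %d up, %d down",
        feature_class, contrast, len(out),
        int((out.status == "up").sum()), int((out.status == "down").sum()),
    )
    return out


def enumerate_contrasts(metadata: pd.DataFrame) -> dict[str, tuple[list[str], list[str]]]:
    """The nine pairwise contrasts of the 2-genotype x 3-leaf design.

    Three between-genotype contrasts (same leaf position) and three
    within-genotype leaf contrasts per genotype.  Each maps a label to
    (samples_A, samples_B).
    """
    def grp(genotype: str, leaf: str) -> list[str]:
        mask = (metadata["genotype"] == genotype) & (metadata["leaf"] == leaf)
        return sorted(metadata.index[mask])

    contrasts: dict[str, tuple[list[str], list[str]]] = {}
    for leaf in LEAVES:
        contrasts[f"wild_{leaf}_vs_mutant_{leaf}"] = (grp("wild", leaf), grp("mutant", leaf))
    for genotype in GENOTYPES:
        for l1, l2 in combinations(LEAVES, 2):
            contrasts[f"{genotype}_{l1}_vs_{genotype}_{l2}"] = (
                grp(genotype, l1), grp(genotype, l2),
            )
    return contrasts


def de_feature_set(
    de_tables: Sequence[pd.DataFrame], contrasts: Sequence[str] | None = None
) -> set[str]:
    """Features called up or down in at least one of the given contrasts."""
    hits: set[str] = set()
    for tab in de_tables:
        sel = tab if contrasts is None else tab[tab["contrast"].isin(contrasts)]
        hits |= set(sel.loc[sel["status"] != "ns", "feature"])
    return hits
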