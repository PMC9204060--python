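"""Weighted co-expression module detection and module-trait association.

The standard soft-threshold workflow: a variance pre-filter drops the least
variable genes (default 45%), adjacency is the unsigned soft-thresholded
correlation a_ij = |cor(x_i, x_j)|^beta (default beta = 8), similarity is the
unsigned topological overlap

    TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

and modules come from average-linkage hierarchical clustering of 1 - TOM
with a static tree cut (height defaults to the 0.99 quantile of the merge
heights -- a deterministic stand-in for dynamic tree cutting).  Clusters
smaller than the minimum size (default 50) fall into the reserved ``grey``
label; module pairs whose eigengenes are closer than the merge cut (default
dissimilarity 0.85) are merged iteratively.  A module's eigengene is the
first principal component of the standardized member expression, oriented to
correlate nonnegatively with the mean member profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression_de import ExpressionMatrix
from .io_formats import logger
from .stats_core import pearson

GREY = "grey"
# color-style labels, assigned to modules in decreasing size order
_PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
)


@dataclass
class CoexprModule:
    label: str
    genes: tuple[str, ...]
    eigengene: pd.Series  # per-sample

    def __len__(self) -> int:
        return len(self.genes)


def variance_prefilter(
    matrix: ExpressionMatrix, drop_fraction: float = 0.45
) -> ExpressionMatrix:
    """Drop the ``drop_fraction`` lowest-variance genes (log2 scale).

    Ties in variance break deterministically by gene id.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must lie in [0, 1)")
    logged = matrix.values if matrix.unit == "log2" else np.log2(matrix.values + 1.0)
    variances = logged.var(axis=1, ddof=1)
    if np.allclose(variances, 0):
        raise ValueError("all genes are constant; nothing to cluster")
    order = sorted(matrix.values.index, key=lambda g: (variances[g], g))
    n_drop = int(round(drop_fraction * len(order)))
    pos = {g: i for i, g in enumerate(matrix.values.index)}
    kept = sorted(order[n_drop:], key=pos.__getitem__)
    logger.info(
        "variance_prefilter: kept %d of %d genes", len(kept), len(order)
    )
    return matrix.subset(kept)


def soft_adjacency(matrix: ExpressionMatrix, beta: float = 8.0) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |pearson|^beta with unit diagonal.

    Constant genes have undefined correlation; they are excluded with a
    warning rather than given spurious adjacency.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if matrix.values.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    vals = matrix.values
    constant = vals.std(axis=1, ddof=1) == 0
    if constant.any():
        dropped = list(vals.index[constant])
        logger.warning("soft_adjacency: excluding constant genes %s", dropped)
        vals = vals.loc[~constant]
    corr = np.corrcoef(vals.to_numpy())
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=vals.index, columns=vals.index)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix of a valid adjacency."""
    a = adjacency.to_numpy(dtype=float)
    n = a.shape[0]
    k = a.sum(axis=1) - 1.0  # connectivity excludes the self-loop
    shared = a @ a - a * 2.0  # sum_{u != i,j} a_iu * a_uj  (diagonal a_ii = 1)
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def eigengene(matrix: ExpressionMatrix, genes: tuple[str, ...]) -> pd.Series:
    """First principal component (per-sample scores) of the member genes.

    Member expression is standardized gene-wise; the sign is fixed so the
    eigengene correlates nonnegatively with the mean member profile.
    """
    sub = matrix.values.loc[list(genes)].to_numpy(dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    std = sub.std(axis=1, ddof=1, keepdims=True)
    std[std == 0] = 1.0
    z = (sub - mean) / std
    # samples x genes SVD; first right-singular vector gives sample scores
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0] * s[0] / np.sqrt(max(len(genes) - 1, 1))
    profile = z.mean(axis=0)
    if np.std(profile) > 0 and np.corrcoef(scores, profile)[0, 1] < 0:
        scores = -scores
    return pd.Series(scores, index=matrix.values.columns, name="eigengene")


def detect_modules(
    tom: pd.DataFrame,
    matrix: ExpressionMatrix,
    min_size: int = 50,
    merge_cut: float = 0.85,
    cut_height: float = 0.98,
) -> list[CoexprModule]:
    """Cluster 1 - TOM, cut statically, drop small clusters, merge by eigengene.

    The static cut height (default 0.98 on the 1 - TOM dissimilarity scale)
    separates genuinely co-expressed groups, whose average-linkage merges sit
    far below it, from unrelated genes whose pairwise topological overlap is
    essentially zero (dissimilarity ~1).  Returns non-grey modules sorted by
    decreasing size (labels follow the conventional color sequence, largest
    = turquoise) plus a final grey module collecting unassigned genes.
    Merging joins module pairs whose eigengene dissimilarity 1 - cor is
    below ``merge_cut``, most similar pair first, until stable.
    """
    genes = list(tom.index)
    if len(genes) < min_size:
        logger.warning("detect_modules: fewer genes than min_size; all grey")
        return [_grey_module(matrix, tuple(genes))]
    dist = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform((dist + dist.T) / 2.0, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    labels = hierarchy.fcluster(linkage, t=cut_height, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for gene, lab in zip(genes, labels):
        clusters.setdefault(int(lab), []).append(gene)
    # deterministic order: decreasing size, tie-break by first gene id
    member_sets = sorted(
        (tuple(sorted(v)) for v in clusters.values() if len(v) >= min_size),
        key=lambda ms: (-len(ms), ms[0]),
    )
    member_sets = [list(ms) for ms in member_sets]

    def eg(ms: list[str]) -> pd.Series:
        return eigengene(matrix, tuple(ms))

    eigengenes = [eg(ms) for ms in member_sets]
    merged = True
    while merged and len(member_sets) > 1:
        merged = False
        best: tuple[float, int, int] | None = None
        for i in range(len(member_sets)):
            for j in range(i + 1, len(member_sets)):
                r = pearson(eigengenes[i].to_numpy(), eigengenes[j].to_numpy())
                if np.isnan(r):
                    continue
                dis = 1.0 - r
                if dis < merge_cut and (best is None or dis < best[0]):
                    best = (dis, i, j)
        if best is not None:
            _, i, j = best
            member_sets[i] = sorted(member_sets[i] + member_sets[j])
            del member_sets[j]
            eigengenes = [eg(ms) for ms in member_sets]
            merged = True

    member_sets.sort(key=lambda ms: (-len(ms), ms[0]))
    modules = []
    for idx, ms in enumerate(member_sets):
        label = _PALETTE[idx] if idx < len(_PALETTE) else f"module{idx + 1}"
        modules.append(
            CoexprModule(label=label, genes=tuple(ms), eigengene=eg(ms))
        )
    assigned = {g for m in modules for g in m.genes}
    grey_genes = tuple(g for g in genes if g not in assigned)
    modules.append(_grey_module(matrix, grey_genes))
    logger.info(
        "detect_modules: %s",
        {m.label: len(m.genes) for m in modules},
    )
    return modules


def _grey_module(matrix: ExpressionMatrix, genes: tuple[str, ...]) -> CoexprModule:
    if genes:
        eg = eigengene(matrix, genes)
    else:
        eg = pd.Series(
            np.zeros(matrix.values.shape[1]), index=matrix.values.columns
        )
    return CoexprModule(label=GREY, genes=genes, eigengene=eg)


def module_trait(
    modules: list[CoexprModule], metadata: pd.DataFrame
) -> pd.DataFrame:
    """Correlate module eigengenes with (genotype, leaf) indicator traits.

    Returns a long DataFrame: module, trait, r, p (t-approximation).  Traits
    are one indicator vector per genotype x leaf group; a constant indicator
    yields nan.
    """
    from scipy import stats as _sps

    rows = []
    groups = sorted(
        metadata.groupby(["genotype", "leaf"]).groups.keys()
    )
    for module in modules:
        samples = module.eigengene.index
        ev = module.eigengene.to_numpy(dtype=float)
        n = len(samples)
        for genotype, leaf in groups:
            indicator = (
                (metadata.loc[samples, "genotype"] == genotype)
                & (metadata.loc[samples, "leaf"] == leaf)
            ).astype(float).to_numpy()
            r = pearson(ev, indicator)
            if np.isnan(r):
                p = float("nan")
            elif abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = float(2.0 * _sps.t.sf(abs(t), n - 2))
            rows.append(
                {
                    "module": module.label,
                    "trait": f"{genotype}_{leaf}",
                    "r": r,
                    "p": p,
                }
            )
    return pd.DataFrame(rows, columns=["module", "trait", "r", "p"])
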