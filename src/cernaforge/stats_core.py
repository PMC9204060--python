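"""Statistical primitives used throughout the pipeline.

Pearson and Spearman correlation, Benjamini-Hochberg FDR adjustment, the
hypergeometric enrichment test, and the chi-square goodness-of-fit test for
Mendelian segregation ratios.

Correlations on a constant vector are undefined; they return ``nan`` rather
than a spurious +/-1, and callers treat ``nan`` as failing any threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise ValueError("correlation needs 1-d vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("correlation inputs must be finite")
    return x, y


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient; nan if either vector is constant."""
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(_sps.pearsonr(x, y).statistic)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average (mid) ranks for ties."""
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(_sps.spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    q_(i) = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j), clipped at
    1; elementwise q >= p and the order of p is preserved.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(N, K, n).

    ``N`` is the universe size, ``K`` the number of genes carrying the term,
    ``n`` the query-set size and ``k`` the observed overlap.  Computed from
    log-space survival probabilities, so small tails do not underflow.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name}={v} must be a nonnegative integer")
    if K > N or n > N or k > min(K, n):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(_sps.hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's enrichment: overlap k of term size K, set n, universe N."""

    term: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float = float("nan")
    significant: bool = False


def enrich_terms(
    geneset: set[str] | Sequence[str],
    universe: set[str] | Sequence[str],
    term2genes: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of ``geneset`` against term->gene annotation.

    The background is the full universe of annotated genes; terms with no
    universe gene are skipped.  Terms are flagged significant at BH FDR
    q <= alpha.  Output order (by term id) is independent of the mapping's
    iteration order.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    geneset = set(geneset)
    stray = geneset - universe
    if stray:
        raise ValueError(f"geneset genes outside universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(geneset)
    partial: list[EnrichmentResult] = []
    for term in sorted(term2genes):
        members = set(term2genes[term]) & universe
        if not members:
            continue
        K = len(members)
        k = len(members & geneset)
        partial.append(
            EnrichmentResult(term=term, k=k, K=K, n=n, N=N, p=hypergeom_upper(k, K, n, N))
        )
    if not partial:
        return []
    qvals = bh_fdr([r.p for r in partial])
    return [
        EnrichmentResult(
            term=r.term, k=r.k, K=r.K, n=r.n, N=r.N, p=r.p,
            q=float(q), significant=bool(q <= alpha),
        )
        for r, q in zip(partial, qvals)
    ]


# ---------------------------------------------------------------------------
# Goodness of fit (Mendelian segregation)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GofResult:
    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...]
    chi2: float
    df: int
    p: float


def chi_square_gof(
    observed: Sequence[int], ratio: Sequence[float] = (0.75, 0.25)
) -> GofResult:
    """Chi-square goodness of fit of observed counts to an expected ratio.

    The default 3:1 ratio is the F2 expectation for a single recessive locus.
    """
    obs = np.asarray(observed, dtype=float)
    r = np.asarray(ratio, dtype=float)
    if obs.size < 2 or obs.size != r.size:
        raise ValueError("need >= 2 categories and matching ratio length")
    if obs.sum() <= 0:
        raise ValueError("total count must be positive")
    if not np.isclose(r.sum(), 1.0):
        raise ValueError("expected proportions must sum to 1")
    expected = obs.sum() * r
    if np.any(expected == 0):
        raise ValueError("zero expected count")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = obs.size - 1
    p = float(_sps.chi2.sf(chi2, df))
    return GofResult(
        observed=tuple(int(v) for v in obs),
        expected_ratio=tuple(float(v) for v in r),
        chi2=chi2,
        df=df,
        p=p,
    )


def chi2_critical(alpha: float = 0.05, df: int = 1) -> float:
    """Upper critical value of the chi-square distribution."""
    return float(_sps.chi2.ppf(1.0 - alpha, df))
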