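"""Independent brute-force reference implementations used only by tests.

Everything here is written from the definitions with explicit loops and
exact arithmetic, deliberately sharing no code with the package.
"""

from fractions import Fraction
from math import comb

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}
_PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}
_PERFECT = {"G": -3.0, "C": -3.0, "A": -2.0, "U": -2.0}


def naive_states(mirna: str, window: str) -> list[str]:
    L = len(mirna)
    out = []
    for i in range(L):  # miRNA position i+1 pairs window position L-i
        pair = (mirna[i], window[L - 1 - i])
        if pair in _WC:
            out.append("WC")
        elif pair in _GU:
            out.append("GU")
        else:
            out.append("MM")
    return out


def naive_score(states: list[str]) -> float:
    return sum(0.5 if s == "GU" else 1.0 if s == "MM" else 0.0 for s in states)


def naive_rules(mirna: str, window: str, ruleset: str) -> dict[str, bool]:
    states = naive_states(mirna, window)
    L = len(states)
    mm = [s != "WC" for s in states]
    score = naive_score(states)

    runs, run = [], 0
    for flag in mm:
        run = run + 1 if flag else 0
        runs.append(run)
    max_run = max(runs) if runs else 0

    r1 = score <= 4.0
    r2 = max_run <= (2 if ruleset == "A" else 1)
    if ruleset == "A":
        r3 = not any(mm[i] and mm[i + 1] for i in range(1, min(11, L - 1)))
    else:
        r3 = not any(mm[1:min(12, L)])
    r4 = all(states[i] == "WC" for i in (9, 10) if i < L)
    r5 = naive_score(states[:12]) <= 2.5
    energy = sum(
        _PAIR_ENERGY.get((mirna[i], window[L - 1 - i]), 0.0) for i in range(L)
    )
    perfect = sum(_PERFECT.get(b, 0.0) for b in mirna)
    ratio = abs(energy) / abs(perfect) if perfect else 0.0
    r6 = ratio >= (0.74 if ruleset == "A" else 0.60)
    return {"r1": r1, "r2": r2, "r3": r3, "r4": r4, "r5": r5, "r6": r6}


def naive_scan(mirna: str, transcript: str, ruleset: str) -> list[int]:
    """Start positions of rule-passing windows."""
    L = len(mirna)
    hits = []
    for s in range(len(transcript) - L + 1):
        if all(naive_rules(mirna, transcript[s : s + L], ruleset).values()):
            hits.append(s)
    return hits


def naive_pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx**0.5 * vy**0.5)


def average_ranks(x) -> list[float]:
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        mean_rank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def naive_spearman(x, y) -> float:
    return naive_pearson(average_ranks(x), average_ranks(y))


def naive_bh(pvals) -> list[float]:
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        q[i] = running
    return q


def naive_hypergeom_upper(k, K, n, N) -> float:
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
    return float(total)


def naive_tom(adjacency) -> list[list[float]]:
    n = len(adjacency)
    k = [sum(adjacency[i][u] for u in range(n) if u != i) for i in range(n)]
    tom = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i][j] = 1.0
                continue
            shared = sum(
                adjacency[i][u] * adjacency[u][j]
                for u in range(n)
                if u != i and u != j
            )
            tom[i][j] = (shared + adjacency[i][j]) / (
                min(k[i], k[j]) + 1.0 - adjacency[i][j]
            )
    return tom


def naive_triplets(mm_pairs, ml_pairs, pcc, pcc_threshold):
    """All (lnc, mirna, mrna) with shared miRNA and pearson above threshold.

    ``mm_pairs``/``ml_pairs`` are (mirna, target) tuples; ``pcc`` maps
    (lnc, mrna) to a correlation.
    """
    out = set()
    for mirna, mrna in mm_pairs:
        for mirna2, lnc in ml_pairs:
            if mirna2 == mirna and pcc[(lnc, mrna)] > pcc_threshold:
                out.add((lnc, mirna, mrna))
    return out
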