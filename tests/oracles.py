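"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: plain-Python dynamic
programming and set arithmetic, written for clarity rather than speed.
"""

from __future__ import annotations

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}


def pair_score(mirna_base: str, utr_base: str, match: float, wobble: float,
               mismatch: float) -> float:
    if (mirna_base, utr_base) in WC:
        return match
    if (mirna_base, utr_base) in WOBBLE:
        return wobble
    return mismatch


def best_local_duplex_score(mirna: str, utr: str, *, match: float = 5.0,
                            wobble: float = 1.0, mismatch: float = -3.0,
                            gap_open: float = -8.0, gap_extend: float = -2.0,
                            seed_start: int = 2, seed_end: int = 8,
                            seed_multiplier: float = 2.0) -> float:
    """Exhaustive affine-gap local alignment score of a miRNA against a UTR.

    The miRNA (5'->3') is reversed so that it faces the UTR antiparallel;
    the pair score at miRNA position p (1-based from the 5' end) is
    multiplied by ``seed_multiplier`` when seed_start <= p <= seed_end.
    Plain dictionary-based Gotoh DP over every cell; returns the single best
    score (0.0 if nothing scores positively).
    """
    rev = mirna[::-1]
    L = len(mirna)
    weights = []
    for idx in range(L):          # idx indexes the reversed miRNA
        p = L - idx               # original 1-based position
        weights.append(seed_multiplier if seed_start <= p <= seed_end else 1.0)
    m, n = len(rev), len(utr)
    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = pair_score(rev[i - 1], utr[j - 1], match, wobble, mismatch)
            diag = H[i - 1][j - 1] + s * weights[i - 1]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def naive_pearson(x, y) -> float:
    """Textbook Pearson correlation without numpy."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


def brute_force_triple_intersection(predicted: dict[str, set[str]],
                                    up: set[str], down: set[str]
                                    ) -> set[tuple[str, str]]:
    calls = set()
    for mirna, genes in predicted.items():
        for g in genes:
            if g in up and g in down:
                calls.add((mirna, g))
    return calls
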