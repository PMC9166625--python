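"""Independent brute-force oracles used by the test suite only.

These deliberately avoid the production code paths: the alignment oracle
is a from-scratch Gotoh DP, the placement oracle an exhaustive
early-exit Hamming scan in pure Python.
"""

from spacernick.seqs import revcomp

MATCH, MISMATCH, OPEN, EXTEND = 1.0, -4.0, -6.0, -1.0


def gotoh_score(a: str, b: str) -> float:
    """Quadratic affine-gap global alignment score.

    Gap of length L costs |OPEN| + (L-1)*|EXTEND|, end gaps included.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = OPEN + (i - 1) * EXTEND
    for j in range(1, m + 1):
        Y[0][j] = OPEN + (j - 1) * EXTEND
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = MATCH if ai == b[j - 1] else MISMATCH
            Mi[j] = max(Mp[j - 1], Xp[j - 1], Yp[j - 1]) + s
            Xi[j] = max(Mp[j] + OPEN, Xp[j] + EXTEND, Yp[j] + OPEN)
            Yi[j] = max(Mi[j - 1] + OPEN, Yi[j - 1] + EXTEND,
                        Xi[j - 1] + OPEN)
    return max(M[n][m], X[n][m], Y[n][m])


def placement_scan(genome: dict, query: str):
    """Best substitution-only placement by exhaustive early-exit scan.

    Returns (best_mismatches, n_best_ties, best_placement) where the
    placement is (contig, start, strand); ties are counted at the best
    mismatch level (the margin rule collapses to exact score ties for
    pure-substitution scoring).
    """
    L = len(query)
    best_mm = L + 1
    ties = 0
    best = None
    for name in sorted(genome):
        seq = genome[name]
        n = len(seq)
        for strand, q in (("+", query), ("-", revcomp(query))):
            for i in range(n - L + 1):
                mm = 0
                for j in range(L):
                    if seq[i + j] != q[j]:
                        mm += 1
                        if mm > best_mm:
                            break
                if mm < best_mm:
                    best_mm, ties, best = mm, 1, (name, i, strand)
                elif mm == best_mm:
                    ties += 1
    return best_mm, ties, best
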