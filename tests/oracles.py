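"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity from its definition by a different route
than the implementation under test: explicit three-state dynamic programming
for local alignment, all-prefix scanning for N50, and exhaustive bipartition
enumeration for tree comparison.
"""

from itertools import combinations


def sw_affine_bruteforce(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Textbook three-matrix Smith-Waterman with affine gaps.

    A gap of length L costs gap_open + L * gap_extend.  `sub` is a callable
    sub(x, y) -> score.  Returns the optimal local score (>= 0).
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]  # ends in a match/mismatch
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub(a[i - 1], b[j - 1])
            M[i][j] = max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend, X[i - 1][j] - gap_extend
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend, Y[i][j - 1] - gap_extend
            )
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


def n50_bruteforce(lengths) -> int:
    """N50 by scanning every prefix of the descending-sorted lengths."""
    total = sum(lengths)
    acc = 0
    for x in sorted(lengths, reverse=True):
        acc += x
        if 2 * acc >= total:
            return x
    raise ValueError("empty input")


def splits_bruteforce(tree) -> set:
    """Non-trivial bipartitions of a dendropy tree by enumerating, for every
    internal edge, the leaf labels below it; canonicalized to the side not
    containing the alphabetically first leaf."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    out = set()
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head is None or head.is_leaf() or head is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in head.leaf_iter())
        if anchor in side:
            side = frozenset(leaves - side)
        if 1 < len(side) < len(leaves) - 1:
            out.add(side)
    return out


def rf_bruteforce(t1, t2) -> int:
    return len(splits_bruteforce(t1) ^ splits_bruteforce(t2))


def adjacency_fraction_bruteforce(order_a, order_b) -> float:
    """Fraction of adjacent pairs in order_a that are adjacent (either
    orientation) in order_b, by direct enumeration."""
    pairs_b = {frozenset(p) for p in zip(order_b, order_b[1:])}
    pairs_a = list(zip(order_a, order_a[1:]))
    return sum(frozenset(p) in pairs_b for p in pairs_a) / len(pairs_a)
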