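"""Independent brute-force oracles used to validate the package's optimised
implementations. Everything here is deliberately written from the textbook
definition, sharing no code with famexpand internals."""

import itertools


def sw_oracle_score(a, b, score_fn, gap_open, gap_extend):
    """Affine-gap local alignment score by the plain three-matrix recurrence.

    score_fn(x, y) gives the substitution score; a gap of length k costs
    gap_open + k * gap_extend.
    """
    n, m = len(a), len(b)
    NEG = -10**9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            H[i][j] = max(0, H[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1]),
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def n50_oracle(lengths):
    """Shortest sequence length at 50% of the assembly, by direct scan."""
    total = sum(lengths)
    running = 0
    for length in sorted(lengths, reverse=True):
        running += length
        if running * 2 >= total:
            return length
    raise AssertionError("unreachable for non-empty input")


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i, block in enumerate(part):
            yield part[:i] + [block + [first]] + part[i + 1:]
        yield [[first]] + part


def min_chain_oracle(intervals, conflict_fn):
    """Minimum number of groups of pairwise non-conflicting intervals, by
    exhaustive enumeration of all set partitions."""
    best = None
    for part in set_partitions(list(range(len(intervals)))):
        valid = all(
            not conflict_fn(intervals[x], intervals[y])
            for block in part
            for x, y in itertools.combinations(block, 2))
        if valid and (best is None or len(part) < best):
            best = len(part)
    return best


def subset_partition_oracle(hit_sets):
    """Brute-force assignment of each query to its exact reference subset."""
    refs = sorted(hit_sets)
    universe = set()
    for r in refs:
        universe |= set(hit_sets[r])
    cells = {}
    for q in universe:
        key = frozenset(r for r in refs if q in set(hit_sets[r]))
        cells[key] = cells.get(key, 0) + 1
    return cells
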