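"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own code paths: the aligner oracle is
a memoized recursive three-state dynamic program over explicit recurrences,
and the component oracle is a plain union-find.
"""

from functools import lru_cache
import math


def nw_affine_score(seq_a, seq_b, matrix, gap_open, gap_extend):
    """Optimal global affine-gap alignment score by recursive three-state DP.

    States: M (a[i-1] aligned to b[j-1]), X (a[i-1] against a gap),
    Y (b[j-1] against a gap).  A gap run of length L costs
    gap_open + (L-1) * gap_extend.  End gaps are penalized.
    """
    n, m = len(seq_a), len(seq_b)
    NEG = -math.inf

    @lru_cache(maxsize=None)
    def best(i, j, state):
        if i == 0 and j == 0:
            return 0.0 if state == "M" else NEG
        if state == "M":
            if i == 0 or j == 0:
                return NEG
            s = matrix[seq_a[i - 1], seq_b[j - 1]]
            return s + max(best(i - 1, j - 1, st) for st in "MXY")
        if state == "X":  # a[i-1] vs gap
            if i == 0:
                return NEG
            return max(
                best(i - 1, j, "M") - gap_open,
                best(i - 1, j, "X") - gap_extend,
                best(i - 1, j, "Y") - gap_open,
            )
        # Y: b[j-1] vs gap
        if j == 0:
            return NEG
        return max(
            best(i, j - 1, "M") - gap_open,
            best(i, j - 1, "X") - gap_open,
            best(i, j - 1, "Y") - gap_extend,
        )

    result = max(best(n, m, st) for st in "MXY")
    best.cache_clear()
    return result


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def components(self):
        groups = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return [frozenset(g) for g in groups.values()]
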