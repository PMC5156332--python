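"""Independent reference implementations used only by the tests.

Deliberately written in the most transparent way possible (memoized
recursion, all-pairs scans, exhaustive enumeration) and kept free of any
code from the package's own alignment/segmentation paths.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

NEG = -(10**9)


def affine_align_oracle(a: str, b: str, match=1, mismatch=-2, gap_open=-5, gap_extend=-1):
    """Optimal global affine-gap alignment value as (score, max matches).

    Full three-state recursion over (i, j, state); among score-optimal
    alignments the match count is maximised (lexicographic objective).
    """

    @lru_cache(maxsize=None)
    def best(i, j, state):
        if i == 0 and j == 0:
            return (0, 0) if state == "H" else (NEG, 0)
        if state == "H":
            cands = []
            if i > 0 and j > 0:
                ps, pm = best(i - 1, j - 1, "H")
                hit = a[i - 1] == b[j - 1] and a[i - 1] != "N"
                cands.append((ps + (match if hit else mismatch), pm + int(hit)))
            if i > 0:
                cands.append(best(i, j, "F"))
            if j > 0:
                cands.append(best(i, j, "E"))
            return max(cands)
        if state == "E":  # gap in a, consumed b[j-1]
            if j == 0:
                return (NEG, 0)
            es, em = best(i, j - 1, "E")
            hs, hm = best(i, j - 1, "H")
            return max((es + gap_extend, em), (hs + gap_open + gap_extend, hm))
        # state == "F": gap in b, consumed a[i-1]
        if i == 0:
            return (NEG, 0)
        fs, fm = best(i - 1, j, "F")
        hs, hm = best(i - 1, j, "H")
        return max((fs + gap_extend, fm), (hs + gap_open + gap_extend, hm))

    return best(len(a), len(b), "H")


def naive_match_track(hybrid: str, parent: str, k: int) -> list[bool]:
    """O(n*m) per-position exact-match track: position i (0-based) of the
    hybrid lies inside some exact substring match of length >= k with the
    parent.  Scans every diagonal explicitly."""
    n, m = len(hybrid), len(parent)
    track = [False] * n
    for d in range(-(n - 1), m):
        i = max(0, -d)
        while i < n and i + d < m:
            if hybrid[i] != "N" and hybrid[i] == parent[i + d]:
                run = 0
                start = i
                while i < n and i + d < m and hybrid[i] != "N" and hybrid[i] == parent[i + d]:
                    run += 1
                    i += 1
                if run >= k:
                    for p in range(start, start + run):
                        track[p] = True
            else:
                i += 1
    return track


def min_switches_bruteforce(categories: list[str], topology: str) -> int:
    """Minimum A<->B switch count over all origin assignments consistent
    with a run-category sequence (categories from {A, B, both, neither}),
    by exhaustive enumeration of the flexible runs."""
    flexible = [i for i, c in enumerate(categories) if c in ("both", "neither")]
    best = None
    for combo in itertools.product("AB", repeat=len(flexible)):
        origins = list(categories)
        for idx, val in zip(flexible, combo):
            origins[idx] = val
        # merge consecutive equal origins, count switches
        switches = sum(1 for x, y in zip(origins, origins[1:]) if x != y)
        if topology == "circular" and len(origins) > 1 and origins[0] != origins[-1]:
            switches += 1
        if best is None or switches < best:
            best = switches
    return best if best is not None else 0
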