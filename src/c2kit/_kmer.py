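"""Shared k-mer machinery: 2-bit encoding and maximal exact-match runs.

Used by the mosaic module (per-position parent matching) and the anchored
genome aligner.  N (and any non-ACGT character) encodes as -1 and never
matches, so exact runs are N-free by construction.
"""

from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    """2-bit-encode a sequence; N and other characters become -1."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Integer codes for all k-mers; windows containing N get code -1."""
    win = np.lib.stride_tricks.sliding_window_view(enc, k)
    valid = (win >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = (win.astype(np.int64) * powers).sum(axis=1)
    codes[~valid] = -1
    return codes


def exact_match_runs(a_enc: np.ndarray, b_enc: np.ndarray, k: int):
    """Yield (i, j, length): maximal exact matches of length >= k between the
    encoded sequences, 0-based, found via shared k-mers grouped by diagonal."""
    n, m = len(a_enc), len(b_enc)
    if n < k or m < k:
        return
    a_codes = _kmer_codes(a_enc, k)
    b_codes = _kmer_codes(b_enc, k)
    order = np.argsort(b_codes, kind="stable")
    b_sorted = b_codes[order]
    lo = np.searchsorted(b_sorted, a_codes, side="left")
    hi = np.searchsorted(b_sorted, a_codes, side="right")
    has_hit = (hi > lo) & (a_codes >= 0)
    idx = np.flatnonzero(has_hit)
    counts = (hi[idx] - lo[idx]).astype(np.int64)
    total = int(counts.sum())
    if total == 0:
        return
    # expand [lo, hi) ranges into flat hit pairs without a Python loop
    cum = np.cumsum(counts) - counts
    flat = np.repeat(lo[idx], counts) + (np.arange(total) - np.repeat(cum, counts))
    j_hits = order[flat]
    i_hits = np.repeat(idx, counts)
    diagonals = np.unique(j_hits - i_hits)
    for d in (int(x) for x in diagonals):
        i0 = max(0, -d)
        i1 = min(n, m - d)
        if i1 - i0 < k:
            continue
        eq = (a_enc[i0:i1] == b_enc[i0 + d : i1 + d]) & (a_enc[i0:i1] >= 0)
        padded = np.concatenate(([False], eq, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= k:
                yield int(i0 + s), int(i0 + s + d), int(e - s)
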