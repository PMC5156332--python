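"""Recombination-mosaic segmentation of hybrid phage genomes.

A hybrid genome arising from co-infection by two parental phages is a
patchwork of blocks copied verbatim from one parent or the other, with
crossovers falling inside sequence tracts the parents share exactly.
Around each crossover the hybrid therefore matches BOTH parents — the
"overlapping identities" seen when maximal per-parent matches are listed —
and the crossover position is only localisable to that shared tract.

This module marks, for each hybrid position, whether it lies inside a
maximal exact match of length >= k with each parent (forward strand only;
C2virus recombinants are colinear), tiles the hybrid into parental-origin
blocks with explicit 'both' (crossover-ambiguity) blocks, and counts the
minimum number of recombination events.  On a circular (or circularly
permuted) genome map, parental-origin switches come in reciprocal pairs,
so events = switches / 2; on a linear map events = switches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kmer import encode, exact_match_runs
from .io import Genome

__all__ = [
    "OriginBlock",
    "MosaicSegmentation",
    "per_position_match",
    "maximal_parent_matches",
    "segment_mosaic",
    "count_events",
]


def _diagonal_runs(h_enc: np.ndarray, p_enc: np.ndarray, k: int):
    """(start, end) 0-based inclusive hybrid intervals of maximal exact
    matches of length >= k with the parent."""
    for i, _j, ln in exact_match_runs(h_enc, p_enc, k):
        yield i, i + ln - 1


def per_position_match(hybrid: Genome, parent: Genome, k: int = 21) -> np.ndarray:
    """Boolean track: hybrid position i (0-based) lies inside a maximal exact
    forward-strand match of length >= k with the parent."""
    if k < 11:
        raise ValueError("k must be >= 11")
    if parent.length < k:
        raise ValueError(f"parent {parent.id} shorter than k={k}")
    track = np.zeros(hybrid.length, dtype=bool)
    h_enc, p_enc = encode(hybrid.seq), encode(parent.seq)
    for s, e in _diagonal_runs(h_enc, p_enc, k):
        track[s : e + 1] = True
    return track


def maximal_parent_matches(hybrid: Genome, parent: Genome, k: int = 21) -> list[tuple[int, int]]:
    """Maximal exact-match intervals (1-based inclusive, on the hybrid),
    the paper-style 'overlapping identities' view."""
    if k < 11:
        raise ValueError("k must be >= 11")
    h_enc, p_enc = encode(hybrid.seq), encode(parent.seq)
    ivals = [(s + 1, e + 1) for s, e in _diagonal_runs(h_enc, p_enc, k)]
    ivals.sort()
    # merge intervals duplicated across diagonals
    merged: list[tuple[int, int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass(frozen=True)
class OriginBlock:
    start: int  # 1-based inclusive on the hybrid
    end: int
    origin: str  # A | B | both | neither
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("block start > end")
        if self.origin not in ("A", "B", "both", "neither"):
            raise ValueError(f"bad origin {self.origin!r}")


@dataclass(frozen=True)
class MosaicSegmentation:
    hybrid_id: str
    blocks: tuple[OriginBlock, ...]
    crossover_intervals: tuple[tuple[int, int], ...]
    switches: int
    events: int
    topology: str

    def origin_sequence(self) -> list[str]:
        """Parental origins of the A/B blocks, in order (both/neither read through)."""
        return [b.origin for b in self.blocks if b.origin in ("A", "B")]


def _forced_switches(origins: list[str], topology: str) -> int:
    switches = sum(1 for x, y in zip(origins, origins[1:]) if x != y)
    if topology == "circular" and len(origins) >= 2 and origins[-1] != origins[0]:
        switches += 1
    return switches


def segment_mosaic(
    hybrid: Genome,
    parentA: Genome,
    parentB: Genome,
    k: int = 21,
    min_block: int = 50,
    topology: str = "circular",
) -> MosaicSegmentation:
    """Tile a hybrid genome into parental-origin blocks.

    Positions matching only one parent force that origin; positions
    matching both parents form 'both' blocks — the crossover-ambiguity
    intervals; 'neither' stretches shorter than ``min_block`` are absorbed
    into the preceding block and flagged.  The resulting origin sequence
    realises the minimum number of A<->B switches consistent with the
    match tracks (flexible blocks never force a switch).
    """
    if topology not in ("linear", "circular"):
        raise ValueError(f"bad topology {topology!r}")
    tA = per_position_match(hybrid, parentA, k=k)
    tB = per_position_match(hybrid, parentB, k=k)
    if not tA.any() and not tB.any():
        raise ValueError(
            f"{hybrid.id} is not a recombinant of {parentA.id} and {parentB.id}: "
            "no exact match to either parent"
        )
    cat = tA.astype(np.int8) + 2 * tB.astype(np.int8)  # 0 neither, 1 A, 2 B, 3 both
    # run-length encode
    change = np.flatnonzero(np.diff(cat)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [len(cat) - 1]))
    runs = [(int(s), int(e), int(cat[s])) for s, e in zip(starts, ends)]

    # absorb short 'neither' runs into the preceding (or following) block
    absorbed: list[tuple[int, int, int, tuple[str, ...]]] = []
    for s, e, c in runs:
        if c == 0 and (e - s + 1) < min_block:
            flag = (f"absorbed_unmatched:{s + 1}-{e + 1}",)
            if absorbed:
                ps, pe, pc, pf = absorbed[-1]
                absorbed[-1] = (ps, e, pc, pf + flag)
            else:
                absorbed.append((s, e, -1, flag))  # placeholder: join next block
            continue
        if absorbed and absorbed[-1][2] == -1:
            ps, pe, pc, pf = absorbed[-1]
            absorbed[-1] = (ps, e, c, pf)
        elif absorbed and absorbed[-1][2] == c:
            ps, pe, pc, pf = absorbed[-1]
            absorbed[-1] = (ps, e, c, pf)
        else:
            absorbed.append((s, e, c, ()))
    if absorbed and absorbed[-1][2] == -1:  # whole genome was one short unmatched run
        s, e, _, f = absorbed[-1]
        absorbed[-1] = (s, e, 0, f)

    origin_of = {0: "neither", 1: "A", 2: "B", 3: "both"}
    blocks = tuple(
        OriginBlock(start=s + 1, end=e + 1, origin=origin_of[c], flags=f)
        for s, e, c, f in absorbed
    )

    # crossover intervals: 'both' blocks whose nearest forced origins differ
    forced_idx = [i for i, b in enumerate(blocks) if b.origin in ("A", "B")]
    crossovers: list[tuple[int, int]] = []
    for i, b in enumerate(blocks):
        if b.origin != "both":
            continue
        prev_f = next((j for j in reversed(forced_idx) if j < i), None)
        next_f = next((j for j in forced_idx if j > i), None)
        if topology == "circular" and forced_idx:
            if prev_f is None:
                prev_f = forced_idx[-1]
            if next_f is None:
                next_f = forced_idx[0]
        if prev_f is None or next_f is None:
            continue
        if blocks[prev_f].origin != blocks[next_f].origin:
            crossovers.append((b.start, b.end))

    origins = [b.origin for b in blocks if b.origin in ("A", "B")]
    switches = _forced_switches(origins, topology)
    if topology == "circular":
        if switches % 2:
            raise ValueError(
                "odd switch count on a circular topology: impossible tiling"
            )
        events = switches // 2
    else:
        events = switches
    return MosaicSegmentation(
        hybrid_id=hybrid.id,
        blocks=blocks,
        crossover_intervals=tuple(crossovers),
        switches=switches,
        events=events,
        topology=topology,
    )


def count_events(seg: MosaicSegmentation, topology: str) -> int:
    """Recombination events implied by a segmentation under a topology."""
    if topology not in ("linear", "circular"):
        raise ValueError(f"bad topology {topology!r}")
    switches = _forced_switches(seg.origin_sequence(), topology)
    if topology == "linear":
        return switches
    if switches % 2:
        raise ValueError("odd switch count on a circular topology: impossible tiling")
    return switches // 2
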