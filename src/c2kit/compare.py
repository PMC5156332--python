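"""Pairwise identity statistics and variable-region localisation.

Small lytic lactococcal phage genomes (genus C2virus, ~22 kb) are nearly
identical along most of their length but carry a ~2-3 kb "variable region"
of late structural genes at roughly 50 % identity whose content decides
which host membrane receptor (Pip or YjaE) the phage requires.  This module
quantifies that structure: end-to-end identities, sliding-window identity
profiles along an alignment, region-restricted identities (nucleotide or
amino acid), and automatic localisation of the low-identity region.

Conventions (documented so full-scale comparisons can be reconciled):
identity = matching columns / total alignment columns x 100, with gap
columns counting against identity; percentages are reported raw and
formatted to one decimal with round-half-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .align import PairwiseAlignment, Scoring, align_pair
from .io import Genome

__all__ = [
    "IdentityResult",
    "IdentityProfile",
    "global_identity",
    "windowed_identity_profile",
    "region_identity",
    "mean_pairwise_identity",
    "find_variable_region",
    "format_percent",
]


def format_percent(x: float, ndigits: int = 1) -> str:
    """Round-half-up percent formatting (91.25 -> '91.3')."""
    q = Decimal(1).scaleb(-ndigits)
    return str(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class IdentityResult:
    matches: int
    aln_length: int

    def __post_init__(self) -> None:
        if self.aln_length <= 0 or not 0 <= self.matches <= self.aln_length:
            raise ValueError("invalid identity counts")

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.matches / self.aln_length

    def __str__(self) -> str:
        return f"{format_percent(self.pct_identity)} % ({self.matches}/{self.aln_length})"


@dataclass(frozen=True)
class IdentityProfile:
    """Sliding-window identity along sequence a of a pairwise alignment."""

    window: int
    step: int
    points: tuple[tuple[int, float], ...]  # (window centre on a, pct identity)

    def positions(self) -> np.ndarray:
        return np.array([p for p, _ in self.points])

    def identities(self) -> np.ndarray:
        return np.array([v for _, v in self.points])

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write("position\tidentity\n")
            for pos, pct in self.points:
                fh.write(f"{pos}\t{pct:.4f}\n")


def _as_seq(x: str | Genome) -> str:
    return x.seq if isinstance(x, Genome) else x


def global_identity(
    a: str | Genome,
    b: str | Genome,
    scoring: Scoring | None = None,
    method: str = "auto",
) -> IdentityResult:
    """End-to-end pairwise identity over alignment columns."""
    aln = align_pair(_as_seq(a), _as_seq(b), scoring=scoring, method=method)
    return IdentityResult(matches=aln.n_matches, aln_length=aln.n_columns)


def region_identity(
    a: str | Genome,
    b: str | Genome,
    region: tuple[int, int],
    alignment: PairwiseAlignment | None = None,
    scoring: Scoring | None = None,
) -> IdentityResult:
    """Identity over alignment columns anchored inside ``region`` of a.

    ``region`` is 1-based inclusive on sequence a.  A cached alignment of
    the same pair may be passed to avoid re-aligning.
    """
    a, b = _as_seq(a), _as_seq(b)
    start, end = region
    if start > end:
        raise ValueError("empty region")
    aln = alignment if alignment is not None else align_pair(a, b, scoring=scoring)
    mask = aln.region_mask(start, end)
    cols = int(mask.sum())
    if cols == 0:
        raise ValueError(f"no alignment columns fall in region {region}")
    return IdentityResult(matches=int(aln.match[mask].sum()), aln_length=cols)


def windowed_identity_profile(
    a: str | Genome,
    b: str | Genome,
    window: int = 500,
    step: int = 100,
    alignment: PairwiseAlignment | None = None,
) -> IdentityProfile:
    """Per-window identity computed on the columns of one global alignment.

    Windows are laid on sequence a; each window [s, s+window-1] scores the
    alignment columns anchored within it.  A window longer than the
    sequence collapses to a single whole-length point.
    """
    a, b = _as_seq(a), _as_seq(b)
    if window < 50:
        raise ValueError("window must be >= 50 nt")
    if step < 1:
        raise ValueError("step must be >= 1")
    aln = alignment if alignment is not None else align_pair(a, b)
    la = len(a)
    # per-a-position column and match counts, via the anchor convention
    anchor = aln.a_anchor
    cols_at = np.bincount(anchor, minlength=la + 1).astype(np.int64)
    match_at = np.bincount(anchor, weights=aln.match, minlength=la + 1).astype(np.int64)
    ccols = np.cumsum(cols_at)
    cmatch = np.cumsum(match_at)
    if window > la:
        pct = 100.0 * cmatch[la] / ccols[la]
        return IdentityProfile(window=window, step=step, points=((la // 2 + 1, pct),))
    starts = np.arange(1, la - window + 2, step)
    ends = starts + window - 1
    ncols = ccols[ends] - ccols[starts - 1]
    nmatch = cmatch[ends] - cmatch[starts - 1]
    with np.errstate(invalid="ignore"):
        pcts = np.where(ncols > 0, 100.0 * nmatch / np.maximum(ncols, 1), 100.0)
    centres = starts + window // 2
    points = tuple((int(c), float(p)) for c, p in zip(centres, pcts))
    return IdentityProfile(window=window, step=step, points=points)


def mean_pairwise_identity(
    seqs,
    region: tuple[int, int] | None = None,
    scoring: Scoring | None = None,
) -> float:
    """Arithmetic mean identity over all n(n-1)/2 pairs.

    With ``region`` set, each pairwise identity is restricted to that
    interval on the first sequence of the pair.
    """
    seqs = [_as_seq(s) for s in seqs]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    vals = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if region is None:
                vals.append(global_identity(seqs[i], seqs[j], scoring=scoring).pct_identity)
            else:
                vals.append(
                    region_identity(seqs[i], seqs[j], region, scoring=scoring).pct_identity
                )
    return float(np.mean(vals))


def find_variable_region(
    profile: IdentityProfile,
    drop_threshold: float | None = None,
) -> tuple[int, int] | None:
    """Locate the low-identity (variable) region from a windowed profile.

    Returns the interval on sequence a spanned by the maximal contiguous
    run of windows at or below ``drop_threshold`` that contains the global
    identity minimum, or None when no window qualifies.  The interval runs
    from the centre of the first qualifying window to the centre of the
    last, i.e. boundaries are resolved to about half a window.

    The default threshold is the profile mean minus 20 percentage points.
    """
    if not profile.points:
        raise ValueError("empty profile")
    ids = profile.identities()
    pos = profile.positions()
    if drop_threshold is None:
        drop_threshold = float(ids.mean()) - 20.0
    below = ids <= drop_threshold
    if not below.any():
        return None
    imin = int(np.argmin(ids))
    if not below[imin]:  # cannot happen: the minimum is always <= threshold if any is
        return None
    lo = imin
    while lo > 0 and below[lo - 1]:
        lo -= 1
    hi = imin
    while hi < len(ids) - 1 and below[hi + 1]:
        hi += 1
    return int(pos[lo]), int(pos[hi])


def plot_profile(profile: IdentityProfile, path, title: str = "") -> None:
    """Write a PNG of the identity profile (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    ax.plot(profile.positions(), profile.identities(), lw=1)
    ax.set_xlabel("position (nt)")
    ax.set_ylabel("% identity")
    ax.set_ylim(0, 102)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
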