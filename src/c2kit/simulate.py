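"""Synthetic C2virus-like data with known truth.

Every generator is a pure function of its parameters and seed and returns
a truth record alongside the data, so each analysis stage can be tested
against construction truth without downloading real genomes.

What is emulated, with defaults mirroring the studied cohort:

* pairs of ~22 kb colinear genomes, ~99.9 % identical along the backbone
  but ~52 % identical across a planted ~2.5 kb variable region holding
  three contiguous marker genes (the l14-l15-l16 vs ORF34-ORF35-ORF36
  analogue);
* hybrids spliced from two such parents at crossovers sampled inside
  exactly shared tracts (recombination between co-infecting phages);
* host receptor-gene mutants: nonsense substitutions, single-base
  frameshifts (homopolymer slippage), and ~1.2 kb IS-element-like
  insertions;
* Poisson plaque-count tables for EOP estimation at a given true EOP.

Divergence between parents is substitution-only (the real genomes are
colinear); generated coordinates are therefore shared between parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import STOP_CODONS, MutationCall
from .io import CdsRecord, Genome, reverse_complement

__all__ = [
    "CohortTruth",
    "HybridTruth",
    "generate_phage_pair",
    "generate_hybrid",
    "generate_host_mutant",
    "generate_plaque_data",
    "estimate_eop",
]

_BASES = np.array(list("ACGT"))

# codons that are neither stops nor create in-frame stops when concatenated
_SAFE_CODONS = [
    c1 + c2 + c3
    for c1 in "ACGT"
    for c2 in "ACGT"
    for c3 in "ACGT"
    if c1 + c2 + c3 not in STOP_CODONS
]


@dataclass(frozen=True)
class CohortTruth:
    """Construction truth for a synthetic parental genome pair."""

    seed: int
    genome_a: Genome
    genome_b: Genome
    cds_a: tuple[CdsRecord, ...]
    cds_b: tuple[CdsRecord, ...]
    variable_region: tuple[int, int]
    marker_names_a: tuple[str, str, str]
    marker_names_b: tuple[str, str, str]
    marker_references: dict[str, str]  # role -> nucleotide sequence
    realized_identity: dict[str, float]  # backbone / variable / overall, percent
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class HybridTruth:
    seed: int
    crossovers: tuple[int, ...]  # 1-based: switch takes effect AFTER this position
    segment_origins: tuple[str, ...]  # 'A'/'B' per spliced segment
    topology: str
    n_events: int


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_cds(rng: np.random.Generator, nt_length: int) -> str:
    """A stop-free CDS of the requested length: ATG + codons + TAA."""
    if nt_length % 3 or nt_length < 9:
        raise ValueError("CDS length must be a multiple of 3 and >= 9")
    n_mid = nt_length // 3 - 2
    mid = rng.integers(0, len(_SAFE_CODONS), size=n_mid)
    return "ATG" + "".join(_SAFE_CODONS[i] for i in mid) + "TAA"


def _mutate_positions(
    rng: np.random.Generator, arr: np.ndarray, mask: np.ndarray
) -> None:
    """Substitute masked positions with a uniformly different base, in place."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    shift = rng.integers(1, 4, size=idx.size)
    arr[idx] = _BASES[(np.searchsorted(_BASES, arr[idx]) + shift) % 4]


def _identity_pct(a: np.ndarray, b: np.ndarray) -> float:
    return 100.0 * float((a == b).mean())


def generate_phage_pair(
    length: int = 22000,
    backbone_identity: float = 99.9,
    var_region: tuple[int, int] = (17601, 20100),
    var_identity: float = 52.0,
    n_genes: int = 38,
    seed: int = 0,
) -> CohortTruth:
    """Generate two colinear phage-like genomes with a planted variable region.

    Genome A carries ``n_genes`` planted non-overlapping CDSs, three of
    which sit contiguously inside ``var_region`` as the c2-analogue
    markers (named l14/l15/l16).  Genome B is derived by per-site
    substitution: at a rate giving ``backbone_identity`` outside the
    variable region and ``var_identity`` inside it, which turns B's marker
    homologues into the bIL67-analogue set (ORF34/ORF35/ORF36) at roughly
    half identity.  Realized identities are recorded in the truth.
    """
    if not (0 < backbone_identity <= 100 and 0 < var_identity <= 100):
        raise ValueError("identities must be in (0, 100]")
    vs, ve = var_region
    if not (1 <= vs <= ve <= length):
        raise ValueError(f"variable region {var_region} outside genome of {length} nt")
    var_len = ve - vs + 1
    margin, gap = 12, 15
    avail = var_len - 2 * margin - 2 * gap
    if avail < 3 * 150:
        raise ValueError(f"variable region of {var_len} nt too small for 3 marker genes")
    rng = np.random.default_rng(seed)

    seq_a = np.array(list(_random_seq(rng, length)))
    cds_a: list[CdsRecord] = []

    # three contiguous marker genes inside the variable region
    third = avail // 3 // 3 * 3
    marker_lens = [third, third, (avail - 2 * third) // 3 * 3]
    cursor = vs + margin
    marker_names_a = ("l14", "l15", "l16")
    for name, glen in zip(marker_names_a, marker_lens):
        gene = _random_cds(rng, glen)
        seq_a[cursor - 1 : cursor - 1 + glen] = list(gene)
        cds_a.append(CdsRecord("synA", cursor, cursor + glen - 1, "+", gene_name=name))
        cursor += glen + gap

    # remaining genes packed outside the variable region
    n_other = n_genes - 3
    placed = 0
    for lo, hi in ((1, vs - 1), (ve + 1, length)):
        cursor = lo + int(rng.integers(2, 40))
        while placed < n_other:
            glen = int(rng.integers(80, 281)) * 3  # 240-840 nt
            if cursor + glen - 1 > hi - 2:
                break
            strand = "+" if rng.random() < 0.8 else "-"
            gene = _random_cds(rng, glen)
            planted = gene if strand == "+" else reverse_complement(gene)
            seq_a[cursor - 1 : cursor - 1 + glen] = list(planted)
            placed += 1
            cds_a.append(
                CdsRecord("synA", cursor, cursor + glen - 1, strand,
                          gene_name=f"g{placed:02d}")
            )
            cursor += glen + int(rng.integers(2, 31))

    # genome B: per-site substitution at region-specific rates
    seq_b = seq_a.copy()
    u = rng.random(length)
    in_var = np.zeros(length, dtype=bool)
    in_var[vs - 1 : ve] = True
    p_back = 1.0 - backbone_identity / 100.0
    p_var = 1.0 - var_identity / 100.0
    mask = (u < p_back) & ~in_var | (u < p_var) & in_var
    _mutate_positions(rng, seq_b, mask)

    marker_names_b = ("ORF34", "ORF35", "ORF36")
    cds_b = [
        CdsRecord(
            "synB", r.start, r.end, r.strand,
            gene_name=(marker_names_b[marker_names_a.index(r.gene_name)]
                       if r.gene_name in marker_names_a else r.gene_name),
        )
        for r in cds_a
    ]

    str_a, str_b = "".join(seq_a), "".join(seq_b)
    genome_a = Genome("synA", str_a)
    genome_b = Genome("synB", str_b)
    refs: dict[str, str] = {}
    for rec_a, rec_b in zip(cds_a, cds_b):
        if rec_a.gene_name in marker_names_a:
            refs[rec_a.gene_name] = str_a[rec_a.start - 1 : rec_a.end]
            refs[rec_b.gene_name] = str_b[rec_b.start - 1 : rec_b.end]

    realized = {
        "backbone": _identity_pct(seq_a[~in_var], seq_b[~in_var]),
        "variable": _identity_pct(seq_a[in_var], seq_b[in_var]),
        "overall": _identity_pct(seq_a, seq_b),
    }
    return CohortTruth(
        seed=seed,
        genome_a=genome_a,
        genome_b=genome_b,
        cds_a=tuple(cds_a),
        cds_b=tuple(cds_b),
        variable_region=var_region,
        marker_names_a=marker_names_a,
        marker_names_b=marker_names_b,
        marker_references=refs,
        realized_identity=realized,
        params={
            "length": length,
            "backbone_identity": backbone_identity,
            "var_identity": var_identity,
            "n_genes": n_genes,
            "n_genes_placed": placed + 3,
        },
    )


def shared_tracts(parentA: Genome, parentB: Genome, min_len: int = 100) -> list[tuple[int, int]]:
    """1-based inclusive intervals where the (equal-length) parents agree
    exactly for at least ``min_len`` nt."""
    if parentA.length != parentB.length:
        raise ValueError("parents must have equal length (colinear, substitution-only)")
    a = np.frombuffer(parentA.seq.encode(), dtype=np.uint8)
    b = np.frombuffer(parentB.seq.encode(), dtype=np.uint8)
    eq = (a == b) & (a != ord("N"))
    padded = np.concatenate(([False], eq, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [
        (int(s) + 1, int(e))
        for s, e in zip(edges[::2], edges[1::2])
        if e - s >= min_len
    ]


def generate_hybrid(
    parentA: Genome,
    parentB: Genome,
    n_events: int,
    topology: str = "circular",
    seed: int = 0,
    min_tract: int = 100,
    hybrid_id: str | None = None,
) -> tuple[Genome, HybridTruth]:
    """Splice a hybrid from two parents at crossovers inside shared tracts.

    On a circular map one recombination event is a reciprocal pair of
    crossovers, so ``n_events`` events place ``2*n_events`` crossovers on
    the linear representation; on a linear map, ``n_events`` crossovers.
    Crossovers land in DISTINCT shared tracts, each with a 25 nt margin
    inside its tract; because maximal shared tracts are separated by at
    least one parent-discriminating site, every spliced segment then
    carries evidence of its origin.
    """
    if topology not in ("linear", "circular"):
        raise ValueError(f"bad topology {topology!r}")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    rng = np.random.default_rng(seed)
    hid = hybrid_id or f"hybrid-{seed}"
    if n_events == 0:
        return Genome(hid, parentA.seq), HybridTruth(seed, (), ("A",), topology, 0)
    n_cross = n_events if topology == "linear" else 2 * n_events
    margin = 25
    # terminal tracts are excluded: a crossover there leaves the segment
    # wrapping the map origin without any parent-discriminating site, so
    # no analysis could localise it even in principle
    tracts = [
        (s, e)
        for s, e in shared_tracts(parentA, parentB, min_len=min_tract)
        if e - margin >= s + margin and s > 1 and e < parentA.length
    ]
    if len(tracts) < n_cross:
        raise ValueError("parents share too few identical tracts for the crossovers")
    which = rng.choice(len(tracts), size=n_cross, replace=False)
    pick = np.sort(
        np.array([int(rng.integers(tracts[t][0] + margin, tracts[t][1] - margin + 1))
                  for t in which])
    )
    crossovers = tuple(int(p) for p in pick)
    first = "A" if rng.integers(2) == 0 else "B"
    origins = tuple(
        (first if i % 2 == 0 else ("B" if first == "A" else "A"))
        for i in range(n_cross + 1)
    )
    bounds = (0,) + crossovers + (parentA.length,)
    parts = []
    for i, origin in enumerate(origins):
        src = parentA.seq if origin == "A" else parentB.seq
        parts.append(src[bounds[i] : bounds[i + 1]])
    return Genome(hid, "".join(parts)), HybridTruth(
        seed, crossovers, origins, topology, n_events
    )


def _leftmost_indel(longer: str, i: int, d: int) -> int:
    """Leftmost equivalent placement of a d-nt indel at 0-based index i."""
    while i > 0 and longer[i - 1] == longer[i + d - 1]:
        i -= 1
    return i


def generate_host_mutant(
    wt_gene: str,
    mtype: str,
    seed: int = 0,
    element_length: int | None = None,
) -> tuple[str, MutationCall]:
    """Introduce one receptor-gene mutation of the requested class.

    mtype is one of nonsense, frameshift_ins, frameshift_del,
    element_insertion.  The returned truth is leftmost-normalised, the
    same convention the classifier reports.
    """
    rng = np.random.default_rng(seed)
    wt = wt_gene.upper()
    n = len(wt)
    if n < 12 or n % 3:
        raise ValueError("wild-type gene must be a CDS of >= 12 nt")
    n_codons = n // 3

    if mtype == "nonsense":
        candidates = []
        for c in range(1, n_codons - 1):  # skip start codon and terminal stop
            codon = wt[3 * c : 3 * c + 3]
            if codon in STOP_CODONS:
                continue
            for off in range(3):
                for base in "ACGT":
                    if base == codon[off]:
                        continue
                    new = codon[:off] + base + codon[off + 1 :]
                    if new in STOP_CODONS:
                        candidates.append((3 * c + off, base))
        if not candidates:
            raise ValueError("no single-substitution nonsense site in this gene")
        pos0, base = candidates[int(rng.integers(len(candidates)))]
        mut = wt[:pos0] + base + wt[pos0 + 1 :]
        truth = MutationCall(
            "substitution", "nonsense", pos0 + 1, f"{wt[pos0]}>{base}"
        )
        return mut, truth

    if mtype == "frameshift_ins":
        i0 = int(rng.integers(3, n - 3))
        base = "ACGT"[int(rng.integers(4))]
        mut = wt[:i0] + base + wt[i0:]
        i = _leftmost_indel(mut, i0, 1)
        return mut, MutationCall("insertion", "frameshift", i + 1, f"+{mut[i]}")

    if mtype == "frameshift_del":
        i0 = int(rng.integers(3, n - 3))
        mut = wt[:i0] + wt[i0 + 1 :]
        i = _leftmost_indel(wt, i0, 1)
        return mut, MutationCall("deletion", "frameshift", i + 1, f"Δ{wt[i]}")

    if mtype == "element_insertion":
        d = int(element_length if element_length is not None else rng.integers(900, 1500))
        if d < 50:
            raise ValueError("element insertions are >= 50 nt by definition")
        elem = _random_seq(rng, d)
        i0 = int(rng.integers(3, n - 3))
        mut = wt[:i0] + elem + wt[i0:]
        i = _leftmost_indel(mut, i0, d)
        consequence = "frameshift" if d % 3 else "in_frame_indel"
        return mut, MutationCall("element_insertion", consequence, i + 1, f"+{d}nt")

    raise ValueError(f"unknown mutation type {mtype!r}")


def generate_plaque_data(
    true_eop: float,
    ref_titer: float = 1e9,
    dilutions: tuple[float, ...] = (1e-7, 1e-5, 1e-3, 1e-1, 1.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Poisson plaque counts for a test and a reference host.

    ``dilutions`` are fractions of the lysate plated (1.0 = undiluted);
    the reference host sees the full titer, the test host ``true_eop``
    times it.  Returns a tidy table (host_role, dilution, count) plus the
    truth record.
    """
    if ref_titer <= 0:
        raise ValueError("titer must be > 0")
    if true_eop < 0:
        raise ValueError("true EOP must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for role, titer in (("ref", ref_titer), ("test", ref_titer * true_eop)):
        for dil in dilutions:
            lam = titer * dil
            count = int(rng.poisson(lam)) if lam > 0 else 0
            rows.append({"host_role": role, "dilution": dil, "count": count})
    df = pd.DataFrame(rows)
    truth = {"true_eop": true_eop, "ref_titer": ref_titer, "seed": seed}
    return df, truth


def _pick_countable(sub: pd.DataFrame) -> tuple[int, float] | None:
    """Pick (count, dilution): the largest count not above 300, else the
    smallest positive count; None when all counts are zero."""
    nonzero = sub[sub["count"] > 0]
    if nonzero.empty:
        return None
    countable = nonzero[nonzero["count"] <= 300]
    row = (countable.loc[countable["count"].idxmax()]
           if not countable.empty else nonzero.loc[nonzero["count"].idxmin()])
    return int(row["count"]), float(row["dilution"])


def estimate_eop(df: pd.DataFrame, **kwargs):
    """Estimate EOP from a generate_plaque_data-style count table."""
    from .phenotype import compute_eop

    ref = _pick_countable(df[df["host_role"] == "ref"])
    if ref is None:
        raise ValueError("no reference titer: all reference counts are zero")
    test = _pick_countable(df[df["host_role"] == "test"])
    if test is None:
        # no plaques at any dilution: bound from the largest volume plated
        dil = float(df[df["host_role"] == "test"]["dilution"].max())
        return compute_eop(0, dil, ref[0], ref[1], **kwargs)
    return compute_eop(test[0], test[1], ref[0], ref[1], **kwargs)
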