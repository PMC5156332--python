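"""Gene-family clustering and marker-based phage typing.

C2virus genomes are typed by the content of their variable region: phages
carrying homologues of the c2 genes l14-l15-l16 require the host membrane
protein Pip (c2-type); phages carrying the bIL67 genes ORF34-ORF35-ORF36
require YjaE (bIL67-type).  CDSs are grouped into gene families by
single-linkage clustering at a nucleotide identity and mutual-coverage
cutoff (80 % / 80 % by default), families are assigned marker roles by
comparison with reference marker CDSs, and genomes are typed from the
marker roles they carry.

The ORF35 slot is special: genuine ORF35 homologues can sit below the
80 % identity cutoff.  Such families are flagged (``below_cutoff_homolog``)
rather than silently dropped, but receive no role.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

from .align import Scoring, align_pair
from .io import CdsRecord

__all__ = [
    "GeneFamily",
    "PhageTypeCall",
    "C2_MARKERS",
    "BIL67_MARKERS",
    "MARKER_SLOTS",
    "cluster_gene_families",
    "assign_marker_roles",
    "type_phage",
]

C2_MARKERS = ("l14", "l15", "l16")
BIL67_MARKERS = ("ORF34", "ORF35", "ORF36")

#: positionally equivalent marker pairs (same slot in the variable region)
MARKER_SLOTS = {
    "l14": 1, "ORF34": 1,
    "l15": 2, "ORF35": 2,
    "l16": 3, "ORF36": 3,
}

#: best-hit identity at or above this (but under the cutoff) raises a
#: below_cutoff_homolog flag instead of an assignment
HOMOLOG_FLOOR_PCT = 50.0


@dataclass
class GeneFamily:
    family_id: str
    members: list[tuple[CdsRecord, str]]  # (record, nucleotide sequence)
    marker_role: str | None = None
    role_evidence: dict = field(default_factory=dict)  # role -> (identity, coverage)
    flags: list[str] = field(default_factory=list)

    @property
    def genome_ids(self) -> set[str]:
        return {rec.genome_id for rec, _ in self.members}


@dataclass(frozen=True)
class PhageTypeCall:
    genome_id: str
    ptype: str  # c2_type | bIL67_type | untyped | conflict
    evidence: tuple[tuple[str, float, float], ...]  # (marker_role, identity, coverage)


def _identity_upper_bound(sa: str, sb: str) -> float:
    """Admissible upper bound on alignment identity, from the unit-cost edit
    distance: any alignment has matches <= min(len) and mismatch+gap columns
    >= the minimal edit distance, so identity <= min/(min+ed).  Lets the
    all-pairs clustering skip alignments that cannot reach the cutoff."""
    ed = edlib.align(sa, sb, mode="NW", task="distance")["editDistance"]
    mn = min(len(sa), len(sb))
    return 100.0 * mn / (mn + ed) if ed > 0 else 100.0


def _pair_identity_coverage(sa: str, sb: str, scoring: Scoring | None = None):
    """(pct identity, pct coverage of a, pct coverage of b) from one alignment."""
    aln = align_pair(sa, sb, scoring=scoring)
    both = (aln.a_pos > 0) & (aln.b_pos > 0)
    n_both = int(both.sum())
    ident = 100.0 * aln.n_matches / aln.n_columns
    return ident, 100.0 * n_both / len(sa), 100.0 * n_both / len(sb)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _member_key(rec: CdsRecord) -> tuple:
    return (rec.genome_id, rec.start, rec.end, rec.strand)


def cluster_gene_families(
    genes: Iterable[tuple[CdsRecord, str]],
    id_threshold: float = 80.0,
    cov_threshold: float = 80.0,
    scoring: Scoring | None = None,
) -> list[GeneFamily]:
    """Single-linkage clustering of CDSs into gene families.

    An edge joins two CDSs iff their global nucleotide identity is at
    least ``id_threshold`` AND the aligned span covers at least
    ``cov_threshold`` percent of BOTH genes.  The partition is therefore
    independent of input order; family ids are derived from the sorted
    member list.  Singletons form their own family.
    """
    items = sorted(genes, key=lambda g: _member_key(g[0]))
    n = len(items)
    uf = _UnionFind(n)
    for i in range(n):
        li = len(items[i][1])
        for j in range(i + 1, n):
            lj = len(items[j][1])
            # a pair failing mutual coverage on length alone cannot join
            if 100.0 * min(li, lj) / max(li, lj) < cov_threshold:
                continue
            if uf.find(i) == uf.find(j):
                continue
            if _identity_upper_bound(items[i][1], items[j][1]) < id_threshold:
                continue
            ident, cov_a, cov_b = _pair_identity_coverage(
                items[i][1], items[j][1], scoring
            )
            if ident >= id_threshold and cov_a >= cov_threshold and cov_b >= cov_threshold:
                uf.union(i, j)
    groups: dict[int, list[tuple[CdsRecord, str]]] = {}
    for idx, item in enumerate(items):
        groups.setdefault(uf.find(idx), []).append(item)
    families = []
    ordered = sorted(groups.values(), key=lambda ms: _member_key(ms[0][0]))
    width = max(3, len(str(len(ordered))))
    for k, members in enumerate(ordered, start=1):
        families.append(GeneFamily(family_id=f"fam{k:0{width}d}", members=members))
    return families


def assign_marker_roles(
    families: Sequence[GeneFamily],
    references: Mapping[str, str],
    id_threshold: float = 80.0,
    cov_threshold: float = 80.0,
    homolog_floor: float = HOMOLOG_FLOOR_PCT,
    scoring: Scoring | None = None,
) -> list[GeneFamily]:
    """Assign variable-region marker roles to families by best reference hit.

    ``references`` maps role names (l14..l16, ORF34..ORF36) to reference
    CDS nucleotide sequences.  A family receives role R iff its best
    member-vs-reference identity is >= id_threshold with coverage >=
    cov_threshold on both sides; ties break by higher coverage then
    lexicographic role.  A family whose best hit for some role lands in
    [homolog_floor, id_threshold) is flagged ``below_cutoff_homolog:<role>``.
    When two roles of the SAME positional slot qualify, the higher-identity
    role wins and the family is flagged ``slot_conflict``.
    """
    unknown = set(references) - set(MARKER_SLOTS)
    if unknown:
        raise ValueError(f"unknown marker roles {sorted(unknown)}")
    for fam in families:
        hits: dict[str, tuple[float, float]] = {}
        near: dict[str, float] = {}
        for role, ref_seq in references.items():
            best: tuple[float, float] | None = None
            best_near = 0.0
            for _, seq in fam.members:
                if 100.0 * min(len(seq), len(ref_seq)) / max(len(seq), len(ref_seq)) \
                        < cov_threshold:
                    continue
                if _identity_upper_bound(seq, ref_seq) < homolog_floor:
                    continue
                ident, cov_a, cov_b = _pair_identity_coverage(seq, ref_seq, scoring)
                cov = min(cov_a, cov_b)
                if cov < cov_threshold:
                    continue
                if ident >= id_threshold:
                    if best is None or (ident, cov) > best:
                        best = (ident, cov)
                elif ident >= homolog_floor:
                    best_near = max(best_near, ident)
            if best is not None:
                hits[role] = best
            elif best_near > 0.0:
                near[role] = best_near
        fam.role_evidence = dict(hits)
        if hits:
            role = max(hits, key=lambda r: (hits[r][0], hits[r][1], r))
            slots = {MARKER_SLOTS[r] for r in hits}
            if len(hits) > 1 and len(slots) < len(hits):
                fam.flags.append("slot_conflict")
            fam.marker_role = role
        else:
            fam.marker_role = None
            for role, ident in sorted(near.items()):
                fam.flags.append(f"below_cutoff_homolog:{role}")
    return list(families)


def type_phage(
    genome_id: str,
    families: Sequence[GeneFamily],
    strict: bool = False,
) -> PhageTypeCall:
    """Type a genome from the marker roles of the families it belongs to.

    c2_type requires at least one of l14/l15/l16 and none of
    ORF34/ORF35/ORF36 (symmetrically for bIL67_type); both kinds of
    evidence give ``conflict``, neither gives ``untyped``.  With
    ``strict=True`` all three markers of a set are required.
    """
    evidence = []
    for fam in families:
        if fam.marker_role is None or genome_id not in fam.genome_ids:
            continue
        ident, cov = fam.role_evidence[fam.marker_role]
        evidence.append((fam.marker_role, ident, cov))
    roles = {e[0] for e in evidence}
    c2_hits = roles & set(C2_MARKERS)
    b67_hits = roles & set(BIL67_MARKERS)
    need = 3 if strict else 1
    if c2_hits and b67_hits:
        ptype = "conflict"
    elif len(c2_hits) >= need and not b67_hits:
        ptype = "c2_type"
    elif len(b67_hits) >= need and not c2_hits:
        ptype = "bIL67_type"
    else:
        ptype = "untyped"
    return PhageTypeCall(
        genome_id=genome_id,
        ptype=ptype,
        evidence=tuple(sorted(evidence)),
    )
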