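"""ORF calling, translation and mutation-consequence prediction.

Implements the arithmetic used when characterising bacteriophage-
insensitive mutants (BIMs) of *Lactococcus lactis*: receptor genes (pip,
yjaE) knocked out by single-base substitutions creating premature stops,
frameshifting single-base indels (typically inside homopolymer runs), or
insertion-sequence (IS-element) integration.  Translation uses the
bacterial/plastid genetic code (table 11) with the alternative start
codons common in phage and bacterial genomes (ATG/GTG/TTG), all of which
translate as methionine in the initiator position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.Data import CodonTable

from .io import CdsRecord, Genome, reverse_complement

__all__ = [
    "DEFAULT_START_CODONS",
    "PrematureStopError",
    "MutationCall",
    "TruncationResult",
    "call_orfs",
    "translate_cds",
    "classify_mutation",
    "predict_truncation",
]

DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})

#: inserted segments at least this long are called IS-element-like
ELEMENT_INSERTION_MIN_NT = 50

_TABLE = CodonTable.unambiguous_dna_by_id[11]
_FORWARD = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)


class PrematureStopError(ValueError):
    """An internal stop codon; carries the 1-based codon index."""

    def __init__(self, codon_index: int):
        super().__init__(f"premature stop at codon {codon_index}")
        self.codon_index = codon_index


@dataclass(frozen=True)
class MutationCall:
    """A single wild-type vs mutant gene difference, leftmost-normalised."""

    mclass: str  # substitution | insertion | deletion | element_insertion
    consequence: str  # synonymous | missense | nonsense | frameshift | in_frame_indel
    position: int  # 1-based nt in the wild-type gene
    detail: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("mutation position must be >= 1")
        if self.consequence == "nonsense" and self.mclass != "substitution":
            raise ValueError("nonsense calls require a substitution")


@dataclass(frozen=True)
class TruncationResult:
    stop_codon_index: int  # 1-based codon number of the new stop
    truncated_length: int  # amino acids in the truncated product
    mechanism: str  # nonsense | frameshift


def _codon_aa(codon: str) -> str | None:
    """Amino acid for a codon, '*' for stop, None for ambiguous codons."""
    if codon in STOP_CODONS:
        return "*"
    return _FORWARD.get(codon)


def translate_cds(
    cds_seq: str,
    start_codons: frozenset[str] = DEFAULT_START_CODONS,
    require_start: bool = True,
) -> str:
    """Translate a CDS with genetic code 11.

    Alternative starts translate as M; a terminal stop is dropped from the
    product; an internal stop raises PrematureStopError with the codon
    index.
    """
    if len(cds_seq) % 3 != 0:
        raise ValueError(f"CDS length {len(cds_seq)} not divisible by 3")
    cds_seq = cds_seq.upper()
    first = cds_seq[:3]
    if require_start and first not in start_codons:
        raise ValueError(f"invalid start codon {first!r}")
    n_codons = len(cds_seq) // 3
    aa = []
    for c in range(n_codons):
        codon = cds_seq[3 * c : 3 * c + 3]
        res = _codon_aa(codon)
        if res == "*":
            if c == n_codons - 1:
                break  # terminal stop, not part of the product
            raise PrematureStopError(c + 1)
        aa.append("M" if c == 0 else (res or "X"))
    return "".join(aa)


def _orfs_one_strand(seq: str, min_codons: int, start_codons: frozenset[str]):
    """Yield (start0, end0) maximal ORFs on the given sequence, 0-based incl."""
    n = len(seq)
    for frame in range(3):
        last_stop_end = frame  # scan boundary: first codon start after previous stop
        pending_start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if pending_start is not None:
                    n_codons = (pos + 3 - pending_start) // 3
                    if n_codons >= min_codons:
                        yield pending_start, pos + 2
                pending_start = None
                last_stop_end = pos + 3
            elif pending_start is None and codon in start_codons:
                pending_start = pos
        # ORFs running off the end without a stop are not called


def call_orfs(
    genome: Genome,
    min_codons: int = 25,
    start_codons: frozenset[str] = DEFAULT_START_CODONS,
) -> list[CdsRecord]:
    """Call all maximal ORFs (leftmost start to in-frame stop) on both strands.

    ``min_codons`` counts the stop codon.  Coordinates are always reported
    on the forward strand, 1-based inclusive, sorted by start.
    """
    if min_codons < 2:
        raise ValueError("min_codons must be >= 2")
    L = genome.length
    records = []
    for strand, seq in (("+", genome.seq), ("-", reverse_complement(genome.seq))):
        for s0, e0 in _orfs_one_strand(seq, min_codons, start_codons):
            if strand == "+":
                start, end = s0 + 1, e0 + 1
            else:
                start, end = L - e0, L - s0
            protein = translate_cds(seq[s0 : e0 + 1], start_codons=start_codons)
            records.append(
                CdsRecord(
                    genome_id=genome.id,
                    start=start,
                    end=end,
                    strand=strand,
                    protein=protein,
                )
            )
    records.sort(key=lambda r: (r.start, r.end, r.strand))
    return records


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _lcs(a: str, b: str, max_len: int) -> int:
    i = 0
    while i < max_len and a[len(a) - 1 - i] == b[len(b) - 1 - i]:
        i += 1
    return i


def _indel_detail(prefix: str, seg: str) -> str:
    if len(seg) <= 10:
        return prefix + seg
    return f"{prefix}{len(seg)}nt"


def classify_mutation(wt: str, mut: str) -> MutationCall:
    """Classify the single contiguous difference between wild-type and mutant.

    Substitutions are classified by comparing translations (synonymous /
    missense / nonsense); indels by frame arithmetic (length mod 3);
    insertions of >= 50 nt are called element insertions (IS-like).  Indel
    positions inside repeat runs are normalised to the LEFTMOST equivalent
    placement, matching how receptor-gene homopolymer deletions are
    conventionally reported.
    """
    if not wt or not mut:
        raise ValueError("sequences must be non-empty")
    wt, mut = wt.upper(), mut.upper()
    if wt == mut:
        raise ValueError("no mutation: sequences are identical")

    if len(wt) == len(mut):
        diffs = [i for i in range(len(wt)) if wt[i] != mut[i]]
        first, last = diffs[0], diffs[-1]
        if last - first + 1 != len(diffs):
            loci = ", ".join(str(i + 1) for i in diffs[:10])
            raise ValueError(f"multiple separated differences at nt {loci}")
        wseg, mseg = wt[first : last + 1], mut[first : last + 1]
        detail = f"{wseg}>{mseg}"
        consequence = _substitution_consequence(wt, mut, first)
        return MutationCall("substitution", consequence, first + 1, detail)

    # length difference: locate the indel by longest common prefix/suffix
    if len(wt) > len(mut):
        longer, shorter, mclass = wt, mut, "deletion"
    else:
        longer, shorter, mclass = mut, wt, "insertion"
    d = len(longer) - len(shorter)
    p = _lcp(longer, shorter)
    s = _lcs(longer, shorter, min(len(shorter) - p, len(longer) - p - d))
    if p + s < len(shorter):
        raise ValueError("more than one difference between the sequences")
    # indel segment sits at 0-based [i, i+d) in the longer sequence
    i = len(longer) - s - d
    if i > p:
        i = p
    # leftmost normalisation within repeat runs
    while i > 0 and longer[i - 1] == longer[i + d - 1]:
        i -= 1
    seg = longer[i : i + d]
    if mclass == "insertion" and d >= ELEMENT_INSERTION_MIN_NT:
        mclass = "element_insertion"
    consequence = "frameshift" if d % 3 else "in_frame_indel"
    if mclass == "deletion":
        detail = _indel_detail("Δ", seg)
    else:
        detail = _indel_detail("+", seg)
    return MutationCall(mclass, consequence, i + 1, detail)


def _substitution_consequence(wt: str, mut: str, first_diff0: int) -> str:
    """Compare translations codon-by-codon over the substituted span."""
    nonsense = False
    changed = False
    n_codons = min(len(wt), len(mut)) // 3
    c0 = first_diff0 // 3
    for c in range(c0, n_codons):
        wc = wt[3 * c : 3 * c + 3]
        mc = mut[3 * c : 3 * c + 3]
        if wc == mc:
            continue
        w_aa, m_aa = _codon_aa(wc), _codon_aa(mc)
        if m_aa == "*" and w_aa != "*":
            nonsense = True
            break
        if w_aa != m_aa:
            changed = True
    # substitutions in a trailing partial codon (non-CDS input) count as missense
    if not nonsense and len(wt) % 3 and first_diff0 >= 3 * n_codons:
        changed = True
    if nonsense:
        return "nonsense"
    return "missense" if changed else "synonymous"


def predict_truncation(
    mutation: MutationCall,
    cds_length: int | None = None,
    mutated_seq: str | None = None,
) -> TruncationResult:
    """Predict the truncated protein produced by a nonsense or frameshift
    mutation in a CDS.

    Nonsense: the new stop lands in codon ceil(position / 3), so the product
    keeps ceil(position/3) - 1 residues.  Frameshift: the mutated sequence is
    translated codon-by-codon from the original start to the first stop.
    """
    if mutation.consequence == "nonsense":
        if cds_length is None:
            raise ValueError("cds_length required for nonsense truncation")
        if mutation.position > cds_length:
            raise ValueError("mutation position beyond CDS length")
        if mutated_seq is not None:
            c = (mutation.position + 2) // 3
            codon = mutated_seq[3 * (c - 1) : 3 * c].upper()
            if codon not in STOP_CODONS:
                raise ValueError(
                    f"substitution at nt {mutation.position} does not create a stop "
                    f"codon in the supplied context (codon {c} is {codon!r})"
                )
        stop_idx = math.ceil(mutation.position / 3)
        return TruncationResult(stop_idx, stop_idx - 1, "nonsense")
    if mutation.consequence == "frameshift":
        if mutated_seq is None:
            raise ValueError("mutated_seq required for frameshift truncation")
        seq = mutated_seq.upper()
        n_codons = len(seq) // 3
        for c in range(n_codons):
            if seq[3 * c : 3 * c + 3] in STOP_CODONS:
                return TruncationResult(c + 1, c, "frameshift")
        raise ValueError("no stop codon reached in mutated sequence")
    raise ValueError(f"no truncation model for consequence {mutation.consequence!r}")
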