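# Methods

This note records the models, conventions and design choices behind
`c2kit`, in the order the pipeline uses them.

## Coordinates and sequence conventions

All coordinates are 1-based and inclusive on the forward strand, so block
and gene positions can be read directly against published genome
coordinates.  FASTA input is uppercased, `U` becomes `T`, IUPAC ambiguity
codes collapse to `N`, and anything else is rejected with its position.
`N` never matches anything in any comparison — not even another `N` — so
exact-match blocks are N-free by construction.  Genomes default to linear
topology; only recombination-event counting interprets the circular flag.

## Pairwise alignment and identity

Identity is matching columns over total columns of one end-to-end global
alignment; gap columns count against identity.  Scoring defaults to match
+1, mismatch −2, gap open −5, gap extend −1 (a gap of length *g* costs
5 + *g*).  Because co-optimal alignments can disagree on match counts, the
aligner maximises (score, matches) lexicographically; the reported
identity is therefore deterministic and testable against an independent
full-matrix oracle.

Three engines sit behind `align_pair`:

* **gotoh** — exact full-matrix affine DP (numba-compiled), used up to a
  few million cells and whenever custom scoring is requested;
* **anchored** — for genome-scale DNA: maximal exact shared runs ≥ 21 nt
  are chained colinearly (highest-coverage non-overlapping chain) and only
  inter-anchor stretches are Gotoh-aligned.  This matches how near-colinear
  phage genomes are compared in practice and keeps a 22 kb × 22 kb
  comparison under a second;
* **edlib** — unit-cost edit alignment, the fallback for oversized
  anchor-free chunks only.

A caveat the tests encode explicitly: in a ~50 %-identity segment, *any*
optimal alignment finds spurious local co-linearity, so alignment-column
identity runs above the generating per-site substitution identity — by
about +1.5 to +2.5 points under the affine defaults (and considerably more
under unit costs, one reason edlib is not used for primary identity).
Region-identity checks against generator truth therefore use a one-sided
tolerance of +3 points in the variable region, while backbone and overall
identities reproduce truth within 0.2.

Region-restricted identity assigns each alignment column an anchor
coordinate on the first sequence (gap-in-a columns inherit the last
consumed position) and scores the columns anchored inside the region; the
windowed profile is the same computation on a sliding window (defaults
500 nt window, 100 nt step, chosen so a ~2.5 kb variable region spans ~20
windows).

## Variable-region localisation

The call is the maximal contiguous run of windows at or below a drop
threshold (default: profile mean − 20 points) that contains the global
minimum; no qualifying window returns an explicit no-region result.  The
reported interval spans the *centres* of the first and last qualifying
windows.  Window spans would systematically over-extend each boundary by
about half a window (a window qualifies once roughly half of it is
divergent), whereas centre spans recover planted regions with ≥ 90 %
reciprocal overlap; boundary resolution is thus about half a window, and
a gene-span mode (type the markers, take their span) is available through
the typing stage when annotations exist.

## ORFs, translation and mutation consequences

ORF calling walks codons in all six frames (genetic code 11), opening at
ATG/GTG/TTG — GTG starts occur in real C2virus genes — and reports maximal
ORFs (leftmost start to in-frame stop, default ≥ 25 codons including the
stop, configurable because small C2virus genes exist).  ORFs running off
the sequence end, and ORFs wrapping a circular origin, are not called.
Alternative starts translate as Met; an internal stop raises an error
carrying the codon index, which doubles as the truncation position for
mutant genes.

`classify_mutation` assumes one contiguous difference (anything else is an
error listing the loci).  Substitutions are classified by comparing
translations over the affected codons (synonymous / missense / nonsense);
indels by length mod 3 (frameshift vs in-frame); insertions ≥ 50 nt are
called `element_insertion` — the threshold separates IS-element
integrations (~1.2 kb) from slippage indels.  Indel positions are
normalised to the **leftmost** equivalent placement, the convention used
when reporting a deletion "within" a homopolymer run by the run's start.
Truncation arithmetic: a nonsense at nucleotide *p* stops translation in
codon ⌈*p*/3⌉ leaving ⌈*p*/3⌉ − 1 residues; frameshifts are resolved by
directly translating the mutated sequence to its first stop.

## Gene families and typing

Single-linkage clustering over the graph whose edges join CDS pairs with
≥ 80 % nucleotide identity *and* ≥ 80 % aligned coverage of both genes
(coverage = columns where both sequences have a residue, over gene
length).  Single linkage is the simplest reproducible reading of a
published-style "80 % cutoff" family assignment that was originally
manually curated; the threshold is a parameter.  An admissible prescreen
(identity ≤ min-length/(min-length + edit distance)) skips pairs that
cannot reach the cutoff; it never changes the partition, only the runtime.
Family ids derive from the sorted member list, so the partition and its
labels are invariant to input order.

Marker roles (l14/l15/l16 vs ORF34/ORF35/ORF36) come from the best
family-member-vs-reference hit at the same cutoffs, ties broken by
coverage then role name.  Hits landing in [50, 80) % set a
`below_cutoff_homolog` flag instead of a role — genuine ORF35-slot
homologues can sit below the cutoff and silently dropping them would be
misleading.  Typing requires at least one marker of a set and none of the
other (both sets → conflict; `strict=True` demands all three, for cohorts
where marker sets are known to travel together).

## Mosaic segmentation and event counting

A hybrid position is assigned to a parent when it lies inside a maximal
exact forward-strand match of length ≥ k (default 21 — effectively unique
in a 22 kb genome; forward-only because C2virus recombinants are
colinear).  Exact matching, rather than probabilistic painting, is the
right tool here because real hybrid blocks are reported at 100 %
identity.  The four per-position states (A-only, B-only, both, neither)
are run-length encoded; `neither` runs shorter than 50 nt are absorbed
into the preceding block and flagged.  `both` runs are kept as explicit
blocks: they are the crossover-ambiguity intervals, and the paper-style
overlapping "maximal match" coordinates are reported alongside the
abutting tiling (`maximal_parent_matches`).

The origin sequence of forced (A/B) blocks realises the minimum number of
switches consistent with the tracks — flexible (`both`/`neither`) runs can
always adopt a neighbour's origin, so the minimum is the alternation count
of the forced sequence; tests confirm minimality by brute-force
enumeration on small instances.  Events: linear maps count one event per
switch; circular (or circularly permuted) maps include the wrap-around
transition and count switches/2, because crossovers come in reciprocal
pairs — this is the default because a B|A|B pattern on a linear map of a
circularly permuted genome is one biological event, not two.  With the
wrap included, a cyclic switch count is always even.

## Plaquing and adsorption

EOP = (test count / fraction plated) / (reference count / fraction
plated).  Zero test plaques give the upper bound "< 1 plaque at the
largest volume plated", which can support an R call but never an S call.
Classes: R strictly below 1e-8 (the published bound); S within 1 ± 0.45
(the published sensitive range, treated as a classification band); the
remainder is labelled `reduced` — a category this package adds, always
flagged, because real assays produce intermediate efficiencies that are
neither fully sensitive nor resistant.  Adsorption uses the standard
depletion definition, (1 − free/initial) × 100, mean ± sample SD over
replicates, with residual > initial clipped and flagged; the cited assay
protocol does not print a formula, so the standard definition is stated
here as the package's choice.

`predict_resistance` returns `R` or `potentially_S`, never `S`: receptor
presence is necessary but not sufficient (the species type phage adsorbs
to hosts it cannot plaque on), so predicted-sensitive cells observed
resistant are annotated exceptions rather than model violations, while
predicted-resistant cells observed sensitive are violations.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (parameters, seed) and return their
truth record.  Defaults mirror the studied system: 22 000 nt genomes, 38
planted CDSs (three contiguous markers inside a 2.5 kb variable region at
positions 17 601–20 100), 99.9 % backbone identity, 52 % variable-region
identity, substitution-only divergence between parents (the real genomes
are colinear), hybrid crossovers sampled uniformly inside exactly shared
tracts ≥ 100 nt with a 25 nt margin, Poisson plaque counts at a 1e9
pfu/ml reference titer.  Two deliberate constraints on hybrid generation:
crossovers land in *distinct* tracts, and terminal tracts (touching the
map ends) are excluded — otherwise a spliced segment, or the segment
wrapping the circular origin, can carry no parent-discriminating site and
no method could localise the crossover even in principle.

Not emulated: insertions/deletions between parents (an indel mode exists
in the aligner but not the generator), codon-usage and GC realism,
phylogenetically structured substitution, sequencing error, or multi-phage
(> 2 parent) mosaics.  Passing tests therefore demonstrate correctness of
the algorithms under colinear, substitution-divergent conditions — the
regime the real cohort occupies — not robustness to assembly artefacts or
distant homology.

## Problem sizes and numerical choices

Tests and the acceptance script run at the generators' default scale:
200 hybrids (1–4 events) for mosaic recovery, 50 cohorts for typing, 100
seeds for variable-region localisation, 200 random pairs against the
alignment oracle.  Reported percentages use round-half-up to one decimal.
The Gotoh engine packs (score, matches) into one integer (matches in the
low 13 bits), limiting single calls to sequences under 8192 nt; longer
pairs go through the anchored engine.  Ties in the DP prefer diagonal
moves, then gap-in-b, then gap-in-a, and gap states prefer opening over
extending at equal value — fixed so outputs are reproducible across runs
and platforms.
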