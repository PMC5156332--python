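"""Reconcile the pipeline against real deposited genomes (optional).

Needs network/manual download, so it is not part of the test suite: fetch
the GenBank nucleotide FASTA records for M5938 (KX373687), M6162
(KX373688), M6653 (KX373691), M6654 (KX373692) and bIL67 (NC_001629.1)
into one directory and pass it as argv[1].  File names must contain the
accession.

Prints, under this package's documented identity convention (alignment
columns; gaps count against identity):
  * the overall M5938 vs M6162 nucleotide identity (published: 90.7 %),
  * M6653 origin blocks vs M5938/bIL67 (published M5938 blocks: 1-7537,
    9590-16083, 22141-22157),
  * M6654 origin blocks (published M5938 block: 1198-16825).
"""

import sys
from pathlib import Path

from c2kit.compare import format_percent, global_identity
from c2kit.io import read_fasta
from c2kit.mosaic import maximal_parent_matches, segment_mosaic

ACCESSIONS = {
    "M5938": "KX373687",
    "M6162": "KX373688",
    "M6653": "KX373691",
    "M6654": "KX373692",
    "bIL67": "NC_001629",
}


def load(directory: Path) -> dict:
    genomes = {}
    for name, acc in ACCESSIONS.items():
        hits = [p for p in directory.iterdir() if acc in p.name]
        if not hits:
            sys.exit(f"missing FASTA for {name} ({acc}) in {directory}")
        genomes[name] = read_fasta(hits[0])[0]
    return genomes


def main() -> None:
    if len(sys.argv) != 2:
        sys.exit(__doc__)
    g = load(Path(sys.argv[1]))

    ident = global_identity(g["M5938"], g["M6162"])
    print(f"M5938 vs M6162 overall identity: {format_percent(ident.pct_identity)} % "
          "(published: 90.7 %)")

    for hybrid in ("M6653", "M6654"):
        seg = segment_mosaic(g[hybrid], g["M5938"], g["bIL67"], topology="circular")
        print(f"\n{hybrid}: switches={seg.switches}, events={seg.events}")
        for parent, label in (("M5938", "A"), ("bIL67", "B")):
            spans = maximal_parent_matches(g[hybrid], g[parent])
            big = [f"{lo}-{hi}" for lo, hi in spans if hi - lo >= 1000]
            print(f"  maximal matches vs {parent}: {big}")


if __name__ == "__main__":
    main()
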