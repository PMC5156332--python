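"""Published reference data for the lactococcal C2virus phage-host system.

Small literature-derived lookup tables: the host genotypes of the
*Lactococcus lactis* DGCC7271 lineage (wild type, pip mutant, yjaE mutant
and pip/yjaE double mutant), the Pip/YjaE typing of the studied phages,
and the published plaquing phenotype matrix (S = sensitive, EOP within
1 +/- 0.45; R = resistant, EOP < 1e-8).  These are inputs for the
receptor-requirement model checks and the worked examples.
"""

from __future__ import annotations

from .phenotype import HostGenotype

__all__ = [
    "HOSTS",
    "PHAGE_TYPES",
    "WILD_TYPE_PHAGES",
    "RESISTANCE_MATRIX",
    "ADSORPTION_PCT_DGCC7271",
]

HOSTS: dict[str, HostGenotype] = {
    "DGCC7271": HostGenotype("DGCC7271", pip_functional=True, yjaE_functional=True),
    "DGCC11032": HostGenotype("DGCC11032", pip_functional=False, yjaE_functional=True),
    "DGCC11785": HostGenotype("DGCC11785", pip_functional=True, yjaE_functional=False),
    "DGCC11572": HostGenotype("DGCC11572", pip_functional=False, yjaE_functional=False),
}

PHAGE_TYPES: dict[str, str] = {
    "D4412": "c2_type",
    "M5938": "c2_type",
    "M5939": "c2_type",
    "M5940": "c2_type",
    "D4410": "bIL67_type",
    "M6162": "bIL67_type",
    "M6165": "bIL67_type",
    "M6202": "bIL67_type",
    "bIL67": "bIL67_type",
    "M6653": "bIL67_type",  # hybrid carrying ORF34-35-36 in a c2-type backbone
    "M6654": "bIL67_type",  # hybrid carrying ORF34-35-36 in a c2-type backbone
}

#: the eight phages isolated from industrial whey on DGCC7271 / DGCC11032
#: (excludes the species type phage bIL67 and the in-vitro hybrids)
WILD_TYPE_PHAGES = ("D4412", "M5938", "M5939", "M5940", "D4410", "M6162", "M6165", "M6202")

_HOST_ORDER = ("DGCC7271", "DGCC11032", "DGCC11785", "DGCC11572")

_ROWS = {
    "D4412": "SRSR",
    "M5938": "SRSR",
    "M5939": "SRSR",
    "M5940": "SRSR",
    "D4410": "SSRR",
    "M6162": "SSRR",
    "M6165": "SSRR",
    "M6202": "SSRR",
    "bIL67": "RRRR",
    "M6653": "SSRR",
    "M6654": "SSRR",
}

#: published plaquing phenotype: (phage, host) -> "S" | "R"
RESISTANCE_MATRIX: dict[tuple[str, str], str] = {
    (phage, host): cls
    for phage, row in _ROWS.items()
    for host, cls in zip(_HOST_ORDER, row)
}

#: published mean percentage adsorption (+/- sd) on the wild-type host
ADSORPTION_PCT_DGCC7271: dict[str, tuple[float, float]] = {
    "M6162": (97.7, 0.4),
    "M6165": (98.0, 0.6),
    "M6202": (91.0, 4.0),
    "D4412": (98.2, 1.4),
    "M5938": (98.5, 0.9),
    "bIL67": (67.3, 8.0),
    "M6653": (96.3, 2.5),
    "M6654": (97.5, 1.7),
}
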