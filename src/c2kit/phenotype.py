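"""Plaquing and adsorption statistics, and the receptor-requirement model.

Efficiency of plaquing (EOP) is the plaque count on a test host relative
to the count on the phage's replicating host, after correcting both for
the dilution plated.  Hosts are classed resistant (R) when the EOP — or
its upper bound, when no plaques are seen — falls below 1e-8, sensitive
(S) when the EOP lies in 1 +/- 0.45, and "reduced" in between (a category
this package adds for the intermediate plaquing efficiencies real assays
produce; it is always flagged as such in output).

The receptor-requirement model: c2-type phages need functional Pip,
bIL67-type phages need functional YjaE.  A host lacking the required
determinant is predicted R.  A host carrying it is predicted only
*potentially* sensitive — receptor presence is necessary, not sufficient
(the species type phage bIL67 adsorbs to hosts it cannot plaque on).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "EOP_RESISTANT_THRESHOLD",
    "EOP_SENSITIVE_BAND",
    "EopResult",
    "HostGenotype",
    "AdsorptionResult",
    "MatrixCheck",
    "compute_eop",
    "classify_resistance",
    "adsorption_percent",
    "predict_resistance",
    "phenotype_matrix_check",
]

EOP_RESISTANT_THRESHOLD = 1e-8
EOP_SENSITIVE_BAND = (0.55, 1.45)


@dataclass(frozen=True)
class HostGenotype:
    host_id: str
    pip_functional: bool
    yjaE_functional: bool


@dataclass(frozen=True)
class EopResult:
    eop: float  # point estimate, or upper bound when is_upper_bound
    is_upper_bound: bool
    resistance_class: str  # S | R | reduced
    test_host: str | None = None
    ref_host: str | None = None

    def __str__(self) -> str:
        bound = "<" if self.is_upper_bound else ""
        return f"EOP {bound}{self.eop:.3g} ({self.resistance_class})"


@dataclass(frozen=True)
class AdsorptionResult:
    pct_adsorbed: float
    replicates: int
    sd: float
    flags: tuple[str, ...] = ()


def classify_resistance(
    eop: float,
    is_upper_bound: bool = False,
    r_threshold: float = EOP_RESISTANT_THRESHOLD,
    s_band: tuple[float, float] = EOP_SENSITIVE_BAND,
) -> str:
    """R below the resistance threshold, S inside the sensitive band,
    otherwise 'reduced'.  An upper bound can support R (bound below the
    threshold) but never S."""
    if eop < 0 or not math.isfinite(eop):
        raise ValueError(f"invalid EOP {eop}")
    if eop < r_threshold:
        return "R"
    if not is_upper_bound and s_band[0] <= eop <= s_band[1]:
        return "S"
    return "reduced"


def compute_eop(
    test_count: int,
    test_dilution: float,
    ref_count: int,
    ref_dilution: float,
    test_host: str | None = None,
    ref_host: str | None = None,
    r_threshold: float = EOP_RESISTANT_THRESHOLD,
    s_band: tuple[float, float] = EOP_SENSITIVE_BAND,
) -> EopResult:
    """EOP = (test_count/test_dilution) / (ref_count/ref_dilution).

    Dilutions are the fraction of the lysate plated (1.0 = undiluted).
    Zero test plaques give an upper bound of <1 plaque at that dilution.
    """
    if test_dilution <= 0 or ref_dilution <= 0:
        raise ValueError("dilution factors must be > 0")
    if ref_count <= 0:
        raise ValueError("no reference titer: reference plaque count must be > 0")
    if test_count < 0:
        raise ValueError("negative plaque count")
    ref_titer = ref_count / ref_dilution
    if test_count == 0:
        bound = (1.0 / test_dilution) / ref_titer
        cls = classify_resistance(bound, True, r_threshold, s_band)
        return EopResult(bound, True, cls, test_host, ref_host)
    eop = (test_count / test_dilution) / ref_titer
    cls = classify_resistance(eop, False, r_threshold, s_band)
    return EopResult(eop, False, cls, test_host, ref_host)


def adsorption_percent(replicates: Sequence[tuple[float, float]]) -> AdsorptionResult:
    """Percent of phage adsorbed, from (initial, residual free) PFU pairs.

    pct = (1 - residual/initial) * 100 per replicate; mean +/- sample SD
    over replicates.  Residual counts exceeding the initial titer (assay
    noise) are clipped to 0 % adsorption and flagged.
    """
    if not replicates:
        raise ValueError("no replicates")
    pcts = []
    flags: list[str] = []
    for i, (initial, residual) in enumerate(replicates, start=1):
        if initial <= 0:
            raise ValueError(f"replicate {i}: initial titer must be > 0")
        if residual < 0:
            raise ValueError(f"replicate {i}: negative residual count")
        if residual > initial:
            flags.append(f"replicate {i}: residual > initial, clipped")
            residual = initial
        pcts.append((1.0 - residual / initial) * 100.0)
    n = len(pcts)
    mean = sum(pcts) / n
    sd = math.sqrt(sum((p - mean) ** 2 for p in pcts) / (n - 1)) if n > 1 else 0.0
    return AdsorptionResult(mean, n, sd, tuple(flags))


def predict_resistance(ptype: str, host: HostGenotype) -> str:
    """'R' iff the determinant the phage type requires is non-functional;
    otherwise 'potentially_S' (presence is necessary, not sufficient)."""
    if ptype == "c2_type":
        required = host.pip_functional
    elif ptype == "bIL67_type":
        required = host.yjaE_functional
    else:
        raise ValueError(f"cannot predict resistance for phage type {ptype!r}")
    return "potentially_S" if required else "R"


@dataclass(frozen=True)
class MatrixCheck:
    violations: tuple[tuple[str, str], ...]  # (phage, host) predicted R, observed S
    annotated_nonviolations: tuple[tuple[str, str], ...]  # predicted potentially_S, observed R
    n_cells: int

    @property
    def n_violations(self) -> int:
        return len(self.violations)


def phenotype_matrix_check(
    predictions: Mapping[tuple[str, str], str],
    observations: Mapping[tuple[str, str], str],
) -> MatrixCheck:
    """Compare model predictions with an observed S/R matrix.

    A predicted R observed as S (or as any plaque formation, 'reduced') is
    a model violation.  A predicted potentially_S observed as R is NOT a
    violation — the determinant is necessary, not sufficient — but is
    listed as an annotated exception.
    """
    if set(predictions) != set(observations):
        raise ValueError("prediction and observation matrices index different cells")
    violations = []
    annotated = []
    for cell in sorted(predictions):
        pred, obs = predictions[cell], observations[cell]
        if pred == "R" and obs in ("S", "reduced"):
            violations.append(cell)
        elif pred == "potentially_S" and obs == "R":
            annotated.append(cell)
    return MatrixCheck(tuple(violations), tuple(annotated), len(predictions))
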