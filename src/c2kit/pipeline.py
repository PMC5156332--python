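"""End-to-end analysis stages with reproducible, config-stamped reports.

Each ``run_*`` function takes parsed inputs plus a RunConfig and returns a
plain-dict report that serialises to JSON.  Every report embeds the
config, its hash, the seed and the package version, so identical inputs
give byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

from . import __version__
from .align import PairwiseAlignment, align_pair
from .compare import (
    find_variable_region,
    global_identity,
    region_identity,
    windowed_identity_profile,
)
from .families import assign_marker_roles, cluster_gene_families, type_phage
from .io import CdsRecord, Genome, cds_sequence
from .mosaic import count_events, maximal_parent_matches, segment_mosaic
from .phenotype import (
    HostGenotype,
    compute_eop,
    phenotype_matrix_check,
    predict_resistance,
)

__all__ = ["RunConfig", "run_compare", "run_type", "run_mosaic", "run_phenotype"]


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and conventions shared by all pipeline stages."""

    seed: int = 0
    id_threshold: float = 80.0
    cov_threshold: float = 80.0
    k: int = 21
    min_block: int = 50
    window: int = 500
    step: int = 100
    eop_r_threshold: float = 1e-8
    eop_s_band: tuple[float, float] = (0.55, 1.45)
    topology: str = "circular"
    drop_threshold: float | None = None  # None = profile mean - 20 points
    strict_typing: bool = False

    def __post_init__(self) -> None:
        for name in ("id_threshold", "cov_threshold", "k", "min_block", "window", "step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys {sorted(bad)}")
        if "eop_s_band" in data:
            data = {**data, "eop_s_band": tuple(data["eop_s_band"])}
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["eop_s_band"] = list(d["eop_s_band"])
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _stamp(config: RunConfig) -> dict:
    return {
        "tool": "c2kit",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
    }


def run_compare(genomes: Sequence[Genome], config: RunConfig,
                include_profiles: bool = False) -> dict:
    """All-pairs identity, windowed profiles and variable-region calls."""
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes to compare")
    pairs = []
    profiles = {}
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            a, b = genomes[i], genomes[j]
            aln = align_pair(a.seq, b.seq)
            ident = region_identity(a.seq, b.seq, (1, a.length), alignment=aln)
            profile = windowed_identity_profile(
                a.seq, b.seq, window=config.window, step=config.step, alignment=aln
            )
            region = find_variable_region(profile, config.drop_threshold)
            pairs.append(
                {
                    "a": a.id,
                    "b": b.id,
                    "pct_identity": ident.pct_identity,
                    "matches": ident.matches,
                    "aln_length": ident.aln_length,
                    "variable_region": list(region) if region else None,
                }
            )
            if include_profiles:
                profiles[f"{a.id}|{b.id}"] = [list(p) for p in profile.points]
    report = {**_stamp(config), "stage": "compare", "pairs": pairs}
    if include_profiles:
        report["profiles"] = profiles
    return report


def run_type(
    genomes: Sequence[Genome],
    features: Sequence[CdsRecord],
    references: Mapping[str, str],
    config: RunConfig,
) -> dict:
    """Cluster CDSs into families, assign marker roles, type each genome."""
    if not references:
        raise ValueError("missing marker reference sequences")
    by_id = {g.id: g for g in genomes}
    genes = []
    for rec in features:
        if rec.genome_id not in by_id:
            raise ValueError(f"feature references unknown genome {rec.genome_id!r}")
        genes.append((rec, cds_sequence(by_id[rec.genome_id], rec)))
    families = cluster_gene_families(
        genes, id_threshold=config.id_threshold, cov_threshold=config.cov_threshold
    )
    assign_marker_roles(
        families, references,
        id_threshold=config.id_threshold, cov_threshold=config.cov_threshold,
    )
    calls = [
        type_phage(g.id, families, strict=config.strict_typing) for g in genomes
    ]
    return {
        **_stamp(config),
        "stage": "type",
        "families": [
            {
                "family_id": f.family_id,
                "marker_role": f.marker_role,
                "flags": f.flags,
                "members": [
                    {"genome_id": r.genome_id, "start": r.start, "end": r.end,
                     "strand": r.strand, "gene_name": r.gene_name}
                    for r, _ in f.members
                ],
            }
            for f in families
        ],
        "typing": [
            {"genome_id": c.genome_id, "ptype": c.ptype,
             "evidence": [list(e) for e in c.evidence]}
            for c in calls
        ],
    }


def run_mosaic(
    hybrid: Genome, parentA: Genome, parentB: Genome, config: RunConfig
) -> dict:
    """Origin-block tiling, crossover intervals and event counts for a hybrid."""
    seg = segment_mosaic(
        hybrid, parentA, parentB,
        k=config.k, min_block=config.min_block, topology=config.topology,
    )
    report = {
        **_stamp(config),
        "stage": "mosaic",
        "hybrid": hybrid.id,
        "parents": [parentA.id, parentB.id],
        "blocks": [
            {"start": b.start, "end": b.end, "origin": b.origin, "flags": list(b.flags)}
            for b in seg.blocks
        ],
        "crossover_intervals": [list(c) for c in seg.crossover_intervals],
        "switches": seg.switches,
        "events": seg.events,
        "topology": seg.topology,
        "maximal_matches": {
            parentA.id: [list(t) for t in maximal_parent_matches(hybrid, parentA, config.k)],
            parentB.id: [list(t) for t in maximal_parent_matches(hybrid, parentB, config.k)],
        },
    }
    try:
        report["events_linear"] = count_events(seg, "linear")
    except ValueError:
        report["events_linear"] = None
    return report


def run_phenotype(
    counts,
    host_genotypes: Mapping[str, HostGenotype],
    phage_types: Mapping[str, str],
    ref_hosts: Mapping[str, str],
    config: RunConfig,
) -> dict:
    """EOP matrix from plaque counts plus model predictions and violations.

    ``counts`` is a tidy table with columns phage, host, dilution, count
    (a pandas DataFrame or list of dicts); ``ref_hosts`` names each
    phage's replicating host.
    """
    import pandas as pd

    df = pd.DataFrame(counts)
    required = {"phage", "host", "dilution", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    cells = []
    observations: dict[tuple[str, str], str] = {}
    for phage, sub in df.groupby("phage", sort=True):
        if phage not in ref_hosts:
            raise ValueError(f"no replicating host declared for phage {phage!r}")
        ref_host = ref_hosts[phage]
        ref_rows = sub[(sub["host"] == ref_host) & (sub["count"] > 0)]
        if ref_rows.empty:
            raise ValueError(f"no reference titer for phage {phage!r} on {ref_host!r}")
        ref_row = ref_rows.loc[ref_rows["count"].idxmax()]
        for host, hsub in sub.groupby("host", sort=True):
            nonzero = hsub[hsub["count"] > 0]
            if nonzero.empty:
                row = hsub.loc[hsub["dilution"].idxmax()]
            else:
                row = nonzero.loc[nonzero["count"].idxmax()]
            res = compute_eop(
                int(row["count"]), float(row["dilution"]),
                int(ref_row["count"]), float(ref_row["dilution"]),
                test_host=str(host), ref_host=ref_host,
                r_threshold=config.eop_r_threshold, s_band=config.eop_s_band,
            )
            cells.append(
                {"phage": phage, "host": host, "eop": res.eop,
                 "is_upper_bound": res.is_upper_bound,
                 "resistance_class": res.resistance_class}
            )
            observations[(phage, host)] = res.resistance_class
    predictions = {
        (phage, host): predict_resistance(phage_types[phage], host_genotypes[host])
        for (phage, host) in observations
        if phage in phage_types and host in host_genotypes
    }
    check = phenotype_matrix_check(
        predictions, {cell: observations[cell] for cell in predictions}
    )
    return {
        **_stamp(config),
        "stage": "phenotype",
        "eop": cells,
        "predictions": [
            {"phage": p, "host": h, "predicted": v} for (p, h), v in sorted(predictions.items())
        ],
        "violations": [list(v) for v in check.violations],
        "annotated_nonviolations": [list(v) for v in check.annotated_nonviolations],
    }
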