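"""Cross-cohort replication of DMPs/DMRs and combined-cohort region scans.

A DMP replicates when the same probe is selected in both cohorts; it is
*consistent* when its delta-beta carries the same sign in both. A DMR
replicates when the same region key (gene) is called in both cohorts
with the same direction.

The combined scan pools the harmonised cohorts (cohort handled as a
batch label upstream) and re-tests every CpG in a target region against
direction-aware thresholds — the follow-up used to refine a replicated
promoter region on the full sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ewaskit.dmp import DMPRecord, dmp_table
from ewaskit.dmr import DMRRecord


@dataclass(frozen=True)
class CommonDMP:
    probe_id: str
    delta_a: float
    delta_b: float

    @property
    def consistent(self) -> bool:
        return np.sign(self.delta_a) == np.sign(self.delta_b)


def intersect_dmps(a: list[DMPRecord], b: list[DMPRecord]) -> dict:
    """Probe-level intersection with per-probe direction consistency."""
    by_id_b = {r.probe_id: r for r in b}
    common = [
        CommonDMP(r.probe_id, r.delta_beta, by_id_b[r.probe_id].delta_beta)
        for r in a
        if r.probe_id in by_id_b
    ]
    n_consistent = sum(c.consistent for c in common)
    return {
        "common_dmps": common,
        "n_common": len(common),
        "n_consistent": n_consistent,
        "n_inconsistent": len(common) - n_consistent,
    }


def intersect_dmrs(a: list[DMRRecord], b: list[DMRRecord]) -> list[tuple[DMRRecord, DMRRecord]]:
    """Region keys present in both cohorts with matching direction.

    Returns (cohort-a record, cohort-b record) pairs ordered as in a.
    """
    by_key_b: dict[tuple[str, str], DMRRecord] = {
        (d.region_key, d.direction): d for d in b
    }
    return [
        (d, by_key_b[(d.region_key, d.direction)])
        for d in a
        if (d.region_key, d.direction) in by_key_b
    ]


def combined_region_scan(
    beta_combined: pd.DataFrame,
    sheet: pd.DataFrame,
    manifest: pd.DataFrame,
    region: str | tuple[str, int, int],
    delta_min: float = 0.05,
    p_max: float = 0.005,
    direction: str = "any",
) -> dict:
    """Per-CpG re-test of one region on the pooled cohorts.

    ``region`` is a gene symbol or a ``(chrom, start, end)`` inclusive
    interval. Keeps CpGs with p < ``p_max`` whose delta passes
    ``delta_min`` in the requested ``direction`` ("hypo": delta <=
    -delta_min, "hyper": delta >= +delta_min, "any": |delta| >=
    delta_min). Returns the kept records, their count and coordinate
    span.
    """
    if direction not in ("hypo", "hyper", "any"):
        raise ValueError(f"unknown direction {direction!r}")
    if isinstance(region, str):
        keys = manifest["gene"].map(
            lambda g: region in [p.strip() for p in str(g).split(";")] if g else False
        )
        probes = manifest.index[keys]
    else:
        chrom, start, end = region
        mask = (
            (manifest["chrom"].astype(str) == str(chrom))
            & (manifest["pos"] >= start)
            & (manifest["pos"] <= end)
        )
        probes = manifest.index[mask]
    probes = probes.intersection(beta_combined.index)
    if len(probes) == 0:
        raise ValueError(f"region {region!r} contains no probes")

    records = dmp_table(beta_combined.loc[probes], sheet, manifest)
    kept = []
    for r in records:
        if r.p_value >= p_max:
            continue
        if direction == "hypo" and r.delta_beta > -delta_min:
            continue
        if direction == "hyper" and r.delta_beta < delta_min:
            continue
        if direction == "any" and abs(r.delta_beta) < delta_min:
            continue
        kept.append(r)
    kept.sort(key=lambda r: r.pos)
    span = kept[-1].pos - kept[0].pos if kept else 0
    return {
        "records": kept,
        "n_kept": len(kept),
        "n_region_probes": len(probes),
        "span_bp": span,
    }
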