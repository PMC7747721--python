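"""DMR calling: grouping selected DMPs into regions.

Two grouping modes are shipped because published gene-level DMR tables
in small-cohort EWAS practice often relax the strict distance rule:

``gene`` (default)
    Group selected DMPs by gene key; a group of >= ``min_cpgs`` members
    sharing one delta sign is a DMR regardless of inter-CpG gaps.
    Mixed-sign gene groups are split into per-sign subgroups so the
    consistent-direction requirement is preserved; each subgroup must
    independently reach ``min_cpgs``. Unannotated (intergenic) DMPs are
    chained by strict distance on their chromosome and keyed
    ``"chrom:start"``.

``strict-distance``
    Within each gene (or chromosome for unannotated probes), chain CpGs
    whose adjacent gaps are < ``max_gap`` bp and whose deltas share one
    sign; maximal chains of >= ``min_cpgs`` are emitted.

Output order is deterministic: (chromosome, leftmost member position).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ewaskit.dmp import DMPRecord


@dataclass(frozen=True)
class DMRRecord:
    """A differentially methylated region: >= 2 same-direction DMPs."""

    region_key: str
    chrom: str
    members: tuple[DMPRecord, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a DMR needs >= 2 member CpGs")
        signs = {np.sign(m.delta_beta) for m in self.members}
        if len(signs) != 1:
            raise ValueError("DMR members must share one delta sign")
        if list(self.members) != sorted(self.members, key=lambda m: m.pos):
            raise ValueError("DMR members must be sorted by position")

    @property
    def n_cpgs(self) -> int:
        return len(self.members)

    @property
    def span_bp(self) -> int:
        return dmr_span(self)

    @property
    def direction(self) -> str:
        return self.members[0].direction

    @property
    def max_abs_delta(self) -> float:
        return max(abs(m.delta_beta) for m in self.members)

    @property
    def index_cpg(self) -> str:
        return index_cpg(self)


def dmr_span(dmr: DMRRecord) -> int:
    """Region extent in bp: max member position minus min member position."""
    positions = [m.pos for m in dmr.members]
    return max(positions) - min(positions)


def index_cpg(dmr: DMRRecord) -> str:
    """The tagging CpG: smallest p, ties to larger |delta|, then lower pos."""
    best = min(dmr.members, key=lambda m: (m.p_value, -abs(m.delta_beta), m.pos))
    return best.probe_id


def _chain_by_distance(
    members: list[DMPRecord], max_gap: int, min_cpgs: int
) -> list[list[DMPRecord]]:
    """Maximal runs with adjacent gaps < max_gap and a common delta sign."""
    members = sorted(members, key=lambda m: m.pos)
    chains: list[list[DMPRecord]] = []
    current: list[DMPRecord] = []
    for m in members:
        if current and (
            m.pos - current[-1].pos >= max_gap
            or np.sign(m.delta_beta) != np.sign(current[-1].delta_beta)
        ):
            if len(current) >= min_cpgs:
                chains.append(current)
            current = []
        current.append(m)
    if len(current) >= min_cpgs:
        chains.append(current)
    return chains


def call_dmrs(
    selected: list[DMPRecord],
    max_gap: int = 1500,
    min_cpgs: int = 2,
    mode: str = "gene",
) -> list[DMRRecord]:
    """Group selected DMPs into DMRs (see module docstring for modes)."""
    if mode not in ("gene", "strict-distance"):
        raise ValueError(f"unknown mode {mode!r}")
    annotated: dict[str, list[DMPRecord]] = {}
    unannotated: dict[str, list[DMPRecord]] = {}
    for r in selected:
        if r.pos is None:
            raise ValueError(f"DMP {r.probe_id!r} lacks a coordinate")
        key = r.gene_key
        (annotated.setdefault(key, []) if key else unannotated.setdefault(r.chrom, [])).append(r)

    regions: list[DMRRecord] = []
    for gene, members in annotated.items():
        if mode == "gene":
            # split by sign, keep gaps — matches gene-level published tables
            for sign in (1, -1):
                subset = sorted(
                    (m for m in members if np.sign(m.delta_beta) == sign),
                    key=lambda m: m.pos,
                )
                if len(subset) >= min_cpgs:
                    regions.append(
                        DMRRecord(region_key=gene, chrom=subset[0].chrom, members=tuple(subset))
                    )
        else:
            for chain in _chain_by_distance(members, max_gap, min_cpgs):
                regions.append(
                    DMRRecord(region_key=gene, chrom=chain[0].chrom, members=tuple(chain))
                )
    # intergenic probes: distance chains on the chromosome in both modes
    for chrom, members in unannotated.items():
        for chain in _chain_by_distance(members, max_gap, min_cpgs):
            regions.append(
                DMRRecord(
                    region_key=f"{chrom}:{chain[0].pos}",
                    chrom=chrom,
                    members=tuple(chain),
                )
            )
    regions.sort(key=lambda d: (d.chrom, d.members[0].pos, d.region_key))
    return regions


def cpg_correlation(
    beta: pd.DataFrame, probes: list[str], coherence_min: float = 0.85
) -> dict:
    """Pairwise Pearson correlation across samples for a probe set.

    Returns the full matrix, the minimum off-diagonal r, and a
    ``coherent`` flag (min r >= ``coherence_min``) indicating the probes
    behave as a single region.
    """
    if len(probes) < 2:
        raise ValueError("need >= 2 probes")
    sub = beta.loc[probes]
    if sub.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    sds = sub.std(axis=1)
    if (sds == 0).any():
        raise ValueError(
            f"zero-variance probe {sds.index[(sds == 0).argmax()]!r}"
        )
    corr = sub.T.corr()
    off = corr.to_numpy()[~np.eye(len(probes), dtype=bool)]
    min_r = float(off.min())
    return {"matrix": corr, "min_r": min_r, "coherent": min_r >= coherence_min}


def dmr_frame(regions: list[DMRRecord]) -> pd.DataFrame:
    """Flat summary table, one row per DMR."""
    return pd.DataFrame(
        [
            {
                "region_key": d.region_key,
                "chrom": d.chrom,
                "start": d.members[0].pos,
                "end": d.members[-1].pos,
                "n_cpgs": d.n_cpgs,
                "span_bp": d.span_bp,
                "direction": d.direction,
                "index_cpg": d.index_cpg,
                "max_abs_delta": d.max_abs_delta,
            }
            for d in regions
        ]
    )
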