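"""Per-CpG differential methylation and the joint P / delta-beta rule.

A differentially methylated position (DMP) is a CpG whose case-vs-control
contrast passes *both* an unadjusted p-value threshold (default 0.05) and
an absolute mean beta difference threshold (default 0.10). With small
cohorts no CpG survives FDR control, so the joint rule trades formal
error control for an explicit effect-size requirement; BH q-values are
still computed and reported.

Tests are two-sided Welch (unequal-variance) t-tests on the beta scale —
effects are reported and thresholded as beta differences, so testing on
the same scale keeps the two criteria commensurable. Missing beta cells
are handled pairwise-complete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ewaskit.data_io import primary_gene


@dataclass(frozen=True)
class DMPRecord:
    """One CpG's differential-methylation summary (one table row)."""

    probe_id: str
    chrom: str
    pos: int
    mean_control: float
    mean_case: float
    delta_beta: float
    p_value: float
    q_value: float = float("nan")
    gene: str = ""
    feature: str = "intergenic"
    cgi_relation: str = "OpenSea"
    #: printed coordinate too coarse for span arithmetic (e.g. "2.4E+08")
    pos_ambiguous: bool = False

    @property
    def direction(self) -> str:
        return "hyper" if self.delta_beta > 0 else "hypo"

    @property
    def gene_key(self) -> str:
        return primary_gene(self.gene)


def records_to_frame(records: list[DMPRecord]) -> pd.DataFrame:
    rows = [
        {
            "probe_id": r.probe_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "mean_control": r.mean_control,
            "mean_case": r.mean_case,
            "delta_beta": r.delta_beta,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "direction": r.direction,
            "gene": r.gene,
            "feature": r.feature,
            "cgi_relation": r.cgi_relation,
        }
        for r in records
    ]
    return pd.DataFrame(rows).set_index("probe_id")


def _group_masks(beta: pd.DataFrame, sheet: pd.DataFrame):
    groups = sheet.loc[beta.columns, "group"]
    case = (groups == "case").to_numpy()
    control = (groups == "control").to_numpy()
    if case.sum() == 0 or control.sum() == 0:
        raise ValueError("both case and control groups must be non-empty")
    return case, control


def delta_beta(beta: pd.DataFrame, sheet: pd.DataFrame) -> pd.Series:
    """Case mean minus control mean per probe, pairwise-complete.

    Raises if any probe has no observed value in one group.
    """
    case, control = _group_masks(beta, sheet)
    values = beta.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        mean_case = np.nanmean(values[:, case], axis=1)
        mean_control = np.nanmean(values[:, control], axis=1)
    empty = np.isnan(mean_case) | np.isnan(mean_control)
    if empty.any():
        raise ValueError(
            f"probe {beta.index[np.argmax(empty)]!r} has no observed values "
            "in one group"
        )
    return pd.Series(mean_case - mean_control, index=beta.index, name="delta_beta")


def dmp_test(beta: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Welch t-test per probe with BH q-values over all tested probes.

    Degenerate probes (zero variance in both groups) get p = 1 when the
    group means are equal, p = 0 otherwise.
    """
    case, control = _group_masks(beta, sheet)
    if case.sum() < 2 or control.sum() < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    values = beta.to_numpy(dtype=float)
    x, y = values[:, case], values[:, control]
    res = stats.ttest_ind(x, y, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)

    # constant probes: Welch statistic is 0/0 -> NaN
    degenerate = np.isnan(p)
    if degenerate.any():
        with np.errstate(invalid="ignore"):
            equal = np.nanmean(x, axis=1) == np.nanmean(y, axis=1)
        p[degenerate] = np.where(equal[degenerate], 1.0, 0.0)

    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"p_value": p, "q_value": q}, index=beta.index)


def dmp_table(
    beta: pd.DataFrame, sheet: pd.DataFrame, manifest: pd.DataFrame
) -> list[DMPRecord]:
    """Full per-probe DMP statistics joined with manifest annotation."""
    case, control = _group_masks(beta, sheet)
    values = beta.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        mean_case = np.nanmean(values[:, case], axis=1)
        mean_control = np.nanmean(values[:, control], axis=1)
    pq = dmp_test(beta, sheet)
    ann = manifest.loc[beta.index]
    return [
        DMPRecord(
            probe_id=pid,
            chrom=str(ann["chrom"].iloc[i]),
            pos=int(ann["pos"].iloc[i]),
            mean_control=float(mean_control[i]),
            mean_case=float(mean_case[i]),
            delta_beta=float(mean_case[i] - mean_control[i]),
            p_value=float(pq["p_value"].iloc[i]),
            q_value=float(pq["q_value"].iloc[i]),
            gene=str(ann["gene"].iloc[i]),
            feature=str(ann["feature"].iloc[i]),
            cgi_relation=str(ann["cgi_relation"].iloc[i]),
        )
        for i, pid in enumerate(beta.index)
    ]


def select_dmps(
    records: list[DMPRecord], p_max: float = 0.05, delta_min: float = 0.1
) -> list[DMPRecord]:
    """Joint selection: keep iff p < p_max and \\|delta_beta\\| >= delta_min."""
    return [r for r in records if r.p_value < p_max and abs(r.delta_beta) >= delta_min]


def summarize_dmps(selected: list[DMPRecord]) -> dict:
    """Headline counts for a DMP list.

    ``n_genes`` counts distinct non-empty (primary) gene keys;
    ``n_unannotated`` counts DMPs with an empty gene field.
    """
    genes = {r.gene_key for r in selected if r.gene_key}
    n_unann = sum(1 for r in selected if not r.gene_key)
    n = len(selected)
    n_hyper = sum(1 for r in selected if r.delta_beta > 0)
    by_feature: dict[str, int] = {}
    by_cgi: dict[str, int] = {}
    for r in selected:
        by_feature[r.feature] = by_feature.get(r.feature, 0) + 1
        by_cgi[r.cgi_relation] = by_cgi.get(r.cgi_relation, 0) + 1
    return {
        "n_dmps": n,
        "n_genes": len(genes),
        "n_unannotated": n_unann,
        "fraction_hyper": n_hyper / n if n else float("nan"),
        "fraction_hypo": (n - n_hyper) / n if n else float("nan"),
        "by_feature": by_feature,
        "by_cgi_relation": by_cgi,
    }
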