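"""Methylation-by-genotype comparisons and the joint SNP + CpG model.

An mQTL shows up as a shift in mean methylation across genotype groups
at a CpG. Two views are provided: the three genotype classes, and the
dominant "carrier" coding (any copy of the risk allele vs none), each
with a one-way ANOVA and — for two classes — a Welch t-test.

The joint logistic model regresses case/control status on the SNP
coding and the CpG beta simultaneously; if the CpG term stays
significant with the SNP in the model, the methylation signal is not
explained by genotype alone. The CpG predictor is z-scored by default
so coefficients are comparable across CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ewaskit.data_io import MISSING, GenotypeData

SEPARATION_COEF = 15.0  # |beta| beyond this flags quasi-separation


def carrier_coding(g: GenotypeData, snp_id: str, risk_allele: str) -> pd.Series:
    """Dominant coding: 1 if the sample carries >= 1 risk allele, else 0.

    Missing genotype calls stay missing (NaN).
    """
    j = g.snp_index(snp_id)
    row = g.snps.iloc[j]
    if risk_allele == row["allele1"]:
        risk_dosage = g.genotypes[:, j].astype(float)
    elif risk_allele == row["allele2"]:
        risk_dosage = 2.0 - g.genotypes[:, j]
    else:
        raise ValueError(
            f"risk allele {risk_allele!r} not among SNP {snp_id!r} alleles "
            f"({row['allele1']}/{row['allele2']})"
        )
    out = np.where(g.genotypes[:, j] == MISSING, np.nan, (risk_dosage >= 1).astype(float))
    return pd.Series(out, index=pd.Index(g.sample_ids, name="sample_id"), name="carrier")


def additive_coding(g: GenotypeData, snp_id: str, risk_allele: str) -> pd.Series:
    """0/1/2 copies of the risk allele; missing stays NaN."""
    j = g.snp_index(snp_id)
    row = g.snps.iloc[j]
    if risk_allele == row["allele1"]:
        dosage = g.genotypes[:, j].astype(float)
    elif risk_allele == row["allele2"]:
        dosage = 2.0 - g.genotypes[:, j]
    else:
        raise ValueError(f"risk allele {risk_allele!r} not among SNP {snp_id!r} alleles")
    out = np.where(g.genotypes[:, j] == MISSING, np.nan, dosage)
    return pd.Series(out, index=pd.Index(g.sample_ids, name="sample_id"), name="dosage")


@dataclass
class GroupComparison:
    group_means: dict[str, float]
    group_sizes: dict[str, int]
    anova_f: float
    anova_p: float
    welch_t_p: float | None          # two-class case only
    underpowered_groups: list[str]   # classes with < 2 samples


def methylation_by_genotype(
    beta: pd.DataFrame, cpg_id: str, classes: pd.Series
) -> GroupComparison:
    """One-way ANOVA of beta at one CpG across genotype/carrier classes.

    ``classes`` maps sample id to a class label (NaN = excluded).
    Classes with fewer than 2 samples are flagged; their means are still
    reported but the F-test needs >= 2 classes with >= 2 samples.
    """
    values = beta.loc[cpg_id]
    classes = classes.dropna()
    common = values.index.intersection(classes.index)
    values, classes = values[common].dropna(), classes[common]
    classes = classes[values.index]

    labels = sorted(classes.unique(), key=str)
    if len(labels) < 2:
        raise ValueError("need >= 2 non-empty classes")
    groups = {str(lv): values[classes == lv].to_numpy(float) for lv in labels}
    means = {lv: float(np.mean(v)) for lv, v in groups.items()}
    sizes = {lv: int(len(v)) for lv, v in groups.items()}
    small = [lv for lv, n in sizes.items() if n < 2]

    testable = [v for v in groups.values() if len(v) >= 2]
    if len(testable) >= 2:
        f_stat, f_p = stats.f_oneway(*testable)
    else:
        f_stat, f_p = float("nan"), float("nan")
    welch_p = None
    if len(groups) == 2 and not small:
        a, b = groups.values()
        welch_p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return GroupComparison(
        group_means=means,
        group_sizes=sizes,
        anova_f=float(f_stat),
        anova_p=float(f_p),
        welch_t_p=welch_p,
        underpowered_groups=small,
    )


@dataclass
class LogisticFit:
    coefficients: pd.Series
    standard_errors: pd.Series
    wald_p: pd.Series
    odds_ratios: pd.Series
    converged: bool
    separation: bool
    n: int


def joint_logistic(
    sheet: pd.DataFrame,
    snp_predictor: pd.Series,
    cpg_values: pd.Series,
    standardize_cpg: bool = True,
) -> LogisticFit:
    """Logistic regression of case status on SNP coding and CpG beta.

    Complete-case rows only. Fit by maximum likelihood (Newton/IRLS) with
    an intercept; Wald z-tests per coefficient. Non-convergence and
    quasi-separation (any |coefficient| > 15) are flagged, never silent.
    """
    df = pd.DataFrame(
        {
            "y": (sheet["group"] == "case").astype(float),
            "snp": snp_predictor.reindex(sheet.index),
            "cpg": cpg_values.reindex(sheet.index),
        }
    ).dropna()
    if df["y"].nunique() < 2:
        raise ValueError("phenotype must include both cases and controls")
    for col in ("snp", "cpg"):
        if df[col].nunique() < 2:
            raise ValueError(f"predictor {col!r} is constant on complete cases")
    if standardize_cpg:
        df["cpg"] = (df["cpg"] - df["cpg"].mean()) / df["cpg"].std(ddof=0)

    x = sm.add_constant(df[["snp", "cpg"]])
    model = sm.Logit(df["y"], x)
    try:
        res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=False)
        converged = bool(res.mle_retvals.get("converged", True))
        params, bse, pvals = res.params, res.bse, res.pvalues
    except Exception:
        # fall back: flag instead of failing silently
        res = model.fit(method="bfgs", maxiter=200, disp=False)
        converged = False
        params, bse, pvals = res.params, res.bse, res.pvalues

    separation = bool(np.max(np.abs(params.to_numpy())) > SEPARATION_COEF)
    return LogisticFit(
        coefficients=params,
        standard_errors=bse,
        wald_p=pvals,
        odds_ratios=np.exp(params),
        converged=converged,
        separation=separation,
        n=len(df),
    )
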