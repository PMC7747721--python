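"""Probe filtering, cross-cohort intersection, batch screening/adjustment.

The filtering stage mirrors standard methylation-array QC: a probe is
dropped if its detection P-value exceeds 0.01 (by default in *any*
sample), if its beadcount is < 3 in at least 5% of samples, if it is
flagged non-CpG / SNP-overlapping / cross-hybridising, or if it maps to
a sex chromosome. Removals are book-kept under the *first* triggering
rule so the counts add up exactly.

Batch screening decomposes the probe-centred beta matrix by SVD and
tests each retained right-singular vector (one score per sample) for
association with each covariate: Kruskal-Wallis for categoricals,
Pearson correlation for numerics.

Batch adjustment is the parametric empirical-Bayes location/scale model
(standardise each probe against a design that protects the biological
group effect, shrink per-batch means and variances toward pooled priors,
then reconstruct). It operates on logit-transformed betas and maps back
through the logistic function, which keeps every adjusted value inside
[0, 1] without truncation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ewaskit.data_io import validate_beta

FILTER_RULES = ("detection_p", "beadcount", "no_cg", "snp_probe", "multi_hit", "xy")

_EPS = 1e-6


@dataclass
class FilterReport:
    n_input: int
    n_removed_by_rule: dict[str, int]
    n_retained: int

    def __post_init__(self) -> None:
        assert self.n_input == self.n_retained + sum(self.n_removed_by_rule.values())


@dataclass
class BatchScreenReport:
    """Per-component variance fractions and covariate association p-values."""

    variance_fraction: np.ndarray          # (n_components,)
    association_p: pd.DataFrame            # components x covariates

    def min_p(self, covariate: str) -> float:
        return float(self.association_p[covariate].min())


# ---------------------------------------------------------------------------
# probe filtering
# ---------------------------------------------------------------------------


def filter_probes(
    beta: pd.DataFrame,
    detp: pd.DataFrame | None = None,
    beadcount: pd.DataFrame | None = None,
    manifest: pd.DataFrame | None = None,
    flags: dict[str, set[str]] | None = None,
    detp_threshold: float = 0.01,
    detp_rule: str = "any",
    detp_frac: float = 0.05,
    beadcount_min: int = 3,
    beadcount_frac: float = 0.05,
    drop_xy: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop bad probes; returns the retained matrix and an itemised report.

    ``flags`` may carry probe-id sets under ``no_cg``, ``snp_probe`` and
    ``multi_hit``. ``detp_rule`` is ``"any"`` (fail if detection P >
    threshold in any sample) or ``"fraction"`` (fail in >= ``detp_frac``
    of samples).
    """
    flags = flags or {}
    n, m = beta.shape
    fail = {}

    if detp is not None:
        if detp.shape != beta.shape:
            raise ValueError("detection-P matrix shape mismatch")
        exceed = (detp.to_numpy() > detp_threshold)
        if detp_rule == "any":
            fail["detection_p"] = exceed.any(axis=1)
        elif detp_rule == "fraction":
            fail["detection_p"] = exceed.mean(axis=1) >= detp_frac
        else:
            raise ValueError(f"unknown detp_rule {detp_rule!r}")
    if beadcount is not None:
        if beadcount.shape != beta.shape:
            raise ValueError("beadcount matrix shape mismatch")
        low = beadcount.to_numpy() < beadcount_min
        fail["beadcount"] = low.mean(axis=1) >= beadcount_frac
    for rule in ("no_cg", "snp_probe", "multi_hit"):
        flagged = flags.get(rule)
        if flagged:
            fail[rule] = beta.index.isin(flagged)
    if drop_xy and manifest is not None:
        chrom = manifest.loc[beta.index, "chrom"].astype(str).str.upper()
        fail["xy"] = chrom.isin(["X", "Y", "CHRX", "CHRY"]).to_numpy()

    removed_by: dict[str, int] = {r: 0 for r in FILTER_RULES}
    already = np.zeros(n, dtype=bool)
    for rule in FILTER_RULES:
        if rule not in fail:
            continue
        hits = np.asarray(fail[rule], dtype=bool) & ~already
        removed_by[rule] = int(hits.sum())
        already |= hits

    kept = beta.loc[~already]
    report = FilterReport(
        n_input=n, n_removed_by_rule=removed_by, n_retained=len(kept)
    )
    return kept, report


def intersect_cohorts(
    a: pd.DataFrame, b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both beta matrices to their shared probes, same order."""
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("cohorts share no probes")
    return a.loc[common], b.loc[common]


# ---------------------------------------------------------------------------
# SVD batch screen
# ---------------------------------------------------------------------------


def svd_batch_screen(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    covariates: list[str] | None = None,
    n_components: int = 5,
) -> BatchScreenReport:
    """Test the top sample-space components for covariate structure.

    With ``covariates=None`` the standard trio (batch, cohort, group) is
    screened, silently skipping any that is absent or constant in this
    sheet; explicitly requested covariates must be present and
    non-constant.
    """
    explicit = covariates is not None
    if covariates is None:
        covariates = ["batch", "cohort", "group"]
    if beta.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    values = beta.to_numpy(dtype=float)
    centered = values - values.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise ValueError("constant beta matrix")
    # economy SVD: right singular vectors are per-sample component scores
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, len(s))
    var_frac = (s[:k] ** 2) / (s**2).sum()

    sheet = sheet.loc[beta.columns]
    pvals = {}
    for cov in covariates:
        if cov not in sheet.columns:
            if explicit:
                raise ValueError(f"covariate {cov!r} absent from sample sheet")
            continue
        col = sheet[cov]
        if col.nunique() < 2:
            if explicit:
                raise ValueError(f"covariate {cov!r} is constant")
            continue
        ps = []
        if pd.api.types.is_numeric_dtype(col):
            for c in range(k):
                ps.append(stats.pearsonr(col.to_numpy(float), vt[c]).pvalue)
        else:
            levels = [vt[:k, col.to_numpy() == lv] for lv in col.unique()]
            if all(lv.shape[1] == 1 for lv in levels):
                raise ValueError(
                    f"covariate {cov!r} has one sample per level: untestable"
                )
            for c in range(k):
                groups = [lv[c] for lv in levels]
                ps.append(stats.kruskal(*groups).pvalue)
        pvals[cov] = ps
    if not pvals:
        raise ValueError("no testable (non-constant) covariates")
    return BatchScreenReport(
        variance_fraction=var_frac,
        association_p=pd.DataFrame(pvals, index=pd.RangeIndex(k, name="component")),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes batch adjustment
# ---------------------------------------------------------------------------


def _logit(b: np.ndarray) -> np.ndarray:
    b = np.clip(b, _EPS, 1 - _EPS)
    return np.log(b / (1 - b))


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var()
    return (m * s2 + m**3) / s2


def _eb_fit(
    z_batch: np.ndarray, gamma_hat: np.ndarray, delta_hat: np.ndarray,
    gamma_bar: float, t2: float, a: float, b: float,
    tol: float = 1e-6, max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the posterior mean/variance equations to convergence."""
    n = np.isfinite(z_batch).sum(axis=1)
    gamma_star, delta_star = gamma_hat.copy(), delta_hat.copy()
    for _ in range(max_iter):
        g_new = (n * t2 * gamma_hat + delta_star * gamma_bar) / (n * t2 + delta_star)
        ssq = np.nansum((z_batch - g_new[:, None]) ** 2, axis=1)
        d_new = (0.5 * ssq + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - gamma_star) / (np.abs(gamma_star) + 1e-12)),
            np.max(np.abs(d_new - delta_star) / (np.abs(delta_star) + 1e-12)),
        )
        gamma_star, delta_star = g_new, d_new
        if change < tol:
            break
    return gamma_star, delta_star


def combat_adjust(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    batch_key: str = "batch",
    protect: list[str] = ("group",),
) -> pd.DataFrame:
    """Empirical-Bayes location/scale batch adjustment of a beta matrix.

    The protected covariates enter the standardisation design, so
    biological contrasts are not absorbed into the batch means. With a
    single batch level the input is returned unchanged.
    """
    sheet = sheet.loc[beta.columns]
    batches = sheet[batch_key].astype(str)
    levels = list(dict.fromkeys(batches))
    if len(levels) == 1:
        return beta.copy()
    sizes = batches.value_counts()
    singleton = sizes[sizes < 2]
    if len(singleton):
        raise ValueError(f"singleton batch level(s): {list(singleton.index)}")

    n_samples = beta.shape[1]
    batch_design = pd.get_dummies(batches, dtype=float)[levels].to_numpy()
    cov_parts = []
    for cov in protect:
        dummies = pd.get_dummies(sheet[cov].astype(str), drop_first=True, dtype=float)
        cov_parts.append(dummies.to_numpy())
    cov_design = (
        np.hstack(cov_parts) if cov_parts else np.empty((n_samples, 0))
    )
    design = np.hstack([batch_design, cov_design])
    expected_rank = len(levels) + cov_design.shape[1]
    if np.linalg.matrix_rank(design) < expected_rank:
        raise ValueError("batch is confounded with a protected covariate")

    y = _logit(beta.to_numpy(dtype=float))  # probes x samples

    # probe-wise OLS against [batch | protected]
    b_hat = np.linalg.lstsq(design, y.T, rcond=None)[0]  # params x probes
    n_batches = len(levels)
    batch_sizes = np.array([np.sum(batches.to_numpy() == lv) for lv in levels])
    grand = (batch_sizes / n_samples) @ b_hat[:n_batches]  # per-probe weighted mean
    cov_effect = (cov_design @ b_hat[n_batches:]).T  # probes x samples
    stand_mean = grand[:, None] + cov_effect

    fitted = (design @ b_hat).T
    resid = y - fitted
    var_pooled = (resid**2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd = np.sqrt(var_pooled)[:, None]

    z = (y - stand_mean) / sd

    adjusted = z.copy()
    for lv in levels:
        mask = (batches.to_numpy() == lv)
        zb = z[:, mask]
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        gamma_bar, t2 = gamma_hat.mean(), gamma_hat.var()
        a, b = _aprior(delta_hat), _bprior(delta_hat)
        gamma_star, delta_star = _eb_fit(zb, gamma_hat, delta_hat, gamma_bar, t2, a, b)
        adjusted[:, mask] = (zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    y_adj = adjusted * sd + stand_mean
    out = pd.DataFrame(_logistic(y_adj), index=beta.index, columns=beta.columns)
    return validate_beta(out, name="combat-adjusted beta")
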