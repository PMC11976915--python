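"""Negative-binomial differential test and target calling.

A self-contained stand-in for the usual count-based DE machinery:
median-of-ratios size factors, method-of-moments dispersion with a
mean-trend shrinkage (weight 0.5), a Wald test on log2 fold changes with
delta-method standard errors, and Benjamini-Hochberg adjustment. On top of
it sit the RIP target-calling rule (fold change over input and over the
control IP, p-value and expression floor) and the synaptosome
enriched/depleted split.

This is deliberately not a DESeq2 re-implementation: no outlier
refitting, no LFC shrinkage, single-factor designs only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_MIN_DISPERSION = 1e-8


@dataclass(frozen=True)
class TargetCallParams:
    """Thresholds of the RIP target-calling rule."""

    lfc_min: float = 1.0
    p_max: float = 0.05
    base_mean_min: float = 10.0
    ctrl_lfc_min: float = 1.0

    def __post_init__(self) -> None:
        for name in ("lfc_min", "p_max", "base_mean_min", "ctrl_lfc_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample scale factors.

    Features with a zero in any sample are excluded from the geometric
    mean reference. Raises if no feature is nonzero in all samples.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no feature with nonzero counts in all samples; consider a "
            "pseudo-reference fallback (add a pseudocount or filter samples)"
        )
    ref = mat[all_nonzero]
    log_geomean = np.mean(np.log(ref), axis=1)
    factors = np.exp(np.median(np.log(ref) - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def _fit_dispersion_trend(mu: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of disp ~ a0 + a1/mu, coefficients clipped >= 0.

    Floored raw estimates (variance below the Poisson expectation) carry no
    information about the trend and are excluded from the fit; including
    them biases the trend low and makes the Wald test anticonservative.
    """
    ok = (mu > 0) & np.isfinite(disp) & (disp > 2 * _MIN_DISPERSION)
    if ok.sum() < 3:
        a0 = float(np.median(disp[ok])) if ok.any() else 0.1
        return max(a0, _MIN_DISPERSION), 0.0
    x = 1.0 / mu[ok]
    y = disp[ok]
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a0, a1 = float(coef[0]), float(coef[1])
    if a0 < 0:
        a0 = max(float(np.median(y)), _MIN_DISPERSION)
    if a1 < 0:
        a1 = 0.0
    return a0, a1


def nb_wald_test(
    counts: pd.DataFrame,
    conditions: pd.Series,
    condition_a: str,
    condition_b: str,
) -> pd.DataFrame:
    """Wald test of ``condition_b`` vs ``condition_a`` on NB counts.

    ``counts`` is features x samples (integers); ``conditions`` maps sample
    name to condition. Returns a frame indexed by feature with columns
    (baseMean, log2fc, se, stat, p, padj, tested). Features with all-zero
    counts are reported untested (NaN statistics). log2fc > 0 means higher
    in ``condition_b``.
    """
    cond = conditions.reindex(counts.columns)
    if cond.isna().any():
        missing = list(cond.index[cond.isna()])
        raise ValueError(f"samples without a condition: {missing}")
    a_cols = list(cond.index[cond == condition_a])
    b_cols = list(cond.index[cond == condition_b])
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError(
            f"need >= 2 replicates per condition; got {len(a_cols)} for "
            f"{condition_a!r} and {len(b_cols)} for {condition_b!r}"
        )

    factors = size_factors(counts)
    norm = counts / factors
    base_mean = norm.mean(axis=1).to_numpy()

    na, nb = len(a_cols), len(b_cols)
    xa = norm[a_cols].to_numpy(dtype=float)
    xb = norm[b_cols].to_numpy(dtype=float)
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)

    tested = counts[a_cols + b_cols].sum(axis=1).to_numpy() > 0

    # method-of-moments dispersion from pooled within-condition variance
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    var_pooled = ss / max(na + nb - 2, 1)
    mu_pooled = (na * mean_a + nb * mean_b) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_raw = (var_pooled - mu_pooled) / mu_pooled**2
    disp_raw = np.where(np.isfinite(disp_raw), disp_raw, _MIN_DISPERSION)
    disp_raw = np.maximum(disp_raw, _MIN_DISPERSION)

    a0, a1 = _fit_dispersion_trend(mu_pooled[tested], disp_raw[tested])
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.maximum(mu_pooled, 1e-12)
    disp = np.maximum(0.5 * disp_raw + 0.5 * trend, _MIN_DISPERSION)

    # delta-method SE of log2(mean + 0.5) per condition:
    # Var(mean_c) = sum_j (mu_c/sf_j + disp * mu_c^2) / n_c^2
    inv_sf_a = float(np.sum(1.0 / factors[a_cols].to_numpy()))
    inv_sf_b = float(np.sum(1.0 / factors[b_cols].to_numpy()))
    var_mean_a = (mean_a * inv_sf_a + disp * mean_a**2 * na) / na**2
    var_mean_b = (mean_b * inv_sf_b + disp * mean_b**2 * nb) / nb**2
    ln2 = np.log(2.0)
    se = np.sqrt(
        var_mean_a / (mean_a + 0.5) ** 2 + var_mean_b / (mean_b + 0.5) ** 2
    ) / ln2
    log2fc = np.log2(mean_b + 0.5) - np.log2(mean_a + 0.5)

    with np.errstate(divide="ignore", invalid="ignore"):
        stat = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(stat))
    p = np.where(tested & (se > 0), p, np.nan)
    stat = np.where(tested, stat, np.nan)

    res = pd.DataFrame(
        dict(
            baseMean=base_mean,
            log2fc=np.where(tested, log2fc, np.nan),
            se=np.where(tested, se, np.nan),
            stat=stat,
            p=p,
            padj=bh_adjust(p),
            tested=tested,
        ),
        index=counts.index,
    )
    n_untested = int((~tested).sum())
    if n_untested:
        logger.info("nb_wald_test: %d all-zero features reported untested", n_untested)
    return res


def gene_level_counts(clusters: pd.DataFrame, sample_cols: list[str]) -> pd.DataFrame:
    """Gene-level counts: sum of each gene's validated cluster counts."""
    return clusters.groupby("gene")[sample_cols].sum()


def call_pum_targets(
    rip_vs_input: pd.DataFrame,
    rip_vs_ctrl: pd.DataFrame,
    params: TargetCallParams = TargetCallParams(),
    absolute_lfc: bool = False,
) -> pd.DataFrame:
    """RIP target calling.

    A gene is a target iff log2fc(rip/input) > lfc_min with p < p_max and
    baseMean > base_mean_min, and log2fc(rip/ctrl) > ctrl_lfc_min. With
    ``absolute_lfc`` the literal two-sided |log2fc| rule is applied
    instead. Genes absent from the control comparison are not callable.
    Returns an evidence frame indexed by gene with an ``is_target`` column.
    """

    def _passes(lfc: pd.Series, thr: float) -> pd.Series:
        return lfc.abs() > thr if absolute_lfc else lfc > thr

    ev = rip_vs_input[["baseMean", "log2fc", "p"]].copy()
    ctrl_lfc = rip_vs_ctrl["log2fc"].reindex(ev.index)
    callable_ = ctrl_lfc.notna() & ev["log2fc"].notna() & ev["p"].notna()
    n_uncallable = int((~callable_).sum())
    if n_uncallable:
        logger.info("call_pum_targets: %d genes not callable (missing comparison)", n_uncallable)
    ev["ctrl_log2fc"] = ctrl_lfc
    ev["callable"] = callable_
    ev["is_target"] = (
        callable_
        & _passes(ev["log2fc"], params.lfc_min)
        & (ev["p"] < params.p_max)
        & (ev["baseMean"] > params.base_mean_min)
        & _passes(ctrl_lfc.fillna(0.0), params.ctrl_lfc_min)
    )
    return ev


def call_synaptosome_de(results: pd.DataFrame, alpha: float = 0.05) -> tuple[set, set]:
    """Split genes into synaptosome-enriched / -depleted by padj and sign."""
    sig = results["padj"] < alpha
    enriched = set(results.index[sig & (results["log2fc"] > 0)])
    depleted = set(results.index[sig & (results["log2fc"] < 0)])
    return enriched, depleted
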