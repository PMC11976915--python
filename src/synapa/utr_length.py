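"""Expression-weighted 3' UTR length statistics and localization calls.

For every gene with more than one expressed 3'-end isoform (APA gene), the
length of each isoform is expressed as a fraction of the longest isoform
(real metric) or as its rank fraction i/k (ranked metric), and averaged
weighted by each isoform's share of the gene's normalized expression in a
condition. Genes are classified as having longer / shorter 3' UTRs in the
synaptosome fraction via one-tailed Z thresholds on four between-condition
difference distributions (subtracted and log2 differences of both
metrics).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: the four difference distributions tested
DIFF_COLUMNS = ("diff_sub_real", "diff_log2_real", "diff_sub_rank", "diff_log2_rank")


def build_isoform_table(
    clusters: pd.DataFrame,
    genes: pd.DataFrame,
    norm_counts: pd.DataFrame,
    sample_conditions: pd.Series,
    conditions: tuple[str, str] = ("input", "synaptosome"),
    min_expr: float = 5.0,
    require_both: bool = True,
) -> pd.DataFrame:
    """Per-isoform length and expression-share table for APA genes.

    ``clusters`` are validated, gene-assigned clusters (one row per
    isoform, with a ``summit`` column); ``norm_counts`` is the
    size-factor-normalized cluster x sample matrix aligned to
    ``clusters.index``. An isoform is "expressed" if its mean normalized
    count is >= ``min_expr`` in at least one condition; genes with >= 2
    expressed isoforms are kept. Isoform 3' UTR length is the strand-aware
    distance from the gene's most proximal 3' UTR start to the cluster
    summit; isoforms with non-positive length are dropped with a warning.

    Returns one row per retained isoform: gene, end_pos, utr_length,
    pct_of_longest, rank_fraction, and one expression-share column per
    condition (``share_<cond>``), plus mean normalized expression per
    condition (``expr_<cond>``).
    """
    cond_a, cond_b = conditions
    ginfo = genes.set_index("gene_id")
    cols_by_cond = {
        c: [s for s in norm_counts.columns if sample_conditions.get(s) == c] for c in conditions
    }
    for c, cols in cols_by_cond.items():
        if not cols:
            raise ValueError(f"no samples for condition {c!r}")
    expr = pd.DataFrame(
        {f"expr_{c}": norm_counts[cols].mean(axis=1) for c, cols in cols_by_cond.items()}
    )

    rows = []
    for gene_id, sub in clusters.groupby("gene"):
        if gene_id not in ginfo.index:
            continue
        g = ginfo.loc[gene_id]
        e = expr.loc[sub.index]
        expressed = (e >= min_expr).any(axis=1)
        sub = sub.loc[expressed.index[expressed]]
        if len(sub) < 2:
            continue  # not an APA gene
        if g.strand == "+":
            lengths = sub["summit"].to_numpy() - int(g.utr_start) + 1
        else:
            lengths = int(g.utr_start) - sub["summit"].to_numpy() + 1
        ok = lengths > 0
        if not ok.all():
            logger.warning(
                "gene %s: dropped %d isoform(s) with 3'-end upstream of the UTR start",
                gene_id,
                int((~ok).sum()),
            )
        sub = sub.loc[sub.index[ok]]
        lengths = lengths[ok]
        if len(sub) < 2:
            continue
        order = np.argsort(lengths, kind="stable")
        k = len(sub)
        longest = float(lengths[order[-1]])
        e = expr.loc[sub.index]
        for rank0, oi in enumerate(order):
            idx = sub.index[oi]
            rows.append(
                dict(
                    gene=gene_id,
                    cluster=idx,
                    end_pos=int(sub["summit"].iloc[oi]),
                    utr_length=int(lengths[oi]),
                    pct_of_longest=float(lengths[oi]) / longest,
                    rank_fraction=(rank0 + 1) / k,
                    **{f"expr_{c}": float(e[f"expr_{c}"].iloc[oi]) for c in conditions},
                )
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table

    # per-condition expression shares; genes with zero total in a condition
    # get NaN shares there (excluded from that comparison downstream)
    for c in conditions:
        tot = table.groupby("gene")[f"expr_{c}"].transform("sum")
        with np.errstate(invalid="ignore", divide="ignore"):
            table[f"share_{c}"] = np.where(tot > 0, table[f"expr_{c}"] / tot, np.nan)
    if require_both:
        bad = table.groupby("gene")[[f"share_{cond_a}", f"share_{cond_b}"]].apply(
            lambda d: d.isna().any().any()
        )
        drop = set(bad.index[bad])
        if drop:
            logger.info("dropping %d genes not expressed in both conditions", len(drop))
            table = table[~table["gene"].isin(drop)]
    return table.reset_index(drop=True)


def weighted_length(records: pd.DataFrame, condition: str) -> tuple[float, float]:
    """Expression-weighted 3' UTR length of one gene in one condition.

    Returns ``(weighted_pct_real, weighted_pct_rank)`` =
    sum_i length_fraction_i * share_i with the real (pct-of-longest) and
    ranked (i/k) length fractions. Raises if the gene has no expression in
    the condition (NaN shares).
    """
    share = records[f"share_{condition}"].to_numpy(dtype=float)
    if np.isnan(share).any():
        raise ValueError("gene has zero total expression in condition; value undefined")
    real = float(np.sum(records["pct_of_longest"].to_numpy() * share))
    rank = float(np.sum(records["rank_fraction"].to_numpy() * share))
    return real, rank


def compute_gene_stats(
    isoforms: pd.DataFrame,
    conditions: tuple[str, str] = ("input", "synaptosome"),
) -> pd.DataFrame:
    """Per-gene weighted lengths in both conditions plus the four
    difference statistics (condition_b minus / over condition_a)."""
    cond_a, cond_b = conditions
    rows = []
    for gene_id, sub in isoforms.groupby("gene"):
        try:
            real_a, rank_a = weighted_length(sub, cond_a)
            real_b, rank_b = weighted_length(sub, cond_b)
        except ValueError:
            logger.info("gene %s skipped: undefined weighted length", gene_id)
            continue
        rows.append(
            dict(
                gene=gene_id,
                weighted_pct_real_a=real_a,
                weighted_pct_real_b=real_b,
                weighted_pct_rank_a=rank_a,
                weighted_pct_rank_b=rank_b,
                diff_sub_real=real_b - real_a,
                diff_log2_real=np.log2(real_b / real_a),
                diff_sub_rank=rank_b - rank_a,
                diff_log2_rank=np.log2(rank_b / rank_a),
            )
        )
    return pd.DataFrame(rows)


def call_localized_genes(stats: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """One-tailed Z classification on the four difference distributions.

    For each distribution, z = (x - mean) / sd across genes; a gene is
    significant if z exceeds the upper or falls below the lower one-tailed
    ``alpha`` point in ANY distribution. The class follows the sign of the
    triggering difference (positive -> longer in condition b); genes whose
    triggering distributions disagree in sign are set to ``ns`` with
    ``conflict=True``. Distributions with zero spread are skipped.
    """
    if len(stats) < 30:
        logger.warning("only %d APA genes: normal Z approximation is shaky", len(stats))
    out = stats.copy()
    zcrit = float(sps.norm.ppf(1.0 - alpha))
    signs = pd.DataFrame(index=stats.index)
    for col in DIFF_COLUMNS:
        x = stats[col].to_numpy(dtype=float)
        mu, sd = np.nanmean(x), np.nanstd(x, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            logger.warning("distribution %s has zero spread; skipped", col)
            out[f"z_{col}"] = np.nan
            signs[col] = 0
            continue
        z = (x - mu) / sd
        out[f"z_{col}"] = z
        signs[col] = np.where(z >= zcrit, 1, np.where(z <= -zcrit, -1, 0))

    pos = (signs > 0).any(axis=1)
    neg = (signs < 0).any(axis=1)
    cls = np.where(
        pos & neg, "ns", np.where(pos, "longer_in_syn", np.where(neg, "shorter_in_syn", "ns"))
    )
    out["conflict"] = (pos & neg).to_numpy()
    out["localization_class"] = cls
    return out
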