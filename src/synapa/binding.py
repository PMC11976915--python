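"""Proximal/distal isoform quantification and binding-preference tests.

Clusters of a gene are split at the gene-specific proximal poly(A) site
into a proximal side (short 3' UTR isoform) and a distal side (long
isoform). The long-isoform proportion distal/(proximal+distal) is compared
between conditions with a paired two-sided t-test across genes. A
whitelisting counter quantifies signal in annotated proximal/distal (nUTR)
regions for downstream differential tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class IsoformSplit:
    """Per-sample proximal/distal counts of one gene."""

    gene: str
    proximal_site: int
    proximal_counts: pd.Series
    distal_counts: pd.Series


def split_proximal_distal(
    gene_clusters: pd.DataFrame,
    proximal_site: int,
    strand: str,
    sample_cols: list[str],
    gene: str = "",
) -> IsoformSplit:
    """Merge a gene's clusters into proximal and distal sides.

    A cluster is proximal iff its summit is at or upstream of
    ``proximal_site`` in transcription coordinates (plus strand: summit <=
    site; minus strand: summit >= site), else distal. A gene with a single
    cluster gets a zero distal side.
    """
    summits = gene_clusters["summit"].to_numpy()
    if strand == "+":
        is_prox = summits <= proximal_site
    else:
        is_prox = summits >= proximal_site
    prox = gene_clusters.loc[is_prox, sample_cols].sum(axis=0)
    dist = gene_clusters.loc[~is_prox, sample_cols].sum(axis=0)
    return IsoformSplit(
        gene=gene, proximal_site=int(proximal_site), proximal_counts=prox, distal_counts=dist
    )


def long_isoform_proportion(split: IsoformSplit, sample_cols: list[str]) -> float:
    """distal / (proximal + distal) over condition-averaged counts.

    Raises when the gene's total is zero (caller excludes the gene).
    """
    prox = float(split.proximal_counts[sample_cols].mean())
    dist = float(split.distal_counts[sample_cols].mean())
    total = prox + dist
    if total <= 0:
        raise ValueError(f"gene {split.gene!r}: zero total count; excluded")
    return dist / total


def proportion_table(
    clusters: pd.DataFrame,
    proximal_sites: pd.Series,
    strands: pd.Series,
    condition_samples: dict[str, list[str]],
) -> pd.DataFrame:
    """Long-isoform proportion per gene per condition.

    ``clusters`` are counted, gene-assigned clusters; ``proximal_sites``
    maps gene -> proximal poly(A) position (typically the most proximal
    expressed isoform end); ``condition_samples`` maps condition name to
    its sample columns. Genes with zero totals in any condition are
    excluded (logged).
    """
    all_cols = sorted({s for cols in condition_samples.values() for s in cols})
    rows = []
    for gene_id, sub in clusters.groupby("gene"):
        if gene_id not in proximal_sites.index:
            continue
        split = split_proximal_distal(
            sub, int(proximal_sites[gene_id]), strands[gene_id], all_cols, gene=gene_id
        )
        rec: dict = {"gene": gene_id}
        try:
            for cond, cols in condition_samples.items():
                rec[cond] = long_isoform_proportion(split, cols)
        except ValueError:
            logger.info("gene %s excluded from proportion table (zero total)", gene_id)
            continue
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame()


def binding_preference_test(
    props_a: pd.Series,
    props_b: pd.Series,
    paired: bool = True,
) -> dict:
    """Two-sided t-test of long-isoform proportions (b vs a) across genes.

    Paired by gene by default (unpaired Student's t optional). Returns a
    dict with t, df, p, n, mean_a, mean_b and a ``degenerate`` flag for
    zero-variance non-identical pairs.
    """
    common = props_a.index.intersection(props_b.index)
    a = props_a[common].to_numpy(dtype=float)
    b = props_b[common].to_numpy(dtype=float)
    n = len(common)
    if n < 3:
        raise ValueError(f"need >= 3 genes with proportions in both samples, got {n}")
    out = dict(n=n, mean_a=float(a.mean()), mean_b=float(b.mean()), degenerate=False)
    if paired:
        d = b - a
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d, 0.0):
                out.update(t=0.0, df=n - 1, p=1.0)
            else:
                out.update(t=np.inf, df=n - 1, p=0.0, degenerate=True)
            return out
        t, p = stats.ttest_rel(b, a)
        out.update(t=float(t), df=n - 1, p=float(p))
    else:
        t, p = stats.ttest_ind(b, a)
        out.update(t=float(t), df=2 * n - 2, p=float(p))
    return out


# ---------------------------------------------------------------------------
# nUTR region whitelisting


@dataclass
class NutrRegions:
    """Whitelisted per-sample counts in proximal and distal 3' UTR regions."""

    gene: str
    proximal_end: int
    distal_end: int
    window: int
    proximal_counts: pd.Series
    distal_counts: pd.Series


def nutr_region_counts(
    gene: pd.Series,
    proximal_end: int,
    distal_end: int,
    reads: pd.DataFrame,
    validated_ends: pd.DataFrame,
    samples: list[str],
    window: int = 100,
    validation_radius: int = 25,
) -> NutrRegions:
    """Count whitelisted 3'-seq signal in the proximal and distal regions.

    The proximal region spans the UTR start through the proximal end, the
    distal region the proximal end (exclusive) through the distal end, in
    transcription coordinates. Reads within ``window`` bases
    upstream-through of a region's 3'-end are counted unconditionally;
    other reads in a region count only when within ``validation_radius`` of
    a same-strand validated end. ``gene`` needs fields (gene_id, chrom,
    strand, utr_start).
    """
    strand = gene["strand"]
    chrom = gene["chrom"]
    sign = 1 if strand == "+" else -1  # transcription coordinate = sign * genomic
    if not sign * distal_end > sign * proximal_end:
        raise ValueError("distal_end must be strictly downstream of proximal_end")
    utr_start = int(gene["utr_start"])

    sub = reads[(reads["chrom"] == chrom) & (reads["strand"] == strand)]
    pos = sub["pos"].to_numpy()
    tpos = sign * pos
    t_utr, t_prox, t_dist = sign * utr_start, sign * proximal_end, sign * distal_end

    vset = validated_ends[
        (validated_ends["chrom"] == chrom) & (validated_ends["strand"] == strand)
    ]["pos"].to_numpy()
    near_validated = np.zeros(len(pos), dtype=bool)
    for v in vset:
        near_validated |= np.abs(pos - v) <= validation_radius

    in_prox_region = (tpos >= t_utr) & (tpos <= t_prox)
    in_dist_region = (tpos > t_prox) & (tpos <= t_dist)
    prox_whitelist = (tpos >= t_prox - window) & (tpos <= t_prox)
    dist_whitelist = (tpos >= t_dist - window) & (tpos <= t_dist)

    prox_ok = in_prox_region & (prox_whitelist | near_validated)
    dist_ok = in_dist_region & (dist_whitelist | near_validated)

    def _counts(ok: np.ndarray) -> pd.Series:
        c = sub.loc[ok, "sample"].value_counts()
        return pd.Series({s: int(c.get(s, 0)) for s in samples})

    return NutrRegions(
        gene=str(gene["gene_id"]),
        proximal_end=int(proximal_end),
        distal_end=int(distal_end),
        window=window,
        proximal_counts=_counts(prox_ok),
        distal_counts=_counts(dist_ok),
    )
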