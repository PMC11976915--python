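"""3'-end site definition and filtering.

Raw read 3'-end positions are turned into validated, gene-assigned 3'-end
clusters with per-sample counts:

1. blacklist bases whose downstream genomic context is A-rich on the
   transcribed strand (internal-priming artifacts), exempting bases near
   annotated 3'-ends;
2. restrict reads to gene bodies plus a fixed downstream window;
3. seed clusters at positions reaching a per-sample depth threshold,
   extend both ways, merge overlapping-or-abutting intervals;
4. re-count all samples across clusters;
5. keep clusters intersecting windows around validated high-confidence
   3'-ends; assign each surviving cluster to a gene.

All coordinates are 0-based, half-open. Two parameter presets exist:
``xrip`` (A-run >= 6, 7 of 10, 500-base window) and ``synaptosome``
(A-run >= 4, 6 of 8, 2000-base window).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BlacklistParams:
    """Internal-priming blacklist and gene-window parameters."""

    run_len: int = 6
    window_hits: int = 7
    window_len: int = 10
    exempt_radius: int = 25
    downstream_limit: int = 500

    def __post_init__(self) -> None:
        if self.window_hits > self.window_len:
            raise ValueError("window_hits must be <= window_len")
        for name in ("run_len", "window_hits", "window_len", "exempt_radius", "downstream_limit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class ClusterParams:
    """Cluster seeding / extension / validation parameters."""

    seed_depth: int = 6
    extension: int = 15
    validation_radius: int = 25

    def __post_init__(self) -> None:
        for name in ("seed_depth", "extension", "validation_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


#: named parameter bundles; any field overridable via dataclasses.replace
MODE_PRESETS: dict[str, BlacklistParams] = {
    "xrip": BlacklistParams(run_len=6, window_hits=7, window_len=10, downstream_limit=500),
    "synaptosome": BlacklistParams(run_len=4, window_hits=6, window_len=8, downstream_limit=2000),
}


def blacklist_params_for_mode(mode: str, **overrides) -> BlacklistParams:
    try:
        base = MODE_PRESETS[mode]
    except KeyError:
        raise ValueError(f"unknown mode {mode!r}; expected one of {sorted(MODE_PRESETS)}") from None
    return replace(base, **overrides) if overrides else base


# ---------------------------------------------------------------------------
# blacklist


def _run_starting_lengths(is_base: np.ndarray) -> np.ndarray:
    """r[i] = length of the run of True starting at i and extending right."""
    n = len(is_base)
    r = np.zeros(n, dtype=np.int64)
    if n == 0:
        return r
    x = is_base.astype(np.int64)
    # indices where runs of True end (next is False or array end)
    idx = np.arange(n)
    run_end = is_base & np.concatenate([~is_base[1:], [True]])
    # distance from i to the end of its run, for positions inside runs
    next_end = np.full(n, -1, dtype=np.int64)
    ends = idx[run_end]
    if len(ends):
        pos_of_next_end = np.searchsorted(ends, idx)
        inside = pos_of_next_end < len(ends)
        next_end[inside] = ends[pos_of_next_end[inside]]
        r = np.where(is_base & inside, next_end - idx + 1, 0)
    return r * x


def compute_blacklist(
    genome: dict[str, str],
    annotated_ends: pd.DataFrame,
    params: BlacklistParams,
) -> dict[tuple[str, str], np.ndarray]:
    """Per-base, per-strand internal-priming blacklist.

    A base ``b`` on strand ``s`` is blacklisted iff, on the transcribed
    strand, the A-run starting at ``b+1`` has length >= ``run_len``, or at
    least ``window_hits`` of the ``window_len`` bases immediately
    downstream are A. Truncated windows at contig ends use the available
    bases with the same hit threshold; the run rule needs >= ``run_len``
    available bases to fire. Bases within ``exempt_radius`` of an annotated
    3'-end on the same strand are never blacklisted.

    ``annotated_ends`` needs columns (chrom, pos, strand). Returns a dict
    mapping ``(chrom, strand)`` to a boolean mask over the chromosome.
    """
    masks: dict[tuple[str, str], np.ndarray] = {}
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
        n = len(arr)
        is_a = arr == b"A"
        is_t = arr == b"T"

        # plus strand: downstream = rightward, A on the reference
        run_a = _run_starting_lengths(is_a)
        plus = np.zeros(n, dtype=bool)
        plus[:-1] = run_a[1:] >= params.run_len
        ca = np.concatenate([[0], np.cumsum(is_a)])
        b = np.arange(n)
        lo = np.minimum(b + 1, n)
        hi = np.minimum(b + 1 + params.window_len, n)
        plus |= (ca[hi] - ca[lo]) >= params.window_hits

        # minus strand: downstream = leftward, A on transcribed = T on reference
        run_t = _run_starting_lengths(is_t[::-1])[::-1]  # run of T ending at i, leftward
        minus = np.zeros(n, dtype=bool)
        minus[1:] = run_t[:-1] >= params.run_len
        ct = np.concatenate([[0], np.cumsum(is_t)])
        lo = np.maximum(b - params.window_len, 0)
        minus |= (ct[b] - ct[lo]) >= params.window_hits

        masks[(chrom, "+")] = plus
        masks[(chrom, "-")] = minus

    # annotation exemption: never blacklist near annotated same-strand 3'-ends
    for (chrom, strand), grp in annotated_ends.groupby(["chrom", "strand"]):
        key = (chrom, strand)
        if key not in masks:
            continue
        mask = masks[key]
        for pos in grp["pos"].to_numpy():
            lo = max(0, int(pos) - params.exempt_radius)
            hi = min(len(mask), int(pos) + params.exempt_radius + 1)
            mask[lo:hi] = False
    return masks


def apply_blacklist(reads: pd.DataFrame, masks: dict[tuple[str, str], np.ndarray]) -> pd.DataFrame:
    """Drop reads whose 3'-end position is blacklisted on its strand."""
    keep = np.ones(len(reads), dtype=bool)
    for (chrom, strand), idx in reads.groupby(["chrom", "strand"]).indices.items():
        mask = masks.get((chrom, strand))
        if mask is None:
            continue
        pos = reads["pos"].to_numpy()[idx]
        in_bounds = (pos >= 0) & (pos < len(mask))
        bad = np.zeros(len(idx), dtype=bool)
        bad[in_bounds] = mask[pos[in_bounds]]
        keep[idx] = ~bad
    dropped = int((~keep).sum())
    if dropped:
        logger.info("blacklist: dropped %d of %d reads", dropped, len(reads))
    return reads.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene windows


def _gene_windows(genes: pd.DataFrame, limit: int) -> pd.DataFrame:
    """Per-gene search interval: body plus ``limit`` bases downstream."""
    w = genes.copy()
    w["win_start"] = np.where(w["strand"] == "+", w["start"], w["start"] - limit)
    w["win_end"] = np.where(w["strand"] == "+", w["end"] + limit, w["end"])
    return w


def restrict_to_gene_windows(
    reads: pd.DataFrame, genes: pd.DataFrame, params: BlacklistParams
) -> pd.DataFrame:
    """Keep reads inside a same-strand gene body or within
    ``downstream_limit`` bases downstream of its 3' boundary."""
    windows = _gene_windows(genes, params.downstream_limit)
    keep = np.zeros(len(reads), dtype=bool)
    for (chrom, strand), idx in reads.groupby(["chrom", "strand"]).indices.items():
        sub = windows[(windows["chrom"] == chrom) & (windows["strand"] == strand)]
        if sub.empty:
            continue
        ivals = _merge_intervals(list(zip(sub["win_start"], sub["win_end"])))
        starts = np.array([s for s, _ in ivals])
        ends = np.array([e for _, e in ivals])
        pos = reads["pos"].to_numpy()[idx]
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
        keep[idx] = ok
    dropped = int((~keep).sum())
    if dropped:
        logger.info("gene windows: dropped %d of %d reads", dropped, len(reads))
    return reads.loc[keep].reset_index(drop=True)


def _merge_intervals(ivals: list[tuple[int, int]], adjacency: bool = True) -> list[tuple[int, int]]:
    """Merge overlapping (and, by default, abutting) half-open intervals."""
    if not ivals:
        return []
    ivals = sorted(ivals)
    out = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s < out[-1][1] or (adjacency and s == out[-1][1]):
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(int(s), int(e)) for s, e in out]


# ---------------------------------------------------------------------------
# clustering


def call_clusters(
    reads: pd.DataFrame,
    masks: dict[tuple[str, str], np.ndarray] | None,
    params: ClusterParams,
) -> pd.DataFrame:
    """Seed-and-extend 3'-end cluster calling.

    Seeds are positions where any single sample's depth reaches
    ``seed_depth``; each seed spawns ``[seed - extension, seed + extension + 1)``;
    overlapping or abutting same-strand intervals merge. The summit is the
    position of maximal pooled depth in the merged interval (leftmost on
    tie). Blacklisted positions contribute no depth.

    Returns a frame with columns (chrom, strand, start, end, summit),
    sorted by (chrom, start).
    """
    if masks is not None:
        reads = apply_blacklist(reads, masks)
    rows = []
    for (chrom, strand), grp in reads.groupby(["chrom", "strand"]):
        per_sample = grp.groupby(["pos", "sample"]).size()
        seed_pos = sorted({pos for (pos, _), d in per_sample.items() if d >= params.seed_depth})
        if not seed_pos:
            continue
        ivals = _merge_intervals(
            [(max(0, p - params.extension), p + params.extension + 1) for p in seed_pos]
        )
        pooled = grp.groupby("pos").size()
        ppos = pooled.index.to_numpy()
        pdep = pooled.to_numpy()
        for s, e in ivals:
            inside = (ppos >= s) & (ppos < e)
            cand_pos = ppos[inside]
            cand_dep = pdep[inside]
            summit = int(cand_pos[np.argmax(cand_dep)])  # argmax returns first max -> leftmost
            rows.append(dict(chrom=chrom, strand=strand, start=s, end=e, summit=summit))
    out = pd.DataFrame(rows, columns=["chrom", "strand", "start", "end", "summit"])
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def count_clusters(reads: pd.DataFrame, clusters: pd.DataFrame) -> pd.DataFrame:
    """Re-count reads of all samples across clusters.

    Each read is assigned to at most one same-strand cluster whose
    half-open interval contains it. Clusters must be non-overlapping per
    (chrom, strand). Adds one integer count column per sample (zeros for
    samples with no reads in a cluster).
    """
    samples = sorted(reads["sample"].unique())
    counts = np.zeros((len(clusters), len(samples)), dtype=np.int64)
    sample_col = {s: j for j, s in enumerate(samples)}
    row_of = {orig: i for i, orig in enumerate(clusters.index)}
    sample_codes = reads["sample"].map(sample_col).to_numpy()
    read_groups = reads.groupby(["chrom", "strand"]).indices

    for (chrom, strand), sub in clusters.groupby(["chrom", "strand"]):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts_s, ends_s = starts[order], ends[order]
        if np.any(starts_s[1:] < ends_s[:-1]):
            raise ValueError(f"overlapping clusters on {chrom} strand {strand}")
        ridx = read_groups.get((chrom, strand))
        if ridx is None:
            continue
        pos = reads["pos"].to_numpy()[ridx]
        j = np.searchsorted(starts_s, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends_s[np.clip(j, 0, len(ends_s) - 1)])
        cluster_rows = sub.index.to_numpy()[order]
        global_rows = np.array([row_of[r] for r in cluster_rows[j[ok]]], dtype=np.int64)
        np.add.at(counts, (global_rows, sample_codes[ridx[ok]]), 1)

    out = clusters.copy().reset_index(drop=True)
    for jcol, s in enumerate(samples):
        out[s] = counts[:, jcol]
    return out


def validate_clusters(
    clusters: pd.DataFrame, validated_ends: pd.DataFrame, params: ClusterParams
) -> pd.DataFrame:
    """Keep clusters intersecting ``[v - radius, v + radius + 1)`` windows
    around same-strand validated 3'-ends; sets ``validated=True``."""
    if validated_ends.empty:
        logger.warning("empty validated-end set: all %d clusters removed", len(clusters))
        out = clusters.iloc[0:0].copy()
        out["validated"] = pd.Series(dtype=bool)
        return out
    r = params.validation_radius
    keep = np.zeros(len(clusters), dtype=bool)
    ends_by_key = {k: g["pos"].to_numpy() for k, g in validated_ends.groupby(["chrom", "strand"])}
    for i, row in enumerate(clusters.itertuples(index=False)):
        vs = ends_by_key.get((row.chrom, row.strand))
        if vs is None:
            continue
        # interval [start,end) intersects [v-r, v+r+1)
        keep[i] = bool(np.any((row.start < vs + r + 1) & (vs - r < row.end)))
    out = clusters.loc[keep].copy().reset_index(drop=True)
    out["validated"] = True
    removed = len(clusters) - len(out)
    if removed:
        logger.info("validation: removed %d of %d clusters", removed, len(clusters))
    return out


def assign_clusters_to_genes(
    clusters: pd.DataFrame, genes: pd.DataFrame, params: BlacklistParams
) -> pd.DataFrame:
    """Assign each cluster to the same-strand gene whose body-or-downstream
    window contains its summit; nearest 3' boundary wins ties. Unassignable
    clusters are dropped."""
    windows = _gene_windows(genes, params.downstream_limit)
    gene_col = []
    keep = np.zeros(len(clusters), dtype=bool)
    for i, row in enumerate(clusters.itertuples(index=False)):
        sub = windows[(windows["chrom"] == row.chrom) & (windows["strand"] == row.strand)]
        hit = sub[(sub["win_start"] <= row.summit) & (row.summit < sub["win_end"])]
        if hit.empty:
            gene_col.append(None)
            continue
        three_prime = np.where(hit["strand"] == "+", hit["end"] - 1, hit["start"])
        dist = np.abs(row.summit - three_prime)
        gene_col.append(hit["gene_id"].iloc[int(np.argmin(dist))])
        keep[i] = True
    dropped = int((~keep).sum())
    if dropped:
        logger.info("gene assignment: dropped %d unassignable clusters", dropped)
    out = clusters.loc[keep].copy()
    out["gene"] = [g for g in gene_col if g is not None]
    return out.reset_index(drop=True)


def sample_columns(clusters: pd.DataFrame) -> list[str]:
    """Names of the per-sample count columns of a counted cluster frame."""
    meta = {"chrom", "strand", "start", "end", "summit", "validated", "gene"}
    return [c for c in clusters.columns if c not in meta]
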