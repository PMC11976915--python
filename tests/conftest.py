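import numpy as np
import pandas as pd
import pytest

from synapa import simulate


@pytest.fixture(scope="session")
def small_config() -> simulate.SimConfig:
    return simulate.SimConfig(
        genome_length=200_000,
        n_chroms=2,
        n_genes=30,
        n_localized_genes=3,
        n_rip_targets=5,
        n_decoy_sites=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return simulate.generate_reference(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_reference):
    genome, genes, validated, truth = small_reference
    design = simulate.default_design(small_config)
    reads = simulate.simulate_end_reads(truth, design, small_config)
    return dict(
        genome=genome,
        genes=genes,
        validated=validated,
        truth=truth,
        design=design,
        reads=reads,
        conditions=pd.Series({d.sample: d.condition for d in design}),
    )


def make_reads(positions: dict[int, int], sample="s1", chrom="chr1", strand="+") -> pd.DataFrame:
    """Reads from a {position: depth} spec, one sample."""
    rows = [(chrom, p, strand, sample) for p, d in positions.items() for _ in range(d)]
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "sample"])


def brute_force_clusters(
    reads: pd.DataFrame, seed_depth: int, extension: int
) -> list[tuple[str, str, int, int, int]]:
    """Independent reference implementation of seed/extend/merge clustering.

    Walks positions one by one; returns (chrom, strand, start, end, summit)
    tuples sorted by (chrom, start).
    """
    out = []
    for (chrom, strand), grp in reads.groupby(["chrom", "strand"]):
        depth_by_sample: dict[str, dict[int, int]] = {}
        pooled: dict[int, int] = {}
        for r in grp.itertuples(index=False):
            depth_by_sample.setdefault(r.sample, {}).setdefault(r.pos, 0)
            depth_by_sample[r.sample][r.pos] += 1
            pooled[r.pos] = pooled.get(r.pos, 0) + 1
        seeds = sorted(
            {
                pos
                for d in depth_by_sample.values()
                for pos, depth in d.items()
                if depth >= seed_depth
            }
        )
        intervals = []
        for s in seeds:
            lo, hi = max(0, s - extension), s + extension + 1
            if intervals and lo <= intervals[-1][1]:
                intervals[-1][1] = max(intervals[-1][1], hi)
            else:
                intervals.append([lo, hi])
        for lo, hi in intervals:
            best_pos, best_depth = None, -1
            for p in range(lo, hi):
                d = pooled.get(p, 0)
                if d > best_depth:
                    best_pos, best_depth = p, d
            out.append((chrom, strand, lo, hi, best_pos))
    return sorted(out, key=lambda t: (t[0], t[2]))


def brute_force_counts(reads: pd.DataFrame, clusters: pd.DataFrame) -> np.ndarray:
    """Per-read membership test; counts matrix aligned to clusters rows and
    sorted sample names."""
    samples = sorted(reads["sample"].unique())
    counts = np.zeros((len(clusters), len(samples)), dtype=int)
    for r in reads.itertuples(index=False):
        for i, c in enumerate(clusters.itertuples(index=False)):
            if (
                r.chrom == c.chrom
                and r.strand == c.strand
                and c.start <= r.pos < c.end
            ):
                counts[i, samples.index(r.sample)] += 1
                break
    return counts
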