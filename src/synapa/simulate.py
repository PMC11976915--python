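"""Synthetic genome / annotation / 3'-end read simulator with planted truth.

Generates the inputs the analysis pipeline expects — genome FASTA, gene
models with 3' UTR starts and isoform 3'-ends, a validated-end set, and
per-sample read 3'-end tables — together with a ground-truth table
(isoform usage per condition, localization direction, RIP target status,
internal-priming decoy positions) for recovery tests.

Coordinates are 0-based, half-open throughout; single-base sites are
0-based positions. "Downstream" means the transcription direction of the
gene: on the minus strand, A-content is realized as T on the plus strand.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

LOCALIZATION_CLASSES = ("shorter_in_synaptosome", "longer_in_synaptosome", "null")

#: conditions understood by the read simulator
CONDITIONS = ("input", "synaptosome", "rip", "control_rip")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic dataset.

    ``isoforms_per_gene`` maps isoform count (1..4) to probability; a bare
    int means "always that many". ``localization_effect`` is the absolute
    shift applied to the distal usage share of planted localized genes
    (sign set by the planted direction).
    """

    genome_length: int = 400_000
    n_chroms: int = 2
    n_genes: int = 100
    isoforms_per_gene: Mapping[int, float] | int = field(
        default_factory=lambda: {1: 0.25, 2: 0.35, 3: 0.25, 4: 0.15}
    )
    utr_start_offset: int = 200
    isoform_spacing: int = 300
    usage_concentration: float = 5.0
    localization_effect: float = 0.4
    n_localized_genes: int = 10
    n_longer_genes: int | None = None  # defaults to n_localized_genes
    n_rip_targets: int = 20
    rip_enrichment: float = 8.0
    distal_binding_weight: float = 2.0
    nb_dispersion: float = 0.1
    mean_depth: float = 200.0
    end_scatter_sd: float = 3.0
    internal_priming_rate: float = 0.05
    n_decoy_sites: int = 20
    replicates: int = 3
    seed: int = 0

    def isoform_dist(self) -> dict[int, float]:
        if isinstance(self.isoforms_per_gene, int):
            return {int(self.isoforms_per_gene): 1.0}
        d = {int(k): float(v) for k, v in self.isoforms_per_gene.items()}
        tot = sum(d.values())
        if tot <= 0:
            raise ValueError("isoforms_per_gene probabilities must sum to > 0")
        return {k: v / tot for k, v in d.items()}

    def validate(self) -> None:
        for name in (
            "genome_length",
            "n_chroms",
            "n_genes",
            "utr_start_offset",
            "isoform_spacing",
            "n_localized_genes",
            "n_rip_targets",
            "n_decoy_sites",
            "replicates",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_chroms < 1:
            raise ValueError("n_chroms must be >= 1")
        if not 0.0 <= self.internal_priming_rate < 1.0:
            raise ValueError("internal_priming_rate must be in [0, 1)")
        if not all(1 <= k <= 4 for k in self.isoform_dist()):
            raise ValueError("isoforms_per_gene keys must be in 1..4")


@dataclass(frozen=True)
class SampleDesign:
    """One sequencing sample: condition plus replicate index."""

    sample: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )


def default_design(config: SimConfig, conditions: Sequence[str] = CONDITIONS) -> list[SampleDesign]:
    """Replicated design over the given conditions (``replicates`` each)."""
    return [
        SampleDesign(sample=f"{cond}_{r + 1}", condition=cond, replicate=r + 1)
        for cond in conditions
        for r in range(config.replicates)
    ]


@dataclass
class TruthTable:
    """Planted ground truth: per-gene, per-isoform, and decoy records.

    genes:    gene_id, chrom, strand, start, end, utr_start, n_isoforms,
              localization, is_rip_target, distal_binding_weight
    isoforms: gene_id, isoform_idx (0 = proximal), chrom, strand, end_pos,
              utr_length, baseline_share, input_share, synaptosome_share
    decoys:   gene_id, chrom, pos, strand
    """

    genes: pd.DataFrame
    isoforms: pd.DataFrame
    decoys: pd.DataFrame


# ---------------------------------------------------------------------------
# reference generation


def _assign_counts(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    dist = config.isoform_dist()
    ks = np.array(sorted(dist), dtype=int)
    ps = np.array([dist[k] for k in ks])
    return rng.choice(ks, size=config.n_genes, p=ps)


def _usage_shares(rng: np.random.Generator, k: int, conc: float) -> np.ndarray:
    if k == 1:
        return np.ones(1)
    return rng.dirichlet(np.full(k, conc))


def shift_distal_share(shares: np.ndarray, delta: float) -> np.ndarray:
    """Shift the distal (last) usage share by ``delta``, clamp to [0.01, 0.99],
    and renormalize the remaining shares proportionally."""
    shares = np.asarray(shares, dtype=float)
    if shares.size < 2:
        return shares.copy()
    new_distal = float(np.clip(shares[-1] + delta, 0.01, 0.99))
    rest = shares[:-1]
    rest_sum = rest.sum()
    if rest_sum <= 0:
        rest = np.full(rest.size, (1.0 - new_distal) / rest.size)
    else:
        rest = rest * (1.0 - new_distal) / rest_sum
    out = np.append(rest, new_distal)
    return out / out.sum()


def generate_reference(
    config: SimConfig,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame, TruthTable]:
    """Build genome, gene models, validated ends and planted truth.

    Returns ``(genome, genes, validated_ends, truth)`` where ``genome`` maps
    chromosome name to sequence, ``genes`` has columns (gene_id, chrom,
    start, end, strand, utr_start), and ``validated_ends`` has columns
    (chrom, pos, strand). Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    chrom_len = config.genome_length // config.n_chroms
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    seqs = {
        name: rng.choice(_BASES, size=chrom_len).astype("U1")
        for name in chrom_names
    }

    n_isoforms = _assign_counts(rng, config)
    kmax = int(n_isoforms.max()) if len(n_isoforms) else 1
    # per-gene genomic footprint: body offset + proximal UTR + spacing between
    # poly(A) sites, plus room for the downstream window and decoys
    proximal_utr = 150
    footprint = config.utr_start_offset + proximal_utr + (kmax - 1) * config.isoform_spacing
    gap = 600
    per_chrom = config.n_genes // config.n_chroms + (config.n_genes % config.n_chroms > 0)
    needed = per_chrom * (footprint + gap) + gap
    if needed > chrom_len:
        raise ValueError(
            f"genome too small: need >= {needed} bases per chromosome to place "
            f"{per_chrom} non-overlapping genes of footprint {footprint} "
            f"with {gap}-base gaps, have {chrom_len}"
        )

    gene_rows = []
    iso_rows = []
    cursor = {name: gap for name in chrom_names}
    for g in range(config.n_genes):
        chrom = chrom_names[g % config.n_chroms]
        strand = "+" if (g // config.n_chroms) % 2 == 0 else "-"
        k = int(n_isoforms[g])
        start = cursor[chrom]
        length = config.utr_start_offset + proximal_utr + (k - 1) * config.isoform_spacing
        end = start + length  # half-open; distal-most end at end-1
        cursor[chrom] = start + footprint + gap

        jitter = rng.integers(0, 40, size=k)
        if strand == "+":
            utr_start = start + config.utr_start_offset
            ends = np.array(
                [start + config.utr_start_offset + proximal_utr + j * config.isoform_spacing - int(jitter[j]) for j in range(k)]
            )
            ends[-1] = end - 1  # distal-most defines the gene 3' boundary
        else:
            utr_start = end - 1 - config.utr_start_offset
            ends = np.array(
                [end - 1 - config.utr_start_offset - proximal_utr - j * config.isoform_spacing + int(jitter[j]) for j in range(k)]
            )
            ends[-1] = start  # distal-most at the left gene boundary
        gene_id = f"gene{g + 1:04d}"
        gene_rows.append(
            dict(gene_id=gene_id, chrom=chrom, start=int(start), end=int(end), strand=strand, utr_start=int(utr_start))
        )
        shares = _usage_shares(rng, k, config.usage_concentration)
        for j in range(k):
            iso_rows.append(
                dict(
                    gene_id=gene_id,
                    isoform_idx=j,
                    chrom=chrom,
                    strand=strand,
                    end_pos=int(ends[j]),
                    utr_length=int(abs(ends[j] - utr_start)) + 1,
                    baseline_share=shares[j],
                )
            )

    genes = pd.DataFrame(gene_rows)
    isoforms = pd.DataFrame(iso_rows)

    # plant localization and RIP-target labels on APA genes
    apa_genes = genes.gene_id[
        genes.gene_id.map(isoforms.groupby("gene_id").size()) >= 2
    ].tolist()
    n_shorter = config.n_localized_genes
    n_longer = config.n_localized_genes if config.n_longer_genes is None else config.n_longer_genes
    n_loc = n_shorter + n_longer
    if n_loc > len(apa_genes):
        raise ValueError(
            f"not enough APA genes ({len(apa_genes)}) to plant "
            f"{n_loc} localized genes; raise n_genes or isoform counts"
        )
    # prefer genes whose baseline distal share can absorb the full shift
    # without clamping, so the planted effect size actually materializes
    distal_share = isoforms.sort_values("isoform_idx").groupby("gene_id")["baseline_share"].last()
    eff = abs(config.localization_effect)
    eligible_shorter = [g for g in apa_genes if distal_share[g] >= eff + 0.02]
    eligible_longer = [g for g in apa_genes if distal_share[g] <= 1.0 - eff - 0.02]
    shorter: set = set()
    longer: set = set()
    if n_shorter:
        pool = eligible_shorter if len(eligible_shorter) >= n_shorter else apa_genes
        shorter = set(rng.choice(pool, size=n_shorter, replace=False))
    if n_longer:
        pool = [g for g in eligible_longer if g not in shorter]
        if len(pool) < n_longer:
            pool = [g for g in apa_genes if g not in shorter]
        longer = set(rng.choice(pool, size=n_longer, replace=False))
    if config.n_rip_targets > len(apa_genes):
        raise ValueError(
            f"not enough APA genes ({len(apa_genes)}) for {config.n_rip_targets} RIP targets"
        )
    targets = set(rng.choice(apa_genes, size=config.n_rip_targets, replace=False)) if config.n_rip_targets else set()

    genes["localization"] = [
        "shorter_in_synaptosome" if gid in shorter else "longer_in_synaptosome" if gid in longer else "null"
        for gid in genes.gene_id
    ]
    genes["is_rip_target"] = genes.gene_id.isin(targets)
    genes["distal_binding_weight"] = np.where(genes.is_rip_target, config.distal_binding_weight, 1.0)
    genes["n_isoforms"] = genes.gene_id.map(isoforms.groupby("gene_id").size()).astype(int)

    # condition-specific usage shares
    input_shares = []
    syn_shares = []
    for gid, grp in isoforms.groupby("gene_id", sort=False):
        base = grp.baseline_share.to_numpy()
        cls = genes.loc[genes.gene_id == gid, "localization"].iloc[0]
        if cls == "shorter_in_synaptosome":
            syn = shift_distal_share(base, -config.localization_effect)
        elif cls == "longer_in_synaptosome":
            syn = shift_distal_share(base, +config.localization_effect)
        else:
            syn = base.copy()
        input_shares.append(base)
        syn_shares.append(syn)
    isoforms["input_share"] = np.concatenate(input_shares)
    isoforms["synaptosome_share"] = np.concatenate(syn_shares)

    # plant internal-priming decoys: A-runs (transcribed strand) >= 8 nt,
    # inside gene bodies, >= 50 bases from every true poly(A) site
    decoy_rows = []
    if config.n_decoy_sites:
        if config.n_decoy_sites > len(genes):
            raise ValueError("n_decoy_sites must be <= n_genes")
        host_idx = rng.choice(len(genes), size=config.n_decoy_sites, replace=False)
        run = 10
        for gi in host_idx:
            row = genes.iloc[gi]
            offset = 60 + int(rng.integers(0, 60))
            if row.strand == "+":
                pos = int(row.start + offset)  # body, upstream of utr_start
                seqs[row.chrom][pos + 1 : pos + 1 + run] = "A"
            else:
                pos = int(row.end - 1 - offset)
                seqs[row.chrom][pos - run : pos] = "T"
            ends_here = isoforms.loc[isoforms.gene_id == row.gene_id, "end_pos"]
            if (abs(ends_here - pos) < 50).any():  # pragma: no cover - layout guarantees
                raise AssertionError("decoy placed within 50 bases of a true site")
            decoy_rows.append(dict(gene_id=row.gene_id, chrom=row.chrom, pos=pos, strand=row.strand))
    decoys = pd.DataFrame(decoy_rows, columns=["gene_id", "chrom", "pos", "strand"])

    genome = {name: "".join(arr) for name, arr in seqs.items()}
    validated = (
        isoforms[["chrom", "end_pos", "strand"]]
        .rename(columns={"end_pos": "pos"})
        .drop_duplicates()
        .reset_index(drop=True)
    )
    truth = TruthTable(genes=genes, isoforms=isoforms, decoys=decoys)
    return genome, genes[["gene_id", "chrom", "start", "end", "strand", "utr_start"]].copy(), validated, truth


# ---------------------------------------------------------------------------
# read simulation


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean=mu, var=mu+alpha*mu^2) draws; Poisson limit for alpha ~ 0."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 1e-12:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def isoform_means(truth: TruthTable, condition: str, config: SimConfig) -> np.ndarray:
    """Expected read count per isoform (row order of ``truth.isoforms``)."""
    iso = truth.isoforms
    genes = truth.genes.set_index("gene_id")
    share = iso["synaptosome_share" if condition == "synaptosome" else "input_share"].to_numpy()
    mu = config.mean_depth * share
    if condition == "rip":
        is_target = genes["is_rip_target"].reindex(iso["gene_id"]).to_numpy()
        dbw = genes["distal_binding_weight"].reindex(iso["gene_id"]).to_numpy()
        n_iso = genes["n_isoforms"].reindex(iso["gene_id"]).to_numpy()
        is_distal = iso["isoform_idx"].to_numpy() == n_iso - 1
        factor = np.where(is_target, config.rip_enrichment, 1.0)
        factor = factor * np.where(is_target & is_distal, dbw, 1.0)
        mu = mu * factor
    return mu


def simulate_isoform_counts(
    truth: TruthTable,
    design: Sequence[SampleDesign],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """NB read counts per true isoform per sample (no read positions).

    Rows follow ``truth.isoforms`` (MultiIndex gene_id/isoform_idx),
    columns are sample ids. The same model feeds the read-level simulator.
    """
    if len(design) == 0:
        raise ValueError("empty sample design")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    cols = {}
    for sd in design:
        mu = isoform_means(truth, sd.condition, config)
        cols[sd.sample] = _nb_draw(rng, mu, config.nb_dispersion)
    idx = pd.MultiIndex.from_frame(truth.isoforms[["gene_id", "isoform_idx"]])
    return pd.DataFrame(cols, index=idx)


def simulate_end_reads(
    truth: TruthTable,
    design: Sequence[SampleDesign],
    config: SimConfig,
) -> pd.DataFrame:
    """Simulate per-sample read 3'-end positions.

    Returns a table with columns (chrom, pos, strand, sample, origin) where
    ``origin`` is ``"site"`` for reads from true poly(A) sites and
    ``"decoy"`` for internal-priming reads planted at decoy positions.
    """
    if len(design) == 0:
        raise ValueError("empty sample design")
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    counts = simulate_isoform_counts(truth, design, config, rng=rng)

    iso = truth.isoforms
    iso_chrom = iso["chrom"].to_numpy()
    iso_strand = iso["strand"].to_numpy()
    iso_end = iso["end_pos"].to_numpy()

    frames = []
    for sd in design:
        c = counts[sd.sample].to_numpy()
        total = int(c.sum())
        pos = np.repeat(iso_end, c)
        jitter = np.rint(rng.normal(0.0, config.end_scatter_sd, size=total)).astype(int)
        frame = pd.DataFrame(
            dict(
                chrom=np.repeat(iso_chrom, c),
                pos=pos + jitter,
                strand=np.repeat(iso_strand, c),
                sample=sd.sample,
                origin="site",
            )
        )
        frames.append(frame)
        # internal-priming reads: a fixed fraction of the sample's total
        rate = config.internal_priming_rate
        if rate > 0 and len(truth.decoys) and total > 0:
            n_decoy = int(round(rate * total / (1.0 - rate)))
            if n_decoy:
                alloc = rng.multinomial(n_decoy, np.full(len(truth.decoys), 1.0 / len(truth.decoys)))
                frames.append(
                    pd.DataFrame(
                        dict(
                            chrom=np.repeat(truth.decoys["chrom"].to_numpy(), alloc),
                            pos=np.repeat(truth.decoys["pos"].to_numpy(), alloc),
                            strand=np.repeat(truth.decoys["strand"].to_numpy(), alloc),
                            sample=sd.sample,
                            origin="decoy",
                        )
                    )
                )

    reads = pd.concat(frames, ignore_index=True)
    reads["pos"] = reads["pos"].astype(int)
    return reads.sort_values(["chrom", "pos", "strand", "sample"], kind="stable").reset_index(drop=True)


def truth_to_frames(truth: TruthTable) -> dict[str, pd.DataFrame]:
    return dataclasses.asdict(truth)
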