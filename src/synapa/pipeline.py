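"""End-to-end pipeline orchestration with a run manifest.

Stages (dependency order): simulate -> call-sites -> de -> call-targets ->
utr-length -> binding -> enrich. Every stage reads plain-text
intermediates from the output directory and can be re-run from them; with
``resume=True`` stages whose outputs already exist are skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import binding, de, enrich, io, simulate, sites, utr_length

logger = logging.getLogger(__name__)

STAGES = ("simulate", "call_sites", "de", "call_targets", "utr_length", "binding", "enrich")


@dataclasses.dataclass
class PipelineConfig:
    """Run configuration; ``sim`` holds the synthetic-data parameters."""

    outdir: Path
    mode: str = "xrip"
    seed: int = 0
    min_expr: float = 5.0
    alpha: float = 0.05
    sim: simulate.SimConfig = dataclasses.field(default_factory=simulate.SimConfig)
    target_params: de.TargetCallParams = dataclasses.field(default_factory=de.TargetCallParams)
    cluster_params: sites.ClusterParams = dataclasses.field(default_factory=sites.ClusterParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = io.load_yaml(path)
        sim = simulate.SimConfig(**raw.pop("sim", {}))
        tp = de.TargetCallParams(**raw.pop("target_params", {}))
        cp = sites.ClusterParams(**raw.pop("cluster_params", {}))
        raw["outdir"] = Path(raw.get("outdir", "synapa_out"))
        return cls(sim=sim, target_params=tp, cluster_params=cp, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            dataclasses.asdict(self), default=str, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    def __init__(self, config: PipelineConfig):
        self.data: dict = {
            "tool": "synapa",
            "version": __import__("synapa").__version__,
            "config_hash": config.config_hash(),
            "stages": {},
        }

    def record(self, stage: str, outputs: list[Path], counts: dict[str, int]) -> None:
        self.data["stages"][stage] = {
            "outputs": {str(p): _sha256(p) for p in outputs},
            "counts": {k: int(v) for k, v in counts.items()},
        }

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config: PipelineConfig, resume: bool = False) -> Manifest:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config)
    paths = {
        "genome": out / "genome.fa",
        "annotation": out / "annotation.gff3",
        "annotation_bed": out / "annotation.bed12",
        "validated": out / "validated_ends.bed",
        "reads": out / "reads.bed",
        "origins": out / "read_origins.tsv",
        "truth_genes": out / "truth_genes.tsv",
        "truth_isoforms": out / "truth_isoforms.tsv",
        "truth_decoys": out / "truth_decoys.tsv",
        "sample_sheet": out / "samples.tsv",
        "clusters": out / "clusters.bed",
        "gene_counts": out / "gene_counts.tsv",
        "de_rip": out / "de_rip_vs_input.tsv",
        "de_ctrl": out / "de_rip_vs_ctrl.tsv",
        "de_syn": out / "de_syn_vs_input.tsv",
        "targets": out / "targets.tsv",
        "utr_stats": out / "utr_length_stats.tsv",
        "proportions": out / "long_isoform_proportions.tsv",
        "binding_test": out / "binding_test.tsv",
        "enrichment": out / "enrichment.tsv",
        "manifest": out / "manifest.json",
    }

    def done(stage: str, *keys: str) -> bool:
        """True when resuming and all stage outputs exist (recorded as reused)."""
        ok = resume and all(paths[k].exists() for k in keys)
        if ok:
            manifest.record(stage, [paths[k] for k in keys], dict(reused=1))
            logger.info("resume: skipping %s", stage)
        return ok

    cfg = dataclasses.replace(config.sim, seed=config.seed)

    # --- stage: simulate -------------------------------------------------
    stage_keys = (
        "genome", "annotation", "annotation_bed", "validated", "reads",
        "origins", "truth_genes", "truth_isoforms", "truth_decoys", "sample_sheet",
    )
    if not done("simulate", *stage_keys):
        genome, genes, validated, truth = simulate.generate_reference(cfg)
        design = simulate.default_design(cfg)
        reads = simulate.simulate_end_reads(truth, design, cfg)
        io.write_fasta(genome, paths["genome"])
        ann_ends = truth.isoforms[["gene_id", "chrom", "end_pos", "strand"]].rename(
            columns={"end_pos": "pos"}
        )
        io.write_gff3(genes, ann_ends, paths["annotation"])
        io.write_bed12(genes, paths["annotation_bed"])
        io.write_validated_ends(validated, paths["validated"])
        io.write_bed6(reads, paths["reads"])
        io.write_table(reads[["chrom", "pos", "strand", "sample", "origin"]], paths["origins"])
        io.write_table(truth.genes, paths["truth_genes"])
        io.write_table(truth.isoforms, paths["truth_isoforms"])
        io.write_table(truth.decoys, paths["truth_decoys"])
        sheet = pd.DataFrame(
            [dataclasses.asdict(sd) for sd in design]
        )
        io.write_table(sheet, paths["sample_sheet"])
        manifest.record(
            "simulate",
            [paths[k] for k in stage_keys],
            dict(genes=len(genes), reads=len(reads), validated_ends=len(validated)),
        )

    genome = io.read_fasta(paths["genome"])
    genes, ann_ends = io.read_gff3(paths["annotation"], genome)
    validated = io.read_validated_ends(paths["validated"], genome)
    reads = io.read_bed6(paths["reads"], genome)
    sheet = io.read_sample_sheet(paths["sample_sheet"])
    conditions = sheet.set_index("sample")["condition"]

    # --- stage: call-sites ----------------------------------------------
    bl_params = sites.blacklist_params_for_mode(config.mode)
    if not done("call_sites", "clusters", "gene_counts"):
        masks = sites.compute_blacklist(genome, ann_ends, bl_params)
        windowed = sites.restrict_to_gene_windows(reads, genes, bl_params)
        filtered = sites.apply_blacklist(windowed, masks)
        clusters = sites.call_clusters(filtered, None, config.cluster_params)
        clusters = sites.count_clusters(filtered, clusters)
        clusters = sites.validate_clusters(clusters, validated, config.cluster_params)
        clusters = sites.assign_clusters_to_genes(clusters, genes, bl_params)
        sample_cols = sites.sample_columns(clusters)
        io.write_clusters_bed(clusters, sample_cols, paths["clusters"])
        gene_counts = de.gene_level_counts(clusters, sample_cols)
        io.write_counts_tsv(gene_counts, paths["gene_counts"], index_label="gene")
        manifest.record(
            "call_sites",
            [paths["clusters"], paths["gene_counts"]],
            dict(
                reads_in=len(reads),
                reads_after_window=len(windowed),
                reads_after_blacklist=len(filtered),
                clusters=len(clusters),
            ),
        )
    clusters, sample_cols = io.read_clusters_bed(paths["clusters"])
    gene_counts = io.read_counts_tsv(paths["gene_counts"])

    # --- stage: de -------------------------------------------------------
    if not done("de", "de_rip", "de_ctrl", "de_syn"):
        res_rip = de.nb_wald_test(gene_counts, conditions, "input", "rip")
        res_ctrl = de.nb_wald_test(gene_counts, conditions, "control_rip", "rip")
        res_syn = de.nb_wald_test(gene_counts, conditions, "input", "synaptosome")
        for res, key in ((res_rip, "de_rip"), (res_ctrl, "de_ctrl"), (res_syn, "de_syn")):
            io.write_table(res, paths[key], index=True, index_label="gene")
        manifest.record(
            "de",
            [paths["de_rip"], paths["de_ctrl"], paths["de_syn"]],
            dict(genes_tested=int(res_rip["tested"].sum())),
        )
    res_rip = pd.read_csv(paths["de_rip"], sep="\t", index_col=0)
    res_ctrl = pd.read_csv(paths["de_ctrl"], sep="\t", index_col=0)
    res_syn = pd.read_csv(paths["de_syn"], sep="\t", index_col=0)

    # --- stage: call-targets --------------------------------------------
    if not done("call_targets", "targets"):
        evidence = de.call_pum_targets(res_rip, res_ctrl, config.target_params)
        io.write_table(evidence, paths["targets"], index=True, index_label="gene")
        manifest.record(
            "call_targets", [paths["targets"]], dict(targets=int(evidence["is_target"].sum()))
        )
    evidence = pd.read_csv(paths["targets"], sep="\t", index_col=0)
    targets = set(evidence.index[evidence["is_target"]])

    # --- stage: utr-length ----------------------------------------------
    factors = de.size_factors(gene_counts)  # gene-level factors reused for clusters
    cluster_counts = clusters[sample_cols]
    norm_clusters = cluster_counts / factors
    if not done("utr_length", "utr_stats"):
        iso = utr_length.build_isoform_table(
            clusters, genes, norm_clusters, conditions, min_expr=config.min_expr
        )
        stats = utr_length.compute_gene_stats(iso)
        called = utr_length.call_localized_genes(stats, alpha=config.alpha)
        io.write_table(called, paths["utr_stats"])
        manifest.record(
            "utr_length",
            [paths["utr_stats"]],
            dict(
                apa_genes=len(called),
                longer_in_syn=int((called["localization_class"] == "longer_in_syn").sum()) if len(called) else 0,
                shorter_in_syn=int((called["localization_class"] == "shorter_in_syn").sum()) if len(called) else 0,
            ),
        )
    called = pd.read_csv(paths["utr_stats"], sep="\t")

    # --- stage: binding --------------------------------------------------
    if not done("binding", "proportions", "binding_test"):
        iso = utr_length.build_isoform_table(
            clusters, genes, norm_clusters, conditions, min_expr=config.min_expr
        )
        # proximal site: most proximal expressed isoform end per gene
        prox = {}
        for gid, sub in iso.groupby("gene"):
            prox[gid] = int(sub.loc[sub["utr_length"].idxmin(), "end_pos"])
        prox_sites = pd.Series(prox)
        strands = genes.set_index("gene_id")["strand"]
        norm_named = norm_clusters.copy()
        norm_named[["chrom", "strand", "start", "end", "summit", "gene"]] = clusters[
            ["chrom", "strand", "start", "end", "summit", "gene"]
        ]
        cond_samples = {
            c: [s for s in sample_cols if conditions.get(s) == c]
            for c in ("input", "rip", "control_rip")
        }
        props = binding.proportion_table(norm_named, prox_sites, strands, cond_samples)
        test_rows = []
        if len(props) >= 3:
            for cond_b, label in (("rip", "rip_vs_input"), ("control_rip", "ctrl_vs_input")):
                r = binding.binding_preference_test(props["input"], props[cond_b])
                r["comparison"] = label
                test_rows.append(r)
        io.write_table(props.reset_index(), paths["proportions"])
        io.write_table(pd.DataFrame(test_rows), paths["binding_test"])
        manifest.record(
            "binding", [paths["proportions"], paths["binding_test"]], dict(genes=len(props))
        )

    # --- stage: enrich ---------------------------------------------------
    if not done("enrich", "enrichment"):
        background = set(gene_counts.index)
        rows = []
        for cls in ("shorter_in_syn", "longer_in_syn"):
            category = set(called.loc[called["localization_class"] == cls, "gene"]) & background
            query = targets & background
            if category and query:
                ratio, table, p = enrich.overlap_enrichment(query, category, background)
                rows.append(
                    dict(
                        category=cls, a=table.a, b=table.b, c=table.c, d=table.d,
                        ratio=ratio, odds_ratio=table.odds_ratio(), p=p,
                    )
                )
        io.write_table(pd.DataFrame(rows), paths["enrichment"])
        manifest.record("enrich", [paths["enrichment"]], dict(categories=len(rows)))

    manifest.write(paths["manifest"])
    return manifest
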