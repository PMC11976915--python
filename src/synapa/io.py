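"""Readers and writers for the plain-text formats the pipeline uses.

Genome: FASTA. Gene models: GFF3 (``gene`` features carrying a
``utr_start`` attribute with ``three_prime_end`` children), plus a BED12
convenience export. Read 3'-ends and validated ends: 6-column BED, one
record per read (name = sample, score = 1). Tables: TSV. Config: YAML.

All records are validated on load: starts before ends, strands in {+,-},
and chromosome names consistent with the genome where one is supplied.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """A malformed input record (message carries file and line number)."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED


def read_bed6(path: str | Path, genome: dict[str, str] | None = None) -> pd.DataFrame:
    """6-column BED of single-base records -> (chrom, pos, strand, sample).

    ``name`` becomes ``sample``. Intervals wider than one base are
    rejected, as are inverted intervals and unknown chromosomes.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{ln}: expected 6 BED columns, got {len(parts)}")
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from None
            if start_i >= end_i:
                raise FormatError(f"{path}:{ln}: start >= end ({start_i} >= {end_i})")
            if end_i - start_i != 1:
                raise FormatError(f"{path}:{ln}: expected single-base record")
            if strand not in "+-":
                raise FormatError(f"{path}:{ln}: strand must be + or -")
            rows.append((chrom, start_i, strand, name))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "sample"])
    if genome is not None:
        check_chromosomes(df["chrom"], genome, str(path))
    return df


def write_bed6(df: pd.DataFrame, path: str | Path, name_col: str = "sample", score: int = 1) -> None:
    out = pd.DataFrame(
        dict(
            chrom=df["chrom"],
            start=df["pos"],
            end=df["pos"] + 1,
            name=df[name_col] if name_col in df else ".",
            score=score,
            strand=df["strand"],
        )
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_validated_ends(path: str | Path, genome: dict[str, str] | None = None) -> pd.DataFrame:
    df = read_bed6(path, genome)
    return (
        df[["chrom", "pos", "strand"]]
        .drop_duplicates()
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )


def write_validated_ends(df: pd.DataFrame, path: str | Path) -> None:
    tmp = df.copy()
    tmp["sample"] = "validated_end"
    write_bed6(tmp, path)


def check_chromosomes(chroms: pd.Series, genome: dict[str, str], source: str) -> None:
    unknown = sorted(set(chroms) - set(genome))
    if unknown:
        known = sorted(genome)
        hint = ""
        stripped = {c.removeprefix("chr") for c in known} | {f"chr{c}" for c in known}
        if set(unknown) & stripped:
            hint = " (naming mismatch, e.g. '2L' vs 'chr2L': rename one side consistently)"
        raise FormatError(
            f"{source}: chromosome(s) {unknown} absent from genome {known}{hint}"
        )


# ---------------------------------------------------------------------------
# GFF3 gene models


def write_gff3(genes: pd.DataFrame, annotated_ends: pd.DataFrame, path: str | Path) -> None:
    """Gene models as GFF3: one ``gene`` per row of ``genes`` (columns
    gene_id, chrom, start, end, strand, utr_start) with ``three_prime_end``
    children from ``annotated_ends`` (gene_id, chrom, pos, strand)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        ends_by_gene = annotated_ends.groupby("gene_id") if len(annotated_ends) else None
        for g in genes.itertuples(index=False):
            attrs = f"ID={g.gene_id};utr_start={g.utr_start}"
            fh.write(
                f"{g.chrom}\tsynapa\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            if ends_by_gene is not None and g.gene_id in ends_by_gene.groups:
                for e in ends_by_gene.get_group(g.gene_id).itertuples(index=False):
                    fh.write(
                        f"{e.chrom}\tsynapa\tthree_prime_end\t{e.pos + 1}\t{e.pos + 1}\t.\t"
                        f"{e.strand}\t.\tParent={g.gene_id}\n"
                    )


def read_gff3(path: str | Path, genome: dict[str, str] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse gene models written by :func:`write_gff3`.

    Returns ``(genes, annotated_ends)``. Every gene must carry a
    ``utr_start`` attribute and at least one ``three_prime_end`` child.
    """
    gene_rows, end_rows = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{ln}: expected 9 GFF3 columns, got {len(parts)}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from None
            if start_i > end_i:
                raise FormatError(f"{path}:{ln}: start > end")
            kv = dict(item.split("=", 1) for item in attrs.split(";") if "=" in item)
            if ftype == "gene":
                if "ID" not in kv or "utr_start" not in kv:
                    raise FormatError(f"{path}:{ln}: gene needs ID and utr_start attributes")
                gene_rows.append(
                    dict(
                        gene_id=kv["ID"],
                        chrom=chrom,
                        start=start_i - 1,
                        end=end_i,
                        strand=strand,
                        utr_start=int(kv["utr_start"]),
                    )
                )
            elif ftype == "three_prime_end":
                if "Parent" not in kv:
                    raise FormatError(f"{path}:{ln}: three_prime_end needs a Parent")
                end_rows.append(
                    dict(gene_id=kv["Parent"], chrom=chrom, pos=start_i - 1, strand=strand)
                )
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "utr_start"])
    ends = pd.DataFrame(end_rows, columns=["gene_id", "chrom", "pos", "strand"])
    with_children = set(ends["gene_id"])
    orphans = [g for g in genes["gene_id"] if g not in with_children]
    if orphans:
        raise FormatError(f"{path}: gene(s) without three_prime_end children: {orphans[:5]}")
    if genome is not None:
        check_chromosomes(genes["chrom"], genome, str(path))
    return genes, ends


def write_bed12(genes: pd.DataFrame, path: str | Path) -> None:
    """Flattened single-block BED12 export of the gene spans."""
    with open(path, "w") as fh:
        for g in genes.itertuples(index=False):
            size = g.end - g.start
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0,0,0\t1\t{size},\t0,\n"
            )


# ---------------------------------------------------------------------------
# cluster / counts tables


def write_clusters_bed(clusters: pd.DataFrame, sample_cols: list[str], path: str | Path) -> None:
    """Clusters as BED6+ (thickStart = summit, extra per-sample counts)."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tname\tscore\tstrand\tsummit\tgene\tvalidated\t"
            + "\t".join(sample_cols)
            + "\n"
        )
        for i, row in enumerate(clusters.itertuples(index=False), start=1):
            gene = getattr(row, "gene", ".") or "."
            validated = int(bool(getattr(row, "validated", False)))
            counts = "\t".join(str(int(getattr(row, s))) for s in sample_cols)
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\tcluster{i:05d}\t0\t{row.strand}\t"
                f"{row.summit}\t{gene}\t{validated}\t{counts}\n"
            )


def read_clusters_bed(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise FormatError(f"{path}:1: missing header line")
        cols = header.lstrip("#").split("\t")
        sample_cols = cols[9:]
        rows = []
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(cols):
                raise FormatError(f"{path}:{ln}: column count mismatch")
            rec = dict(zip(cols, parts))
            row = dict(
                chrom=rec["chrom"],
                strand=rec["strand"],
                start=int(rec["start"]),
                end=int(rec["end"]),
                summit=int(rec["summit"]),
                gene=None if rec["gene"] == "." else rec["gene"],
                validated=bool(int(rec["validated"])),
            )
            if row["start"] >= row["end"]:
                raise FormatError(f"{path}:{ln}: start >= end")
            for s in sample_cols:
                row[s] = int(rec[s])
            rows.append(row)
    return pd.DataFrame(rows), sample_cols


def write_counts_tsv(counts: pd.DataFrame, path: str | Path, index_label: str = "feature") -> None:
    counts.to_csv(path, sep="\t", index_label=index_label)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False, index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label, float_format=FLOAT_FORMAT)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "condition"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: sample sheet needs columns {sorted(required)}")
    return df


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line (first TSV column; '#' comments skipped)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split("\t")[0])
    return out


# ---------------------------------------------------------------------------
# config


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_yaml(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
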