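"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: chrom-sizes TSV, GFF3 gene annotation, BED6,
FASTA (Biopython out, pyfaidx in), headered TSV tables (probes, expression,
spikes, FISH coordinates, candidate table) and JASPAR plain-text PWMs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .regions import GeneModel, GenomicInterval

PROBE_COLUMNS = [
    "probe_id", "chrom", "start", "end", "e4c", "control", "replicate", "condition",
]
FISH_COLUMNS = ["nucleus_id", "condition", "gene", "x_um", "y_um", "z_um"]


# ---------------------------------------------------------------- chrom sizes

def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, size = line.split("\t")
        sizes[chrom] = int(size)
    return sizes


# ----------------------------------------------------------------------- GFF3

def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 ``gene`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};Name={g.symbol}"
            fh.write(
                f"{g.interval.chrom}\tgfap4c\tgene\t{g.interval.start + 1}\t"
                f"{g.interval.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9 or fields[2] != "gene":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
        )
        genes.append(
            GeneModel(
                gene_id=attrs.get("ID", ""),
                symbol=attrs.get("Name", attrs.get("ID", "")),
                interval=GenomicInterval(
                    fields[0], int(fields[3]) - 1, int(fields[4]), fields[6]
                ),
            )
        )
    return genes


# ----------------------------------------------------------------------- BED6

def write_bed6(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Iterable[str] | None = None,
) -> None:
    rows = list(intervals)
    labels = list(names) if names is not None else [
        f"region_{i}" for i in range(len(rows))
    ]
    with open(path, "w") as fh:
        for iv, name in zip(rows, labels, strict=True):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed6(path: str | Path) -> list[GenomicInterval]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        strand = f[5] if len(f) > 5 else "."
        out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


# ---------------------------------------------------------------------- FASTA

def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def open_fasta(path: str | Path):
    """Open a FASTA for random access (indexed via pyfaidx)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


# ----------------------------------------------------------------- TSV tables

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_probe_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"probe table {path} missing columns {sorted(missing)}")
    return df


def read_fish_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(FISH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"FISH table {path} missing columns {sorted(missing)}")
    return df


def read_gene_set(path: str | Path) -> set[str]:
    """One accession per line, blank lines and ``#`` comments ignored."""
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }


# --------------------------------------------------------------------- JASPAR

def read_jaspar(path: str | Path) -> tuple[str, np.ndarray]:
    """Read a JASPAR plain-text matrix; returns (motif name, 4xL counts).

    Accepts both the bracketed ``A [ 1 2 3 ]`` and the bare whitespace layout.
    Rows are returned in A, C, G, T order.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    name = "motif"
    rows: dict[str, list[float]] = {}
    order = []
    for ln in lines:
        if ln.startswith(">"):
            name = ln[1:].strip().split()[0]
            continue
        token = ln.strip()
        base = token[0].upper()
        if base not in "ACGT":
            raise ValueError(f"unexpected JASPAR row: {ln!r}")
        body = token[1:].replace("[", " ").replace("]", " ")
        rows[base] = [float(x) for x in body.split()]
        order.append(base)
    if sorted(order) != ["A", "C", "G", "T"]:
        raise ValueError("JASPAR matrix must have exactly one row per base")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ValueError("JASPAR rows have unequal lengths")
    return name, np.array([rows[b] for b in "ACGT"], dtype=float)


def write_jaspar(name: str, counts: np.ndarray, path: str | Path) -> None:
    counts = np.asarray(counts, dtype=float)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for base, row in zip("ACGT", counts):
            body = " ".join(f"{x:g}" for x in row)
            fh.write(f"{base} [ {body} ]\n")


# ------------------------------------------------------------ bundle on disk

def write_bundle(bundle, outdir: str | Path) -> dict[str, Path]:
    """Write every synthetic-study input (and truth labels) as text files."""
    from .config import dump_config

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chrom_sizes": outdir / "chrom_sizes.tsv",
        "genes": outdir / "genes.gff3",
        "genome": outdir / "genome.fa",
        "probes": outdir / "probes.tsv",
        "e4c_signals": outdir / "e4c_signals.tsv",
        "e4c_truth": outdir / "e4c_truth.tsv",
        "expression": outdir / "expression_intensities.tsv",
        "spikes": outdir / "spikes.tsv",
        "true_copies": outdir / "true_copies.tsv",
        "planted_assoc": outdir / "planted_assoc_genes.tsv",
        "truth_candidates": outdir / "truth_candidates.txt",
        "config": outdir / "config.yaml",
    }
    write_chrom_sizes(bundle.chrom_sizes, paths["chrom_sizes"])
    write_gff3(bundle.genes, paths["genes"])
    write_fasta(bundle.sequences, paths["genome"])
    write_table(bundle.probes, paths["probes"])
    write_table(bundle.e4c_signals, paths["e4c_signals"])
    write_table(bundle.e4c_truth, paths["e4c_truth"])
    write_table(bundle.expression_intensities, paths["expression"])
    write_table(bundle.spikes, paths["spikes"])
    write_table(bundle.true_copies, paths["true_copies"])
    rows = [
        (cond, gid)
        for cond, ids in bundle.planted_assoc.items()
        for gid in sorted(ids)
    ]
    pd.DataFrame(rows, columns=["condition", "gene_id"]).to_csv(
        paths["planted_assoc"], sep="\t", index=False
    )
    paths["truth_candidates"].write_text(
        "\n".join(sorted(bundle.truth_candidates)) + "\n"
    )
    from .config import PipelineConfig

    dump_config(bundle.config, PipelineConfig(), paths["config"])
    return paths
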