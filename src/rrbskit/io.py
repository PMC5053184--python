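"""File input/output for every format the toolkit touches.

All genomic coordinates are 0-based half-open in memory and 1-based in
exported per-cytosine tables (BED stays 0-based half-open, as the format
requires).  Every reader/writer is gzip-transparent based on the ``.gz``
suffix.  No other module opens files directly.
"""

from __future__ import annotations

import gzip
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    GeneModel,
    GenomeAnnotation,
    Region,
    RepeatRegion,
    REPORT_COLUMNS,
    make_report,
)

TOOL_TAG = "rrbskit 0.1.0"


class _DeterministicGzip(gzip.GzipFile):
    """Gzip writer with fixed mtime and no embedded filename, so repeated
    runs produce byte-identical archives; closes the underlying file too."""

    def __init__(self, path):
        self._raw = open(path, "wb")
        super().__init__(filename="", mode="wb", fileobj=self._raw, mtime=0)

    def close(self):
        super().close()
        if not self._raw.closed:
            self._raw.close()


def xopen(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            raw = _DeterministicGzip(path)
            return raw if "b" in mode else _io.TextIOWrapper(raw)
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(path, chromosomes: dict) -> None:
    """Write chromosomes in insertion order, 80-column wrapped."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in chromosomes.items()
    ]
    with xopen(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict:
    with xopen(path, "rt") as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fastq(path, reads, quality_char: str = "I") -> None:
    """Write ``(read_id, sequence)`` pairs with constant Phred+33 quality."""
    with xopen(path, "wt") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path):
    """Yield ``(read_id, sequence)`` pairs."""
    try:
        import pysam

        with pysam.FastxFile(str(path)) as fx:
            for entry in fx:
                yield entry.name, entry.sequence.upper()
        return
    except (ImportError, OSError):
        pass
    with xopen(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq).upper()


# ---------------------------------------------------------------------------
# BED


def write_bed6(path, regions, names=None, scores=None, strands=None) -> None:
    with xopen(path, "wt") as fh:
        for i, r in enumerate(regions):
            name = names[i] if names is not None else f"feature_{i}"
            score = scores[i] if scores is not None else 0
            strand = strands[i] if strands is not None else "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}\t{strand}\n")


def read_bed6(path):
    """Return (regions, names, strands) from a BED3+/BED6 file."""
    regions, names, strands = [], [], []
    with xopen(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED record needs >= 3 fields")
            try:
                regions.append(Region(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            names.append(parts[3] if len(parts) > 3 else f"feature_{lineno}")
            strands.append(parts[5] if len(parts) > 5 else ".")
    return regions, names, strands


def write_gene_models_bed12(path, genes) -> None:
    with xopen(path, "wt") as fh:
        for g in genes:
            exons = g.exons or ((g.start, g.end),)
            sizes = ",".join(str(e - s) for s, e in exons) + ","
            starts = ",".join(str(s - g.start) for s, e in exons) + ","
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(exons)}\t{sizes}\t{starts}\n"
            )


def read_gene_models(path):
    """Read BED12 gene models (one collapsed transcript per gene)."""
    genes = []
    with xopen(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            if len(p) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 fields")
            start, end = int(p[1]), int(p[2])
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            offsets = [int(x) for x in p[11].rstrip(",").split(",")]
            exons = tuple(
                (start + off, start + off + size) for off, size in zip(offsets, sizes)
            )
            genes.append(
                GeneModel(
                    name=p[3], chrom=p[0], strand=p[5], start=start, end=end, exons=exons
                )
            )
    return genes


# ---------------------------------------------------------------------------
# annotation bundle


def write_annotation(outdir, genome: GenomeAnnotation) -> dict:
    """Write the full annotation bundle; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.bed",
        "cg_islands": outdir / "cg_islands.bed",
        "repeats": outdir / "repeats.bed",
        "meta": outdir / "genome_meta.json",
    }
    write_fasta(paths["genome"], genome.chromosomes)
    write_gene_models_bed12(paths["genes"], genome.genes)
    write_bed6(
        paths["cg_islands"],
        genome.cg_islands,
        names=[f"CGI_{i}" for i in range(len(genome.cg_islands))],
    )
    write_bed6(
        paths["repeats"],
        [r.region for r in genome.repeats],
        names=[r.family for r in genome.repeats],
    )
    paths["meta"].write_text(
        json.dumps({"spike_in": genome.spike_in, "tool": TOOL_TAG}, indent=1)
    )
    return {k: str(v) for k, v in paths.items()}


def read_annotation(outdir) -> GenomeAnnotation:
    outdir = Path(outdir)
    chromosomes = read_fasta(outdir / "genome.fa")
    genes = read_gene_models(outdir / "genes.bed")
    cgis, _, _ = read_bed6(outdir / "cg_islands.bed")
    rep_regions, rep_names, _ = read_bed6(outdir / "repeats.bed")
    meta = json.loads((outdir / "genome_meta.json").read_text())
    genome = GenomeAnnotation(
        chromosomes=chromosomes,
        genes=genes,
        cg_islands=cgis,
        repeats=[RepeatRegion(r, n) for r, n in zip(rep_regions, rep_names)],
        spike_in=meta.get("spike_in"),
    )
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# tabular formats


def _header_comment(params: dict | None) -> str:
    if not params:
        return f"# {TOOL_TAG}\n"
    kv = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"# {TOOL_TAG} {kv}\n"


def write_report(path, report: pd.DataFrame, params: dict | None = None) -> None:
    """Write a per-cytosine report; positions exported 1-based."""
    out = report.copy()
    out["pos"] = out["pos"] + 1
    out = out.rename(columns={"pos": "pos_1based"})
    with xopen(path, "wt") as fh:
        fh.write(_header_comment(params))
        out.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def read_report(path) -> pd.DataFrame:
    df = pd.read_csv(xopen(path, "rt"), sep="\t", comment="#")
    df = df.rename(columns={"pos_1based": "pos"})
    df["pos"] = df["pos"] - 1
    return make_report(df[REPORT_COLUMNS])


def write_bedgraph(path, report: pd.DataFrame) -> None:
    """Export per-cytosine levels as bedGraph (0-based half-open)."""
    with xopen(path, "wt") as fh:
        fh.write('track type=bedGraph name="methylation level"\n')
        for row in report.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.level:.6g}\n")


def write_tsv(path, df: pd.DataFrame, params: dict | None = None) -> None:
    with xopen(path, "wt") as fh:
        fh.write(_header_comment(params))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(xopen(path, "rt"), sep="\t", comment="#")


def write_expression(path, table: pd.DataFrame) -> None:
    """Expression table: ``gene`` column plus one column per sample."""
    out = table.reset_index() if table.index.name == "gene" else table
    write_tsv(path, out)


def read_expression(path) -> pd.DataFrame:
    df = read_tsv(path)
    return df.set_index("gene")


def write_newick(path, newick: str) -> None:
    Path(path).write_text(newick.rstrip() + "\n")


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
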