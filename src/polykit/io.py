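"""Readers and writers for the standard text formats the pipeline speaks.

VCFv4.2 (uncompressed), GFF3 (1-based inclusive), BED (0-based
half-open) and TSV-with-header tables.  Writing is deterministic:
identical in-memory objects serialize to byte-identical files.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, PopulationMap, SYNTELOG_COLUMNS

_GT_STRINGS = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


# ---------------------------------------------------------------------------
# VCF

def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal deterministic VCFv4.2 file.

    The ancestral allele, when resolved, is emitted as ``AA=<base>`` in
    INFO; unresolved sites carry ``.``.
    """
    path = Path(path)
    contigs = dict.fromkeys(g.chrom.tolist())
    lengths = g.contig_lengths or {}
    lines = ["##fileformat=VCFv4.2", "##source=polykit"]
    for c in contigs:
        length = lengths.get(c)
        if length is None:
            length = int(g.pos[g.chrom == c].max())
        lines.append(f"##contig=<ID={c},length={length}>")
    lines.append('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.samples))
    anc = g.ancestral
    for j in range(g.n_sites):
        if anc is None or anc[j] < 0:
            info = "."
        else:
            info = f"AA={g.ref[j] if anc[j] == 0 else g.alt[j]}"
        gts = "\t".join(_GT_STRINGS[int(v)] for v in g.genotypes[:, j])
        lines.append(
            f"{g.chrom[j]}\t{g.pos[j]}\t.\t{g.ref[j]}\t{g.alt[j]}\t.\t.\t{info}\tGT\t{gts}"
        )
    _atomic_write(path, "\n".join(lines) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`."""
    from cyvcf2 import VCF

    reader = VCF(os.fspath(path))
    samples = list(reader.samples)
    chrom, pos, ref, alt, anc_codes, rows = [], [], [], [], [], []
    any_aa = False
    for v in reader:
        if len(v.ALT) != 1:
            raise ValueError(f"non-biallelic record at {v.CHROM}:{v.POS}")
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        aa = v.INFO.get("AA")
        if aa is None:
            anc_codes.append(-1)
        else:
            any_aa = True
            anc_codes.append(0 if aa == v.REF else 1 if aa == v.ALT[0] else -1)
        row = []
        for call in v.genotypes:
            a, b = call[0], call[1]
            row.append(-1 if a < 0 or b < 0 else a + b)
        rows.append(row)
    lengths = {
        name: int(n) for name, n in zip(reader.seqnames, reader.seqlens)
    } if reader.seqlens else None
    reader.close()
    genotypes = (
        np.array(rows, dtype=np.int8).T if rows else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        genotypes=genotypes,
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        ancestral=np.array(anc_codes, dtype=np.int8) if any_aa else None,
        contig_lengths=lengths,
    )


# ---------------------------------------------------------------------------
# GFF3

def write_gff3(genes: pd.DataFrame, path, source: str = "polykit") -> None:
    """Write gene models (columns gene_id, chrom, start, end[, strand])."""
    lines = ["##gff-version 3"]
    strand = genes["strand"] if "strand" in genes.columns else ["+"] * len(genes)
    for (_, row), st in zip(genes.iterrows(), strand):
        lines.append(
            f"{row['chrom']}\t{source}\tgene\t{int(row['start'])}\t{int(row['end'])}"
            f"\t.\t{st}\t.\tID={row['gene_id']}"
        )
    _atomic_write(Path(path), "\n".join(lines) + "\n")


def read_gff3(path, feature_type: str = "gene") -> pd.DataFrame:
    """Read features of one type; returns gene_id, chrom, start, end, strand."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line in {path}: {line!r}")
            if fields[2] != feature_type:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "gene_id": attrs.get("ID", ""),
                    "chrom": fields[0],
                    "start": int(fields[3]),
                    "end": int(fields[4]),
                    "strand": fields[6],
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


# ---------------------------------------------------------------------------
# BED / TSV

def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write 0-based half-open intervals (chrom, start, end[, name, ...])."""
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, names=("chrom", "start", "end", "name")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names)[: df.shape[1]]
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_syntelogs(syntelogs: pd.DataFrame, path) -> None:
    cols = [c for c in SYNTELOG_COLUMNS if c in syntelogs.columns]
    syntelogs[cols].to_csv(path, sep="\t", index=False)


def read_syntelogs(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_cc": "string", "gene_ee": "string", "origin_class": "string"}
    )
    for col in ("gene_cc", "gene_ee", "origin_class"):
        if col in df.columns:
            df[col] = df[col].fillna("").astype(str)
    return df


# ---------------------------------------------------------------------------
# Population map

def write_popmap(popmap: PopulationMap, path) -> None:
    df = pd.DataFrame(
        {"sample": list(popmap.labels), "population": list(popmap.labels.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def read_popmap(path) -> PopulationMap:
    df = pd.read_csv(path, sep="\t")
    return PopulationMap(dict(zip(df["sample"], df["population"])))


def _atomic_write(path: Path, text: str) -> None:
    try:
        tmp = path.with_suffix(path.suffix + ".tmp")
        tmp.write_text(text)
        tmp.replace(path)
    except OSError as exc:
        raise OSError(f"failed writing {path}: {exc}") from exc
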