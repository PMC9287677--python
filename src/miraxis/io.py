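"""Readers and writers for the standard formats the pipeline consumes.

Coordinate conventions: GTF is 1-based inclusive, BED is 0-based
half-open, and everything inside the package is 0-based half-open, so
GTF coordinates are converted here and nowhere else. Round-trips
(``write`` then ``read``) reproduce tables bit-for-bit.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import (
    DNA_ALPHABET,
    GeneModel,
    GeneSetCollection,
    HostMap,
    MirnaRecord,
    ParseError,
    SchemaError,
    UtrSet,
    ValidationError,
)

log = logging.getLogger(__name__)

DE_REQUIRED_COLS = ("feature_id", "log2fc", "pvalue")
DE_OPTIONAL_COLS = ("padj", "base_mean")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, alphabet: str) -> Union[UtrSet, List[MirnaRecord]]:
    """Read FASTA records.

    ``alphabet="rna"`` returns a list of :class:`MirnaRecord`;
    ``alphabet="dna"`` returns a :class:`UtrSet`. Records are uppercased
    and alphabet-validated; order is preserved.
    """
    if alphabet not in ("rna", "dna"):
        raise ValueError("alphabet must be 'rna' or 'dna'")
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header '>', got {line[:30]!r}"
                )
            break
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        log.warning("%s: empty FASTA, returning empty set", path)
    if alphabet == "rna":
        return [MirnaRecord(mir_id=i, sequence=s) for i, s in records]
    return UtrSet.from_pairs(records)


def write_fasta(records: Union[Mapping[str, str], Iterable[Tuple[str, str]]], path) -> None:
    if isinstance(records, Mapping):
        records = records.items()
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# GTF

def read_gtf(path) -> Dict[str, GeneModel]:
    """Read gene models (``gene`` + ``exon`` features) from a GTF file.

    1-based inclusive coordinates become 0-based half-open; exons are
    merged per gene across all transcripts.
    """
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises a zoo of exception types
        raise ParseError(f"{path}: failed to parse GTF ({exc})") from exc

    raw: Dict[str, dict] = {}
    for f in db.features_of_type("gene"):
        gids = f.attributes.get("gene_id", [])
        if not gids:
            raise ParseError(f"{path}: gene feature without gene_id attribute")
        raw[gids[0]] = dict(
            chrom=f.seqid, strand=f.strand, start=f.start - 1, end=f.end, exons=[]
        )
    for f in db.features_of_type("exon"):
        gids = f.attributes.get("gene_id", [])
        if not gids:
            raise ParseError(f"{path}: exon feature without gene_id attribute")
        if gids[0] not in raw:
            raise ParseError(f"{path}: exon references unknown gene_id {gids[0]!r}")
        raw[gids[0]]["exons"].append((f.start - 1, f.end))
    return {gid: GeneModel(gene_id=gid, **spec) for gid, spec in raw.items()}


def write_gtf(models: Mapping[str, GeneModel], path, source: str = "miraxis") -> None:
    with open(path, "w") as fh:
        for g in models.values():
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED

def read_bed(path) -> pd.DataFrame:
    """Read read intervals from BED (0-based half-open, first 3 columns)."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"],
            dtype={"chrom": str},
        )
    except Exception as exc:
        raise ParseError(f"{path}: failed to parse BED ({exc})") from exc
    if df.empty:
        return df
    try:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-integer BED coordinates ({exc})") from exc
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise ValidationError(f"{path}: BED interval with start >= end or start < 0")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path) -> GeneSetCollection:
    """Read a gene-set collection. Layout per line: set_id, description, genes..."""
    path = Path(path)
    sets: GeneSetCollection = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"{path}: line {lineno}: GMT line needs set_id, description and "
                    f">=1 gene, got {len(fields)} fields"
                )
            set_id = fields[0]
            if set_id in sets:
                raise ValidationError(f"{path}: duplicate set_id {set_id!r}")
            members = {g for g in fields[2:] if g}
            if not members:
                raise ValidationError(f"{path}: line {lineno}: empty gene set {set_id!r}")
            sets[set_id] = members
    return sets


def write_gmt(collection: Mapping[str, set], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for set_id, members in collection.items():
            fh.write("\t".join([set_id, description] + sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# Differential-expression tables

def validate_de_table(df: pd.DataFrame, name: str = "DE table") -> pd.DataFrame:
    missing = [c for c in DE_REQUIRED_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required columns {missing}")
    if df["feature_id"].duplicated().any():
        dups = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise ValidationError(f"{name}: duplicate feature_id {dups!r}")
    p = df["pvalue"].to_numpy(dtype=float)
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValidationError(f"{name}: pvalue outside [0,1]")
    if "padj" in df.columns:
        q = df["padj"].to_numpy(dtype=float)
        both = valid & ~np.isnan(q)
        if np.any((q[both] < 0) | (q[both] > 1)):
            raise ValidationError(f"{name}: padj outside [0,1]")
        if np.any(q[both] + 1e-9 < p[both]):
            raise ValidationError(f"{name}: padj < pvalue violates the BH property")
    if "base_mean" in df.columns:
        b = df["base_mean"].to_numpy(dtype=float)
        if np.any(b[~np.isnan(b)] < 0):
            raise ValidationError(f"{name}: negative base_mean")
    return df


def read_de_table(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    return validate_de_table(df, name=str(path))


def write_de_table(df: pd.DataFrame, path) -> None:
    validate_de_table(df)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count matrices and condition maps

def read_tsv_counts(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "feature_id"
    return df


def write_tsv_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("feature_id").to_csv(path, sep="\t")


def read_conditions(path) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "condition"]:
        raise SchemaError(f"{path}: expected columns sample_id, condition")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_id")
    return dict(zip(df["sample_id"], df["condition"]))


def write_conditions(condition: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"sample_id": list(condition), "condition": list(condition.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Host map (MiRIAD-style intronic-miRNA -> host gene)

def read_host_map(path) -> HostMap:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["mir_id", "host_gene_id"]:
        raise SchemaError(f"{path}: expected columns mir_id, host_gene_id")
    if df["mir_id"].duplicated().any():
        dup = df.loc[df["mir_id"].duplicated(), "mir_id"].iloc[0]
        raise ValidationError(f"{path}: miR {dup!r} maps to more than one host gene")
    return dict(zip(df["mir_id"], df["host_gene_id"]))


def write_host_map(host_map: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"mir_id": list(host_map), "host_gene_id": list(host_map.values())}
    ).to_csv(path, sep="\t", index=False)
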