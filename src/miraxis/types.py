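"""Core domain types shared across the pipeline.

Sequences are stored uppercase: mature miRNAs in the RNA alphabet
(5'->3'), 3' UTRs in DNA (``N`` allowed, never matching any word).
Genomic coordinates are 0-based half-open everywhere inside the package;
conversion to and from 1-based file formats happens only in
:mod:`miraxis.io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .intervals import Interval, merge_intervals

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")
UTR_ALPHABET = frozenset("ACGTN")


class MiraxisError(Exception):
    """Base class for all package errors."""


class ParseError(MiraxisError):
    """A file could not be parsed."""


class ValidationError(MiraxisError):
    """A value violates a domain-type invariant."""


class SchemaError(MiraxisError):
    """A table lacks required columns."""


@dataclass(frozen=True)
class MirnaRecord:
    """A mature miRNA sequence, 5'->3', RNA alphabet."""

    mir_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValidationError(f"miRNA {self.mir_id!r}: empty sequence")
        bad = sorted(set(seq) - RNA_ALPHABET)
        if bad:
            raise ValidationError(
                f"miRNA {self.mir_id!r}: characters {bad} outside RNA alphabet ACGU"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class UtrSet:
    """Mapping gene_id -> 3' UTR sequence (uppercase DNA, N allowed)."""

    records: Dict[str, str]

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]]) -> "UtrSet":
        records: Dict[str, str] = {}
        for gene_id, seq in pairs:
            if gene_id in records:
                raise ValidationError(f"duplicate gene_id {gene_id!r} in UTR set")
            s = str(seq).upper()
            if not s:
                raise ValidationError(f"UTR {gene_id!r}: empty sequence")
            bad = sorted(set(s) - UTR_ALPHABET)
            if bad:
                raise ValidationError(
                    f"UTR {gene_id!r}: characters {bad} outside DNA alphabet ACGTN"
                )
            records[gene_id] = s
        return cls(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __getitem__(self, gene_id: str) -> str:
        return self.records[gene_id]

    def items(self):
        return self.records.items()

    @property
    def gene_ids(self) -> List[str]:
        return list(self.records)


@dataclass
class GeneModel:
    """Exon/intron structure of one gene: span plus merged exon union."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: List[Interval]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: malformed span [{self.start},{self.end})"
            )
        for s, e in self.exons:
            if s >= e:
                raise ValidationError(
                    f"gene {self.gene_id!r}: exon with start >= end: [{s},{e})"
                )
            if s < self.start or e > self.end:
                raise ValidationError(
                    f"gene {self.gene_id!r}: exon [{s},{e}) outside gene span "
                    f"[{self.start},{self.end})"
                )
        self.exons = merge_intervals(self.exons)

    @property
    def span(self) -> Interval:
        return (self.start, self.end)


@dataclass
class CountMatrix:
    """Nonnegative integer counts, features x samples, with optional
    sample -> condition labels (required by contrast operations)."""

    counts: pd.DataFrame
    condition: Optional[Dict[str, str]] = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValidationError("duplicate feature_ids in count matrix")
        if c.columns.has_duplicates:
            raise ValidationError("duplicate sample_ids in count matrix")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.isfinite(vals)) or np.any(np.mod(vals, 1) != 0):
                raise ValidationError("counts must be finite integers")
            self.counts = c = c.astype(np.int64)
            vals = c.to_numpy()
        if vals.size and vals.min() < 0:
            raise ValidationError("counts must be nonnegative")
        if self.condition is not None:
            missing = [s for s in c.columns if s not in self.condition]
            if missing:
                raise ValidationError(f"samples without condition label: {missing}")

    @property
    def feature_ids(self) -> List[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.counts.columns)

    def samples_for(self, label: str) -> List[str]:
        if self.condition is None:
            raise ValidationError("count matrix has no condition labels")
        return [s for s in self.counts.columns if self.condition[s] == label]


# Simple alias types; loaders in miraxis.io validate their invariants.
HostMap = Dict[str, str]  # mir_id -> host_gene_id (each miR maps to one host)
GeneSetCollection = Dict[str, set]  # set_id -> set of gene_ids


@dataclass
class SimTruth:
    """Planted ground truth of a synthetic scenario; the oracle that
    downstream recovery tests consume."""

    seed: Optional[int] = None
    planted_target_genes: set = field(default_factory=set)
    # gene_id -> [(offset, site_word), ...]
    planted_site_positions: Dict[str, List[Tuple[int, str]]] = field(default_factory=dict)
    planted_log2fc: Dict[str, float] = field(default_factory=dict)
    planted_mature_log2fc: Dict[str, float] = field(default_factory=dict)
    # mir_id -> (n_datasets_sig, direction)
    planted_consensus_mirs: Dict[str, Tuple[int, str]] = field(default_factory=dict)
    # host_gene_id -> {"transcriptional" | "processing" | "null"}
    scenario: Dict[str, str] = field(default_factory=dict)
    nb_dispersion: Optional[float] = None
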