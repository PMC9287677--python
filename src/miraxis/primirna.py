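"""Pri-miRNA transcription inference from host-gene intronic reads.

For an intronic miRNA, the unspliced primary transcript of its host
gene is the pri-miRNA, so reads falling entirely within host-gene
introns proxy pri-miRNA abundance. Comparing intronic fold changes with
mature-miRNA fold changes separates transcriptional regulation (both
move together) from processing defects (the mature miR moves while the
primary transcript does not).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Interval, overlaps, subtract_intervals
from .types import CountMatrix, GeneModel, HostMap, ValidationError

log = logging.getLogger(__name__)


def intronic_regions(
    gene_models: Mapping[str, GeneModel], host_gene_id: str
) -> List[Interval]:
    """Intronic intervals of a host gene: the gene span minus the exon
    union of every gene overlapping that span (a neighbour's exon inside
    the host must not be mistaken for intron). Empty for intronless
    hosts; a gene with no annotated exons yields its whole span with a
    warning."""
    if host_gene_id not in gene_models:
        raise ValidationError(f"unknown host gene {host_gene_id!r}")
    host = gene_models[host_gene_id]
    blocks: List[Interval] = []
    for g in gene_models.values():
        if g.chrom != host.chrom or not overlaps(g.span, host.span):
            continue
        blocks.extend(g.exons)
    if not blocks:
        log.warning("host gene %s has no annotated exons; whole span treated as intron",
                    host_gene_id)
        return [host.span]
    introns = subtract_intervals(host.span, blocks)
    if not introns:
        log.info("host gene %s is intronless after exon subtraction", host_gene_id)
    return introns


def count_intronic_reads(
    reads: Mapping[str, pd.DataFrame],
    introns: Mapping[str, Sequence[Interval]],
    gene_models: Mapping[str, GeneModel],
    condition: Optional[Dict[str, str]] = None,
) -> CountMatrix:
    """Count, per sample, the reads fully contained in a host gene's
    intronic intervals.

    A read overlapping any exon or an exon-intron junction contributes
    nothing; each read counts at most once per gene.
    """
    sample_ids = list(reads)
    data = np.zeros((len(introns), len(sample_ids)), dtype=np.int64)
    gene_intervals = {
        g: (np.array([s for s, _ in ivs]), np.array([e for _, e in ivs]))
        for g, ivs in introns.items()
        if ivs
    }
    for si, sample in enumerate(sample_ids):
        df = reads[sample]
        if df.empty:
            continue
        if (df["start"] >= df["end"]).any():
            raise ValidationError(f"sample {sample!r}: malformed read interval")
        by_chrom = {
            chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
            for chrom, sub in df.groupby("chrom", sort=False)
        }
        for gi, gene_id in enumerate(introns):
            if gene_id not in gene_intervals:
                continue
            chrom = gene_models[gene_id].chrom
            if chrom not in by_chrom:
                continue
            istart, iend = gene_intervals[gene_id]
            rs, re = by_chrom[chrom]
            idx = np.searchsorted(istart, rs, side="right") - 1
            ok = idx >= 0
            ok[ok] &= re[ok] <= iend[idx[ok]]
            data[gi, si] = int(ok.sum())
    counts = pd.DataFrame(data, index=list(introns), columns=sample_ids)
    return CountMatrix(counts=counts, condition=condition)


def pri_fold_change(
    intronic: CountMatrix,
    condition_a: str,
    condition_b: str,
    pseudocount: float = 0.5,
    min_count: int = 20,
) -> pd.DataFrame:
    """Per-host-gene pri-miRNA log2 fold change (b relative to baseline a).

    Size factors come from total intronic counts per sample — not whole-
    library totals — so exonic amplitude changes cannot masquerade as
    pri-miRNA changes. Genes with fewer than ``min_count`` total intronic
    reads across the contrast are flagged low-coverage.
    """
    a_samples = intronic.samples_for(condition_a)
    b_samples = intronic.samples_for(condition_b)
    if not a_samples or not b_samples:
        raise ValidationError(
            f"conditions {condition_a!r}/{condition_b!r} missing from count matrix"
        )
    counts = intronic.counts[a_samples + b_samples].to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValidationError("a sample has zero total intronic counts")
    sf = totals / totals.mean()
    norm = counts / sf
    na = len(a_samples)
    mean_a = norm[:, :na].mean(axis=1)
    mean_b = norm[:, na:].mean(axis=1)
    lfc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)
    total_per_gene = counts.sum(axis=1)
    return pd.DataFrame(
        dict(
            host_gene_id=intronic.feature_ids,
            pri_log2fc=lfc,
            total_intronic_count=total_per_gene.astype(np.int64),
            low_coverage=total_per_gene < min_count,
        )
    )


def classify_regulation(
    mature_log2fc: float,
    pri_log2fc: float,
    lfc_threshold: float = 0.5,
    concordance_fraction: float = 0.5,
) -> str:
    """Label one miR/host pair.

    transcriptional: the mature change is echoed by a same-sign pri
    change of at least ``concordance_fraction`` of its magnitude;
    post_transcriptional: the mature miR moves but the primary transcript
    does not; discordant: both move past the threshold in opposite
    directions; unchanged: everything else.
    """
    m, p = mature_log2fc, pri_log2fc
    if abs(m) >= lfc_threshold:
        if m * p > 0 and abs(p) >= concordance_fraction * abs(m):
            return "transcriptional"
        if abs(p) < concordance_fraction * abs(m):
            return "post_transcriptional"
        if m * p < 0 and abs(p) >= lfc_threshold:
            return "discordant"
    return "unchanged"


@dataclass(frozen=True)
class CorrelationResult:
    n_mirs: int
    rho: float  # Spearman rank correlation
    rho_p: float
    r: float  # Pearson linear correlation
    r_p: float


def correlate_mature_vs_pri(
    mature_de: pd.DataFrame,
    pri: pd.DataFrame,
    host_map: HostMap,
    lfc_threshold: float = 0.5,
    concordance_fraction: float = 0.5,
) -> Tuple[CorrelationResult, pd.DataFrame]:
    """Pair each intronic miR's mature log2fc with its host's intronic
    (pri) log2fc; report rank and linear correlations over the pairs and
    a per-miR table with scenario calls.

    miRs lacking either measurement, or flagged low-coverage, are kept
    in the table (``included=False``) but excluded from the correlation.
    At least 3 included pairs are required.
    """
    mature_lfc = dict(zip(mature_de["feature_id"], mature_de["log2fc"]))
    pri_lfc = dict(zip(pri["host_gene_id"], pri["pri_log2fc"]))
    low_cov = dict(zip(pri["host_gene_id"], pri["low_coverage"]))
    rows = []
    for mir_id, host in host_map.items():
        m = mature_lfc.get(mir_id, np.nan)
        p = pri_lfc.get(host, np.nan)
        lc = bool(low_cov.get(host, True))
        included = np.isfinite(m) and np.isfinite(p) and not lc
        call = (
            classify_regulation(m, p, lfc_threshold, concordance_fraction)
            if included
            else "not_assessed"
        )
        rows.append(
            dict(
                mir_id=mir_id,
                host_gene_id=host,
                mature_log2fc=m,
                pri_log2fc=p,
                low_coverage=lc,
                included=included,
                scenario_call=call,
            )
        )
    table = pd.DataFrame(rows)
    used = table[table["included"]]
    if len(used) < 3:
        raise ValidationError(
            f"only {len(used)} miR/host pairs with both measurements; need >= 3"
        )
    rho, rho_p = stats.spearmanr(used["mature_log2fc"], used["pri_log2fc"])
    r, r_p = stats.pearsonr(used["mature_log2fc"], used["pri_log2fc"])
    result = CorrelationResult(
        n_mirs=int(len(used)), rho=float(rho), rho_p=float(rho_p),
        r=float(r), r_p=float(r_p),
    )
    return result, table
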