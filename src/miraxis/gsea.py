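"""Permutation-based gene-set enrichment on a ranked gene list.

Genes are ranked from most upregulated to most downregulated; the
enrichment score (ES) is the extremum of a weighted running sum that
increments at gene-set hits and decrements at misses. Significance comes
from gene-label permutation: random same-size sets drawn from the
ranking, with the p-value conditioned on the sign of the observed ES

    p = (1 + #{|ES_perm| >= |ES|, same sign}) / (1 + #{same sign}).

NES normalizes ES by the mean |ES_perm| of the same-sign permutations.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .seed_enrichment import bh_adjust
from .types import GeneSetCollection, ValidationError

log = logging.getLogger(__name__)


def rank_genes(de: pd.DataFrame, metric: str = "log2fc") -> pd.DataFrame:
    """Total ordering of genes: score descending, gene_id ascending on ties.

    ``metric="signed_logp"`` ranks by sign(log2fc) * (-log10 pvalue); if
    any p-value is missing it falls back to log2fc with a logged warning.
    """
    if de.empty:
        raise ValidationError("cannot rank an empty DE table")
    if metric not in ("log2fc", "signed_logp"):
        raise ValidationError(f"unknown ranking metric {metric!r}")
    df = de[["feature_id"]].copy()
    df.rename(columns={"feature_id": "gene_id"}, inplace=True)
    if metric == "signed_logp":
        p = de["pvalue"].to_numpy(dtype=float)
        if np.any(np.isnan(p)):
            log.warning("missing p-values; falling back to log2fc ranking metric")
            df["score"] = de["log2fc"].to_numpy(dtype=float)
        else:
            lfc = de["log2fc"].to_numpy(dtype=float)
            df["score"] = np.sign(lfc) * (-np.log10(np.clip(p, 1e-300, None)))
    else:
        df["score"] = de["log2fc"].to_numpy(dtype=float)
    return df.sort_values(
        ["score", "gene_id"], ascending=[False, True], ignore_index=True
    )


@dataclass
class EsResult:
    es: float
    running_sum: np.ndarray
    leading_edge: List[str]
    n_hits: int
    n_dropped: int


def enrichment_score(
    ranked: pd.DataFrame, gene_set: Iterable[str], weight: float = 1.0
) -> EsResult:
    """Weighted running-sum enrichment score of ``gene_set`` in ``ranked``.

    Hits increment by |score|^weight / sum over hits of |score|^weight,
    misses decrement by 1/(N - n_hits); ES is the extremum of largest
    magnitude. The leading edge is the hits at or before (after, for a
    negative ES) the extremum. Set members absent from the ranking are
    dropped with a logged count.
    """
    gene_set = set(gene_set)
    ids = ranked["gene_id"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    N = ids.size
    hit = np.isin(ids, list(gene_set))
    n_hits = int(hit.sum())
    n_dropped = len(gene_set) - n_hits
    if n_dropped:
        log.info("%d gene-set members absent from the ranking; dropped", n_dropped)
    if n_hits == 0:
        raise ValidationError("gene set has no overlap with the ranked list")
    if n_hits == N:
        raise ValidationError("gene set covers the entire ranked list")
    w = np.where(hit, np.abs(scores) ** weight, 0.0)
    W = w.sum()
    if W == 0:
        log.warning("all hit scores are zero; using equal hit weights")
        w = hit.astype(float)
        W = w.sum()
    steps = np.where(hit, w / W, -1.0 / (N - n_hits))
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    es = float(running[idx])
    if es >= 0:
        leading = [g for i, g in enumerate(ids) if hit[i] and i <= idx]
    else:
        leading = [g for i, g in enumerate(ids) if hit[i] and i >= idx]
    return EsResult(es=es, running_sum=running, leading_edge=leading,
                    n_hits=n_hits, n_dropped=n_dropped)


def _permutation_es(
    abs_scores_w: np.ndarray, n_hits: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES of ``n_perm`` random same-size hit sets, from hit positions only.

    For sorted hit positions p_0 < ... < p_{k-1} with weights w_j, the
    running sum immediately after hit j is cumw_j/W - (p_j - j)/(N - k)
    and immediately before it is cumw_{j-1}/W - (p_j - j)/(N - k); all
    extrema lie at these 2k candidate points.
    """
    N = abs_scores_w.size
    k = n_hits
    # k smallest of i.i.d. uniforms index a uniform random k-subset
    pos = np.argpartition(rng.random((n_perm, N)), k, axis=1)[:, :k]
    pos = np.sort(pos, axis=1)
    w = abs_scores_w[pos]
    W = w.sum(axis=1, keepdims=True)
    zero = (W == 0).ravel()
    if zero.any():
        w[zero] = 1.0
        W = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) / W
    d = 1.0 / (N - k)
    j = np.arange(k)
    miss_drop = (pos - j) * d
    after = cum - miss_drop
    before = np.concatenate([np.zeros((n_perm, 1)), cum[:, :-1]], axis=1) - miss_drop
    cand = np.empty((n_perm, 2 * k))
    cand[:, 0::2] = before
    cand[:, 1::2] = after
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(n_perm), idx]


@dataclass
class GseaResult:
    set_id: Optional[str]
    es: float
    nes: float  # NaN when < 10 same-sign permutations
    pvalue: float
    n_hits: int
    leading_edge: List[str] = field(default_factory=list)


def gsea_permutation(
    ranked: pd.DataFrame,
    gene_set: Iterable[str],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: Optional[int] = None,
    set_id: Optional[str] = None,
) -> GseaResult:
    """Gene-label permutation p-value and NES for one gene set."""
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    esr = enrichment_score(ranked, gene_set, weight=weight)
    scores = ranked["score"].to_numpy(dtype=float)
    abs_w = np.abs(scores) ** weight
    rng = np.random.default_rng(seed)
    perm = _permutation_es(abs_w, esr.n_hits, n_perm, rng)
    sign = np.sign(esr.es)
    same = np.sign(perm) == sign
    n_same = int(same.sum())
    if sign == 0 or n_same == 0:
        log.warning("no same-sign permutations; reporting p = 1.0")
        pvalue, nes = 1.0, float("nan")
    else:
        n_ge = int(np.sum(same & (np.abs(perm) >= abs(esr.es))))
        pvalue = (1 + n_ge) / (1 + n_same)
        nes = esr.es / float(np.mean(np.abs(perm[same]))) if n_same >= 10 else float("nan")
    return GseaResult(
        set_id=set_id,
        es=esr.es,
        nes=nes,
        pvalue=pvalue,
        n_hits=esr.n_hits,
        leading_edge=esr.leading_edge,
    )


def gsea_collection(
    ranked: pd.DataFrame,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: Optional[int] = None,
) -> Tuple[pd.DataFrame, List[str]]:
    """Run the permutation test over a collection; BH across its sets.

    Returns the per-set result table (sorted by padj, then p, then id)
    and the list of sets skipped for lack of overlap with the ranking.
    """
    present = set(ranked["gene_id"])
    skipped: List[str] = []
    results: List[GseaResult] = []
    ss = np.random.SeedSequence(seed)
    set_ids = sorted(collection)
    children = ss.spawn(len(set_ids))
    for set_id, child in zip(set_ids, children):
        members = collection[set_id]
        if not members & present:
            skipped.append(set_id)
            continue
        results.append(
            gsea_permutation(
                ranked,
                members,
                n_perm=n_perm,
                weight=weight,
                seed=child.generate_state(1)[0],
                set_id=set_id,
            )
        )
    if not results:
        raise ValidationError("no gene set overlaps the ranked list")
    df = pd.DataFrame(
        dict(
            set_id=[r.set_id for r in results],
            es=[r.es for r in results],
            nes=[r.nes for r in results],
            pvalue=[r.pvalue for r in results],
            n_hits=[r.n_hits for r in results],
            leading_edge=[",".join(r.leading_edge) for r in results],
        )
    )
    df["padj"] = bh_adjust(df["pvalue"])
    df = df[["set_id", "es", "nes", "pvalue", "padj", "n_hits", "leading_edge"]]
    if skipped:
        log.info("skipped %d sets with no overlap: %s", len(skipped), skipped[:5])
    return df.sort_values(["padj", "pvalue", "set_id"], ignore_index=True), skipped
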