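"""Positional seed-word enrichment, target de-repression CDF tests, and
multi-database target-vote scoring.

The central statistic: for each 7mer window starting at positions 1-15
of a mature miRNA, count how many genes of a query set (typically the
significantly downregulated genes after miRNA overexpression) carry the
DNA reverse complement of that word in their 3' UTR, against the same
count in a universe of genes, and score the over-representation with an
exact hypergeometric upper tail. A miRNA represses through base-pairing,
so the signal of direct targeting is expected at the seed window
(position 2) of the complement-matched scan.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import DNA_ALPHABET, MirnaRecord, UtrSet, ValidationError

log = logging.getLogger(__name__)

# RNA base -> complementary DNA base (A pairs T, U pairs A)
_RNA_TO_DNA_COMPLEMENT = str.maketrans("ACGU", "TGCA")
# literal mapping for the --match-literal alternative reading: U -> T
_RNA_TO_DNA_LITERAL = str.maketrans("U", "T")


def rna_site_word(mirna_word: str) -> str:
    """DNA reverse complement of an RNA word — the putative UTR site."""
    return mirna_word.upper().translate(_RNA_TO_DNA_COMPLEMENT)[::-1]


def mirna_words(
    mirna: MirnaRecord, k: int = 7, start_min: int = 1, start_max: int = 15
) -> List[Tuple[int, str, str]]:
    """All k-mers of the miRNA starting at 1-based positions
    ``start_min..start_max``, each with its DNA site word."""
    required = start_max + k - 1
    if len(mirna) < required:
        raise ValidationError(
            f"miRNA {mirna.mir_id!r} is {len(mirna)} nt; scanning k={k} words at "
            f"starts {start_min}-{start_max} requires >= {required} nt"
        )
    rows = []
    for pos in range(start_min, start_max + 1):
        word = mirna.sequence[pos - 1 : pos - 1 + k]
        rows.append((pos, word, rna_site_word(word)))
    return rows


def genes_with_word(utrs: UtrSet, site_word: str) -> Set[str]:
    """Genes whose UTR contains >= 1 exact occurrence of ``site_word``.

    Presence/absence only: multiplicity is ignored, and N never matches.
    """
    bad = sorted(set(site_word.upper()) - DNA_ALPHABET)
    if bad:
        raise ValidationError(f"site word {site_word!r}: characters {bad} not in ACGT")
    w = site_word.upper()
    return {g for g, seq in utrs.items() if w in seq}


def hypergeom_tail(
    n_universe: int, n_universe_with: int, n_query: int, n_query_with: int
) -> float:
    """Exact upper-tail P(X >= n_query_with) for X ~
    Hypergeom(N=n_universe, K=n_universe_with, n=n_query)."""
    N, K, n, k = n_universe, n_universe_with, n_query, n_query_with
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"inconsistent hypergeometric counts N={N}, K={K}, n={n}")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise ValidationError(
            f"inconsistent draw count k={k} for N={N}, K={K}, n={n}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def seed_scan(
    mirna: MirnaRecord,
    utrs: UtrSet,
    query_genes: Iterable[str],
    universe_genes: Optional[Iterable[str]] = None,
    k: int = 7,
    start_range: Tuple[int, int] = (1, 15),
    report_threshold: float = 0.01,
    match_literal: bool = False,
) -> pd.DataFrame:
    """Positional k-mer enrichment scan of a miRNA against a UTR set.

    One row per start position; hypergeometric p-value with the query as
    the draw; BH adjustment across the scanned positions of this miRNA.
    Both raw and adjusted p are emitted, with ``significant`` flagging
    ``padj < report_threshold``.
    """
    universe = set(universe_genes) if universe_genes is not None else set(utrs.gene_ids)
    query = set(query_genes)
    if not query or not universe:
        raise ValidationError("query and universe must be non-empty")
    if not query <= universe:
        raise ValidationError("query_genes must be a subset of universe_genes")
    missing = [g for g in universe if g not in utrs]
    if missing:
        raise ValidationError(f"universe genes without a UTR: {missing[:5]}")

    rows = []
    for pos, word, site in mirna_words(mirna, k=k, start_min=start_range[0], start_max=start_range[1]):
        if match_literal:
            site = word.translate(_RNA_TO_DNA_LITERAL)
        with_site = genes_with_word(utrs, site) & universe
        n_qw = len(with_site & query)
        p = hypergeom_tail(len(universe), len(with_site), len(query), n_qw)
        rows.append(
            dict(
                start_pos=pos,
                mirna_word=word,
                site_word=site,
                n_universe=len(universe),
                n_universe_with_site=len(with_site),
                n_query=len(query),
                n_query_with_site=n_qw,
                pvalue=p,
            )
        )
    df = pd.DataFrame(rows)
    df["padj"] = bh_adjust(df["pvalue"])
    df["significant"] = df["padj"] < report_threshold
    return df


def select_query_genes(
    de: pd.DataFrame,
    utrs: UtrSet,
    padj_threshold: float = 0.05,
    lfc_threshold: float = -0.5,
) -> Tuple[Set[str], Set[str]]:
    """Default query/universe for a scan: downregulated significant genes
    (padj < threshold and log2fc < lfc_threshold) among all DE genes that
    have a UTR. Recomputes BH from raw p when padj is absent."""
    df = de.copy()
    if "padj" not in df.columns or df["padj"].isna().all():
        log.info("padj missing from DE table; recomputing BH from raw p-values")
        df["padj"] = bh_adjust(df["pvalue"].to_numpy())
    universe = {g for g in df["feature_id"] if g in utrs}
    sig = df[(df["padj"] < padj_threshold) & (df["log2fc"] < lfc_threshold)]
    query = {g for g in sig["feature_id"] if g in utrs}
    return query, universe


@dataclass(frozen=True)
class ShiftResult:
    """Two-sample KS comparison of query vs background log2 fold changes."""

    d_stat: float
    pvalue: float
    n_query: int
    n_background: int
    median_shift: float  # median(query) - median(background); sign = direction


def cdf_shift(
    query_log2fc: Sequence[float], background_log2fc: Sequence[float]
) -> ShiftResult:
    """Two-sided two-sample Kolmogorov-Smirnov test of a fold-change shift.

    Exact null distribution when min(n, m) <= 25, asymptotic otherwise.
    The test is two-sided; read direction from ``median_shift``.
    """
    q = np.asarray(query_log2fc, dtype=float)
    b = np.asarray(background_log2fc, dtype=float)
    if q.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    method = "exact" if min(q.size, b.size) <= 25 else "asymp"
    res = stats.ks_2samp(q, b, alternative="two-sided", method=method)
    return ShiftResult(
        d_stat=float(res.statistic),
        pvalue=float(res.pvalue),
        n_query=int(q.size),
        n_background=int(b.size),
        median_shift=float(np.median(q) - np.median(b)),
    )


def vote_score(prediction_tables: Sequence[Tuple[str, Set[str]]]) -> pd.DataFrame:
    """Vote-count target predictions across databases.

    One row per gene in the union of all sources; ``score`` is the number
    of databases supporting the interaction. Sorted by score descending,
    then gene_id.
    """
    if not prediction_tables:
        raise ValidationError("need at least one prediction source")
    names = [n for n, _ in prediction_tables]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate source names in {names}")
    support: dict = {}
    for name, genes in prediction_tables:
        for g in genes:
            support.setdefault(g, set()).add(name)
    df = pd.DataFrame(
        [
            dict(
                gene_id=g,
                score=len(srcs),
                supporting_sources=",".join(sorted(srcs)),
            )
            for g, srcs in support.items()
        ]
    )
    if df.empty:
        return pd.DataFrame(columns=["gene_id", "score", "supporting_sources"])
    return df.sort_values(
        ["score", "gene_id"], ascending=[False, True], ignore_index=True
    )
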