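"""Cross-dataset differential-expression consensus by vote counting.

Independent case/control miRNA datasets rarely agree feature by
feature, so candidate miRNAs are retained when they change significantly
in at least ``min_datasets`` of the datasets in which they were
measured, and flagged as all-concordant when they are significant and
move the same way in every dataset that measured them. Missing is kept
distinct from not-significant throughout.

Also houses a minimal DE layer (`de_contrast`) used to turn synthetic
count matrices into DE tables; it is plumbing, not a full replicate-
variance model — real data should arrive as externally produced tables.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .seed_enrichment import bh_adjust
from .types import CountMatrix, ValidationError

log = logging.getLogger(__name__)


def de_contrast(
    cm: CountMatrix, condition_a: str, condition_b: str, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Minimal two-condition contrast on a count matrix.

    Median-of-ratios library normalization, log2 fold change of
    normalized means (b over a) with a pseudocount, Welch t-test on
    log2(CPM + pseudocount), BH-adjusted p-values.
    """
    a_samples = cm.samples_for(condition_a)
    b_samples = cm.samples_for(condition_b)
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValidationError(
            f"need >= 2 samples per condition; got {len(a_samples)} in "
            f"{condition_a!r} and {len(b_samples)} in {condition_b!r}"
        )
    # size factors in the matrix's own column order so that swapping the
    # condition labels negates every log2fc exactly
    wanted = set(a_samples + b_samples)
    canon = [s for s in cm.counts.columns if s in wanted]
    canon_counts = cm.counts[canon].to_numpy(dtype=float)

    # median-of-ratios size factors over features observed in every sample
    all_pos = np.all(canon_counts > 0, axis=1)
    if all_pos.sum() >= 1:
        logc = np.log(canon_counts[all_pos])
        ref = logc.mean(axis=1, keepdims=True)
        sf_canon = np.exp(np.median(logc - ref, axis=0))
    else:
        log.warning("no feature observed in all samples; using total-count size factors")
        totals = canon_counts.sum(axis=0)
        sf_canon = totals / totals.mean()
    sf_map = dict(zip(canon, sf_canon))

    counts = cm.counts[a_samples + b_samples].to_numpy(dtype=float)
    sf = np.array([sf_map[s] for s in a_samples + b_samples])
    norm = counts / sf

    na, nb = len(a_samples), len(b_samples)
    mean_a = norm[:, :na].mean(axis=1)
    mean_b = norm[:, na:].mean(axis=1)
    log2fc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)

    lib = counts.sum(axis=0)
    cpm = counts / lib * 1e6
    logcpm = np.log2(cpm + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        tres = stats.ttest_ind(
            logcpm[:, na:], logcpm[:, :na], axis=1, equal_var=False
        )
    pvalue = np.where(np.isnan(tres.pvalue), 1.0, tres.pvalue)
    return pd.DataFrame(
        dict(
            feature_id=cm.feature_ids,
            base_mean=norm.mean(axis=1),
            log2fc=log2fc,
            pvalue=pvalue,
            padj=bh_adjust(pvalue),
        )
    )


@dataclass
class Harmonized:
    """Outer join of per-dataset DE tables keyed by mir_id.

    ``measured`` distinguishes missing from measured-but-null;
    ``criterion`` records, per dataset, whether adjusted or raw p is the
    significance criterion (padj when the table carries it, else raw p).
    """

    datasets: List[str]
    log2fc: pd.DataFrame  # mir x dataset, NaN where unmeasured
    crit_p: pd.DataFrame  # the per-dataset significance p (padj or raw p)
    measured: pd.DataFrame  # boolean mir x dataset
    criterion: Dict[str, str] = field(default_factory=dict)


def harmonize(tables: Mapping[str, pd.DataFrame]) -> Harmonized:
    """Outer-join per-dataset DE tables on mir_id."""
    if len(tables) < 2:
        raise ValidationError("need >= 2 datasets to harmonize")
    if all(t.empty for t in tables.values()):
        raise ValidationError("all DE tables are empty")
    criterion: Dict[str, str] = {}
    lfc_cols, p_cols = {}, {}
    for name, df in tables.items():
        if df["feature_id"].duplicated().any():
            dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
            raise ValidationError(f"dataset {name!r}: feature {dup!r} present twice")
        use_padj = "padj" in df.columns and df["padj"].notna().any()
        criterion[name] = "padj" if use_padj else "pvalue"
        if not use_padj:
            log.info("dataset %r has no padj; using raw p-values as its criterion", name)
        idx = df["feature_id"]
        lfc_cols[name] = pd.Series(df["log2fc"].to_numpy(dtype=float), index=idx)
        p_cols[name] = pd.Series(
            df[criterion[name]].to_numpy(dtype=float), index=idx
        )
    log2fc = pd.DataFrame(lfc_cols).sort_index()
    crit_p = pd.DataFrame(p_cols).sort_index()
    measured = log2fc.notna() & crit_p.notna()
    datasets = sorted(tables)
    return Harmonized(
        datasets=datasets,
        log2fc=log2fc[datasets],
        crit_p=crit_p[datasets],
        measured=measured[datasets],
        criterion=criterion,
    )


def consensus_filter(
    harmonized: Harmonized,
    min_datasets: int = 3,
    padj_threshold: float = 0.05,
    lfc_threshold: float = 0.5,
    require_measured_in_all: bool = False,
) -> pd.DataFrame:
    """Apply the >= ``min_datasets``-of-K retention rule and direction flags.

    A miR is significant in a dataset when its criterion p is below
    ``padj_threshold`` and |log2fc| exceeds ``lfc_threshold``. ``all_down``
    (``all_up``) marks miRs significant in every dataset in which they
    were measured with all changes downward (upward); with
    ``require_measured_in_all`` the miR must also be measured in every
    dataset of the harmonization.
    """
    if padj_threshold <= 0 or lfc_threshold <= 0:
        raise ValidationError("thresholds must be positive")
    h = harmonized
    sig = (
        (h.crit_p < padj_threshold)
        & (h.log2fc.abs() > lfc_threshold)
        & h.measured
    )
    down = sig & (h.log2fc < 0)
    up = sig & (h.log2fc > 0)
    n_measured = h.measured.sum(axis=1)
    n_sig = sig.sum(axis=1)
    n_sig_down = down.sum(axis=1)
    n_sig_up = up.sum(axis=1)
    retained = n_sig >= min_datasets
    concordant_all = (n_sig == n_measured) & (n_measured > 0)
    if require_measured_in_all:
        concordant_all &= n_measured == len(h.datasets)
    all_down = concordant_all & (n_sig_down == n_sig)
    all_up = concordant_all & (n_sig_up == n_sig)
    out = pd.DataFrame(
        dict(
            mir_id=h.log2fc.index,
            n_datasets_measured=n_measured.to_numpy(),
            n_datasets_sig=n_sig.to_numpy(),
            n_sig_down=n_sig_down.to_numpy(),
            n_sig_up=n_sig_up.to_numpy(),
            retained=retained.to_numpy(),
            all_down=all_down.to_numpy(),
            all_up=all_up.to_numpy(),
        )
    )
    for ds in h.datasets:
        out[f"log2fc_{ds}"] = h.log2fc[ds].to_numpy()
    return out.sort_values(
        ["retained", "n_datasets_sig", "mir_id"],
        ascending=[False, False, True],
        ignore_index=True,
    )
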