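"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here with known
planted effects, recorded in a :class:`~miraxis.types.SimTruth` that
downstream recovery tests treat as the oracle. Defaults emulate the
study conditions the analyses assume: negative-binomial count data with
planted log2 fold changes, background UTRs as i.i.d. per-base sequence
at a stated GC content with seed-complementary sites planted into a
target fraction, six DE datasets with controlled overlap of significant
miRNAs, and host-gene read sets whose intronic compartment is perturbed
under transcriptional versus processing regimes (planting magnitudes
-1.32 and -0.51, i.e. 60% and 30% reductions).
"""
from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import total_length
from .seed_enrichment import bh_adjust, rna_site_word
from .types import (
    CountMatrix,
    GeneModel,
    HostMap,
    MirnaRecord,
    SimTruth,
    UtrSet,
    ValidationError,
)

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

# Planting magnitudes mirroring the study's reported pri-miR-139 regimes:
# a 60% intronic-read reduction (homozygous-mutant deep RNA-seq) and a 30%
# reduction (the second FUS line).
PRI_LFC_60PCT = -1.32
PRI_LFC_30PCT = -0.51


def _gc_probs(gc_content: float) -> np.ndarray:
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    return np.array([at, gc, gc, at])  # A C G T


def random_dna(rng: np.random.Generator, length: int, gc_content: float) -> str:
    return "".join(rng.choice(_BASES, size=length, p=_gc_probs(gc_content)))


def canonical_seed_site(mirna: MirnaRecord, k: int = 7, seed_start: int = 2) -> str:
    """DNA reverse complement of the miRNA seed word (positions 2-8 by
    default) — the canonical planted site type."""
    word = mirna.sequence[seed_start - 1 : seed_start - 1 + k]
    if len(word) < k:
        raise ValidationError(f"miRNA {mirna.mir_id!r} too short for a {k}-mer seed")
    return rna_site_word(word)


def generate_utr_set(
    n_genes: int,
    mirna: MirnaRecord,
    length_range: Tuple[int, int] = (200, 500),
    gc_content: float = 0.45,
    target_fraction: float = 0.3,
    sites_per_target: int = 1,
    seed: Optional[int] = None,
    max_retries: int = 50,
) -> Tuple[UtrSet, SimTruth]:
    """Background UTRs with seed-complementary sites planted into a
    target fraction of genes.

    ``round(n_genes * target_fraction)`` genes carry ``sites_per_target``
    non-overlapping copies of the DNA reverse complement of the miRNA
    seed (positions 2-8); the rest are i.i.d. background at the stated
    GC. Truth records every planted offset.
    """
    if not 0 <= target_fraction <= 1:
        raise ValidationError("target_fraction must lie in [0,1]")
    site = canonical_seed_site(mirna)
    k = len(site)
    if length_range[0] < k:
        raise ValidationError(f"length_range minimum must be >= word length {k}")
    rng = np.random.default_rng(seed)
    n_targets = int(round(n_genes * target_fraction))
    records: Dict[str, str] = {}
    truth = SimTruth(seed=seed)
    for i in range(n_genes):
        gene_id = f"g{i + 1:05d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = random_dna(rng, length, gc_content)
        if i < n_targets:
            placed: List[int] = []
            for _ in range(sites_per_target):
                for attempt in range(max_retries + 1):
                    off = int(rng.integers(0, length - k + 1))
                    if all(abs(off - o) >= k for o in placed):
                        placed.append(off)
                        break
                else:
                    raise ValidationError(
                        f"could not place {sites_per_target} non-overlapping sites "
                        f"in a {length} nt UTR after {max_retries} retries"
                    )
            for off in placed:
                seq = seq[:off] + site + seq[off + k:]
            truth.planted_target_genes.add(gene_id)
            truth.planted_site_positions[gene_id] = [(off, site) for off in sorted(placed)]
        records[gene_id] = seq
    return UtrSet.from_pairs(records.items()), truth


def mutate_seed_site(
    utr_sequence: str,
    site_offset: int,
    site_length: int,
    positions: Sequence[int] = (2, 4, 6),
) -> str:
    """Delete the given 1-based positions within a binding site, leaving
    the flanks untouched (the site-disruption used to abolish repression
    in reporter constructs)."""
    if site_offset < 0 or site_offset + site_length > len(utr_sequence):
        raise ValidationError(
            f"site [{site_offset},{site_offset + site_length}) outside sequence "
            f"of length {len(utr_sequence)}"
        )
    bad = [p for p in positions if not 1 <= p <= site_length]
    if bad:
        raise ValidationError(f"positions {bad} outside the {site_length} nt site")
    site = utr_sequence[site_offset : site_offset + site_length]
    drop = set(positions)
    kept = "".join(b for i, b in enumerate(site, start=1) if i not in drop)
    return utr_sequence[:site_offset] + kept + utr_sequence[site_offset + site_length:]


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mean, dispersion) with var = mean + dispersion * mean^2."""
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def generate_counts(
    n_features: int,
    samples_per_condition: int,
    baseline_mean_range: Tuple[float, float] = (20.0, 2000.0),
    nb_dispersion: float = 0.1,
    planted_log2fc: Optional[Mapping[str, float]] = None,
    seed: Optional[int] = None,
    conditions: Tuple[str, str] = ("ctrl", "case"),
) -> Tuple[CountMatrix, SimTruth]:
    """Negative-binomial count matrix with planted fold changes.

    Condition-2 means equal condition-1 means times 2^planted_log2fc;
    a shared dispersion sets var = mu + dispersion * mu^2.
    """
    if nb_dispersion <= 0:
        raise ValidationError("nb_dispersion must be positive")
    rng = np.random.default_rng(seed)
    feature_ids = [f"f{i + 1:05d}" for i in range(n_features)]
    planted = dict(planted_log2fc or {})
    unknown = set(planted) - set(feature_ids)
    if unknown:
        raise ValidationError(f"planted features not in matrix: {sorted(unknown)[:5]}")
    lo, hi = baseline_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_features))
    lfc = np.array([planted.get(f, 0.0) for f in feature_ids])
    ns = samples_per_condition
    mean_a = np.repeat(base[:, None], ns, axis=1)
    mean_b = np.repeat((base * 2.0 ** lfc)[:, None], ns, axis=1)
    counts_a = _nb_draw(rng, mean_a, nb_dispersion)
    counts_b = _nb_draw(rng, mean_b, nb_dispersion)
    sample_ids = [f"{conditions[0]}_{i + 1}" for i in range(ns)] + [
        f"{conditions[1]}_{i + 1}" for i in range(ns)
    ]
    condition = {s: (conditions[0] if i < ns else conditions[1]) for i, s in enumerate(sample_ids)}
    cm = CountMatrix(
        counts=pd.DataFrame(
            np.hstack([counts_a, counts_b]), index=feature_ids, columns=sample_ids
        ),
        condition=condition,
    )
    truth = SimTruth(seed=seed, planted_log2fc=planted, nb_dispersion=nb_dispersion)
    return cm, truth


def generate_multi_dataset_de(
    n_mirs: int,
    plant_spec: Mapping[str, Tuple[int, str]],
    n_datasets: int = 6,
    seed: Optional[int] = None,
    padj_threshold: float = 0.05,
    lfc_threshold: float = 0.5,
    sig_lfc_range: Tuple[float, float] = (0.8, 2.0),
    null_lfc_sd: float = 0.1,
) -> Tuple[Dict[str, pd.DataFrame], SimTruth]:
    """Six (by default) DE tables with controlled overlap of significant
    miRNAs.

    Each planted miR is significant (padj below threshold, |log2fc|
    above threshold) with the stated direction in exactly its
    ``n_datasets_sig`` randomly chosen datasets and null elsewhere;
    unplanted miRs are null everywhere. Directions are "up" or "down".
    """
    rng = np.random.default_rng(seed)
    for mir, (n_sig, direction) in plant_spec.items():
        if not 0 <= n_sig <= n_datasets:
            raise ValidationError(f"{mir}: n_datasets_sig {n_sig} > n_datasets {n_datasets}")
        if direction not in ("up", "down"):
            raise ValidationError(f"{mir}: direction must be 'up' or 'down'")
    mir_ids = list(plant_spec)
    if len(mir_ids) > n_mirs:
        raise ValidationError("plant_spec larger than n_mirs")
    mir_ids += [f"mir_null_{i + 1:04d}" for i in range(n_mirs - len(mir_ids))]
    ds_names = [f"ds{i + 1}" for i in range(n_datasets)]
    sig_in = {
        mir: set(rng.choice(n_datasets, size=plant_spec[mir][0], replace=False).tolist())
        for mir in plant_spec
    }
    tables: Dict[str, pd.DataFrame] = {}
    for d, name in enumerate(ds_names):
        lfc = rng.normal(0.0, null_lfc_sd, size=len(mir_ids))
        pval = rng.uniform(0.0, 1.0, size=len(mir_ids))
        for i, mir in enumerate(mir_ids):
            if mir in plant_spec and d in sig_in[mir]:
                sign = 1.0 if plant_spec[mir][1] == "up" else -1.0
                lfc[i] = sign * rng.uniform(*sig_lfc_range)
                pval[i] = 10.0 ** (-rng.uniform(5.0, 9.0))
        tables[name] = pd.DataFrame(
            dict(feature_id=mir_ids, log2fc=lfc, pvalue=pval, padj=bh_adjust(pval))
        )
    # self-check: the planted design must survive the BH adjustment
    for mir, (n_sig, _) in plant_spec.items():
        n_obs = sum(
            bool(
                (t.loc[t["feature_id"] == mir, "padj"].iloc[0] < padj_threshold)
                and (abs(t.loc[t["feature_id"] == mir, "log2fc"].iloc[0]) > lfc_threshold)
            )
            for t in tables.values()
        )
        if n_obs != n_sig:
            raise ValidationError(
                f"planting failed for {mir}: significant in {n_obs} datasets, wanted {n_sig}"
            )
    truth = SimTruth(seed=seed, planted_consensus_mirs=dict(plant_spec))
    return tables, truth


def generate_derepression_de(
    n_genes: int,
    target_genes: Sequence[str],
    shift: float = -0.5,
    noise_sd: float = 0.5,
    seed: Optional[int] = None,
    gene_ids: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, SimTruth]:
    """A DE table whose target genes' log2 fold changes are shifted by a
    constant against a Gaussian background — the regime a CDF-shift test
    should detect. P-values are two-sided z-tests against the background
    spread, so the table is a valid DeTable."""
    rng = np.random.default_rng(seed)
    ids = list(gene_ids) if gene_ids is not None else [f"g{i + 1:05d}" for i in range(n_genes)]
    if len(ids) != n_genes:
        raise ValidationError("gene_ids length must equal n_genes")
    targets = set(target_genes)
    missing = targets - set(ids)
    if missing:
        raise ValidationError(f"target genes not in gene list: {sorted(missing)[:5]}")
    lfc = rng.normal(0.0, noise_sd, size=n_genes)
    lfc += np.array([shift if g in targets else 0.0 for g in ids])
    pval = 2.0 * stats.norm.sf(np.abs(lfc) / noise_sd)
    de = pd.DataFrame(
        dict(feature_id=ids, log2fc=lfc, pvalue=pval, padj=bh_adjust(pval))
    )
    truth = SimTruth(
        seed=seed,
        planted_target_genes=targets,
        planted_log2fc={g: shift for g in targets},
    )
    return de, truth


def make_host_gene_models(
    n_hosts: int,
    seed: Optional[int] = None,
    n_exons: int = 4,
    exon_length_range: Tuple[int, int] = (200, 400),
    intron_length_range: Tuple[int, int] = (1500, 3000),
) -> Tuple[Dict[str, GeneModel], HostMap]:
    """Synthetic host-gene annotation: one multi-exon gene per chromosome
    with an intronic miRNA, plus the miR -> host map."""
    rng = np.random.default_rng(seed)
    models: Dict[str, GeneModel] = {}
    host_map: HostMap = {}
    for i in range(n_hosts):
        gene_id = f"HOST{i + 1:03d}"
        chrom = f"chr{i + 1}"
        pos = 1000
        exons = []
        for e in range(n_exons):
            elen = int(rng.integers(*exon_length_range))
            exons.append((pos, pos + elen))
            pos += elen
            if e < n_exons - 1:
                pos += int(rng.integers(*intron_length_range))
        models[gene_id] = GeneModel(
            gene_id=gene_id, chrom=chrom, strand="+", start=1000, end=pos, exons=exons
        )
        host_map[f"mir_{i + 1:03d}"] = gene_id
    return models, host_map


def _place_reads(
    rng: np.random.Generator,
    intervals: Sequence[Tuple[int, int]],
    n_reads: int,
    read_length: int,
) -> np.ndarray:
    """Uniformly place fully contained reads in a set of intervals;
    returns start positions."""
    place = np.array([e - s - read_length + 1 for s, e in intervals])
    if np.any(place <= 0):
        raise ValidationError("read length exceeds an interval; infeasible geometry")
    probs = place / place.sum()
    which = rng.choice(len(intervals), size=n_reads, p=probs)
    offsets = rng.integers(0, place[which])
    starts = np.array([intervals[i][0] for i in which]) + offsets
    return starts


def generate_host_gene_experiment(
    gene_models: Mapping[str, GeneModel],
    host_map: HostMap,
    scenario: str,
    pri_log2fc: Union[float, Mapping[str, float]] = PRI_LFC_60PCT,
    mature_log2fc: Union[float, Mapping[str, float]] = PRI_LFC_60PCT,
    intronic_depth: float = 500.0,
    exonic_depth: float = 300.0,
    read_length: int = 75,
    samples_per_condition: int = 3,
    mature_mean: float = 500.0,
    nb_dispersion: float = 0.05,
    seed: Optional[int] = None,
    conditions: Tuple[str, str] = ("ctrl", "case"),
) -> Tuple[Dict[str, pd.DataFrame], CountMatrix, SimTruth]:
    """Per-sample aligned-read intervals plus mature-miR counts under a
    planted regulatory regime.

    transcriptional: intronic read totals AND mature counts of affected
    miRs scale by 2^pri_log2fc in condition 2. processing: mature counts
    scale by 2^mature_log2fc while intronic totals are unchanged. null:
    nothing scales. Reads are uniform within their compartment (intron
    or exon) and Poisson-thinned to the stated depth; exonic reads are
    emitted so the intron-containment rule is actually exercised.
    """
    if scenario not in ("transcriptional", "processing", "null"):
        raise ValidationError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    from .primirna import intronic_regions  # late import avoids a cycle

    mirs = list(host_map)
    if isinstance(pri_log2fc, Mapping):
        pri_map = {m: float(pri_log2fc.get(m, 0.0)) for m in mirs}
    else:
        pri_map = {m: float(pri_log2fc) for m in mirs}
    if isinstance(mature_log2fc, Mapping):
        mat_map = {m: float(mature_log2fc.get(m, 0.0)) for m in mirs}
    else:
        mat_map = {m: float(mature_log2fc) for m in mirs}
    if scenario == "null":
        pri_map = {m: 0.0 for m in mirs}
        mat_map = {m: 0.0 for m in mirs}
    elif scenario == "transcriptional":
        mat_map = dict(pri_map)  # mature follows the primary transcript
    else:  # processing: the primary transcript is untouched
        pri_map = {m: 0.0 for m in mirs}

    introns = {g: intronic_regions(gene_models, g) for g in host_map.values()}
    ns = samples_per_condition
    sample_ids = [f"{conditions[0]}_{i + 1}" for i in range(ns)] + [
        f"{conditions[1]}_{i + 1}" for i in range(ns)
    ]
    condition = {s: (conditions[0] if i < ns else conditions[1]) for i, s in enumerate(sample_ids)}

    reads: Dict[str, pd.DataFrame] = {}
    for si, sample in enumerate(sample_ids):
        cond2 = si >= ns
        chroms, starts = [], []
        for mir, gene in host_map.items():
            model = gene_models[gene]
            iscale = 2.0 ** pri_map[mir] if cond2 else 1.0
            n_i = rng.poisson(intronic_depth * iscale)
            if n_i > 0:
                s = _place_reads(rng, introns[gene], n_i, read_length)
                starts.append(s)
                chroms.extend([model.chrom] * n_i)
            n_e = rng.poisson(exonic_depth)
            if n_e > 0:
                s = _place_reads(rng, model.exons, n_e, read_length)
                starts.append(s)
                chroms.extend([model.chrom] * n_e)
        allstarts = np.concatenate(starts) if starts else np.array([], dtype=int)
        reads[sample] = pd.DataFrame(
            dict(chrom=chroms, start=allstarts, end=allstarts + read_length)
        )

    mat_lfc = np.array([mat_map[m] for m in mirs])
    mean_a = np.full((len(mirs), ns), mature_mean)
    mean_b = (mature_mean * 2.0 ** mat_lfc)[:, None] * np.ones((1, ns))
    mature = np.hstack(
        [_nb_draw(rng, mean_a, nb_dispersion), _nb_draw(rng, mean_b, nb_dispersion)]
    )
    mature_cm = CountMatrix(
        counts=pd.DataFrame(mature, index=mirs, columns=sample_ids),
        condition=condition,
    )
    truth = SimTruth(
        seed=seed,
        planted_log2fc={host_map[m]: pri_map[m] for m in mirs},
        planted_mature_log2fc=dict(mat_map),
        scenario={
            host_map[m]: (scenario if (pri_map[m] != 0 or mat_map[m] != 0) else "null")
            for m in mirs
        },
        nb_dispersion=nb_dispersion,
    )
    return reads, mature_cm, truth
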