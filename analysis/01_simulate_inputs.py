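#!/usr/bin/env python
"""Generate the synthetic study: every input the downstream analyses
consume, with planted ground truth.

Emulates the study design end to end: a miR-139-5p overexpression
experiment (UTRs with planted seed sites and a DE table in which the
planted targets are de-repressed downward), six case/control miRNA DE
datasets with miR-139 planted down in all six, and a host-gene
experiment in which pri-miR-139 transcription is reduced by 60%
(log2fc -1.32) against a background of null intronic miRNAs.

Raw sequence/read files go to scratch/simulated/ (regenerable); the
planted truth is stored alongside them.
"""
import json
import sys
from pathlib import Path

import numpy as np

import miraxis as mx
from miraxis import io as mio
from miraxis.seed_enrichment import bh_adjust

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "simulated"
SEED = 1

MIR139 = mx.MirnaRecord("miR-139-5p", "UCUACAGUGCACGUGUCUCCAGU")


def main() -> None:
    SIM.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    truth_out = {}

    # --- miR-139 overexpression experiment: UTRs + de-repression DE table
    utrs, utr_truth = mx.generate_utr_set(
        300, mirna=MIR139, target_fraction=0.3, seed=SEED
    )
    mio.write_fasta(utrs.records, SIM / "utrs.fa")
    mio.write_fasta([(MIR139.mir_id, MIR139.sequence)], SIM / "mirna.fa")
    targets = sorted(utr_truth.planted_target_genes)
    de_oe, _ = mx.generate_derepression_de(
        300, targets, shift=-1.0, noise_sd=0.4, seed=SEED + 1,
        gene_ids=utrs.gene_ids,
    )
    mio.write_de_table(de_oe, SIM / "de_mir139_oe.tsv")
    (SIM / "predicted_targets.txt").write_text("\n".join(targets) + "\n")
    truth_out["planted_target_genes"] = targets

    # three overlapping "prediction databases" drawn from the true targets
    for name, frac in (("miRWalk_like", 0.9), ("TargetScan_like", 0.7), ("miRDB_like", 0.5)):
        picked = sorted(rng.choice(targets, int(frac * len(targets)), replace=False))
        noise = sorted(rng.choice(
            [g for g in utrs.gene_ids if g not in targets], 10, replace=False))
        (SIM / f"pred_{name}.txt").write_text("\n".join(picked + noise) + "\n")

    # gene sets for enrichment: one set of true targets among nulls
    collection = {"planted_target_set": set(rng.choice(targets, 20, replace=False))}
    for i in range(30):
        collection[f"null_set_{i:02d}"] = set(rng.choice(utrs.gene_ids, 20, replace=False))
    mio.write_gmt(collection, SIM / "sets.gmt")

    # --- six-dataset miRNA DE with miR-139 planted down in all six
    plant = {
        "miR-139-5p": (6, "down"),
        "mir_alt_a": (4, "down"),
        "mir_alt_b": (3, "up"),
        "mir_alt_c": (2, "down"),
    }
    tables, _ = mx.generate_multi_dataset_de(250, plant, seed=SEED + 2)
    for name, df in tables.items():
        mio.write_de_table(df, SIM / f"de_{name}.tsv")
    truth_out["planted_consensus_mirs"] = {k: list(v) for k, v in plant.items()}

    # --- host-gene experiment: pri-miR-139 down 60%, others null
    models, host_map = mx.make_host_gene_models(24, seed=SEED + 3)
    pri_plant = {"mir_001": mx.PRI_LFC_60PCT, "mir_002": mx.PRI_LFC_30PCT}
    reads, mature_cm, host_truth = mx.generate_host_gene_experiment(
        models, host_map, "transcriptional", pri_log2fc=pri_plant, seed=SEED + 4
    )
    mio.write_gtf(models, SIM / "genes.gtf")
    mio.write_host_map(host_map, SIM / "host_map.tsv")
    for sample, df in reads.items():
        mio.write_bed(df, SIM / f"reads_{sample}.bed")
    mio.write_tsv_counts(mature_cm.counts, SIM / "mature_counts.tsv")
    mio.write_conditions(mature_cm.condition, SIM / "mature_conditions.tsv")
    truth_out["host_scenario"] = host_truth.scenario
    truth_out["planted_pri_log2fc"] = host_truth.planted_log2fc

    (SIM / "truth.json").write_text(json.dumps(truth_out, indent=2))
    print(f"Simulated study written to {SIM}")
    print(f"  {len(utrs)} UTRs, {len(targets)} planted miR-139 targets")
    print(f"  6 DE datasets, miR-139 planted down in all 6")
    print(f"  24 host genes; pri-miR planted at {mx.PRI_LFC_60PCT} (60% down) "
          f"and {mx.PRI_LFC_30PCT} (30% down)")


if __name__ == "__main__":
    sys.exit(main())
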