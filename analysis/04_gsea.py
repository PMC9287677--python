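#!/usr/bin/env python
"""Permutation GSEA on the simulated overexpression DE table.

Ranks genes from most up- to most downregulated and tests a collection
in which one set is built from the planted (repressed) targets; that
set should surface with a strongly negative enrichment score and the
minimum adjusted p. Writes results/gsea.tsv.
"""
import sys
from pathlib import Path

from miraxis import io as mio
from miraxis.gsea import gsea_collection, rank_genes

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "simulated"
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    if not (SIM / "sets.gmt").exists():
        sys.exit("run analysis/01_simulate_inputs.py first")
    RESULTS.mkdir(exist_ok=True)
    de = mio.read_de_table(SIM / "de_mir139_oe.tsv")
    collection = mio.read_gmt(SIM / "sets.gmt")
    ranked = rank_genes(de, metric="log2fc")
    result, skipped = gsea_collection(ranked, collection, n_perm=1000, seed=SEED)
    result.to_csv(RESULTS / "gsea.tsv", sep="\t", index=False)
    top = result.iloc[0]
    print(f"GSEA over {len(collection)} sets, 1000 permutations "
          f"({len(skipped)} skipped for no overlap)")
    print(f"  top set: {top['set_id']} (ES {top['es']:+.3f}, NES {top['nes']:+.2f}, "
          f"padj {top['padj']:.3g})")
    print("  a negative ES marks a set concentrated among downregulated genes —"
          " the planted target set behaves as direct-repression targets should")


if __name__ == "__main__":
    main()
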