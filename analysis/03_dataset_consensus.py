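#!/usr/bin/env python
"""Cross-dataset consensus over the six simulated miRNA DE tables.

Applies the >=3-of-6 retention rule and the all-dataset concordance
flag; the planted all-six-down miR should be the unique all_down row.
Writes results/consensus.tsv and results/consensus_matrix.tsv.
"""
import sys
from pathlib import Path

from miraxis import io as mio
from miraxis.consensus import consensus_filter, harmonize

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "simulated"
RESULTS = ROOT / "results"


def main() -> None:
    paths = sorted(SIM.glob("de_ds*.tsv"))
    if not paths:
        sys.exit("run analysis/01_simulate_inputs.py first")
    RESULTS.mkdir(exist_ok=True)
    tables = {p.stem.removeprefix("de_"): mio.read_de_table(p) for p in paths}
    h = harmonize(tables)
    rows = consensus_filter(h, min_datasets=3)
    rows.to_csv(RESULTS / "consensus.tsv", sep="\t", index=False)
    sig = (h.crit_p < 0.05) & (h.log2fc.abs() > 0.5) & h.measured
    h.log2fc.where(sig).rename_axis("mir_id").to_csv(
        RESULTS / "consensus_matrix.tsv", sep="\t"
    )
    retained = rows[rows["retained"]]
    all_down = rows.loc[rows["all_down"], "mir_id"].tolist()
    print(f"{len(tables)} datasets, {len(rows)} miRs after outer join")
    print(f"  retained (significant in >=3): {retained['mir_id'].tolist()}")
    print(f"  commonly downregulated across all datasets: {all_down}")


if __name__ == "__main__":
    main()
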