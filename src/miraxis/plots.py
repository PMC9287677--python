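"""Small plotting helpers for the CLI and analysis drivers."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def positional_profile(scan: pd.DataFrame, path, threshold: float = 0.01) -> None:
    """-log10 p by miRNA start position, with the report threshold marked."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.barh(scan["start_pos"], -np.log10(np.clip(scan["padj"], 1e-300, None)),
            color="steelblue")
    ax.axvline(-np.log10(threshold), ls=":", color="black")
    ax.set_xlabel("-log10 adjusted p")
    ax.set_ylabel("miRNA start position")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cdf_plot(query, background, path, labels=("targets", "all genes")) -> None:
    """Empirical CDFs of query vs background log2 fold changes."""
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    for vals, label, color in ((background, labels[1], "black"), (query, labels[0], "tab:blue")):
        x = np.sort(np.asarray(vals, dtype=float))
        y = np.arange(1, x.size + 1) / x.size
        ax.step(x, y, where="post", label=label, color=color)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("cumulative fraction")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def running_sum_plot(running_sum: np.ndarray, path, set_id: str = "") -> None:
    """Running-sum enrichment profile along the ranked list."""
    fig, ax = plt.subplots(figsize=(4.5, 2.8))
    ax.plot(running_sum, color="tab:green")
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel("rank (most up to most down)")
    ax.set_ylabel("running enrichment")
    if set_id:
        ax.set_title(set_id, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
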