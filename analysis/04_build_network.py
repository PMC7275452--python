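#!/usr/bin/env python
"""Build an RMT-thresholded co-occurrence network with Zi-Pi node roles.

Runs on a planted-partition community (5 blocks of 20 OTUs over 30 samples)
so module recovery can be scored against truth: the correlation threshold is
chosen at the GOE→Poisson transition of the eigenvalue spacing distribution,
a Maslov-Sneppen null checks that the empirical modularity is not a degree-
sequence artifact, and nodes are classified by within-module degree z-score
and participation coefficient.

Writes results/network_edges.tsv and results/network_nodes.tsv.
"""

from pathlib import Path

import pandas as pd

from vansip import io, pipeline
from vansip.simulate import simulate_block_abundance

SEED = 1
ROOT = Path(__file__).resolve().parents[1] / "results"


def run() -> None:
    frame, blocks = simulate_block_abundance(
        n_blocks=5, per_block=20, n_samples=30, seed=SEED
    )
    threshold, edges, nodes = pipeline.network_report(
        frame, min_present=10, seed=SEED
    )
    io.write_tsv(edges, ROOT / "network_edges.tsv", seed=SEED, index=False)
    io.write_tsv(nodes, ROOT / "network_nodes.tsv", seed=SEED)

    merged = nodes.join(blocks)
    purity = (
        pd.crosstab(merged["module"], merged["block"]).max(axis=1).sum()
        / len(merged)
    )
    print(
        f"threshold {threshold:.2f}: {len(edges)} edges, {len(nodes)} nodes, "
        f"{merged['module'].nunique()} modules "
        f"(purity vs planted blocks {purity:.2f})"
    )
    print(
        f"modularity {nodes.attrs.get('modularity', float('nan')):.3f} vs "
        f"Maslov-Sneppen null {nodes.attrs.get('null_modularity', float('nan')):.3f}"
    )
    print(nodes["role"].value_counts().to_string())
    print(f"wrote {ROOT / 'network_nodes.tsv'}")


if __name__ == "__main__":
    run()
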