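#!/usr/bin/env python
"""Quantify substrate-derived C and the priming effect per treatment.

Reads the demo flux series, converts daily headspace ppm to μmol with the
ideal gas law, partitions cumulative CO₂-C with the atom-fraction mixing
model, and reports primed C per vessel and per treatment (mean ± SE with a
one-way ANOVA on the warmed-vs-control contrast), compared against the
generator's truth (19.1 vs 9.9 μmol).

Writes results/priming.tsv and results/priming_summary.tsv.
"""

from pathlib import Path

from vansip import io, pipeline, summaries

SEED = 1
ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"


def run() -> None:
    vessels, vmeta = io.read_flux_table(DATA / "flux.tsv")
    per_vessel, summary = pipeline.priming_report(vessels, vmeta)
    io.write_tsv(per_vessel, ROOT / "priming.tsv", seed=SEED)
    io.write_tsv(summary, ROOT / "priming_summary.tsv", seed=SEED)

    truth = io.read_tsv(DATA / "truth_priming.tsv")
    for tr in ("warmed", "control"):
        est = per_vessel.loc[per_vessel["treatment"] == tr, "primed_umol"]
        mean, se = summaries.mean_se(est)
        true = truth.loc[truth["treatment"] == tr, "primed_umol"].mean()
        print(f"{tr}: primed C = {mean:.1f} ± {se:.1f} μmol (truth {true:.1f})")
    p = summary.loc["primed_umol", "anova_p"]
    print(f"warmed vs control primed C, one-way ANOVA p = {p:.4f}")
    print(f"wrote {ROOT / 'priming_summary.tsv'}")


if __name__ == "__main__":
    run()
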