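# vansip

Tools for DNA stable-isotope probing (SIP) of soil decomposers and for
quantifying the priming effect of a fresh carbon substrate — built around a
study design in which ¹³C-vanillin (a lignin-decomposition intermediate) is
fed to soil, labeled DNA is separated on CsCl buoyant-density gradients,
and headspace CO₂/¹³CO₂ is tracked over a 6-day incubation.

The package is aimed at microbial ecologists who have per-fraction gradient
data (buoyant density, 16S qPCR copies, OTU read counts) and daily gas
measurements, and want defensible answers to three questions:

1. **Which OTUs actually incorporated the label?** Heavy (≈1.748 g/ml) and
   light (≈1.720 g/ml) fraction sets are assigned from the copies-vs-density
   profile, every fraction is resampled to a fixed depth of 29,845 reads,
   and a three-step filter separates true ¹³C incorporation from high-GC and
   sequencing-error false positives: (i) an exact rank-sum test of
   heavy-fraction abundance, ¹³C vs ¹²C incubations (α = 0.10); (ii) the
   MSNH statistic — heavy-fraction relative abundance in ¹³C samples minus
   the paired ¹²C samples; (iii) MSNH ≥ 20% of the OTU's total relative
   abundance. Calls are reported with absolute abundances
   (relative share × total labeled 16S copies).
2. **How much native soil C did the substrate prime?** Headspace ppm
   converts to μmol by *PV = nRT* (101 kPa, 25 ml, 298 K), and cumulative
   CO₂-C is partitioned by two-pool isotope mixing — exactly, in atom
   fraction: S = n·(AF_T − AF_C)/(AF_L − AF_C) — giving
   primed C = total − substrate-derived − water-control respiration.
3. **How is the active community organized?** Pearson co-occurrence
   networks thresholded where the eigenvalue spacing distribution crosses
   from GOE (Wigner surmise) to Poisson, with Maslov–Sneppen
   degree-preserving nulls and Zi–Pi (within-module degree z-score /
   participation coefficient) node roles.

A synthetic-data module generates 24-fraction gradients (Gaussian DNA bands
at ρ(GC) = 1.660 + 0.098·GC, isotope shift +0.036 g/ml at full labeling)
and 6-day flux series with known truth, so every stage is testable without
any sequencing download. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

The numbered scripts under `analysis/` run the whole demo study and write
their tables under `results/`:

```sh
python analysis/01_simulate_dataset.py
python analysis/02_call_decomposers.py
python analysis/03_quantify_priming.py
python analysis/04_build_network.py
```

Output of the run committed here (seed 1):

```
warmed: 10 decomposer OTUs called (10/10 truth-labeled recovered, 0 false), total labeled 16S ≈ 3.01e+05 copies
control: 10 decomposer OTUs called (10/10 truth-labeled recovered, 0 false), total labeled 16S ≈ 9.84e+04 copies
warmed: primed C = 19.1 ± 0.1 μmol (truth 19.1)
control: primed C = 9.9 ± 0.2 μmol (truth 9.9)
warmed vs control primed C, one-way ANOVA p = 0.0000
threshold 0.38: 1075 edges, 100 nodes, 4 modules (purity vs planted blocks 0.80)
modularity 0.715 vs Maslov-Sneppen null 0.149
```

Reading this: the labeling filter recovered all 10 truth-labeled OTUs in
both treatments with no false calls; warming tripled the labeled taxa's
total 16S copies (3.0×10⁵ vs 9.8×10⁴); the priming estimator recovered the
generator's doubled priming under warming (19.1 vs 9.9 μmol, ANOVA
p < 10⁻⁴); and the RMT network's modularity (0.72) far exceeds its
degree-preserving null (0.15), though the conservative threshold keeps some
noise edges (module purity 0.80).

The same stages are available as a CLI — `vansip simulate|sip|priming|
network|all` — with every parameter overridable by flag or a YAML config;
outputs carry version/config-hash/seed headers and reruns are
byte-identical.

```python
>>> from vansip.priming import vanillin_c_budget
>>> vanillin_c_budget(82.6, n_labeled_c=6, n_total_c=8)
110.13333333333333
```

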