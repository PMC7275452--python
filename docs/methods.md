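# Methods

`vansip` implements the quantitative core of a DNA stable-isotope-probing
(SIP) study of vanillin (a lignin-decomposition intermediate) turnover in
soil: identifying which OTUs actively incorporated a ¹³C-labeled substrate,
putting their abundances on an absolute (16S copies) scale, partitioning
respired CO₂ into substrate-derived and primed native soil carbon, and
building random-matrix-theory (RMT) co-occurrence networks. This note
records the models, the parameters that matter, and the design choices made
where the procedure was genuinely open.

## Gradient model and heavy/light assignment

A CsCl gradient run is 24 fractions, densest first, each with a buoyant
density (optionally converted from a refractometer reading by the linear
calibration ρ = 10.8601·RI − 13.4974, a standard CsCl fit at 20 °C;
both coefficients are arguments), a 16S qPCR copy number, and OTU read
counts. Unlabeled DNA bands near 1.720 g/ml; fully ¹³C-labeled DNA shifts
about +0.036 g/ml, so labeled DNA appears near 1.748 g/ml.

"Heavy" and "light" are defined strictly by density windows — heavy
[1.735, 1.765], light [1.705, 1.735) g/ml — because density is what "heavy"
physically means; the shared boundary belongs to the heavy window so the
windows partition cleanly. Each peak set is the 4 highest-copy fractions in
its window (an assignment error, not padding, if fewer than 4 fractions fall
in a window); non-contiguous peak sets are warned about but accepted.

Whether a heavy band is *present* is a prominence question, since the
labeled band is absent from ¹²C and water gradients. With a paired
reference gradient the heavy-window mode must exceed 3× the reference's
copies interpolated at the same density; without one, 3× the copy minimum
between the two modes. Both are ratios, so peak assignment is invariant to
uniform rescaling of copy numbers. The windows and the prominence multiple
are configuration, not constants.

## The three-step labeling filter

High-GC genomes band at high density without any label, and sequencing
errors seed spurious OTUs, so presence in heavy fractions is not evidence
of labeling by itself. Before filtering, every fraction column is resampled
to a fixed depth of 29,845 reads (without replacement when the column is at
least that deep; with replacement, and flagged, otherwise), putting columns
on a common footing; resampling applies per fraction.

1. **Enrichment test.** For each OTU, the per-replicate mean relative
   abundance over the 4 heavy fractions is compared between ¹³C and ¹²C
   incubations with an exact two-sided Wilcoxon rank-sum test (midranks for
   ties, full enumeration of the conditional permutation distribution). With
   3 vs 3 replicates the smallest attainable two-sided p is exactly 0.10,
   so the default α = 0.10 retains only complete separations — a strict
   filter by construction. High-GC false positives band identically in both
   isotope groups and fail here.
2. **MSNH.** The modified sequence number in heavy fractions: the OTU's
   replicate-averaged heavy-fraction relative abundance in ¹³C samples minus
   the same in ¹²C samples. Step 2 computes the statistic (it can be
   negative); it removes nothing by itself.
3. **Magnitude rule.** The MSNH must be at least 20% of the OTU's total
   relative abundance. "Total" is read as the OTU's relative abundance
   summed over the heavy + light columns of the ¹³C samples (the fractions
   actually analyzed), with the numerator on the same summed scale — this
   makes the ratio ≤ 1 by construction. `heavy_only` and `whole_gradient`
   denominators are available as options.

An OTU is a decomposer call iff it passes steps 1 and 3. Decomposer
absolute abundances are reported as each call's share of positive MSNH
times the total labeled copies (mean heavy-fraction copy excess of ¹³C over
¹²C gradients).

## Priming accounting

Daily headspace ppm converts to μmol by the ideal gas law
n = P·(V·ppm·10⁻⁶)/(R·T) with defaults P = 101 kPa, V = 25 ml, T = 298 K,
R = 8.314 J K⁻¹ mol⁻¹; bottles are vented daily, so cumulative amounts are
sums of daily amounts. A per-observation dilution factor (default 1) covers
aliquots diluted before analysis.

Isotope arithmetic is done in ¹³C atom fraction (AF), with δ¹³C ↔ AF
conversions through R_VPDB = 0.0111802. Two-pool mixing is exactly linear
in AF, so the default substrate partition is the per-day mass balance

    S_d = n_d · (AF_treatment,d − AF_background,d) / (AF_label − AF_background,d),

where the background AF comes from the water-only vessel measured the same
day. The classical δ-notation formula %C = (δ_C − δ_T)/(δ_C − δ_L) is
implemented and exposed (`method="delta"`), but it is a linearization: at
this substrate's enrichment (phenyl-¹³C₆ vanillin, AF ≈ 0.75) it
underestimates the substrate fraction severely (a true fraction of 0.80
comes out near 0.51), so it is not the default. A third route scales
cumulative excess ¹³C by the labeled-carbon share. Mixing fractions outside
[0, 1] are reported with a warning, never clipped.

The vanillin carbon budget scales added ¹³C by total-to-labeled carbons
(8/6): 82.6 μmol ¹³C ⇒ 110.13 μmol oxidizable C. Priming is then
primed = total − substrate-derived − water-control respiration; it may be
negative.

## RMT networks

OTUs present in at least 10 of 12 samples enter a Pearson correlation
matrix (pairwise-complete; constant rows give r = 0). For each candidate
threshold, sub-threshold entries are zeroed, isolated rows dropped, and the
eigenvalue spectrum unfolded with a Gaussian-broadened cumulative density
(Silverman bandwidth by default; configurable). Unit-mean nearest-neighbor
spacings are scored by binned χ² distance (10 bins on [0, 3] plus overflow)
against the Wigner surmise (GOE) and exp(−s) (Poisson); the chosen
threshold is the smallest grid point whose spectrum is Poisson-closer and
stays so at every larger grid point (grid 0.30–0.94 in steps of 0.02, which
contains the 0.74 operating point of the motivating study). The paper
behind this design states neither its unfolding, spacing statistic, module
algorithm nor role cutoffs, so all are explicit defaults here and recorded
in output metadata.

Null networks are degree-preserving Maslov–Sneppen double-edge swaps
(self-loops and multi-edges rejected; the degree sequence is asserted on
every call; graphs admitting no legal swap are returned intact with a
warning). Modules come from greedy modularity maximization (deterministic);
node roles use the standard Zi/Pi convention: within-module degree z-score
(Zi = 0 when a module's within-degrees have no spread; NaN for singletons),
participation coefficient Pi = 1 − Σ(k_im/k_i)², module hub at Zi ≥ 2.5,
connector at Pi ≥ 0.62.

## Synthetic data: what it emulates, and what it does not

The gradient generator places each taxon's DNA as a Gaussian band (σ =
0.004 g/ml) centered at ρ(GC) = 1.660 + 0.098·GC plus AF·0.036 g/ml,
integrates band mass over the 24 density bins spanning 1.66–1.78 g/ml,
applies lognormal noise (CV 5%) to per-fraction qPCR totals, and draws
reads multinomially at depth 30,000 per fraction. The default community is
100 OTUs: bulk taxa around GC 0.61 (light peak near 1.720 g/ml), a small
high-GC contingent (GC 0.82–0.92) that bands inside the heavy window
*unlabeled* — the false-positive challenge the filter exists for — and 10
labeled taxa at atom fraction 0.9 whose band lands near 1.748 g/ml.
Abundances follow a lognormal rank curve; labeled taxa respond 3× to
warming.

The flux generator mirrors the 6-day incubation: daily CO₂ = basal
respiration (9.2 μmol/day) + substrate mineralization (daily fractions
0.40/0.25/0.15/0.08/0.05/0.02 of the 110.13 μmol substrate C) + a primed
increment (9.9 μmol control, 19.1 μmol warmed in the demo) released in
proportion to substrate turnover. ¹³C bookkeeping is exact: substrate CO₂
carries the substrate's ¹³C share, soil CO₂ the background AF (δ¹³C =
−25‰). Measurement noise is multiplicative lognormal on concentrations
(CV 1%, typical of laser/IRMS gas analysis) with a separate, much smaller
noise on the isotope ratio (0.2%), reflecting that the ratio is measured on
the same aliquot. With zero noise every pipeline estimate inverts its
generator parameter exactly (band shift, substrate fraction, primed C);
this closure is asserted in tests.

What the generator does **not** emulate: chimeras and other sequencing
artifacts beyond multinomial noise, PCR amplification bias, compositional
coupling between taxa, gradient smearing/tailing, day-to-day temperature
drift, or diffusive losses — so passing recovery tests demonstrates the
estimators invert the stated model, not that real gradients are this clean.

## Problem sizes and numerical notes

Recovery ensembles use 20 simulated gradient datasets (3 vs 3 replicates,
100 OTUs) and 100 simulated vessels — sizes at which the Monte Carlo error
of the reported sensitivity/FDR/median-error statistics is well below the
thresholds being checked. All randomness flows from explicit integer seeds
through `numpy.random.Generator` (per-column seeds via `SeedSequence.spawn`),
so every table is reproducible byte-for-byte; output headers record package
version, configuration hash and seed. Degenerate inputs (all-zero columns,
empty windows, identity correlation matrices, graphs without legal swaps)
raise typed errors or warn rather than returning silent defaults.

## Known limitations

* The filter's step 1 is intentionally strict at n = 3: only complete
  separations pass, so sensitivity falls quickly for weakly labeled taxa
  (atom fraction ≲ 0.3 at these band widths).
* The δ-route mixing formula is retained for comparability but biased at
  high enrichment; cross-study comparisons should state the route used.
* The RMT scan returns the *smallest* Poisson-stable threshold; on sparse
  noisy correlation matrices this can sit below the value a practitioner
  would pick by eye, keeping some noise edges (module recovery on planted
  partitions is then imperfect, as the demo reports).
* Absolute abundances inherit all qPCR caveats (extraction and primer
  bias); they are copies per gram of the assayed template, not cells.
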