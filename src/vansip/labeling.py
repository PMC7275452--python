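"""qPCR-weighted resampling and the three-step ¹³C-labeling filter.

OTUs recovered from the heavy fractions of a ¹³C-substrate gradient are not
all isotopically labeled: high-GC genomes band at high density without any
label, and sequencing errors seed spurious low-abundance OTUs.  The filter
distinguishes true decomposers in three consecutive steps:

1. an exact two-sided rank-sum test of per-replicate heavy-fraction
   abundance, ¹³C vs ¹²C incubations (high-GC false positives look the same
   in both groups and fail);
2. the modified sequence number in heavy fractions (MSNH): the OTU's
   heavy-fraction relative abundance in the ¹³C samples minus that in the
   paired ¹²C samples;
3. a magnitude rule: the MSNH must be at least ``msnh_ratio_min`` (default
   20%) of the OTU's total relative abundance over the analyzed (heavy +
   light) fractions, removing sequencing-error artifacts.

Only steps 1 and 3 remove OTUs; step 2 computes the statistic used by
step 3 and reported as the decomposer's relative abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    DomainError,
    InsufficientReplicationError,
    PairingError,
)
from .gradient import GradientSample, PeakAssignment

#: Per-fraction resampling depth used by the upstream study pipeline.
DEFAULT_RESAMPLING_DEPTH = 29_845

DEFAULT_ALPHA = 0.10
DEFAULT_MSNH_RATIO_MIN = 0.20


# ---------------------------------------------------------------------------
# OTU table container


@dataclass
class OtuTable:
    """OTU x fraction-column count matrix with per-column qPCR scaling.

    Columns are keyed by ``(sample_id, fraction_index)``; ``column_copies``
    holds the 16S copy number of each fraction so relative abundances can be
    put on an absolute (copies) scale.
    """

    otu_ids: list[str]
    counts: np.ndarray
    column_keys: list[tuple[str, int]]
    column_copies: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.otu_ids), len(self.column_keys)):
            raise ConfigurationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.column_keys)} columns"
            )
        if np.any(self.counts < 0):
            raise DomainError("negative counts in OTU table")
        if self.column_copies is not None:
            self.column_copies = np.asarray(self.column_copies, dtype=float)
            if self.column_copies.shape != (len(self.column_keys),):
                raise ConfigurationError("column_copies length mismatch")
            if np.any(self.column_copies < 0):
                raise DomainError("negative qPCR copies")

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Per-column relative abundances; all-zero columns stay zero."""
        totals = self.column_sums.astype(float)
        safe = np.where(totals > 0, totals, 1.0)
        return self.counts / safe

    def columns_for(self, sample_id: str, fraction_indices: Sequence[int] | frozenset[int]) -> list[int]:
        wanted = set(fraction_indices)
        return [
            j
            for j, (sid, fi) in enumerate(self.column_keys)
            if sid == sample_id and fi in wanted
        ]

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(
            self.column_keys, names=["sample_id", "fraction_index"]
        )
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=cols)

    @classmethod
    def from_samples(cls, samples: Sequence[GradientSample]) -> "OtuTable":
        """Assemble the table from per-fraction OTU counts of gradient samples."""
        otu_ids = sorted({o for s in samples for f in s.fractions for o in f.otu_counts})
        keys: list[tuple[str, int]] = []
        copies: list[float] = []
        cols: list[np.ndarray] = []
        for s in samples:
            for f in s.fractions:
                keys.append((s.sample_id, f.index))
                copies.append(f.copies)
                cols.append(np.array([f.otu_counts.get(o, 0) for o in otu_ids]))
        counts = np.column_stack(cols) if cols else np.zeros((len(otu_ids), 0), int)
        return cls(otu_ids, counts, keys, np.array(copies))


def qpcr_weight(table: OtuTable) -> np.ndarray:
    """Copy-scaled abundances: per-column relative abundance x qPCR copies.

    Raw counts are untouched; the returned matrix is on a 16S-copies scale.
    Columns with zero copies come out all-zero (they carry no absolute
    information) and are left to the caller to flag.
    """
    if table.column_copies is None:
        raise ConfigurationError("OTU table has no per-column qPCR copies")
    return table.relative_abundance() * table.column_copies


# ---------------------------------------------------------------------------
# Resampling


def resample_column(
    counts: np.ndarray,
    depth: int = DEFAULT_RESAMPLING_DEPTH,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Resample one fraction-column of counts to a fixed depth.

    Columns at least as deep as ``depth`` are subsampled without replacement
    (multivariate hypergeometric); shallower columns are resampled with
    replacement (multinomial on the observed proportions).  Deterministic
    for a fixed seed.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise DomainError("negative counts")
    total = int(counts.sum())
    if total == 0:
        raise DegenerateInputError("cannot resample an all-zero column")
    if depth <= 0:
        raise DomainError("depth must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if total >= depth:
        return rng.multivariate_hypergeometric(counts.astype(np.int64), depth)
    return rng.multinomial(depth, counts / total)


def resample_table(
    table: OtuTable,
    depth: int = DEFAULT_RESAMPLING_DEPTH,
    seed: int = 0,
) -> tuple[OtuTable, list[tuple[str, int]]]:
    """Resample every column to ``depth``; returns the new table and the
    list of columns that were shallower than ``depth`` (resampled with
    replacement)."""
    ss = np.random.SeedSequence(seed)
    child_rngs = [np.random.default_rng(s) for s in ss.spawn(len(table.column_keys))]
    out = np.zeros_like(table.counts)
    shallow: list[tuple[str, int]] = []
    for j, rng in enumerate(child_rngs):
        col = table.counts[:, j]
        if col.sum() == 0:
            continue  # all-zero columns stay zero; flagged by callers
        if col.sum() < depth:
            shallow.append(table.column_keys[j])
        out[:, j] = resample_column(col, depth, rng)
    return (
        OtuTable(table.otu_ids, out, list(table.column_keys), table.column_copies),
        shallow,
    )


# ---------------------------------------------------------------------------
# Exact rank-sum test


def exact_ranksum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact Wilcoxon rank-sum p-value with midranks for ties.

    Enumerates every assignment of the pooled observations to the two
    groups (conditional permutation distribution of the rank sum), so ties
    are handled exactly.  Falls back to the normal approximation with tie
    correction when the enumeration would exceed ~2x10^5 assignments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientReplicationError(
            "rank-sum test needs at least 2 replicates per group"
        )
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    n1, n = x.size, pooled.size
    n_assign = comb(n, n1)
    if n_assign > 200_000:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return float(res.pvalue)
    w_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    dev_obs = abs(w_obs - mu)
    hits = 0
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        if abs(w - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / n_assign


def permutation_t_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact permutation p-value of the mean-difference statistic."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientReplicationError(
            "permutation test needs at least 2 replicates per group"
        )
    pooled = np.concatenate([x, y])
    n1, n = x.size, pooled.size
    if comb(n, n1) > 200_000:
        res = stats.ttest_ind(x, y)
        return 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    total = pooled.sum()
    obs = abs(x.mean() - y.mean())
    hits = 0
    n_assign = 0
    for idx in combinations(range(n), n1):
        s1 = pooled[list(idx)].sum()
        diff = abs(s1 / n1 - (total - s1) / (n - n1))
        hits += diff >= obs - 1e-12
        n_assign += 1
    return hits / n_assign


def heavy_enrichment_test(
    heavy_c13: Sequence[float],
    heavy_c12: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    statistic: str = "rank",
) -> tuple[float, bool]:
    """Step-1 test: per-replicate heavy-fraction abundance, ¹³C vs ¹²C.

    Returns the exact two-sided p-value and whether the OTU passes
    (p <= alpha).  ``statistic`` selects the exact rank-sum test (default)
    or an exact permutation test of the t-like mean difference
    (``t_permutation``).  With 3 vs 3 replicates the rank test's smallest
    attainable p is exactly 0.10, so the default alpha keeps only complete
    separations.
    """
    if statistic == "rank":
        p = exact_ranksum_p(heavy_c13, heavy_c12)
    elif statistic == "t_permutation":
        p = permutation_t_p(heavy_c13, heavy_c12)
    else:
        raise ConfigurationError(f"unknown test statistic {statistic!r}")
    return p, bool(p <= alpha)


def compute_msnh(rel_heavy_c13: float, rel_heavy_c12: float) -> float:
    """Modified sequence number in heavy fractions (MSNH).

    The OTU's mean heavy-fraction relative abundance in the ¹³C sample minus
    the same quantity in the paired ¹²C sample.  May be negative.
    """
    for v in (rel_heavy_c13, rel_heavy_c12):
        if not (0.0 <= v <= 1.0):
            raise DomainError(f"relative abundance {v} outside [0, 1]")
    return rel_heavy_c13 - rel_heavy_c12


def absolute_abundance(relative_abundance: float, total_labeled_copies: float) -> float:
    """Absolute abundance (copies/g): relative share x total labeled copies."""
    if relative_abundance < 0 or total_labeled_copies < 0:
        raise DomainError("inputs must be non-negative")
    return relative_abundance * total_labeled_copies


# ---------------------------------------------------------------------------
# The three-step filter


@dataclass
class LabelFilterResult:
    """Per-OTU record of the three filter steps."""

    otu_id: str
    p_value: float
    msnh: float
    msnh_ratio: float
    passed_step1: bool
    passed_step2: bool
    passed_step3: bool
    is_decomposer: bool


def _heavy_light_sums(
    rel: np.ndarray,
    table: OtuTable,
    sample: GradientSample,
    peaks: Mapping[str, PeakAssignment],
) -> tuple[np.ndarray, np.ndarray]:
    pk = peaks[sample.sample_id]
    heavy_cols = table.columns_for(sample.sample_id, pk.heavy_indices)
    light_cols = table.columns_for(sample.sample_id, pk.light_indices)
    if len(heavy_cols) != len(pk.heavy_indices) or len(light_cols) != len(pk.light_indices):
        raise ConfigurationError(
            f"sample {sample.sample_id}: peak fractions missing from the OTU table"
        )
    return rel[:, heavy_cols].sum(axis=1), rel[:, light_cols].sum(axis=1)


def apply_label_filter(
    table: OtuTable,
    peaks: Mapping[str, PeakAssignment],
    samples: Sequence[GradientSample],
    treatment: str,
    alpha: float = DEFAULT_ALPHA,
    msnh_ratio_min: float = DEFAULT_MSNH_RATIO_MIN,
    ratio_denominator: str = "heavy_plus_light",
    statistic: str = "rank",
) -> list[LabelFilterResult]:
    """Run the three-step labeling filter for one treatment.

    ``samples`` supplies the design metadata; every ¹³C replicate of the
    treatment must have a ¹²C replicate of the same treatment (the groups
    need not be matched one-to-one beyond that).  Results are returned for
    every OTU, with pass flags, so removed OTUs stay visible in reports.

    ``ratio_denominator`` selects the "total relative abundance" used by the
    20% rule: ``heavy_plus_light`` (default; the analyzed fractions of the
    ¹³C samples), ``heavy_only``, or ``whole_gradient``.
    """
    c13 = [s for s in samples if s.treatment == treatment and s.isotope == "C13"]
    c12 = [s for s in samples if s.treatment == treatment and s.isotope == "C12"]
    if not c13:
        raise PairingError(f"no ¹³C samples for treatment {treatment!r}")
    c12_reps = {s.replicate for s in c12}
    unpaired = [s.sample_id for s in c13 if s.replicate not in c12_reps]
    if unpaired:
        raise PairingError(
            f"¹³C samples without a paired ¹²C sample: {', '.join(unpaired)}"
        )
    if len(c13) < 2 or len(c12) < 2:
        raise InsufficientReplicationError(
            "need >= 2 replicates in both isotope groups"
        )

    rel = table.relative_abundance()
    heavy13 = np.column_stack(
        [_heavy_light_sums(rel, table, s, peaks)[0] for s in c13]
    )
    heavy12 = np.column_stack(
        [_heavy_light_sums(rel, table, s, peaks)[0] for s in c12]
    )
    light13 = np.column_stack(
        [_heavy_light_sums(rel, table, s, peaks)[1] for s in c13]
    )
    n_heavy = len(next(iter(peaks.values())).heavy_indices)

    # replicate-averaged heavy-column sums, on the per-fraction-mean scale
    mean_h13 = heavy13.mean(axis=1)
    mean_h12 = heavy12.mean(axis=1)
    msnh = (mean_h13 - mean_h12) / n_heavy

    if ratio_denominator == "heavy_plus_light":
        denom = (heavy13 + light13).mean(axis=1)
    elif ratio_denominator == "heavy_only":
        denom = mean_h13
    elif ratio_denominator == "whole_gradient":
        all13 = np.column_stack(
            [
                rel[:, [j for j, (sid, _) in enumerate(table.column_keys) if sid == s.sample_id]].sum(axis=1)
                for s in c13
            ]
        )
        denom = all13.mean(axis=1)
    else:
        raise ConfigurationError(
            f"unknown ratio_denominator {ratio_denominator!r}"
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, (mean_h13 - mean_h12) / denom, np.nan)

    results: list[LabelFilterResult] = []
    for i, otu in enumerate(table.otu_ids):
        if np.all(heavy13[i] == 0) and np.all(heavy12[i] == 0):
            # absent from every heavy fraction: no evidence, fails step 1
            p = 1.0
        else:
            p, _ = heavy_enrichment_test(
                heavy13[i], heavy12[i], alpha, statistic=statistic
            )
        p1 = bool(p <= alpha)
        p2 = bool(np.isfinite(msnh[i]))
        p3 = bool(np.isfinite(ratio[i]) and ratio[i] >= msnh_ratio_min)
        results.append(
            LabelFilterResult(
                otu_id=otu,
                p_value=float(p),
                msnh=float(msnh[i]),
                msnh_ratio=float(ratio[i]) if np.isfinite(ratio[i]) else np.nan,
                passed_step1=p1,
                passed_step2=p2,
                passed_step3=p3,
                is_decomposer=p1 and p3,
            )
        )
    return results


def results_frame(results: Sequence[LabelFilterResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("otu_id")


def total_labeled_copies(
    table: OtuTable,
    peaks: Mapping[str, PeakAssignment],
    samples: Sequence[GradientSample],
    treatment: str,
) -> float:
    """Mean (over ¹³C replicates) excess heavy-fraction 16S copies vs ¹²C.

    An estimate of the total abundance of ¹³C-labeled DNA: copies summed over
    the heavy fractions of each ¹³C gradient minus the same sum in the paired
    ¹²C gradients (the unlabeled high-density background).
    Clipped at zero."""
    if table.column_copies is None:
        raise ConfigurationError("OTU table has no per-column qPCR copies")

    def heavy_copy_sum(group: str) -> float:
        vals = []
        for s in samples:
            if s.treatment != treatment or s.isotope != group:
                continue
            cols = table.columns_for(s.sample_id, peaks[s.sample_id].heavy_indices)
            vals.append(float(table.column_copies[cols].sum()))
        if not vals:
            raise PairingError(f"no {group} samples for treatment {treatment!r}")
        return float(np.mean(vals))

    return max(heavy_copy_sum("C13") - heavy_copy_sum("C12"), 0.0)
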