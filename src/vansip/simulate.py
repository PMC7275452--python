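"""Synthetic gradient and flux generators with known ground truth.

The gradient generator places each taxon's DNA as a Gaussian band along
buoyant density.  The band center combines the GC-density relation
ρ(GC) = 1.660 + 0.098·GC (g/ml) with an isotope shift proportional to the
taxon's ¹³C atom fraction (full labeling shifts DNA by +0.036 g/ml).  Band
mass is integrated over the density bins of a 24-fraction gradient; qPCR
copies get multiplicative lognormal noise and reads are multinomial at a
fixed depth, mimicking amplicon sequencing of each fraction.

The flux generator produces 6-day headspace series for a vessel triplet
(¹³C-substrate, ¹²C-substrate, water-only) from a daily budget of basal
respiration, substrate mineralization, and a primed increment, with exact
¹³C bookkeeping so the pipeline's estimates can be checked against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DomainError
from .gradient import Fraction, GradientSample
from .labeling import OtuTable
from .priming import (
    DEFAULT_PRESSURE_PA,
    DEFAULT_TEMPERATURE_K,
    DEFAULT_VOLUME_ML,
    FluxObservation,
    PrimingResult,
    R_GAS,
    delta_to_atom_fraction,
    vanillin_c_budget,
)

#: GC→density intercept/slope (g/ml) and the full-label density shift.
GC_DENSITY_INTERCEPT = 1.660
GC_DENSITY_SLOPE = 0.098
FULL_LABEL_SHIFT = 0.036


# ---------------------------------------------------------------------------
# Gradient simulation


@dataclass(frozen=True)
class TaxonSpec:
    """One community member: GC content, abundance, labeling, warming response."""

    otu_id: str
    gc_content: float
    baseline_relative_abundance: float
    atom_fraction_label: float = 0.0
    response_multiplier_warmed: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_content <= 1.0):
            raise ConfigurationError("gc_content must be in [0, 1]")
        if self.baseline_relative_abundance < 0:
            raise ConfigurationError("abundance must be non-negative")
        if not (0.0 <= self.atom_fraction_label <= 1.0):
            raise ConfigurationError("atom_fraction_label must be in [0, 1]")
        if self.response_multiplier_warmed < 0:
            raise ConfigurationError("response multiplier must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Physical and sampling parameters of a simulated gradient dataset."""

    n_fractions: int = 24
    density_range: tuple[float, float] = (1.66, 1.78)
    band_sigma: float = 0.004
    density_shift_full_label: float = FULL_LABEL_SHIFT
    qpcr_cv: float = 0.05
    read_depth: int = 30_000
    replicates: int = 3
    total_copies: float = 1.0e6
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.density_range
        if not (1.60 <= lo < hi <= 1.80):
            raise ConfigurationError("density_range must lie within [1.60, 1.80]")
        if self.band_sigma < 0 or self.qpcr_cv < 0:
            raise ConfigurationError("dispersions must be >= 0")
        if self.n_fractions < 2 or self.read_depth < 1 or self.replicates < 1:
            raise ConfigurationError("n_fractions/read_depth/replicates too small")


def band_center(
    taxon: TaxonSpec, labeled: bool, shift_full_label: float = FULL_LABEL_SHIFT
) -> float:
    """Closed-form band center: ρ(GC) plus the isotope shift when labeled."""
    rho = GC_DENSITY_INTERCEPT + GC_DENSITY_SLOPE * taxon.gc_content
    if labeled:
        rho += taxon.atom_fraction_label * shift_full_label
    return rho


def _fraction_edges(cfg: SimulationConfig) -> np.ndarray:
    """Density bin edges, descending (fraction 1 = densest)."""
    lo, hi = cfg.density_range
    return np.linspace(hi, lo, cfg.n_fractions + 1)


def simulate_gradient(
    taxa: Sequence[TaxonSpec],
    cfg: SimulationConfig,
    treatment: str,
    isotope: str,
    replicate: int,
    rng: np.random.Generator,
) -> GradientSample:
    """Simulate one gradient run for one design cell.

    ``isotope`` of ``C12`` or ``water`` forces every taxon's label to zero.
    Reads per fraction sum exactly to ``cfg.read_depth``.
    """
    if not taxa:
        raise ConfigurationError("empty taxon list")
    total_rel = sum(t.baseline_relative_abundance for t in taxa)
    if total_rel <= 0:
        raise ConfigurationError("community abundances sum to zero")
    labeled = isotope == "C13"
    edges = _fraction_edges(cfg)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # per-taxon mass per fraction bin (copies), Gaussian band integrated
    masses = np.zeros((len(taxa), cfg.n_fractions))
    for i, t in enumerate(taxa):
        mult = t.response_multiplier_warmed if treatment == "warmed" else 1.0
        total = cfg.total_copies * (t.baseline_relative_abundance / total_rel) * mult
        mu = band_center(t, labeled, cfg.density_shift_full_label)
        if cfg.band_sigma == 0:
            j = int(np.argmin(np.abs(centers - mu)))
            masses[i, j] = total
        else:
            upper = stats.norm.cdf(edges[:-1], mu, cfg.band_sigma)
            lower = stats.norm.cdf(edges[1:], mu, cfg.band_sigma)
            masses[i] = total * (upper - lower)

    frac_mass = masses.sum(axis=0)
    if cfg.qpcr_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.qpcr_cv**2))
        noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, cfg.n_fractions))
    else:
        noise = np.ones(cfg.n_fractions)
    copies = frac_mass * noise

    otu_ids = [t.otu_id for t in taxa]
    fractions = []
    for j in range(cfg.n_fractions):
        if frac_mass[j] > 0:
            reads = rng.multinomial(cfg.read_depth, masses[:, j] / frac_mass[j])
        else:
            reads = np.zeros(len(taxa), dtype=int)
        fractions.append(
            Fraction(
                index=j + 1,
                buoyant_density=float(centers[j]),
                copies=float(copies[j]),
                otu_counts=dict(zip(otu_ids, reads.tolist())),
            )
        )
    sample_id = f"{treatment}_{isotope}_r{replicate}"
    return GradientSample(sample_id, treatment, isotope, replicate, tuple(fractions))


def simulate_dataset(
    taxa: Sequence[TaxonSpec],
    cfg: SimulationConfig,
    treatments: Sequence[str] = ("warmed", "control"),
    isotopes: Sequence[str] = ("C13", "C12", "water"),
) -> tuple[list[GradientSample], OtuTable, pd.DataFrame]:
    """Full design: treatments x isotope groups x replicates.

    Returns the gradient samples, the assembled OTU table, and the truth
    table of taxa (``labeled`` = carries any ¹³C label).
    """
    rng = np.random.default_rng(cfg.seed)
    samples = [
        simulate_gradient(taxa, cfg, tr, iso, rep, rng)
        for tr in treatments
        for iso in isotopes
        for rep in range(1, cfg.replicates + 1)
    ]
    table = OtuTable.from_samples(samples)
    truth = pd.DataFrame(
        {
            "otu_id": [t.otu_id for t in taxa],
            "gc_content": [t.gc_content for t in taxa],
            "baseline_relative_abundance": [
                t.baseline_relative_abundance for t in taxa
            ],
            "atom_fraction_label": [t.atom_fraction_label for t in taxa],
            "labeled": [t.atom_fraction_label > 0 for t in taxa],
        }
    ).set_index("otu_id")
    return samples, table, truth


def default_community(
    n_otus: int = 100,
    n_labeled: int = 10,
    atom_fraction_label: float = 0.9,
    labeled_gc: float = 0.575,
    seed: int = 12345,
) -> list[TaxonSpec]:
    """The default demo community: mostly unlabeled taxa around GC ~0.61
    (light band near 1.720 g/ml), a high-GC minority (labeling false-positive
    challenge), and ``n_labeled`` vanillin consumers whose labeled band sits
    near 1.748 g/ml.  Abundances follow a lognormal rank curve."""
    rng = np.random.default_rng(seed)
    n_unlabeled = n_otus - n_labeled
    gc = np.clip(rng.normal(0.61, 0.03, n_unlabeled), 0.30, 0.75)
    # a few genuinely high-GC taxa that band inside the heavy window unlabeled
    n_high_gc = max(2, n_unlabeled // 20)
    gc[:n_high_gc] = rng.uniform(0.82, 0.92, n_high_gc)
    abund = rng.lognormal(0.0, 1.0, n_otus)
    abund /= abund.sum()
    taxa: list[TaxonSpec] = []
    for i in range(n_unlabeled):
        taxa.append(
            TaxonSpec(
                otu_id=f"OTU{i + 1:04d}",
                gc_content=float(gc[i]),
                baseline_relative_abundance=float(abund[i]),
            )
        )
    for i in range(n_labeled):
        taxa.append(
            TaxonSpec(
                otu_id=f"OTU{n_unlabeled + i + 1:04d}",
                gc_content=labeled_gc,
                baseline_relative_abundance=float(abund[n_unlabeled + i]),
                atom_fraction_label=atom_fraction_label,
                response_multiplier_warmed=3.0,
            )
        )
    return taxa


def simulate_block_abundance(
    n_blocks: int = 5,
    per_block: int = 20,
    n_samples: int = 12,
    within_weight: float = 0.75,
    global_weight: float = 0.10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Planted-partition OTU x sample abundance table for network tests.

    Each block shares a latent factor (weight ``within_weight``), all OTUs
    share a weak global factor (``global_weight``), and the rest is
    independent noise, so within-block correlations are strong and
    between-block correlations weak.  Returns the (non-negative) abundance
    frame and the true block label per OTU.
    """
    if not (0 <= within_weight + global_weight <= 1):
        raise ConfigurationError("factor weights must sum to <= 1")
    rng = np.random.default_rng(seed)
    noise_weight = 1.0 - within_weight - global_weight
    g = rng.normal(size=n_samples)
    rows, ids, blocks = [], [], []
    for b in range(n_blocks):
        f = rng.normal(size=n_samples)
        for i in range(per_block):
            x = (
                np.sqrt(within_weight) * f
                + np.sqrt(global_weight) * g
                + np.sqrt(noise_weight) * rng.normal(size=n_samples)
            )
            rows.append(x - x.min() + 0.1)  # shift positive: read-count-like
            ids.append(f"OTU_b{b}_{i:02d}")
            blocks.append(b)
    frame = pd.DataFrame(rows, index=ids)
    frame.columns = [f"S{j + 1:02d}" for j in range(n_samples)]
    return frame, pd.Series(blocks, index=ids, name="block")


# ---------------------------------------------------------------------------
# Flux simulation


@dataclass(frozen=True)
class FluxSimSpec:
    """Ground-truth parameters of a simulated 6-day incubation triplet."""

    substrate_13c_umol: float = 82.6
    n_labeled_c: int = 6
    n_total_c: int = 8
    substrate_mineralized_fraction: tuple[float, ...] = (
        0.40,
        0.25,
        0.15,
        0.08,
        0.05,
        0.02,
    )
    basal_respiration_umol_per_day: float = 9.2
    primed_umol_total: float = 9.9
    background_delta13c: float = -25.0
    noise_cv: float = 0.01
    isotope_noise_cv: float = 0.002
    volume_ml: float = DEFAULT_VOLUME_ML
    pressure_pa: float = DEFAULT_PRESSURE_PA
    temperature_k: float = DEFAULT_TEMPERATURE_K
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.substrate_mineralized_fraction)
        if np.any(fr < 0) or np.any(fr > 1) or fr.sum() > 1 + 1e-12:
            raise ConfigurationError(
                "daily mineralized fractions must be in [0, 1] with sum <= 1"
            )
        if self.basal_respiration_umol_per_day < 0:
            raise ConfigurationError("basal respiration must be >= 0")
        if self.noise_cv < 0 or self.isotope_noise_cv < 0:
            raise ConfigurationError("noise CVs must be >= 0")

    @property
    def total_substrate_c_umol(self) -> float:
        return vanillin_c_budget(
            self.substrate_13c_umol, self.n_labeled_c, self.n_total_c
        )

    @property
    def label_atom_fraction(self) -> float:
        """¹³C per substrate C atom implied by the bookkeeping (6/8 default)."""
        return self.substrate_13c_umol / self.total_substrate_c_umol


def _micromol_to_ppm(umol: float, spec: FluxSimSpec) -> float:
    return (
        umol
        * 1e-6
        * R_GAS
        * spec.temperature_k
        / (spec.pressure_pa * spec.volume_ml * 1e-6)
        * 1e6
    )


def simulate_flux(
    spec: FluxSimSpec,
) -> tuple[dict[str, list[FluxObservation]], PrimingResult]:
    """Simulate the vessel triplet and return the truth priming budget.

    The primed increment is released in proportion to daily substrate
    mineralization (priming tracks substrate turnover).  ¹³C bookkeeping:
    substrate-derived CO₂ carries the substrate's ¹³C share exactly, all
    soil-derived CO₂ (basal + primed) carries the background atom fraction.
    """
    rng = np.random.default_rng(spec.seed)
    days = range(1, len(spec.substrate_mineralized_fraction) + 1)
    af_bg = delta_to_atom_fraction(spec.background_delta13c)
    af_label = spec.label_atom_fraction
    frac = np.asarray(spec.substrate_mineralized_fraction)
    frac_total = frac.sum()

    def noisy(value: float, cv: float) -> float:
        if cv == 0 or value == 0:
            return value
        sigma = np.sqrt(np.log1p(cv**2))
        return value * float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))

    series: dict[str, list[FluxObservation]] = {
        "C13": [],
        "C12": [],
        "water": [],
    }
    for d in days:
        f = frac[d - 1]
        substrate_c = f * spec.total_substrate_c_umol
        primed_c = (
            spec.primed_umol_total * f / frac_total if frac_total > 0 else 0.0
        )
        basal = spec.basal_respiration_umol_per_day

        budgets = {
            "C13": (basal + substrate_c + primed_c, substrate_c * af_label
                    + (basal + primed_c) * af_bg),
            "C12": (basal + substrate_c + primed_c,
                    (basal + substrate_c + primed_c) * af_bg),
            "water": (basal, basal * af_bg),
        }
        for group, (total_umol, c13_umol) in budgets.items():
            total_meas = noisy(total_umol, spec.noise_cv)
            af = c13_umol / total_umol if total_umol > 0 else 0.0
            af_meas = min(noisy(af, spec.isotope_noise_cv), 1.0)
            series[group].append(
                FluxObservation(
                    day=d,
                    co2_ppm=_micromol_to_ppm(total_meas, spec),
                    c13_ppm=_micromol_to_ppm(total_meas * af_meas, spec),
                    volume_ml=spec.volume_ml,
                    pressure_pa=spec.pressure_pa,
                    temperature_k=spec.temperature_k,
                )
            )

    total_true = (
        spec.basal_respiration_umol_per_day * len(frac)
        + frac_total * spec.total_substrate_c_umol
        + spec.primed_umol_total
    )
    substrate_true = frac_total * spec.total_substrate_c_umol
    water_true = spec.basal_respiration_umol_per_day * len(frac)
    truth = PrimingResult(
        total_co2=total_true,
        substrate_derived=substrate_true,
        water_control_respiration=water_true,
        primed=spec.primed_umol_total,
        c13_cumulative=substrate_true * af_label + (water_true + spec.primed_umol_total) * af_bg,
    )
    return series, truth


def replicate_flux_specs(spec: FluxSimSpec, n: int) -> list[FluxSimSpec]:
    """n independent replicate specs differing only in their child seeds."""
    ss = np.random.SeedSequence(spec.seed)
    return [
        replace(spec, seed=int(child.generate_state(1)[0] % (2**31 - 1)))
        for child in ss.spawn(n)
    ]
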