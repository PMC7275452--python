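"""Gradient-level data model and heavy/light peak assignment.

A CsCl buoyant-density gradient run is represented as an ordered list of
fractions (densest first), each carrying its measured buoyant density, the
16S rRNA gene copy number from qPCR, and per-OTU read counts.  ¹³C-labeled
("heavy") DNA bands at a higher density than unlabeled ("light") DNA, so
peak assignment works on fixed density windows: the four highest-copy
fractions inside each window form the heavy and light fraction sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DegenerateInputError,
    DomainError,
    PeakAssignmentError,
)

TREATMENTS = ("warmed", "control")
ISOTOPES = ("C13", "C12", "water")

#: Default density windows (g/ml).  The light window is half-open on the
#: right so the shared 1.735 boundary belongs to the heavy window only.
HEAVY_WINDOW = (1.735, 1.765)
LIGHT_WINDOW = (1.705, 1.735)

#: Default linear refractometer calibration rho = a*RI + b for CsCl.
RI_CALIBRATION = (10.8601, -13.4974)

DENSITY_BOUNDS = (1.60, 1.80)


def ri_to_density(
    refractive_index: float,
    a: float = RI_CALIBRATION[0],
    b: float = RI_CALIBRATION[1],
) -> float:
    """Convert a refractometer reading to CsCl buoyant density (g/ml).

    Linear calibration ``rho = a*RI + b``; the defaults are a standard
    CsCl calibration at 20 degC.  Readings outside [1.3, 1.5] are rejected
    as physically implausible for a CsCl gradient.
    """
    if not (1.3 <= refractive_index <= 1.5):
        raise DomainError(
            f"refractive index {refractive_index!r} outside [1.3, 1.5]"
        )
    return a * refractive_index + b


@dataclass(frozen=True)
class Fraction:
    """One gradient fraction: position, density, qPCR copies, OTU counts."""

    index: int
    buoyant_density: float
    copies: float
    otu_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (DENSITY_BOUNDS[0] <= self.buoyant_density <= DENSITY_BOUNDS[1]):
            raise DomainError(
                f"fraction {self.index}: buoyant density "
                f"{self.buoyant_density} outside {DENSITY_BOUNDS} g/ml"
            )
        if self.copies < 0:
            raise DomainError(f"fraction {self.index}: negative copies")
        if any(c < 0 for c in self.otu_counts.values()):
            raise DomainError(f"fraction {self.index}: negative OTU count")


@dataclass(frozen=True)
class GradientSample:
    """One gradient run with its experimental-design coordinates."""

    sample_id: str
    treatment: str
    isotope: str
    replicate: int
    fractions: tuple[Fraction, ...]

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise DomainError(f"unknown treatment {self.treatment!r}")
        if self.isotope not in ISOTOPES:
            raise DomainError(f"unknown isotope group {self.isotope!r}")
        if self.replicate < 1:
            raise DomainError("replicate must be a positive integer")
        object.__setattr__(self, "fractions", tuple(self.fractions))
        # density monotonicity (densest first) is an expectation of the
        # fractionation protocol; violations are reported by validate_dataset
        # rather than rejected here, so raw tables can still be inspected.

    @property
    def densities(self) -> np.ndarray:
        return np.array([f.buoyant_density for f in self.fractions])

    @property
    def copies(self) -> np.ndarray:
        return np.array([f.copies for f in self.fractions])

    @property
    def indices(self) -> np.ndarray:
        return np.array([f.index for f in self.fractions])


@dataclass(frozen=True)
class PeakAssignment:
    """Heavy/light fraction sets for one gradient sample."""

    heavy_indices: frozenset[int]
    light_indices: frozenset[int]
    heavy_mode_density: float
    light_mode_density: float
    heavy_present: bool

    def __post_init__(self) -> None:
        if self.heavy_indices & self.light_indices:
            raise DomainError("heavy and light fraction sets overlap")
        if self.heavy_present and not (
            self.heavy_mode_density > self.light_mode_density
        ):
            raise DomainError(
                "heavy mode must be denser than light mode when present"
            )


def _in_window(rho: np.ndarray, window: tuple[float, float], closed_right: bool) -> np.ndarray:
    lo, hi = window
    if closed_right:
        return (rho >= lo) & (rho <= hi)
    return (rho >= lo) & (rho < hi)


def _top_fractions(
    sample: GradientSample, mask: np.ndarray, k: int, label: str
) -> tuple[np.ndarray, int]:
    """Indices (positions) of the k highest-copy in-window fractions and the mode."""
    pos = np.flatnonzero(mask)
    if pos.size == 0:
        raise PeakAssignmentError(
            f"sample {sample.sample_id}: no fraction inside the {label} window"
        )
    if pos.size < k:
        raise PeakAssignmentError(
            f"sample {sample.sample_id}: only {pos.size} fractions in the "
            f"{label} window, {k} required"
        )
    copies = sample.copies[pos]
    # stable sort by (-copies, position) so ties resolve to denser fractions
    order = np.lexsort((pos, -copies))
    top = pos[order[:k]]
    mode = pos[order[0]]
    return top, int(mode)


def detect_peaks(
    sample: GradientSample,
    heavy_window: tuple[float, float] = HEAVY_WINDOW,
    light_window: tuple[float, float] = LIGHT_WINDOW,
    reference: GradientSample | None = None,
    prominence: float = 3.0,
    n_peak_fractions: int = 4,
) -> PeakAssignment:
    """Assign heavy and light fraction sets from the copies-vs-density profile.

    The mode of each window is the in-window fraction with the highest qPCR
    copy number; the peak set is the ``n_peak_fractions`` highest-copy
    fractions in the window.  ``heavy_present`` asks whether the heavy-window
    mode is a real labeled-DNA band rather than the tail of the light peak:

    * with a paired ``reference`` gradient (the ¹²C or water control), the
      heavy mode must exceed ``prominence`` times the reference's copies
      interpolated at the same density;
    * without a reference, it must exceed ``prominence`` times the copy
      minimum (valley) between the light and heavy modes.

    Both criteria are ratios, so the assignment is invariant to uniform
    rescaling of copy numbers.
    """
    if light_window[1] > heavy_window[0]:
        raise DomainError("windows must not overlap; heavy window lies above light")
    copies = sample.copies
    if np.all(copies == 0):
        raise DegenerateInputError(
            f"sample {sample.sample_id}: all fractions have zero copies"
        )
    if np.count_nonzero(copies > 0) < 12:
        raise DomainError(
            f"sample {sample.sample_id}: fewer than 12 fractions with copies > 0"
        )
    rho = sample.densities

    heavy_mask = _in_window(rho, heavy_window, closed_right=True)
    light_mask = _in_window(rho, light_window, closed_right=False)
    heavy_pos, heavy_mode = _top_fractions(sample, heavy_mask, n_peak_fractions, "heavy")
    light_pos, light_mode = _top_fractions(sample, light_mask, n_peak_fractions, "light")

    heavy_mode_copies = copies[heavy_mode]
    if reference is not None:
        # reference profile interpolated at the heavy-mode density;
        # np.interp wants ascending x, densities are stored descending
        ref_rho = reference.densities[::-1]
        ref_copies = reference.copies[::-1]
        baseline = float(np.interp(rho[heavy_mode], ref_rho, ref_copies))
    else:
        lo, hi = sorted((heavy_mode, light_mode))
        baseline = float(copies[lo : hi + 1].min())
    if baseline > 0:
        heavy_present = bool(heavy_mode_copies >= prominence * baseline)
    else:
        heavy_present = bool(heavy_mode_copies > 0)

    for pos, label in ((heavy_pos, "heavy"), (light_pos, "light")):
        srt = np.sort(pos)
        if np.any(np.diff(srt) != 1):
            warnings.warn(
                f"sample {sample.sample_id}: {label} peak fractions are "
                "non-contiguous",
                stacklevel=2,
            )

    idx = sample.indices
    return PeakAssignment(
        heavy_indices=frozenset(int(idx[p]) for p in heavy_pos),
        light_indices=frozenset(int(idx[p]) for p in light_pos),
        heavy_mode_density=float(rho[heavy_mode]),
        light_mode_density=float(rho[light_mode]),
        heavy_present=heavy_present,
    )


@dataclass
class ValidationIssue:
    code: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, code: str, message: str) -> None:
        self.issues.append(ValidationIssue(code, message))


def validate_dataset(samples: Sequence[GradientSample]) -> ValidationReport:
    """Report-only consistency checks over a set of gradient samples.

    Flags missing (treatment, isotope, replicate) design cells, duplicate
    cells, density-monotonicity violations, and OTU-id mismatches between
    samples.  Never mutates or rejects data.
    """
    report = ValidationReport()
    seen: dict[tuple[str, str, int], int] = {}
    for s in samples:
        key = (s.treatment, s.isotope, s.replicate)
        seen[key] = seen.get(key, 0) + 1
    treatments = sorted({k[0] for k in seen})
    isotopes = sorted({k[1] for k in seen})
    replicates = sorted({k[2] for k in seen})
    for t in treatments:
        for i in isotopes:
            for r in replicates:
                n = seen.get((t, i, r), 0)
                if n == 0:
                    report.add(
                        "missing_cell",
                        f"no sample for treatment={t}, isotope={i}, replicate={r}",
                    )
                elif n > 1:
                    report.add(
                        "duplicate_cell",
                        f"{n} samples for treatment={t}, isotope={i}, replicate={r}",
                    )

    otu_sets: dict[str, frozenset[str]] = {}
    for s in samples:
        rho = s.densities
        if np.any(np.diff(rho) > 0):
            report.add(
                "density_order",
                f"sample {s.sample_id}: densities not monotone non-increasing",
            )
        ids = frozenset(
            otu for f in s.fractions for otu in f.otu_counts
        )
        if ids:
            otu_sets[s.sample_id] = ids
    if otu_sets:
        universe = frozenset().union(*otu_sets.values())
        for sid, ids in otu_sets.items():
            missing = universe - ids
            if missing:
                report.add(
                    "otu_mismatch",
                    f"sample {sid}: {len(missing)} OTU ids absent that other "
                    "samples report",
                )
    return report


def sample_lookup(samples: Iterable[GradientSample]) -> dict[tuple[str, str, int], GradientSample]:
    """Index samples by (treatment, isotope, replicate)."""
    return {(s.treatment, s.isotope, s.replicate): s for s in samples}
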