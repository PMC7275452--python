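"""End-to-end steps shared by the CLI and the analysis scripts.

Each function takes in-memory objects, runs one pipeline stage, and returns
plain DataFrames ready for TSV export, so the CLI, the analysis drivers and
the tests all exercise exactly the same code path.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import gradient, labeling, network, priming, summaries
from .errors import VansipError
from .gradient import GradientSample, PeakAssignment
from .labeling import OtuTable
from .priming import FluxObservation
from .simulate import FluxSimSpec


def assign_peaks(
    samples: Sequence[GradientSample],
    heavy_window: tuple[float, float] = gradient.HEAVY_WINDOW,
    light_window: tuple[float, float] = gradient.LIGHT_WINDOW,
    prominence: float = 3.0,
) -> dict[str, PeakAssignment]:
    """Peak assignment for every sample, using the paired water gradient of
    the same treatment/replicate (fallback: the ¹²C gradient) as the
    heavy-presence reference for ¹³C samples."""
    lookup = gradient.sample_lookup(samples)
    peaks: dict[str, PeakAssignment] = {}
    for s in samples:
        ref = None
        if s.isotope == "C13":
            ref = lookup.get((s.treatment, "water", s.replicate)) or lookup.get(
                (s.treatment, "C12", s.replicate)
            )
        peaks[s.sample_id] = gradient.detect_peaks(
            s,
            heavy_window=heavy_window,
            light_window=light_window,
            reference=ref,
            prominence=prominence,
        )
    return peaks


def peaks_frame(peaks: Mapping[str, PeakAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": sid,
                "heavy_indices": ",".join(map(str, sorted(p.heavy_indices))),
                "light_indices": ",".join(map(str, sorted(p.light_indices))),
                "heavy_mode_density": p.heavy_mode_density,
                "light_mode_density": p.light_mode_density,
                "heavy_present": p.heavy_present,
            }
            for sid, p in peaks.items()
        ]
    ).set_index("sample_id")


def call_decomposers(
    table: OtuTable,
    peaks: Mapping[str, PeakAssignment],
    samples: Sequence[GradientSample],
    treatment: str,
    alpha: float = labeling.DEFAULT_ALPHA,
    msnh_ratio_min: float = labeling.DEFAULT_MSNH_RATIO_MIN,
    resample_depth: int | None = labeling.DEFAULT_RESAMPLING_DEPTH,
    seed: int = 0,
) -> pd.DataFrame:
    """Resample, filter, and attach absolute abundances for one treatment."""
    if resample_depth is not None:
        table, _shallow = labeling.resample_table(table, resample_depth, seed)
    results = labeling.apply_label_filter(
        table, peaks, samples, treatment, alpha=alpha, msnh_ratio_min=msnh_ratio_min
    )
    frame = labeling.results_frame(results)
    total = labeling.total_labeled_copies(table, peaks, samples, treatment)
    pos = frame["msnh"].where(frame["is_decomposer"], 0.0).clip(lower=0.0)
    share = pos / pos.sum() if pos.sum() > 0 else pos
    frame["absolute_abundance_copies_per_g"] = [
        labeling.absolute_abundance(s, total) for s in share
    ]
    return frame


def priming_report(
    vessels: Mapping[str, Sequence[FluxObservation]],
    vessel_meta: pd.DataFrame,
    label_atom_fraction: float = FluxSimSpec().label_atom_fraction,
    method: str = "atom_fraction",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-vessel priming budgets plus per-treatment mean ± SE and ANOVA.

    ``vessel_meta`` needs columns ``treatment`` and ``group`` where group is
    one of C13/C12/water; each C13 vessel is paired with the water vessel of
    the same treatment (replicate-matched by sort order).
    """
    rows = []
    for treatment in sorted(vessel_meta["treatment"].unique()):
        sub = vessel_meta[vessel_meta["treatment"] == treatment]
        c13_ids = sorted(sub[sub["group"] == "C13"].index)
        water_ids = sorted(sub[sub["group"] == "water"].index)
        if not c13_ids or not water_ids:
            continue
        for i, vid in enumerate(c13_ids):
            water_vid = water_ids[min(i, len(water_ids) - 1)]
            res = priming.estimate_priming(
                vessels[vid], vessels[water_vid], label_atom_fraction, method=method
            )
            rows.append(
                {
                    "vessel_id": vid,
                    "treatment": treatment,
                    "total_co2_umol": res.total_co2,
                    "substrate_derived_umol": res.substrate_derived,
                    "water_control_umol": res.water_control_respiration,
                    "primed_umol": res.primed,
                    "c13_cumulative_umol": res.c13_cumulative,
                }
            )
    per_vessel = pd.DataFrame(rows).set_index("vessel_id")

    summary_rows = []
    metrics = [
        "total_co2_umol",
        "substrate_derived_umol",
        "primed_umol",
        "c13_cumulative_umol",
    ]
    treatments = sorted(per_vessel["treatment"].unique())
    for metric in metrics:
        row: dict[str, object] = {"metric": metric}
        groups = []
        for tr in treatments:
            vals = per_vessel.loc[per_vessel["treatment"] == tr, metric].to_numpy()
            mean, se = summaries.mean_se(vals)
            row[f"{tr}_mean"] = mean
            row[f"{tr}_se"] = se
            if vals.size >= 2:
                groups.append(vals)
        if len(groups) >= 2:
            try:
                row["anova_p"] = summaries.one_way_anova(*groups)
            except VansipError:
                row["anova_p"] = float("nan")
        else:
            row["anova_p"] = float("nan")
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows).set_index("metric")
    return per_vessel, summary


def network_report(
    abundance: pd.DataFrame,
    min_present: int = 10,
    n_samples: int | None = None,
    grid: np.ndarray = network.DEFAULT_THRESHOLD_GRID,
    seed: int = 0,
) -> tuple[float, pd.DataFrame, pd.DataFrame]:
    """Prevalence filter, RMT threshold, network, null, and node roles.

    Returns (threshold, edge table, node table); the node table records the
    Maslov-Sneppen null's modularity alongside the empirical one.
    """
    filtered = network.prevalence_filter(
        abundance, min_present=min_present, n_samples=n_samples or abundance.shape[1]
    )
    corr = network.correlation_matrix(filtered)
    threshold = network.rmt_threshold_scan(corr, grid=grid)
    g = network.build_network(corr, threshold)
    roles = network.zi_pi(g)
    nodes = network.roles_frame(roles)
    edges = network.edge_frame(g)
    if g.number_of_edges() >= 2:
        null = network.maslov_sneppen(g, seed=seed)
        null_mod = nx_modularity(null)
        nodes.attrs["null_modularity"] = null_mod
        nodes.attrs["modularity"] = nx_modularity(g)
    return threshold, edges, nodes


def nx_modularity(g) -> float:
    import networkx as nx

    communities = nx.algorithms.community.greedy_modularity_communities(g)
    return float(nx.algorithms.community.modularity(g, communities))


def collapse_to_samples(table: OtuTable) -> pd.DataFrame:
    """OTU x sample matrix: counts summed over the fractions of each sample."""
    frame = table.to_frame()
    return frame.T.groupby(level="sample_id").sum().T
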