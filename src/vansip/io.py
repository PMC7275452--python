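"""Plain-text TSV readers and writers.

All outputs are TSV with a small ``#``-prefixed header (package version,
config hash, seed) so reruns under the same configuration are byte-identical
and traceable.  Fraction tables are accepted in both a wide dialect (one
column per OTU) and a long dialect (one row per OTU per fraction); long is
written.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError
from .gradient import Fraction, GradientSample
from .labeling import OtuTable
from .priming import FluxObservation

_NON_OTU_COLUMNS = {"sample_id", "fraction_index", "buoyant_density", "copies_16s"}


def config_hash(config: Mapping[str, Any]) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def header_lines(config: Mapping[str, Any] | None = None, seed: int | None = None) -> list[str]:
    lines = [f"# vansip {__version__}"]
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return lines


def write_tsv(
    frame: pd.DataFrame,
    path: str | Path,
    config: Mapping[str, Any] | None = None,
    seed: int | None = None,
    index: bool = True,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines(config, seed):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# Fraction tables and sample metadata


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = read_tsv(path)
    required = {"sample_id", "treatment", "isotope", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ConfigurationError(f"metadata lacks columns: {sorted(missing)}")
    return meta


def write_metadata(samples: Sequence[GradientSample], path: str | Path) -> None:
    meta = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "treatment": s.treatment,
                "isotope": s.isotope,
                "replicate": s.replicate,
            }
            for s in samples
        ]
    )
    write_tsv(meta, path, index=False)


def write_fraction_table(samples: Sequence[GradientSample], path: str | Path) -> None:
    """Long dialect: sample_id, fraction_index, buoyant_density, copies_16s,
    otu_id, count (zero counts omitted)."""
    rows = []
    for s in samples:
        for f in s.fractions:
            if f.otu_counts:
                for otu, c in sorted(f.otu_counts.items()):
                    if c > 0:
                        rows.append(
                            (s.sample_id, f.index, f.buoyant_density, f.copies, otu, c)
                        )
            # always keep one row per fraction so densities/copies survive
            rows.append((s.sample_id, f.index, f.buoyant_density, f.copies, "", 0))
    frame = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "fraction_index",
            "buoyant_density",
            "copies_16s",
            "otu_id",
            "count",
        ],
    )
    write_tsv(frame, path, index=False)


def read_fraction_table(
    path: str | Path, metadata: pd.DataFrame
) -> list[GradientSample]:
    """Read a fraction table in either the wide or the long dialect."""
    frame = read_tsv(path)
    cols = set(frame.columns)
    if not {"sample_id", "fraction_index", "buoyant_density"} <= cols:
        raise ConfigurationError(
            "fraction table needs sample_id, fraction_index, buoyant_density"
        )
    long_dialect = {"otu_id", "count"} <= cols
    meta_by_id = metadata.set_index("sample_id")

    samples: list[GradientSample] = []
    for sid, group in frame.groupby("sample_id", sort=False):
        if sid not in meta_by_id.index:
            raise ConfigurationError(f"sample {sid!r} absent from metadata")
        fractions = []
        for fi, sub in group.groupby("fraction_index", sort=True):
            density = float(sub["buoyant_density"].iloc[0])
            copies = float(sub["copies_16s"].iloc[0]) if "copies_16s" in cols else 0.0
            if long_dialect:
                counts = {
                    str(r.otu_id): int(r.count)
                    for r in sub.itertuples()
                    if isinstance(r.otu_id, str) and r.otu_id and r.count > 0
                }
            else:
                otu_cols = [c for c in frame.columns if c not in _NON_OTU_COLUMNS]
                row = sub.iloc[0]
                counts = {c: int(row[c]) for c in otu_cols if row[c] > 0}
            fractions.append(Fraction(int(fi), density, copies, counts))
        fractions.sort(key=lambda f: f.index)
        m = meta_by_id.loc[sid]
        samples.append(
            GradientSample(
                sample_id=str(sid),
                treatment=str(m["treatment"]),
                isotope=str(m["isotope"]),
                replicate=int(m["replicate"]),
                fractions=tuple(fractions),
            )
        )
    return samples


def read_biom_json(path: str | Path) -> OtuTable:
    """Minimal reader for BIOM-format JSON (dense or sparse) OTU tables.

    Column ids must follow the ``sample_id|fraction_index`` convention used
    by this package's exports.
    """
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    col_keys = []
    for c in doc["columns"]:
        sid, _, fi = str(c["id"]).rpartition("|")
        col_keys.append((sid, int(fi)))
    shape = (len(otu_ids), len(col_keys))
    counts = np.zeros(shape, dtype=int)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            counts[int(i), int(j)] = int(v)
    else:
        counts = np.asarray(doc["data"], dtype=int)
    return OtuTable(otu_ids, counts, col_keys)


# ---------------------------------------------------------------------------
# Flux series


def write_flux_table(
    vessels: Mapping[str, Sequence[FluxObservation]],
    metadata: Mapping[str, Mapping[str, Any]],
    path: str | Path,
) -> None:
    """``vessels`` maps vessel_id -> series; ``metadata`` maps vessel_id ->
    {treatment, group}."""
    rows = []
    for vid, series in vessels.items():
        m = metadata[vid]
        for o in series:
            rows.append(
                {
                    "vessel_id": vid,
                    "treatment": m["treatment"],
                    "group": m["group"],
                    "day": o.day,
                    "co2_ppm": o.co2_ppm,
                    "c13_ppm": o.c13_ppm if o.c13_ppm is not None else "",
                    "delta13c": o.delta13c if o.delta13c is not None else "",
                    "volume_ml": o.volume_ml,
                    "pressure_pa": o.pressure_pa,
                    "temperature_k": o.temperature_k,
                    "dilution_factor": o.dilution_factor,
                }
            )
    write_tsv(pd.DataFrame(rows), path, index=False)


def read_flux_table(path: str | Path) -> tuple[dict[str, list[FluxObservation]], pd.DataFrame]:
    """Returns vessel_id -> observation series plus a vessel metadata frame."""
    frame = read_tsv(path)
    required = {"vessel_id", "treatment", "group", "day", "co2_ppm"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigurationError(f"flux table lacks columns: {sorted(missing)}")
    vessels: dict[str, list[FluxObservation]] = {}
    meta_rows = {}
    for r in frame.itertuples():
        c13 = getattr(r, "c13_ppm", None)
        delta = getattr(r, "delta13c", None)
        c13 = None if c13 is None or pd.isna(c13) or c13 == "" else float(c13)
        delta = None if delta is None or pd.isna(delta) or delta == "" else float(delta)
        obs = FluxObservation(
            day=int(r.day),
            co2_ppm=float(r.co2_ppm),
            c13_ppm=c13,
            delta13c=delta,
            volume_ml=float(getattr(r, "volume_ml", 25.0)),
            pressure_pa=float(getattr(r, "pressure_pa", 101_000.0)),
            temperature_k=float(getattr(r, "temperature_k", 298.0)),
            dilution_factor=float(getattr(r, "dilution_factor", 1.0)),
        )
        vessels.setdefault(str(r.vessel_id), []).append(obs)
        meta_rows[str(r.vessel_id)] = {
            "vessel_id": str(r.vessel_id),
            "treatment": str(r.treatment),
            "group": str(r.group),
        }
    for series in vessels.values():
        series.sort(key=lambda o: o.day)
    meta = pd.DataFrame(meta_rows.values()).set_index("vessel_id")
    return vessels, meta
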