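"""Plain-text I/O: spike CSVs, metadata sidecars, labels, and reports.

Spike files carry two columns ``cell_id,time_s`` (one row per spike); the
metadata sidecar is keyed by ``cell_id`` with the per-cell covariate fields.
Every artifact written by the pipeline embeds the seed and a configuration
hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .trains import CellMeta, Drug, Estrous, Region, Sex, SpikeTrain, Treatment

_META_COLUMNS = (
    "cell_id",
    "region",
    "sex",
    "estrous",
    "treatment",
    "drug",
    "concentration_nM",
)


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_spike_csv(trains: Iterable[SpikeTrain], path: str | Path) -> None:
    rows = [
        {"cell_id": t.meta.cell_id, "time_s": float(x)} for t in trains for x in t.times
    ]
    pd.DataFrame(rows, columns=["cell_id", "time_s"]).to_csv(path, index=False)


def write_metadata_csv(trains: Iterable[SpikeTrain], path: str | Path) -> None:
    rows = []
    for t in trains:
        m = t.meta
        rows.append(
            {
                "cell_id": m.cell_id,
                "region": m.region.value,
                "sex": m.sex.value,
                "estrous": m.estrous.value,
                "treatment": m.treatment.value,
                "drug": m.drug.value,
                "concentration_nM": m.concentration_nM,
                "t0": t.t0,
                "duration": t.duration,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_spike_csv(
    spike_path: str | Path,
    metadata_path: str | Path | None = None,
    default_duration: float = 180.0,
    missing_meta: str = "fail",
) -> list[SpikeTrain]:
    """Read per-cell spike trains, sorted by time and joined with metadata.

    Duplicate timestamps within one cell are a validation error. Cells absent
    from the metadata sidecar either fail (default) or get default metadata
    when ``missing_meta='warn'``.
    """
    df = pd.read_csv(spike_path)
    if not {"cell_id", "time_s"} <= set(df.columns):
        raise ValueError("spike CSV must have columns cell_id,time_s")
    meta_df = None
    if metadata_path is not None:
        # keep_default_na: the estrous field legitimately holds the string "NA"
        meta_df = pd.read_csv(metadata_path, keep_default_na=False).set_index("cell_id")

    trains = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        times = np.sort(grp["time_s"].to_numpy(dtype=float))
        if np.any(np.diff(times) == 0):
            raise ValueError(f"duplicate timestamps for cell {cell_id!r}")
        t0, duration = 0.0, default_duration
        if meta_df is not None and cell_id in meta_df.index:
            row = meta_df.loc[cell_id]
            meta = CellMeta(
                cell_id=str(cell_id),
                region=Region(row.get("region", "unknown")),
                sex=Sex(row.get("sex", "unknown")),
                estrous=Estrous(row.get("estrous", "NA")),
                treatment=Treatment(row.get("treatment", "none")),
                drug=Drug(row.get("drug", "none")),
                concentration_nM=float(row.get("concentration_nM", 0.0)),
            )
            t0 = float(row.get("t0", 0.0))
            duration = float(row.get("duration", default_duration))
        elif meta_df is not None and missing_meta == "fail":
            raise ValueError(f"no metadata for cell {cell_id!r}")
        else:
            meta = CellMeta(cell_id=str(cell_id))
        if times.size:
            duration = max(duration, float(times[-1] - t0) + 1e-9)
        trains.append(SpikeTrain(times=times, t0=t0, duration=duration, meta=meta))
    return trains


def write_labels_csv(labelled: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    out = labelled.copy()
    if provenance:
        out["config_hash"] = config_hash(provenance)
        out["seed"] = provenance.get("seed")
    out.to_csv(path, index=False)


def write_report_json(payload: dict, path: str | Path, provenance: dict | None = None) -> None:
    if provenance:
        payload = {**payload, "config_hash": config_hash(provenance), "seed": provenance.get("seed")}

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return str(o)

    Path(path).write_text(json.dumps(payload, indent=2, default=_default))
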