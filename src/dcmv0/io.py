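"""Plain-text serialisation: events TSV, BOLD CSV + JSON sidecar, datasets.

Formats:

* stimulus — tab-separated events file with header ``onset\tduration\t
  amplitude`` (seconds; amplitude defaults to 1), one block per row;
* BOLD — CSV with one header row of region names and one row per scan
  (fractional signal change); scan timing lives in a JSON sidecar with keys
  ``tr``, ``n_scans``, ``region_names``;
* dataset — the clean/noisy CSV pair, the events TSV, a ground-truth JSON
  and a ``dataset.json`` manifest linking them with the generating spec.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .forward_model import BOLDTimeSeries, StimulusDesign
from .synthetic_data import SyntheticDataset

__all__ = [
    "write_events",
    "read_events",
    "design_from_events",
    "events_from_design",
    "write_bold",
    "read_bold",
    "load_roi_timeseries",
    "write_dataset",
]

_EVENT_COLUMNS = ["onset", "duration", "amplitude"]


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    ev = events.copy()
    if "amplitude" not in ev.columns:
        ev["amplitude"] = 1.0
    ev[_EVENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t")
    missing = [c for c in ("onset", "duration") if c not in ev.columns]
    if missing:
        raise ValueError(f"events file {path} lacks required column(s) {missing}")
    if "amplitude" not in ev.columns:
        ev["amplitude"] = 1.0
    return ev[_EVENT_COLUMNS]


def events_from_design(design: StimulusDesign, input_index: int = 0) -> pd.DataFrame:
    """Recover onset/duration/amplitude rows from a piecewise-constant input."""
    u = design.inputs[input_index]
    rows = []
    k = 0
    while k < u.size:
        if u[k] != 0:
            start = k
            amp = u[k]
            while k < u.size and u[k] == amp:
                k += 1
            rows.append(
                {
                    "onset": start * design.dt,
                    "duration": (k - start) * design.dt,
                    "amplitude": amp,
                }
            )
        else:
            k += 1
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def design_from_events(
    events: pd.DataFrame, tr: float, n_scans: int, dt: float = 0.125
) -> StimulusDesign:
    """Rasterise an events table onto the fine integration grid."""
    K = int(round(n_scans * tr / dt))
    u = np.zeros(K)
    t = np.arange(K) * dt
    for _, row in events.iterrows():
        on = (t >= row["onset"]) & (t < row["onset"] + row["duration"])
        u[on] = row["amplitude"]
    return StimulusDesign(tr=tr, n_scans=n_scans, dt=dt, inputs=u[None])


def write_bold(bold: BOLDTimeSeries, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame(bold.values, columns=list(bold.region_names)).to_csv(
        csv_path, index=False, float_format="%.10g"
    )
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "tr": bold.tr,
                "n_scans": bold.n_scans,
                "region_names": list(bold.region_names),
            },
            indent=1,
        )
    )


def read_bold(csv_path: str | Path) -> BOLDTimeSeries:
    csv_path = Path(csv_path)
    sidecar = csv_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    return load_roi_timeseries(csv_path, tr=meta["tr"])


def load_roi_timeseries(path: str | Path, tr: float = 2.0) -> BOLDTimeSeries:
    """Read a region-of-interest time-series CSV (header = region names)."""
    df = pd.read_csv(path)
    numeric_header = all(
        c.replace(".", "", 1).replace("-", "", 1).isdigit() for c in df.columns
    )
    if numeric_header:
        raise ValueError(f"{path}: missing header row of region names")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: non-finite values in the time series")
    return BOLDTimeSeries(tr=tr, values=values, region_names=tuple(df.columns))


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict:
    """Write the CSV + TSV + JSON triple and its manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bold(dataset.clean, outdir / "bold_clean.csv")
    write_bold(dataset.noisy, outdir / "bold_noisy.csv")
    write_events(events_from_design(dataset.design), outdir / "events.tsv")
    truth = {
        "A": dataset.connectivity.A.tolist(),
        "C": dataset.connectivity.C.tolist(),
        "region_names": list(dataset.connectivity.region_names),
        "hemodynamics": [dataclasses.asdict(h) for h in dataset.hemodynamics],
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    manifest = {
        "spec": dataclasses.asdict(dataset.spec),
        "seed": dataset.spec.seed,
        "files": {
            "clean": "bold_clean.csv",
            "noisy": "bold_noisy.csv",
            "events": "events.tsv",
            "ground_truth": "ground_truth.json",
        },
    }
    manifest = json.loads(json.dumps(manifest))  # normalise tuples to lists
    (outdir / "dataset.json").write_text(json.dumps(manifest, indent=1))
    return manifest
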