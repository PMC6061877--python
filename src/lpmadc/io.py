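"""Plain-text input/output: voxel tables, histograms, models, result tables.

Formats are deliberately simple so that synthetic and real data are
interchangeable: voxel tables are CSV with header ``tumor_id,time,adc``;
each histogram is a CSV ``bin_lo,bin_hi,count_t0,count_t72`` with a JSON
sidecar holding the binning scheme; a model directory holds a metadata JSON
plus one CSV of flattened PMFs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .histogram_builder import BinningScheme, PairedHistogram, TIME_LEVELS
from .lpm_core import ComponentSet, LPModel

VOXEL_COLUMNS = ("tumor_id", "time", "adc")


def read_voxel_table(path) -> pd.DataFrame:
    """Read and validate a per-voxel ADC table (tumor_id,time,adc)."""
    df = pd.read_csv(path)
    missing = [c for c in VOXEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"voxel table missing columns: {missing}")
    if df.empty:
        raise ValueError("voxel table is empty")
    bad_time = set(df["time"].unique()) - set(TIME_LEVELS)
    if bad_time:
        raise ValueError(f"unknown time labels {sorted(bad_time)}; "
                         f"expected {TIME_LEVELS}")
    if (df["adc"] < 0).any():
        raise ValueError("negative ADC values in voxel table")
    df["tumor_id"] = df["tumor_id"].astype(str)
    return df


def write_histogram(hist: PairedHistogram, csv_path) -> None:
    """Write one paired histogram as CSV plus a JSON binning sidecar."""
    csv_path = Path(csv_path)
    edges = hist.binning.adc_edges
    df = pd.DataFrame({
        "bin_lo": edges[:-1], "bin_hi": edges[1:],
        "count_t0": hist.counts[:, 0], "count_t72": hist.counts[:, 1],
    })
    df.to_csv(csv_path, index=False)
    sidecar = {"tumor_id": hist.tumor_id, "binning": hist.binning.to_dict()}
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_histogram(csv_path) -> PairedHistogram:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    binning = BinningScheme.from_dict(sidecar["binning"])
    counts = np.column_stack([df["count_t0"].to_numpy(),
                              df["count_t72"].to_numpy()])
    return PairedHistogram(counts, str(sidecar["tumor_id"]), binning)


def write_study(control_histos, treated_histos, out_dir, extra=None) -> None:
    """Write a study directory: per-tumor histogram CSVs plus manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for h in list(control_histos) + list(treated_histos):
        write_histogram(h, out / f"{h.tumor_id}.csv")
    manifest = {
        "control_ids": [h.tumor_id for h in control_histos],
        "treated_ids": [h.tumor_id for h in treated_histos],
    }
    if extra:
        manifest.update(extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_study(data_dir):
    """Read a study directory back into (control_histos, treated_histos)."""
    data = Path(data_dir)
    manifest = json.loads((data / "manifest.json").read_text())
    controls = [read_histogram(data / f"{t}.csv") for t in manifest["control_ids"]]
    treated = [read_histogram(data / f"{t}.csv") for t in manifest["treated_ids"]]
    return controls, treated, manifest


def save_model(model: LPModel, model_dir) -> None:
    """Serialize a trained model: metadata JSON + CSV of flattened PMFs."""
    out = Path(model_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "labels": list(model.components.labels),
        "binning": model.binning.to_dict(),
        "quantities": {t: q.tolist() for t, q in model.quantities.items()},
        "training_meta": _jsonable(model.training_meta),
    }
    (out / "model.json").write_text(json.dumps(meta, indent=2))
    flat = model.components.flat
    header = ",".join(f"cell_{i}" for i in range(flat.shape[1]))
    np.savetxt(out / "pmfs.csv", flat, delimiter=",", header=header,
               comments="", fmt="%.17e")


def load_model(model_dir) -> LPModel:
    out = Path(model_dir)
    meta = json.loads((out / "model.json").read_text())
    binning = BinningScheme.from_dict(meta["binning"])
    flat = np.loadtxt(out / "pmfs.csv", delimiter=",", skiprows=1, ndmin=2)
    flat /= flat.sum(axis=1, keepdims=True)  # remove text round-trip drift
    pmfs = flat.reshape(flat.shape[0], binning.n_bins, 2)
    components = ComponentSet(pmfs, tuple(meta["labels"]))
    quantities = {t: np.asarray(q, dtype=float)
                  for t, q in meta["quantities"].items()}
    return LPModel(components, binning, quantities, meta["training_meta"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
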