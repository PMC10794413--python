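"""Reading and writing trace datasets, ground truth and configuration.

Traces travel as CSV (one file per trace, columns ``frame, time_s`` plus
either ``E`` or the three ALEX channels ``I_DD, I_DA, I_AA``) or as a
single HDF5 container; ground truth as a JSON sidecar; configuration as
YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .kinetics import RateMatrix
from .simulate import GroundTruth

INTENSITY_COLUMNS = ("I_DD", "I_DA", "I_AA")


def write_trace_csv(trace: pd.DataFrame, path) -> None:
    trace.to_csv(path, index=False)


def read_trace_csv(path) -> pd.DataFrame:
    """Read a per-trace table; raises naming the file on malformed input."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with the file name
        raise ValueError(f"cannot read trace file {path}: {exc}") from exc
    has_e = "E" in df.columns
    has_i = all(c in df.columns for c in INTENSITY_COLUMNS)
    if not (has_e or has_i):
        raise ValueError(
            f"trace file {path} has neither an 'E' column nor the three "
            f"intensity columns {INTENSITY_COLUMNS}")
    return df


def write_dataset(traces, out_dir, ground_truth: GroundTruth | None = None,
                  config: dict | None = None) -> Path:
    """Write a trace set as trace_XXXX.csv files plus JSON/YAML sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, tr in enumerate(traces):
        write_trace_csv(tr, out / f"trace_{i:04d}.csv")
    if ground_truth is not None:
        (out / "ground_truth.json").write_text(
            json.dumps(ground_truth_to_dict(ground_truth), indent=1))
    if config is not None:
        (out / "config.yaml").write_text(yaml.safe_dump(config))
    return out


def read_dataset(in_dir) -> tuple[list[pd.DataFrame], GroundTruth | None]:
    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob("trace_*.csv"))
    if not paths:
        raise ValueError(f"no trace_*.csv files in {in_dir}")
    traces = [read_trace_csv(p) for p in paths]
    gt = None
    gt_path = in_dir / "ground_truth.json"
    if gt_path.exists():
        gt = ground_truth_from_dict(json.loads(gt_path.read_text()))
    return traces, gt


def ground_truth_to_dict(gt: GroundTruth) -> dict:
    return {
        "state_sequences": gt.state_sequences.tolist(),
        "rates": gt.rates.to_dict(),
        "delta_g_kBT": gt.delta_g,
        "e_means": list(gt.e_means),
        "e_sds": list(gt.e_sds),
        "seed": gt.seed,
        "populations": gt.populations.tolist(),
    }


def ground_truth_from_dict(d: dict) -> GroundTruth:
    return GroundTruth(
        state_sequences=np.asarray(d["state_sequences"], dtype=np.int64),
        rates=RateMatrix.from_dict(d["rates"]),
        delta_g=d.get("delta_g_kBT"),
        e_means=tuple(d["e_means"]),
        e_sds=tuple(d["e_sds"]),
        seed=d.get("seed", 0),
        populations=np.asarray(d["populations"]),
    )


def write_dataset_hdf5(traces, path, ground_truth: GroundTruth | None = None) -> None:
    """Single-file HDF5 alternative to the CSV directory layout."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("traces")
        for i, tr in enumerate(traces):
            g = grp.create_group(f"trace_{i:04d}")
            for col in tr.columns:
                g.create_dataset(col, data=tr[col].to_numpy())
        if ground_truth is not None:
            g = f.create_group("ground_truth")
            g.create_dataset("state_sequences", data=ground_truth.state_sequences)
            g.create_dataset("rates", data=ground_truth.rates.k)
            g.attrs["delta_g_kBT"] = (np.nan if ground_truth.delta_g is None
                                      else ground_truth.delta_g)
            g.attrs["seed"] = ground_truth.seed


def read_dataset_hdf5(path) -> list[pd.DataFrame]:
    traces = []
    with h5py.File(path, "r") as f:
        for name in sorted(f["traces"]):
            g = f["traces"][name]
            traces.append(pd.DataFrame({col: g[col][...] for col in g}))
    return traces


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "to_dict"):
        return o.to_dict()
    raise TypeError(f"cannot serialise {type(o)}")
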