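"""Persistence: HDF5 for epoched/TFR arrays, TSV for tables.

Epoch layout: ``/<subject>/<ear>/<hemisphere>`` groups with ``data``,
``time_axis`` and ``vertex_coords`` datasets; group, laterality and subject
id stored as attributes.  The simulator's hidden polarity labels travel in an
optional ``vertex_polarity_truth`` dataset so that ground-truth checks can be
run on files round-tripped through disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import EpochedSourceData
from .spectral import TFRParams, TFRResult

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_cohort",
    "load_cohort",
    "save_tfr",
    "load_tfr",
    "write_tsv",
    "write_json",
]

COHORT_COLUMNS = [
    "subject_id", "group", "age",
    "sequential_iq", "simultaneous_iq", "mpi", "srs", "scq", "aq",
]


def save_epochs(path, epochs_iter, mode: str = "w") -> None:
    """Write EpochedSourceData objects to one HDF5 container."""
    with h5py.File(path, mode) as f:
        for e in epochs_iter:
            g = f.require_group(f"{e.subject_id}/{e.stimulated_ear}/{e.hemisphere}")
            g.create_dataset("data", data=e.data, compression="gzip", compression_opts=1)
            g.create_dataset("time_axis", data=e.time_axis)
            g.create_dataset("vertex_coords", data=e.vertex_coords)
            if e.vertex_polarity_truth is not None:
                g.create_dataset("vertex_polarity_truth", data=e.vertex_polarity_truth)
            g.attrs["subject_id"] = e.subject_id
            g.attrs["group"] = e.group
            g.attrs["hemisphere"] = e.hemisphere
            g.attrs["stimulated_ear"] = e.stimulated_ear
            g.attrs["laterality"] = e.laterality


def load_epochs(path) -> list[EpochedSourceData]:
    out = []
    with h5py.File(path, "r") as f:
        for sid in f:
            for ear in f[sid]:
                for hemi in f[sid][ear]:
                    g = f[sid][ear][hemi]
                    out.append(
                        EpochedSourceData(
                            subject_id=g.attrs["subject_id"],
                            group=g.attrs["group"],
                            hemisphere=g.attrs["hemisphere"],
                            stimulated_ear=g.attrs["stimulated_ear"],
                            data=g["data"][()],
                            time_axis=g["time_axis"][()],
                            vertex_coords=g["vertex_coords"][()],
                            vertex_polarity_truth=g["vertex_polarity_truth"][()]
                            if "vertex_polarity_truth" in g
                            else None,
                        )
                    )
    return out


def save_cohort(path, cohort: pd.DataFrame) -> None:
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns] + [
        c for c in cohort.columns if c not in COHORT_COLUMNS
    ]
    cohort[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_tfr(path, results: dict, mode: str = "w") -> None:
    """Persist TFRResult maps keyed by '<subject>/<ear>/<hemisphere>'."""
    with h5py.File(path, mode) as f:
        for key, r in results.items():
            g = f.require_group(key)
            for name in ("itpc", "z_itpc", "power_change", "baseline_itpc",
                         "freqs", "times"):
                g.create_dataset(name, data=getattr(r, name))
            g.attrs["n_trials"] = r.n_trials
            g.attrs["params"] = json.dumps(
                {k: v for k, v in r.params.__dict__.items()}
            )


def load_tfr(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        def visit(name, obj):
            if isinstance(obj, h5py.Group) and "itpc" in obj:
                params = json.loads(obj.attrs["params"])
                for k in ("freqs", "band_for_average", "stim_interval",
                          "baseline_interval"):
                    params[k] = tuple(params[k])
                out[name] = TFRResult(
                    freqs=obj["freqs"][()],
                    times=obj["times"][()],
                    itpc=obj["itpc"][()],
                    z_itpc=obj["z_itpc"][()],
                    power_change=obj["power_change"][()],
                    baseline_itpc=obj["baseline_itpc"][()],
                    n_trials=int(obj.attrs["n_trials"]),
                    params=TFRParams(**params),
                )
        f.visititems(visit)
    return out


def write_tsv(path, table: pd.DataFrame, columns: list | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if columns is not None:
        table = table.reindex(columns=columns)
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="records"))
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    return obj


def write_json(path, payload: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonify(payload), fh, indent=1, sort_keys=True)
        fh.write("\n")
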