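"""HDF5 / TSV / JSON persistence for pipeline artifacts.

Epoch sets live in one HDF5 file under ``/subjects/<id>/<paradigm>`` with
datasets ``data``, ``labels``, ``time_ms``, ``vertices`` and (naturalistic)
``word_ids``; decoding results under ``/results/accuracy/<paradigm>/<id>``
and ``/results/tgm/<direction>/<id>``. Tables travel as TSV with a one-line
header; clusters and reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .decoding import AccuracyMap
from .simulate import EpochSet, SAMPLE_RATE_HZ
from .stats import ClusterResult
from .tgm import TGMMatrix

__all__ = [
    "save_epochs",
    "load_epochs",
    "list_subjects",
    "save_accuracy_map",
    "load_accuracy_map",
    "save_tgm",
    "load_tgm",
    "save_table",
    "load_table",
    "clusters_to_json",
    "clusters_from_json",
]


def save_epochs(path: str | Path, epochs: EpochSet, mesh_level: int | None = None) -> None:
    with h5py.File(path, "a") as f:
        grp = f.require_group(f"subjects/{epochs.subject_id}")
        key = epochs.paradigm if epochs.provenance != "residual" else f"{epochs.paradigm}_residual"
        if key in grp:
            del grp[key]
        g = grp.create_group(key)
        g.create_dataset("data", data=epochs.data)
        g.create_dataset("labels", data=epochs.labels)
        g.create_dataset("time_ms", data=epochs.time_ms)
        g.create_dataset("vertices", data=epochs.vertices)
        if epochs.word_ids is not None:
            g.create_dataset("word_ids", data=epochs.word_ids)
        g.attrs["provenance"] = epochs.provenance
        f.attrs["sample_rate_hz"] = SAMPLE_RATE_HZ
        if mesh_level is not None:
            f.attrs["mesh_level"] = mesh_level


def load_epochs(path: str | Path, subject_id: str, paradigm: str) -> EpochSet:
    with h5py.File(path, "r") as f:
        g = f[f"subjects/{subject_id}/{paradigm}"]
        word_ids = g["word_ids"][()] if "word_ids" in g else None
        return EpochSet(
            subject_id=subject_id,
            paradigm=paradigm.removesuffix("_residual"),
            data=g["data"][()],
            labels=g["labels"][()],
            time_ms=g["time_ms"][()],
            vertices=g["vertices"][()],
            word_ids=word_ids,
            provenance=g.attrs.get("provenance", "simulated"),
        )


def list_subjects(path: str | Path) -> list[str]:
    with h5py.File(path, "r") as f:
        return sorted(f["subjects"].keys())


def save_accuracy_map(path: str | Path, amap: AccuracyMap, paradigm: str) -> None:
    with h5py.File(path, "a") as f:
        key = f"results/accuracy/{paradigm}/{amap.subject_id}"
        if key in f:
            del f[key]
        g = f.create_group(key)
        g.create_dataset("values", data=amap.values)
        g.create_dataset("vertices", data=amap.vertices)
        g.create_dataset("time_ms", data=amap.time_ms)
        g.attrs["evaluation_mode"] = amap.evaluation_mode
        g.attrs["provenance"] = amap.provenance


def load_accuracy_map(path: str | Path, paradigm: str, subject_id: str) -> AccuracyMap:
    with h5py.File(path, "r") as f:
        g = f[f"results/accuracy/{paradigm}/{subject_id}"]
        return AccuracyMap(
            subject_id=subject_id,
            values=g["values"][()],
            vertices=g["vertices"][()],
            time_ms=g["time_ms"][()],
            evaluation_mode=g.attrs["evaluation_mode"],
            provenance=g.attrs.get("provenance", "epochs"),
        )


def save_tgm(path: str | Path, matrix: TGMMatrix, direction: str) -> None:
    with h5py.File(path, "a") as f:
        key = f"results/tgm/{direction}/{matrix.subject_id}"
        if key in f:
            del f[key]
        g = f.create_group(key)
        g.create_dataset("values", data=matrix.values)
        g.create_dataset("train_time_ms", data=matrix.train_time_ms)
        g.create_dataset("test_time_ms", data=matrix.test_time_ms)
        g.create_dataset("source_set", data=matrix.source_set)
        g.attrs["train_paradigm"] = matrix.train_paradigm
        g.attrs["test_paradigm"] = matrix.test_paradigm


def load_tgm(path: str | Path, direction: str, subject_id: str) -> TGMMatrix:
    with h5py.File(path, "r") as f:
        g = f[f"results/tgm/{direction}/{subject_id}"]
        return TGMMatrix(
            subject_id=subject_id,
            train_paradigm=g.attrs["train_paradigm"],
            test_paradigm=g.attrs["test_paradigm"],
            values=g["values"][()],
            train_time_ms=g["train_time_ms"][()],
            test_time_ms=g["test_time_ms"][()],
            source_set=g["source_set"][()],
        )


def save_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def clusters_to_json(clusters: list[ClusterResult]) -> str:
    return json.dumps([c.to_dict() for c in clusters], indent=2)


def clusters_from_json(text: str) -> list[ClusterResult]:
    out = []
    for obj in json.loads(text):
        out.append(
            ClusterResult(
                method=obj["method"],
                members=np.asarray(obj["members"], dtype=np.int64),
                p=obj["p"],
                peak_t=obj["peak_t"],
                mass=obj["mass"],
                n_cells=obj["extent"]["cells"],
                n_sources=obj["extent"]["sources"],
                n_times=obj["extent"]["timepoints"],
                vertices=np.asarray(obj["vertices"], dtype=np.int64),
                time_window_ms=tuple(obj["time_window_ms"])
                if obj["time_window_ms"] is not None
                else None,
            )
        )
    return out
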