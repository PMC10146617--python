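"""Plain-text file formats for pipeline artifacts.

Everything is delimited text plus JSON sidecars so that intermediates
are diffable and portable: epochs as a TSV matrix (trials stacked along
rows) with a sidecar naming channels, sampling rate, and pulse index;
ERPs likewise; ROI activations as tidy CSV (subject_id, roi, sample,
value) matching the pipeline's CSV interchange stage; head models and
ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .localize import RoiSeries
from .preprocess import EpochSet, ErpSignal
from .synthetic import ToyHeadModel

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_erp",
    "load_erp",
    "save_roi_series",
    "load_roi_series",
    "save_head_model",
    "load_head_model",
]


def _sidecar_path(prefix) -> Path:
    return Path(str(prefix) + ".json")


def _matrix_path(prefix) -> Path:
    return Path(str(prefix) + ".tsv")


def save_epochs(epochs: EpochSet, prefix) -> tuple[Path, Path]:
    """Write an epoch set as ``<prefix>.tsv`` + ``<prefix>.json``."""
    k, c, s = epochs.data.shape
    mat = epochs.data.reshape(k * c, s)
    np.savetxt(_matrix_path(prefix), mat, fmt="%.6g", delimiter="\t")
    sidecar = {
        "kind": "epochs",
        "n_trials": k,
        "channels": list(epochs.channel_labels),
        "fs_hz": epochs.fs_hz,
        "pulse_sample": epochs.pulse_sample,
        "subject_id": epochs.subject_id,
    }
    _sidecar_path(prefix).write_text(json.dumps(sidecar, indent=2))
    return _matrix_path(prefix), _sidecar_path(prefix)


def load_epochs(prefix) -> EpochSet:
    meta = json.loads(_sidecar_path(prefix).read_text())
    mat = np.loadtxt(_matrix_path(prefix), delimiter="\t", ndmin=2)
    k = meta["n_trials"]
    c = len(meta["channels"])
    return EpochSet(
        data=mat.reshape(k, c, -1),
        fs_hz=meta["fs_hz"],
        pulse_sample=meta["pulse_sample"],
        channel_labels=tuple(meta["channels"]),
        subject_id=meta.get("subject_id"),
    )


def save_erp(erp: ErpSignal, prefix) -> tuple[Path, Path]:
    np.savetxt(_matrix_path(prefix), erp.data, fmt="%.8g", delimiter="\t")
    sidecar = {
        "kind": "erp",
        "channels": list(erp.channel_labels),
        "fs_hz": erp.fs_hz,
        "pulse_sample": erp.pulse_sample,
        "n_trials_used": erp.n_trials_used,
        "subject_id": erp.subject_id,
    }
    _sidecar_path(prefix).write_text(json.dumps(sidecar, indent=2))
    return _matrix_path(prefix), _sidecar_path(prefix)


def load_erp(prefix) -> ErpSignal:
    meta = json.loads(_sidecar_path(prefix).read_text())
    mat = np.loadtxt(_matrix_path(prefix), delimiter="\t", ndmin=2)
    return ErpSignal(
        data=mat,
        fs_hz=meta["fs_hz"],
        pulse_sample=meta["pulse_sample"],
        n_trials_used=meta["n_trials_used"],
        channel_labels=tuple(meta["channels"]),
        subject_id=meta.get("subject_id"),
    )


def save_roi_series(rs: RoiSeries, path) -> Path:
    """Tidy CSV: subject_id, group, site, fs_hz, roi, sample, value."""
    n = rs.n_samples
    frames = []
    for r, roi in enumerate(rs.roi_names):
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": rs.subject_id,
                    "group": rs.group,
                    "site": rs.site,
                    "fs_hz": rs.fs_hz,
                    "roi": roi,
                    "sample": np.arange(n),
                    "value": rs.values[r],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return Path(path)


def load_roi_series(path) -> RoiSeries:
    df = pd.read_csv(path)
    rois = list(dict.fromkeys(df["roi"]))
    n = int(df["sample"].max()) + 1
    values = np.empty((len(rois), n))
    for r, roi in enumerate(rois):
        sub = df[df["roi"] == roi].sort_values("sample")
        values[r] = sub["value"].to_numpy()
    first = df.iloc[0]
    opt = lambda v: None if pd.isna(v) else v
    return RoiSeries(
        values=values,
        roi_names=tuple(rois),
        fs_hz=opt(first.get("fs_hz")),
        subject_id=opt(first.get("subject_id")),
        group=opt(first.get("group")),
        site=opt(first.get("site")),
    )


def save_head_model(head: ToyHeadModel, path) -> Path:
    Path(path).write_text(json.dumps(head.to_jsonable()))
    return Path(path)


def load_head_model(path) -> ToyHeadModel:
    return ToyHeadModel.from_jsonable(json.loads(Path(path).read_text()))
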