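"""Delimited-text readers and writers.

Everything is plain CSV or JSON: recordings (`time_s,emg1..emg6,mmg,label`),
feature matrices (24 named columns plus `label`), per-window sequences,
threshold sets and LDA models. Floats are written with 12 significant
digits, which round-trips all quantities used here.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detectors import ThresholdSet
from .errors import InvalidInputError
from .features import FeatureMatrix
from .lda import LDAModel
from .signals import SignalRecording

FLOAT_FMT = "%.12g"


def write_recording(recording: SignalRecording, path) -> None:
    n = recording.n_samples
    data = {"time_s": np.arange(n) / recording.sampling_rate}
    for ch in range(recording.n_channels):
        data[f"emg{ch + 1}"] = recording.emg[ch]
    data["mmg"] = recording.mmg
    data["label"] = recording.labels
    pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_recording(path) -> SignalRecording:
    df = pd.read_csv(path)
    emg_cols = [c for c in df.columns if c.startswith("emg")]
    if not emg_cols or "mmg" not in df.columns or "label" not in df.columns:
        raise InvalidInputError(f"{path}: not a recording file")
    if len(df) > 1:
        fs = 1.0 / float(df["time_s"].iloc[1] - df["time_s"].iloc[0])
    else:
        fs = 1000.0
    return SignalRecording(
        emg=df[emg_cols].to_numpy().T,
        mmg=df["mmg"].to_numpy(),
        labels=df["label"].to_numpy(dtype="<U2"),
        sampling_rate=float(round(fs, 6)),
    )


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    df = pd.DataFrame(fm.values, columns=list(fm.columns))
    df["label"] = fm.labels
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_feature_matrix(path) -> FeatureMatrix:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise InvalidInputError(f"{path}: not a feature-matrix file")
    cols = [c for c in df.columns if c != "label"]
    return FeatureMatrix(
        values=df[cols].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype="<U2"),
        columns=tuple(cols),
    )


def write_sequence(seq, path) -> None:
    pd.DataFrame(
        {"window": np.arange(len(seq)), "label": np.asarray(seq, dtype="<U2")}
    ).to_csv(path, index=False)


def read_sequence(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise InvalidInputError(f"{path}: not a sequence file")
    return df["label"].to_numpy(dtype="<U2")


def write_thresholds(thresholds: ThresholdSet, path) -> None:
    payload = {
        "kind": thresholds.kind,
        "onset": thresholds.onset,
        "offset": thresholds.offset,
        "offset_map": thresholds.offset_map,
        "provenance": thresholds.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_thresholds(path) -> ThresholdSet:
    payload = json.loads(Path(path).read_text())
    return ThresholdSet(
        kind=payload["kind"],
        onset=payload["onset"],
        offset=payload.get("offset"),
        offset_map=payload.get("offset_map"),
        provenance=payload.get("provenance", {}),
    )


def write_model(model: LDAModel, path) -> None:
    payload = {
        "class_order": list(model.class_order),
        "class_means": model.class_means.tolist(),
        "pooled_covariance": model.pooled_covariance.tolist(),
        "priors": model.priors.tolist(),
        "shrinkage": model.shrinkage,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_model(path) -> LDAModel:
    payload = json.loads(Path(path).read_text())
    return LDAModel(
        class_means=np.array(payload["class_means"], dtype=float),
        pooled_covariance=np.array(payload["pooled_covariance"], dtype=float),
        priors=np.array(payload["priors"], dtype=float),
        class_order=tuple(payload["class_order"]),
        shrinkage=float(payload.get("shrinkage", 1e-6)),
    )


def write_run_table(path, states, detector_values, oco, output) -> None:
    """Per-window `window,state,detector,oco,output` table of an online run."""
    pd.DataFrame(
        {
            "window": np.arange(len(output)),
            "state": states if states is not None else np.zeros(len(output), int),
            "detector": detector_values,
            "oco": np.asarray(oco, dtype="<U2"),
            "output": np.asarray(output, dtype="<U2"),
        }
    ).to_csv(path, index=False, float_format=FLOAT_FMT)
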