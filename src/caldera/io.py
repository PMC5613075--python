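"""File formats, model persistence and run manifests.

Recordings travel as plain CSV (`t,ax,ay,az[,gx,gy,gz]`, time in seconds
from recording start) with a JSON metadata sidecar carrying the sample
rate, body site and recording id.  Labels are a CSV table of half-open
[start_s, end_s) intervals with a possibly fractional 0-4 grade (rater
averaging), an activity tag and the sensor site.  Trained classifiers are
version-stamped JSON.  Every CLI command records a RunManifest sufficient
to reproduce its artefacts bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .signal import Recording, Site

MODEL_SCHEMA_VERSION = 1
TOOL_VERSION = "0.1.0"

ACTIVITIES = ("sitting", "walking", "other")


@dataclass
class LabelledSegment:
    """A labelled interval of a recording: [start_s, end_s) in seconds from
    recording start, with a rater-averaged dyskinesia grade in [0, 4]."""

    recording_id: str
    start_s: float
    end_s: float
    grade: float
    activity: str = "other"
    site: str = "left_arm"

    def validate(self, duration_s: Optional[float] = None) -> None:
        if not 0.0 <= self.grade <= 4.0:
            raise ValueError(f"grade outside [0,4]: {self.grade}")
        if self.end_s <= self.start_s or self.start_s < 0:
            raise ValueError(f"end <= start: [{self.start_s}, {self.end_s})")
        if duration_s is not None and self.end_s > duration_s + 1e-9:
            raise ValueError("segment extends past recording end")
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity: {self.activity}")


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".meta.json")


def write_recording(recording: Recording, path) -> None:
    """Write `t,ax,ay,az[,gx,gy,gz]` CSV plus `<stem>.meta.json` sidecar."""
    path = Path(path)
    # time gets fixed-point precision so the 1e-6 s reader tolerance holds
    # regardless of recording length; samples keep compact float formatting
    t_rel = recording.times - recording.t0
    data = {"t": [f"{v:.7f}" for v in t_rel]}
    for i, c in enumerate("xyz"):
        data[f"a{c}"] = recording.accel[:, i]
    if recording.gyro is not None:
        for i, c in enumerate("xyz"):
            data[f"g{c}"] = recording.gyro[:, i]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.8g")
    meta = {
        "recording_id": recording.recording_id,
        "sample_rate": recording.sample_rate,
        "t0": recording.t0,
        "site": recording.site.value,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_recording(path) -> Recording:
    """Read a recording CSV + sidecar; validates header, monotone time and
    consistency of the time step with the declared sample rate."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"missing metadata sidecar: {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path)
    required = ["t", "ax", "ay", "az"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {', '.join(missing)}")
    bad = df[required].isna().any(axis=1)
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # 1-based + header
        raise ValueError(f"malformed rows at lines {lines[:10]}")
    t = df["t"].to_numpy(dtype=float)
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("non-monotone time column")
        expected = 1.0 / float(meta["sample_rate"])
        if np.max(np.abs(dt - expected)) > 1e-6:
            raise ValueError(
                f"rate mismatch: declared {meta['sample_rate']} Hz but median "
                f"time step is {np.median(dt):.6g} s"
            )
    gyro = None
    if all(f"g{c}" in df.columns for c in "xyz"):
        gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float)
    return Recording(
        recording_id=meta["recording_id"],
        accel=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        gyro=gyro,
        sample_rate=float(meta["sample_rate"]),
        t0=float(meta.get("t0", 0.0)),
        site=Site(meta.get("site", "left_arm")),
    )


LABEL_COLUMNS = ["recording_id", "start_s", "end_s", "grade", "activity", "site"]


def write_labels(segments: Sequence[LabelledSegment], path) -> None:
    rows = [dataclasses.asdict(s) for s in segments]
    pd.DataFrame(rows, columns=LABEL_COLUMNS).to_csv(path, index=False)


def read_labels(path) -> List[LabelledSegment]:
    """Read and validate the labels table.

    Fractional grades (e.g. 2.5 from rater averaging) are accepted; grades
    outside [0, 4], inverted intervals, and overlapping segments for the
    same recording and site are rejected with their line numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {', '.join(missing)}")
    segments: List[LabelledSegment] = []
    for i, row in enumerate(df.itertuples(index=False)):
        seg = LabelledSegment(
            recording_id=str(row.recording_id),
            start_s=float(row.start_s),
            end_s=float(row.end_s),
            grade=float(row.grade),
            activity=str(row.activity),
            site=str(row.site),
        )
        try:
            seg.validate()
        except ValueError as exc:
            raise ValueError(f"line {i + 2}: {exc}") from exc
        segments.append(seg)
    by_key: Dict[tuple, List[tuple]] = {}
    for i, seg in enumerate(segments):
        by_key.setdefault((seg.recording_id, seg.site), []).append((i, seg))
    for key, entries in by_key.items():
        entries = sorted(entries, key=lambda e: e[1].start_s)
        for (i1, s1), (i2, s2) in zip(entries, entries[1:]):
            if s2.start_s < s1.end_s - 1e-9:
                raise ValueError(
                    f"overlapping segments for {key[0]}/{key[1]} at lines "
                    f"{i1 + 2} and {i2 + 2}"
                )
    return segments


# ---------------------------------------------------------------------------
# Model persistence


def save_model(model, path) -> None:
    """Serialise a ClassifierModel to version-stamped JSON."""
    from .cgp import genome_to_dict
    from .evolution import FeatureMode

    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "tool_version": TOOL_VERSION,
        "feature_mode": FeatureMode(model.feature_mode).value,
        "genome": genome_to_dict(model.genome),
        "thresholds": model.thresholds,
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path):
    """Load a ClassifierModel; older minor schemas load with defaulted new
    fields, anything unreadable raises a clean error with no partial model."""
    from .cgp import genome_from_dict
    from .evolution import ClassifierModel, FeatureMode

    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"incompatible model file: {exc}") from exc
    if not isinstance(payload, dict) or "genome" not in payload:
        raise ValueError("incompatible model file: missing genome")
    version = payload.get("schema_version", 0)
    if version > MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"incompatible model file: schema {version} newer than supported "
            f"{MODEL_SCHEMA_VERSION}"
        )
    try:
        genome = genome_from_dict(payload["genome"])
        mode = FeatureMode(payload.get("feature_mode", "time"))
    except ValueError as exc:
        raise ValueError(f"incompatible model file: {exc}") from exc
    return ClassifierModel(
        genome=genome,
        feature_mode=mode,
        thresholds=payload.get("thresholds"),
        provenance=payload.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# Run manifests and YAML config


@dataclass
class RunManifest:
    """Everything needed to reproduce a command's artefacts bit-exactly."""

    command: str
    config: Dict
    seed: Optional[int]
    input_digests: Dict[str, str] = field(default_factory=dict)
    artefacts: List[str] = field(default_factory=list)
    tool_version: str = TOOL_VERSION


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(manifest: RunManifest, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(manifest), indent=1))


def load_config_yaml(path) -> Dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def save_config_yaml(config: Dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
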