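"""Disk formats: delimited feature tables with JSON sidecars, mask and
report JSON, YAML configs, PNG images.  Every structured output embeds a
config hash so artifacts are traceable to the settings that produced them."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .selection import FeatureMask, SelectionResult
from .texture import FeatureMatrix

__all__ = [
    "config_hash",
    "save_image",
    "load_image",
    "write_feature_table",
    "read_feature_table",
    "write_mask",
    "read_mask",
    "write_report",
    "load_config",
    "dump_config",
]

LABEL_COLUMN = "label"


def config_hash(obj) -> str:
    """Short sha256 of the canonical JSON form of a config mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def save_image(img: np.ndarray, path: str | Path) -> None:
    arr = np.clip(np.asarray(img, dtype=float), 0, 1)
    Image.fromarray((arr * 255).round().astype(np.uint8)).save(path)


def load_image(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=float) / 255.0
    return arr


def write_feature_table(fm: FeatureMatrix, path: str | Path,
                        sidecar: dict | None = None) -> None:
    """CSV with a header of feature names (plus a label column when labels
    exist) and a JSON sidecar recording block spans and provenance."""
    path = Path(path)
    df = pd.DataFrame(fm.values, columns=fm.feature_names)
    if fm.labels is not None:
        df[LABEL_COLUMN] = fm.labels
    df.to_csv(path, index=False)
    meta = {
        "block_spans": {k: list(v) for k, v in fm.block_spans.items()},
        "n_samples": fm.n_samples,
        "n_features": fm.n_features,
        "has_labels": fm.labels is not None,
    }
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2, sort_keys=True))


def read_feature_table(path: str | Path, require_labels: bool = False) -> FeatureMatrix:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"cannot parse feature table {path}: {exc}") from exc
    labels = None
    if LABEL_COLUMN in df.columns:
        labels = df.pop(LABEL_COLUMN).to_numpy()
    elif require_labels:
        raise ValueError(f"feature table {path} lacks the required "
                         f"{LABEL_COLUMN!r} column")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        spans = {k: tuple(v) for k, v in meta.get("block_spans", {}).items()}
    else:
        spans = {"features": (0, df.shape[1])}
    return FeatureMatrix(values=df.to_numpy(dtype=float),
                         feature_names=list(df.columns),
                         block_spans=spans, labels=labels)


def write_mask(result: SelectionResult, feature_names: list[str] | None,
               path: str | Path) -> None:
    bits = result.mask.bits
    payload = {
        "method": result.method,
        "bits": bits.tolist(),
        "selected_count": result.mask.selected_count,
        "best_fitness": result.best_fitness,
        "history": result.history,
        "config": result.config.to_dict(),
        "config_hash": config_hash(result.config.to_dict()),
    }
    if feature_names is not None:
        payload["selected_features"] = [feature_names[i]
                                        for i in result.mask.selected_indices()]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_mask(path: str | Path) -> FeatureMask:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed mask file {path}: {exc}") from exc
    if "bits" not in payload:
        raise ValueError(f"mask file {path} lacks a 'bits' field")
    return FeatureMask(bits=np.asarray(payload["bits"]))


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return data


def dump_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
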