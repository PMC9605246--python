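"""File formats: E4-dialect channel CSVs, label CSVs, manifests, feature
matrices, model JSON, reports, and the YAML experiment configuration.

The channel-CSV dialect follows the Empatica E4 export: line 1 is the session
start as a UNIX timestamp, line 2 the sampling rate in Hz, and each following
line one sample (the three accelerometer axes share one file with three
comma-separated columns).  Samples are written at %.17g so that a write/read
round trip is bit-exact for float64.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import Channel, SAMPLING_RATES, SensorRecording
from .features import FEATURE_COLUMNS
from .strategies import PredictionSet, StrategyResult

#: Fixed synthetic session-start timestamp, so repeated runs are byte-identical.
SESSION_START_TIMESTAMP = 1600000000.0


class ChannelCSVError(ValueError):
    """Base class for channel-file parse errors."""


class MalformedHeaderError(ChannelCSVError):
    """Timestamp or rate line is missing or non-numeric."""


class NonNumericSampleError(ChannelCSVError):
    """A sample line could not be parsed as numbers."""


class EmptyBodyError(ChannelCSVError):
    """The file has a header but no samples."""


class ConfigError(ValueError):
    """Experiment configuration is malformed."""


def write_channel_csv(
    path: str | Path,
    start_timestamp: float,
    sampling_rate: float,
    samples: np.ndarray,
) -> None:
    samples = np.asarray(samples, float)
    body = samples.reshape(len(samples), -1)
    with open(path, "w") as fh:
        fh.write(f"{start_timestamp:.6f}\n{sampling_rate:.6f}\n")
        np.savetxt(fh, body, fmt="%.17g", delimiter=",")


def read_channel_csv(path: str | Path) -> tuple[float, float, np.ndarray]:
    """Parse (start timestamp, sampling rate, samples) from an E4-dialect CSV."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise MalformedHeaderError(f"{path}: expected timestamp and rate header lines")
    try:
        timestamp = float(lines[0])
        rate = float(lines[1])
    except ValueError as err:
        raise MalformedHeaderError(f"{path}: non-numeric header: {err}") from err
    body = [ln for ln in lines[2:] if ln.strip()]
    if not body:
        raise EmptyBodyError(f"{path}: no sample lines after the header")
    try:
        rows = [[float(v) for v in ln.split(",")] for ln in body]
    except ValueError as err:
        raise NonNumericSampleError(f"{path}: non-numeric sample: {err}") from err
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise NonNumericSampleError(f"{path}: ragged sample rows")
    arr = np.asarray(rows, float)
    return timestamp, rate, arr[:, 0] if width == 1 else arr


def write_labels_csv(path: str | Path, labels: np.ndarray) -> None:
    pd.DataFrame({"second_index": np.arange(len(labels)), "condition": labels}).to_csv(
        path, index=False
    )


def read_labels_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    if list(df.columns) != ["second_index", "condition"]:
        raise ChannelCSVError(f"{path}: expected columns second_index,condition")
    return df.sort_values("second_index")["condition"].to_numpy(dtype="<U9")


def write_cohort(cohort: list[SensorRecording], directory: str | Path) -> Path:
    """One CSV per channel per participant plus a JSON manifest; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"cohort_id": "synthetic", "participants": []}
    for rec in cohort:
        pdir = directory / f"participant_{rec.participant_id:02d}"
        pdir.mkdir(exist_ok=True)
        entry = {"participant_id": rec.participant_id, "channels": {}, "labels": None}
        acc = np.column_stack(
            [rec.channels[a].samples for a in ("ACCx", "ACCy", "ACCz")]
        )
        files = {"ST": rec.channels["ST"].samples, "ACC": acc, "EDA": rec.channels["EDA"].samples,
                 "BVP": rec.channels["BVP"].samples}
        rates = {"ST": SAMPLING_RATES["ST"], "ACC": SAMPLING_RATES["ACCx"],
                 "EDA": SAMPLING_RATES["EDA"], "BVP": SAMPLING_RATES["BVP"]}
        for name, data in files.items():
            fpath = pdir / f"{name}.csv"
            write_channel_csv(fpath, SESSION_START_TIMESTAMP, rates[name], data)
            entry["channels"][name] = {
                "path": str(fpath.relative_to(directory)),
                "sampling_rate": rates[name],
            }
        lpath = pdir / "labels.csv"
        write_labels_csv(lpath, rec.labels)
        entry["labels"] = str(lpath.relative_to(directory))
        manifest["participants"].append(entry)
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def load_cohort(manifest_path: str | Path) -> list[SensorRecording]:
    """Read a cohort back from its manifest (ground truth is not persisted)."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    cohort = []
    for entry in manifest["participants"]:
        channels: dict[str, Channel] = {}
        for name, info in entry["channels"].items():
            fpath = root / info["path"]
            if not fpath.exists():
                raise FileNotFoundError(f"manifest refers to missing file {fpath}")
            _, rate, samples = read_channel_csv(fpath)
            if rate <= 0:
                raise ChannelCSVError(f"{fpath}: sampling rate must be positive")
            if name == "ACC":
                for i, axis in enumerate(("ACCx", "ACCy", "ACCz")):
                    channels[axis] = Channel(rate, samples[:, i].copy())
            else:
                channels[name] = Channel(rate, samples)
        labels = read_labels_csv(root / entry["labels"])
        cohort.append(
            SensorRecording(
                participant_id=int(entry["participant_id"]), channels=channels, labels=labels
            )
        )
    return cohort


def write_feature_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index_label="window_id", float_format="%.17g")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="window_id", float_precision="round_trip")
    expected = [*FEATURE_COLUMNS, "label", "participant"]
    if list(df.columns) != expected:
        raise ChannelCSVError(f"{path}: unexpected feature-matrix columns")
    return df


def write_predictions(result: StrategyResult, path: str | Path) -> None:
    frames = []
    for pid, pred in sorted(result.predictions.items()):
        frames.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    "window_id": pred.window_ids,
                    "true": pred.y_true,
                    "predicted": pred.y_pred,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False)


def read_predictions(path: str | Path, strategy: str) -> StrategyResult:
    df = pd.read_csv(path)
    preds = {}
    for pid, g in df.groupby("participant", sort=True):
        preds[int(pid)] = PredictionSet(
            y_true=g["true"].to_numpy(np.int64),
            y_pred=g["predicted"].to_numpy(np.int64),
            window_ids=g["window_id"].to_numpy(np.int64),
        )
    return StrategyResult(strategy, {}, preds)


# --------------------------------------------------------------------------
# Experiment configuration
# --------------------------------------------------------------------------

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "output_dir", "cohort", "split", "strategies", "train", "federated"},
    "cohort": {
        "n_participants",
        "session_seconds",
        "atypical_fraction",
        "heterogeneity",
        "manifest",
        "noise_scales",
    },
    "heterogeneity": {"st_baseline_sd", "eda_baseline_sd", "heart_rate_sd", "stress_scale_sd"},
    "split": {"mode", "train_fraction", "seed"},
    "train": {
        "l2_strength",
        "max_iterations",
        "tolerance",
        "learning_rate",
        "local_epochs",
        "batch_size",
        "seed",
    },
    "federated": {"rounds", "local_epochs", "client_fraction", "seed"},
}


def _check_keys(section: str, mapping: Mapping) -> None:
    unknown = set(mapping) - _SCHEMA[section]
    if unknown:
        where = section or "top level"
        raise ConfigError(f"unknown config key(s) {sorted(unknown)} in {where}")


@dataclass
class ExperimentConfig:
    seed: int
    output_dir: str
    cohort: dict = field(default_factory=dict)
    split: dict = field(default_factory=dict)
    strategies: list[str] = field(default_factory=lambda: ["individual", "centralized", "federated"])
    train: dict = field(default_factory=dict)
    federated: dict = field(default_factory=dict)


def load_experiment_config(path: str | Path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: config must be a mapping")
    _check_keys("", raw)
    if "seed" not in raw:
        raise ConfigError("config must set a seed")
    if "output_dir" not in raw:
        raise ConfigError("config must set output_dir")
    for section in ("cohort", "split", "train", "federated"):
        if section in raw:
            if not isinstance(raw[section], Mapping):
                raise ConfigError(f"{section} must be a mapping")
            _check_keys(section, raw[section])
    if "heterogeneity" in raw.get("cohort", {}):
        _check_keys("heterogeneity", raw["cohort"]["heterogeneity"])
    strategies = list(raw.get("strategies", ["individual", "centralized", "federated"]))
    unknown = set(strategies) - {"individual", "centralized", "federated"}
    if unknown:
        raise ConfigError(f"unknown strategies {sorted(unknown)}")
    return ExperimentConfig(
        seed=int(raw["seed"]),
        output_dir=str(raw["output_dir"]),
        cohort=dict(raw.get("cohort", {})),
        split=dict(raw.get("split", {})),
        strategies=strategies,
        train=dict(raw.get("train", {})),
        federated=dict(raw.get("federated", {})),
    )
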