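"""EXPERIMENTAL adapter for real wrist-device exports (untested).

Maps an Empatica-E4 export directory (TEMP.csv, EDA.csv, ACC.csv, BVP.csv plus
a labels.csv in this package's two-column dialect) onto a
:class:`~fedstress.cohort.SensorRecording`.  This adapter has never been run
against real device exports and is excluded from the test surface; the rest
of the package operates on synthetic cohorts.
"""

from __future__ import annotations

from pathlib import Path

from .cohort import Channel, SensorRecording
from .io import read_channel_csv, read_labels_csv

_FILE_MAP = {"TEMP.csv": "ST", "EDA.csv": "EDA", "BVP.csv": "BVP"}


def load_e4_session_dir(directory: str | Path, participant_id: int = 1) -> SensorRecording:
    """Read one session's channel CSVs from a device-export directory."""
    directory = Path(directory)
    channels: dict[str, Channel] = {}
    for fname, channel in _FILE_MAP.items():
        _, rate, samples = read_channel_csv(directory / fname)
        channels[channel] = Channel(rate, samples)
    _, rate, acc = read_channel_csv(directory / "ACC.csv")
    for i, axis in enumerate(("ACCx", "ACCy", "ACCz")):
        channels[axis] = Channel(rate, acc[:, i].copy())
    labels = read_labels_csv(directory / "labels.csv")
    return SensorRecording(participant_id=participant_id, channels=channels, labels=labels)
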