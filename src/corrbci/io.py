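"""Recording / event containers and their plain-text serialization.

A :class:`Recording` is stored as one CSV per data plane (channels as rows,
header row of sample indices) next to a JSON sidecar holding the sampling
rate, modality, channel names, hemisphere map and (for optical-density data)
the two wavelengths. Events follow the BIDS-events convention: a TSV with
``onset``, ``duration`` and ``trial_type`` columns, one row per trial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MODALITIES = ("eeg", "fnirs_od", "fnirs_hbo", "fnirs_hbr")


@dataclass
class Recording:
    """Multichannel time series with montage metadata.

    ``data`` is channels x samples for scalar modalities and
    wavelengths x channels x samples for ``fnirs_od`` (two planes).
    """

    data: np.ndarray
    fs: float
    modality: str
    channel_names: list[str]
    hemisphere_map: dict[str, str]
    wavelengths: list[float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.modality not in MODALITIES:
            raise ValueError(
                f"unknown modality {self.modality!r}; valid: {MODALITIES}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n_ch = self.data.shape[-2]
        if len(self.channel_names) != n_ch:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {n_ch} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        missing = [c for c in self.channel_names if c not in self.hemisphere_map]
        if missing:
            raise ValueError(f"channels missing from hemisphere map: {missing}")
        if self.modality == "fnirs_od":
            if self.data.ndim != 3 or self.data.shape[0] != 2:
                raise ValueError("fnirs_od data must have exactly 2 wavelength planes")
            if self.wavelengths is None or len(self.wavelengths) != 2:
                raise ValueError("fnirs_od requires 2 wavelengths")
        elif self.data.ndim != 2:
            raise ValueError(f"{self.modality} data must be 2-D (channels x samples)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[-2]

    @property
    def n_samples(self) -> int:
        return self.data.shape[-1]

    def hemisphere_channels(self, hemisphere: str) -> list[str]:
        return [c for c in self.channel_names if self.hemisphere_map[c] == hemisphere]

    def channel_index(self, names: list[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.channel_names)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"channel {exc.args[0]!r} not in recording") from None

    def copy_with(self, data: np.ndarray, fs: float | None = None,
                  modality: str | None = None) -> "Recording":
        return Recording(
            data=data,
            fs=self.fs if fs is None else fs,
            modality=self.modality if modality is None else modality,
            channel_names=list(self.channel_names),
            hemisphere_map=dict(self.hemisphere_map),
            wavelengths=None if (modality or self.modality) != "fnirs_od"
            else list(self.wavelengths),
        )


@dataclass
class EventTable:
    """Per-trial events: onset (s), duration (s), trial_type.

    Each row covers a whole trial block; the task window is the trailing
    ``task_duration_s`` seconds and the rest window the remainder.
    """

    frame: pd.DataFrame
    task_duration_s: float = 6.0
    classes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        required = {"onset", "duration", "trial_type"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"event table needs columns {sorted(required)}")
        f = self.frame.sort_values("onset", kind="stable").reset_index(drop=True)
        if (f["onset"] < 0).any():
            raise ValueError("negative onset")
        if (f["duration"] <= 0).any():
            raise ValueError("non-positive trial duration")
        ends = (f["onset"] + f["duration"]).to_numpy()
        bad = np.nonzero(f["onset"].to_numpy()[1:] < ends[:-1] - 1e-9)[0] + 1
        if len(bad):
            raise ValueError(f"overlapping trials at rows {list(bad)}")
        if self.classes is not None:
            bad = sorted(set(f["trial_type"]) - set(self.classes))
            if bad:
                raise ValueError(f"unknown trial labels {bad}")
        if self.task_duration_s <= 0:
            raise ValueError("task duration must be positive")
        self.frame = f

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> list[str]:
        return list(self.frame["trial_type"])


# ---------------------------------------------------------------------------
# serialization

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def write_recording(rec: Recording, out_dir: str | Path, stem: str) -> list[Path]:
    """Write ``<stem>.csv`` (or one CSV per wavelength plane) + JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    planes = rec.data[None, ...] if rec.data.ndim == 2 else rec.data
    for p, plane in enumerate(planes):
        if rec.modality == "fnirs_od":
            path = out_dir / f"{stem}.wl{int(round(rec.wavelengths[p]))}.csv"
        else:
            path = out_dir / f"{stem}.csv"
        df = pd.DataFrame(plane, index=rec.channel_names,
                          columns=np.arange(plane.shape[1]))
        df.to_csv(path, float_format=_FLOAT_FMT, index_label="channel")
        written.append(path)
    sidecar = out_dir / f"{stem}.json"
    sidecar.write_text(json.dumps({
        "fs": rec.fs,
        "modality": rec.modality,
        "channel_names": rec.channel_names,
        "hemisphere_map": rec.hemisphere_map,
        "wavelengths": rec.wavelengths,
    }, indent=2))
    written.append(sidecar)
    return written


def read_recording(in_dir: str | Path, stem: str) -> Recording:
    in_dir = Path(in_dir)
    sidecar = in_dir / f"{stem}.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    modality = meta.get("modality")
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; valid: {MODALITIES}")
    if modality == "fnirs_od":
        paths = [in_dir / f"{stem}.wl{int(round(w))}.csv" for w in meta["wavelengths"]]
        planes = [pd.read_csv(p, index_col="channel", float_precision="round_trip")
                  for p in paths]
        data = np.stack([p.values for p in planes])
        names = list(planes[0].index)
    else:
        df = pd.read_csv(in_dir / f"{stem}.csv", index_col="channel",
                         float_precision="round_trip")
        data = df.values
        names = list(df.index)
    if names != meta["channel_names"]:
        raise ValueError("sidecar channel names do not match CSV rows")
    return Recording(
        data=data, fs=meta["fs"], modality=modality,
        channel_names=names, hemisphere_map=meta["hemisphere_map"],
        wavelengths=meta.get("wavelengths"),
    )


def write_events(events: EventTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events.frame[["onset", "duration", "trial_type"]].to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_events(path: str | Path, task_duration_s: float = 6.0,
                classes: tuple[str, ...] | None = None) -> EventTable:
    frame = pd.read_csv(path, sep="\t")
    return EventTable(frame=frame, task_duration_s=task_duration_s, classes=classes)
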