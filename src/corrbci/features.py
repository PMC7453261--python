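"""Trial epoching, spatial averaging and the four statistical features.

Each trial's task window is spatially averaged over the selected channels of
each hemisphere, and four features are computed per averaged series with
population (1/N) moments:

    M  = mean,
    SK = E[((X - mu)/sigma)^3]   (third standardized moment),
    KR = E[((X - mu)/sigma)^4]   (fourth standardized moment, non-excess:
                                  Gaussian data -> 3),
    P  = max_i X_i               (signed maximum).

Feature columns are min-max normalized to [0, 1] across trials. Per modality
the feature sets are all C(4,2) = 6 unordered feature pairs; the hybrid mode
forms the 6 x 6 = 36 cartesian pairings of one EEG pair with one fNIRS pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EventTable, Recording

__all__ = [
    "Epoch", "epoch_trials", "spatial_average", "signal_mean",
    "signal_skewness", "signal_kurtosis", "signal_peak", "minmax_normalize",
    "extract_features", "build_feature_sets", "FEATURE_NAMES", "FEATURE_PAIRS",
]

FEATURE_NAMES = ("M", "P", "SK", "KR")
FEATURE_PAIRS = tuple(itertools.combinations(FEATURE_NAMES, 2))
# ids: MP, MSK, MKR, PSK, PKR, SKKR
PAIR_IDS = tuple("".join(p) for p in FEATURE_PAIRS)


@dataclass
class Epoch:
    """One trial's slice: channels x samples over the requested segment."""

    index: int
    label: str
    data: np.ndarray


def epoch_trials(x: np.ndarray, fs: float, events: EventTable,
                 segment: str = "task") -> list[Epoch]:
    """Slice one epoch per event row.

    ``segment="task"`` takes the trailing ``task_duration_s`` of each trial
    (labelled with the trial class); ``segment="rest"`` takes the leading
    remainder (always labelled ``rest``).
    """
    if segment not in ("task", "rest"):
        raise ValueError("segment must be 'task' or 'rest'")
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = x.shape[1]
    out: list[Epoch] = []
    for i, row in events.frame.iterrows():
        task_s = events.task_duration_s
        rest_s = row["duration"] - task_s
        if rest_s < -1e-9:
            raise ValueError(f"trial {i}: duration shorter than the task window")
        if segment == "task":
            start_s, dur_s, label = row["onset"] + rest_s, task_s, row["trial_type"]
        else:
            if rest_s <= 0:
                raise ValueError(f"trial {i} has no rest segment")
            start_s, dur_s, label = row["onset"], rest_s, "rest"
        start = int(round(start_s * fs))
        length = int(round(dur_s * fs))
        if length < 1:
            raise ValueError(f"trial {i}: empty window at fs={fs}")
        if start < 0 or start + length > n:
            raise ValueError(
                f"trial {i}: window [{start}, {start + length}) outside "
                f"signal of {n} samples")
        out.append(Epoch(index=int(i), label=str(label),
                         data=x[:, start:start + length]))
    return out


def spatial_average(data: np.ndarray, rows: np.ndarray | list[int]) -> np.ndarray:
    """Samplewise mean over the given channel rows."""
    rows = np.asarray(rows, dtype=int)
    if rows.size == 0:
        raise ValueError("empty channel selection")
    return np.asarray(data, dtype=float)[rows].mean(axis=0)


def signal_mean(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty series")
    return float(x.mean())


def _std_moments(x: np.ndarray, min_n: int) -> tuple[np.ndarray, float]:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} samples")
    d = x - x.mean()
    sigma = np.sqrt(np.mean(d * d))
    if sigma == 0:
        raise ValueError("zero variance: standardized moment undefined")
    return d, sigma


def signal_skewness(x: np.ndarray) -> float:
    """Third standardized moment (population)."""
    d, sigma = _std_moments(x, 3)
    return float(np.mean((d / sigma) ** 3))


def signal_kurtosis(x: np.ndarray) -> float:
    """Fourth standardized moment, non-excess (Gaussian -> 3)."""
    d, sigma = _std_moments(x, 4)
    return float(np.mean((d / sigma) ** 4))


def signal_peak(x: np.ndarray) -> float:
    """Signed maximum: the value X_p with X_i <= X_p for all i."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty series")
    return float(x.max())


_FEATURE_FUNCS = {
    "M": signal_mean, "SK": signal_skewness,
    "KR": signal_kurtosis, "P": signal_peak,
}


def minmax_normalize(column: np.ndarray, name: str = "feature") -> np.ndarray:
    """Rescale to [0, 1]: (x - min) / (max - min)."""
    column = np.asarray(column, dtype=float)
    lo, hi = column.min(), column.max()
    if hi == lo:
        raise ValueError(f"column {name!r} is constant; min-max undefined")
    return (column - lo) / (hi - lo)


def extract_features(rec: Recording, events: EventTable, selected: list[str],
                     tag: str, scheme: str = "hemisphere") -> pd.DataFrame:
    """Per-trial feature table from the selected channels.

    ``scheme="hemisphere"`` averages the selected channels of each hemisphere
    separately (columns ``{tag}.{left|right}.{feature}``); ``"pooled"``
    averages all selected channels into one series. A ``label`` column holds
    the trial class. Features are raw here; normalization happens at
    feature-set build time.
    """
    if not selected:
        raise ValueError("empty channel selection")
    if scheme not in ("hemisphere", "pooled"):
        raise ValueError("scheme must be 'hemisphere' or 'pooled'")
    epochs = epoch_trials(rec.data, rec.fs, events, segment="task")
    if scheme == "hemisphere":
        groups = {}
        for hemi in ("left", "right"):
            ids = [c for c in selected if rec.hemisphere_map[c] == hemi]
            if not ids:
                raise ValueError(f"no selected channels in {hemi} hemisphere")
            groups[hemi] = rec.channel_index(ids)
    else:
        groups = {"all": rec.channel_index(selected)}
    rows = []
    for ep in epochs:
        row: dict[str, float | str] = {}
        for gname, idx in groups.items():
            series = spatial_average(ep.data, idx)
            for fname, func in _FEATURE_FUNCS.items():
                row[f"{tag}.{gname}.{fname}"] = func(series)
        row["label"] = ep.label
        rows.append(row)
    return pd.DataFrame(rows)


def _pair_columns(table: pd.DataFrame, pair: tuple[str, str]) -> list[str]:
    cols = [c for c in table.columns
            if c != "label" and c.rsplit(".", 1)[-1] in pair]
    if not cols:
        raise ValueError(f"no columns for feature pair {pair}")
    return cols


def _normalize_table(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if c != "label":
            out[c] = minmax_normalize(out[c].to_numpy(), name=c)
    return out


def build_feature_sets(eeg: pd.DataFrame | None = None,
                       fnirs: pd.DataFrame | None = None,
                       mode: str = "hybrid",
                       normalize: bool = True) -> list[tuple[str, pd.DataFrame]]:
    """Enumerate feature sets: 6 per single modality, 36 hybrid.

    Hybrid set ids read ``{eeg_pair}|{fnirs_pair}``; each hybrid table holds
    the EEG pair's columns plus the fNIRS pair's columns (per averaging
    group) and the shared label column.
    """
    if mode not in ("eeg", "fnirs", "hybrid"):
        raise ValueError("mode must be eeg, fnirs or hybrid")
    if mode in ("eeg", "hybrid") and eeg is None:
        raise ValueError("eeg feature table required")
    if mode in ("fnirs", "hybrid") and fnirs is None:
        raise ValueError("fnirs feature table required")
    if mode == "hybrid":
        if len(eeg) != len(fnirs) or not eeg["label"].equals(fnirs["label"]):
            raise ValueError("EEG and fNIRS tables disagree on trials/labels")
    out: list[tuple[str, pd.DataFrame]] = []
    if mode in ("eeg", "fnirs"):
        table = eeg if mode == "eeg" else fnirs
        for pid, pair in zip(PAIR_IDS, FEATURE_PAIRS):
            df = table[_pair_columns(table, pair) + ["label"]].copy()
            out.append((pid, _normalize_table(df) if normalize else df))
        return out
    for e_id, e_pair in zip(PAIR_IDS, FEATURE_PAIRS):
        for f_id, f_pair in zip(PAIR_IDS, FEATURE_PAIRS):
            df = pd.concat(
                [eeg[_pair_columns(eeg, e_pair)],
                 fnirs[_pair_columns(fnirs, f_pair)],
                 eeg[["label"]]], axis=1)
            out.append((f"{e_id}|{f_id}",
                        _normalize_table(df) if normalize else df))
    return out
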