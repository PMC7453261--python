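"""Synthetic hybrid EEG-fNIRS sessions with known task-responsive channels.

The generator emulates a block-design motor-task session: each trial is a
rest period followed by a task period (6 s + 6 s by default), with four
movement classes (left/right hand gripping, left/right arm raising) plus an
explicit rest class, in a seed-randomized order. A configurable number of
"planted" channels per hemisphere carries a task-locked response; all other
channels are noise. Responses are lateralized: left-hemisphere channels
respond to right-side classes and vice versa. Hand and arm classes share the
same channels but differ in temporal activation profile -- hand gripping is
sustained over the whole task window, arm raising is a shorter movement
covering the first half at a slightly lower drive. Profile differences
survive spatial averaging (standardized-moment features are scale-free),
which is what makes the four movement classes mutually distinguishable in
hemisphere-averaged features.

EEG planted channels add an amplitude-modulated mu-band (8-12 Hz) carrier --
one band-limited source per hemisphere, shared by that hemisphere's planted
channels -- on top of white noise. fNIRS planted channels add a hemodynamic
response (per-class-profile boxcar convolved with a canonical double-gamma
HRF) to the oxyhemoglobin concentration; deoxyhemoglobin mirrors it with a
negative ratio. Concentrations are emitted as optical-density changes at
760/850 nm through the forward Beer-Lambert relation, so the preprocessing
module's MBLL inversion recovers the injected concentrations exactly.

``snr`` is the amplitude ratio of the task component (RMS over its active
task windows, at gain 1) to the noise standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .io import EventTable, Recording
from .montage import default_eeg_montage, default_fnirs_montage
from .preprocessing import MbllParams, mbll_forward

__all__ = ["SyntheticConfig", "GroundTruth", "hrf", "generate_session"]

DEFAULT_CLASSES = ("left_hand", "left_arm", "right_hand", "right_arm", "rest")
# (gain, duty): response amplitude and active fraction of the task window.
# Hand gripping is modelled as sustained activity over the whole 6 s window;
# an arm raise as a brief transient movement (~2 s) at slightly lower drive.
DEFAULT_CLASS_PROFILES = {
    "left_hand": (1.0, 1.0), "right_hand": (1.0, 1.0),
    "left_arm": (0.8, 1.0 / 3.0), "right_arm": (0.8, 1.0 / 3.0),
    "rest": (0.0, 0.0),
}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic session."""

    n_trials_per_class: int = 60   # 5 classes x 60 x 12 s = a one-hour session
    classes: tuple[str, ...] = DEFAULT_CLASSES
    rest_duration_s: float = 6.0
    task_duration_s: float = 6.0
    eeg_fs: float = 250.0
    fnirs_fs: float = 10.42
    n_eeg_channels: int = 21
    n_fnirs_channels: int = 34
    planted_eeg: dict[str, int] = field(default_factory=lambda: {"left": 3, "right": 3})
    planted_fnirs: dict[str, int] = field(default_factory=lambda: {"left": 5, "right": 5})
    snr: float = 2.0
    class_profiles: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROFILES))
    drift_amplitude: float = 2.0          # fNIRS 0.01 Hz drift, in noise-SD units
    eeg_noise_sd: float = 1.0             # arbitrary voltage units
    fnirs_noise_sd_mM: float = 1e-3       # 1 uM hemoglobin noise
    hbr_ratio: float = -0.3               # dHbR = hbr_ratio * dHbO task component
    mu_band: tuple[float, float] = (8.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_class <= 0:
            raise ValueError("n_trials_per_class must be positive")
        if not self.classes:
            raise ValueError("need at least one class")
        if min(self.rest_duration_s, self.task_duration_s) <= 0:
            raise ValueError("durations must be positive")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")

    @property
    def trial_duration_s(self) -> float:
        return self.rest_duration_s + self.task_duration_s

    @property
    def n_trials(self) -> int:
        return self.n_trials_per_class * len(self.classes)

    @property
    def total_duration_s(self) -> float:
        return self.n_trials * self.trial_duration_s


@dataclass
class GroundTruth:
    """Oracle bookkeeping: which channels carry signal, and what was injected."""

    planted_eeg: list[str]
    planted_fnirs: list[str]
    labels: list[str]
    hbo_mM: np.ndarray    # injected dHbO, channels x samples (incl. noise+drift)
    hbr_mM: np.ndarray


def hrf(t, peak_time: float = 6.0, undershoot_time: float = 16.0,
        undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response.

    Difference of two unit-scale gamma densities with modes at ``peak_time``
    and ``undershoot_time``; the undershoot term is scaled by
    ``undershoot_ratio``. Returns 0 at t=0 and decays to 0 for large t.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("hrf is defined for t >= 0")
    if not peak_time < undershoot_time:
        raise ValueError("peak_time must precede undershoot_time")
    main = stats.gamma.pdf(t, a=peak_time + 1.0, scale=1.0)
    under = stats.gamma.pdf(t, a=undershoot_time + 1.0, scale=1.0)
    return main - undershoot_ratio * under


def _class_side(label: str) -> str | None:
    if "left" in label:
        return "left"
    if "right" in label:
        return "right"
    return None


def _responding_hemisphere(label: str) -> str | None:
    """Contralateral mapping: the hemisphere driven by a class label."""
    side = _class_side(label)
    if side is None:
        return None
    return "right" if side == "left" else "left"


def _task_gain_series(cfg: SyntheticConfig, labels: list[str], fs: float,
                      n_samples: int, hemisphere: str) -> np.ndarray:
    """Boxcar of per-class activation profiles over this hemisphere's
    active task windows (amplitude = gain, length = duty * task window)."""
    g = np.zeros(n_samples)
    for i, label in enumerate(labels):
        if _responding_hemisphere(label) != hemisphere:
            continue
        gain, duty = cfg.class_profiles.get(label, (1.0, 1.0))
        t_on = i * cfg.trial_duration_s + cfg.rest_duration_s
        start = int(round(t_on * fs))
        stop = int(round((t_on + duty * cfg.task_duration_s) * fs))
        g[start:min(stop, n_samples)] = gain
    return g


def _mu_source(rng: np.random.Generator, cfg: SyntheticConfig, n: int) -> np.ndarray:
    """Unit-variance band-limited (mu-band) oscillatory source."""
    sos = signal.butter(4, list(cfg.mu_band), btype="bandpass", fs=cfg.eeg_fs,
                        output="sos")
    src = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = src.std()
    return src / sd if sd > 0 else src


def _pick_planted(rng: np.random.Generator, channels: list[str],
                  hemisphere_map: dict[str, str], counts: dict[str, int]) -> list[str]:
    picked: list[str] = []
    for hemi in ("left", "right"):
        pool = [c for c in channels if hemisphere_map[c] == hemi]
        k = int(counts.get(hemi, 0))
        if k > len(pool):
            raise ValueError(
                f"cannot plant {k} channels in {hemi} hemisphere of {len(pool)}")
        if k:
            picked.extend(sorted(rng.choice(pool, size=k, replace=False)))
    return picked


def generate_session(config: SyntheticConfig
                     ) -> tuple[Recording, Recording, EventTable, GroundTruth]:
    """Simulate one session: (eeg, fnirs_od, events, ground truth)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    labels = list(np.repeat(cfg.classes, cfg.n_trials_per_class))
    labels = [labels[i] for i in rng.permutation(len(labels))]

    eeg_names, eeg_hemis = default_eeg_montage(cfg.n_eeg_channels)
    fnirs_names, fnirs_hemis = default_fnirs_montage(cfg.n_fnirs_channels)
    planted_eeg = _pick_planted(rng, eeg_names, eeg_hemis, cfg.planted_eeg)
    planted_fnirs = _pick_planted(rng, fnirs_names, fnirs_hemis, cfg.planted_fnirs)

    n_eeg = int(np.ceil(cfg.total_duration_s * cfg.eeg_fs))
    n_fnirs = int(np.ceil(cfg.total_duration_s * cfg.fnirs_fs))

    # --- EEG: shared mu source per hemisphere, amplitude-modulated per class
    sources = {h: _mu_source(rng, cfg, n_eeg) for h in ("left", "right")}
    envelopes = {h: _task_gain_series(cfg, labels, cfg.eeg_fs, n_eeg, h)
                 for h in ("left", "right")}
    eeg = rng.standard_normal((cfg.n_eeg_channels, n_eeg)) * cfg.eeg_noise_sd
    for ch in planted_eeg:
        h = eeg_hemis[ch]
        idx = eeg_names.index(ch)
        eeg[idx] += cfg.snr * cfg.eeg_noise_sd * envelopes[h] * sources[h]

    # --- fNIRS: HRF-convolved per-class boxcar, emitted as dOD at 760/850 nm
    kernel_t = np.arange(0, 32.0, 1.0 / cfg.fnirs_fs)
    kernel = hrf(kernel_t)
    sd = cfg.fnirs_noise_sd_mM
    regressors: dict[str, np.ndarray] = {}
    for h in ("left", "right"):
        box = _task_gain_series(cfg, labels, cfg.fnirs_fs, n_fnirs, h)
        reg = np.convolve(box, kernel)[:n_fnirs] / cfg.fnirs_fs
        active = box > 0
        rms = np.sqrt(np.mean(reg[active] ** 2)) if active.any() else 0.0
        regressors[h] = reg / rms if rms > 0 else reg
    hbo = rng.standard_normal((cfg.n_fnirs_channels, n_fnirs)) * sd
    hbr = rng.standard_normal((cfg.n_fnirs_channels, n_fnirs)) * sd * abs(cfg.hbr_ratio)
    # channel-specific slow drift (vasomotor band); per-channel frequency and
    # phase keep noise channels mutually uncorrelated
    t_f = np.arange(n_fnirs) / cfg.fnirs_fs
    phases = rng.uniform(0, 2 * np.pi, size=(cfg.n_fnirs_channels, 2))
    freqs = rng.uniform(0.003, 0.015, size=(cfg.n_fnirs_channels, 2))
    hbo += cfg.drift_amplitude * sd * np.sin(
        2 * np.pi * freqs[:, :1] * t_f + phases[:, :1])
    hbr += cfg.drift_amplitude * sd * abs(cfg.hbr_ratio) * np.sin(
        2 * np.pi * freqs[:, 1:] * t_f + phases[:, 1:])
    for ch in planted_fnirs:
        h = fnirs_hemis[ch]
        idx = fnirs_names.index(ch)
        comp = cfg.snr * sd * regressors[h]
        hbo[idx] += comp
        hbr[idx] += cfg.hbr_ratio * comp
    od = mbll_forward(hbo, hbr, MbllParams())

    eeg_rec = Recording(data=eeg, fs=cfg.eeg_fs, modality="eeg",
                        channel_names=eeg_names, hemisphere_map=eeg_hemis)
    fnirs_rec = Recording(data=od, fs=cfg.fnirs_fs, modality="fnirs_od",
                          channel_names=fnirs_names, hemisphere_map=fnirs_hemis,
                          wavelengths=[760.0, 850.0])
    frame = pd.DataFrame({
        "onset": [i * cfg.trial_duration_s for i in range(len(labels))],
        "duration": cfg.trial_duration_s,
        "trial_type": labels,
    })
    events = EventTable(frame=frame, task_duration_s=cfg.task_duration_s,
                        classes=cfg.classes)
    truth = GroundTruth(planted_eeg=planted_eeg, planted_fnirs=planted_fnirs,
                        labels=labels, hbo_mM=hbo, hbr_mM=hbr)
    return eeg_rec, fnirs_rec, events, truth
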