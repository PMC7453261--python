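"""Signal conditioning: baseline correction, band-pass filtering, the
modified Beer-Lambert conversion, z-normalization and window-average
downsizing.

EEG is band-passed at 1-25 Hz and fNIRS optical density at 0.01-0.2 Hz, both
with 4th-order IIR Butterworth filters applied forward-backward (zero phase)
by default, so epochs are not shifted in time; the effective magnitude
response is the square of the single-pass Butterworth response. A causal
single-pass option is kept for online-oriented use.

The modified Beer-Lambert law (MBLL) relates the optical-density change at
each wavelength to oxy-/deoxyhemoglobin concentration changes:

    dOD(lambda) = [eps_HbO(lambda) * dHbO + eps_HbR(lambda) * dHbR] * d * DPF(lambda)

with eps the molar extinction coefficients (1/(mM*cm)), d the source-detector
separation (cm) and DPF the differential pathlength factor. With two
wavelengths this is a 2x2 linear system solved exactly per channel/sample.

Window-average downsizing replaces non-overlapping 0.096 s blocks by their
mean; at 250 Hz this is a block of 24 samples and a new rate of ~10.417 Hz,
bringing EEG into parity with the 10.42 Hz fNIRS stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import Recording

__all__ = [
    "FilterSpec", "MbllParams", "EEG_FILTER", "FNIRS_FILTER",
    "DEFAULT_EXTINCTION", "baseline_correct", "bandpass_filter",
    "mbll_convert", "zscore_normalize", "window_average_downsample",
    "preprocess_eeg", "preprocess_fnirs",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification."""

    low_hz: float
    high_hz: float
    order: int = 4
    family: str = "Butterworth band-pass"

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, fs: float) -> np.ndarray:
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high cutoff {self.high_hz} Hz not below Nyquist {fs / 2} Hz")
        return signal.butter(self.order, [self.low_hz, self.high_hz],
                             btype="bandpass", fs=fs, output="sos")


EEG_FILTER = FilterSpec(1.0, 25.0, order=4)
FNIRS_FILTER = FilterSpec(0.01, 0.2, order=4)

# Molar extinction coefficients in 1/(mM*cm) at the instrument's two
# wavelengths, rows = wavelength (760, 850 nm), columns = (HbO, HbR).
DEFAULT_EXTINCTION = np.array([
    [0.1496, 0.3865],   # 760 nm
    [0.2526, 0.1798],   # 850 nm
])


@dataclass
class MbllParams:
    """Parameters of the modified Beer-Lambert conversion.

    ``extinction`` is wavelength x (HbO, HbR) in 1/(mM*cm); ``distance`` the
    source-detector separation in cm; ``dpf`` the differential pathlength
    factor per wavelength (a scalar is broadcast to both).
    """

    extinction: np.ndarray = field(default_factory=lambda: DEFAULT_EXTINCTION.copy())
    distance: float = 3.4
    dpf: np.ndarray | float = 6.0

    def __post_init__(self) -> None:
        self.extinction = np.asarray(self.extinction, dtype=float)
        if self.extinction.shape != (2, 2):
            raise ValueError("extinction must be a 2x2 matrix")
        if abs(np.linalg.det(self.extinction)) < 1e-12:
            raise ValueError("extinction matrix is singular")
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        self.dpf = np.broadcast_to(np.asarray(self.dpf, dtype=float), (2,)).copy()
        if np.any(self.dpf <= 0):
            raise ValueError("DPF must be positive")

    def forward_matrix(self) -> np.ndarray:
        """2x2 matrix A with dOD = A @ (dHbO, dHbR)."""
        return self.extinction * (self.distance * self.dpf[:, None])


def _as_matrix(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.size == 0:
        raise ValueError("empty input")
    return x


def baseline_correct(x: np.ndarray) -> np.ndarray:
    """Subtract each channel's mean (row-wise baseline correction)."""
    x = _as_matrix(x)
    return x - x.mean(axis=1, keepdims=True)


def bandpass_filter(x: np.ndarray, fs: float, spec: FilterSpec,
                    zero_phase: bool = True) -> np.ndarray:
    """Butterworth band-pass along the sample axis, zero-phase by default."""
    x = _as_matrix(x)
    if x.shape[1] <= 3 * (2 * spec.order + 1):
        raise ValueError("signal too short for the requested filter order")
    sos = spec.sos(fs)
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=1)
    return signal.sosfilt(sos, x, axis=1)


def mbll_convert(od: np.ndarray, params: MbllParams | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Invert the MBLL 2x2 system: dOD planes -> (dHbO, dHbR) in mM.

    ``od`` is wavelengths(2) x channels x samples (a 2 x samples array is
    treated as a single channel).
    """
    params = params or MbllParams()
    od = np.asarray(od, dtype=float)
    squeeze = od.ndim == 2
    if squeeze:
        od = od[:, None, :]
    if od.ndim != 3 or od.shape[0] != 2:
        raise ValueError("od must have exactly 2 wavelength planes")
    a = params.forward_matrix()
    # solve A @ c = od for every channel/sample at once
    conc = np.linalg.solve(a, od.reshape(2, -1)).reshape(od.shape)
    dhbo, dhbr = conc[0], conc[1]
    if squeeze:
        dhbo, dhbr = dhbo[0], dhbr[0]
    return dhbo, dhbr


def mbll_forward(dhbo: np.ndarray, dhbr: np.ndarray,
                 params: MbllParams | None = None) -> np.ndarray:
    """Forward MBLL: concentration changes (mM) -> dOD wavelength planes."""
    params = params or MbllParams()
    dhbo = np.asarray(dhbo, dtype=float)
    dhbr = np.asarray(dhbr, dtype=float)
    if dhbo.shape != dhbr.shape:
        raise ValueError("dHbO and dHbR shapes differ")
    a = params.forward_matrix()
    stacked = np.stack([dhbo.ravel(), dhbr.ravel()])
    return (a @ stacked).reshape((2,) + dhbo.shape)


def zscore_normalize(x: np.ndarray) -> np.ndarray:
    """Per-channel standardization to mean 0, population SD 1."""
    x = _as_matrix(x)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    flat = np.nonzero(sd.ravel() == 0)[0]
    if len(flat):
        raise ValueError(
            f"constant channel(s) at row(s) {[int(i) for i in flat]}: zero variance")
    return (x - mu) / sd


def window_average_downsample(x: np.ndarray, fs: float, window_s: float = 0.096
                              ) -> tuple[np.ndarray, float]:
    """Non-overlapping block averaging over ``window_s`` seconds.

    Block length is ``L = max(1, round(window_s * fs))``; a trailing partial
    block is averaged as-is. Returns the downsized matrix and ``fs / L``.
    """
    if window_s <= 0:
        raise ValueError("window must be positive")
    x = _as_matrix(x)
    n = x.shape[1]
    L = max(1, int(round(window_s * fs)))
    if L == 1:
        return x.copy(), float(fs)
    n_full = n // L
    out_cols = n_full + (1 if n % L else 0)
    out = np.empty((x.shape[0], out_cols))
    out[:, :n_full] = x[:, : n_full * L].reshape(x.shape[0], n_full, L).mean(axis=2)
    if n % L:
        out[:, -1] = x[:, n_full * L:].mean(axis=1)
    return out, fs / L


# ---------------------------------------------------------------------------
# recording-level pipelines: baseline -> filter -> (MBLL) -> zscore -> downsize

def preprocess_eeg(rec: Recording, spec: FilterSpec = EEG_FILTER,
                   window_s: float = 0.096, zero_phase: bool = True) -> Recording:
    if rec.modality != "eeg":
        raise ValueError(f"expected an eeg recording, got {rec.modality}")
    x = baseline_correct(rec.data)
    x = bandpass_filter(x, rec.fs, spec, zero_phase=zero_phase)
    x = zscore_normalize(x)
    x, new_fs = window_average_downsample(x, rec.fs, window_s)
    return rec.copy_with(x, fs=new_fs)


def preprocess_fnirs(rec: Recording, spec: FilterSpec = FNIRS_FILTER,
                     mbll: MbllParams | None = None, window_s: float = 0.096,
                     zero_phase: bool = True,
                     return_hbr: bool = False) -> Recording | tuple[Recording, Recording]:
    """Optical density -> filtered, normalized HbO recording (HbR optional)."""
    if rec.modality != "fnirs_od":
        raise ValueError(f"expected an fnirs_od recording, got {rec.modality}")
    planes = [bandpass_filter(baseline_correct(p), rec.fs, spec, zero_phase=zero_phase)
              for p in rec.data]
    dhbo, dhbr = mbll_convert(np.stack(planes), mbll)
    out = []
    for mat, modality in ((dhbo, "fnirs_hbo"), (dhbr, "fnirs_hbr")):
        z = zscore_normalize(mat)
        z, new_fs = window_average_downsample(z, rec.fs, window_s)
        out.append(rec.copy_with(z, fs=new_fs, modality=modality))
    return (out[0], out[1]) if return_hbr else out[0]
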