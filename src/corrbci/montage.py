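"""Default channel montages.

The montages mirror a bilateral motor-task recording setup: 21 lateral EEG
electrodes (10-20 names, odd index = left hemisphere, even = right) and 34
fNIRS channels split 17/17 between hemispheres. Midline sites are omitted so
that every channel belongs to exactly one hemisphere group, which the
correlation-ranking step requires.
"""

from __future__ import annotations

EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P3", "P4", "O1",
)


def eeg_hemisphere(name: str) -> str:
    """Hemisphere of a 10-20 electrode name (odd digit left, even right)."""
    digits = [c for c in name if c.isdigit()]
    if not digits:
        raise ValueError(f"cannot infer hemisphere for channel {name!r}")
    return "left" if int(digits[-1]) % 2 == 1 else "right"


def default_eeg_montage(n_channels: int = 21) -> tuple[list[str], dict[str, str]]:
    if n_channels > len(EEG_CHANNELS):
        # extend with generic lateral labels, alternating hemispheres
        extra = [f"X{i}" for i in range(1, n_channels - len(EEG_CHANNELS) + 1)]
        names = list(EEG_CHANNELS) + extra
        hemis = {n: eeg_hemisphere(n) for n in EEG_CHANNELS}
        for i, n in enumerate(extra):
            hemis[n] = "left" if i % 2 == 0 else "right"
        return names, hemis
    names = list(EEG_CHANNELS[:n_channels])
    return names, {n: eeg_hemisphere(n) for n in names}


def default_fnirs_montage(n_channels: int = 34) -> tuple[list[str], dict[str, str]]:
    """fNIRS optode-pair channels; first half left hemisphere, second right."""
    names = [f"N{i:02d}" for i in range(1, n_channels + 1)]
    half = (n_channels + 1) // 2
    hemis = {n: ("left" if i < half else "right") for i, n in enumerate(names)}
    return names, hemis
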