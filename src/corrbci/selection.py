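"""Pearson-correlation rank-matrix channel selection per hemisphere.

Channels are grouped by hemisphere; within each group every pairwise Pearson
product-moment correlation

    rho_ij = E[(x_i - mu_i)(x_j - mu_j)] / (sigma_i * sigma_j)

is computed over the concatenation of all task epochs, a rank matrix is
formed, and each channel is scored by the mean absolute correlation to the
other channels in its group. The top-k channels per hemisphere are selected
as task-active; low-ranked channels are treated as noise or artefact
carriers and dropped. Defaults keep 3 EEG channels per hemisphere (6 of 21)
and 5 fNIRS channels per hemisphere (10 of 34).

The absolute value is used so that strongly anticorrelated channels still
count as associated (the conventional strength-of-association bins treat
negative coefficients symmetrically); a signed-mean variant is available via
``score="signed"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EventTable, Recording

__all__ = [
    "HemisphereGroup", "ChannelRanking", "pearson_correlation",
    "correlation_matrix", "rank_channels", "rank_hemispheres",
    "select_channels", "association_strength", "ranking_report",
]


@dataclass(frozen=True)
class HemisphereGroup:
    hemisphere: str
    channel_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        if not self.channel_ids:
            raise ValueError("empty hemisphere group")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("duplicate channel ids in group")


@dataclass
class ChannelRanking:
    """Rank matrix and derived ordering for one hemisphere group."""

    hemisphere: str
    channel_ids: list[str]
    corr: np.ndarray          # symmetric, unit diagonal
    scores: np.ndarray        # per channel, aligned with channel_ids
    order: list[str]          # channel ids by descending score

    def top(self, k: int) -> list[str]:
        if not 0 < k <= len(self.order):
            raise ValueError(
                f"k={k} outside 1..{len(self.order)} for {self.hemisphere} group")
        return self.order[:k]


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("inputs must be 1-D")
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(np.mean(dx * dx))
    sy = np.sqrt(np.mean(dy * dy))
    if sx == 0 or sy == 0:
        raise ValueError("constant input: correlation undefined (sigma = 0)")
    rho = float(np.mean(dx * dy) / (sx * sy))
    return max(-1.0, min(1.0, rho))


def correlation_matrix(x: np.ndarray, channel_ids: list[str] | None = None
                       ) -> np.ndarray:
    """Pairwise Pearson correlations of the rows of ``x`` (channels x samples)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 channels")
    ids = channel_ids or [str(i) for i in range(x.shape[0])]
    sd = x.std(axis=1)
    bad = np.nonzero(sd == 0)[0]
    if len(bad):
        raise ValueError(f"constant channel(s): {[ids[i] for i in bad]}")
    centered = x - x.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / x.shape[1]
    corr = cov / np.outer(sd, sd)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def rank_channels(corr: np.ndarray, ids: list[str], hemisphere: str = "left",
                  score: str = "abs") -> ChannelRanking:
    """Score channels by mean (absolute) off-diagonal correlation and sort.

    Ties are broken by ascending position in ``ids`` for determinism.
    """
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if corr.shape != (n, n) or n != len(ids):
        raise ValueError("corr must be square and match ids")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("corr must be symmetric")
    if np.any(np.abs(corr) > 1 + 1e-10):
        raise ValueError("correlations must lie in [-1, 1]")
    if n < 2:
        raise ValueError("need at least 2 channels to rank")
    if score not in ("abs", "signed"):
        raise ValueError("score must be 'abs' or 'signed'")
    off = np.abs(corr) if score == "abs" else corr
    scores = (off.sum(axis=1) - np.diag(off)) / (n - 1)
    perm = sorted(range(n), key=lambda i: (-scores[i], i))
    return ChannelRanking(hemisphere=hemisphere, channel_ids=list(ids),
                          corr=corr, scores=scores,
                          order=[ids[i] for i in perm])


def _task_concatenation(rec: Recording, events: EventTable) -> np.ndarray:
    """Concatenate all non-rest task windows along the sample axis."""
    from .features import epoch_trials  # local import to avoid a cycle
    epochs = epoch_trials(rec.data, rec.fs, events, segment="task")
    task = [e.data for e in epochs if e.label != "rest"]
    if not task:
        raise ValueError("no task epochs to correlate over")
    return np.concatenate(task, axis=1)


def rank_hemispheres(rec: Recording, events: EventTable | None = None,
                     score: str = "abs") -> dict[str, ChannelRanking]:
    """Per-hemisphere rankings over task-epoch data (whole record if no events)."""
    data = _task_concatenation(rec, events) if events is not None else rec.data
    out: dict[str, ChannelRanking] = {}
    for hemi in ("left", "right"):
        ids = rec.hemisphere_channels(hemi)
        if len(ids) < 2:
            raise ValueError(f"{hemi} hemisphere group has < 2 channels")
        sub = data[rec.channel_index(ids)]
        out[hemi] = rank_channels(correlation_matrix(sub, ids), ids,
                                  hemisphere=hemi, score=score)
    return out


def select_channels(rec: Recording, k_left: int, k_right: int,
                    events: EventTable | None = None,
                    score: str = "abs") -> list[str]:
    """Top-k channels of each hemisphere's correlation ranking (left + right)."""
    rankings = rank_hemispheres(rec, events, score=score)
    return rankings["left"].top(k_left) + rankings["right"].top(k_right)


def association_strength(rho: float) -> tuple[str, str]:
    """Qualitative strength-of-association bin and sign for a coefficient.

    Bins on |rho|: [0.1, 0.3) small, [0.3, 0.5) medium, [0.5, 1.0] large,
    below 0.1 negligible.
    """
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    a = abs(rho)
    if a < 0.1:
        label = "negligible"
    elif a < 0.3:
        label = "small"
    elif a < 0.5:
        label = "medium"
    else:
        label = "large"
    sign = "positive" if rho > 0 else ("negative" if rho < 0 else "zero")
    return label, sign


def ranking_report(rankings: dict[str, ChannelRanking],
                   k_per_hemisphere: dict[str, int]) -> pd.DataFrame:
    """Tabular report: channel, hemisphere, score, rank, selected, association."""
    rows = []
    for hemi, ranking in rankings.items():
        k = k_per_hemisphere.get(hemi, 0)
        rank_of = {c: r for r, c in enumerate(ranking.order, start=1)}
        for i, ch in enumerate(ranking.channel_ids):
            label, _ = association_strength(float(ranking.scores[i]))
            rows.append({
                "channel": ch, "hemisphere": hemi,
                "score": float(ranking.scores[i]), "rank": rank_of[ch],
                "selected": rank_of[ch] <= k, "association": label,
            })
    return pd.DataFrame(rows).sort_values(["hemisphere", "rank"]).reset_index(drop=True)
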