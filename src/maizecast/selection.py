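"""Minimum-redundancy-maximum-relevance (MRMR) channel ranking.

Candidate channels are summarized to one scalar per sample, discretized into
quantile bins, and ranked by greedy forward selection: the first pick
maximizes mutual information (MI) with the target; each later pick maximizes
relevance minus mean redundancy with the already-selected set (the MID
criterion; MIQ, the quotient form, is available as an option).

The ranking is a report: the pipeline's default model input remains the
canonical ten-channel set, with MRMR used to confirm that weak channels rank
low rather than to auto-select.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["mutual_information", "mrmr_rank", "MRMRResult", "summarize_panel"]


def quantile_discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Integer codes from quantile binning; degenerate inputs collapse safely."""
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    if uniq.size <= bins:
        # already (effectively) discrete: one code per distinct value
        return np.searchsorted(uniq, x).astype(np.intp)
    codes = pd.qcut(x, bins, labels=False, duplicates="drop")
    return np.asarray(codes, dtype=np.intp)


def _mi_from_codes(xc: np.ndarray, yc: np.ndarray) -> float:
    """Plug-in mutual information (bits) between two integer code vectors."""
    joint = np.zeros((xc.max() + 1, yc.max() + 1))
    np.add.at(joint, (xc, yc), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


def mutual_information(x, y, bins: int = 10) -> float:
    """Plug-in MI estimate (bits) between quantile-discretized samples.

    Symmetric and nonnegative; a constant input carries zero information.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    if x.size < 2:
        raise ValueError("need at least two samples")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN values in input")
    return _mi_from_codes(quantile_discretize(x, bins), quantile_discretize(y, bins))


@dataclass
class MRMRResult:
    """Ordered selection trace plus the parameters that produced it."""

    ranking: list[dict]   # rank, channel, relevance_bits, redundancy_bits, score
    bins: int
    criterion: str
    summary: str
    k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranking)

    @property
    def selected(self) -> list[str]:
        return [row["channel"] for row in self.ranking]


def mrmr_rank(
    summaries: pd.DataFrame,
    target: np.ndarray,
    k: int | None = None,
    bins: int = 10,
    criterion: str = "mid",
    summary: str = "mean",
) -> MRMRResult:
    """Greedy MRMR ranking of per-sample channel summaries against a target.

    ``summaries``: one row per sample, one column per channel.  Step 1 picks
    the channel with maximal MI with the target; step j maximizes
    relevance - mean(MI with selected) (``mid``) or relevance / mean
    redundancy (``miq``).  Exact score ties break lexicographically by name.
    """
    if criterion not in ("mid", "miq"):
        raise ValueError(f"unknown criterion {criterion!r}")
    names = sorted(summaries.columns)
    k = len(names) if k is None else int(k)
    if k > len(names):
        raise ValueError(f"k={k} exceeds the {len(names)} candidate channels")

    target = np.asarray(target, dtype=float)
    codes = {n: quantile_discretize(summaries[n].to_numpy(), bins) for n in names}
    ycodes = quantile_discretize(target, bins)
    relevance = {n: _mi_from_codes(codes[n], ycodes) for n in names}
    pair_mi: dict[tuple[str, str], float] = {}

    def redundancy(n: str, selected: list[str]) -> float:
        if not selected:
            return 0.0
        total = 0.0
        for s in selected:
            key = (n, s) if n < s else (s, n)
            if key not in pair_mi:
                pair_mi[key] = _mi_from_codes(codes[key[0]], codes[key[1]])
            total += pair_mi[key]
        return total / len(selected)

    selected: list[str] = []
    ranking: list[dict] = []
    remaining = list(names)
    for rank in range(1, k + 1):
        best_name, best_score, best_red = None, -np.inf, 0.0
        for n in remaining:  # lexicographic order -> ties keep the first name
            red = redundancy(n, selected)
            if criterion == "mid":
                score = relevance[n] - red
            else:
                score = relevance[n] / max(red, 1e-12)
            if score > best_score:
                best_name, best_score, best_red = n, score, red
        selected.append(best_name)
        remaining.remove(best_name)
        ranking.append(
            {
                "rank": rank,
                "channel": best_name,
                "relevance_bits": relevance[best_name],
                "redundancy_bits": best_red,
                "score": best_score,
            }
        )
    return MRMRResult(ranking=ranking, bins=bins, criterion=criterion, summary=summary, k=k)


def summarize_panel(panel, stat: str = "mean") -> tuple[pd.DataFrame, np.ndarray]:
    """Collapse each daily channel to one scalar per sample for MRMR.

    ``mean`` (season mean; the constant value for broadcast channels),
    ``sum`` (season total) or ``last`` (end-of-season value, natural for
    cumulative channels).  Returns (summaries, target) aligned by sample.
    """
    if stat not in ("mean", "sum", "last"):
        raise ValueError(f"unknown summary statistic {stat!r}")
    fn = {"mean": np.mean, "sum": np.sum, "last": lambda a: a[-1]}[stat]
    keys = panel.keys
    rows = {name: [fn(panel.channels[key][name]) for key in keys] for name in panel.channel_names}
    target = np.array([panel.target[key] for key in keys])
    return pd.DataFrame(rows, index=pd.Index(range(len(keys)))), target
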