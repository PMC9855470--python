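"""Clustering-efficiency evaluation by within-class pairwise distances.

A space clusters the DILI-positive compounds efficiently when the mean
pairwise distance among positives is small. For each space the mean and
population standard deviation of Euclidean and Manhattan distances are
computed over all unordered within-class pairs (each pair counted once,
no self-pairs, no cross-class pairs); the cross-class mean is reported as
supplementary output because it aids interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

METRICS = ("euclidean", "manhattan")
_SCIPY_METRIC = {"euclidean": "euclidean", "manhattan": "cityblock"}


@dataclass
class DistanceSummary:
    """Within-class pairwise distance statistics of one space."""

    space_name: str
    metric: str
    mean_within_positive: float
    sd_within_positive: float
    mean_within_negative: float
    sd_within_negative: float
    n_positive: int
    n_negative: int
    mean_cross_class: float = float("nan")
    is_fused: bool = False

    def to_dict(self) -> dict:
        return {
            "space": self.space_name,
            "metric": self.metric,
            "mean_within_positive": self.mean_within_positive,
            "sd_within_positive": self.sd_within_positive,
            "mean_within_negative": self.mean_within_negative,
            "sd_within_negative": self.sd_within_negative,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "mean_cross_class": self.mean_cross_class,
            "is_fused": self.is_fused,
        }


def pairwise_distance_summary(space, labels, metric: str = "euclidean") -> DistanceSummary:
    """Mean/SD of distances over all unordered within-class pairs.

    Requires at least 2 compounds in each class. SDs are population SDs
    over the C(n_c, 2) pair distances of each class.
    """
    if metric not in _SCIPY_METRIC:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    labels = np.asarray(labels, dtype=bool)
    coords = np.asarray(space.coords, dtype=float)
    if labels.shape[0] != coords.shape[0]:
        raise ValueError("labels length does not match space size")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    for cls, count in (("positive", n_pos), ("negative", n_neg)):
        if count < 2:
            raise ValueError(f"class {cls!r} has {count} member(s); need at least 2")
    m = _SCIPY_METRIC[metric]
    d_pos = pdist(coords[labels], metric=m)
    d_neg = pdist(coords[~labels], metric=m)
    cross = cdist(coords[labels], coords[~labels], metric=m)
    return DistanceSummary(
        space_name=space.space_name,
        metric=metric,
        mean_within_positive=float(d_pos.mean()),
        sd_within_positive=float(d_pos.std()),
        mean_within_negative=float(d_neg.mean()),
        sd_within_negative=float(d_neg.std()),
        n_positive=n_pos,
        n_negative=n_neg,
        mean_cross_class=float(cross.mean()),
        is_fused=isinstance(space, _consensus_type()) or "consensus" in space.space_name,
    )


def _consensus_type():
    from .fusion import ConsensusEmbedding

    return ConsensusEmbedding


def compare_spaces(summaries: list[DistanceSummary]) -> pd.DataFrame:
    """Rank spaces by clustering efficiency on one metric.

    Returns a table sorted ascending by ``mean_within_positive`` (stable:
    ties keep input order) with a ``fused_first`` column that is True on
    every row iff every fused space precedes every single-representation
    space.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 summaries to compare")
    metrics = {s.metric for s in summaries}
    if len(metrics) != 1:
        raise ValueError(f"summaries mix metrics: {sorted(metrics)}")
    frame = pd.DataFrame([s.to_dict() for s in summaries])
    frame = frame.sort_values("mean_within_positive", kind="stable").reset_index(drop=True)
    if frame["is_fused"].any() and (~frame["is_fused"]).any():
        last_fused = frame.index[frame["is_fused"]].max()
        first_single = frame.index[~frame["is_fused"]].min()
        fused_first = bool(last_fused < first_single)
    else:
        fused_first = False
    frame["fused_first"] = fused_first
    return frame


def summarize_all(
    spaces: list, labels, metrics=METRICS
) -> pd.DataFrame:
    """Distance summaries for every (space, metric) pair, as one table."""
    rows = []
    for metric in metrics:
        for space in spaces:
            rows.append(pairwise_distance_summary(space, labels, metric).to_dict())
    return pd.DataFrame(rows)


def plot_distance_bars(frame: pd.DataFrame, path, metric: str = "euclidean"):
    """Bar plot of within-class mean distances (with SD error bars)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = frame[frame["metric"] == metric]
    x = np.arange(len(sub))
    fig, ax = plt.subplots(figsize=(max(6, len(sub) * 1.2), 4))
    width = 0.38
    ax.bar(
        x - width / 2, sub["mean_within_positive"], width,
        yerr=sub["sd_within_positive"], color="tab:red", label="DILI-positive",
        capsize=3,
    )
    ax.bar(
        x + width / 2, sub["mean_within_negative"], width,
        yerr=sub["sd_within_negative"], color="tab:blue", label="DILI-negative",
        capsize=3,
    )
    ax.set_xticks(x)
    ax.set_xticklabels(sub["space"], rotation=30, ha="right", fontsize=8)
    ax.set_ylabel(f"mean within-class {metric} distance")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
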