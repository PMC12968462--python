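"""Per-window community detection seeded from canonical network labels.

Each window starts from the literature-based resting-state assignment and
iteratively reallocates the worst-embedded region to the community it is
most strongly connected to, until the same region is selected in two
consecutive iterations (saturation), a proposed move changes nothing, or a
hard iteration cap is reached.  Detection is fully deterministic: ties are
broken by lowest index, with "keep the current label" preferred on
reallocation ties.  No new communities are ever created; labels are drawn
from the initial label set only.

The assignment-quality score is pluggable (``quality_fn``): the default is
the region's mean connectivity to its own community minus its best mean
connectivity to any other community, which makes selection (lowest quality)
and reallocation (maximal mean connectivity) two views of the same quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from netreconf.io import NETWORKS, AtlasLabels
from netreconf.windows import WindowedConnectivity


@dataclass
class AssignmentMatrix:
    """Regions × windows integer community labels — the central object.

    Labels lie in 1..K; K is fixed across windows (8 networks by default)
    even when some communities go unused in a particular window.
    """

    labels: np.ndarray  # (n_regions, n_windows) int
    n_communities: int
    region_ids: list

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("labels must be regions × windows")
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.n_communities):
            raise ValueError(f"labels must lie in 1..{self.n_communities}")
        if len(self.region_ids) != self.labels.shape[0]:
            raise ValueError("region_ids misaligned with label rows")

    @property
    def n_regions(self) -> int:
        return self.labels.shape[0]

    @property
    def n_windows(self) -> int:
        return self.labels.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.labels, index=self.region_ids,
                            columns=[f"w{t}" for t in range(self.n_windows)])

    @staticmethod
    def label_legend(n_communities: int = 8) -> dict:
        return {i + 1: n for i, n in enumerate(NETWORKS[:n_communities])}


@dataclass
class DetectionTrace:
    """Audit trail of one window's iterative reassignment."""

    steps: list = field(default_factory=list)  # (region, old_label, new_label, quality)
    converged: bool = False
    stop_reason: str = ""

    @property
    def n_iterations(self) -> int:
        return len(self.steps)


def community_means(weights: np.ndarray, labels: np.ndarray, n_communities: int) -> np.ndarray:
    """Mean edge weight from every region to every community, self excluded.

    Returns an (n_regions, K) matrix; entries for empty communities (or a
    region's own community when the region is its sole member) are NaN.
    """
    n = weights.shape[0]
    onehot = np.zeros((n, n_communities))
    onehot[np.arange(n), labels - 1] = 1.0
    sums = weights @ onehot                      # self excluded: diagonal is 0
    counts = onehot.sum(axis=0)[None, :] - onehot  # own community: one fewer member
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    means[counts == 0] = np.nan
    return means


def assignment_quality(weights: np.ndarray, labels: np.ndarray, region: int,
                       n_communities: int | None = None) -> float:
    """Embeddedness of one region under the current labelling.

    q_i = mean weight to own community (self excluded) minus the maximum
    over other communities of the mean weight to that community.  Higher is
    better embedded; a region that is the only member of its community gets
    −inf so it is reallocated first.
    """
    labels = np.asarray(labels, dtype=int)
    if not 0 <= region < weights.shape[0]:
        raise IndexError(f"region {region} out of range for {weights.shape[0]} regions")
    K = n_communities if n_communities is not None else int(labels.max())
    means = community_means(weights, labels, K)
    return float(_quality_from_means(means, labels)[region])


def _quality_from_means(means: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n, K = means.shape
    own = means[np.arange(n), labels - 1]
    others = means.copy()
    others[np.arange(n), labels - 1] = np.nan
    with np.errstate(all="ignore"):
        best_other = np.nanmax(others, axis=1)
    best_other = np.where(np.isnan(best_other), -np.inf, best_other)
    q = np.where(np.isnan(own), -np.inf, own - best_other)
    return q


def _validate_weights(weights: np.ndarray) -> None:
    if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
        raise ValueError("weights must be a square matrix")
    if (weights < 0).any():
        raise ValueError("weights must be nonnegative")
    if not np.allclose(weights, weights.T):
        raise ValueError("weights must be symmetric")


def detect_window_communities(weights: np.ndarray, initial_labels: np.ndarray,
                              n_communities: int = 8, max_iterations: int = 1000,
                              quality_fn=None):
    """Iterative reassignment for a single window.

    Loop: (1) score every region's assignment quality; (2) select the region
    with the lowest quality (ties → lowest index); (3) reallocate it to the
    community with maximal mean connectivity (ties → keep the current label
    if it is among the tied set, otherwise lowest community index); (4) stop
    when the same region is selected in two consecutive iterations, when the
    proposed move changes nothing, or at ``max_iterations``.

    Returns ``(labels, trace)``.
    """
    _validate_weights(weights)
    labels = np.asarray(initial_labels, dtype=int).copy()
    if labels.shape[0] != weights.shape[0]:
        raise ValueError("initial_labels misaligned with weights")
    if labels.min() < 1 or labels.max() > n_communities:
        raise ValueError(f"initial labels must lie in 1..{n_communities}")

    trace = DetectionTrace()
    prev_selected = -1
    for _ in range(max_iterations):
        means = community_means(weights, labels, n_communities)
        if quality_fn is None:
            q = _quality_from_means(means, labels)
        else:
            q = np.array([quality_fn(weights, labels, i, n_communities)
                          for i in range(len(labels))])
        selected = int(np.argmin(q))  # argmin takes the lowest index on ties

        row = means[selected]
        if np.all(np.isnan(row)):
            new_label = int(labels[selected])  # no populated community to move to
        else:
            with np.errstate(all="ignore"):
                best = np.nanmax(row)
            tied = np.where(row == best)[0] + 1
            cur = int(labels[selected])
            new_label = cur if cur in tied else int(tied.min())

        trace.steps.append((selected, int(labels[selected]), new_label, float(q[selected])))
        if selected == prev_selected:
            trace.converged = True
            trace.stop_reason = "same_region_consecutive"
            break
        if new_label == labels[selected]:
            trace.converged = True
            trace.stop_reason = "no_change"
            break
        labels[selected] = new_label
        prev_selected = selected
    else:
        trace.stop_reason = "max_iterations"
    return labels, trace


def detect_all(wc: WindowedConnectivity, initial_labels, n_communities: int = 8,
               max_iterations: int = 1000, quality_fn=None,
               return_traces: bool = False):
    """Run per-window detection across all windows of one subject.

    Every window is seeded independently from the literature-based labels;
    there is no temporal coupling between windows.  Returns the regions ×
    windows :class:`AssignmentMatrix` (and the per-window traces when
    ``return_traces`` is set).
    """
    if isinstance(initial_labels, AtlasLabels):
        init = initial_labels.to_int_labels(wc.region_ids)
    else:
        init = np.asarray(initial_labels, dtype=int)
    out = np.empty((wc.n_regions, wc.n_windows), dtype=int)
    traces = []
    for w in range(wc.n_windows):
        labels, trace = detect_window_communities(
            wc.weights[w], init, n_communities=n_communities,
            max_iterations=max_iterations, quality_fn=quality_fn)
        out[:, w] = labels
        traces.append(trace)
    am = AssignmentMatrix(out, n_communities, list(wc.region_ids))
    return (am, traces) if return_traces else am
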