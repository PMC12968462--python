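"""Node, network and global reconfiguration metrics.

Four per-node measures are computed from a regions × windows assignment
matrix with T windows and K available communities:

- promiscuity: distinct communities visited / K
- flexibility: label changes / (T − 1)
- cohesion: switches made jointly with ≥ 1 other node (same source AND same
  destination at the same transition) / (T − 1)
- disjointedness: switches with no such partner / (T − 1)

Every switch is classified exactly once as cohesive or disjoint, so
flexibility = cohesion + disjointedness holds exactly per node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from netreconf.communities import AssignmentMatrix
from netreconf.io import NETWORKS, AtlasLabels

METRIC_NAMES = ("promiscuity", "flexibility", "cohesion", "disjointedness")

#: transition classification codes
NONE, COHESIVE, DISJOINT = 0, 1, 2


@dataclass
class SwitchClassification:
    """Per-node, per-transition switch labels and cohesive partner sets.

    ``kinds[i, t]`` is 0 (no switch), 1 (cohesive) or 2 (disjoint) for the
    transition t → t+1.  ``partners`` maps (node, transition) to the tuple
    of co-moving node indices for cohesive switches.
    """

    kinds: np.ndarray  # (n_nodes, T-1) int8
    partners: dict


@dataclass
class ReconfigMetrics:
    """Per-node metrics with global and per-network aggregates."""

    node: pd.DataFrame          # rows: region_id; columns: network + METRIC_NAMES
    global_means: pd.Series     # one mean per metric
    network_means: pd.DataFrame  # rows: networks; NaN where a network has no node
    n_windows: int
    n_communities: int


def promiscuity(node_row, n_communities: int) -> float:
    """Fraction of all K available communities the node ever belongs to.

    The initial label counts as visited, and the denominator stays K even if
    some communities never occur, so a node that never moves scores 1/K.
    """
    row = np.asarray(node_row, dtype=int)
    if row.size < 1 or n_communities < 1:
        raise ValueError("need at least one window and one community")
    if row.min() < 1 or row.max() > n_communities:
        raise ValueError(f"labels must lie in 1..{n_communities}")
    return len(np.unique(row)) / n_communities


def flexibility(node_row) -> float:
    """Fraction of between-window transitions where the label changes."""
    row = np.asarray(node_row, dtype=int)
    if row.size < 2:
        raise ValueError("flexibility needs at least 2 windows")
    return float(np.mean(row[:-1] != row[1:]))


def classify_switches(assignments: AssignmentMatrix | np.ndarray) -> SwitchClassification:
    """Label every switch cohesive or disjoint.

    A node's switch at transition t is cohesive iff at least one *other*
    node switches at the same transition from the same source label to the
    same destination label; otherwise it is disjoint.  In a single-node
    matrix every switch is disjoint — there is no possible partner.
    """
    labels = assignments.labels if isinstance(assignments, AssignmentMatrix) else np.asarray(assignments, dtype=int)
    n, T = labels.shape
    if T < 2:
        raise ValueError("switch classification needs at least 2 windows")
    kinds = np.zeros((n, T - 1), dtype=np.int8)
    partners: dict = {}
    for t in range(T - 1):
        src, dst = labels[:, t], labels[:, t + 1]
        movers = np.where(src != dst)[0]
        groups: dict = {}
        for i in movers:
            groups.setdefault((src[i], dst[i]), []).append(i)
        for members in groups.values():
            if len(members) >= 2:
                for i in members:
                    kinds[i, t] = COHESIVE
                    partners[(int(i), t)] = tuple(j for j in members if j != i)
            else:
                kinds[members[0], t] = DISJOINT
    return SwitchClassification(kinds, partners)


def cohesion_and_disjointedness(cls: SwitchClassification, n_windows: int):
    """Per-node (cohesion, disjointedness) as fractions of the T−1 transitions."""
    denom = n_windows - 1
    coh = (cls.kinds == COHESIVE).sum(axis=1) / denom
    dis = (cls.kinds == DISJOINT).sum(axis=1) / denom
    return coh, dis


def compute_metrics(assignments: AssignmentMatrix, atlas: AtlasLabels | None = None,
                    promiscuity_denominator: int | None = None) -> ReconfigMetrics:
    """All four node metrics plus global and per-network aggregates.

    ``promiscuity_denominator`` overrides K for the promiscuity ratio (the
    default uses the assignment matrix's full community count).  Per-network
    aggregation uses the static literature-based membership from ``atlas``,
    not the time-resolved assignments.
    """
    labels = assignments.labels
    K = promiscuity_denominator if promiscuity_denominator is not None else assignments.n_communities
    T = assignments.n_windows
    cls = classify_switches(assignments)
    coh, dis = cohesion_and_disjointedness(cls, T)
    node = pd.DataFrame(
        {
            "promiscuity": [promiscuity(labels[i], K) for i in range(assignments.n_regions)],
            "flexibility": [flexibility(labels[i]) for i in range(assignments.n_regions)],
            "cohesion": coh,
            "disjointedness": dis,
        },
        index=pd.Index(assignments.region_ids, name="region_id"),
    )
    if atlas is not None:
        node.insert(0, "network", [atlas.label_of(r) for r in assignments.region_ids])
    g, nw = aggregate(node, atlas)
    return ReconfigMetrics(node, g, nw, T, K)


def aggregate(node_metrics: pd.DataFrame, atlas: AtlasLabels | None = None):
    """Unweighted global mean and per-network means of the node metrics.

    A network with zero member nodes gets NaN (flagged absent), never 0.
    """
    cols = [c for c in METRIC_NAMES if c in node_metrics.columns]
    global_means = node_metrics[cols].mean()
    if atlas is None and "network" not in node_metrics.columns:
        return global_means, pd.DataFrame(index=pd.Index(NETWORKS, name="network"), columns=cols, dtype=float)
    networks = (node_metrics["network"] if "network" in node_metrics.columns
                else pd.Series([atlas.label_of(r) for r in node_metrics.index], index=node_metrics.index))
    by_net = node_metrics[cols].groupby(networks).mean()
    network_means = by_net.reindex(list(NETWORKS))
    network_means.index.name = "network"
    return global_means, network_means


def subject_summary(metrics: ReconfigMetrics, subject_id: str) -> pd.DataFrame:
    """One-row summary: global and per-network means, keyed for statistics.

    Columns: ``global_<metric>`` and ``<network>_<metric>`` — the layout the
    statistics layer consumes, one row per subject.
    """
    row: dict = {}
    for m in METRIC_NAMES:
        row[f"global_{m}"] = metrics.global_means[m]
    for net in metrics.network_means.index:
        for m in METRIC_NAMES:
            row[f"{net}_{m}"] = metrics.network_means.loc[net, m]
    return pd.DataFrame(row, index=pd.Index([subject_id], name="subject_id"))
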