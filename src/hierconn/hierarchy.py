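"""Rich-club / feeder / peripheral node taxonomy and subnetwork metrics.

The classification is computed once, from the control group-average network,
and then applied unchanged to every subject and condition: rich-club nodes
are the top fraction (default 15%) of nodes by binary degree; feeder nodes
are the non-rich nodes with at least one retained connection to a rich node
in the source network; peripheral nodes are the rest.  The diverse club is
the analogous top fraction by participation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphmetrics import (
    CommunityPartition,
    degree_and_strength,
    detect_communities,
    global_efficiency,
    participation_coefficient,
)
from .netbuild import GroupNetwork, ThresholdedNetwork

__all__ = [
    "NodeClassification",
    "SubnetworkReport",
    "classify_nodes",
    "diverse_club",
    "diverse_subnetwork_metrics",
    "subnetwork_metrics",
    "reports_to_frame",
    "change_rates",
]

CLASSES = ("rich", "feeder", "peripheral")


@dataclass
class NodeClassification:
    labels: list[str]
    classes: np.ndarray  # per node: 'rich' | 'feeder' | 'peripheral'
    fraction: float
    source: str = "control_group_average"

    def __post_init__(self) -> None:
        if not set(np.unique(self.classes)) <= set(CLASSES):
            raise ValueError("unknown class label")

    def nodes_of(self, cls: str) -> np.ndarray:
        return np.flatnonzero(self.classes == cls)

    @property
    def rich(self) -> np.ndarray:
        return self.nodes_of("rich")

    @property
    def feeder(self) -> np.ndarray:
        return self.nodes_of("feeder")

    @property
    def peripheral(self) -> np.ndarray:
        return self.nodes_of("peripheral")


@dataclass
class SubnetworkReport:
    """Per-scan scalar metrics of the three class-induced subnetworks.

    Strengths are weight sums over edges inside a class; interactions are
    weight sums over between-class edges (rich-feeder and feeder-peripheral
    only); degree sums use each node's whole-network binary degree.  Edges
    between rich and peripheral nodes belong to no named subnetwork and are
    kept separately so that the edge-weight conservation identity

        sum of strengths + both interactions + rich_peripheral = total weight

    holds exactly.
    """

    strength_rich: float
    strength_feeder: float
    strength_peripheral: float
    eff_rich: float
    eff_feeder: float
    eff_peripheral: float
    degsum_rich: float
    degsum_feeder: float
    degsum_peripheral: float
    interaction_RF: float
    interaction_FP: float
    rich_peripheral: float
    total_weight: float

    FIELDS = (
        "strength_rich",
        "strength_feeder",
        "strength_peripheral",
        "eff_rich",
        "eff_feeder",
        "eff_peripheral",
        "degsum_rich",
        "degsum_feeder",
        "degsum_peripheral",
        "interaction_RF",
        "interaction_FP",
    )


def _ranked(primary: np.ndarray, secondary: np.ndarray) -> np.ndarray:
    """Indices sorted by descending primary, then descending secondary, then index."""
    n = primary.size
    return np.lexsort((np.arange(n), -secondary, -primary))


def classify_nodes(
    source: GroupNetwork, fraction: float = 0.15, centrality: str = "degree"
) -> NodeClassification:
    """Partition nodes into rich / feeder / peripheral from a source network.

    Rich nodes are the top ``floor(fraction * n)`` nodes by binary degree
    (ties broken by strength, then node index); on a 90-node network the
    default fraction yields 13 rich-club nodes.  ``centrality='strength'``
    ranks by weighted strength instead (ties broken by degree).
    """
    n = source.n_nodes
    n_rich = int(np.floor(fraction * n))
    if n_rich < 1:
        raise ValueError("fraction yields zero rich-club nodes")
    deg, stren = degree_and_strength(source)
    if centrality == "degree":
        rich = np.sort(_ranked(deg.astype(float), stren)[:n_rich])
    elif centrality == "strength":
        rich = np.sort(_ranked(stren, deg.astype(float))[:n_rich])
    else:
        raise ValueError("centrality must be 'degree' or 'strength'")
    classes = np.full(n, "peripheral", dtype=object)
    classes[rich] = "rich"
    non_rich = np.setdiff1d(np.arange(n), rich)
    touches_rich = (source.weights[np.ix_(non_rich, rich)] > 0).any(axis=1)
    classes[non_rich[touches_rich]] = "feeder"
    cls = NodeClassification(list(source.labels), classes.astype("U10"), fraction)
    assert cls.rich.size + cls.feeder.size + cls.peripheral.size == n
    return cls


def diverse_club(
    source: GroupNetwork,
    fraction: float = 0.15,
    partition: CommunityPartition | None = None,
    p: np.ndarray | None = None,
    resolution: float = 1.0,
    n_restarts: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, CommunityPartition, np.ndarray]:
    """Top fraction of nodes by participation coefficient on the source network.

    Returns (club node indices, community partition, per-node participation).
    Ties are broken by strength, then node index, as for the rich club.
    """
    n = source.n_nodes
    n_club = int(np.floor(fraction * n))
    if n_club < 1:
        raise ValueError("fraction yields zero diverse-club nodes")
    if partition is None:
        partition = detect_communities(source, resolution=resolution, n_restarts=n_restarts, seed=seed)
    if p is None:
        p = participation_coefficient(source, partition)
    _, stren = degree_and_strength(source)
    club = np.sort(_ranked(p, stren)[:n_club])
    return club, partition, p


def diverse_subnetwork_metrics(net: ThresholdedNetwork, club: np.ndarray) -> tuple[float, float]:
    """(connection strength, global efficiency) of the club-induced subgraph."""
    sub = net.weights[np.ix_(club, club)]
    return float(np.triu(sub, 1).sum()), global_efficiency(sub)


def subnetwork_metrics(net: ThresholdedNetwork, cls: NodeClassification) -> SubnetworkReport:
    """All per-scan subnetwork metrics under a fixed classification."""
    if net.labels != cls.labels:
        raise ValueError("network and classification node labels differ")
    w = net.weights
    deg = np.count_nonzero(w, axis=1)
    idx = {c: cls.nodes_of(c) for c in CLASSES}

    def block(a: np.ndarray, b: np.ndarray) -> float:
        return float(w[np.ix_(a, b)].sum())

    strengths = {c: float(np.triu(w[np.ix_(idx[c], idx[c])], 1).sum()) for c in CLASSES}
    effs = {
        c: global_efficiency(w[np.ix_(idx[c], idx[c])]) if idx[c].size >= 2 else 0.0
        for c in CLASSES
    }
    report = SubnetworkReport(
        strength_rich=strengths["rich"],
        strength_feeder=strengths["feeder"],
        strength_peripheral=strengths["peripheral"],
        eff_rich=effs["rich"],
        eff_feeder=effs["feeder"],
        eff_peripheral=effs["peripheral"],
        degsum_rich=float(deg[idx["rich"]].sum()),
        degsum_feeder=float(deg[idx["feeder"]].sum()),
        degsum_peripheral=float(deg[idx["peripheral"]].sum()),
        interaction_RF=block(idx["rich"], idx["feeder"]),
        interaction_FP=block(idx["feeder"], idx["peripheral"]),
        rich_peripheral=block(idx["rich"], idx["peripheral"]),
        total_weight=float(np.triu(w, 1).sum()),
    )
    # conservation: class strengths + interactions + rich-peripheral = total
    parts = (
        report.strength_rich
        + report.strength_feeder
        + report.strength_peripheral
        + report.interaction_RF
        + report.interaction_FP
        + report.rich_peripheral
    )
    assert abs(parts - report.total_weight) <= 1e-8 * max(1.0, report.total_weight)
    return report


def reports_to_frame(reports: dict[str, SubnetworkReport]) -> pd.DataFrame:
    """Tidy table: one row per scan id, one column per metric."""
    rows = {sid: vars(r).copy() for sid, r in reports.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df


def change_rates(off: pd.DataFrame, on: pd.DataFrame) -> pd.DataFrame:
    """Paired medication change rates per metric.

    ``change = (OFF - ON) / OFF`` and ``improvement = (ON - OFF) / OFF``;
    pairs with a zero OFF value get NaN and are excluded downstream.  The two
    inputs must be indexed by pair id with identical index sets.
    """
    if set(off.index) != set(on.index):
        raise ValueError("off/on pair ids differ")
    on = on.loc[off.index]
    with np.errstate(divide="ignore", invalid="ignore"):
        change = (off - on) / off.where(off != 0)
    out = pd.concat(
        {"change": change, "improvement": -change},
        axis=1,
    )
    return out
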