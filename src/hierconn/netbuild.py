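"""From time series to weighted connectomes.

Pipeline: Pearson correlation -> drop negative edges -> proportional
(density) thresholding -> optional consensus group average.  Thresholded
networks stay weighted; binary degree counts retained edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "ThresholdedNetwork",
    "GroupNetwork",
    "compute_fc",
    "threshold_proportional",
    "group_average",
    "expected_edge_count",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative weight matrix with zero diagonal."""

    weights: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if len(self.labels) != w.shape[0]:
            raise ValueError("label count must match matrix size")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class ThresholdedNetwork(ConnectivityMatrix):
    """Connectivity matrix kept at a fixed edge density (sparsity)."""

    sparsity: float = 1.0
    n_edges: int = 0
    truncated: bool = False  # fewer positive weights than the density asked for

    def degrees(self) -> np.ndarray:
        return np.count_nonzero(self.weights, axis=1)

    def strengths(self) -> np.ndarray:
        return self.weights.sum(axis=1)


@dataclass
class GroupNetwork(ThresholdedNetwork):
    """Consensus group average: mean over subjects in which each edge is present."""

    consensus: float = 0.6
    support: np.ndarray | None = None  # per-edge contributing-subject count


def expected_edge_count(n_nodes: int, sparsity: float) -> int:
    """Edges at a given density: round-half-away-from-zero of S*n(n-1)/2."""
    return int(np.floor(sparsity * n_nodes * (n_nodes - 1) / 2 + 0.5))


def compute_fc(ts: np.ndarray, labels: list[str] | None = None) -> ConnectivityMatrix:
    """Pearson functional connectivity of a node x time matrix.

    Negative correlations are omitted (set to zero) and the diagonal is
    zeroed, so the result is ready for proportional thresholding.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D node x time matrix")
    n_nodes, n_t = ts.shape
    if n_t < 3:
        raise ValueError("at least 3 timepoints are required")
    if np.isnan(ts).any():
        raise ValueError("time series contain NaN")
    if labels is None:
        labels = [f"node{i:03d}" for i in range(n_nodes)]
    sd = ts.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance time series at node(s): {[labels[i] for i in dead]}")
    w = np.corrcoef(ts)
    w = np.clip(w, 0.0, 1.0)
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2
    return ConnectivityMatrix(w, list(labels))


def threshold_proportional(mat: ConnectivityMatrix, sparsity: float) -> ThresholdedNetwork:
    """Keep the strongest positive edges at the requested density.

    The target edge count is ``round(S * n(n-1)/2)``; ties at the cutoff are
    broken by ascending (i, j) node-index order so the result is
    deterministic.  If fewer positive weights exist than the density asks
    for, all of them are kept and the network is flagged ``truncated``.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must be in (0, 1]")
    n = mat.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    w = mat.weights[iu, ju]
    target = expected_edge_count(n, sparsity)
    # sort by descending weight, then ascending (i, j)
    order = np.lexsort((ju, iu, -w))
    n_pos = int(np.count_nonzero(w > 0))
    kept = min(target, n_pos)
    truncated = kept < target
    if truncated:
        warnings.warn(
            f"only {n_pos} positive weights available for target {target} edges",
            stacklevel=2,
        )
    sel = order[:kept]
    out = np.zeros_like(mat.weights)
    out[iu[sel], ju[sel]] = w[sel]
    out = out + out.T
    return ThresholdedNetwork(out, list(mat.labels), sparsity=sparsity, n_edges=kept, truncated=truncated)


def group_average(nets: list[ThresholdedNetwork], proportion: float = 0.6) -> GroupNetwork:
    """Consensus group-average network.

    An edge is retained only if it is nonzero in at least ``proportion`` of
    the subjects; its weight is the mean over the subjects in which it is
    nonzero.
    """
    if len(nets) < 2:
        raise ValueError("need at least 2 networks")
    if not 0 < proportion <= 1:
        raise ValueError("proportion must be in (0, 1]")
    labels = nets[0].labels
    for net in nets[1:]:
        if net.labels != labels:
            raise ValueError("networks have mismatched node labels")
    stack = np.stack([net.weights for net in nets])
    support = np.count_nonzero(stack, axis=0)
    keep = support >= proportion * len(nets) - 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(keep & (support > 0), stack.sum(axis=0) / np.maximum(support, 1), 0.0)
    np.fill_diagonal(avg, 0.0)
    n_edges = int(np.count_nonzero(np.triu(avg, 1)))
    sparsity = n_edges / (len(labels) * (len(labels) - 1) / 2)
    return GroupNetwork(
        avg,
        list(labels),
        sparsity=sparsity,
        n_edges=n_edges,
        consensus=proportion,
        support=support,
    )


def write_matrix_tsv(mat: ConnectivityMatrix, path: str | Path) -> None:
    header = "\t".join(mat.labels)
    np.savetxt(path, mat.weights, delimiter="\t", fmt="%.8g", header=header, comments="")


def read_matrix_tsv(path: str | Path) -> ConnectivityMatrix:
    """Square TSV with a header row of node labels."""
    with open(path) as fh:
        labels = fh.readline().rstrip("\n").split("\t")
    w = np.loadtxt(path, delimiter="\t", skiprows=1)
    return ConnectivityMatrix(np.atleast_2d(w), labels)
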