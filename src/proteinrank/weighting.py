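"""Stage 1: fold-change-biased impact values and the weighted network.

Differentially expressed proteins (DEPs) carry raw — not log-transformed —
abundance fold changes from a quantitative proteomics experiment.  These
bias the start distribution of a restart walk whose stationary values
p(v_i) measure each protein's impact on the network under the measured
expression context.  Edge weights are then set to

    w_ij = p(v_j) / sum_{l in N_i} p(v_l)      for j in N_i,

so each node distributes its outgoing weight over its neighbors in
proportion to their impact; larger-impact neighbors attract more weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network import PPINetwork, TransitionMatrix, column_normalize
from .propagation import StationaryVector, WalkConfig, rwr

__all__ = [
    "FoldChangeTable",
    "WeightedNetwork",
    "read_fold_changes",
    "fold_changes_to_start_vector",
    "compute_impact",
    "build_weighted_network",
    "weighted_transition",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldChangeTable:
    """Protein id -> raw fold change.  Values in (0, 1) mean down-regulation."""

    entries: dict[str, float]

    def __post_init__(self) -> None:
        for pid, fc in self.entries.items():
            if not np.isfinite(fc) or fc <= 0:
                raise ValueError(
                    f"fold change for {pid!r} must be a positive finite raw "
                    f"ratio, got {fc}"
                )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class WeightedNetwork:
    """Impact-weighted adjacency; row i is normalized over i's neighborhood."""

    matrix: sp.csr_matrix


def read_fold_changes(path) -> FoldChangeTable:
    """Read a TSV with header columns ``protein_id`` and ``fold_change``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("protein_id", "fold_change"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    ids = df["protein_id"].astype(str)
    if ids.duplicated().any():
        dups = ids[ids.duplicated()].tolist()[:5]
        raise ValueError(f"{path}: duplicate protein ids: {dups}")
    return FoldChangeTable(entries=dict(zip(ids, df["fold_change"].astype(float))))


def write_fold_changes(fc: FoldChangeTable, path) -> None:
    pd.DataFrame(
        {"protein_id": list(fc.entries), "fold_change": list(fc.entries.values())}
    ).to_csv(path, sep="\t", index=False)


def fold_changes_to_start_vector(
    net: PPINetwork, fc: FoldChangeTable, mode: str = "raw"
) -> np.ndarray:
    """Build the biased start distribution p0 from DEP fold changes.

    mode="raw" uses the fold changes as given; mode="symmetric" replaces
    each f with max(f, 1/f) so that a 2-fold decrease contributes the same
    start mass as a 2-fold increase.  Proteins absent from the network are
    dropped with a logged count.
    """
    if mode not in ("raw", "symmetric"):
        raise ValueError(f"unknown fold-change mode {mode!r}")
    p0 = np.zeros(net.n_nodes)
    unmatched = []
    for pid, f in fc.entries.items():
        if pid in net:
            p0[net.index_of(pid)] = max(f, 1.0 / f) if mode == "symmetric" else f
        else:
            unmatched.append(pid)
    if unmatched:
        log.info(
            "%d of %d fold-change proteins absent from the network; dropped",
            len(unmatched), len(fc),
        )
    total = p0.sum()
    if total == 0:
        raise ValueError("no fold-change protein matches the network")
    return p0 / total


def compute_impact(
    net: PPINetwork, p0: np.ndarray, cfg: WalkConfig
) -> StationaryVector:
    """Stage-1 walk: propagate DEP fold changes over the unweighted network."""
    return rwr(column_normalize(net), p0, cfg)


def build_weighted_network(net: PPINetwork, impact: np.ndarray) -> WeightedNetwork:
    """Re-weight each edge by the impact of its target node.

    w_ij = p(v_j) / sum over i's neighbors of p(v_l); weights on i's
    out-edges sum to one.  Invariant under rescaling of the impact values.
    """
    impact = np.asarray(impact, dtype=float).ravel()
    if impact.shape[0] != net.n_nodes:
        raise ValueError("impact vector length does not match network size")
    if np.any(impact < 0) or not np.all(np.isfinite(impact)):
        raise ValueError("impact values must be nonnegative and finite")
    neighborhood_sum = np.asarray(net.adjacency @ impact).ravel()
    if np.any(neighborhood_sum <= 0):
        bad = net.node_ids[int(np.flatnonzero(neighborhood_sum <= 0)[0])]
        raise ValueError(
            f"zero total impact over the neighborhood of {bad!r}; "
            "cannot normalize edge weights"
        )
    # W = D^{-1} A diag(impact), rows normalized over each neighborhood
    w = sp.diags(1.0 / neighborhood_sum) @ net.adjacency @ sp.diags(impact)
    return WeightedNetwork(matrix=w.tocsr())


def weighted_transition(wn: WeightedNetwork, norm: str = "column") -> TransitionMatrix:
    """Turn the weighted matrix into a column-stochastic transition matrix.

    The walk convention throughout the package is ``p <- W p`` with
    W[i, j] the probability of stepping from j to i, so column j must hold
    node j's out-distribution.  norm="column" (default) therefore
    transposes the row-normalized weight matrix — a walker at i moves to
    neighbor j with probability w_ij — which is exactly column-stochastic
    and reduces to plain degree normalization under uniform impact.
    norm="row" instead reads w_ij as an affinity of j for i and
    column-renormalizes without transposing; provided for sensitivity
    checks, it does not satisfy the uniform-impact reduction exactly.
    """
    m = wn.matrix
    if norm == "column":
        out = m.T.tocsr()
        sums = np.asarray(out.sum(axis=0)).ravel()
        if np.any(sums <= 0):
            raise ValueError("weighted matrix has a zero neighborhood")
        if np.abs(sums - 1.0).max() > 1e-9:  # defensive; rows of w sum to 1
            out = (out @ sp.diags(1.0 / sums)).tocsr()
    elif norm == "row":
        sums = np.asarray(m.sum(axis=0)).ravel()
        if np.any(sums <= 0):
            raise ValueError("weighted matrix has a zero column")
        out = (m @ sp.diags(1.0 / sums)).tocsr()
    else:
        raise ValueError(f"unknown normalization {norm!r}")
    return TransitionMatrix(matrix=out)
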