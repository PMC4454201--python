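"""Stages 2–3: impact vectors, PCC similarity, rank scores, permutation p.

Every node u gets an *impact vector* p_u — the stationary distribution of a
restart walk started from the unit vector e_u on the (weighted) network.
Candidates are ranked by the sum over seed proteins of the absolute Pearson
correlation between impact vectors:

    RankScore(i) = sum_{v in seeds} | Corr(p_i, p_v) |,   range [0, k].

Seeds are scored against the full seed set including themselves, so a
seed's self-correlation contributes exactly 1 and seed scores may exceed 1.
Significance comes from a permutation null: random seed sets of matched
size, with an add-one correction keeping p in (0, 1].
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import PPINetwork, TransitionMatrix, column_normalize
from .propagation import WalkConfig, impact_vector_matrix
from .weighting import (
    FoldChangeTable,
    build_weighted_network,
    compute_impact,
    fold_changes_to_start_vector,
    weighted_transition,
)

__all__ = [
    "ImpactVectorSet",
    "SeedSet",
    "RankResult",
    "read_seed_list",
    "compute_impact_vectors",
    "impact_vector",
    "pcc",
    "rank_score",
    "prioritize",
    "permutation_pvalue",
    "write_rank_result",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeedSet:
    """Known drug-resistance proteins used as the reference set."""

    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("seed set is empty")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("seed ids are not unique")

    @property
    def k(self) -> int:
        return len(self.ids)

    def restrict_to(self, net: PPINetwork) -> "SeedSet":
        """Drop seeds absent from the network, logging how many."""
        present = tuple(s for s in self.ids if s in net)
        dropped = [s for s in self.ids if s not in net]
        if dropped:
            log.info("%d seed(s) absent from the network; dropped: %s",
                     len(dropped), dropped)
        if not present:
            raise ValueError("no seed protein is present in the network")
        return SeedSet(ids=present)


def read_seed_list(path) -> SeedSet:
    """One protein id per line; '#' comments and blank lines ignored."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line.split()[0])
    if not ids:
        raise ValueError(f"{path}: no seed identifiers found")
    return SeedSet(ids=tuple(dict.fromkeys(ids)))


class ImpactVectorSet:
    """All impact vectors of a network, with standardized columns cached.

    Column u of ``matrix`` is node u's impact vector; ``zscores`` holds the
    per-column standardization used for fast pairwise Pearson correlation.
    """

    def __init__(self, node_ids: tuple[str, ...], matrix: np.ndarray,
                 restart_prob: float, network_digest: str):
        self.node_ids = node_ids
        self.matrix = matrix
        self.restart_prob = restart_prob
        self.network_digest = network_digest
        self._index = {v: i for i, v in enumerate(node_ids)}
        n = matrix.shape[0]
        mean = matrix.mean(axis=0)
        std = matrix.std(axis=0)
        if np.any(std == 0):
            bad = node_ids[int(np.flatnonzero(std == 0)[0])]
            raise ValueError(
                f"impact vector of {bad!r} is constant; Pearson correlation "
                "is undefined"
            )
        self.zscores = (matrix - mean) / std
        self._n = n

    @property
    def n(self) -> int:
        return self._n

    def index_of(self, node_id: str) -> int:
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(f"no impact vector for {node_id!r}") from None

    def vector(self, node_id: str) -> np.ndarray:
        return self.matrix[:, self.index_of(node_id)]

    def abs_corr(self, candidates: np.ndarray, others: np.ndarray) -> np.ndarray:
        """|PCC| between every candidate column and every other column."""
        z = self.zscores
        return np.abs(z[:, candidates].T @ z[:, others]) / self._n


def _digest(transition: TransitionMatrix, node_ids) -> str:
    h = hashlib.sha1()
    h.update("\n".join(node_ids).encode())
    h.update(np.ascontiguousarray(transition.matrix.tocoo().data).tobytes())
    return h.hexdigest()[:16]


def compute_impact_vectors(
    net: PPINetwork,
    fc: FoldChangeTable | None,
    cfg: WalkConfig,
    fc_mode: str = "raw",
    stage2_norm: str = "column",
) -> ImpactVectorSet:
    """Impact vectors for every node, on the weighted or unweighted network.

    With ``fc`` given, runs the full stage-1 pipeline (biased walk → impact
    values → impact-weighted transition matrix) before computing the
    vectors; with ``fc=None`` the vectors are computed on the plain
    degree-normalized network, which is the topological baseline.
    """
    if fc is None:
        wt = column_normalize(net)
    else:
        p0 = fold_changes_to_start_vector(net, fc, mode=fc_mode)
        impact = compute_impact(net, p0, cfg).values
        wt = weighted_transition(build_weighted_network(net, impact), norm=stage2_norm)
    mat = impact_vector_matrix(wt, cfg.restart_prob)
    return ImpactVectorSet(
        node_ids=net.node_ids,
        matrix=mat,
        restart_prob=cfg.restart_prob,
        network_digest=_digest(wt, net.node_ids),
    )


def impact_vector(u: str, wt: TransitionMatrix, node_ids, cfg: WalkConfig) -> np.ndarray:
    """Single impact vector: restart walk from e_u on ``wt``."""
    node_ids = tuple(node_ids)
    if u not in node_ids:
        raise KeyError(f"unknown protein identifier: {u!r}")
    from .propagation import rwr

    p0 = np.zeros(len(node_ids))
    p0[node_ids.index(u)] = 1.0
    return rwr(wt, p0, cfg).values


def pcc(pu: np.ndarray, pv: np.ndarray) -> float:
    """Pearson correlation over all entries of two impact vectors."""
    pu = np.asarray(pu, float).ravel()
    pv = np.asarray(pv, float).ravel()
    if pu.shape != pv.shape or pu.size < 2:
        raise ValueError("vectors must share a common length >= 2")
    su, sv = pu.std(), pv.std()
    if su == 0 or sv == 0:
        raise ValueError("Pearson correlation is undefined for a constant vector")
    return float(((pu - pu.mean()) * (pv - pv.mean())).mean() / (su * sv))


def rank_score(candidate: str, ivs: ImpactVectorSet, seeds: SeedSet) -> float:
    """Sum over seeds of |PCC| with the candidate's impact vector."""
    ci = np.array([ivs.index_of(candidate)])
    si = np.array([ivs.index_of(s) for s in seeds.ids])
    return float(ivs.abs_corr(ci, si).sum())


def _scores_for(ivs: ImpactVectorSet, candidate_idx: np.ndarray,
                seed_idx: np.ndarray) -> np.ndarray:
    return ivs.abs_corr(candidate_idx, seed_idx).sum(axis=1)


@dataclass(frozen=True)
class RankResult:
    """Ranked table: rank, protein_id, rank_score, p_value, is_seed."""

    table: pd.DataFrame
    k: int
    method: str = "proteinrank"

    def score_of(self, protein_id: str) -> float:
        row = self.table.loc[self.table["protein_id"] == protein_id]
        if row.empty:
            raise KeyError(protein_id)
        return float(row["rank_score"].iloc[0])


def _rank_table(node_ids, scores: np.ndarray, seed_ids: set,
                p_values: np.ndarray | None) -> pd.DataFrame:
    df = pd.DataFrame({
        "protein_id": list(node_ids),
        "rank_score": scores,
        "is_seed": [v in seed_ids for v in node_ids],
    })
    if p_values is not None:
        df["p_value"] = p_values
    # stable tie-break: score descending, then id ascending
    df = df.sort_values(
        ["rank_score", "protein_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    cols = ["rank", "protein_id", "rank_score"]
    if p_values is not None:
        cols.append("p_value")
    cols.append("is_seed")
    return df[cols]


def prioritize(
    net: PPINetwork,
    fc: FoldChangeTable | None,
    seeds: SeedSet,
    cfg: WalkConfig = WalkConfig(),
    n_permutations: int = 0,
    rng_seed: int = 0,
    fc_mode: str = "raw",
    stage2_norm: str = "column",
    ivs: ImpactVectorSet | None = None,
) -> RankResult:
    """Full pipeline: impact values → weighted network → vectors → ranking.

    Every network node is scored, seeds included.  A precomputed
    ``ivs`` may be supplied to amortize the vector computation across
    repeated rankings on the same network and fold changes.
    """
    seeds = seeds.restrict_to(net)
    if ivs is None:
        ivs = compute_impact_vectors(net, fc, cfg, fc_mode=fc_mode,
                                     stage2_norm=stage2_norm)
    n = ivs.n
    all_idx = np.arange(n)
    seed_idx = np.array([ivs.index_of(s) for s in seeds.ids])
    scores = _scores_for(ivs, all_idx, seed_idx)
    p_values = None
    if n_permutations > 0:
        p_values = _permutation_pvalues_all(ivs, scores, seeds.k,
                                            n_permutations, rng_seed)
    table = _rank_table(ivs.node_ids, scores, set(seeds.ids), p_values)
    return RankResult(table=table, k=seeds.k,
                      method="proteinrank" if fc is not None else "topological")


def _null_scores(abs_corr_row: np.ndarray, candidate_idx: int, k: int,
                 n_permutations: int, rng: np.random.Generator) -> np.ndarray:
    n = abs_corr_row.shape[0]
    if k >= n:
        raise ValueError(f"seed-set size k={k} must be < network size {n}")
    pool = np.delete(np.arange(n), candidate_idx)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        pick = rng.choice(pool, size=k, replace=False)
        null[b] = abs_corr_row[pick].sum()
    return null


def permutation_pvalue(
    observed_score: float,
    candidate: str,
    ivs: ImpactVectorSet,
    k: int,
    n_permutations: int,
    rng_seed: int,
) -> float:
    """Add-one-corrected permutation p: random size-k seed sets as the null.

    p = (1 + #{null >= observed}) / (1 + n_permutations); the candidate is
    excluded from the null draws.  Deterministic given ``rng_seed``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    ci = ivs.index_of(candidate)
    row = ivs.abs_corr(np.array([ci]), np.arange(ivs.n)).ravel()
    rng = np.random.default_rng(rng_seed)
    null = _null_scores(row, ci, k, n_permutations, rng)
    return float((1 + np.sum(null >= observed_score)) / (1 + n_permutations))


def _permutation_pvalues_all(ivs: ImpactVectorSet, scores: np.ndarray, k: int,
                             n_permutations: int, rng_seed: int) -> np.ndarray:
    n = ivs.n
    A = ivs.abs_corr(np.arange(n), np.arange(n))
    rng = np.random.default_rng(rng_seed)
    p = np.empty(n)
    for ci in range(n):
        null = _null_scores(A[ci], ci, k, n_permutations, rng)
        p[ci] = (1 + np.sum(null >= scores[ci])) / (1 + n_permutations)
    return p


def write_rank_result(result: RankResult, path, precision: str = "table") -> None:
    """Write the ranked TSV; scores to 4 decimals unless precision='full'."""
    df = result.table.copy()
    if precision == "table":
        df["rank_score"] = df["rank_score"].map(lambda x: f"{x:.4f}")
        if "p_value" in df:
            df["p_value"] = df["p_value"].map(lambda x: f"{x:.4f}")
    elif precision != "full":
        raise ValueError(f"unknown precision {precision!r}")
    df.to_csv(path, sep="\t", index=False)
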