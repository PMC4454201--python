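"""Synthetic networks with a planted drug-resistance module.

The generator emulates the study's three inputs — a binary PPI network, a
table of differentially expressed proteins (DEPs) with raw fold changes,
and a list of known seed proteins — with a known ground truth: a densely
wired module whose members carry elevated fold changes.  Some module
members are declared as known seeds; the rest are the hidden truth a
prioritizer should recover.

Fold changes are lognormal: raw abundance ratios are positive and
multiplicative, so noise is modeled on the log scale (sd ``fc_noise_sd``
around 1.0 for background proteins, around ``fc_signal`` inside the
module).  Only proteins whose |log2 fold change| exceeds a threshold enter
the DEP table, emulating upstream differential-expression calling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .network import PPINetwork, build_network, write_edge_list
from .ranking import SeedSet
from .weighting import FoldChangeTable, write_fold_changes

__all__ = ["SyntheticSpec", "generate", "write_fixture"]

_MODEL_DEFAULTS = {
    "erdos_renyi": {"p": 0.03},
    "scale_free": {"m": 2},
    "modular": {"n_blocks": 6, "p_intra": 0.15, "p_inter": 0.01},
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic study; fully determined by ``rng_seed``.

    ``fc_signal`` is the geometric-mean raw fold change inside the planted
    module (3.0 by default, a strong but realistic proteomic effect);
    ``fc_noise_sd`` the lognormal sd of all fold changes; ``module_density``
    the probability of each extra within-module edge beyond the spanning
    tree that keeps the module connected.
    """

    n_nodes: int = 300
    model: str = "scale_free"
    model_params: dict = field(default_factory=dict)
    module_size: int = 30
    module_density: float = 0.3
    fc_signal: float = 3.0
    fc_noise_sd: float = 0.25
    n_seeds: int = 10
    dep_log2_threshold: float = 0.585
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in _MODEL_DEFAULTS:
            raise ValueError(f"unknown model {self.model!r}")
        if not 0 < self.module_size <= self.n_nodes:
            raise ValueError("module_size must be in (0, n_nodes]")
        if not 0 < self.n_seeds <= self.module_size:
            raise ValueError("n_seeds must be in (0, module_size]")
        if self.fc_signal <= 0:
            raise ValueError("fc_signal must be positive")
        if self.fc_noise_sd < 0:
            raise ValueError("fc_noise_sd must be nonnegative")

    def params(self) -> dict:
        return {**_MODEL_DEFAULTS[self.model], **self.model_params}


def _base_graph(spec: SyntheticSpec, seed: int) -> nx.Graph:
    p = spec.params()
    if spec.model == "erdos_renyi":
        return nx.gnp_random_graph(spec.n_nodes, p["p"], seed=seed)
    if spec.model == "scale_free":
        return nx.barabasi_albert_graph(spec.n_nodes, p["m"], seed=seed)
    sizes = np.full(p["n_blocks"], spec.n_nodes // p["n_blocks"])
    sizes[: spec.n_nodes % p["n_blocks"]] += 1
    probs = np.full((p["n_blocks"], p["n_blocks"]), p["p_inter"])
    np.fill_diagonal(probs, p["p_intra"])
    return nx.stochastic_block_model(sizes.tolist(), probs.tolist(), seed=seed)


def _label(i: int, width: int) -> str:
    return f"P{i:0{width}d}"


def generate(
    spec: SyntheticSpec,
) -> tuple[PPINetwork, FoldChangeTable, SeedSet, frozenset[str]]:
    """Generate (network, DEP fold changes, known seeds, hidden truth)."""
    rng = np.random.default_rng(spec.rng_seed)
    g = _base_graph(spec, seed=int(rng.integers(2**31)))
    width = max(4, len(str(spec.n_nodes - 1)))
    edges = {
        tuple(sorted((_label(u, width), _label(v, width))))
        for u, v in g.edges()
        if u != v
    }

    module_idx = rng.choice(spec.n_nodes, size=spec.module_size, replace=False)
    module = [_label(int(i), width) for i in module_idx]
    # random recursive tree keeps the module connected ...
    for pos in range(1, len(module)):
        anchor = module[int(rng.integers(pos))]
        edges.add(tuple(sorted((module[pos], anchor))))
    # ... plus extra internal edges at the requested density
    for a in range(len(module)):
        for b in range(a + 1, len(module)):
            if rng.random() < spec.module_density:
                edges.add(tuple(sorted((module[a], module[b]))))

    net = build_network(sorted(edges))
    module_set = frozenset(m for m in module if m in net)
    if len(module_set) != spec.module_size:
        raise RuntimeError("planted module lost members; spec unsatisfiable")

    log_fc = rng.normal(0.0, spec.fc_noise_sd, size=net.n_nodes)
    for m in module_set:
        log_fc[net.index_of(m)] += np.log(spec.fc_signal)
    fold = np.exp(log_fc)
    is_dep = np.abs(np.log2(fold)) > spec.dep_log2_threshold
    if not is_dep.any():
        warnings.warn(
            "no protein passes the DEP threshold; fold-change table is empty "
            "(degenerate spec, e.g. fc_signal=1 with fc_noise_sd=0)",
            UserWarning,
            stacklevel=2,
        )
    fc = FoldChangeTable(entries={
        net.node_ids[i]: float(fold[i]) for i in np.flatnonzero(is_dep)
    })

    seed_ids = tuple(
        rng.choice(sorted(module_set), size=spec.n_seeds, replace=False)
    )
    hidden = module_set - set(seed_ids)
    return net, fc, SeedSet(ids=seed_ids), hidden


def write_fixture(
    directory,
    net: PPINetwork,
    fc: FoldChangeTable,
    seeds: SeedSet,
    hidden_truth: frozenset[str],
) -> dict[str, Path]:
    """Write the four fixture files in the dialects the readers consume."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": directory / "network.tsv",
        "fold_changes": directory / "fold_changes.tsv",
        "seeds": directory / "seeds.txt",
        "truth": directory / "truth.txt",
    }
    write_edge_list(net, paths["network"])
    write_fold_changes(fc, paths["fold_changes"])
    with open(paths["seeds"], "w") as fh:
        fh.write("# known seed proteins\n")
        for s in seeds.ids:
            fh.write(s + "\n")
    with open(paths["truth"], "w") as fh:
        fh.write("# hidden planted-module members\n")
        for s in sorted(hidden_truth):
            fh.write(s + "\n")
    return paths
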