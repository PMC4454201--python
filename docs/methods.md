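# Methods

## Model

The package treats a binary, undirected PPI network as the state space of
a random walk with restart (RWR).  For a column-stochastic transition
matrix `W`, restart probability `r` and start distribution `p0`, the walk

    p(t+1) = (1 − r)·W·p(t) + r·p0

is a contraction (factor `1 − r` in L1), so its fixed point
`p = r·(I − (1−r)W)⁻¹·p0` exists and is unique for every `r > 0`; the
iterative solver and the sparse-LU direct solver are interchangeable
backends for the same object, and the direct solve is used whenever many
walks run on one network (one factorization, `n` triangular solves).

The ranking pipeline composes three uses of this walk:

1. *Impact values* — start mass proportional to DEP raw fold changes on
   the degree-normalized network.  Raw (not log) ratios are used: the
   start vector only needs relative magnitudes, and raw ratios keep
   up-regulated proteins' mass proportional to their measured change.  A
   consequence is that down-regulated DEPs (ratio < 1) contribute *less*
   start mass than up-regulated ones of equal magnitude; the `symmetric`
   fold-change mode (`f → max(f, 1/f)`) is provided for studies where
   down-regulation should count equally, and each run's manifest records
   which mode was used.
2. *Edge weighting* — `w_ij = p(v_j) / Σ_{l∈N_i} p(v_l)` over each node's
   neighborhood.  This is the minimal rule with the required properties:
   weights normalize over the neighborhood, are invariant to rescaling of
   the impact values, and increase monotonically with the target's
   impact.
3. *Impact vectors and scoring* — one walk per node from its unit vector
   on the weighted network; candidates scored by summed |Pearson
   correlation| with the seed vectors over all `n` entries (no masking of
   the self entry).  Seeds are scored against the full seed set including
   themselves, so a seed's score is at least 1 and the score range is
   `[0, k]`; a flag `exclude-self` reading is deliberately not the
   default because ranked tables that include seeds are only consistent
   with the self term present.

### Orientation of the weighted walk

The package fixes one convention everywhere: `W` acts on probability
*columns*, so entry `(i, j)` is the probability of stepping from `j` to
`i`.  The weight matrix `w` is row-normalized by construction (`w_ij` is
the probability that a walker at `i` moves to `j`), so the
column-stochastic matrix of the weighted walk is exactly its transpose —
no renormalization is needed, mass is conserved, and under uniform impact
values the weighted walk collapses *identically* to the degree-normalized
walk.  The alternative reading (treating `w_ij` as an affinity of `j` for
`i` and renormalizing columns without transposing) is kept behind
`stage2_norm="row"` for sensitivity analysis; it does not satisfy the
uniform-impact reduction exactly and is not the default.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `restart_prob` | 0.4 | per-step restart probability of every walk; the value used throughout the original drug-resistance study.  No selection rule is implemented — it is a plain configuration knob. |
| `tol` | 1e-10 | L1 convergence threshold; tight enough that rank scores are stable to 4 decimals.  Non-convergence warns, never silently returns. |
| `max_iter` | 1000 | iteration cap; with `r = 0.4` convergence takes ~60 iterations, so the cap is generous. |
| `fc_mode` | `raw` | fold-change handling (see above). |
| `stage2_norm` | `column` | orientation of the weighted walk (see above). |
| permutation `p` | add-one | `p = (1 + #{null ≥ obs}) / (1 + B)` over `B` random size-`k` seed sets excluding the candidate; keeps `p ∈ (0, 1]` and is conservative. |

## Evaluation protocol

Leave-one-out: each seed is hidden among 99 controls drawn uniformly from
the non-seed nodes, scored against the remaining `k − 1` seeds, and its
1-based rank among the 100 recorded.  Ties are resolved against the seed
(it takes the worse rank).  Controls are drawn per held-out seed, keyed
deterministically by `(rng_seed, held-out id)`; this makes paired
comparisons exact — two methods, or the with/without arms of the
false-seed experiment, see byte-identical test lists — while remaining a
single-seed reproducible protocol.

Sensitivity at threshold `t` is the fraction of held-out seeds with rank
ratio ≤ `t`; specificity is the fraction of *controls* ranked below `t`.
Because the controls occupy every rank except the seed's, their rank
distribution is derived exactly from the recorded seed ranks; AUC is the
trapezoid area over 101 thresholds (step 0.01, matching the granularity
of a 100-protein list).  Under this control-based definition a
perfect-ranking run (every seed first) gives AUC exactly 1.0, and
uniformly spread seed ranks give exactly 0.5.  MRR is the mean rank
ratio.

Impact vectors depend only on the network and fold changes — not on the
seed set — so one vector set is computed per study and shared across all
LOO rounds and both methods.

## Synthetic studies

The generator emulates the study's three inputs with a known answer.  A
base graph (Barabási–Albert `m = 2` by default, matching the heavy-tailed
degree structure of real PPI networks; Erdős–Rényi and a
stochastic-block "modular" model are also available) receives a planted
module: `module_size` random nodes wired by a random recursive tree (so
the module is always connected) plus extra internal edges with
probability `module_density` (0.3 by default).  Fold changes are
lognormal — raw ratios are positive and multiplicative, so noise lives on
the log scale — with sd 0.25 everywhere and geometric mean `fc_signal`
(3.0) inside the module.  Proteins with `|log2 fc| > 0.585` (1.5-fold)
enter the DEP table, emulating upstream DEP calling; `n_seeds` module
members are revealed as seeds and the rest are the hidden truth.

Recovery benchmarks use the modular base model: its equally dense
background blocks are decoys that topology alone cannot separate from
the planted module, so the benchmark measures what the fold-change signal
adds.  At the default `module_density` the planted module is also
topologically strong, which makes the topological baseline genuinely
competitive — the paired AUC margin of the weighted method is therefore
modest by design rather than inflated by a strawman baseline.

What the generator does *not* emulate: iTRAQ channel noise structure,
peptide-level quantitation, identifier mapping noise, or the extreme
degree skew and size (~10⁴ nodes) of curated human interactomes.  Passing
benchmarks here show the machinery is correct and calibrated, not that
real-data performance will match any particular published figure.

Two statistical checks deserve a note:

- *Null AUC.*  With `fc_signal = 1` and random seed sets, LOO AUC is
  0.5 in expectation; the acceptance surface asserts the mean over 30
  replicate studies within ±0.06.  On *signal-carrying* fixtures the
  random-seed control typically falls below 0.5: high-impact module
  proteins appear among the controls and outrank random seeds, the same
  below-chance behaviour the original study reported for its random-seed
  control on real data.
- *Permutation-p uniformity.*  Within one study all candidates are
  compared against the same single seed-set draw, so their p-values are
  strongly correlated and a one-study Kolmogorov–Smirnov test has an
  effective sample size of a few, not hundreds.  Uniformity is therefore
  checked across independent null studies (one candidate each, 400
  studies), which tests the marginal distribution the p-value actually
  promises.

## Numerical choices and degenerate inputs

- Iterative/direct backends agree to < 1e-8 (L1) by construction; both
  are exercised against each other in the tests.
- Rank-table ties break by protein id (ascending) after score
  (descending), so output is bit-reproducible.
- Isolated nodes are dropped at network load (a node appearing only in a
  removed self-loop counts as isolated); every remaining node has degree
  ≥ 1, so the column normalization never divides by zero and no
  teleportation patch is needed.
- Disconnected networks are allowed: a walk started in one component
  assigns exactly zero mass elsewhere.  A constant impact vector (never
  observed on valid inputs, since the restart floor pins the start node's
  entry at ≥ r) raises an explicit error rather than producing NaN
  correlations.
- The full impact-vector set is materialized densely (`n × n`), which is
  the right trade-off up to a few thousand nodes; interactome-scale runs
  (~10⁴ nodes, ~1 GB) remain feasible but memory-bound.
- Problem sizes in the shipped benchmarks (300-node studies, 50-node
  oracle comparisons, 20–400 replicates) were chosen so the whole suite
  and the acceptance script each run in well under a minute while leaving
  the statistical assertions comfortable margins.

## Known limitations

- The edge-weighting rule is reconstructed from the method's stated
  constraints (neighborhood normalization, monotonicity in the target's
  impact); plausible variants (e.g. symmetric weighting by both
  endpoints' impacts) are not implemented.
- The permutation scheme (random matched-size seed sets) is a standard,
  conservative choice; published p-values produced by other null
  constructions are not directly comparable.
- No identifier mapping: joining DEP tables and seed lists to network
  identifiers is the caller's responsibility, and unmatched identifiers
  are dropped with a logged count rather than resolved.
- Reproducing published interactome-scale figures requires the external
  network and supplementary tables those figures were computed on; the
  CLI `rank`/`validate` commands are the drivers for such runs.
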