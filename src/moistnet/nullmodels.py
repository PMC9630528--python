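"""Null-model comparison of motif abundance.

Two ensembles quantify how strongly the backbone is organized in motifs:

* ``density_matched_random``: directed Erdős–Rényi-type graphs with the same
  node and edge count, edges drawn uniformly without replacement;
* ``degree_preserving_rewire``: the observed network with 10·m accepted
  pairwise edge swaps per replicate, preserving every node's in- and
  out-degree.

Observed per-type motif totals (FFL occurrences, reciprocal pairs, NBr
occurrences, pattern mode) are compared with the null mean/sd, and the ratio
observed / null-mean is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .backbone import MoistureNetwork
from .census import census, degrees
from .errors import ParameterError

__all__ = ["NullModelSummary", "null_model_compare", "density_matched_random",
           "degree_preserving_rewire", "NULL_MODELS"]

NULL_MODELS = ("density_matched_random", "degree_preserving_rewire")


@dataclass
class NullModelSummary:
    model: str
    replicates: int
    seed: int
    observed: dict[str, int]
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    ratio: dict[str, float]
    # per-replicate motif totals, kept for dispersion diagnostics
    replicate_totals: dict[str, np.ndarray]


def density_matched_random(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly draw m distinct ordered pairs (no self-loops) on n nodes."""
    n_pairs = n * (n - 1)
    if m > n_pairs:
        raise ParameterError(f"cannot place {m} edges on {n} nodes")
    flat = rng.choice(n_pairs, size=m, replace=False)
    src, rem = np.divmod(flat, n - 1)
    tgt = rem + (rem >= src)  # skip the diagonal
    return np.column_stack([src, tgt]).astype(np.int64)


def degree_preserving_rewire(
    edges: np.ndarray,
    rng: np.random.Generator,
    n_swaps: int | None = None,
    max_proposals: int | None = None,
) -> tuple[np.ndarray, int]:
    """Rewire by accepted pairwise swaps (a->b, c->d) => (a->d, c->b).

    Swaps that would create a self-loop or a duplicate edge are rejected.
    Returns the rewired edge array and the number of accepted swaps; if the
    proposal budget runs out first, the achieved count is returned (the
    caller decides whether to warn).
    """
    edges = np.asarray(edges, dtype=np.int64).copy()
    m = edges.shape[0]
    if m < 2:
        return edges, 0
    if n_swaps is None:
        n_swaps = 10 * m
    if max_proposals is None:
        max_proposals = 100 * n_swaps
    present = {(int(s), int(t)) for s, t in edges}
    accepted = 0
    proposals = 0
    while accepted < n_swaps and proposals < max_proposals:
        budget = min(4 * (n_swaps - accepted) + 16, max_proposals - proposals)
        idx = rng.integers(0, m, size=(budget, 2))
        for i, j in idx:
            proposals += 1
            if i == j:
                continue
            a, b = edges[i]
            c, d = edges[j]
            if a == d or c == b:
                continue
            if (a, d) in present or (c, b) in present:
                continue
            present.discard((a, b))
            present.discard((c, d))
            present.add((a, d))
            present.add((c, b))
            edges[i, 1] = d
            edges[j, 1] = b
            accepted += 1
            if accepted >= n_swaps:
                break
    return edges, accepted


def _motif_totals(net: MoistureNetwork) -> dict[str, int]:
    cen = census(net, "pattern")
    return {"ffl": cen.n_ffl, "zl": cen.n_zl_pairs, "nbr": cen.n_nbr}


def null_model_compare(
    net: MoistureNetwork,
    model: str,
    replicates: int = 50,
    seed: int = 0,
) -> NullModelSummary:
    """Compare observed motif totals with a null ensemble (see module docs)."""
    if model not in NULL_MODELS:
        raise ParameterError(f"unknown null model {model!r}")
    if replicates < 2:
        raise ParameterError("need at least 2 replicates")
    rng = np.random.default_rng(seed)
    observed = _motif_totals(net)
    totals: dict[str, list[int]] = {k: [] for k in observed}
    n, m = net.n_nodes, net.n_edges
    for _ in range(replicates):
        if model == "density_matched_random":
            edges = density_matched_random(n, m, rng)
        else:
            edges, achieved = degree_preserving_rewire(net.edges, rng)
            if achieved < 10 * m:
                warnings.warn(
                    f"degree-preserving rewire achieved only {achieved} of "
                    f"{10 * m} requested swaps",
                    stacklevel=2,
                )
        replica = MoistureNetwork(
            grid=net.grid,
            edges=edges,
            rho=net.rho,
            captured_fraction=net.captured_fraction,
            link_class=net.link_class,
        )
        for k, v in _motif_totals(replica).items():
            totals[k].append(v)
    arr = {k: np.asarray(v, dtype=np.float64) for k, v in totals.items()}
    null_mean = {k: float(v.mean()) for k, v in arr.items()}
    null_sd = {k: float(v.std(ddof=1)) for k, v in arr.items()}
    ratio = {
        k: (observed[k] / null_mean[k]) if null_mean[k] > 0 else np.inf if observed[k] else 1.0
        for k in observed
    }
    return NullModelSummary(
        model=model,
        replicates=replicates,
        seed=seed,
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        ratio=ratio,
        replicate_totals=arr,
    )
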