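"""Backbone extraction: the unweighted directed network of strongest flows.

Links are included step-wise from the strongest until their cumulative volume
first reaches (>=) a fraction ``rho`` of the total moisture transport; the
result is the minimal prefix of the descending flow ranking whose captured
volume is at least ``rho``.  Ties are broken by a recorded, reproducible rule
(flow descending, then source index, then target index).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .errors import DegenerateInputError, ParameterError, ValidationError
from .flow_field import FlowField, restrict_link_class
from .grid import GridSpec

__all__ = ["MoistureNetwork", "build_backbone", "backbone_for_link_class",
           "write_network", "read_network"]

TIE_RULES = ("stable",)
SELF_LOOP_POLICIES = ("exclude", "retain_denominator")


@dataclass
class MoistureNetwork:
    """Unweighted directed backbone of a flow field.

    ``edges`` is an ``(m, 2)`` integer array of (source, target) cell pairs,
    ordered from the strongest underlying flow downward.  ``captured_fraction``
    is the fraction of total flow represented by the edge set; by construction
    it is >= ``rho`` and dropping the weakest edge would take it below.
    """

    grid: GridSpec
    edges: np.ndarray
    rho: float
    captured_fraction: float
    link_class: str = "all_to_all"
    tie_rule: str = "stable"
    self_loop_policy: str = "exclude"
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.edges.size and np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValidationError("self-loops are not allowed in a MoistureNetwork")

    @property
    def n_nodes(self) -> int:
        return self.grid.n_cells

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def adjacency(self) -> sp.csr_matrix:
        """Boolean adjacency matrix a_ij over all grid cells."""
        n = self.grid.n_cells
        if not self.n_edges:
            return sp.csr_matrix((n, n))
        data = np.ones(self.n_edges)
        return sp.csr_matrix((data, (self.edges[:, 0], self.edges[:, 1])), shape=(n, n))

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(s), int(t)) for s, t in self.edges}


def _ranked_links(field: FlowField, self_loop_policy: str):
    """Candidate links sorted by (flow desc, source asc, target asc)."""
    coo = field.flows.tocoo()
    src, tgt, val = coo.row.astype(np.int64), coo.col.astype(np.int64), coo.data
    loops = src == tgt
    loop_total = float(val[loops].sum())
    src, tgt, val = src[~loops], tgt[~loops], val[~loops]
    order = np.lexsort((tgt, src, -val))
    return src[order], tgt[order], val[order], loop_total


def build_backbone(
    field: FlowField,
    rho: float,
    tie_rule: str = "stable",
    self_loop_policy: str = "exclude",
    link_class: str = "all_to_all",
) -> MoistureNetwork:
    """Extract the backbone capturing at least ``rho`` of total flow.

    ``self_loop_policy``: within-cell recycling flows (i -> i) are never edge
    candidates (motifs require distinct nodes); ``"exclude"`` also removes
    them from the total-flow denominator, ``"retain_denominator"`` keeps them
    in the denominator only.
    """
    if not (0.0 < rho < 1.0):
        raise ParameterError(f"rho must be in (0, 1), got {rho}")
    if tie_rule not in TIE_RULES:
        raise ParameterError(f"unknown tie_rule {tie_rule!r}")
    if self_loop_policy not in SELF_LOOP_POLICIES:
        raise ParameterError(f"unknown self_loop_policy {self_loop_policy!r}")

    src, tgt, val, loop_total = _ranked_links(field, self_loop_policy)
    total = float(val.sum())
    if self_loop_policy == "retain_denominator":
        total += loop_total
    if total <= 0 or val.size == 0:
        raise DegenerateInputError("total flow is zero; backbone is undefined")

    cum = np.cumsum(val)
    # first index whose cumulative flow reaches rho * total ("exceeds" read as >=)
    k = int(np.searchsorted(cum, rho * total - 1e-12 * total, side="left")) + 1
    k = min(k, val.size)
    captured = float(cum[k - 1] / total)
    edges = np.column_stack([src[:k], tgt[:k]])
    return MoistureNetwork(
        grid=field.grid,
        edges=edges,
        rho=float(rho),
        captured_fraction=captured,
        link_class=link_class,
        tie_rule=tie_rule,
        self_loop_policy=self_loop_policy,
        meta={"time_label": field.time_label, "total_flow": total},
    )


def backbone_for_link_class(
    field: FlowField,
    rho: float,
    link_class: str = "all_to_all",
    threshold_scope: str = "restricted",
    tie_rule: str = "stable",
    self_loop_policy: str = "exclude",
) -> MoistureNetwork:
    """Backbone for a link class, with the two thresholding scopes.

    ``threshold_scope="restricted"`` (default) restricts the field to the link
    class first and thresholds against the class subtotal;  ``"global"``
    thresholds the full field first, then drops edges outside the class.
    """
    if threshold_scope not in ("restricted", "global"):
        raise ParameterError(f"unknown threshold_scope {threshold_scope!r}")
    if threshold_scope == "restricted" or link_class == "all_to_all":
        restricted = restrict_link_class(field, link_class)
        net = build_backbone(restricted, rho, tie_rule, self_loop_policy, link_class)
        net.meta["threshold_scope"] = threshold_scope
        return net
    net = build_backbone(field, rho, tie_rule, self_loop_policy, link_class="all_to_all")
    keep = field.land_mask[net.edges[:, 0]] & field.land_mask[net.edges[:, 1]]
    kept = net.edges[keep]
    out = MoistureNetwork(
        grid=net.grid,
        edges=kept,
        rho=net.rho,
        captured_fraction=net.captured_fraction,
        link_class=link_class,
        tie_rule=tie_rule,
        self_loop_policy=self_loop_policy,
        meta={**net.meta, "threshold_scope": "global"},
    )
    return out


# ---------------------------------------------------------------------------
# edge-list serialization
# ---------------------------------------------------------------------------


def write_network(net: MoistureNetwork, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# moistnet backbone edge list (source target)\n")
        for key, value in (
            ("n_lat", net.grid.n_lat),
            ("n_lon", net.grid.n_lon),
            ("resolution_deg", net.grid.resolution_deg),
            ("rho", net.rho),
            ("captured_fraction", net.captured_fraction),
            ("link_class", net.link_class),
            ("tie_rule", net.tie_rule),
            ("self_loop_policy", net.self_loop_policy),
        ):
            fh.write(f"# {key} = {value}\n")
        for s, t in net.edges:
            fh.write(f"{s} {t}\n")
    return path


def read_network(path: str | Path) -> MoistureNetwork:
    header: dict[str, str] = {}
    edges: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, value = line.lstrip("# ").split("=", 1)
                    header[key.strip()] = value.strip()
                continue
            s, t = line.split()
            edges.append((int(s), int(t)))
    try:
        grid = GridSpec.from_dict(header)
        return MoistureNetwork(
            grid=grid,
            edges=np.asarray(edges, dtype=np.int64).reshape(-1, 2),
            rho=float(header["rho"]),
            captured_fraction=float(header["captured_fraction"]),
            link_class=header.get("link_class", "all_to_all"),
            tie_rule=header.get("tie_rule", "stable"),
            self_loop_policy=header.get("self_loop_policy", "exclude"),
        )
    except KeyError as exc:
        raise ValidationError(f"network file missing header field {exc}") from exc
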