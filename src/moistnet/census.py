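"""Degree measures and the FFL / ZL / NBr motif census.

Motif definitions (on the unweighted directed backbone, no self-loops):

* feed-forward loop (FFL): nodes A, B, C with edges A->B, B->C, A->C.  The
  node the triangle converges on (C) is the *target*; conglomerates of FFLs
  act as directed lenses of moisture flow.
* zero loop (ZL): a reciprocally connected pair i <-> j - a positive
  hydrological feedback between two cells ("washing machine" regions).
* neighboring loop (NBr): a ZL c <-> p plus an external source s with a
  directed edge s -> c into one ZL member, the *center* (directed corridors).
  The source is distinct from both ZL members.

Per-node counts follow the role conventions: FFLs are counted at the target,
ZLs at both members (the count is the number of reciprocal partners), NBrs at
the center.  Two counting modes are supported:

* ``pattern`` (default): an occurrence is counted whenever its required edges
  exist, regardless of extra edges among the triple/pair;
* ``induced``: additionally requires the absence of every non-motif edge
  among the participating nodes.

Beyond role counts, the census reports per-edge participation (number of
counted occurrences, of any type, whose edge set contains the edge) and
per-node total involvement (occurrences containing the node in any role).

All quantities are computed with dense boolean/float64 matrix algebra; counts
are small integers, exactly representable in float64.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import MoistureNetwork
from .errors import ParameterError

__all__ = [
    "DegreeTable",
    "MotifCensus",
    "MotifStrength",
    "StrengthDifference",
    "degrees",
    "census",
    "motif_strength",
    "strength_difference",
    "MOTIF_TYPES",
    "STRENGTH_PAIRS",
]

MOTIF_TYPES = ("ffl", "zl", "nbr")
STRENGTH_PAIRS = ("ffl_minus_zl", "ffl_minus_nbr")
COUNTING_MODES = ("pattern", "induced")


@dataclass
class DegreeTable:
    """Per-node in/out degree of the backbone (Σ k_in = Σ k_out = m)."""

    k_in: np.ndarray
    k_out: np.ndarray

    @property
    def n_edges(self) -> int:
        return int(self.k_in.sum())


def degrees(net: MoistureNetwork) -> DegreeTable:
    """In-degree k_in(i) = |{j: j->i}| and out-degree k_out(i) = |{j: i->j}|."""
    n = net.n_nodes
    k_in = np.bincount(net.edges[:, 1], minlength=n).astype(np.int64)
    k_out = np.bincount(net.edges[:, 0], minlength=n).astype(np.int64)
    return DegreeTable(k_in=k_in, k_out=k_out)


@dataclass
class MotifCensus:
    """Per-node role counts, per-edge participation and total involvement.

    ``edge_participation`` is aligned with ``edges`` (one row per backbone
    edge).  ``total_involvement`` counts, for each node, the motif
    occurrences (all three types, any role) containing it.
    """

    ffl_target: np.ndarray
    zl: np.ndarray
    nbr_center: np.ndarray
    total_involvement: np.ndarray
    edges: np.ndarray
    edge_participation: np.ndarray
    counting_mode: str

    @property
    def n_ffl(self) -> int:
        """Total number of FFL occurrences."""
        return int(self.ffl_target.sum())

    @property
    def n_zl_pairs(self) -> int:
        """Number of reciprocal pairs (each pair is one ZL occurrence)."""
        return int(self.zl.sum()) // 2

    @property
    def n_nbr(self) -> int:
        """Total number of NBr occurrences."""
        return int(self.nbr_center.sum())

    def counts(self, motif_type: str) -> np.ndarray:
        if motif_type not in MOTIF_TYPES:
            raise ParameterError(f"unknown motif type {motif_type!r}")
        return {"ffl": self.ffl_target, "zl": self.zl, "nbr": self.nbr_center}[motif_type]


def census(net: MoistureNetwork, counting_mode: str = "pattern") -> MotifCensus:
    """Census of FFL / ZL / NBr motifs on a backbone network."""
    if counting_mode not in COUNTING_MODES:
        raise ParameterError(f"unknown counting_mode {counting_mode!r}")
    n = net.n_nodes
    A = np.zeros((n, n), dtype=np.float64)
    if net.n_edges:
        A[net.edges[:, 0], net.edges[:, 1]] = 1.0
    AT = A.T
    R = A * AT  # reciprocal-pair indicator (symmetric)
    zl = R.sum(axis=1)
    k_in = A.sum(axis=0)

    eu, ev = (net.edges[:, 0], net.edges[:, 1]) if net.n_edges else (np.empty(0, int),) * 2

    if counting_mode == "pattern":
        # FFL: roles via path/co-neighbor products of the raw adjacency.
        A2 = A @ A
        AAT = A @ AT
        ATA = AT @ A
        ffl_target = (A * A2).sum(axis=0)
        ffl_role_a = (A * A2).sum(axis=1)
        ffl_role_b = (A * AAT).sum(axis=0)
        # NBr: center c has one occurrence per (reciprocal partner p, extra
        # in-neighbor s != p); the partner itself always contributes one
        # in-edge, hence the (k_in - 1) factor.
        nbr_center = zl * np.maximum(k_in - 1.0, 0.0)
        nbr_center[zl == 0] = 0.0
        nbr_role_p = R @ np.maximum(k_in - 1.0, 0.0)
        nbr_role_s = A @ zl - zl  # s -> c with c <-> p, minus the p = s cases

        ffl_edge = AAT[eu, ev] + ATA[eu, ev] + A2[eu, ev]
        zl_edge = R[eu, ev]
        nbr_edge = (zl[ev] - R[eu, ev]) + R[eu, ev] * (
            np.maximum(k_in[eu] - 1.0, 0.0) + np.maximum(k_in[ev] - 1.0, 0.0)
        )
    else:
        # induced mode: occurrence edges must be the only edges among the triple
        U = A * (1.0 - AT)  # strictly one-way edges
        NE = (1.0 - A) * (1.0 - AT)  # no edge either way
        np.fill_diagonal(NE, 0.0)
        U2 = U @ U
        UUT = U @ U.T
        UTU = U.T @ U
        ffl_target = (U * U2).sum(axis=0)
        ffl_role_a = (U * U2).sum(axis=1)
        ffl_role_b = (U * UUT).sum(axis=0)

        UTNE = U.T @ NE
        NEU = NE @ U
        UR = U @ R
        nbr_center = (R * UTNE).sum(axis=1)
        nbr_role_p = (R * NEU).sum(axis=1)
        nbr_role_s = (NE * UR).sum(axis=1)

        ffl_edge = U[eu, ev] * (UUT[eu, ev] + UTU[eu, ev] + U2[eu, ev])
        zl_edge = R[eu, ev]
        NER = NE @ R
        nbr_edge = (
            U[eu, ev] * NER[eu, ev]  # edge as s -> c
            + R[eu, ev] * UTNE[eu, ev]  # edge as c -> p
            + R[eu, ev] * NEU[eu, ev]  # edge as p -> c
        )

    involvement = (
        ffl_role_a + ffl_role_b + ffl_target + zl + nbr_center + nbr_role_p + nbr_role_s
    )
    participation = ffl_edge + zl_edge + nbr_edge
    return MotifCensus(
        ffl_target=np.rint(ffl_target).astype(np.int64),
        zl=np.rint(zl).astype(np.int64),
        nbr_center=np.rint(nbr_center).astype(np.int64),
        total_involvement=np.rint(involvement).astype(np.int64),
        edges=net.edges.copy(),
        edge_participation=np.rint(participation).astype(np.int64),
        counting_mode=counting_mode,
    )


# ---------------------------------------------------------------------------
# strengths
# ---------------------------------------------------------------------------


@dataclass
class MotifStrength:
    """Per-node motif counts rescaled by the global maximum per type.

    When a type has no occurrence anywhere, all its strengths are 0 and the
    type is recorded in ``zero_types``.
    """

    strengths: dict[str, np.ndarray]
    normalizers: dict[str, int]
    zero_types: tuple[str, ...]

    def __getitem__(self, motif_type: str) -> np.ndarray:
        return self.strengths[motif_type]


def motif_strength(cen: MotifCensus) -> MotifStrength:
    strengths: dict[str, np.ndarray] = {}
    normalizers: dict[str, int] = {}
    zero: list[str] = []
    for t in MOTIF_TYPES:
        counts = cen.counts(t)
        m = int(counts.max()) if counts.size else 0
        normalizers[t] = m
        if m == 0:
            strengths[t] = np.zeros_like(counts, dtype=np.float64)
            zero.append(t)
        else:
            strengths[t] = counts / float(m)
    return MotifStrength(strengths=strengths, normalizers=normalizers, zero_types=tuple(zero))


@dataclass
class StrengthDifference:
    """Per-node difference of two motif strengths, in [-1, 1]."""

    pair: str
    values: np.ndarray


def strength_difference(st: MotifStrength, pair: str) -> StrengthDifference:
    if pair not in STRENGTH_PAIRS:
        raise ParameterError(f"unknown strength pair {pair!r}")
    other = "zl" if pair == "ffl_minus_zl" else "nbr"
    return StrengthDifference(pair=pair, values=st["ffl"] - st[other])
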