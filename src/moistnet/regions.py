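"""Regional aggregation, threshold sensitivity and hub-regime classification.

Focus regions (rectangles in lat/lon or explicit cell sets) aggregate the
per-node motif strength-difference fields.  A region's regime follows the
sign structure of its aggregated FFL-ZL and FFL-NBr differences:

* ``directed_lens``      - FFL dominates (FFL-ZL > eps);
* ``washing_machine``    - reciprocity dominates (FFL-ZL < -eps and either
  FFL-NBr >= -eps or FFL-ZL is the more negative of the two);
* ``directed_corridor``  - fed reciprocity dominates (FFL-NBr < -eps,
  symmetric rule);
* ``mixed``              - neither difference clears the dead zone, or an
  exact tie between two negative aggregates.

``eps`` (default 0.01) is a dead zone against labeling numerical noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .backbone import backbone_for_link_class
from .census import STRENGTH_PAIRS, census, motif_strength, strength_difference
from .errors import ParameterError, ValidationError
from .flow_field import FlowField
from .grid import GridSpec

__all__ = [
    "FocusRegion",
    "RegionalSummary",
    "default_focus_regions",
    "aggregate_region",
    "classify_region",
    "strength_difference_fields",
    "sensitivity_over_rho",
    "monthly_profile",
    "REGIME_LABELS",
]

REGIME_LABELS = ("directed_lens", "washing_machine", "directed_corridor", "mixed")
DEFAULT_RHO_GRID = (0.20, 0.25, 0.30)
DEFAULT_EPS = 0.01


@dataclass
class FocusRegion:
    """A named set of grid cells (from a lat/lon rectangle or explicit list)."""

    name: str
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.unique(np.asarray(self.cells, dtype=np.int64))
        if self.cells.size == 0:
            raise ValidationError(f"region {self.name!r} has an empty mask")

    @classmethod
    def from_bounds(
        cls,
        name: str,
        grid: GridSpec,
        lon_min: float,
        lon_max: float,
        lat_min: float,
        lat_max: float,
    ) -> "FocusRegion":
        lats = grid.cell_latitudes()
        cols = np.arange(grid.n_cells) % grid.n_lon
        lons = -180.0 + grid.resolution_deg / 2.0 + cols * grid.resolution_deg
        keep = (lats >= lat_min) & (lats <= lat_max)
        if lon_min <= lon_max:
            keep &= (lons >= lon_min) & (lons <= lon_max)
        else:  # rectangle crossing the antimeridian
            keep &= (lons >= lon_min) | (lons <= lon_max)
        return cls(name, np.flatnonzero(keep))

    def validate_on(self, grid: GridSpec) -> None:
        if self.cells.max() >= grid.n_cells:
            raise ValidationError(f"region {self.name!r} has cells outside the grid")


def default_focus_regions(grid: GridSpec) -> list[FocusRegion]:
    """Rectangles approximating the four classical moisture-recycling hubs.

    Amazon Basin (AB), Congo Rainforest (CR), South Asia (SA) and the
    Indonesian Archipelago (IA).  The coordinates are configurable defaults,
    not authoritative region definitions.
    """
    boxes = {
        "AB": (-80.0, -45.0, -20.0, 10.0),
        "CR": (10.0, 32.0, -10.0, 8.0),
        "SA": (65.0, 95.0, 5.0, 32.0),
        "IA": (95.0, 150.0, -10.0, 8.0),
    }
    return [
        FocusRegion.from_bounds(name, grid, *bounds) for name, bounds in boxes.items()
    ]


# ---------------------------------------------------------------------------
# aggregation and classification
# ---------------------------------------------------------------------------


def aggregate_region(
    values: np.ndarray,
    region: FocusRegion,
    grid: GridSpec,
    weighting: str = "uniform",
) -> float:
    """Mean of a per-node field over a region's cells.

    ``weighting="cos_lat"`` weights each cell by the cosine of its center
    latitude (area weighting on the sphere); ``"uniform"`` is a plain mean.
    """
    if weighting not in ("uniform", "cos_lat"):
        raise ParameterError(f"unknown weighting {weighting!r}")
    region.validate_on(grid)
    vals = np.asarray(values, dtype=np.float64)[region.cells]
    if weighting == "uniform":
        return float(vals.mean())
    w = np.cos(np.deg2rad(grid.cell_latitudes()[region.cells]))
    return float(np.average(vals, weights=w))


def classify_region(
    ffl_minus_zl: float,
    ffl_minus_nbr: float,
    eps: float = DEFAULT_EPS,
) -> str:
    """Regime label from the two aggregated strength differences."""
    dz, dn = ffl_minus_zl, ffl_minus_nbr
    if dz > eps:
        return "directed_lens"
    if dz < -eps and dn < -eps:
        if dz < dn:
            return "washing_machine"
        if dn < dz:
            return "directed_corridor"
        return "mixed"  # exact tie carries no direction
    if dz < -eps:
        return "washing_machine"
    if dn < -eps:
        return "directed_corridor"
    return "mixed"


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def strength_difference_fields(
    field: FlowField,
    rho: float,
    link_class: str = "all_to_all",
    counting_mode: str = "pattern",
    threshold_scope: str = "restricted",
) -> dict[str, np.ndarray]:
    """Backbone -> census -> strengths -> both per-node difference fields."""
    net = backbone_for_link_class(field, rho, link_class, threshold_scope)
    st = motif_strength(census(net, counting_mode))
    return {pair: strength_difference(st, pair).values for pair in STRENGTH_PAIRS}


@dataclass
class RegionalSummary:
    """Aggregated strength difference for one region and pair, with the
    spread across the rho sensitivity grid and the regime label (assigned
    from both pairs at the reference rho)."""

    region: str
    pair: str
    link_class: str
    rho_reference: float
    mean: float
    spread_min: float
    spread_max: float
    label: str
    per_rho: dict[float, float] = dc_field(default_factory=dict)


def sensitivity_over_rho(
    field: FlowField,
    regions: Sequence[FocusRegion],
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    rho_reference: float = 0.25,
    link_class: str = "all_to_all",
    weighting: str = "uniform",
    eps: float = DEFAULT_EPS,
    counting_mode: str = "pattern",
) -> list[RegionalSummary]:
    """Run the full pipeline over a rho grid and summarize per region.

    For every rho the backbone is rebuilt and the census recomputed; the
    summary holds the aggregate at the reference rho and the (min, max)
    spread across the grid - the error bars of the regional values.
    """
    rho_grid = tuple(rho_grid)
    if not rho_grid:
        raise ParameterError("rho_grid must be nonempty")
    for r in rho_grid:
        if not (0.0 < r < 1.0):
            raise ParameterError(f"rho {r} outside (0, 1)")
    if rho_reference not in rho_grid:
        rho_grid = tuple(sorted({*rho_grid, rho_reference}))

    per_rho: dict[float, dict[str, np.ndarray]] = {
        rho: strength_difference_fields(field, rho, link_class, counting_mode)
        for rho in rho_grid
    }
    out: list[RegionalSummary] = []
    for region in regions:
        agg = {
            pair: {rho: aggregate_region(per_rho[rho][pair], region, field.grid, weighting)
                   for rho in rho_grid}
            for pair in STRENGTH_PAIRS
        }
        label = classify_region(
            agg["ffl_minus_zl"][rho_reference], agg["ffl_minus_nbr"][rho_reference], eps
        )
        for pair in STRENGTH_PAIRS:
            vals = agg[pair]
            out.append(
                RegionalSummary(
                    region=region.name,
                    pair=pair,
                    link_class=link_class,
                    rho_reference=rho_reference,
                    mean=vals[rho_reference],
                    spread_min=min(vals.values()),
                    spread_max=max(vals.values()),
                    label=label,
                    per_rho=dict(vals),
                )
            )
    return out


def summaries_to_frame(summaries: Sequence[RegionalSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region": s.region,
                "pair": s.pair,
                "link_class": s.link_class,
                "rho": s.rho_reference,
                "mean": s.mean,
                "min": s.spread_min,
                "max": s.spread_max,
                "label": s.label,
            }
            for s in summaries
        ]
    )


def monthly_profile(
    monthly_fields: Sequence[FlowField],
    regions: Sequence[FocusRegion],
    pair: str = "ffl_minus_zl",
    rho: float = 0.25,
    link_class: str = "all_to_all",
    weighting: str = "uniform",
    annual_field: FlowField | None = None,
) -> pd.DataFrame:
    """Per-month regional aggregates, their mean, and the annual-field value.

    The annual field defaults to the per-pair sum of the monthly fields.
    Returns a tidy frame with one row per (region, month) plus rows with
    month ``"monthly_mean"`` and ``"annual"``.
    """
    if not monthly_fields:
        raise ValidationError("need at least one monthly field")
    grid = monthly_fields[0].grid
    for f in monthly_fields:
        if f.grid != grid:
            raise ValidationError("monthly fields are on different grids")
    if annual_field is None:
        from .flow_field import annual_sum

        annual_field = annual_sum(monthly_fields)

    rows = []
    per_region: dict[str, list[float]] = {r.name: [] for r in regions}
    for f in monthly_fields:
        diff = strength_difference_fields(f, rho, link_class)[pair]
        for region in regions:
            v = aggregate_region(diff, region, grid, weighting)
            per_region[region.name].append(v)
            rows.append({"region": region.name, "month": f.time_label, "value": v})
    annual_diff = strength_difference_fields(annual_field, rho, link_class)[pair]
    for region in regions:
        rows.append(
            {
                "region": region.name,
                "month": "monthly_mean",
                "value": float(np.mean(per_region[region.name])),
            }
        )
        rows.append(
            {
                "region": region.name,
                "month": "annual",
                "value": aggregate_region(annual_diff, region, grid, weighting),
            }
        )
    return pd.DataFrame(rows)
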