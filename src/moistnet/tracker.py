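"""Desk-scale Lagrangian moisture tracker.

Forward-tracks parcels of evaporated moisture through toy atmospheric states
and accumulates the evaporation-to-precipitation flow matrix ``m_ij`` from
first principles.  The scheme per parcel and time step:

* the parcel is advected by the bilinearly interpolated wind at its level
  (winds in grid cells per hour; longitude wraps, latitude clamps);
* with probability ``step_hours / mixing_period_hours`` the parcel's level is
  resampled along the column with probability proportional to the vertical
  moisture profile;
* a fraction ``P/TPW`` of the column moisture rains out: the parcel allocates
  ``A = P * W * E_source / TPW`` to its current cell (credited against its
  origin cell), its moisture is updated with local evaporation and
  precipitation, ``W <- W + (E - P) * W / TPW``, and its source fraction is
  updated.

Two source-fraction updates are available.  The default
(``fraction_conserving``) keeps two buckets - source moisture decays by the
rainout factor ``(1 - P/TPW)`` while moisture gained from local evaporation
is non-source - which keeps ``E_source`` in [0, 1] and conserves mass
exactly.  The ``literal`` mode applies the update
``E_source <- E_source * W_prev * A / W`` as an alternative reading; it is
dimensionally inconsistent as a fraction update and is flagged experimental.

Parcels are released in proportion to evaporation (``parcels_per_mm`` per mm,
at uniform random positions within the cell, one level offset above the
surface) and retired after ``max_age_days`` or once the stop fraction of
their initial moisture has precipitated.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import ParameterError, ValidationError
from .flow_field import FlowField
from .grid import GridSpec

__all__ = [
    "AtmosphericState",
    "Parcel",
    "TrackerConfig",
    "TrackDiagnostics",
    "release_parcels",
    "step_parcel",
    "allocate_precipitation",
    "track",
]

SOURCE_UPDATE_MODES = ("fraction_conserving", "literal")


@dataclass
class AtmosphericState:
    """Forcing fields for one tracker time step.

    Winds ``u`` (eastward) and ``v`` (northward) are in grid cells per hour,
    shape (levels, n_lat, n_lon).  ``E``, ``P`` (mm per step) and ``TPW``
    (mm) are per-cell surfaces.  ``profile`` holds the vertical moisture
    distribution used for column redistribution (normalized per column);
    ``surface_level`` is the level index of the surface in each column.
    """

    grid: GridSpec
    u: np.ndarray
    v: np.ndarray
    E: np.ndarray
    P: np.ndarray
    TPW: np.ndarray
    profile: np.ndarray | None = None
    surface_level: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape2 = (self.grid.n_lat, self.grid.n_lon)
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.u.ndim == 2:
            self.u = self.u[None]
        if self.v.ndim == 2:
            self.v = self.v[None]
        if self.u.shape[1:] != shape2 or self.v.shape != self.u.shape:
            raise ValidationError("wind field shape does not match grid")
        for name in ("E", "P", "TPW"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != shape2:
                raise ValidationError(f"{name} shape does not match grid")
            setattr(self, name, arr)
        if np.any(self.P > 0) and np.any(self.TPW[self.P > 0] <= 0):
            raise ValidationError("TPW must be positive wherever P > 0")
        levels = self.u.shape[0]
        if self.profile is None:
            self.profile = np.full((levels,) + shape2, 1.0 / levels)
        else:
            self.profile = np.asarray(self.profile, dtype=np.float64)
            if self.profile.shape != (levels,) + shape2:
                raise ValidationError("profile shape does not match wind levels/grid")
            if np.any(self.profile < 0):
                raise ValidationError("profile weights must be non-negative")
            col = self.profile.sum(axis=0)
            if np.any(col <= 0):
                raise ValidationError("profile columns must have positive total weight")
            self.profile = self.profile / col
        if self.surface_level is None:
            self.surface_level = np.zeros(shape2, dtype=np.int64)
        else:
            self.surface_level = np.asarray(self.surface_level, dtype=np.int64)
            if self.surface_level.shape != shape2:
                raise ValidationError("surface_level shape does not match grid")

    @property
    def n_levels(self) -> int:
        return self.u.shape[0]


@dataclass
class TrackerConfig:
    """Tracker settings; defaults follow the standard forward-tracking setup
    (100 parcels per mm of evaporation, 0.1 h steps, 24 h vertical mixing
    period, release one level above the surface, 30-day maximum age, parcels
    retired once 99% of their initial moisture has precipitated)."""

    parcels_per_mm: float = 100.0
    step_hours: float = 0.1
    mixing_period_hours: float | None = 24.0
    release_level_offset: int = 1
    max_age_days: float = 30.0
    stop_precipitated_fraction: float = 0.99
    source_update_mode: str = "fraction_conserving"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.parcels_per_mm <= 0 or self.step_hours <= 0 or self.max_age_days <= 0:
            raise ParameterError("tracker sizes must be positive")
        if self.mixing_period_hours is not None and self.mixing_period_hours <= 0:
            raise ParameterError("mixing_period_hours must be positive or None")
        if not (0.0 < self.stop_precipitated_fraction <= 1.0):
            raise ParameterError("stop_precipitated_fraction must be in (0, 1]")
        if self.source_update_mode not in SOURCE_UPDATE_MODES:
            raise ParameterError(f"unknown source_update_mode {self.source_update_mode!r}")


@dataclass
class Parcel:
    """One tracked moisture parcel.

    Position is continuous in grid coordinates: ``r`` in [0, n_lat) with cell
    row = floor(r), ``c`` likewise modulo n_lon.  ``W`` is total parcel
    moisture (mm), ``E_source`` the fraction of it that evaporated at the
    origin cell.
    """

    r: float
    c: float
    level: int
    W: float
    E_source: float
    origin: int
    age_hours: float = 0.0
    allocated: float = 0.0
    W0: float = dc_field(default=None)  # type: ignore[assignment]
    alive: bool = True

    def __post_init__(self) -> None:
        if self.W0 is None:
            self.W0 = self.W
        if self.W < 0 or not (0.0 <= self.E_source <= 1.0):
            raise ValidationError("parcel requires W >= 0 and E_source in [0, 1]")

    @property
    def source_moisture(self) -> float:
        return self.W * self.E_source


def _cell_of(grid: GridSpec, r: float, c: float) -> tuple[int, int]:
    row = min(max(int(np.floor(r)), 0), grid.n_lat - 1)
    col = int(np.floor(c)) % grid.n_lon
    return row, col


def _bilinear(field2d: np.ndarray, r: float, c: float) -> float:
    """Interpolate a (n_lat, n_lon) field at continuous grid coordinates,
    sampling between cell centers; columns wrap, rows clamp."""
    n_lat, n_lon = field2d.shape
    rr = min(max(r - 0.5, 0.0), n_lat - 1.0)
    cc = (c - 0.5) % n_lon
    i0 = min(int(np.floor(rr)), n_lat - 2) if n_lat > 1 else 0
    j0 = int(np.floor(cc))
    fi = rr - i0
    fj = cc - j0
    i1 = min(i0 + 1, n_lat - 1)
    j1 = (j0 + 1) % n_lon
    return float(
        field2d[i0, j0] * (1 - fi) * (1 - fj)
        + field2d[i1, j0] * fi * (1 - fj)
        + field2d[i0, j1] * (1 - fi) * fj
        + field2d[i1, j1] * fi * fj
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def release_parcels(
    state: AtmosphericState,
    cell: int,
    config: TrackerConfig,
    rng: np.random.Generator,
) -> list[Parcel]:
    """Release parcels for one cell's evaporation this step.

    ``round(parcels_per_mm * E)`` parcels, each carrying an equal share of the
    cell's evaporation, at uniform random positions within the cell, one
    release offset above the surface level.  Zero evaporation releases none.
    """
    row, col = state.grid.rowcol(cell)
    E = float(state.E[row, col])
    if E < 0:
        raise ValidationError("evaporation must be non-negative")
    n = int(round(config.parcels_per_mm * E))
    if n == 0:
        return []
    level = int(
        min(state.surface_level[row, col] + config.release_level_offset, state.n_levels - 1)
    )
    w = E / n
    return [
        Parcel(
            r=row + rng.uniform(),
            c=col + rng.uniform(),
            level=level,
            W=w,
            E_source=1.0,
            origin=cell,
        )
        for _ in range(n)
    ]


def step_parcel(
    p: Parcel,
    state: AtmosphericState,
    config: TrackerConfig,
    rng: np.random.Generator,
) -> Parcel:
    """Advect a parcel over one time step and maybe redistribute its level."""
    level = min(p.level, state.n_levels - 1)
    u = _bilinear(state.u[level], p.r, p.c)
    v = _bilinear(state.v[level], p.r, p.c)
    p.r = min(max(p.r + v * config.step_hours, 0.0), state.grid.n_lat - 1e-9)
    p.c = (p.c + u * config.step_hours) % state.grid.n_lon
    if config.mixing_period_hours is not None:
        if rng.uniform() < config.step_hours / config.mixing_period_hours:
            row, col = _cell_of(state.grid, p.r, p.c)
            weights = state.profile[:, row, col]
            p.level = int(rng.choice(state.n_levels, p=weights))
    p.age_hours += config.step_hours
    return p


def allocate_precipitation(
    p: Parcel,
    state: AtmosphericState,
    config: TrackerConfig,
) -> tuple[float, Parcel]:
    """Rain out the parcel's share of this step's precipitation.

    Returns the allocated amount ``A`` (credited to the parcel's current cell
    against its origin) and updates the parcel's moisture and source
    fraction in place.
    """
    row, col = _cell_of(state.grid, p.r, p.c)
    P = float(state.P[row, col])
    E = float(state.E[row, col])
    if P <= 0:
        f = 0.0
    else:
        tpw = float(state.TPW[row, col])
        if tpw <= 0:
            raise ValidationError("P > 0 with TPW <= 0 at parcel location")
        f = min(P / tpw, 1.0)
    tpw = float(state.TPW[row, col])
    gain = E * p.W / tpw if tpw > 0 else 0.0

    A = f * p.W * p.E_source
    W_prev, E_prev = p.W, p.E_source
    p.W = p.W + gain - f * p.W
    if config.source_update_mode == "fraction_conserving":
        source = W_prev * E_prev * (1.0 - f)
        p.E_source = source / p.W if p.W > 0 else 0.0
    else:  # literal update, experimental
        p.E_source = (E_prev * W_prev * A) / p.W if p.W > 0 else 0.0
    p.allocated += A
    return A, p


@dataclass
class TrackDiagnostics:
    """Per-origin mass budget: released = allocated + remaining source
    moisture (still held by live parcels or retained in retired ones)."""

    released: np.ndarray
    allocated: np.ndarray
    remaining: np.ndarray


def track(
    states: list[AtmosphericState],
    config: TrackerConfig,
    time_label: str = "annual",
    return_diagnostics: bool = False,
):
    """Run the tracker over a sequence of states and build the flow field.

    Each state is one time step of forcing: its evaporation releases parcels,
    then every live parcel is advected, optionally vertically mixed, and
    rains out against that state's P/TPW.  ``m_ij`` accumulates moisture
    allocated to cell j from parcels originating in cell i.
    """
    if not states:
        raise ValidationError("need at least one atmospheric state")
    grid = states[0].grid
    for s in states:
        if s.grid != grid:
            raise ValidationError("states are on different grids")
    rng = np.random.default_rng(config.seed)
    n = grid.n_cells
    m = np.zeros((n, n))
    released = np.zeros(n)
    remaining_retired = np.zeros(n)
    parcels: list[Parcel] = []
    max_age = config.max_age_days * 24.0

    for state in states:
        for cell in np.flatnonzero(state.E.ravel() > 0):
            new = release_parcels(state, int(cell), config, rng)
            for p in new:
                released[p.origin] += p.W
            parcels.extend(new)
        survivors: list[Parcel] = []
        for p in parcels:
            step_parcel(p, state, config, rng)
            A, _ = allocate_precipitation(p, state, config)
            if A > 0:
                row, col = _cell_of(grid, p.r, p.c)
                m[p.origin, grid.cell_index(row, col)] += A
            if (
                p.age_hours >= max_age
                or p.allocated >= config.stop_precipitated_fraction * p.W0
            ):
                p.alive = False
                remaining_retired[p.origin] += p.source_moisture
            else:
                survivors.append(p)
        parcels = survivors

    remaining = remaining_retired.copy()
    for p in parcels:
        remaining[p.origin] += p.source_moisture
    land = np.ones(n, dtype=bool)
    field = FlowField(grid, m, time_label=time_label, land_mask=land)
    if return_diagnostics:
        diag = TrackDiagnostics(
            released=released, allocated=m.sum(axis=1), remaining=remaining
        )
        return field, diag
    return field
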