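"""Sparse cell-to-cell moisture flow fields and their on-disk formats.

A :class:`FlowField` holds the monthly (or annual) moisture volume ``m_ij``
evaporated in grid cell *i* that precipitates in grid cell *j*, as a sparse
non-negative matrix over the flat cell indexing of a :class:`~moistnet.grid.GridSpec`,
together with a per-cell land mask.

Two interchangeable file formats are supported:

* netCDF (scipy/NetCDF3 dialect): sparse link list ``source_cell(link)``,
  ``target_cell(link)``, ``flow(link)`` plus ``land_mask(lat, lon)`` and grid
  metadata in global attributes;
* plain-text triplets ``source_index target_index flow`` with a YAML sidecar
  declaring the grid and the land cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
import xarray as xr
import yaml

from .errors import FormatError, ValidationError
from .grid import GridSpec

__all__ = [
    "FlowField",
    "read_flow_field",
    "write_flow_field",
    "restrict_link_class",
    "annual_sum",
]

LINK_CLASSES = ("all_to_all", "land_to_land")


@dataclass
class FlowField:
    """Pairwise moisture flows for one time label.

    Attributes
    ----------
    grid
        The lat-lon grid the cell indices refer to.
    flows
        ``(n_cells, n_cells)`` sparse CSR matrix; entry (i, j) is the flow
        from evaporation in cell i to precipitation in cell j (mm per time
        unit).  All entries finite and >= 0.
    time_label
        ``"annual"`` or a month identifier such as ``"01"``.
    land_mask
        Boolean per-cell array, True on land.
    """

    grid: GridSpec
    flows: sp.csr_matrix
    time_label: str = "annual"
    land_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.grid.n_cells
        self.flows = sp.csr_matrix(self.flows, shape=(n, n), dtype=np.float64)
        self.flows.eliminate_zeros()
        if self.land_mask is None:
            self.land_mask = np.ones(n, dtype=bool)
        self.land_mask = np.asarray(self.land_mask, dtype=bool).ravel()
        if self.land_mask.size != n:
            raise ValidationError("land_mask size does not match grid")
        data = self.flows.data
        if data.size and not np.all(np.isfinite(data)):
            raise ValidationError("flow values must be finite")
        if data.size and data.min() < 0:
            raise ValidationError("flow values must be non-negative")

    # -- convenience ---------------------------------------------------------

    @classmethod
    def from_pairs(
        cls,
        grid: GridSpec,
        pairs: dict[tuple[int, int], float] | Iterable[tuple[int, int, float]],
        time_label: str = "annual",
        land_mask: np.ndarray | None = None,
    ) -> "FlowField":
        """Build a field from ``{(src, tgt): flow}`` or ``(src, tgt, flow)`` triples."""
        if isinstance(pairs, dict):
            items = [(s, t, v) for (s, t), v in pairs.items()]
        else:
            items = list(pairs)
        if items:
            src, tgt, val = (np.asarray(x) for x in zip(*items))
        else:
            src = tgt = np.empty(0, dtype=int)
            val = np.empty(0)
        n = grid.n_cells
        if src.size and (src.min() < 0 or src.max() >= n or tgt.min() < 0 or tgt.max() >= n):
            raise ValidationError("cell index outside grid")
        mat = sp.coo_matrix((val.astype(float), (src, tgt)), shape=(n, n)).tocsr()
        mat.sum_duplicates()
        return cls(grid, mat, time_label=time_label, land_mask=land_mask)

    def to_pairs(self) -> dict[tuple[int, int], float]:
        coo = self.flows.tocoo()
        return {(int(s), int(t)): float(v) for s, t, v in zip(coo.row, coo.col, coo.data)}

    @property
    def n_links(self) -> int:
        return int(self.flows.nnz)

    def total_flow(self, include_self_loops: bool = True) -> float:
        total = float(self.flows.sum())
        if not include_self_loops:
            total -= float(self.flows.diagonal().sum())
        return total


# ---------------------------------------------------------------------------
# link classes
# ---------------------------------------------------------------------------


def restrict_link_class(
    field: FlowField,
    link_class: str,
    land_mask: np.ndarray | None = None,
) -> FlowField:
    """Restrict a field to a link class.

    ``land_to_land`` keeps exactly the pairs whose source *and* target cells
    are land; ``all_to_all`` is the identity.  ``land_mask`` overrides the
    field's own mask when given.
    """
    if link_class not in LINK_CLASSES:
        raise ValidationError(f"unknown link class {link_class!r}")
    if link_class == "all_to_all":
        return field
    mask = field.land_mask if land_mask is None else np.asarray(land_mask, dtype=bool).ravel()
    if mask.size != field.grid.n_cells:
        raise ValidationError("land_mask size does not match grid")
    d = sp.diags(mask.astype(float))
    restricted = (d @ field.flows @ d).tocsr()
    restricted.eliminate_zeros()
    return FlowField(field.grid, restricted, time_label=field.time_label, land_mask=mask)


def annual_sum(fields: Sequence[FlowField]) -> FlowField:
    """Per-pair sum of monthly fields (mm/yr); grids and masks must agree."""
    if not fields:
        raise ValidationError("no monthly fields given")
    g = fields[0].grid
    mask = fields[0].land_mask
    total = sp.csr_matrix((g.n_cells, g.n_cells))
    for f in fields:
        if f.grid != g:
            raise ValidationError("monthly fields are on different grids")
        if not np.array_equal(f.land_mask, mask):
            raise ValidationError("monthly fields have different land masks")
        total = total + f.flows
    return FlowField(g, total, time_label="annual", land_mask=mask)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".grid.yaml")


def write_flow_field(field: FlowField, path: str | Path) -> Path:
    """Write a field; dialect chosen by extension (``.nc`` netCDF, else text).

    The text format writes a companion ``<name>.grid.yaml`` sidecar holding the
    grid and the land-cell list.  Returns the main path written.
    """
    path = Path(path)
    coo = field.flows.tocoo()
    if path.suffix == ".nc":
        ds = xr.Dataset(
            {
                "source_cell": ("link", coo.row.astype(np.int32)),
                "target_cell": ("link", coo.col.astype(np.int32)),
                "flow": ("link", coo.data.astype(np.float64)),
                "land_mask": (
                    ("lat", "lon"),
                    field.land_mask.reshape(field.grid.n_lat, field.grid.n_lon).astype(np.int8),
                ),
            },
            attrs={
                "n_lat": field.grid.n_lat,
                "n_lon": field.grid.n_lon,
                "resolution_deg": field.grid.resolution_deg,
                "time_label": field.time_label,
                "flow_units": "mm/month" if field.time_label != "annual" else "mm/yr",
                "convention": "moistnet sparse link list, row-major cell indexing",
            },
        )
        ds["flow"].attrs["units"] = ds.attrs["flow_units"]
        ds.to_netcdf(path, engine="scipy")
        return path
    with open(path, "w") as fh:
        fh.write("# moistnet flow field (source_index target_index flow)\n")
        fh.write(f"# time_label = {field.time_label}\n")
        for s, t, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{int(s)} {int(t)} {float(v)!r}\n")
    sidecar = {
        **field.grid.to_dict(),
        "land_cells": [int(c) for c in np.flatnonzero(field.land_mask)],
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(sidecar, fh)
    return path


def _read_netcdf(path: Path) -> FlowField:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    for name in ("n_lat", "n_lon", "resolution_deg"):
        if name not in ds.attrs:
            raise FormatError(f"netCDF file missing grid attribute {name!r}")
    grid = GridSpec.from_dict({k: ds.attrs[k] for k in ("n_lat", "n_lon", "resolution_deg")})
    for var in ("source_cell", "target_cell", "flow", "land_mask"):
        if var not in ds:
            raise FormatError(f"netCDF file missing variable {var!r}")
    src = np.asarray(ds["source_cell"].values, dtype=np.int64)
    tgt = np.asarray(ds["target_cell"].values, dtype=np.int64)
    val = np.asarray(ds["flow"].values, dtype=np.float64)
    mask = np.asarray(ds["land_mask"].values).astype(bool).ravel()
    if val.size and val.min() < 0:
        raise ValidationError("variable 'flow' contains negative values")
    if src.size and (src.max() >= grid.n_cells or tgt.max() >= grid.n_cells or src.min() < 0 or tgt.min() < 0):
        raise FormatError("variable 'source_cell'/'target_cell' references unknown cells")
    f = FlowField.from_pairs(grid, zip(src, tgt, val), land_mask=mask)
    f.time_label = str(ds.attrs.get("time_label", "annual"))
    return f


def _read_text(path: Path) -> FlowField:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing grid sidecar {sidecar.name!r}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    grid = GridSpec.from_dict(meta)
    mask = np.zeros(grid.n_cells, dtype=bool)
    land_cells = np.asarray(meta.get("land_cells", []), dtype=int)
    if land_cells.size and (land_cells.min() < 0 or land_cells.max() >= grid.n_cells):
        raise FormatError("sidecar 'land_cells' references unknown cells")
    mask[land_cells] = True
    time_label = "annual"
    triples: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "time_label" in line and "=" in line:
                    time_label = line.split("=", 1)[1].strip()
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"line {lineno}: expected 'source target flow', got {line!r}")
            try:
                s, t, v = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: could not parse 'flow' triplet") from exc
            if not (0 <= s < grid.n_cells and 0 <= t < grid.n_cells):
                raise FormatError(f"line {lineno}: cell index outside grid")
            if v < 0:
                raise ValidationError(f"line {lineno}: negative flow")
            triples.append((s, t, v))
    f = FlowField.from_pairs(grid, triples, land_mask=mask)
    f.time_label = time_label
    return f


def read_flow_field(
    path: str | Path | Sequence[str | Path],
    time_selector: str = "annual",
) -> FlowField:
    """Read one or several flow-field files.

    A single path reads that file.  A sequence of monthly files combined with
    ``time_selector="annual"`` returns the per-pair sum; with a month label it
    returns the file whose ``time_label`` matches.
    """
    if isinstance(path, (str, Path)):
        return _read_netcdf(Path(path)) if Path(path).suffix == ".nc" else _read_text(Path(path))
    fields = [read_flow_field(p) for p in path]
    if time_selector == "annual":
        return annual_sum(fields)
    for f in fields:
        if f.time_label == time_selector:
            return f
    raise ValidationError(f"no field with time_label {time_selector!r}")
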