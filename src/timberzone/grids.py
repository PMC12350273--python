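"""Lattice containers for climate stacks and suitability surfaces.

A :class:`ClimateGrid` holds the 17 annual climate variables produced by
dynamic downscaling tools (ClimateAP-style) as co-registered 2-D lattices.
Two of the variables are *derived* rather than primary:

* ``TD``  = ``MWMT - MCMT``  (continentality)
* ``AHM`` = ``(MAT + 10) / (MAP / 1000)``  (annual heat:moisture index)

These identities are enforced by construction everywhere a grid is created
or perturbed, and re-checked by :meth:`ClimateGrid.validate`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

#: The 17 annual climate variable codes, in canonical order.
CLIMATE_VARIABLES: tuple[str, ...] = (
    "MAT", "MWMT", "MCMT", "TD", "MAP", "AHM",
    "DD<0", "DD>5", "DD<18", "DD>18",
    "NFFD", "PAS", "EMT", "EXT", "Eref", "CMD", "RH",
)

#: Temperature-like variables that take additive scenario shifts (deg C).
TEMPERATURE_VARIABLES: frozenset[str] = frozenset(
    {"MAT", "MWMT", "MCMT", "EMT", "EXT"}
)

#: Variables recomputed from their parents, never perturbed directly.
DERIVED_VARIABLES: frozenset[str] = frozenset({"TD", "AHM"})

#: Degree-day variable codes (non-negative by definition).
DEGREE_DAY_VARIABLES: tuple[str, ...] = ("DD<0", "DD>5", "DD<18", "DD>18")

_SAFE_NAMES = {"DD<0": "DD_lt_0", "DD>5": "DD_gt_5",
               "DD<18": "DD_lt_18", "DD>18": "DD_gt_18"}
_SAFE_NAMES_INV = {v: k for k, v in _SAFE_NAMES.items()}

#: Mean Earth radius, km (spherical model).
EARTH_RADIUS_KM = 6371.0
#: Kilometres per degree of latitude on that sphere.
KM_PER_DEGREE = EARTH_RADIUS_KM * np.pi / 180.0


class GridError(ValueError):
    """Raised when a lattice violates a structural invariant."""


@dataclass(frozen=True)
class GridTransform:
    """Affine placement of a lattice in geographic coordinates.

    Row 0 / col 0 is the north-west corner; cell centres are returned.
    The default origin sits inside the species' natural range in
    subtropical China (23°30′–33°30′N, 103°30′–122°00′E).
    """

    lon_min: float = 104.0
    lat_max: float = 33.0
    cell_deg: float = 10.0 / KM_PER_DEGREE

    def cell_center(self, row, col):
        lon = self.lon_min + (np.asarray(col) + 0.5) * self.cell_deg
        lat = self.lat_max - (np.asarray(row) + 0.5) * self.cell_deg
        return lon, lat

    def cell_index(self, lon, lat):
        col = np.floor((np.asarray(lon) - self.lon_min) / self.cell_deg)
        row = np.floor((self.lat_max - np.asarray(lat)) / self.cell_deg)
        return row.astype(int), col.astype(int)


@dataclass
class ClimateGrid:
    """Co-registered stack of the 17 annual climate variables."""

    variables: dict[str, np.ndarray]
    cell_size_km: float = 10.0
    period_label: str = "1961-1990"
    scenario_label: str = "current"
    nodata_mask: np.ndarray | None = None  # True where no data
    transform: GridTransform = field(default_factory=GridTransform)

    def __post_init__(self):
        if not self.variables:
            raise GridError("climate grid holds no variables")
        shapes = {v.shape for v in self.variables.values()}
        if len(shapes) != 1:
            raise GridError(f"variable lattices disagree in shape: {shapes}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.shape, dtype=bool)
        if self.nodata_mask.shape != self.shape:
            raise GridError("nodata mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.variables.values())).shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean lattice, True at cells carrying data."""
        return ~self.nodata_mask

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def cell_area_km2(self) -> float:
        return float(self.cell_size_km) ** 2

    def copy(self) -> "ClimateGrid":
        return replace(
            self,
            variables={k: v.copy() for k, v in self.variables.items()},
            nodata_mask=self.nodata_mask.copy(),
        )

    def validate(self, *, atol: float = 1e-9, rtol: float = 1e-6) -> None:
        """Check every structural invariant; raise :class:`GridError` on failure."""
        m = self.valid
        v = self.variables
        missing = [c for c in CLIMATE_VARIABLES if c not in v]
        if missing:
            raise GridError(f"missing climate variables: {missing}")
        if np.any(v["MAP"][m] < 0):
            raise GridError("MAP has negative cells")
        if np.any((v["RH"][m] < 0) | (v["RH"][m] > 100)):
            raise GridError("RH outside [0, 100]")
        for code in DEGREE_DAY_VARIABLES:
            if np.any(v[code][m] < 0):
                raise GridError(f"{code} has negative cells")
        if np.any((v["NFFD"][m] < 0) | (v["NFFD"][m] > 366)):
            raise GridError("NFFD outside [0, 366]")
        if not np.allclose(v["TD"][m], v["MWMT"][m] - v["MCMT"][m], atol=atol):
            raise GridError("TD != MWMT - MCMT")
        wet = m & (v["MAP"] > 0)
        ahm = (v["MAT"][wet] + 10.0) / (v["MAP"][wet] / 1000.0)
        if not np.allclose(v["AHM"][wet], ahm, rtol=rtol):
            raise GridError("AHM identity violated")
        chain = (v["EXT"][m] >= v["MWMT"][m]) & (v["MWMT"][m] >= v["MAT"][m]) \
            & (v["MAT"][m] >= v["MCMT"][m]) & (v["MCMT"][m] >= v["EMT"][m])
        if not chain.all():
            raise GridError("temperature ordering EXT>=MWMT>=MAT>=MCMT>=EMT violated")

    def table(self, rows: np.ndarray, cols: np.ndarray):
        """Extract a (points x variables) predictor table at lattice cells."""
        import pandas as pd

        data = {c: self.variables[c][rows, cols] for c in CLIMATE_VARIABLES}
        return pd.DataFrame(data)


def derive_td(mwmt: np.ndarray, mcmt: np.ndarray) -> np.ndarray:
    return mwmt - mcmt


def derive_ahm(mat: np.ndarray, map_: np.ndarray) -> np.ndarray:
    """Annual heat:moisture index, (MAT + 10) / (MAP / 1000)."""
    with np.errstate(divide="ignore"):
        return np.where(map_ > 0, (mat + 10.0) / (map_ / 1000.0), np.inf)


@dataclass
class SuitabilitySurface:
    """Model-predicted (or generative-truth) habitat suitability in [0, 1]."""

    values: np.ndarray
    model_tag: str = "truth"
    period_label: str = "1961-1990"
    scenario_label: str = "current"
    nodata_mask: np.ndarray | None = None
    cell_size_km: float = 10.0
    transform: GridTransform = field(default_factory=GridTransform)

    def __post_init__(self):
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        m = ~self.nodata_mask
        vals = self.values[m]
        if vals.size and (np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1 + 1e-12):
            raise GridError("suitability values outside [0, 1]")

    @property
    def shape(self):
        return self.values.shape

    @property
    def valid(self):
        return ~self.nodata_mask

    @property
    def cell_area_km2(self) -> float:
        return float(self.cell_size_km) ** 2


# ---------------------------------------------------------------------------
# Text raster I/O (ESRI ASCII grid + JSON sidecar)

def _write_ascii(path: Path, lattice: np.ndarray, mask: np.ndarray,
                 transform: GridTransform, nodata: float = -9999.0) -> None:
    nrows, ncols = lattice.shape
    out = np.where(mask, nodata, lattice)
    yll = transform.lat_max - nrows * transform.cell_deg
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {transform.lon_min!r}\nyllcorner {yll!r}\n"
        f"cellsize {transform.cell_deg!r}\nNODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def _read_ascii(path: Path) -> tuple[np.ndarray, np.ndarray, GridTransform]:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        data = np.loadtxt(fh).reshape(int(hdr["nrows"]), int(hdr["ncols"]))
    mask = data == hdr["nodata_value"]
    tr = GridTransform(
        lon_min=hdr["xllcorner"],
        lat_max=hdr["yllcorner"] + hdr["nrows"] * hdr["cellsize"],
        cell_deg=hdr["cellsize"],
    )
    return data, mask, tr


def write_climate_grid(grid: ClimateGrid, directory: str | Path) -> Path:
    """Write one ASCII-grid file per variable plus a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for code, lattice in grid.variables.items():
        fname = _SAFE_NAMES.get(code, code) + ".asc"
        _write_ascii(directory / fname, lattice, grid.nodata_mask, grid.transform)
    meta = {
        "variables": list(grid.variables),
        "cell_size_km": grid.cell_size_km,
        "period_label": grid.period_label,
        "scenario_label": grid.scenario_label,
    }
    (directory / "grid.json").write_text(json.dumps(meta, indent=2))
    return directory


def read_climate_grid(directory: str | Path) -> ClimateGrid:
    directory = Path(directory)
    meta = json.loads((directory / "grid.json").read_text())
    variables, mask, tr = {}, None, None
    for code in meta["variables"]:
        fname = _SAFE_NAMES.get(code, code) + ".asc"
        lattice, m, tr = _read_ascii(directory / fname)
        variables[code] = lattice
        mask = m if mask is None else (mask | m)
    return ClimateGrid(
        variables=variables,
        cell_size_km=meta["cell_size_km"],
        period_label=meta["period_label"],
        scenario_label=meta["scenario_label"],
        nodata_mask=mask,
        transform=tr,
    )


def write_surface(surface: SuitabilitySurface, path: str | Path) -> Path:
    path = Path(path)
    _write_ascii(path, surface.values, surface.nodata_mask, surface.transform)
    return path
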