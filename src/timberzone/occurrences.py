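"""Occurrence handling: reading, validation, spatial thinning, pseudo-absences.

Occurrence sets are plain DataFrames with columns ``lon, lat, label, source``
(label 1 = presence, 0 = absence).  Distances are great-circle (haversine)
on a sphere of radius 6371 km.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import EARTH_RADIUS_KM, GridTransform

#: The species' natural range box (lon_min, lon_max, lat_min, lat_max).
NATURAL_RANGE_BOUNDS = (103.5, 122.0, 23.5, 33.5)

REQUIRED_COLUMNS = ("lon", "lat")


class SchemaError(ValueError):
    """Input table does not match the documented column schema."""


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between coordinate arrays (degrees)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_distances_km(df: pd.DataFrame) -> np.ndarray:
    """All-pairs haversine distance matrix for an occurrence frame."""
    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    return haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


def read_occurrences(
    path: str | Path,
    bounds: tuple[float, float, float, float] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Read an occurrence CSV, validating rows and optionally box-filtering.

    Returns ``(frame, diagnostics)`` where diagnostics lists each rejected
    row with its reason.  Missing ``lon``/``lat`` columns raise
    :class:`SchemaError`; ``label`` defaults to 1 and ``source`` to the file
    stem when absent.  ``bounds`` is ``(lon_min, lon_max, lat_min, lat_max)``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    if "label" not in df.columns:
        df["label"] = 1
    if "source" not in df.columns:
        df["source"] = path.stem

    diagnostics: list[str] = []
    keep = np.ones(len(df), dtype=bool)
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    for i in range(len(df)):
        if not np.isfinite(lon.iloc[i]) or not np.isfinite(lat.iloc[i]):
            diagnostics.append(f"row {i}: non-numeric coordinates")
            keep[i] = False
        elif not -180.0 <= lon.iloc[i] <= 180.0:
            diagnostics.append(f"row {i}: longitude {lon.iloc[i]} outside [-180, 180]")
            keep[i] = False
        elif not -90.0 <= lat.iloc[i] <= 90.0:
            diagnostics.append(f"row {i}: latitude {lat.iloc[i]} outside [-90, 90]")
            keep[i] = False
    df = df.loc[keep].copy()
    df["lon"] = lon[keep]
    df["lat"] = lat[keep]
    if bounds is not None:
        lon_min, lon_max, lat_min, lat_max = bounds
        inside = (
            df["lon"].between(lon_min, lon_max)
            & df["lat"].between(lat_min, lat_max)
        )
        df = df.loc[inside].copy()
    if df.empty:
        warnings.warn(f"{path.name}: no occurrence rows survived validation",
                      stacklevel=2)
    return df.reset_index(drop=True), diagnostics


#: Conflict components up to this size are thinned to a provably maximum
#: retained subset; larger components fall back to greedy removal.
_EXACT_COMPONENT_CAP = 18


def _mis_size(mask: int, closed_nbrs: list[int], cache: dict) -> int:
    """Maximum independent set size on the subgraph induced by ``mask``."""
    if mask == 0:
        return 0
    hit = cache.get(mask)
    if hit is not None:
        return hit
    v = (mask & -mask).bit_length() - 1
    out = max(_mis_size(mask & ~(1 << v), closed_nbrs, cache),
              1 + _mis_size(mask & ~closed_nbrs[v], closed_nbrs, cache))
    cache[mask] = out
    return out


def _thin_component_exact(comp: list[int], conflict: np.ndarray) -> list[int]:
    """Lexicographically-smallest maximum conflict-free subset of ``comp``."""
    k = len(comp)
    closed = [(1 << i) | sum(1 << j for j in range(k)
                             if conflict[comp[i], comp[j]])
              for i in range(k)]
    cache: dict = {}
    full = (1 << k) - 1
    target = _mis_size(full, closed, cache)
    chosen: list[int] = []
    mask = full
    for i in range(k):
        if not mask & (1 << i):
            continue
        with_i = mask & ~closed[i]
        if len(chosen) + 1 + _mis_size(with_i, closed, cache) >= target:
            chosen.append(i)  # taking i still reaches the maximum
            mask = with_i
        else:
            mask &= ~(1 << i)
    return [comp[i] for i in chosen]


def _thin_component_greedy(comp: list[int], conflict: np.ndarray) -> list[int]:
    """Repeatedly drop the most-conflicted point (lowest index on ties)."""
    alive = {i: True for i in comp}
    while True:
        degrees = {i: sum(conflict[i, j] for j in comp if alive[j])
                   for i in comp if alive[i]}
        worst = max(degrees.values(), default=0)
        if worst == 0:
            break
        victim = min(i for i, d in degrees.items() if d == worst)
        alive[victim] = False
    return [i for i in comp if alive[i]]


def thin_occurrences(
    df: pd.DataFrame, min_km: float = 5.0, seed: int | None = None
) -> pd.DataFrame:
    """Enforce a minimum great-circle distance between retained points.

    Retention is maximised: within each connected component of the
    conflict graph (pairs closer than ``min_km``) the largest conflict-free
    subset is kept, found exactly for components of up to 18 points
    (deterministic lexicographic tie-break) and by greedy most-conflicted
    removal for larger components.  ``seed`` is accepted for interface
    compatibility with randomised thinning tools but the procedure is
    deterministic.
    """
    if min_km <= 0:
        raise ValueError("thinning distance must be positive")
    n = len(df)
    if n <= 1:
        return df.reset_index(drop=True)
    dist = pairwise_distances_km(df)
    conflict = (dist < min_km) & ~np.eye(n, dtype=bool)

    # connected components of the conflict graph
    unvisited = set(range(n))
    keep: list[int] = []
    while unvisited:
        start = min(unvisited)
        comp, queue = [], [start]
        unvisited.discard(start)
        while queue:
            v = queue.pop()
            comp.append(v)
            for w in np.nonzero(conflict[v])[0]:
                if w in unvisited:
                    unvisited.discard(int(w))
                    queue.append(int(w))
        comp.sort()
        if len(comp) == 1:
            keep.extend(comp)
        elif len(comp) <= _EXACT_COMPONENT_CAP:
            keep.extend(_thin_component_exact(comp, conflict))
        else:
            keep.extend(_thin_component_greedy(comp, conflict))
    return df.loc[sorted(keep)].reset_index(drop=True)


def generate_pseudo_absences(
    n: int,
    mask: np.ndarray,
    transform: GridTransform,
    presences: pd.DataFrame,
    seed: int,
    source: str = "pseudo-absence",
) -> pd.DataFrame:
    """Uniform random background cells, excluding cells holding a presence.

    Cells are drawn without replacement from the study mask (True = inside),
    labels are 0 and coordinates are cell centres.  Requesting more points
    than free cells raises a capacity error naming the available count.
    """
    free = mask.copy()
    if len(presences):
        r, c = transform.cell_index(
            presences["lon"].to_numpy(), presences["lat"].to_numpy())
        inside = (r >= 0) & (r < mask.shape[0]) & (c >= 0) & (c < mask.shape[1])
        free[r[inside], c[inside]] = False
    rows, cols = np.nonzero(free)
    if n > rows.size:
        raise ValueError(
            f"requested {n} pseudo-absences but only {rows.size} free cells")
    rng = np.random.default_rng(seed)
    take = rng.choice(rows.size, size=n, replace=False)
    lon, lat = transform.cell_center(rows[take], cols[take])
    return pd.DataFrame({"lon": lon, "lat": lat, "label": 0, "source": source})


def assemble_dataset(presences: pd.DataFrame, absences: pd.DataFrame) -> pd.DataFrame:
    """Stack presences and pseudo-absences into one modelling frame."""
    return pd.concat([presences, absences], ignore_index=True)
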