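"""Suitability-to-zone classification and area accounting.

Habitat classes use the standard SDM breaks — unsuitable [0, 0.2), low
[0.2, 0.4), medium [0.4, 0.6), high [0.6, 1.0] (left-closed; a cell at
exactly 0.6 is high).  Timber eligibility requires annual DBH growth
strictly above 0.6 cm/yr AND wood basic density strictly above 0.5 g/cm^3.
Optimal / sub-optimal production zones are the top 10% / 20% of eligible
cells by a composite score (geometric mean of min-max-normalised growth and
density), with ties at a cutoff admitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import SuitabilitySurface
from .traits import TraitLinkResults, evaluate_form

HABITAT_LABELS = {0: "unsuitable", 1: "low", 2: "medium", 3: "high"}
TIMBER_LABELS = {0: "none", 1: "eligible", 2: "sub-optimal", 3: "optimal"}
NODATA_CODE = -1


@dataclass(frozen=True)
class ZoningConfig:
    """Thresholds and fractions governing all zoning steps."""

    habitat_breaks: tuple[float, float, float] = (0.2, 0.4, 0.6)
    growth_threshold_cm: float = 0.6
    density_threshold_gcm3: float = 0.5
    optimal_fraction: float = 0.10
    suboptimal_fraction: float = 0.20
    rank_by: str = "composite"  # or "suitability"

    def __post_init__(self):
        b = self.habitat_breaks
        if not (0 < b[0] < b[1] < b[2] < 1):
            raise ValueError("habitat breaks must be strictly increasing in (0, 1)")
        for f in (self.optimal_fraction, self.suboptimal_fraction):
            if not 0 < f <= 1:
                raise ValueError("zone fractions must lie in (0, 1]")
        if self.optimal_fraction > self.suboptimal_fraction:
            raise ValueError("optimal fraction must not exceed sub-optimal")


@dataclass
class ZoneMap:
    """Categorical lattice with a code table and per-cell area."""

    codes: np.ndarray  # int lattice; NODATA_CODE outside the mask
    labels: dict[int, str]
    cell_area_km2: float
    model_tag: str = ""
    period_label: str = ""
    scenario_label: str = ""

    @property
    def valid(self) -> np.ndarray:
        return self.codes != NODATA_CODE


@dataclass
class AreaSummary:
    """Per-class areas (km^2) and shares (% of total valid area)."""

    area_km2: dict[str, float]
    share_pct: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.share_pct:
            total = sum(self.area_km2.values())
            self.share_pct = {
                k: (100.0 * a / total if total > 0 else 0.0)
                for k, a in self.area_km2.items()}

    @property
    def total_km2(self) -> float:
        return sum(self.area_km2.values())

    @classmethod
    def from_zone_map(cls, zones: ZoneMap) -> "AreaSummary":
        areas = {}
        for code, label in zones.labels.items():
            areas[label] = float((zones.codes == code).sum()) * zones.cell_area_km2
        return cls(area_km2=areas)

    @classmethod
    def from_areas(cls, area_km2: dict[str, float]) -> "AreaSummary":
        """Summary from externally reported per-class areas."""
        return cls(area_km2=dict(area_km2))


def classify_habitat(surface: SuitabilitySurface,
                     cfg: ZoningConfig = ZoningConfig()) -> ZoneMap:
    """Four-class habitat map by left-closed suitability intervals."""
    codes = np.digitize(surface.values, cfg.habitat_breaks, right=False)
    codes = codes.astype(int)
    codes[~surface.valid] = NODATA_CODE
    return ZoneMap(codes=codes, labels=dict(HABITAT_LABELS),
                   cell_area_km2=surface.cell_area_km2,
                   model_tag=surface.model_tag,
                   period_label=surface.period_label,
                   scenario_label=surface.scenario_label)


def predict_trait_surface(link: TraitLinkResults,
                          surface: SuitabilitySurface) -> tuple[np.ndarray, int]:
    """Apply a fitted trait-suitability form cellwise.

    For a lag-1 growth link the supplied surface must be the *prior* year's
    suitability.  Returns ``(trait lattice, n_masked)`` where cells outside
    the form's domain (e.g. log at suitability 0) are NaN and counted.
    """
    values = evaluate_form(link.form, link.coefs, surface.values)
    values = np.where(surface.valid, values, np.nan)
    n_masked = int(np.isnan(values[surface.valid]).sum())
    if n_masked:
        warnings.warn(
            f"{n_masked} cells outside the domain of the {link.form} form",
            stacklevel=2)
    return values, n_masked


def delineate_timber_zones(growth_surface: np.ndarray,
                           density_surface: np.ndarray,
                           reference: SuitabilitySurface,
                           cfg: ZoningConfig = ZoningConfig()) -> ZoneMap:
    """Timber eligibility: growth > 0.6 cm/yr AND density > 0.5 g/cm^3."""
    if growth_surface.shape != density_surface.shape:
        raise ValueError(
            f"surfaces not co-registered: {growth_surface.shape} vs "
            f"{density_surface.shape}")
    with np.errstate(invalid="ignore"):
        eligible = ((growth_surface > cfg.growth_threshold_cm)
                    & (density_surface > cfg.density_threshold_gcm3))
    codes = eligible.astype(int)
    codes[~reference.valid] = NODATA_CODE
    return ZoneMap(codes=codes, labels={0: "none", 1: "eligible"},
                   cell_area_km2=reference.cell_area_km2,
                   model_tag=reference.model_tag,
                   period_label=reference.period_label,
                   scenario_label=reference.scenario_label)


def rank_percentile_zones(growth_surface: np.ndarray,
                          density_surface: np.ndarray,
                          eligibility: ZoneMap,
                          cfg: ZoningConfig = ZoningConfig(),
                          suitability: SuitabilitySurface | None = None) -> ZoneMap:
    """Optimal (top 10%) and sub-optimal (top 20%) production zones.

    The composite score over eligible cells is the geometric mean of
    min-max-normalised growth and density (or raw suitability when
    ``cfg.rank_by == "suitability"``).  The top-f cutoff is the
    ceil(f * n)-th largest score; all ties at the cutoff are admitted, so
    optimal cells are always nested inside sub-optimal cells.
    """
    codes = np.where(eligibility.codes == 1, 1, eligibility.codes)
    mask = eligibility.codes == 1
    n_elig = int(mask.sum())
    out = ZoneMap(codes=codes, labels=dict(TIMBER_LABELS),
                  cell_area_km2=eligibility.cell_area_km2,
                  model_tag=eligibility.model_tag,
                  period_label=eligibility.period_label,
                  scenario_label=eligibility.scenario_label)
    if n_elig == 0:
        warnings.warn("no eligible cells; optimal/sub-optimal zones are empty",
                      stacklevel=2)
        return out
    if cfg.rank_by == "suitability":
        if suitability is None:
            raise ValueError("suitability surface required for rank_by='suitability'")
        score = suitability.values[mask]
    else:
        def _norm(v):
            vals = v[mask]
            rng = vals.max() - vals.min()
            return np.ones_like(vals) if rng == 0 else (vals - vals.min()) / rng

        score = np.sqrt(_norm(growth_surface) * _norm(density_surface))

    order = np.sort(score)[::-1]
    for frac, code in ((cfg.suboptimal_fraction, 2), (cfg.optimal_fraction, 3)):
        k = int(np.ceil(frac * n_elig))
        cutoff = order[k - 1]
        sel = np.zeros_like(mask)
        sel[mask] = score >= cutoff
        out.codes[sel] = code
    return out


def area_summary(zones: ZoneMap) -> AreaSummary:
    """Exact per-class area and share accounting."""
    return AreaSummary.from_zone_map(zones)


def change_stats(current: AreaSummary, future: AreaSummary) -> dict[str, float | None]:
    """Per-class percent change, 100 * (future - current) / current.

    A class absent now (area 0) has undefined change, reported as None.
    """
    if set(current.area_km2) != set(future.area_km2):
        raise ValueError(
            f"class vocabulary mismatch: {sorted(current.area_km2)} vs "
            f"{sorted(future.area_km2)}")
    return {k: percent_change(current.area_km2[k], future.area_km2[k])
            for k in current.area_km2}


def percent_change(current: float, future: float) -> float | None:
    """100 * (future - current) / current; None when current is zero."""
    if current == 0:
        return None
    return 100.0 * (future - current) / current
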