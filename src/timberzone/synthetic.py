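"""Synthetic landscape and trait generator.

Emulates the statistical structure of the study inputs at desk scale: 17
spatially autocorrelated annual climate fields with the derived-variable
identities intact, a known true suitability surface driven by continentality
(TD), precipitation (MAP) and moisture deficit (CMD), presence samples drawn
from that surface, warmer/drier future scenario grids, and ring-width trait
series whose growth responds more strongly to the *previous* year's
suitability than to the current year's (a lag-1 climatic effect).

Everything here is a pure function of its parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grids import (
    CLIMATE_VARIABLES,
    DERIVED_VARIABLES,
    TEMPERATURE_VARIABLES,
    ClimateGrid,
    GridError,
    GridTransform,
    SuitabilitySurface,
    derive_ahm,
    derive_td,
)

#: Suitability drivers used by the generative truth.
TRUTH_DRIVERS = ("TD", "MAP", "CMD")


@dataclass(frozen=True)
class TruthParams:
    """Generative parameters of the synthetic study.

    ``beta`` applies to z-scored driver fields; the defaults make wetter,
    less continental, less moisture-stressed cells more suitable, matching
    the humid-subtropical optimum of the modelled species, and are strong
    enough (with the negative intercept) that high suitability is confined
    to a small fraction of the landscape — the sharp realised niche that
    real occurrence compilations exhibit.  ``growth_coeffs`` = (g0, g1, g2)
    with g1 the previous-year and g2 the current-year suitability weight
    (cm / yr); the default g1 > g2 embeds the lag-1 growth response.
    ``density_coeffs`` = (d0, d1) in g / cm^3.  ``site_sd_growth`` is a
    persistent between-site growth offset (microsite / stand quality),
    drawn once per site.
    """

    beta0: float = -8.0
    beta: dict = field(
        default_factory=lambda: {"TD": -2.4, "MAP": 3.0, "CMD": -3.6}
    )
    growth_coeffs: tuple[float, float, float] = (0.15, 0.55, 0.15)
    density_coeffs: tuple[float, float] = (0.40, 0.35)
    noise_sd_growth: float = 0.08
    noise_sd_density: float = 0.04
    site_sd_growth: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd_growth < 0 or self.noise_sd_density < 0:
            raise ValueError("noise standard deviations must be >= 0")


def gaussian_field(shape, rng, smoothness: float = 4.0) -> np.ndarray:
    """Zero-mean, unit-sd spatially autocorrelated field.

    White noise convolved with a Gaussian kernel of radius ``smoothness``
    cells, then re-standardised.  Larger smoothness -> longer-range
    autocorrelation.
    """
    noise = rng.standard_normal(shape)
    f = gaussian_filter(noise, sigma=smoothness, mode="reflect")
    sd = f.std()
    if sd == 0:  # pragma: no cover - degenerate one-cell field
        return np.zeros(shape)
    return (f - f.mean()) / sd


def generate_climate_grid(
    shape: tuple[int, int],
    seed: int,
    smoothness: float = 4.0,
    cell_size_km: float = 10.0,
    transform: GridTransform | None = None,
    period_label: str = "1961-1990",
    scenario_label: str = "current",
) -> ClimateGrid:
    """Generate a structurally valid 17-variable climate stack.

    Base variables are independent smoothed-noise fields placed on realistic
    subtropical scales; TD and AHM are always derived from their parents,
    and the temperature chain EXT >= MWMT >= MAT >= MCMT >= EMT is enforced
    by construction (amplitudes are strictly positive offsets).
    """
    nrows, ncols = int(shape[0]), int(shape[1])
    if nrows <= 0 or ncols <= 0:
        raise GridError(f"grid shape must be positive, got {shape}")
    rng = np.random.default_rng(seed)
    f = {k: gaussian_field((nrows, ncols), rng, smoothness)
         for k in ("mat", "amp_w", "amp_c", "ext", "emt", "map", "cmd",
                   "rh", "dd", "nffd", "pas", "eref")}

    v: dict[str, np.ndarray] = {}
    v["MAT"] = 16.0 + 4.0 * f["mat"]
    warm_amp = np.clip(9.0 + 1.5 * f["amp_w"], 2.0, None)
    cold_amp = np.clip(13.0 + 2.5 * f["amp_c"], 2.0, None)
    v["MWMT"] = v["MAT"] + warm_amp
    v["MCMT"] = v["MAT"] - cold_amp
    v["EXT"] = v["MWMT"] + np.clip(6.0 + 1.5 * f["ext"], 0.5, None)
    v["EMT"] = v["MCMT"] - np.clip(10.0 + 2.0 * f["emt"], 0.5, None)
    v["TD"] = derive_td(v["MWMT"], v["MCMT"])
    v["MAP"] = np.clip(1300.0 + 450.0 * f["map"], 60.0, None)
    v["AHM"] = derive_ahm(v["MAT"], v["MAP"])
    # degree-days track MAT; chilling runs opposite to growing degree-days
    v["DD>5"] = np.clip(4200.0 + 330.0 * (v["MAT"] - 16.0) + 150.0 * f["dd"], 0.0, None)
    v["DD<0"] = np.clip(90.0 - 28.0 * (v["MAT"] - 16.0) + 25.0 * f["dd"], 0.0, None)
    v["DD<18"] = np.clip(1500.0 - 110.0 * (v["MAT"] - 16.0) - 60.0 * f["dd"], 0.0, None)
    v["DD>18"] = np.clip(650.0 + 130.0 * (v["MAT"] - 16.0) + 80.0 * f["dd"], 0.0, None)
    v["NFFD"] = np.clip(265.0 + 9.0 * (v["MAT"] - 16.0) + 12.0 * f["nffd"], 0.0, 366.0)
    v["PAS"] = np.clip(25.0 - 8.0 * (v["MAT"] - 16.0) + 12.0 * f["pas"], 0.0, None)
    v["Eref"] = np.clip(900.0 + 40.0 * (v["MAT"] - 16.0) + 90.0 * f["eref"], 0.0, None)
    # moisture deficit rises with evaporative demand, falls with rainfall
    v["CMD"] = np.clip(
        430.0 + 0.45 * (v["Eref"] - 900.0) - 0.22 * (v["MAP"] - 1300.0)
        + 140.0 * f["cmd"], 0.0, None)
    v["RH"] = np.clip(70.0 + 7.0 * (0.6 * f["rh"] + 0.4 * f["map"]), 0.0, 100.0)

    grid = ClimateGrid(
        variables={c: v[c] for c in CLIMATE_VARIABLES},
        cell_size_km=cell_size_km,
        period_label=period_label,
        scenario_label=scenario_label,
        transform=transform or GridTransform(),
    )
    grid.validate()
    return grid


@dataclass(frozen=True)
class ScenarioDeltas:
    """Additive temperature shifts (deg C) and multiplicative MAP factor.

    ``cmd_warming_gain`` (mm / deg C) and ``cmd_drying_gain`` (dimensionless)
    parameterise the monotone moisture-deficit response
    ``CMD' = max(0, CMD + a * dMAT - b * (factor - 1) * MAP)``: warming or
    drying never decreases CMD.
    """

    temp_shift: float = 0.0
    map_factor: float = 1.0
    label: str = "current"
    period: str = "1961-1990"
    cmd_warming_gain: float = 30.0
    cmd_drying_gain: float = 0.30

    def __post_init__(self):
        if np.any(np.asarray(self.map_factor) <= 0):
            raise ValueError("precipitation factor must be > 0")


#: Emulated scenario set: intermediate (SSP2-4.5) and high (SSP5-8.5)
#: emission pathways for the 2020s and 2050s, warmer and slightly drier.
SCENARIO_PRESETS: dict[tuple[str, str], ScenarioDeltas] = {
    ("2020s", "SSP2-4.5"): ScenarioDeltas(1.2, 0.97, "SSP2-4.5", "2020s"),
    ("2020s", "SSP5-8.5"): ScenarioDeltas(1.5, 0.95, "SSP5-8.5", "2020s"),
    ("2050s", "SSP2-4.5"): ScenarioDeltas(2.2, 0.94, "SSP2-4.5", "2050s"),
    ("2050s", "SSP5-8.5"): ScenarioDeltas(3.0, 0.90, "SSP5-8.5", "2050s"),
}


def project_future_climate(grid: ClimateGrid, deltas: ScenarioDeltas) -> ClimateGrid:
    """Apply a scenario perturbation and recompute all derived variables.

    Temperature lattices shift additively, MAP scales multiplicatively,
    TD / AHM are recomputed from the perturbed parents, CMD follows the
    monotone rule documented on :class:`ScenarioDeltas`, and the secondary
    thermal variables (degree-days, NFFD, PAS, Eref) move monotonically with
    the shift.  Zero shift and unit factor return an identical grid.
    """
    out = grid.copy()
    v = out.variables
    dt = np.asarray(deltas.temp_shift, dtype=float)
    factor = float(deltas.map_factor)
    for code in TEMPERATURE_VARIABLES:
        v[code] = v[code] + dt
    v["MAP"] = v["MAP"] * factor
    v["TD"] = derive_td(v["MWMT"], v["MCMT"])
    v["AHM"] = derive_ahm(v["MAT"], v["MAP"])
    v["CMD"] = np.clip(
        v["CMD"] + deltas.cmd_warming_gain * dt
        - deltas.cmd_drying_gain * (factor - 1.0) * v["MAP"] / factor,
        0.0, None)
    v["DD>5"] = np.clip(v["DD>5"] + 330.0 * dt, 0.0, None)
    v["DD<0"] = np.clip(v["DD<0"] - 28.0 * dt, 0.0, None)
    v["DD<18"] = np.clip(v["DD<18"] - 110.0 * dt, 0.0, None)
    v["DD>18"] = np.clip(v["DD>18"] + 130.0 * dt, 0.0, None)
    v["NFFD"] = np.clip(v["NFFD"] + 9.0 * dt, 0.0, 366.0)
    v["PAS"] = np.clip(v["PAS"] - 8.0 * dt, 0.0, None)
    v["Eref"] = np.clip(v["Eref"] + 40.0 * dt, 0.0, None)
    rh_scale = 20.0 * (1.0 - factor)
    v["RH"] = np.clip(v["RH"] - rh_scale, 0.0, 100.0)
    out.period_label = deltas.period
    out.scenario_label = deltas.label
    return out


def true_suitability_surface(
    grid: ClimateGrid, truth: TruthParams, reference: ClimateGrid | None = None
) -> SuitabilitySurface:
    """Logistic suitability over z-scored driver fields.

    S(cell) = expit(beta0 + sum_v beta_v * z_v(cell)), z-scores taken over
    valid cells.  A constant driver field has no z-score and is rejected.
    When ``reference`` is given (e.g. the current-period normals while
    scoring a scenario or single-year grid), the z-scoring uses the
    reference field's mean and sd, so uniform climate shifts move the
    suitability instead of being absorbed by re-standardisation.
    """
    m = grid.valid
    ref = reference if reference is not None else grid
    eta = np.full(grid.shape, truth.beta0, dtype=float)
    for code, b in truth.beta.items():
        if code not in grid.variables:
            raise KeyError(f"driver variable {code!r} missing from grid")
        vals = grid.variables[code]
        ref_vals = ref.variables[code][ref.valid]
        sd = ref_vals.std()
        if sd == 0:
            raise GridError(f"driver field {code!r} is constant; z-score undefined")
        eta = eta + b * (vals - ref_vals.mean()) / sd
    values = expit(eta)
    values[~m] = np.nan
    values = np.where(m, values, 0.0)
    return SuitabilitySurface(
        values=values,
        model_tag="truth",
        period_label=grid.period_label,
        scenario_label=grid.scenario_label,
        nodata_mask=grid.nodata_mask.copy(),
        cell_size_km=grid.cell_size_km,
        transform=grid.transform,
    )


def sample_occurrences(
    surface: SuitabilitySurface, n_presence: int, seed: int
) -> pd.DataFrame:
    """Draw presence cells without replacement, probability proportional to S.

    Sequential probability-proportional-to-size sampling implemented through
    Gumbel-top-k keys (equivalent to successive weighted draws without
    replacement).  Returns a ``lon, lat, label, source`` frame with
    coordinates at cell centres.
    """
    m = surface.valid & (surface.values > 0)
    rows, cols = np.nonzero(m)
    weights = surface.values[rows, cols].astype(float)
    if n_presence > rows.size:
        raise ValueError(
            f"requested {n_presence} presences but only {rows.size} valid cells")
    rng = np.random.default_rng(seed)
    gumbel = rng.gumbel(size=rows.size)
    keys = np.log(weights) + gumbel
    take = np.argsort(keys)[::-1][:n_presence]
    lon, lat = surface.transform.cell_center(rows[take], cols[take])
    return pd.DataFrame(
        {"lon": lon, "lat": lat, "label": 1, "source": "synthetic-survey"}
    )


def perturb_climate_grid(
    grid: ClimateGrid,
    rng: np.random.Generator,
    temp_sd: float = 0.5,
    map_sd: float = 0.06,
    smoothness: float = 3.0,
) -> ClimateGrid:
    """One interannual realisation: smooth anomaly fields around the normals.

    Temperature variables receive a shared autocorrelated anomaly (sd
    ``temp_sd`` deg C), MAP a multiplicative log-normal-style factor field
    (sd ~ ``map_sd``); TD, AHM and CMD are recomputed via the same monotone
    rules used for scenario projection.
    """
    dt_field = temp_sd * gaussian_field(grid.shape, rng, smoothness)
    factor_field = np.exp(map_sd * gaussian_field(grid.shape, rng, smoothness))
    out = grid.copy()
    v = out.variables
    for code in TEMPERATURE_VARIABLES:
        v[code] = v[code] + dt_field
    v["MAP"] = v["MAP"] * factor_field
    v["TD"] = derive_td(v["MWMT"], v["MCMT"])
    v["AHM"] = derive_ahm(v["MAT"], v["MAP"])
    v["CMD"] = np.clip(
        v["CMD"] + 30.0 * dt_field - 0.30 * (factor_field - 1.0) * v["MAP"] / factor_field,
        0.0, None)
    return out


def annual_suitability_series(
    grid: ClimateGrid,
    predict,
    sites: pd.DataFrame,
    n_years: int,
    seed: int,
    temp_sd: float = 0.5,
    map_sd: float = 0.06,
) -> np.ndarray:
    """(n_sites x n_years) suitability series from per-year perturbed grids.

    ``predict`` maps a ClimateGrid to a SuitabilitySurface (the generative
    truth or a fitted model's ``predict_surface``).  Year order is
    chronological (column 0 = earliest).
    """
    rng = np.random.default_rng(seed)
    r, c = grid.transform.cell_index(sites["lon"].to_numpy(), sites["lat"].to_numpy())
    series = np.empty((len(sites), n_years))
    for year in range(n_years):
        annual = perturb_climate_grid(grid, rng, temp_sd=temp_sd, map_sd=map_sd)
        surf = predict(annual)
        series[:, year] = surf.values[r, c]
    return series


def simulate_traits(
    sites: pd.DataFrame,
    annual_suitability: np.ndarray,
    truth: TruthParams,
    n_rings: int = 20,
    seed: int | None = None,
) -> pd.DataFrame:
    """Ring-width traits from the lagged growth model.

    growth_t = g0 + u_s + g1 * S_{t-1} + g2 * S_t + eps_t  (cm / yr, >= 0)
    density  = d0 + d1 * mean(S over ring years) + eps_d   (g / cm^3)

    u_s is a persistent site offset with sd ``truth.site_sd_growth``
    (set it to 0 for the pure two-lag model).

    ``annual_suitability`` is (n_sites x >= n_rings + 1) chronological; the
    first column is the year preceding the first ring.  Output rings are
    stored outermost-first (``ring01`` = most recent year) and the 20-year
    DBH growth is the exact sum of the annual increments.  A ``truncated``
    column counts increments clipped at zero.
    """
    S = np.asarray(annual_suitability, dtype=float)
    if S.ndim != 2 or S.shape[0] != len(sites):
        raise ValueError("annual_suitability must be (n_sites x n_years)")
    if S.shape[1] < n_rings + 1:
        raise ValueError(
            f"need >= {n_rings + 1} suitability years (lag-1 requires a "
            f"preceding year), got {S.shape[1]}")
    g0, g1, g2 = truth.growth_coeffs
    d0, d1 = truth.density_coeffs
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    S = S[:, -(n_rings + 1):]
    prev, curr = S[:, :-1], S[:, 1:]
    growth = g0 + g1 * prev + g2 * curr
    if truth.site_sd_growth > 0:
        growth = growth + rng.normal(0.0, truth.site_sd_growth,
                                     (len(sites), 1))
    if truth.noise_sd_growth > 0:
        growth = growth + rng.normal(0.0, truth.noise_sd_growth, growth.shape)
    truncated = (growth < 0).sum(axis=1)
    growth = np.clip(growth, 0.0, None)
    density = d0 + d1 * curr.mean(axis=1)
    if truth.noise_sd_density > 0:
        density = density + rng.normal(0.0, truth.noise_sd_density, density.shape)
    density = np.clip(density, 1e-6, None)

    out = pd.DataFrame({
        "pop": [f"P{i + 1:02d}" for i in range(len(sites))],
        "lon": sites["lon"].to_numpy(),
        "lat": sites["lat"].to_numpy(),
        "growth20_cm": growth.sum(axis=1),
    })
    # ring01 = outermost = most recent growth year
    for k in range(n_rings):
        out[f"ring{k + 1:02d}_cm"] = growth[:, n_rings - 1 - k]
    out["density_gcm3"] = density
    out["truncated"] = truncated
    return out


def rings_to_chronological(traits: pd.DataFrame, n_rings: int = 20) -> np.ndarray:
    """(n_sites x n_rings) annual growth, column 0 = earliest year."""
    cols = [f"ring{k:02d}_cm" for k in range(n_rings, 0, -1)]
    return traits[cols].to_numpy()
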