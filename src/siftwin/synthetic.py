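"""Synthetic inputs for twin experiments.

Generates, from a grid definition and a seed, everything the assimilation needs:
daily forcing with latitudinal gradients and AR(1) weather noise, PFT
fraction maps with guaranteed high-coverage cells per PFT, a Köppen-Geiger
class map, a "truth" parameter vector, and noisy monthly SIF
pseudo-observations y = H(truth) + eps with diagonal Gaussian noise.

Every generator is a pure function of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.signal

from siftwin.param_space import (
    ParameterTable,
    ParameterVector,
    build_parameter_vector,
    default_parameter_table,
)
from siftwin.sif_operator import SIFField, SIFLinkParams, forward_sif
from siftwin.surrogate import (
    DAYS_PER_YEAR,
    Forcing,
    GPPField,
    PFTMap,
    SurrogateConfig,
    DEFAULT_CONFIG,
    simulate,
)

__all__ = [
    "Grid",
    "SyntheticScenario",
    "generate_forcing",
    "generate_pft_and_kg_maps",
    "make_truth_scenario",
    "make_observations",
    "make_benchmark_gpp",
    "make_scenario",
]

EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class Grid:
    """Regular lat-lon grid; cells are flattened row-major (lat, then lon)."""

    n_lat: int = 24
    n_lon: int = 36
    lat_min: float = -60.0
    lat_max: float = 84.0

    @property
    def n_cells(self) -> int:
        return self.n_lat * self.n_lon

    @property
    def lat_edges(self) -> np.ndarray:
        return np.linspace(self.lat_min, self.lat_max, self.n_lat + 1)

    @property
    def lat_centers(self) -> np.ndarray:
        e = self.lat_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        return (np.arange(self.n_lon) + 0.5) * 360.0 / self.n_lon

    @property
    def cell_lat(self) -> np.ndarray:
        return np.repeat(self.lat_centers, self.n_lon)

    @property
    def cell_lon(self) -> np.ndarray:
        return np.tile(self.lon_centers, self.n_lat)

    @property
    def cell_area(self) -> np.ndarray:
        """Spherical cell areas in m^2 (cos-lat weighted)."""
        e = np.deg2rad(self.lat_edges)
        dlam = 2.0 * np.pi / self.n_lon
        band = EARTH_RADIUS_M**2 * dlam * (np.sin(e[1:]) - np.sin(e[:-1]))
        return np.repeat(band, self.n_lon)

    def dry_mask(self) -> np.ndarray:
        """Cells in the configured arid bands (subtropics, western half)."""
        lat, lon = self.cell_lat, self.cell_lon
        return (np.abs(lat) >= 15) & (np.abs(lat) < 30) & (lon < 180.0)


# ---------------------------------------------------------------------------
# Forcing
# ---------------------------------------------------------------------------


def _ar1(rng: np.random.Generator, shape: tuple[int, int], sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) noise along axis 0 with marginal sd `sd`."""
    if sd == 0:
        return np.zeros(shape)
    eps = rng.standard_normal(shape) * sd * np.sqrt(1.0 - rho**2)
    eps[0] = rng.standard_normal(shape[1]) * sd
    return scipy.signal.lfilter([1.0], [1.0, -rho], eps, axis=0)


def generate_forcing(
    grid: Grid,
    years: int,
    seed: int,
    year0: int = 2007,
    temp_noise_sd: float = 2.0,
    temp_noise_rho: float = 0.8,
    moisture_noise_sd: float = 0.02,
) -> Forcing:
    """Seasonally sinusoidal daily forcing with latitudinal gradients.

    Temperature: mean decreasing poleward, seasonal amplitude increasing
    poleward (phase flipped in the south), plus AR(1) weather noise.
    Shortwave: noon solar-elevation proxy from declination.  Soil moisture:
    smooth seasonal cycle in [0, 1], with a pronounced dry season in the
    configured arid bands.
    """
    rng = np.random.default_rng(seed)
    lat, lon = grid.cell_lat, grid.cell_lon
    n_days = years * DAYS_PER_YEAR
    doy = (np.arange(n_days) % DAYS_PER_YEAR + 1).astype(float)[:, None]
    absl = np.abs(lat) / 90.0
    t_mean = 27.0 - 42.0 * absl**1.8
    amp = 3.0 + 20.0 * absl
    shift = np.where(lat < 0, 182.0, 0.0)
    seasonal = np.sin(2.0 * np.pi * (doy - 105.0 - shift[None, :]) / 365.0)
    tair = t_mean[None, :] + amp[None, :] * seasonal
    tair = tair + _ar1(rng, (n_days, grid.n_cells), temp_noise_sd, temp_noise_rho)

    decl = np.deg2rad(23.44) * np.sin(2.0 * np.pi * (doy + 284.0) / 365.0)
    phi = np.deg2rad(lat)[None, :]
    mu = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl)
    shortwave = np.maximum(0.0, 420.0 * mu)

    dry = grid.dry_mask()
    w0 = np.where(dry, 0.35, np.where(np.abs(lat) < 15, 0.65, 0.70))
    aw = np.where(dry, 0.30, np.where(np.abs(lat) < 15, 0.25, 0.15))
    wshift = np.where(lat < 0, 182.0, 0.0)
    wseason = np.sin(2.0 * np.pi * (doy - 120.0 - wshift[None, :]) / 365.0)
    moisture = w0[None, :] + aw[None, :] * wseason
    moisture = moisture + _ar1(rng, (n_days, grid.n_cells), moisture_noise_sd, 0.9)
    moisture = np.clip(moisture, 0.02, 0.98)

    return Forcing(
        air_temperature=tair,
        shortwave=shortwave,
        soil_moisture=moisture,
        lat=lat,
        lon=lon,
        year0=year0,
    )


# ---------------------------------------------------------------------------
# PFT fractions and Köppen-Geiger classes
# ---------------------------------------------------------------------------

# base vegetated mixtures per latitude band: {pft: fraction}, rest bare;
# C4 types reach into the temperate band and C3 crops into the dry band so
# every trigger parameter binds somewhere in the site network
_BAND_MIX = {
    "tropical": ({2: 0.40, 3: 0.20, 10: 0.05, 11: 0.15}, 0.20),
    "dry": ({3: 0.15, 10: 0.10, 11: 0.20, 12: 0.10, 13: 0.15}, 0.30),
    "subtropic": ({2: 0.10, 3: 0.15, 5: 0.20, 11: 0.15, 13: 0.10}, 0.30),
    "temperate": ({4: 0.12, 5: 0.13, 6: 0.18, 10: 0.14, 11: 0.05, 12: 0.18, 13: 0.05}, 0.15),
    "boreal": ({7: 0.30, 8: 0.15, 9: 0.20, 10: 0.15}, 0.20),
    "polar": ({7: 0.10, 9: 0.10, 10: 0.10}, 0.70),
}

# home band used to place the guaranteed high-coverage (anchor) cells
_HOME_BAND = {
    2: "tropical", 3: "tropical", 4: "temperate", 5: "temperate",
    6: "temperate", 7: "boreal", 8: "boreal", 9: "boreal",
    10: "temperate", 11: "dry", 12: "temperate", 13: "dry",
}

MIN_ANCHORS = 16  # anchors per PFT (>= the 15 sites selected downstream)
ANCHOR_FRACTION = 0.7
BOBD_ANCHOR_FRACTION = 0.25  # boreal broadleaved deciduous cover stays low


def _band_of(lat: np.ndarray, dry: np.ndarray) -> np.ndarray:
    absl = np.abs(lat)
    band = np.full(lat.shape, "polar", dtype=object)
    band[absl < 15] = "tropical"
    mid = (absl >= 15) & (absl < 30)
    band[mid] = "subtropic"
    band[mid & dry] = "dry"
    band[(absl >= 30) & (absl < 45)] = "temperate"
    band[(absl >= 45) & (absl < 65)] = "boreal"
    return band


def generate_pft_and_kg_maps(grid: Grid, seed: int) -> tuple[PFTMap, np.ndarray]:
    """Latitudinally structured PFT fractions plus a KG class map.

    Guarantees at least :data:`MIN_ANCHORS` cells with dominant fraction
    > 0.6 for every PFT except the boreal broadleaved deciduous one
    (> 0.2).  KG classes: A tropical (|lat| < 15), B arid (dry bands),
    C 15-45, D 45-65, E beyond 65.
    """
    rng = np.random.default_rng(seed)
    lat = grid.cell_lat
    dry = grid.dry_mask()
    band = _band_of(lat, dry)
    pft_indices = tuple(range(2, 14))
    n = grid.n_cells
    frac = np.zeros((n, 12))
    bare = np.zeros(n)
    for name, (mix, b) in _BAND_MIX.items():
        cells = band == name
        jitter = rng.uniform(0.7, 1.3, size=(int(cells.sum()), len(mix)))
        base = np.array([mix[p] for p in sorted(mix)])
        veg = base[None, :] * jitter
        veg *= (1.0 - b) / veg.sum(axis=1, keepdims=True)
        for k, p in enumerate(sorted(mix)):
            frac[cells, pft_indices.index(p)] = veg[:, k]
        bare[cells] = b

    # anchor cells: guaranteed high coverage per PFT
    taken = np.zeros(n, dtype=bool)
    for pft in pft_indices:
        home = np.nonzero((band == _HOME_BAND[pft]) & ~taken)[0]
        if home.size < MIN_ANCHORS:
            raise ValueError(
                f"grid too small to guarantee {MIN_ANCHORS} anchor cells for "
                f"PFT {pft}; enlarge the grid (need >= "
                f"{MIN_ANCHORS * len(pft_indices)} cells spread over bands)"
            )
        chosen = rng.choice(home, size=MIN_ANCHORS, replace=False)
        taken[chosen] = True
        a = BOBD_ANCHOR_FRACTION if pft == 8 else ANCHOR_FRACTION
        j = pft_indices.index(pft)
        for c in chosen:
            others = frac[c].copy()
            others[j] = 0.0
            s = others.sum()
            room = 1.0 - a - 0.05  # keep a sliver of bare soil
            if s > 0:
                others *= room / s
            frac[c] = others
            frac[c, j] = a
            bare[c] = 0.05

    kg = np.full(n, "C", dtype="U1")
    kg[np.abs(lat) < 15] = "A"
    kg[dry] = "B"
    kg[(np.abs(lat) >= 45) & (np.abs(lat) < 65)] = "D"
    kg[np.abs(lat) >= 65] = "E"

    pft_map = PFTMap(
        fractions=frac, bare=bare, area=grid.cell_area, pft_indices=pft_indices
    )
    return pft_map, kg


# ---------------------------------------------------------------------------
# Truth and pseudo-observations
# ---------------------------------------------------------------------------


def make_truth_scenario(
    table: ParameterTable,
    perturbation: float,
    seed: int,
    only: Sequence[str] | None = None,
) -> ParameterVector:
    """Truth vector: prior + perturbation * sigma * z, clipped to bounds.

    ``only`` restricts the perturbation to the named parameters (all
    others stay at their prior), which is how identifiable-subset twins
    are built.
    """
    if perturbation < 0:
        raise ValueError("perturbation must be >= 0")
    vec = build_parameter_vector(table)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(len(vec))
    if only is not None:
        allowed = set(only)
        keep = np.array([name in allowed for (name, _) in vec.keys])
        z = z * keep
    values = np.clip(
        vec.prior + perturbation * vec.prior_sigma * z, vec.lower, vec.upper
    )
    return vec.with_values(values)


def _link_from_vector(truth: ParameterVector, pft_indices) -> SIFLinkParams:
    a = {p: truth.get("SIF_a", p) for p in pft_indices}
    b = {p: truth.get("SIF_b", p) for p in pft_indices}
    return SIFLinkParams(a=a, b=b)


def make_observations(
    truth: ParameterVector,
    forcing: Forcing,
    pft_map: PFTMap,
    noise_sd: float,
    seed: int,
    config: SurrogateConfig = DEFAULT_CONFIG,
    missing_fraction: float = 0.0,
) -> SIFField:
    """Monthly SIF pseudo-observations y = H(truth) + N(0, noise_sd^2)."""
    gpp = simulate(truth, forcing, pft_map, config)
    monthly = gpp.monthly_mean()
    link = _link_from_vector(truth, pft_map.pft_indices)
    sif = forward_sif(monthly, pft_map.fractions, pft_map.bare, link, pft_map.pft_indices)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        sif = sif + rng.standard_normal(sif.shape) * noise_sd
    mask = np.ones(sif.shape, dtype=bool)
    if missing_fraction > 0:
        mask = rng.uniform(size=sif.shape) >= missing_fraction
    return SIFField(
        sif=sif,
        sigma_obs=np.full(sif.shape, max(noise_sd, 1e-9)),
        mask=mask,
        year0=forcing.year0,
    )


def make_benchmark_gpp(
    truth: ParameterVector,
    forcing: Forcing,
    pft_map: PFTMap,
    grid: Grid,
    bias: float = 0.85,
    config: SurrogateConfig = DEFAULT_CONFIG,
) -> GPPField:
    """A clearly synthetic benchmark GPP field: truth GPP with a smooth
    multiplicative bias (for exercising comparison diagnostics only)."""
    gpp = simulate(truth, forcing, pft_map, config)
    lat = grid.cell_lat
    smooth = bias * (1.0 + 0.1 * np.cos(np.deg2rad(lat)))[None, :]
    return GPPField(
        gpp=gpp.gpp * smooth[:, :, None],
        aggregate=gpp.aggregate * smooth,
        pft_indices=gpp.pft_indices,
        year0=gpp.year0,
    )


# ---------------------------------------------------------------------------
# Scenario bundle
# ---------------------------------------------------------------------------


@dataclass
class SyntheticScenario:
    """Everything a twin experiment needs, reproducible from (config, seed)."""

    grid: Grid
    seed: int
    years: int
    truth: ParameterVector
    noise_sd: float
    forcing: Forcing
    pft_map: PFTMap
    kg: np.ndarray
    observations: SIFField
    table: ParameterTable = field(repr=False, default=None)


def make_scenario(
    grid: Grid | None = None,
    years: int = 5,
    seed: int = 0,
    perturbation: float = 0.0,
    noise_sd: float = 0.1,
    only: Sequence[str] | None = None,
    table: ParameterTable | None = None,
    config: SurrogateConfig = DEFAULT_CONFIG,
    missing_fraction: float = 0.0,
) -> SyntheticScenario:
    """Build a complete reproducible twin scenario.

    Child seeds are derived deterministically from ``seed`` so the forcing,
    maps, truth and observation noise are independent streams.
    """
    grid = grid or Grid()
    table = table or default_parameter_table()
    ss = np.random.SeedSequence(seed).spawn(4)
    child = [int(s.generate_state(1)[0]) for s in ss]
    forcing = generate_forcing(grid, years, child[0])
    pft_map, kg = generate_pft_and_kg_maps(grid, child[1])
    truth = make_truth_scenario(table, perturbation, child[2], only=only)
    obs = make_observations(
        truth, forcing, pft_map, noise_sd, child[3], config, missing_fraction
    )
    return SyntheticScenario(
        grid=grid,
        seed=seed,
        years=years,
        truth=truth,
        noise_sd=noise_sd,
        forcing=forcing,
        pft_map=pft_map,
        kg=kg,
        observations=obs,
        table=table,
    )
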