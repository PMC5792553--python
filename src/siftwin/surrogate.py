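"""Surrogate per-PFT process model: daily GPP with prognostic LAI phenology.

This module is an explicitly documented *surrogate*: it exposes the same
parameter names, units and roles as a full terrestrial biosphere model
(maximum carboxylation rate, stomatal slope, tent-shaped temperature
response, hydric stress, specific leaf area, growing-degree-day onset,
temperature/moisture senescence, leaf-fall rate, SIF link), but the
functional forms are the simplest ones that give every parameter a
detectable influence on simulated GPP.  All tunable constants live in
:class:`SurrogateConfig`.

Time stepping is daily on a 365-day (no-leap) calendar.  State and forcing
arrays are vectorised over an ensemble axis so that finite-difference
parameter perturbations can share one pass over the forcing.

Phenology state machine (deciduous PFTs): dormant -> growth -> mature ->
senescent -> dormant.  Onset is triggered by growing-degree days and/or a
days-since-moisture-minimum counter, depending on which onset parameters
apply to the PFT (both where both apply).  Evergreen PFTs have no explicit
phenology: leaf turnover is a function of leaf age only, with growth
relaxing LAI towards its maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from siftwin.param_space import ParameterTable, ParameterVector

__all__ = [
    "MONTH_LENGTHS",
    "DAYS_PER_YEAR",
    "month_index_for",
    "SurrogateConfig",
    "Forcing",
    "PFTMap",
    "PhenoState",
    "GPPField",
    "temperature_response",
    "water_stress",
    "light_response",
    "canopy_absorption",
    "daily_gpp",
    "step_phenology",
    "spin_up",
    "simulate",
    "run_pft_ensemble",
]

# ---------------------------------------------------------------------------
# Calendar (fixed 365-day years)
# ---------------------------------------------------------------------------

MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
DAYS_PER_YEAR = 365
_DOY_MONTH = np.repeat(np.arange(12), MONTH_LENGTHS)  # doy-1 -> month 0..11


def month_index_for(n_days: int) -> np.ndarray:
    """Running month index (0-based, monotone) for a daily series starting 1 Jan."""
    if n_days % DAYS_PER_YEAR:
        raise ValueError("daily series must cover whole 365-day years")
    n_years = n_days // DAYS_PER_YEAR
    return np.concatenate([_DOY_MONTH + 12 * y for y in range(n_years)])


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurrogateConfig:
    """All tunable surrogate constants in one visible, overridable block."""

    c_day: float = 1.0368  # gC m-2 day-1 per (umol m-2 s-1) of carboxylation
    g0: float = 2.0  # gC m-2 day-1 scale of the supply-limited rate
    k_ext: float = 0.5  # canopy light-extinction coefficient
    r_half: float = 100.0  # W m-2 half-saturation of the light response
    gdd_base: float = 5.0  # degC base for growing-degree days
    gdd_ref: float = 200.0  # degC days; onset threshold = K_pheno_crit * gdd_ref
    b_day: float = 10.0  # g m-2 day-1 biomass allocated to leaves during growth
    r_grow: float = 1.0  # dimensionless growth-rate multiplier
    lai_dormant_cutoff: float = 0.05  # LAI below which a senescent PFT goes dormant
    happy_ramp: float = 0.2  # LAI width of the reserve-halving blend
    colimitation_theta: float = 0.97  # quadratic co-limitation; 1.0 = hard min
    min_growth_days: int = 30  # senescence grace period after onset
    min_dormancy_days: int = 10  # minimum dormancy length before re-onset
    onset_window_days: int = 180  # moisture onset valid this long past M_Tmin
    gdd_onset_window: float = 400.0  # degC days past threshold while onset stays valid
    max_season_days: int = 280  # forced senescence so one cycle fits in a year
    mean_window: int = 7  # days in the trailing means used for triggers
    sh_shift: int = 182  # southern-hemisphere shift of the thermal-year origin
    spin_tol: float = 1e-3  # max year-over-year LAI change at convergence
    spin_max_cycles: int = 50


DEFAULT_CONFIG = SurrogateConfig()


# ---------------------------------------------------------------------------
# Forcing
# ---------------------------------------------------------------------------


def _trailing_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Trailing mean over `window` days (shorter at the start), along axis 0."""
    c = np.cumsum(x, axis=0, dtype=float)
    out = np.empty_like(c)
    out[:window] = c[:window] / np.arange(1, window + 1)[:, None]
    out[window:] = (c[window:] - c[:-window]) / window
    return out


@dataclass
class Forcing:
    """Daily meteorological forcing on a set of grid cells.

    Arrays are (n_days, n_cells); the series must start on 1 January of
    ``year0`` and cover whole 365-day years.
    """

    air_temperature: np.ndarray  # degC
    shortwave: np.ndarray  # W m-2
    soil_moisture: np.ndarray  # relative, 0-1
    lat: np.ndarray  # degrees, (n_cells,)
    lon: np.ndarray  # degrees, (n_cells,)
    year0: int = 2007
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        shp = self.air_temperature.shape
        if self.shortwave.shape != shp or self.soil_moisture.shape != shp:
            raise ValueError("forcing variable shapes differ")
        if shp[0] % DAYS_PER_YEAR:
            raise ValueError("forcing must cover whole 365-day years")
        if np.any(~np.isfinite(self.air_temperature)):
            raise ValueError("missing days in air temperature")
        if np.any((self.soil_moisture < 0) | (self.soil_moisture > 1)):
            raise ValueError("soil moisture must lie in [0, 1]")

    @property
    def n_days(self) -> int:
        return self.air_temperature.shape[0]

    @property
    def n_cells(self) -> int:
        return self.air_temperature.shape[1]

    @property
    def n_years(self) -> int:
        return self.n_days // DAYS_PER_YEAR

    def arrays(self, config: SurrogateConfig = DEFAULT_CONFIG) -> dict:
        """Forcing plus derived trigger fields for the full series (cached)."""
        key = ("full", config.mean_window, config.gdd_base, config.sh_shift)
        if key not in self._cache:
            self._cache[key] = self._derive(
                self.air_temperature, self.shortwave, self.soil_moisture, config
            )
        return self._cache[key]

    def spin_arrays(self, config: SurrogateConfig = DEFAULT_CONFIG) -> dict:
        """One cyclic year of forcing (first year) for spin-up (cached)."""
        key = ("spin", config.mean_window, config.gdd_base, config.sh_shift)
        if key not in self._cache:
            n = DAYS_PER_YEAR
            self._cache[key] = self._derive(
                self.air_temperature[:n],
                self.shortwave[:n],
                self.soil_moisture[:n],
                config,
                cyclic=True,
            )
        return self._cache[key]

    def _derive(self, tair, sw, w, config: SurrogateConfig, cyclic: bool = False) -> dict:
        n_days = tair.shape[0]
        win = config.mean_window
        if cyclic:
            # wrap the single year so trailing statistics are seamless
            t_ext = np.concatenate([tair[-win:], tair])
            w_ext = np.concatenate([w[-win:], w])
            t7 = _trailing_mean(t_ext, win)[win:]
            w7 = _trailing_mean(w_ext, win)[win:]
        else:
            t7 = _trailing_mean(tair, win)
            w7 = _trailing_mean(w, win)
        gdd, reset = self._gdd(tair, config)
        mdays = self._moisture_days(w7)
        return {
            "tair": tair,
            "sw": sw,
            "w": w,
            "t7": t7,
            "w7": w7,
            "gdd": gdd,
            "mdays": mdays,
            "reset": reset,
        }

    def _gdd(self, tair: np.ndarray, config: SurrogateConfig):
        """Growing-degree days accumulated from the thermal-year origin
        (doy 1 north of the equator, shifted by half a year in the south)."""
        n_days = tair.shape[0]
        doy = np.arange(n_days) % DAYS_PER_YEAR  # 0-based
        south = self.lat < 0
        origin = np.where(south, config.sh_shift, 0)  # (n_cells,)
        thermal_day = (doy[:, None] - origin[None, :]) % DAYS_PER_YEAR
        reset = thermal_day == 0
        dd = np.maximum(0.0, tair - config.gdd_base)
        gdd = np.empty_like(dd)
        # cells whose thermal year began before the series starts carry the
        # accumulation from that preceding part-year (first year as proxy)
        acc = np.zeros(self.n_cells)
        for c in np.nonzero(origin > 0)[0]:
            acc[c] = dd[origin[c] : min(DAYS_PER_YEAR, n_days), c].sum()
        for d in range(n_days):
            acc = np.where(reset[d], 0.0, acc) + dd[d]
            gdd[d] = acc
        return gdd, reset

    @staticmethod
    def _moisture_days(w7: np.ndarray) -> np.ndarray:
        """Days since the trailing-365-day minimum of the smoothed moisture.

        The counter is zero on every day that attains the trailing-window
        minimum and increments otherwise, so it measures time since the
        most recent (smoothed) moisture minimum.
        """
        from scipy.ndimage import minimum_filter1d

        n_days, n_cells = w7.shape
        win = min(DAYS_PER_YEAR, n_days)
        # pad with the first year (cyclic assumption) so the window is full
        padded = np.concatenate([w7[:win], w7])
        tmin = minimum_filter1d(padded, win, axis=0, origin=win // 2, mode="nearest")
        at_min = padded <= tmin + 1e-12
        counter = np.zeros(n_cells)
        out = np.empty((n_days, n_cells))
        for d in range(padded.shape[0]):
            counter = np.where(at_min[d], 0.0, counter + 1.0)
            if d >= win:
                out[d - win] = counter
        return out

    def subset(self, cells: np.ndarray) -> "Forcing":
        """Forcing restricted to a subset of cells (fresh cache)."""
        return Forcing(
            air_temperature=self.air_temperature[:, cells],
            shortwave=self.shortwave[:, cells],
            soil_moisture=self.soil_moisture[:, cells],
            lat=self.lat[cells],
            lon=self.lon[cells],
            year0=self.year0,
        )


# ---------------------------------------------------------------------------
# PFT map
# ---------------------------------------------------------------------------


@dataclass
class PFTMap:
    """Per-cell PFT fractional cover (12 vegetated PFTs) plus bare soil."""

    fractions: np.ndarray  # (n_cells, 12)
    bare: np.ndarray  # (n_cells,)
    area: np.ndarray  # m2, (n_cells,)
    pft_indices: tuple[int, ...] = tuple(range(2, 14))

    def __post_init__(self) -> None:
        if self.fractions.shape[1] != len(self.pft_indices):
            raise ValueError("fractions second axis must match pft_indices")
        total = self.fractions.sum(axis=1) + self.bare
        if np.any((self.fractions < -1e-12) | (self.fractions > 1 + 1e-12)):
            raise ValueError("fractions must lie in [0, 1]")
        if np.any(np.abs(total - 1.0) > 1e-9):
            raise ValueError("fractions + bare must sum to 1")

    @property
    def n_cells(self) -> int:
        return self.fractions.shape[0]

    def column(self, pft: int) -> np.ndarray:
        return self.fractions[:, self.pft_indices.index(pft)]

    def subset(self, cells: np.ndarray) -> "PFTMap":
        return PFTMap(
            fractions=self.fractions[cells],
            bare=self.bare[cells],
            area=self.area[cells],
            pft_indices=self.pft_indices,
        )


# ---------------------------------------------------------------------------
# Phenology state
# ---------------------------------------------------------------------------

PHASES = ("dormant", "growth", "mature", "senescent")
DORMANT, GROWTH, MATURE, SENESCENT = range(4)


@dataclass
class PhenoState:
    """Per-(ensemble, cell) phenological state for one PFT."""

    lai: np.ndarray
    mean_leaf_age: np.ndarray  # days
    phase: np.ndarray  # int codes into PHASES
    reserve_flag: np.ndarray  # bool
    days_in_phase: np.ndarray  # days since last phase change
    chilled: np.ndarray  # bool: thermal-year reset seen while dormant
    converged: bool = True

    @classmethod
    def initial(cls, shape: tuple[int, ...], deciduous: bool) -> "PhenoState":
        lai0 = 0.0 if deciduous else 0.1
        phase0 = DORMANT if deciduous else MATURE
        return cls(
            lai=np.full(shape, lai0),
            mean_leaf_age=np.zeros(shape),
            phase=np.full(shape, phase0, dtype=np.int8),
            reserve_flag=np.ones(shape, dtype=bool),
            days_in_phase=np.zeros(shape, dtype=np.int32),
            chilled=np.ones(shape, dtype=bool),
        )

    def copy(self) -> "PhenoState":
        return PhenoState(
            lai=self.lai.copy(),
            mean_leaf_age=self.mean_leaf_age.copy(),
            phase=self.phase.copy(),
            reserve_flag=self.reserve_flag.copy(),
            days_in_phase=self.days_in_phase.copy(),
            chilled=self.chilled.copy(),
            converged=self.converged,
        )

    def phase_names(self) -> np.ndarray:
        return np.array(PHASES, dtype=object)[self.phase]


# ---------------------------------------------------------------------------
# Elementary response functions
# ---------------------------------------------------------------------------


def temperature_response(T, T_min, T_opt, T_max):
    """Tent-shaped temperature response: 0 at/below T_min, 1 at T_opt,
    0 at/above T_max, linear in between."""
    T, T_min, T_opt, T_max = np.broadcast_arrays(
        np.asarray(T, dtype=float), T_min, T_opt, T_max
    )
    if np.any(~((T_min < T_opt) & (T_opt < T_max))):
        raise ValueError("temperature limits must satisfy T_min < T_opt < T_max")
    rise = (T - T_min) / (T_opt - T_min)
    fall = (T_max - T) / (T_max - T_opt)
    return np.clip(np.minimum(rise, fall), 0.0, 1.0)


def water_stress(W, F_stress_h):
    """Hydric limitation factor: clip(1 - F_stress_h * (1 - W), 0, 1)."""
    W = np.asarray(W, dtype=float)
    if np.any((W < 0) | (W > 1)):
        raise ValueError("relative soil moisture must lie in [0, 1]")
    return np.clip(1.0 - np.asarray(F_stress_h, dtype=float) * (1.0 - W), 0.0, 1.0)


def light_response(R, R_half=DEFAULT_CONFIG.r_half):
    """Saturating light response R / (R + R_half) in [0, 1)."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("shortwave radiation must be non-negative")
    return R / (R + R_half)


def canopy_absorption(lai, k_ext=DEFAULT_CONFIG.k_ext):
    """Beer-Lambert absorbed fraction 1 - exp(-k_ext * lai)."""
    return 1.0 - np.exp(-k_ext * np.asarray(lai, dtype=float))


def _colimit(a_c, a_w, theta: float):
    """Quadratic co-limitation of two rates; theta = 1 is the exact minimum.

    Smaller root of theta*x^2 - (a+b)*x + a*b = 0; theta slightly below 1
    keeps a small, smooth sensitivity to the non-limiting rate.
    """
    s = a_c + a_w
    disc = s * s - 4.0 * theta * a_c * a_w  # = (a-b)^2 + 4ab(1-theta) >= 0
    return (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * theta)


def daily_gpp(params: Mapping[str, float], T, R, W, state: PhenoState,
              config: SurrogateConfig = DEFAULT_CONFIG):
    """Daily GPP (gC m-2 day-1) for one PFT.

    The carboxylation-limited rate A_c and the supply-limited rate A_w are
    co-limited (quadratic blend; the hard minimum at theta = 1), then
    scaled by the hydric stress factor.
    """
    f_T = temperature_response(T, params["T_min"], params["T_opt"], params["T_max"])
    f_R = light_response(R, config.r_half)
    f_L = canopy_absorption(state.lai, config.k_ext)
    f_age = np.clip(1.0 - state.mean_leaf_age / (2.0 * params["L_age_crit"]), 0.0, 1.0)
    f_W = water_stress(W, params["F_stress_h"])
    a_c = config.c_day * params["V_cmax"] * f_T * f_R * f_L * f_age
    a_w = config.g0 * params["G_s_slope"] * np.asarray(W, dtype=float) * f_L
    return _colimit(a_c, a_w, config.colimitation_theta) * f_W


# ---------------------------------------------------------------------------
# Phenology stepping (vectorised over an ensemble axis)
# ---------------------------------------------------------------------------

_PARAM_NAMES = (
    "V_cmax", "G_s_slope", "T_opt", "T_min", "T_max", "F_stress_h", "SLA",
    "LAI_max", "K_LAI_happy", "K_pheno_crit", "M_Tmin", "L_age_crit",
    "T_senes", "M_senes_nosenes", "L_fall", "SIF_a", "SIF_b",
)


def _as_ens(params: Mapping[str, float | np.ndarray]) -> dict[str, np.ndarray]:
    """Broadcast a parameter mapping to (n_ens, 1) arrays."""
    n_ens = 1
    for v in params.values():
        n_ens = max(n_ens, np.asarray(v).size)
    out = {}
    for name in _PARAM_NAMES:
        v = np.asarray(params[name], dtype=float).reshape(-1)
        if v.size == 1:
            v = np.full(n_ens, v[0])
        elif v.size != n_ens:
            raise ValueError(f"parameter {name}: inconsistent ensemble size")
        out[name] = v[:, None]
    return out


@dataclass(frozen=True)
class PFTTraits:
    """Which phenology branches a PFT uses (derived from applicability)."""

    deciduous: bool
    temp_onset: bool
    moist_onset: bool
    temp_senes: bool
    moist_senes: bool

    @classmethod
    def from_table(cls, table: ParameterTable, pft: int) -> "PFTTraits":
        return cls(
            deciduous=table.pft(pft).deciduous,
            temp_onset=pft in table["K_pheno_crit"].pft_applicability,
            moist_onset=pft in table["M_Tmin"].pft_applicability,
            temp_senes=pft in table["T_senes"].pft_applicability,
            moist_senes=pft in table["M_senes_nosenes"].pft_applicability,
        )


def _step_deciduous(d, fa, p, st, cfg: SurrogateConfig, traits: PFTTraits):
    phase = st.phase
    st.days_in_phase += 1
    # --- onset: dormant -> growth
    if traits.temp_onset:
        gdd_thresh = p["K_pheno_crit"] * cfg.gdd_ref
        gdd = fa["gdd"][d]
        above = gdd > gdd_thresh
        if traits.moist_onset:
            # the moisture window below supplies the annual phase lock
            gdd_ok = above
        else:
            # onset valid only in a bounded GDD window past the threshold,
            # so green-up stays pinned to the season of threshold crossing
            # even where GDD sits above the threshold most of the year
            gdd_ok = above & (gdd < gdd_thresh + cfg.gdd_onset_window)
        # re-greening is armed whenever GDD sits below the onset threshold
        # (i.e. a cold season happened, whatever the phase at the time) and
        # consumed at onset; cells that senesce just after the thermal-year
        # reset can therefore still green up in the same season
        st.chilled |= ~above
    if traits.moist_onset:
        # onset is tied to the early wet season: the days-since-moisture-
        # minimum counter must exceed M_Tmin but not by more than a window,
        # which phase-locks re-greening to the annual moisture cycle
        md = fa["mdays"][d]
        moist_ok = (md > p["M_Tmin"]) & (md < p["M_Tmin"] + cfg.onset_window_days)
    if traits.temp_onset and traits.moist_onset:
        onset = gdd_ok & moist_ok
    elif traits.temp_onset:
        onset = gdd_ok
    else:
        onset = moist_ok
    # no green-up while conditions that would trigger senescence persist
    climate_sen = np.zeros(phase.shape, dtype=bool)
    if traits.temp_senes:
        climate_sen |= fa["t7"][d] < p["T_senes"]
    if traits.moist_senes:
        climate_sen |= fa["w7"][d] < p["M_senes_nosenes"]
    dormant = phase == DORMANT
    start = dormant & (st.days_in_phase >= cfg.min_dormancy_days) & onset & ~climate_sen
    if traits.temp_onset:
        start &= st.chilled
    phase[start] = GROWTH
    st.days_in_phase[start] = 0
    st.mean_leaf_age[start] = 0.0
    st.reserve_flag[start] = True
    st.chilled[start] = False
    # --- growth: reserve-driven rate halves past the happy-LAI threshold
    # (blended over a small ramp so the threshold stays identifiable)
    growing = phase == GROWTH
    lai_max = p["LAI_max"]
    over = (st.lai - p["K_LAI_happy"] * lai_max) / cfg.happy_ramp + 0.5
    rate = cfg.r_grow * p["SLA"] * cfg.b_day * (1.0 - 0.5 * np.clip(over, 0.0, 1.0))
    st.lai = np.where(growing, np.minimum(st.lai + rate, lai_max), st.lai)
    st.reserve_flag &= st.lai < p["K_LAI_happy"] * lai_max
    to_mature = growing & (st.lai >= lai_max - 1e-9)
    phase[to_mature] = MATURE
    st.days_in_phase[to_mature] = 0
    # --- senescence trigger: climate thresholds, or the canopy ageing out
    # (age death at 2*L_age_crit, where the GPP ageing factor reaches zero,
    # capped at max_season_days so one full cycle always fits in a year)
    sen = climate_sen | (
        st.mean_leaf_age
        > np.minimum(2.0 * p["L_age_crit"], float(cfg.max_season_days))
    )
    eligible = (phase == MATURE) | (
        (phase == GROWTH) & (st.days_in_phase >= cfg.min_growth_days)
    )
    to_sen = eligible & sen
    phase[to_sen] = SENESCENT
    st.days_in_phase[to_sen] = 0
    # --- leaf fall and return to dormancy
    falling = phase == SENESCENT
    st.lai = np.where(falling, st.lai * (1.0 - p["L_fall"]), st.lai)
    to_dorm = falling & (st.lai < cfg.lai_dormant_cutoff)
    phase[to_dorm] = DORMANT
    st.lai = np.where(to_dorm, 0.0, st.lai)
    st.mean_leaf_age[to_dorm] = 0.0
    st.reserve_flag[to_dorm] = True
    st.days_in_phase[to_dorm] = 0
    st.mean_leaf_age += phase != DORMANT


def _step_evergreen(d, fa, p, st, cfg: SurrogateConfig, f_t, f_w):
    lai_max = p["LAI_max"]
    # growth halves once LAI passes the reserve threshold; blended over a
    # small LAI ramp so the annual map stays contractive (a hard switch
    # produces limit cycles straddling the threshold)
    over = (st.lai - p["K_LAI_happy"] * lai_max) / cfg.happy_ramp + 0.5
    halved = 1.0 - 0.5 * np.clip(over, 0.0, 1.0)
    room = np.clip(1.0 - st.lai / lai_max, 0.0, None)
    growth = cfg.r_grow * p["SLA"] * cfg.b_day * f_t * f_w * halved * room
    turnover = st.lai / p["L_age_crit"]
    lai_old = st.lai
    st.lai = np.clip(st.lai + growth - turnover, 0.0, lai_max)
    # mass-weighted mean leaf age: new leaves enter at age 0
    denom = lai_old + growth
    aged = np.where(
        denom > 1e-12, lai_old * (st.mean_leaf_age + 1.0) / np.maximum(denom, 1e-12), 0.0
    )
    st.mean_leaf_age = np.where(st.lai > 1e-12, aged, 0.0)
    st.days_in_phase += 1


def step_phenology(
    state: PhenoState,
    day_forcing: Mapping[str, np.ndarray],
    params: Mapping[str, float | np.ndarray],
    traits: PFTTraits,
    config: SurrogateConfig = DEFAULT_CONFIG,
) -> PhenoState:
    """Advance the phenology state by one day.

    ``day_forcing`` needs keys tair, w, t7, w7, gdd, mdays, reset, each an
    (n_cells,) array for the day in question.
    """
    st = state.copy()
    p = _as_ens(params)
    # repackage the day's forcing as day 0 of a 1-day series
    fa = {
        k: np.asarray(v, dtype=(bool if k == "reset" else float)).reshape(1, -1)
        for k, v in day_forcing.items()
    }
    if traits.deciduous:
        _step_deciduous(0, fa, p, st, config, traits)
    else:
        f_t = temperature_response(fa["tair"][0], p["T_min"], p["T_opt"], p["T_max"])
        f_w = water_stress(fa["w"][0], p["F_stress_h"])
        _step_evergreen(0, fa, p, st, config, f_t, f_w)
    return st


# ---------------------------------------------------------------------------
# Core integration kernel
# ---------------------------------------------------------------------------


def _run_days(
    fa: dict,
    p: dict[str, np.ndarray],
    st: PhenoState,
    cfg: SurrogateConfig,
    traits: PFTTraits,
    collect: str | None,
    month_index: np.ndarray | None = None,
):
    """Integrate one PFT over all days in `fa`, mutating `st` in place.

    collect: None (state only), "daily" -> (n_days, n_ens, n_cells) GPP,
    "monthly" -> (n_months, n_ens, n_cells) monthly-mean GPP,
    "lai" -> (n_days, n_ens, n_cells) LAI trajectory.
    """
    tair, sw, w = fa["tair"], fa["sw"], fa["w"]
    n_days = tair.shape[0]
    shape = st.lai.shape
    out = None
    if collect == "daily" or collect == "lai":
        out = np.empty((n_days,) + shape)
    elif collect == "monthly":
        n_months = int(month_index[-1]) + 1
        out = np.zeros((n_months,) + shape)
        mcount = np.zeros(n_months)
    t_min, t_opt, t_max = p["T_min"], p["T_opt"], p["T_max"]
    inv_rise = 1.0 / (t_opt - t_min)
    inv_fall = 1.0 / (t_max - t_opt)
    for d in range(n_days):
        td = tair[d]
        f_t = np.clip(
            np.minimum((td - t_min) * inv_rise, (t_max - td) * inv_fall), 0.0, 1.0
        )
        f_w = np.clip(1.0 - p["F_stress_h"] * (1.0 - w[d]), 0.0, 1.0)
        if traits.deciduous:
            _step_deciduous(d, fa, p, st, cfg, traits)
        else:
            _step_evergreen(d, fa, p, st, cfg, f_t, f_w)
        if collect == "lai":
            out[d] = st.lai
            continue
        if collect is None:
            continue
        f_r = sw[d] / (sw[d] + cfg.r_half)
        f_l = 1.0 - np.exp(-cfg.k_ext * st.lai)
        f_age = np.clip(
            1.0 - st.mean_leaf_age / (2.0 * p["L_age_crit"]), 0.0, 1.0
        )
        a_c = cfg.c_day * p["V_cmax"] * f_t * f_r * f_l * f_age
        a_w = cfg.g0 * p["G_s_slope"] * w[d] * f_l
        gpp = _colimit(a_c, a_w, cfg.colimitation_theta) * f_w
        if collect == "daily":
            out[d] = gpp
        else:
            m = month_index[d]
            out[m] += gpp
            mcount[m] += 1
    if collect == "monthly":
        out /= mcount[:, None, None]
    return out


def _check_params(p: dict[str, np.ndarray]) -> None:
    if np.any(~((p["T_min"] < p["T_opt"]) & (p["T_opt"] < p["T_max"]))):
        raise ValueError("temperature limits must satisfy T_min < T_opt < T_max")


# ---------------------------------------------------------------------------
# Public simulation API
# ---------------------------------------------------------------------------


def spin_up(
    params: Mapping[str, float | np.ndarray],
    forcing: Forcing,
    traits: PFTTraits,
    config: SurrogateConfig = DEFAULT_CONFIG,
    state: PhenoState | None = None,
) -> PhenoState:
    """Cycle the first forcing year until the LAI trajectory repeats.

    Convergence: the maximum absolute difference between successive annual
    LAI trajectories falls below ``config.spin_tol`` (a state that enters
    already on the attractor converges within one cycle via the
    endpoint-equality check).  Non-convergence after ``spin_max_cycles``
    returns the final state flagged ``converged=False`` with a warning.
    """
    fa = forcing.spin_arrays(config)
    p = _as_ens(params)
    _check_params(p)
    n_ens = p["V_cmax"].shape[0]
    if state is None:
        state = PhenoState.initial((n_ens, forcing.n_cells), traits.deciduous)
    st = state.copy()
    prev_traj = None
    for cycle in range(config.spin_max_cycles):
        lai_begin = st.lai.copy()
        traj = _run_days(fa, p, st, config, traits, collect="lai")
        if prev_traj is not None:
            if np.max(np.abs(traj - prev_traj)) < config.spin_tol:
                st.converged = True
                return st
        elif np.max(np.abs(st.lai - lai_begin)) < config.spin_tol:
            st.converged = True
            return st
        prev_traj = traj
    warnings.warn("spin-up did not converge within the cycle limit")
    st.converged = False
    return st


def run_pft_ensemble(
    params: Mapping[str, float | np.ndarray],
    forcing: Forcing,
    traits: PFTTraits,
    config: SurrogateConfig = DEFAULT_CONFIG,
    collect: str = "monthly",
    spin: bool = True,
    state: PhenoState | None = None,
):
    """Simulate one PFT for an ensemble of parameter sets sharing the forcing.

    Returns (gpp, final_state); gpp has shape (n_months|n_days, n_ens,
    n_cells) depending on ``collect``.
    """
    p = _as_ens(params)
    _check_params(p)
    if state is None:
        if spin:
            state = spin_up(params, forcing, traits, config)
        else:
            state = PhenoState.initial(
                (p["V_cmax"].shape[0], forcing.n_cells), traits.deciduous
            )
    st = state.copy()
    fa = forcing.arrays(config)
    month_index = month_index_for(forcing.n_days)
    out = _run_days(fa, p, st, config, traits, collect, month_index)
    return out, st


@dataclass
class GPPField:
    """Daily GPP per (cell, PFT) plus the PFT-fraction-weighted aggregate."""

    gpp: np.ndarray  # (n_days, n_cells, n_pfts), gC m-2 day-1
    aggregate: np.ndarray  # (n_days, n_cells)
    pft_indices: tuple[int, ...]
    year0: int

    @property
    def n_days(self) -> int:
        return self.gpp.shape[0]

    def monthly_mean(self) -> np.ndarray:
        """(n_months, n_cells, n_pfts) calendar-month means."""
        m = month_index_for(self.n_days)
        n_months = int(m[-1]) + 1
        out = np.zeros((n_months,) + self.gpp.shape[1:])
        np.add.at(out, m, self.gpp)
        counts = np.bincount(m, minlength=n_months).astype(float)
        return out / counts[:, None, None]

    def monthly_aggregate_mean(self) -> np.ndarray:
        """(n_months, n_cells) monthly means of the cell aggregate."""
        m = month_index_for(self.n_days)
        n_months = int(m[-1]) + 1
        out = np.zeros((n_months,) + self.aggregate.shape[1:])
        np.add.at(out, m, self.aggregate)
        counts = np.bincount(m, minlength=n_months).astype(float)
        return out / counts[:, None]

    def annual_per_cell(self) -> np.ndarray:
        """(n_years, n_cells) annual sums of the aggregate (gC m-2 yr-1)."""
        n_years = self.n_days // DAYS_PER_YEAR
        return self.aggregate.reshape(n_years, DAYS_PER_YEAR, -1).sum(axis=1)


def simulate(
    params: ParameterVector,
    forcing: Forcing,
    pft_map: PFTMap,
    config: SurrogateConfig = DEFAULT_CONFIG,
    spin: bool = True,
) -> GPPField:
    """Run the surrogate for all PFTs and aggregate with PFT fractions.

    Rejects parameter vectors with any entry outside its bounds.  The run is
    deterministic: there is no hidden randomness anywhere in the model.
    """
    if np.any(params.values < params.lower - 1e-12) or np.any(
        params.values > params.upper + 1e-12
    ):
        raise ValueError("parameter vector has entries outside bounds")
    table = params.table
    if table is None:
        raise ValueError("parameter vector must carry its table")
    pfts = pft_map.pft_indices
    gpp = np.zeros((forcing.n_days, forcing.n_cells, len(pfts)))
    for j, pft in enumerate(pfts):
        frac = pft_map.column(pft)
        if not np.any(frac > 0):
            continue
        traits = PFTTraits.from_table(table, pft)
        theta = params.effective_params(pft)
        daily, _ = run_pft_ensemble(
            theta, forcing, traits, config, collect="daily", spin=spin
        )
        gpp[:, :, j] = daily[:, 0, :]
    aggregate = np.einsum("tcp,cp->tc", gpp, pft_map.fractions)
    return GPPField(
        gpp=gpp, aggregate=aggregate, pft_indices=tuple(pfts), year0=forcing.year0
    )
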