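"""Site selection, biome aggregation and results diagnostics.

Budgets are in PgC yr-1 (1 Pg = 1e15 g); latitudinal profiles in
kgC m-2 yr-1; seasonal cycles in PgC month-1.  Biomes follow the
Köppen-Geiger main classes grouped as tropical (A), arid (B) and
temperate+boreal (C-E), with a boreal sub-group (D-E).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from siftwin.assimilation import PosteriorResult
from siftwin.surrogate import PFTMap

__all__ = [
    "select_sites",
    "select_all_sites",
    "kg_group",
    "region_masks",
    "annual_budget",
    "productivity_metrics",
    "seasonal_cycle",
    "latitudinal_profile",
    "monthly_correlation",
    "uncertainty_maps_and_param_summary",
    "iav_trend",
]

GRAMS_PER_PG = 1e15

DEFAULT_SITES_PER_PFT = 15
DEFAULT_FRACTION_THRESHOLD = 0.6
BOBD_PFT = 8
BOBD_FRACTION_THRESHOLD = 0.2


def select_sites(
    pft_map: PFTMap,
    pft: int,
    lat: np.ndarray,
    n: int = DEFAULT_SITES_PER_PFT,
    threshold: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Seeded random sample of up to ``n`` cells with PFT fraction above a
    threshold, stratified over latitude terciles of the eligible cells so
    the sites track the PFT's spatial distribution.

    Default threshold is 0.6 (0.2 for the boreal broadleaved deciduous PFT,
    whose fractional cover never gets that high).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if threshold is None:
        threshold = (
            BOBD_FRACTION_THRESHOLD if pft == BOBD_PFT else DEFAULT_FRACTION_THRESHOLD
        )
    eligible = np.nonzero(pft_map.column(pft) > threshold)[0]
    if eligible.size == 0:
        warnings.warn(f"no eligible cells for PFT {pft} above fraction {threshold}")
        return np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    order = eligible[np.argsort(lat[eligible], kind="stable")]
    terciles = np.array_split(order, 3)
    per = n // 3
    chosen: list[np.ndarray] = []
    for t in terciles:
        k = min(per, t.size)
        if k:
            chosen.append(rng.choice(t, size=k, replace=False))
    flat = np.concatenate(chosen) if chosen else np.array([], dtype=int)
    leftover = np.setdiff1d(eligible, flat)
    want = min(n, eligible.size) - flat.size
    if want > 0 and leftover.size:
        flat = np.concatenate([flat, rng.choice(leftover, size=min(want, leftover.size), replace=False)])
    return np.sort(flat.astype(int))


def select_all_sites(
    pft_map: PFTMap,
    lat: np.ndarray,
    n: int = DEFAULT_SITES_PER_PFT,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Site lists for every PFT (distinct child seed per PFT)."""
    ss = np.random.SeedSequence(seed).spawn(len(pft_map.pft_indices))
    return {
        pft: select_sites(pft_map, pft, lat, n=n, seed=int(s.generate_state(1)[0]))
        for pft, s in zip(pft_map.pft_indices, ss)
    }


_KG_GROUPS = {
    "A": "tropical",
    "B": "arid",
    "C": "temperate+boreal",
    "D": "temperate+boreal",
    "E": "temperate+boreal",
}


def kg_group(kg_class: str) -> str:
    """Köppen-Geiger main class -> biome group label."""
    try:
        return _KG_GROUPS[kg_class]
    except KeyError:
        raise ValueError(f"unknown KG class {kg_class!r}; expected one of A-E")


def is_boreal(kg_class: str) -> bool:
    """Boreal sub-group: KG classes D and E."""
    if kg_class not in _KG_GROUPS:
        raise ValueError(f"unknown KG class {kg_class!r}")
    return kg_class in ("D", "E")


def region_masks(kg: np.ndarray) -> dict[str, np.ndarray]:
    """Standard region masks from a per-cell KG class array."""
    kg = np.asarray(kg)
    groups = np.array([kg_group(c) for c in kg])
    return {
        "global": np.ones(kg.shape, dtype=bool),
        "tropical": groups == "tropical",
        "arid": groups == "arid",
        "temperate+boreal": groups == "temperate+boreal",
        "boreal": np.isin(kg, ("D", "E")),
    }


def annual_budget(
    annual_gpp: np.ndarray, areas: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Region total GPP in PgC yr-1.

    ``annual_gpp`` is per-cell annual GPP in gC m-2 yr-1, either (n_cells,)
    or (n_years, n_cells); multi-year input is averaged over years.
    """
    g = np.atleast_2d(np.asarray(annual_gpp, dtype=float))
    if mask is None:
        mask = np.ones(g.shape[1], dtype=bool)
    per_year = (g[:, mask] * areas[None, mask]).sum(axis=1) / GRAMS_PER_PG
    return float(per_year.mean())


def productivity_metrics(
    prior: Mapping[str, float], posterior: Mapping[str, float]
) -> dict[str, float | None]:
    """Prior-posterior differences and biome productivity ratios.

    Expects region -> annual budget (PgC yr-1) with at least the keys
    tropical, temperate+boreal, boreal and (optionally) global.  Ratios are
    tropical:(temperate+boreal) and tropical:boreal; zero denominators mask
    the metric as None.
    """

    def ratio(num: float, den: float) -> float | None:
        return None if den == 0 else num / den

    out: dict[str, float | None] = {}
    for region in prior:
        if region in posterior:
            out[f"reduction_{region}"] = prior[region] - posterior[region]
    for label, den_key in (
        ("tropical_to_temperate_boreal", "temperate+boreal"),
        ("tropical_to_boreal", "boreal"),
    ):
        if "tropical" not in prior or den_key not in prior:
            continue
        rp = ratio(prior["tropical"], prior[den_key])
        rq = ratio(posterior["tropical"], posterior[den_key])
        out[f"prior_ratio_{label}"] = rp
        out[f"posterior_ratio_{label}"] = rq
        out[f"ratio_change_{label}"] = (
            None if rp in (None, 0) or rq is None else (rq - rp) / rp
        )
    return out


def seasonal_cycle(
    monthly_gpp: np.ndarray, areas: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """12-value climatology of region-integrated GPP (PgC month-1).

    ``monthly_gpp`` is (n_months, n_cells) in gC m-2 month-1 and must cover
    whole years.
    """
    g = np.asarray(monthly_gpp, dtype=float)
    if g.shape[0] % 12:
        raise ValueError("seasonal cycle needs whole years of monthly data")
    if mask is None:
        mask = np.ones(g.shape[1], dtype=bool)
    integrated = (g[:, mask] * areas[None, mask]).sum(axis=1) / GRAMS_PER_PG
    return integrated.reshape(-1, 12).mean(axis=0)


def latitudinal_profile(
    annual_gpp: np.ndarray,
    areas: np.ndarray,
    lat: np.ndarray,
    mask: np.ndarray | None = None,
) -> pd.Series:
    """Area-weighted zonal-mean annual GPP per latitude row (kgC m-2 yr-1)."""
    g = np.asarray(annual_gpp, dtype=float)
    if g.ndim == 2:
        g = g.mean(axis=0)
    if mask is None:
        mask = np.ones(g.shape, dtype=bool)
    rows = {}
    for latv in np.unique(lat):
        sel = (lat == latv) & mask
        if not np.any(sel):
            continue
        rows[float(latv)] = float(
            (g[sel] * areas[sel]).sum() / areas[sel].sum() / 1000.0
        )
    return pd.Series(rows).sort_index()


def monthly_correlation(
    sif_monthly: np.ndarray,
    gpp_monthly: np.ndarray,
    region_mask: Mapping[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, dict[str, float], int]:
    """Per-cell Pearson r between monthly SIF and GPP, plus region means.

    Cells with a constant series have undefined r; they are excluded from
    the region means and counted.  Returns (per_cell_r, region_means,
    n_excluded); excluded cells carry NaN in per_cell_r.
    """
    s = np.asarray(sif_monthly, dtype=float)
    g = np.asarray(gpp_monthly, dtype=float)
    if s.shape != g.shape:
        raise ValueError("SIF and GPP monthly series must be aligned")
    sc = s - s.mean(axis=0)
    gc = g - g.mean(axis=0)
    ss = (sc**2).sum(axis=0)
    gg = (gc**2).sum(axis=0)
    defined = (ss > 0) & (gg > 0)
    r = np.full(s.shape[1], np.nan)
    r[defined] = (sc[:, defined] * gc[:, defined]).sum(axis=0) / np.sqrt(
        ss[defined] * gg[defined]
    )
    n_excluded = int((~defined).sum())
    means: dict[str, float] = {}
    if region_mask is not None:
        for name, m in region_mask.items():
            sel = m & defined
            means[name] = float(r[sel].mean()) if np.any(sel) else float("nan")
    return r, means, n_excluded


def uncertainty_maps_and_param_summary(
    result: PosteriorResult, reduction_threshold: float = 0.5
) -> tuple[np.ndarray, pd.DataFrame, dict[str, int]]:
    """Per-cell state error-reduction map plus a per-(param, PFT) table.

    The table lists prior value, posterior value, % sigma reduction and an
    at-bound flag; counts report parameters above the reduction threshold
    and edge-hitters.
    """
    x = result.x_post
    state_map = result.error_reduction_state.mean(axis=0)  # mean over months
    bound = x.at_bound()
    rows = []
    for (name, pft), i in sorted(x.index_map.items(), key=lambda kv: kv[1]):
        rows.append(
            {
                "parameter": name,
                "pft": pft,
                "prior": float(x.prior[i]),
                "posterior": float(x.values[i]),
                "sigma_reduction_pct": 100.0 * float(result.error_reduction_params[i]),
                "at_bound": bool(bound[i]),
            }
        )
    table = pd.DataFrame(rows)
    counts = {
        "n_params": len(x),
        "n_above_threshold": int(
            (result.error_reduction_params > reduction_threshold).sum()
        ),
        "n_edge_hitting": len(result.edge_hitting),
    }
    return state_map, table, counts


def iav_trend(
    annual_series: np.ndarray, reference: np.ndarray | None = None
) -> dict[str, float]:
    """OLS trend, detrended (IAV) standard deviation, and phase correlation
    against a reference annual series."""
    ysr = np.asarray(annual_series, dtype=float)
    if ysr.size < 3:
        raise ValueError("need at least 3 years for trend/IAV statistics")
    t = np.arange(ysr.size, dtype=float)
    slope, intercept = np.polyfit(t, ysr, 1)
    resid = ysr - (slope * t + intercept)
    out = {
        "slope": float(slope),
        "iav_sd": float(resid.std(ddof=0)),
    }
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != ysr.shape:
            raise ValueError("reference series must match in length")
        if ysr.std() == 0 or ref.std() == 0:
            out["phase_correlation"] = float("nan")
        else:
            out["phase_correlation"] = float(np.corrcoef(ysr, ref)[0, 1])
    return out
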