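"""Linear SIF observation operator: per-PFT GPP -> monthly grid-cell SIF.

SIF for one PFT is an affine function of its GPP (slope a, intercept b); a
grid cell's SIF is the PFT-fraction-weighted sum over vegetated PFTs, with
bare soil contributing zero.  Monthly values are calendar-month means of the
daily series, so the operator commutes with temporal aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from siftwin.surrogate import DAYS_PER_YEAR, MONTH_LENGTHS

__all__ = [
    "SIFField",
    "SIFLinkParams",
    "pft_sif",
    "cell_sif",
    "monthly_aggregate",
    "forward_sif",
]

SIF_A_BOUNDS = (-0.5, 1.0)
SIF_B_BOUNDS = (-1.5, 2.5)


@dataclass
class SIFLinkParams:
    """Per-PFT slope/intercept of the linear SIF-GPP relationship."""

    a: Mapping[int, float]
    b: Mapping[int, float]

    def __post_init__(self) -> None:
        for pft, v in self.a.items():
            if not SIF_A_BOUNDS[0] <= v <= SIF_A_BOUNDS[1]:
                raise ValueError(f"SIF slope for PFT {pft} outside {SIF_A_BOUNDS}")
        for pft, v in self.b.items():
            if not SIF_B_BOUNDS[0] <= v <= SIF_B_BOUNDS[1]:
                raise ValueError(f"SIF intercept for PFT {pft} outside {SIF_B_BOUNDS}")


@dataclass
class SIFField:
    """Monthly SIF per grid cell with per-value observation error and mask.

    ``sif`` has shape (n_months, n_cells); ``mask`` is True where data are
    present.  ``sigma_obs`` must be strictly positive wherever data are
    present.
    """

    sif: np.ndarray
    sigma_obs: np.ndarray
    mask: np.ndarray | None = None
    year0: int = 2007

    def __post_init__(self) -> None:
        self.sif = np.asarray(self.sif, dtype=float)
        self.sigma_obs = np.broadcast_to(
            np.asarray(self.sigma_obs, dtype=float), self.sif.shape
        ).copy()
        if self.mask is None:
            self.mask = np.ones(self.sif.shape, dtype=bool)
        if self.mask.shape != self.sif.shape:
            raise ValueError("mask shape must match sif")
        if np.any(self.sigma_obs[self.mask] <= 0):
            raise ValueError("sigma_obs must be > 0 where data are present")

    @property
    def n_months(self) -> int:
        return self.sif.shape[0]

    @property
    def n_cells(self) -> int:
        return self.sif.shape[1]

    def vector(self) -> np.ndarray:
        """Flattened observation vector over unmasked values."""
        return self.sif[self.mask]

    def sigma_vector(self) -> np.ndarray:
        return self.sigma_obs[self.mask]

    def subset(self, cells: np.ndarray) -> "SIFField":
        return SIFField(
            sif=self.sif[:, cells],
            sigma_obs=self.sigma_obs[:, cells],
            mask=self.mask[:, cells],
            year0=self.year0,
        )


def pft_sif(gpp, a, b):
    """SIF = a * GPP + b for one PFT (affine in both parameters)."""
    return np.asarray(a, dtype=float) * np.asarray(gpp, dtype=float) + b


def cell_sif(pft_sif_values: np.ndarray, fractions: np.ndarray, bare: np.ndarray):
    """PFT-fraction-weighted cell SIF; bare soil contributes zero.

    ``pft_sif_values`` has PFT as its last axis, matching ``fractions``
    (n_cells, n_pfts).
    """
    total = fractions.sum(axis=-1) + bare
    if np.any(np.abs(total - 1.0) > 1e-9):
        raise ValueError("PFT fractions + bare soil must sum to 1")
    return np.einsum("...cp,cp->...c", np.asarray(pft_sif_values, dtype=float), fractions)


def monthly_aggregate(daily: np.ndarray, mask: np.ndarray | None = None):
    """Calendar-month arithmetic means of a daily series (time on axis 0).

    Partial trailing months are excluded with a warning.  With a mask, a
    month averages its present days only; an all-masked month is masked in
    the output.  Returns (monthly, month_mask).
    """
    daily = np.asarray(daily, dtype=float)
    n_days = daily.shape[0]
    full_years = n_days // DAYS_PER_YEAR
    # cumulative month-end day counts covering the whole series
    bounds = np.cumsum(np.tile(MONTH_LENGTHS, full_years + 1))
    n_complete = int(np.searchsorted(bounds, n_days, side="right"))
    if n_complete == 0:
        raise ValueError("need at least one full month of daily data")
    used = int(bounds[n_complete - 1])
    if used < n_days:
        warnings.warn("partial trailing month excluded from monthly aggregation")
    daily = daily[:used]
    n_days = used
    midx = np.concatenate(
        [np.repeat(np.arange(12), MONTH_LENGTHS) + 12 * y for y in range(full_years + 1)]
    )[:n_days]
    n_months = int(midx[-1]) + 1
    if mask is None:
        mask_d = np.ones(daily.shape, dtype=bool)
    else:
        mask_d = np.asarray(mask[:used], dtype=bool)
    sums = np.zeros((n_months,) + daily.shape[1:])
    counts = np.zeros((n_months,) + daily.shape[1:])
    np.add.at(sums, midx, np.where(mask_d, daily, 0.0))
    np.add.at(counts, midx, mask_d.astype(float))
    month_mask = counts > 0
    monthly = np.divide(sums, counts, out=np.zeros_like(sums), where=month_mask)
    return np.ma.masked_array(monthly, mask=~month_mask), month_mask


def forward_sif(
    monthly_gpp_per_pft: np.ndarray,
    fractions: np.ndarray,
    bare: np.ndarray,
    link: SIFLinkParams,
    pft_indices,
) -> np.ndarray:
    """Monthly cell SIF from monthly per-PFT GPP (n_months, n_cells, n_pfts)."""
    a = np.array([link.a[p] for p in pft_indices])
    b = np.array([link.b[p] for p in pft_indices])
    per_pft = monthly_gpp_per_pft * a[None, None, :] + b[None, None, :]
    return cell_sif(per_pft, fractions, bare)
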