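"""Optimisable parameter space: definitions, vector construction, standardisation.

The parameter table lists 17 parameters grouped as photosynthesis, phenology
and the per-PFT linear SIF-GPP link (slope/intercept).  Each parameter applies
to a subset of the 12 vegetated plant functional types (PFTs, indices 2-13);
the concatenated (parameter, PFT) vector over all 12 PFTs has 172 entries.

Prior values for the process parameters are *surrogate defaults* in
physiologically plausible ranges; they are not taken from any particular
biosphere model and every one of them can be overridden via the CSV interface
(:func:`read_parameter_table`).  The SIF link priors and bounds, and the
40%-of-range prior uncertainty rule, are fixed conventions of the method.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PFT_INDICES",
    "PFTDescriptor",
    "ParameterDef",
    "ParameterTable",
    "ParameterVector",
    "StandardisedVector",
    "default_parameter_table",
    "build_parameter_vector",
    "build_prior",
    "standardise",
    "unstandardise",
    "read_parameter_table",
    "write_parameter_table",
]

#: Vegetated PFT indices (bare soil is index 1 and is never optimised).
PFT_INDICES: tuple[int, ...] = tuple(range(2, 14))

PRIOR_SIGMA_RANGE_FRACTION = 0.4  # prior 1-sigma = 40% of the bound range


@dataclass(frozen=True)
class PFTDescriptor:
    """One plant functional type."""

    index: int
    acronym: str
    deciduous: bool
    c4: bool


#: The 12 vegetated PFTs in canonical order.
DEFAULT_PFTS: tuple[PFTDescriptor, ...] = (
    PFTDescriptor(2, "TrBE", False, False),
    PFTDescriptor(3, "TrBR", True, False),
    PFTDescriptor(4, "TeNE", False, False),
    PFTDescriptor(5, "TeBE", False, False),
    PFTDescriptor(6, "TeBD", True, False),
    PFTDescriptor(7, "BoNE", False, False),
    PFTDescriptor(8, "BoBD", True, False),
    PFTDescriptor(9, "BoND", True, False),
    PFTDescriptor(10, "NC3", True, False),
    PFTDescriptor(11, "NC4", True, True),
    PFTDescriptor(12, "AC3", True, False),
    PFTDescriptor(13, "AC4", True, True),
)


@dataclass(frozen=True)
class ParameterDef:
    """Definition of one optimisable parameter.

    ``prior_value`` is either a single float (uniform across PFTs) or a
    mapping from PFT index to float.
    """

    name: str
    group: str  # photosynthesis | phenology | sif_link
    units: str
    pft_applicability: frozenset[int]
    prior_value: float | Mapping[int, float]
    lower_bound: float
    upper_bound: float
    description: str = ""

    def __post_init__(self) -> None:
        if not self.lower_bound < self.upper_bound:
            raise ValueError(
                f"{self.name}: lower_bound must be < upper_bound "
                f"({self.lower_bound} vs {self.upper_bound})"
            )
        if not self.pft_applicability:
            raise ValueError(f"{self.name}: pft_applicability must be non-empty")
        bad = set(self.pft_applicability) - set(PFT_INDICES)
        if bad:
            raise ValueError(f"{self.name}: unknown PFT indices {sorted(bad)}")
        for pft in self.pft_applicability:
            v = self.prior_for(pft)
            if not (self.lower_bound <= v <= self.upper_bound):
                raise ValueError(
                    f"{self.name}: prior {v} for PFT {pft} outside bounds "
                    f"[{self.lower_bound}, {self.upper_bound}]"
                )

    def prior_for(self, pft: int) -> float:
        """Prior value for one PFT."""
        if isinstance(self.prior_value, Mapping):
            return float(self.prior_value[pft])
        return float(self.prior_value)


@dataclass
class ParameterTable:
    """Ordered parameter definitions plus the PFT descriptors they refer to."""

    defs: list[ParameterDef]
    pfts: tuple[PFTDescriptor, ...] = DEFAULT_PFTS

    def __post_init__(self) -> None:
        names = [d.name for d in self.defs]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        idx = [p.index for p in self.pfts]
        if len(set(idx)) != len(idx) or set(idx) - set(PFT_INDICES):
            raise ValueError("PFT indices must be unique and within 2-13")

    def __getitem__(self, name: str) -> ParameterDef:
        for d in self.defs:
            if d.name == name:
                return d
        raise KeyError(name)

    def names(self) -> list[str]:
        return [d.name for d in self.defs]

    def pft(self, index: int) -> PFTDescriptor:
        for p in self.pfts:
            if p.index == index:
                return p
        raise KeyError(index)

    def effective_params(self, pft: int) -> dict[str, float]:
        """Full parameter dict for one PFT (priors; includes non-applicable
        parameters pinned at their default so the process model is closed)."""
        out: dict[str, float] = {}
        for d in self.defs:
            if isinstance(d.prior_value, Mapping):
                v = d.prior_value.get(pft)
                if v is None:  # fall back to the mean of the defined priors
                    v = float(np.mean(list(d.prior_value.values())))
                out[d.name] = float(v)
            else:
                out[d.name] = float(d.prior_value)
        return out


@dataclass
class ParameterVector:
    """Concatenated (parameter, PFT) vector with prior, bounds and prior sigma.

    Ordering is parameter-major (table order) then PFT index, which keeps
    positions stable across runs for regression testing.
    """

    values: np.ndarray
    index_map: dict[tuple[str, int], int]
    prior: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    prior_sigma: np.ndarray | None = None
    table: ParameterTable | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.values)
        for arr_name in ("prior", "lower", "upper"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"{arr_name} length mismatch")
        if self.prior_sigma is not None and len(self.prior_sigma) != n:
            raise ValueError("prior_sigma length mismatch")
        if len(self.index_map) != n:
            raise ValueError("index_map must cover every vector position")
        if np.any(self.values < self.lower - 1e-12) or np.any(
            self.values > self.upper + 1e-12
        ):
            raise ValueError("values outside bounds")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def keys(self) -> list[tuple[str, int]]:
        """(parameter, PFT) pairs in vector order."""
        inv = {i: k for k, i in self.index_map.items()}
        return [inv[i] for i in range(len(self))]

    def position(self, name: str, pft: int) -> int:
        return self.index_map[(name, pft)]

    def get(self, name: str, pft: int) -> float:
        return float(self.values[self.position(name, pft)])

    def set(self, name: str, pft: int, value: float) -> None:
        self.values[self.position(name, pft)] = value

    def prior_covariance_diag(self) -> np.ndarray:
        """Diagonal of P_b (sigma^2); parameters are independent a priori."""
        if self.prior_sigma is None:
            raise ValueError("prior_sigma not set; call build_prior first")
        return self.prior_sigma**2

    def with_values(self, values: np.ndarray) -> "ParameterVector":
        """Copy with new values (same prior/bounds/indexing)."""
        return ParameterVector(
            values=np.asarray(values, dtype=float).copy(),
            index_map=self.index_map,
            prior=self.prior,
            lower=self.lower,
            upper=self.upper,
            prior_sigma=self.prior_sigma,
            table=self.table,
        )

    def effective_params(self, pft: int) -> dict[str, float]:
        """Parameter dict for one PFT: table defaults overridden by the
        entries of this vector where (param, pft) is optimisable."""
        if self.table is None:
            raise ValueError("vector has no attached table")
        out = self.table.effective_params(pft)
        for d in self.table.defs:
            key = (d.name, pft)
            if key in self.index_map:
                out[d.name] = float(self.values[self.index_map[key]])
        return out

    def at_bound(self, rtol: float = 1e-6) -> np.ndarray:
        """Boolean mask of entries lying on a bound (edge-hitting)."""
        span = self.upper - self.lower
        return (np.abs(self.values - self.lower) <= rtol * span) | (
            np.abs(self.values - self.upper) <= rtol * span
        )

    def to_json(self, path) -> None:
        rows = []
        bound = self.at_bound()
        for (name, pft), i in sorted(self.index_map.items(), key=lambda kv: kv[1]):
            rows.append(
                {
                    "name": name,
                    "pft": pft,
                    "value": float(self.values[i]),
                    "sigma": None
                    if self.prior_sigma is None
                    else float(self.prior_sigma[i]),
                    "at_bound": bool(bound[i]),
                }
            )
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)


@dataclass(frozen=True)
class StandardisedVector:
    """Dimensionless parameter vector x' = P_b^(-1/2) (x - x_b)."""

    values: np.ndarray


ALL_PFTS = frozenset(PFT_INDICES)
_TEMP_TRIGGERED = frozenset({6, 8, 9, 10, 11, 12, 13})
_MOIST_TRIGGERED = frozenset({3, 10, 11, 12, 13})
_LEAF_FALL = frozenset({3, 6, 8, 9})


def default_parameter_table() -> ParameterTable:
    """The default 17-parameter table.

    Applicability: twelve parameters apply to all 12 PFTs; the growing-season
    onset threshold and senescence temperature apply to the temperature-
    triggered deciduous PFTs {6, 8-13}; the moisture-onset delay and moisture
    senescence threshold to {3, 10-13}; the leaf-fall rate to {3, 6, 8, 9}.
    """
    d = ParameterDef
    defs = [
        d("V_cmax", "photosynthesis", "umol m-2 s-1", ALL_PFTS,
          {2: 50.0, 3: 55.0, 4: 35.0, 5: 45.0, 6: 50.0, 7: 30.0, 8: 45.0,
           9: 35.0, 10: 55.0, 11: 70.0, 12: 60.0, 13: 70.0},
          20.0, 100.0, "Maximum carboxylation rate"),
        d("G_s_slope", "photosynthesis", "-", ALL_PFTS, 9.0, 3.0, 15.0,
          "Stomatal (Ball-Berry) slope scaling the supply-limited rate"),
        d("T_opt", "photosynthesis", "degC", ALL_PFTS,
          {2: 28.0, 3: 28.0, 4: 20.0, 5: 24.0, 6: 22.0, 7: 16.0, 8: 16.0,
           9: 16.0, 10: 20.0, 11: 30.0, 12: 22.0, 13: 30.0},
          12.0, 36.0, "Optimal photosynthesis temperature"),
        d("T_min", "photosynthesis", "degC", ALL_PFTS,
          {2: 2.0, 3: 2.0, 4: -4.0, 5: -2.0, 6: -2.0, 7: -6.0, 8: -6.0,
           9: -6.0, 10: -4.0, 11: 4.0, 12: -4.0, 13: 4.0},
          -10.0, 10.0, "Minimum photosynthesis temperature"),
        d("T_max", "photosynthesis", "degC", ALL_PFTS,
          {2: 45.0, 3: 45.0, 4: 42.0, 5: 44.0, 6: 44.0, 7: 40.0, 8: 40.0,
           9: 40.0, 10: 42.0, 11: 48.0, 12: 42.0, 13: 48.0},
          37.0, 55.0, "Maximum photosynthesis temperature"),
        d("F_stress_h", "photosynthesis", "-", ALL_PFTS, 1.0, 0.0, 2.0,
          "Strength of the hydric limitation of photosynthesis"),
        d("SLA", "phenology", "m2 g-1", ALL_PFTS,
          {2: 0.015, 3: 0.018, 4: 0.009, 5: 0.013, 6: 0.020, 7: 0.009,
           8: 0.022, 9: 0.022, 10: 0.025, 11: 0.025, 12: 0.025, 13: 0.025},
          0.004, 0.05, "Specific leaf area"),
        d("LAI_max", "phenology", "m2 m-2", ALL_PFTS,
          {2: 6.0, 3: 5.0, 4: 5.0, 5: 5.0, 6: 5.0, 7: 4.5, 8: 4.0, 9: 4.0,
           10: 3.0, 11: 3.0, 12: 4.0, 13: 4.0},
          1.5, 9.0, "Maximum leaf area index"),
        d("K_LAI_happy", "phenology", "-", ALL_PFTS, 0.5, 0.2, 0.9,
          "LAI fraction at which carbohydrate-reserve growth stops"),
        d("K_pheno_crit", "phenology", "-", _TEMP_TRIGGERED, 1.0, 0.3, 2.5,
          "Multiplier of the growing-degree-day onset threshold"),
        d("M_Tmin", "phenology", "days", _MOIST_TRIGGERED, 35.0, 5.0, 90.0,
          "Days since moisture minimum required for leaf growth"),
        d("L_age_crit", "phenology", "days", ALL_PFTS,
          {2: 730.0, 3: 140.0, 4: 910.0, 5: 730.0, 6: 180.0, 7: 910.0,
           8: 160.0, 9: 160.0, 10: 120.0, 11: 120.0, 12: 110.0, 13: 110.0},
          60.0, 1500.0, "Average critical age of leaves"),
        d("T_senes", "phenology", "degC", _TEMP_TRIGGERED,
          {6: 7.0, 8: 2.0, 9: 2.0, 10: 5.0, 11: 8.0, 12: 7.0, 13: 8.0},
          -2.0, 20.0, "Temperature threshold for senescence"),
        d("M_senes_nosenes", "phenology", "-", _MOIST_TRIGGERED, 0.45, 0.05,
          0.8, "Moisture threshold for senescence"),
        d("L_fall", "phenology", "day-1", _LEAF_FALL, 0.08, 0.01, 0.5,
          "Rate of leaf fall during senescence"),
        d("SIF_a", "sif_link", "mW m-2 sr-1 nm-1 per gC m-2 day-1", ALL_PFTS,
          0.25, -0.5, 1.0, "Slope of the linear SIF-GPP relationship"),
        d("SIF_b", "sif_link", "mW m-2 sr-1 nm-1", ALL_PFTS, 0.25, -1.5, 2.5,
          "Intercept of the linear SIF-GPP relationship"),
    ]
    return ParameterTable(defs=defs)


def build_parameter_vector(
    table: ParameterTable, pfts: Sequence[int] | None = None
) -> ParameterVector:
    """Concatenate (parameter, PFT) entries permitted by applicability.

    Ordering is parameter-major (table order) then ascending PFT index.
    """
    if pfts is None:
        pfts = [p.index for p in table.pfts]
    known = {p.index for p in table.pfts}
    unknown = set(pfts) - known
    if unknown:
        raise ValueError(f"unknown PFT indices: {sorted(unknown)}")
    values: list[float] = []
    prior: list[float] = []
    lower: list[float] = []
    upper: list[float] = []
    index_map: dict[tuple[str, int], int] = {}
    for d in table.defs:
        for pft in sorted(pfts):
            if pft not in d.pft_applicability:
                continue
            index_map[(d.name, pft)] = len(values)
            v = d.prior_for(pft)
            values.append(v)
            prior.append(v)
            lower.append(d.lower_bound)
            upper.append(d.upper_bound)
    vec = ParameterVector(
        values=np.array(values, dtype=float),
        index_map=index_map,
        prior=np.array(prior, dtype=float),
        lower=np.array(lower, dtype=float),
        upper=np.array(upper, dtype=float),
        table=table,
    )
    return build_prior(vec)


def build_prior(vector: ParameterVector) -> ParameterVector:
    """Fill prior_sigma with 40% of each parameter's bound range (diag P_b)."""
    if not (np.all(np.isfinite(vector.lower)) and np.all(np.isfinite(vector.upper))):
        raise ValueError("bounds must be finite to derive prior uncertainties")
    vector.prior_sigma = PRIOR_SIGMA_RANGE_FRACTION * (vector.upper - vector.lower)
    return vector


def standardise(x: ParameterVector, values: np.ndarray | None = None) -> StandardisedVector:
    """x' = P_b^(-1/2) (x - x_b) with diagonal P_b."""
    if x.prior_sigma is None:
        raise ValueError("prior_sigma not set; call build_prior first")
    if np.any(x.prior_sigma <= 0):
        raise ValueError("prior_sigma must be strictly positive")
    v = x.values if values is None else np.asarray(values, dtype=float)
    return StandardisedVector((v - x.prior) / x.prior_sigma)


def unstandardise(x: ParameterVector, z: StandardisedVector | np.ndarray) -> np.ndarray:
    """Inverse of :func:`standardise`."""
    if x.prior_sigma is None:
        raise ValueError("prior_sigma not set; call build_prior first")
    zv = z.values if isinstance(z, StandardisedVector) else np.asarray(z, dtype=float)
    return x.prior + zv * x.prior_sigma


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

_CSV_FIELDS = ["name", "group", "units", "pft_list", "prior", "lower", "upper", "description"]


def write_parameter_table(table: ParameterTable, path) -> None:
    """Serialise a table to CSV (per-PFT priors as 'pft:value' pairs)."""
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        w.writeheader()
        for d in table.defs:
            if d.pft_applicability == ALL_PFTS:
                pft_list = "all"
            else:
                pft_list = ";".join(str(i) for i in sorted(d.pft_applicability))
            if isinstance(d.prior_value, Mapping):
                prior = ";".join(
                    f"{k}:{v!r}" for k, v in sorted(d.prior_value.items())
                )
            else:
                prior = repr(float(d.prior_value))
            w.writerow(
                {
                    "name": d.name,
                    "group": d.group,
                    "units": d.units,
                    "pft_list": pft_list,
                    "prior": prior,
                    "lower": repr(d.lower_bound),
                    "upper": repr(d.upper_bound),
                    "description": d.description,
                }
            )


def read_parameter_table(path, pfts: Iterable[PFTDescriptor] = DEFAULT_PFTS) -> ParameterTable:
    """Read a table written by :func:`write_parameter_table`."""
    defs: list[ParameterDef] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            raw = row["pft_list"].strip().lower()
            if raw == "all":
                applicability = ALL_PFTS
            else:
                applicability = frozenset(int(t) for t in raw.split(";") if t)
            prior_raw = row["prior"].strip()
            prior: float | dict[int, float]
            if ":" in prior_raw:
                prior = {
                    int(k): float(v)
                    for k, v in (t.split(":") for t in prior_raw.split(";") if t)
                }
            else:
                prior = float(prior_raw)
            defs.append(
                ParameterDef(
                    name=row["name"],
                    group=row["group"],
                    units=row["units"],
                    pft_applicability=applicability,
                    prior_value=prior,
                    lower_bound=float(row["lower"]),
                    upper_bound=float(row["upper"]),
                    description=row.get("description", ""),
                )
            )
    return ParameterTable(defs=defs, pfts=tuple(pfts))
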