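"""Scenario configuration, calendar/weather series, forage production and grazing bookkeeping.

All parameters that drive the simulator live on :class:`HerdConfig`.  Several
tables (culling minima, conception/abortion hazards, health hazard means,
postpartum-interval PERT cells, BCS tables, breed EBV trends, diet prices,
DMI caps) are documented stand-ins: the simulator's behaviour is defined in
terms of them, their published sources are not reproducible here, and every
default is replaceable from a YAML scenario file.

The environment is a Kansas Flint Hills-like grazing system: May 1 - Oct 31
grazing on native bluestem range whose net-energy density peaks in spring
and collapses after August, with drylot feeding of an alfalfa-based base
diet the rest of the year.  A synthetic-weather generator emulates
Manhattan, KS monthly climatology so that runs need no external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from cowcalfsim.ration import DietSpec

LB_PER_KG = 2.205

#: Monthly mean temperature climatology, deg C (Manhattan, KS-like), Jan..Dec.
MONTHLY_TEMP_NORMALS_C = np.array(
    [-1.7, 0.8, 6.7, 12.9, 18.6, 24.2, 26.9, 26.1, 21.4, 14.6, 6.9, 0.3]
)
#: Monthly mean precipitation climatology, mm, Jan..Dec.
MONTHLY_PRECIP_NORMALS_MM = np.array(
    [22.0, 32.0, 64.0, 84.0, 122.0, 138.0, 112.0, 99.0, 82.0, 67.0, 43.0, 29.0]
)

# Grazed-forage nutrient density by calendar month (Mcal/kg DM for NEm/NEg,
# Mcal/kg for digestible energy): Apr-Jun peak, Jul-Aug summer slump,
# Sep-Mar dormant.
_FORAGE_BY_MONTH = {
    "nem": np.array([0.71, 0.71, 0.71, 1.48, 1.48, 1.48, 1.10, 1.10, 0.71, 0.71, 0.71, 0.71]),
    "neg": np.array([0.18, 0.18, 0.18, 0.90, 0.90, 0.90, 0.54, 0.54, 0.18, 0.18, 0.18, 0.18]),
    "de": np.array([1.89, 1.89, 1.89, 2.86, 2.86, 2.86, 2.12, 2.12, 1.89, 1.89, 1.89, 1.89]),
}

#: Base full-season acreage allocation per head, indexed to a 612.25 kg cow.
ACREAGE_BASE = {"pair": 7.3, "yearling": 4.0, "weaned_heifer": 2.7}
REFERENCE_COW_KG = 612.25


@dataclass
class EnvironmentCalendar:
    """Monthly weather and forage-nutrient series for a run.

    Arrays are shaped ``(n_years, 12)`` and indexed by (year offset from
    ``start_year``, month-1).
    """

    start_year: int
    temp_c: np.ndarray
    precip_mm: np.ndarray
    forage_nem: np.ndarray
    forage_neg: np.ndarray
    forage_de: np.ndarray
    grazing_start: tuple[int, int] = (5, 1)
    grazing_end: tuple[int, int] = (10, 31)

    @property
    def n_years(self) -> int:
        return self.temp_c.shape[0]

    def jan_aug_precip(self, year: int) -> float:
        """Cumulative January-August precipitation (mm) for a calendar year."""
        return float(self.precip_mm[year - self.start_year, :8].sum())

    def to_frame(self) -> pd.DataFrame:
        years = np.repeat(np.arange(self.start_year, self.start_year + self.n_years), 12)
        months = np.tile(np.arange(1, 13), self.n_years)
        return pd.DataFrame(
            {
                "year": years,
                "month": months,
                "temp_c": self.temp_c.ravel(),
                "precip_mm": self.precip_mm.ravel(),
                "nem_mcal_kg": self.forage_nem.ravel(),
                "neg_mcal_kg": self.forage_neg.ravel(),
                "de_mcal_kg": self.forage_de.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EnvironmentCalendar":
        frame = frame.sort_values(["year", "month"]).reset_index(drop=True)
        years = frame["year"].unique()
        if len(frame) != 12 * len(years):
            raise ValueError("environment table must have 12 monthly rows per year")
        shape = (len(years), 12)
        return cls(
            start_year=int(years.min()),
            temp_c=frame["temp_c"].to_numpy().reshape(shape),
            precip_mm=frame["precip_mm"].to_numpy().reshape(shape),
            forage_nem=frame["nem_mcal_kg"].to_numpy().reshape(shape),
            forage_neg=frame["neg_mcal_kg"].to_numpy().reshape(shape),
            forage_de=frame["de_mcal_kg"].to_numpy().reshape(shape),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EnvironmentCalendar":
        return cls.from_frame(pd.read_csv(path))


def generate_synthetic_weather(
    years: int,
    seed: int,
    start_year: int = 1995,
    temp_noise_sd: float = 1.5,
    precip_cv: float = 0.35,
) -> EnvironmentCalendar:
    """Seeded synthetic monthly weather emulating Manhattan, KS climatology.

    Temperature is the monthly climatological normal plus Gaussian noise;
    precipitation is the monthly normal perturbed by lognormal-like
    multiplicative noise (clipped at zero).  Deterministic per seed.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = np.random.default_rng(seed)
    temp = MONTHLY_TEMP_NORMALS_C + rng.normal(0.0, temp_noise_sd, size=(years, 12))
    precip = MONTHLY_PRECIP_NORMALS_MM * np.clip(
        1.0 + precip_cv * rng.normal(size=(years, 12)), 0.0, None
    )
    ones = np.ones((years, 12))
    return EnvironmentCalendar(
        start_year=start_year,
        temp_c=temp,
        precip_mm=precip,
        forage_nem=_FORAGE_BY_MONTH["nem"] * ones,
        forage_neg=_FORAGE_BY_MONTH["neg"] * ones,
        forage_de=_FORAGE_BY_MONTH["de"] * ones,
    )


def forage_production(
    jan_aug_precip: float,
    prior_pct_remaining: float,
    coefficients: tuple[float, float, float] = (150.0, 0.9, 220.0),
) -> float:
    """Annual forage production, kg DM/acre, linear in cumulative Jan-Aug
    precipitation (mm) and the fraction of forage remaining at the end of the
    prior grazing season.

    The default coefficients are calibrated so that at mean synthetic
    precipitation (~673 mm) and 0.6 prior remaining, a 7.3-acre allocation
    carries a 612 kg pair through Oct 31 with roughly 45% forage remaining.
    """
    if jan_aug_precip < 0 or prior_pct_remaining < 0:
        raise ValueError("inputs must be non-negative")
    c0, c_precip, c_prior = coefficients
    return max(c0 + c_precip * jan_aug_precip + c_prior * prior_pct_remaining, 0.0)


def acreage_allocation(mean_mw: float, animal_class: str) -> float:
    """Acres per head, scaled from the 612.25 kg reference by metabolic weight.

    ``animal_class`` is one of ``pair`` (7.3 acres), ``yearling`` (4.0) or
    ``weaned_heifer`` (2.7).
    """
    if mean_mw <= 0:
        raise ValueError("mean_mw must be positive")
    try:
        base = ACREAGE_BASE[animal_class]
    except KeyError:
        raise ValueError(f"unknown animal class: {animal_class!r}") from None
    return base * (mean_mw**0.75) / (REFERENCE_COW_KG**0.75)


@dataclass
class GrazingLedger:
    """Standing-forage bookkeeping for one grazing season."""

    production_per_acre: float
    acres: float
    waste_fraction: float = 0.25
    removal_threshold: float = 0.40
    cumulative_removed: float = 0.0

    @property
    def standing_total(self) -> float:
        return self.production_per_acre * self.acres

    @property
    def pct_remaining(self) -> float:
        total = self.standing_total
        if total <= 0:
            return 0.0
        return max(1.0 - self.cumulative_removed / total, 0.0)


def update_grazing_ledger(ledger: GrazingLedger, herd_intake_today: float) -> bool:
    """Charge one day of herd intake against standing forage.

    Effective removal is intake inflated by trampling/waste
    (``intake / (1 - waste_fraction)``).  Returns True when the percent of
    forage remaining has fallen below the removal threshold, signalling that
    animals come off grass.
    """
    if herd_intake_today < 0:
        raise ValueError("intake must be non-negative")
    ledger.cumulative_removed += herd_intake_today / (1.0 - ledger.waste_fraction)
    return ledger.pct_remaining < ledger.removal_threshold


def _linear_ramp(y0: int, v0: float, y1: int, v1: float) -> dict[int, float]:
    years = np.arange(y0, y1 + 1)
    vals = v0 + (v1 - v0) * (years - y0) / (y1 - y0)
    return {int(y): float(v) for y, v in zip(years, vals)}


@dataclass
class HealthHazardConfig:
    """Mean/SD pairs for the truncated-normal daily hazard draws.

    Calf mortality has eight cells: (age class: neonatal <=3 d vs older) x
    (dystocia) x (prior morbidity).  One value per cell is drawn per
    simulation iteration and applied herd-wide.  Defaults are stand-ins
    chosen so total pre-weaning calf mortality is ~4.5-5% of calves born and
    annual breeding-female mortality is ~1.5%.
    """

    calf_morbidity: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "neonatal": (0.004, 0.001),
            "neonatal_dystocia": (0.012, 0.003),
            "post": (0.0004, 0.0001),
            "post_dystocia": (0.0012, 0.0003),
        }
    )
    calf_mortality: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "neonatal": (0.006, 0.0015),
            "neonatal_morbid": (0.030, 0.008),
            "neonatal_dystocia": (0.018, 0.005),
            "neonatal_dystocia_morbid": (0.090, 0.020),
            "post": (0.00012, 0.00003),
            "post_morbid": (0.0006, 0.00015),
            "post_dystocia": (0.00036, 0.0001),
            "post_dystocia_morbid": (0.0018, 0.0005),
        }
    )
    female_mortality: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "replacement": (3.0e-5, 0.8e-5),
            "breeding": (4.2e-5, 1.0e-5),
        }
    )


@dataclass
class HerdConfig:
    """All scenario parameters for a simulation run."""

    # --- herd management -------------------------------------------------
    target_exposed: int = 100
    breeding_start: tuple[int, int] = (5, 1)  # May 1
    breeding_end: tuple[int, int] = (7, 3)  # Jul 3 (63 d season)
    preg_check_lag: int = 60  # days after breeding end
    weaning_trigger_age: int = 220  # oldest calf age on the herd weaning date
    max_cow_age: int = 13
    #: Minimum culled fraction per cow age (voluntary culls top up opens).
    min_cull_fraction_by_age: dict[int, float] = field(
        default_factory=lambda: {age: 0.10 for age in range(2, 14)}
    )
    burn_in_years: int = 5

    # --- genetics --------------------------------------------------------
    sire_mw_gp: float = 590.0  # kg
    sire_pl_gp: float = 11.3  # kg/d
    mw_gp_sd: float = 25.4  # kg
    pl_gp_sd: float = 1.0  # kg/d
    bw_gp_sd_lb: float = 3.76
    ww_gp_sd_lb: float = 22.0
    bw_phenotype_sd_lb: float = 4.07
    female_bw_factor: float = 0.94
    female_ww_factor: float = 0.93
    corr_mw_pl: float = 0.14
    corr_mw_ww: float = 0.44
    corr_ww_bw: float = 0.29
    corr_bw_gestation: float = 0.30
    #: Breed-average WW/BW EBV trends by calf birth year, lb (stand-ins:
    #: linear ramps through the simulated period; EBV = 2 x EPD).
    ww_ebv_by_year: dict[int, float] = field(
        default_factory=lambda: _linear_ramp(1985, 18.0, 2020, 104.0)
    )
    bw_ebv_by_year: dict[int, float] = field(
        default_factory=lambda: _linear_ramp(1985, 5.4, 2020, 2.0)
    )
    ww_ebv_1992_lb: float | None = None  # defaults to ww_ebv_by_year[1992]
    founder_parent_years: tuple[int, int] = (1989, 1992)
    #: Additive dam-age adjustments, lb, keyed by dam age (BIF-guideline
    #: stand-ins; ages outside the table use the nearest entry).
    bw_dam_age_adj_lb: dict[int, float] = field(
        default_factory=lambda: {2: 8.0, 3: 5.0, 4: 2.0, 5: 0.0, 10: 0.0, 11: 3.0}
    )
    ww_dam_age_adj_lb: dict[int, float] = field(
        default_factory=lambda: {2: 60.0, 3: 40.0, 4: 20.0, 5: 0.0, 10: 0.0, 11: 20.0}
    )

    # --- nutrition -------------------------------------------------------
    lactation_k: float = 0.1175
    low_milk_threshold: float = 7.0  # kg/d
    cow_low_milk_factor: float = 0.88
    calf_low_milk_factor: float = 0.89
    milk_nem_mcal_kg: float = 0.55
    milk_neg_mcal_kg: float = 0.33
    milk_only_age: int = 50  # d; forage allowed afterwards
    calf_growth_cap_age: int = 80  # d; ADG capped at genetic need afterwards
    dmi_pct_cap: float = 0.026  # max DMI as fraction of CSBW, young animals
    #: Mcal of energy per kg empty-body-weight change by BCS (stand-ins
    #: anchored to NASEM-convention magnitudes).
    mcal_per_kg_gain_by_bcs: dict[int, float] = field(
        default_factory=lambda: {b: 5.4 + 0.2 * b for b in range(1, 10)}
    )
    mcal_per_kg_loss_by_bcs: dict[int, float] = field(
        default_factory=lambda: {b: 4.4 + 0.15 * b for b in range(1, 10)}
    )
    #: Body-fat fraction of shrunk BW at each BCS (young-animal method),
    #: NRC-convention slope anchored at 0.1889 for BCS 5.
    fat_frac_by_bcs: dict[int, float] = field(
        default_factory=lambda: {b: 0.1889 + 0.037 * (b - 5) for b in range(1, 10)}
    )
    #: CSBW as a fraction of mature shrunk BW at each BCS (mature method),
    #: anchored at 1.0 for BCS 5.
    csbw_ratio_by_bcs: dict[int, float] = field(
        default_factory=lambda: {b: 1.0 + 0.07 * (b - 5) for b in range(1, 10)}
    )

    # --- diets and feeding policy ---------------------------------------
    base_diet: DietSpec = field(
        default_factory=lambda: DietSpec("base_73alf_19straw_8corn", 1.20, 0.64, 3.08, 0.13)
    )
    supplement_diet: DietSpec = field(
        default_factory=lambda: DietSpec("suppl_60alf_40corn", 1.63, 1.02, 3.08, 0.18)
    )
    grazing_supplement_dmi_cap: float = 0.20  # fraction of daily DMI
    overcondition_intake_restriction: float = 0.70  # of NEmR intake at BCS > 6
    available_base_kg: float = 1.0e6  # Available BR cap, generous default
    bcs_target: int = 5
    #: Condition-recovery allowance for mature cows below the BCS target:
    #: supplementation targets this much shrunk-weight regain per day on top
    #: of maintenance, implementing the keep-cows-at-BCS-5-or-6 goal.
    bcs_regain_kg_per_day: float = 0.3

    # --- grazing / land --------------------------------------------------
    grazing_start: tuple[int, int] = (5, 1)
    grazing_end: tuple[int, int] = (10, 31)
    forage_waste_fraction: float = 0.25
    forage_removal_threshold: float = 0.40
    forage_coefficients: tuple[float, float, float] = (150.0, 0.9, 220.0)
    initial_pct_remaining: float = 0.6

    # --- reproduction ----------------------------------------------------
    conception_prob_per_estrus: float = 0.65
    daily_abortion_hazard: float = 5.0e-5
    gestation_mean: float = 285.0
    gestation_sd: float = 5.0
    gestation_bounds: tuple[float, float] = (260.0, 310.0)
    first_estrus_mean: float = 300.0
    first_estrus_sd: float = 20.0
    puberty_weight_fraction: float = 0.40
    estrus_interval: tuple[float, float, float, float] = (21.0, 0.75, 18.0, 24.0)
    #: Postpartum-interval beta-PERT (min, mode, max) by parity class and
    #: BCS class (stand-ins spanning cited literature ranges).
    ppi_pert: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "multiparous_low": (42.0, 62.0, 92.0),
            "multiparous_moderate": (40.0, 60.0, 90.0),
            "multiparous_high": (36.0, 56.0, 86.0),
            "primiparous_low": (44.0, 64.0, 94.0),
            "primiparous_moderate": (42.0, 62.0, 92.0),
            "primiparous_high": (40.0, 60.0, 90.0),
        }
    )
    dystocia_ppi_addon: tuple[float, float] = (10.0, 3.0)  # trunc-normal mean, SD
    dystocia_risk_base: tuple[float, float] = (0.05, 0.01)
    dystocia_risk_primiparous_heavy: tuple[float, float] = (0.08, 0.01)
    dystocia_heavy_bw_lb: float = 90.0

    # --- health ----------------------------------------------------------
    health: HealthHazardConfig = field(default_factory=HealthHazardConfig)

    def __post_init__(self) -> None:
        if not (0.0 <= self.conception_prob_per_estrus <= 1.0):
            raise ValueError("conception probability must be in [0, 1]")
        if not (0.0 <= self.daily_abortion_hazard <= 1.0):
            raise ValueError("abortion hazard must be in [0, 1]")
        if self.breeding_start >= self.breeding_end:
            raise ValueError("breeding season must start before it ends")
        if self.ww_ebv_1992_lb is None:
            self.ww_ebv_1992_lb = self.ww_ebv_by_year[1992]
        for age in range(2, self.max_cow_age + 1):
            if age not in self.min_cull_fraction_by_age:
                raise ValueError(f"no culling minimum for cow age {age}")

    # --- serialization ---------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, default_flow_style=False, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "HerdConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "HerdConfig":
        kwargs = dict(payload)
        for key in ("base_diet", "supplement_diet"):
            if key in kwargs and isinstance(kwargs[key], (dict, list, tuple)):
                value = kwargs[key]
                kwargs[key] = DietSpec(**value) if isinstance(value, dict) else DietSpec(*value)
        if "health" in kwargs and isinstance(kwargs["health"], dict):
            health = {
                k: {cat: tuple(v) for cat, v in tbl.items()}
                for k, tbl in kwargs["health"].items()
            }
            kwargs["health"] = HealthHazardConfig(**health)
        for key in (
            "min_cull_fraction_by_age",
            "ww_ebv_by_year",
            "bw_ebv_by_year",
            "bw_dam_age_adj_lb",
            "ww_dam_age_adj_lb",
            "mcal_per_kg_gain_by_bcs",
            "mcal_per_kg_loss_by_bcs",
            "fat_frac_by_bcs",
            "csbw_ratio_by_bcs",
        ):
            if key in kwargs:
                kwargs[key] = {int(k): float(v) for k, v in kwargs[key].items()}
        for key in (
            "breeding_start",
            "breeding_end",
            "grazing_start",
            "grazing_end",
            "founder_parent_years",
            "gestation_bounds",
            "estrus_interval",
            "dystocia_ppi_addon",
            "dystocia_risk_base",
            "dystocia_risk_primiparous_heavy",
            "forage_coefficients",
        ):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "ppi_pert" in kwargs:
            kwargs["ppi_pert"] = {k: tuple(v) for k, v in kwargs["ppi_pert"].items()}
        return cls(**kwargs)


def default_config(**overrides) -> HerdConfig:
    """A :class:`HerdConfig` with the documented default parameterization."""
    return dataclasses.replace(HerdConfig(), **overrides) if overrides else HerdConfig()


def lookup_age_table(table: dict[int, float], age: np.ndarray | int) -> np.ndarray:
    """Look ages up in an age-keyed table, clamping to the nearest key."""
    keys = np.array(sorted(table))
    vals = np.array([table[k] for k in keys])
    ages = np.atleast_1d(np.asarray(age))
    idx = np.clip(np.searchsorted(keys, ages, side="right") - 1, 0, len(keys) - 1)
    # exact-match-or-below semantics except below the smallest key
    below = ages < keys[0]
    out = vals[idx]
    out = np.where(below, vals[0], out)
    return out if np.ndim(age) else float(out[0])
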