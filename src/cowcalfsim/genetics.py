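"""Per-animal genetic potentials and pre-weaning growth potential.

Four traits carry genetic potential (GP): mature weight (MW, kg, defined at
BCS 5 / body-fat fraction 0.1889), peak lactation (PL, kg milk/d), 205-d
weaning weight (WW, lb, steer base) and birth weight (BW, lb, bull base).
Sire WW/BW potentials derive from regressions on MW/WW plus breed-average
EBV trends (EBV = 2 x EPD); progeny sample around the parental average; and
a constructive correlation-enforcement step fixes the intra-population
correlations between trait pairs in each calf crop exactly at their targets
while leaving the anchor trait untouched.

Internal arithmetic for the WW/BW regressions is in pounds, matching the
published constants; conversion happens at the module boundary at
2.205 lb/kg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LB_PER_KG = 2.205

#: Regression constants for the sire weaning-weight base (lb): a 1,400 lb
#: mature cow weans 42% of her weight, and each pound of MW deviation moves
#: WW by 0.125 lb.
_WW_BASE_FRACTION = 0.42
_WW_BASE_REF_LB = 1400.0
_WW_PER_MW_SLOPE = 0.125
#: Birth-weight-on-weaning-weight regression: slope and Angus-base intercept.
_BW_ON_WW_SLOPE = 0.037
_BW_INTERCEPT_LB = 54.202

PREWEANING_REFERENCE_DAYS = 205


@dataclass
class GeneticProfile:
    """Genetic potentials for one animal."""

    mw_gp: float  # kg, mature weight at BCS 5
    pl_gp: float  # kg milk/d at lactation peak
    ww_gp_lb: float  # lb, 205-d weaning weight, steer base
    bw_gp_lb: float  # lb, birth weight, bull base
    gestation_length: float = 285.0  # d

    def __post_init__(self) -> None:
        if self.mw_gp <= 0 or self.pl_gp <= 0:
            raise ValueError("MW and PL genetic potentials must be positive")


@dataclass
class CalfGrowthPlan:
    """Pre-weaning growth potential for one calf."""

    actual_bw: float  # kg
    badg: float  # kg/d, base pre-weaning ADG potential
    baww: float  # kg, base potential actual weaning weight
    weaning_age: float  # d


def sire_ww_gp_base(sire_mw_gp: float) -> float:
    """Sire 205-d WW GP base (lb) from mature-weight GP (kg)."""
    if sire_mw_gp <= 0:
        raise ValueError("sire MW GP must be positive")
    mw_lb = sire_mw_gp * LB_PER_KG
    return _WW_BASE_FRACTION * _WW_BASE_REF_LB + (mw_lb - _WW_BASE_REF_LB) * _WW_PER_MW_SLOPE


def four_year_sire_ebv(year: int, trend: dict[int, float]) -> float:
    """Average EBV over birth years ``year-5 .. year-2`` (a sire serving four
    seasons with first progeny at age two)."""
    try:
        return sum(trend[year - lag] for lag in (2, 3, 4, 5)) / 4.0
    except KeyError as exc:
        raise KeyError(f"EBV trend table missing year {exc.args[0]} (needed for {year})") from exc


def sire_ww_gp(year: int, base: float, trend: dict[int, float]) -> float:
    """Sire WW GP (lb) for calves born in ``year``."""
    return base + four_year_sire_ebv(year, trend)


def sire_bw_gp(
    year: int, ww_base: float, trend: dict[int, float], ww_ebv_1992: float
) -> float:
    """Sire BW GP (lb) for calves born in ``year``.

    The regression input is the WW base at its 1992 EBV anchor; the
    four-year mean BW EBV is added on top.
    """
    base = _BW_ON_WW_SLOPE * (ww_base + ww_ebv_1992) + _BW_INTERCEPT_LB
    return base + four_year_sire_ebv(year, trend)


def sample_progeny_gp(sire_gp, dam_gp, sd: float, rng: np.random.Generator):
    """Progeny GP ~ Normal(parental average, sd).  Array-friendly in the dam
    argument (one sire, many dams)."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    dam_gp = np.asarray(dam_gp, dtype=float)
    mean = 0.5 * (sire_gp + dam_gp)
    if sd == 0:
        return mean if mean.ndim else float(mean)
    out = rng.normal(mean, sd)
    return out if np.ndim(dam_gp) else float(out)


def enforce_correlation(fixed, adjustable, target_r: float):
    """Rescale ``adjustable`` so its sample correlation with ``fixed`` equals
    ``target_r`` exactly, preserving the adjustable vector's sample mean and
    SD; ``fixed`` is untouched.

    Constructively equivalent to a Cholesky blend: standardize both vectors,
    take ``r * x + sqrt(1 - r^2) * z`` with ``z`` the standardized residual
    of y on x, then restore y's original mean and SD.
    """
    x = np.asarray(fixed, dtype=float)
    y = np.asarray(adjustable, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must share a length of at least 3")
    if not abs(target_r) < 1.0:
        raise ValueError("|target_r| must be < 1")
    sx = x.std()
    if sx < 1e-12:
        raise ValueError("fixed vector has (near) zero variance")
    my, sy = y.mean(), y.std()
    xs = (x - x.mean()) / sx
    if sy < 1e-12:
        # zero-spread adjustable: preserving its SD forces a constant output
        return np.full_like(y, my)
    ys = (y - my) / sy
    r_xy = float(np.mean(xs * ys))
    z = ys - r_xy * xs
    sz = z.std()
    if sz < 1e-12:
        # adjustable is collinear with fixed; no independent residual exists
        blended = target_r * xs
    else:
        blended = target_r * xs + np.sqrt(1.0 - target_r**2) * (z / sz)
    sb = blended.std()
    if sb < 1e-12:
        return np.full_like(y, my)
    out = my + sy * (blended - blended.mean()) / sb
    return out


def phenotypic_birth_weight(
    bw_gp_lb,
    dam_age_adj_lb,
    is_female,
    rng: np.random.Generator,
    sd_lb: float = 4.07,
    female_factor: float = 0.94,
):
    """Actual birth weight (kg): Normal(BW GP, sd) minus the dam-age
    adjustment, scaled for heifer calves.  Array-friendly."""
    bw_gp_lb = np.asarray(bw_gp_lb, dtype=float)
    draw = rng.normal(bw_gp_lb, sd_lb) if sd_lb > 0 else bw_gp_lb.copy()
    draw = draw - np.asarray(dam_age_adj_lb, dtype=float)
    draw = np.where(np.asarray(is_female, dtype=bool), female_factor * draw, draw)
    out = np.maximum(draw, 1.0) / LB_PER_KG  # floor guards pathological draws
    return out if bw_gp_lb.ndim else float(out)


def badg_baww(
    ww_gp_sexed_lb,
    bw_gp_sexed_lb,
    ww_dam_age_adj_lb,
    bw_dam_age_adj_lb,
    actual_bw_kg,
    weaning_age,
):
    """Base pre-weaning ADG (kg/d) and base potential actual weaning weight
    (kg).  Array-friendly; scalar inputs return a :class:`CalfGrowthPlan`."""
    weaning_age_arr = np.asarray(weaning_age, dtype=float)
    if np.any(weaning_age_arr <= 0):
        raise ValueError("weaning age must be positive")
    badg_lb = (
        (np.asarray(ww_gp_sexed_lb, dtype=float) - np.asarray(ww_dam_age_adj_lb, dtype=float))
        - (np.asarray(bw_gp_sexed_lb, dtype=float) - np.asarray(bw_dam_age_adj_lb, dtype=float))
    ) / PREWEANING_REFERENCE_DAYS
    badg = badg_lb / LB_PER_KG
    baww = np.asarray(actual_bw_kg, dtype=float) + badg * weaning_age_arr
    if np.ndim(weaning_age) or np.ndim(ww_gp_sexed_lb):
        return badg, baww
    return CalfGrowthPlan(
        actual_bw=float(actual_bw_kg),
        badg=float(badg),
        baww=float(baww),
        weaning_age=float(weaning_age),
    )


def max_adg(baww, weight_today, age_today, weaning_age):
    """Maximum ADG (kg/d) from age 80 d on: the straight-line rate needed to
    reach the base weaning-weight potential, floored at zero.  Array-friendly."""
    age = np.asarray(age_today, dtype=float)
    wa = np.asarray(weaning_age, dtype=float)
    if np.any(age >= wa):
        raise ValueError("age_today must be before weaning age")
    out = np.maximum(
        (np.asarray(baww, dtype=float) - np.asarray(weight_today, dtype=float)) / (wa - age),
        0.0,
    )
    return out if np.ndim(age_today) or np.ndim(baww) else float(out)
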