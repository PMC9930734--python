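"""Daily net-energy requirements, intake, lactation, gestation, growth and
body-condition dynamics.

All functions are elementwise array-friendly so the herd engine can evaluate
them over the whole herd each day.  Energy units are Mcal, weights kg,
intakes kg dry matter (DM).

Conventions
-----------
* ``CSBW`` current shrunk body weight; ``EBW`` empty body weight; ``EQSBW``
  size-equivalent shrunk weight (scaled to a 478 kg reference); ``MSBW``
  mature shrunk weight at BCS 5.
* ``NEmD``/``NEgD`` are diet net-energy densities (Mcal/kg DM); ``NEmR`` the
  maintenance + lactation + gestation requirement; ``NEgI`` the energy
  available for gain after maintenance is met.
* Weeks postpartum ``n`` is days-postpartum / 7 rounded to the nearest
  integer week.
"""

from __future__ import annotations

import numpy as np

KCAL_SBW_PER_EBW = 0.956  # shrunk-weight change per kg empty-body change
EBW_PER_EQSBW = 0.891
EQSBW_REFERENCE = 478.0  # kg
LACTATION_K = 0.1175
KM_GESTATION = 0.576
ME_TO_NE_PREG = 0.13


def age_factor(age_years):
    """Lactation age factor: 0.74 for two-year-olds and younger, 0.88 at
    three, 1.0 for mature cows."""
    age = np.asarray(age_years)
    return np.where(age <= 2, 0.74, np.where(age == 3, 0.88, 1.0))


def lactation_yield(pl, age_years, n_weeks, k: float = LACTATION_K):
    """Daily milk yield, kg/d, for week ``n`` postpartum.

    A Wood-type curve scaled so the peak equals ``PL * AF`` exactly at
    ``n = 1/k`` weeks: ``Lact = PL * k * e * n * exp(-k n) * AF``.
    """
    pl = np.asarray(pl, dtype=float)
    n = np.asarray(n_weeks, dtype=float)
    out = pl * k * np.e * n * np.exp(-k * n) * age_factor(age_years)
    return out if out.ndim else float(out)


def weeks_postpartum(days_postpartum):
    """Days postpartum rounded to the nearest integer week."""
    return np.rint(np.asarray(days_postpartum, dtype=float) / 7.0)


def nemr(csbw, temp_c, nemlg, factor=1.0):
    """Daily NEm requirement for maintenance + lactation + gestation, Mcal.

    The temperature-adjusted maintenance coefficient is
    ``0.0007 * (20 - T) + 0.077`` per kg metabolic weight.  ``factor``
    carries the low-milk reductions (0.88 for cows with PL < 7 kg/d, 0.89
    for calves whose dam's PL < 7 kg/d).
    """
    csbw = np.asarray(csbw, dtype=float)
    coef = 0.0007 * (20.0 - np.asarray(temp_c, dtype=float)) + 0.077
    out = (coef * csbw**0.75 + np.asarray(nemlg, dtype=float)) * factor
    return out if out.ndim else float(out)


def gestation_energy(cbw, t):
    """Gestation energy at day ``t`` of gestation for a conceptus with
    (pre-drawn) actual birth weight ``cbw`` kg.

    Returns ``(NEpreg, MEpreg, NEmG)`` in Mcal: the conceptus net-energy
    deposition, its metabolizable-energy equivalent (efficiency 0.13), and
    the maintenance-equivalent charge ``km * MEpreg`` with km = 0.576.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any((t_arr < 0) | (t_arr > 310)):
        raise ValueError("gestation day must be within [0, 310]")
    cbw = np.asarray(cbw, dtype=float)
    nepreg = cbw * (0.05855 - 0.0000996 * t_arr) * np.exp(
        0.03233 * t_arr - 0.0000275 * t_arr**2
    ) / 1000.0
    mepreg = nepreg / ME_TO_NE_PREG
    nemg = KM_GESTATION * mepreg
    if np.ndim(t) or np.ndim(cbw):
        return nepreg, mepreg, nemg
    return float(nepreg), float(mepreg), float(nemg)


def dmi_cow(csbw, nemd, lact, t):
    """Daily DMI (kg) for cows two years old and older.

    ``t`` is the day of gestation; early gestation (and lactating open
    cows, by convention t = 0) uses the 0.0384 intercept, late gestation and
    dry open cows the 0.04631 intercept.  Milk adds 0.2 kg DMI per kg.
    """
    csbw = np.asarray(csbw, dtype=float)
    nemd = np.asarray(nemd, dtype=float)
    coef = np.where(np.asarray(t, dtype=float) <= 93.0, 0.0384, 0.04631)
    nema = np.where(nemd >= 1.0, nemd, 0.95)
    out = csbw**0.75 * (coef + 0.04997 * nemd**2) / nema + 0.2 * np.asarray(lact, dtype=float)
    return out if out.ndim else float(out)


def dmi_pct_young(nemd, cap_pct: float = 1.0):
    """DMI as a fraction of CSBW for weaned animals under two years."""
    nemd = np.asarray(nemd, dtype=float)
    pct = (1.2425 + 1.9218 * nemd - 0.7259 * nemd**2) / 100.0
    out = np.minimum(pct, cap_pct)
    return out if out.ndim else float(out)


def dmi_young(csbw, nemd, cap_pct: float = 1.0):
    """Daily DMI (kg) for weaned animals under two years."""
    out = dmi_pct_young(nemd, cap_pct) * np.asarray(csbw, dtype=float)
    return out if out.ndim else float(out)


def neg_intake(dmi, nemd, negd, nemr_mcal):
    """NEg intake (Mcal): gain-density energy of the DMI left after the
    intake needed to meet NEmR, floored at zero."""
    dmi = np.asarray(dmi, dtype=float)
    nemd = np.asarray(nemd, dtype=float)
    out = np.maximum(
        np.asarray(negd, dtype=float)
        * (dmi - np.asarray(nemr_mcal, dtype=float) / np.maximum(nemd, 1e-9)),
        0.0,
    )
    return out if out.ndim else float(out)


def grow_young(csbw, mw, negi, ebl):
    """Daily shrunk body gain (kg/d) for growing animals (three years old and
    younger): allometric gain from NEg intake plus any empty-body loss."""
    csbw = np.asarray(csbw, dtype=float)
    eqsbw = (EQSBW_REFERENCE / np.asarray(mw, dtype=float)) * csbw
    ebw = EBW_PER_EQSBW * eqsbw
    negi = np.maximum(np.asarray(negi, dtype=float), 0.0)
    gain = 12.341 * ebw**-0.6837 * negi**0.9116
    out = gain + np.asarray(ebl, dtype=float) / KCAL_SBW_PER_EBW
    return out if out.ndim else float(out)


def energy_balance_loss(nemi, nemr_mcal, mcal_per_kg_loss):
    """Empty-body loss (kg, <= 0) on maintenance-deficit days."""
    nemi = np.asarray(nemi, dtype=float)
    nemr_arr = np.asarray(nemr_mcal, dtype=float)
    mcal = np.asarray(mcal_per_kg_loss, dtype=float)
    if np.any(mcal <= 0):
        raise ValueError("Mcal per kg loss must be positive")
    out = np.where(nemi < nemr_arr, (nemi - nemr_arr) / mcal, 0.0)
    return out if out.ndim else float(out)


def body_fat_gain(negi, ebl, surplus):
    """Daily body-fat change (kg): a quadratic share of NEg intake on
    surplus days (floored at zero), the empty-body loss on deficit days."""
    negi = np.asarray(negi, dtype=float)
    gain = np.maximum(0.15 * negi - 0.0057 * negi**2 - 0.162, 0.0)
    out = np.where(np.asarray(surplus, dtype=bool), gain, np.asarray(ebl, dtype=float))
    return out if out.ndim else float(out)


def grow_mature(nemi, nemr_mcal, mcal_per_kg_gain, mcal_per_kg_loss):
    """Daily shrunk body gain (kg/d) for mature cows: the NEm surplus or
    deficit divided by the BCS-specific energy content of body change."""
    nemi = np.asarray(nemi, dtype=float)
    nemr_arr = np.asarray(nemr_mcal, dtype=float)
    balance = nemi - nemr_arr
    ebg = np.where(balance > 0, balance / np.asarray(mcal_per_kg_gain, dtype=float), 0.0)
    ebl = np.where(balance < 0, balance / np.asarray(mcal_per_kg_loss, dtype=float), 0.0)
    out = (ebg + ebl) / KCAL_SBW_PER_EBW
    return out if out.ndim else float(out)


def _nearest_table_bcs(values, table: dict[int, float]):
    """Round values to the nearest BCS via an ascending table of anchors."""
    keys = np.array(sorted(table))
    anchors = np.array([table[k] for k in keys])
    mids = 0.5 * (anchors[1:] + anchors[:-1])
    idx = np.searchsorted(mids, np.asarray(values, dtype=float))
    return keys[idx]


def assign_bcs(
    age_years,
    body_fat,
    csbw,
    msbw,
    fat_frac_by_bcs: dict[int, float],
    csbw_ratio_by_bcs: dict[int, float],
):
    """Daily BCS (1-9).

    Animals two years and younger score by body fat as a fraction of CSBW;
    mature cows (four and older) by CSBW relative to MSBW; three-year-olds
    take the maximum of the two methods.  Both tables anchor BCS 5 at a fat
    fraction of 0.1889 and CSBW/MSBW = 1.
    """
    age = np.asarray(age_years)
    csbw = np.asarray(csbw, dtype=float)
    fat_frac = np.asarray(body_fat, dtype=float) / np.maximum(csbw, 1e-9)
    young_bcs = _nearest_table_bcs(fat_frac, fat_frac_by_bcs)
    ratio = csbw / np.maximum(np.asarray(msbw, dtype=float), 1e-9)
    mature_bcs = _nearest_table_bcs(ratio, csbw_ratio_by_bcs)
    out = np.where(
        age <= 2, young_bcs, np.where(age >= 4, mature_bcs, np.maximum(young_bcs, mature_bcs))
    )
    return out if out.ndim else int(out)


def calf_forage_intake(
    age_days,
    csbw,
    milk_today,
    forage_nemd,
    cap_pct: float = 0.026,
    milk_only_age: int = 50,
    full_intake_age: int = 140,
    milk_substitution: float = 0.12,
):
    """Default pre-weaning forage DMI (kg) for a nursing calf.

    Forage is withheld through ``milk_only_age`` days; afterwards the
    young-animal DMI-percent form is ramped in linearly to full by
    ``full_intake_age`` days, and the day's actual milk supply substitutes
    for forage at ``milk_substitution`` kg DM per kg milk.  Using the actual
    (declining) daily milk rather than a static peak raises late-season
    forage intake.  This component is pluggable on the herd engine.
    """
    age = np.asarray(age_days, dtype=float)
    potential = dmi_young(csbw, forage_nemd, cap_pct)
    ramp = np.clip((age - milk_only_age) / max(full_intake_age - milk_only_age, 1), 0.0, 1.0)
    forage = np.maximum(
        potential * ramp - milk_substitution * np.asarray(milk_today, dtype=float), 0.0
    )
    out = np.where(age <= milk_only_age, 0.0, forage)
    return out if out.ndim else float(out)


def calf_daily_intake(
    age_days,
    csbw,
    milk_today,
    forage_nemd,
    cap_pct: float = 0.026,
    milk_only_age: int = 50,
    forage_fn=None,
):
    """Daily (milk kg, forage kg DM) for a nursing calf.

    Milk supply is the dam's daily production; forage comes from the
    pluggable ``forage_fn`` (default :func:`calf_forage_intake`).
    """
    if forage_fn is None:
        forage_fn = calf_forage_intake
    milk = np.asarray(milk_today, dtype=float)
    forage = forage_fn(age_days, csbw, milk, forage_nemd, cap_pct, milk_only_age)
    if np.ndim(age_days) or np.ndim(milk_today):
        return milk, forage
    return float(milk), float(forage)
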