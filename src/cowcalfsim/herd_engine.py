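"""Daily time-step herd orchestration and management decision rules.

One simulated herd targets 100 females exposed for breeding each May 1 -
Jul 3, with pregnancy diagnosis 60 d after the season, a single herd-wide
weaning date (the day the oldest calf turns 220 d), culling at the later of
weaning and pregnancy diagnosis (opens, all 13-yr-olds, voluntary minima
per age group), oldest-first replacement-heifer retention topped up by
purchases, and May 1 - Oct 31 grazing with forage-budget removal.  Animal
state lives in flat numpy arrays (struct-of-arrays) so each daily sub-step
is one vectorized pass over the herd.

Daily sub-step order (fixed): nutrition and ration -> growth and BCS ->
reproduction events -> health events -> calendar-driven management.  The
first burn-in production years are dropped from reported output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cowcalfsim import genetics, nutrition, reproduction
from cowcalfsim.config_environment import (
    EnvironmentCalendar,
    GrazingLedger,
    HerdConfig,
    acreage_allocation,
    default_config,
    forage_production,
    generate_synthetic_weather,
    lookup_age_table,
    update_grazing_ledger,
)
from cowcalfsim.health import daily_calf_health, daily_female_mortality, draw_risk_profile
from cowcalfsim.ration import grazing_supplement_policy, solve_ration_batch

LB_PER_KG = 2.205

#: Scenario grids for sire mature-weight (kg) and peak-lactation (kg/d)
#: genetic potential.
MW_GRID = (454.0, 499.0, 544.0, 590.0, 635.0, 680.0, 726.0, 771.0)
PL_GRID = (6.8, 9.0, 11.3, 13.6)

# fixed 365-day calendar with real month boundaries
MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MONTH_STARTS = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)])
MONTH_OF_DOY = np.repeat(np.arange(1, 13), MONTH_LENGTHS)
DAYS_PER_YEAR = 365

ROLE_CALF, ROLE_HEIFER, ROLE_COW = 0, 1, 2
_NEVER = -(10**6)


def doy_of(month: int, day: int) -> int:
    """Zero-based day-of-year of a (month, day) date."""
    return int(_MONTH_STARTS[month - 1] + day - 1)


@dataclass
class ScenarioSpec:
    """One genetic scenario: sire mature-weight and peak-lactation GP."""

    sire_mw_gp: float = 590.0
    sire_pl_gp: float = 11.3
    years: int = 24
    iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sire_mw_gp <= 0 or self.sire_pl_gp <= 0:
            raise ValueError("sire genetic potentials must be positive")


class Herd:
    """Struct-of-arrays animal state with amortized growth."""

    _FLOAT = (
        "mw", "pl", "ww_lb", "bwgp_lb", "csbw", "fat", "next_estrus", "gest",
        "ccbw", "cmw", "cpl", "cww", "cbwgp", "abw", "badg", "baww",
        "estrus_draw", "dam_pl", "ww_adj_lb", "bw_adj_lb", "wwgp_sexed",
        "bwgp_sexed",
    )
    _INT = ("birth", "dam", "conc", "calved", "calf", "wean", "dam_birth")
    _SMALL = ("role", "bcs")
    _BOOL = (
        "alive", "female", "exposed", "cycling", "pregnant", "ever_preg",
        "cfem", "diag", "aborted_season", "lact", "dyst", "morbid", "tocull",
    )
    _COUNTER = ("parity", "cohort")

    def __init__(self, capacity: int = 1024):
        self.n = 0
        self._cap = capacity
        for name in self._FLOAT:
            setattr(self, name, np.zeros(capacity))
        for name in self._INT:
            setattr(self, name, np.full(capacity, _NEVER, dtype=np.int64))
        for name in self._SMALL:
            setattr(self, name, np.zeros(capacity, dtype=np.int8))
        for name in self._BOOL:
            setattr(self, name, np.zeros(capacity, dtype=bool))
        for name in self._COUNTER:
            setattr(self, name, np.zeros(capacity, dtype=np.int16))
        self.next_estrus[:] = np.inf

    def add(self, count: int) -> np.ndarray:
        while self.n + count > self._cap:
            self._cap *= 2
            for name in self._FLOAT + self._INT + self._SMALL + self._BOOL + self._COUNTER:
                old = getattr(self, name)
                new = np.zeros(self._cap, dtype=old.dtype)
                if name in self._INT:
                    new[:] = _NEVER
                elif name == "next_estrus":
                    new[:] = np.inf
                new[: self.n] = old[: self.n]
                setattr(self, name, new)
        idx = np.arange(self.n, self.n + count)
        self.n += count
        self.next_estrus[idx] = np.inf
        self.calf[idx] = -1
        self.dam[idx] = -1
        self.wean[idx] = -1
        self.bcs[idx] = 5
        return idx

    def age_days(self, abs_day: int, idx) -> np.ndarray:
        return abs_day - self.birth[idx]

    def age_years(self, abs_day: int, idx) -> np.ndarray:
        return (abs_day - self.birth[idx]) // DAYS_PER_YEAR


@dataclass
class _CohortStats:
    """One breeding-season cohort (exposure year)."""

    exposed: int = 0
    pregnant_at_diag: int = 0
    lost_post_diag: int = 0
    diag_day: int = 10**9


@dataclass
class _CropStats:
    """One spring calf crop (birth year)."""

    born: int = 0
    deaths: int = 0
    abw_sum: float = 0.0
    first_birth: int = 10**9
    wean_abs: int = -1
    finalized: bool = False
    weaned: bool = False
    culled: bool = False
    mage: float = np.nan
    madg: float = np.nan
    mcage: float = np.nan
    total_weaned_kg: float = 0.0
    n_weaned: int = 0


@dataclass
class _Accumulators:
    cohorts: dict = field(default_factory=dict)
    crops: dict = field(default_factory=dict)
    individual: list = field(default_factory=list)
    herd_year: list = field(default_factory=list)
    events: list = field(default_factory=list)


class _Iteration:
    """State and daily logic for one simulation iteration."""

    def __init__(
        self,
        cfg: HerdConfig,
        env: EnvironmentCalendar,
        rng: np.random.Generator,
        years: int,
        calf_forage_fn=None,
    ):
        self.cfg = cfg
        self.env = env
        self.rng = rng
        self.years = years
        self.calf_forage_fn = calf_forage_fn or nutrition.calf_forage_intake
        self.profile = draw_risk_profile(cfg.health, rng)
        self.dyst_risks = reproduction.draw_dystocia_risks(
            rng, cfg.dystocia_risk_base, cfg.dystocia_risk_primiparous_heavy
        )
        self.acc = _Accumulators()
        self.herd = Herd(2048)
        self.grazing_on = False
        self.ledger: GrazingLedger | None = None
        self.prior_pct_remaining = cfg.initial_pct_remaining
        self.losses_counter = 0  # breeding-female losses since last reset
        self.expected_losses = 5  # last observed off-season losses
        ww_base = genetics.sire_ww_gp_base(cfg.sire_mw_gp)
        self._sire_ww = {}
        self._sire_bw = {}
        for year in range(env.start_year - 1, env.start_year + years + 2):
            self._sire_ww[year] = genetics.sire_ww_gp(year, ww_base, cfg.ww_ebv_by_year)
            self._sire_bw[year] = genetics.sire_bw_gp(
                year, ww_base, cfg.bw_ebv_by_year, cfg.ww_ebv_1992_lb
            )
        self._loss_tbl = np.array([cfg.mcal_per_kg_loss_by_bcs[b] for b in range(1, 10)])
        self._gain_tbl = np.array([cfg.mcal_per_kg_gain_by_bcs[b] for b in range(1, 10)])
        self._doy_season_start = doy_of(*cfg.breeding_start)
        self._doy_season_end = doy_of(*cfg.breeding_end)
        self._doy_graze_end = doy_of(*cfg.grazing_end)
        self._diag_doy = self._doy_season_end + cfg.preg_check_lag
        self._init_herd()

    # ------------------------------------------------------------------
    def _founder_gps(self, count: int):
        """Trait draws for founder-type females: both parents carry the
        average GP of the configured founder-parent birth-year window."""
        cfg, rng = self.cfg, self.rng
        window_year = cfg.founder_parent_years[1] + 2  # 4-yr EBV window ends there
        mw = rng.normal(cfg.sire_mw_gp, cfg.mw_gp_sd, count)
        pl = np.maximum(rng.normal(cfg.sire_pl_gp, cfg.pl_gp_sd, count), 0.5)
        ww = rng.normal(self._sire_ww[window_year], cfg.ww_gp_sd_lb, count)
        bw = rng.normal(self._sire_bw[window_year], cfg.bw_gp_sd_lb, count)
        if count >= 3:
            pl = genetics.enforce_correlation(mw, pl, cfg.corr_mw_pl)
            ww = genetics.enforce_correlation(mw, ww, cfg.corr_mw_ww)
            bw = genetics.enforce_correlation(ww, bw, cfg.corr_ww_bw)
        return mw, pl, ww, bw

    def _init_herd(self) -> None:
        cfg, rng, h = self.cfg, self.rng, self.herd
        n_cows = cfg.target_exposed
        ages = np.arange(2, cfg.max_cow_age + 1)
        weights = 0.865 ** (ages - 2)
        counts = np.floor(weights / weights.sum() * n_cows).astype(int)
        counts[0] += n_cows - counts.sum()
        cow_ages = np.repeat(ages, counts)
        idx = h.add(n_cows)
        h.alive[idx] = True
        h.female[idx] = True
        h.role[idx] = ROLE_COW
        calving_doy = 59 + rng.integers(-15, 31, n_cows)  # around Mar 1
        h.birth[idx] = -(cow_ages * DAYS_PER_YEAR) + calving_doy
        mw, pl, ww, bw = self._founder_gps(n_cows)
        h.mw[idx], h.pl[idx], h.ww_lb[idx], h.bwgp_lb[idx] = mw, pl, ww, bw
        h.csbw[idx] = mw
        h.fat[idx] = 0.1889 * mw
        h.parity[idx] = (cow_ages - 1).astype(np.int16)
        # founders enter mid-gestation from last year's breeding season
        conc_off = self._sample_conception_offsets(n_cows)
        h.pregnant[idx] = True
        h.ever_preg[idx] = True
        h.diag[idx] = True
        h.exposed[idx] = True
        h.cohort[idx] = np.int16(-1)
        h.conc[idx] = -DAYS_PER_YEAR + self._doy_season_start + conc_off
        h.gest[idx] = reproduction.draw_gestation_length(
            rng, n_cows, cfg.gestation_mean, cfg.gestation_sd, cfg.gestation_bounds
        )
        self._draw_conceptus(idx, birth_year=self.env.start_year)
        self.acc.cohorts[self.env.start_year - 1] = _CohortStats(
            exposed=n_cows, pregnant_at_diag=n_cows, diag_day=_NEVER
        )

    def _sample_conception_offsets(self, count: int) -> np.ndarray:
        """Day-of-season conception offsets: uniform first estrus over one
        cycle plus geometric retries at the per-estrus conception rate."""
        cfg, rng = self.cfg, self.rng
        season = self._doy_season_end - self._doy_season_start
        first = rng.uniform(0, 21, count)
        retries = rng.geometric(max(cfg.conception_prob_per_estrus, 0.05), count) - 1
        off = first + 21 * retries
        resample = off > season
        off[resample] = rng.uniform(0, season, int(resample.sum()))
        return off.astype(np.int64)

    # ------------------------------------------------------------------
    def _draw_conceptus(self, idx: np.ndarray, birth_year: int) -> None:
        """Draw conceptus genetics and birth phenotype for pregnant females
        ``idx`` whose calves are born in ``birth_year``, then enforce the
        trait-correlation targets across the conception cohort."""
        cfg, rng, h = self.cfg, self.rng, self.herd
        n = idx.size
        if n == 0:
            return
        cmw = np.atleast_1d(genetics.sample_progeny_gp(cfg.sire_mw_gp, h.mw[idx], cfg.mw_gp_sd, rng))
        cpl = np.maximum(
            np.atleast_1d(genetics.sample_progeny_gp(cfg.sire_pl_gp, h.pl[idx], cfg.pl_gp_sd, rng)),
            0.5,
        )
        cww = np.atleast_1d(
            genetics.sample_progeny_gp(self._sire_ww[birth_year], h.ww_lb[idx], cfg.ww_gp_sd_lb, rng)
        )
        cbw = np.atleast_1d(
            genetics.sample_progeny_gp(self._sire_bw[birth_year], h.bwgp_lb[idx], cfg.bw_gp_sd_lb, rng)
        )
        gest = h.gest[idx]
        if n >= 3:
            cpl = genetics.enforce_correlation(cmw, cpl, cfg.corr_mw_pl)
            cww = genetics.enforce_correlation(cmw, cww, cfg.corr_mw_ww)
            cbw = genetics.enforce_correlation(cww, cbw, cfg.corr_ww_bw)
            gest = np.clip(
                genetics.enforce_correlation(cbw, gest, cfg.corr_bw_gestation),
                *cfg.gestation_bounds,
            )
        female = rng.random(n) < 0.5
        dam_age_at_calving = (h.conc[idx] + gest.astype(np.int64) - h.birth[idx]) // DAYS_PER_YEAR
        bw_adj = lookup_age_table(cfg.bw_dam_age_adj_lb, dam_age_at_calving)
        abw = genetics.phenotypic_birth_weight(
            cbw, bw_adj, female, rng, cfg.bw_phenotype_sd_lb, cfg.female_bw_factor
        )
        h.cmw[idx], h.cpl[idx], h.cww[idx], h.cbwgp[idx] = cmw, cpl, cww, cbw
        h.gest[idx] = gest
        h.cfem[idx] = female
        h.ccbw[idx] = np.atleast_1d(abw)

    # ------------------------------------------------------------------
    # daily sub-steps
    def _nutrition_growth(self, abs_day: int, year_idx: int, doy: int) -> None:
        cfg, h = self.cfg, self.herd
        month = MONTH_OF_DOY[doy]
        temp = self.env.temp_c[year_idx, month - 1]
        adults = np.nonzero(h.alive[: h.n] & (h.role[: h.n] != ROLE_CALF))[0]
        calves = np.nonzero(h.alive[: h.n] & (h.role[: h.n] == ROLE_CALF))[0]
        herd_forage = 0.0
        lact = np.zeros(adults.size)
        if adults.size:
            age_yr = h.age_years(abs_day, adults)

            lmask = h.lact[adults]
            if lmask.any():
                li = adults[lmask]
                n_wk = nutrition.weeks_postpartum(abs_day - h.calved[li])
                lact[lmask] = nutrition.lactation_yield(h.pl[li], h.age_years(abs_day, li), n_wk)

            nemg = np.zeros(adults.size)
            pmask = h.pregnant[adults]
            if pmask.any():
                pi = adults[pmask]
                t = np.clip((abs_day - h.conc[pi]).astype(float), 0.0, 310.0)
                cbw = np.where(h.ccbw[pi] > 0, h.ccbw[pi], 37.0)
                nemg[pmask] = nutrition.gestation_energy(cbw, t)[2]

            nemlg = 0.72 * lact + nemg
            factor = np.where(h.pl[adults] < cfg.low_milk_threshold, cfg.cow_low_milk_factor, 1.0)
            nemr = nutrition.nemr(h.csbw[adults], temp, nemlg, factor)
            t_dmi = np.where(
                h.pregnant[adults],
                (abs_day - h.conc[adults]).astype(float),
                np.where(h.lact[adults], 0.0, 200.0),
            )
            young = age_yr < 2
            bcs_idx = np.clip(h.bcs[adults], 1, 9) - 1
            # condition-recovery allowance: thin mature cows are fed toward
            # BCS 5, not merely held at maintenance
            regain = np.where(
                (age_yr >= 4) & (h.bcs[adults] < cfg.bcs_target),
                cfg.bcs_regain_kg_per_day * nutrition.KCAL_SBW_PER_EBW * self._gain_tbl[bcs_idx],
                0.0,
            )

            if self.grazing_on:
                nem_d = self.env.forage_nem[year_idx, month - 1]
                neg_d = self.env.forage_neg[year_idx, month - 1]
                dmi = np.where(
                    young,
                    nutrition.dmi_young(h.csbw[adults], nem_d, cfg.dmi_pct_cap),
                    nutrition.dmi_cow(h.csbw[adults], nem_d, lact, t_dmi),
                )
                suppl = grazing_supplement_policy(
                    h.bcs[adults], nemr + regain, dmi, nem_d, dmi, cfg.supplement_diet,
                    cfg.grazing_supplement_dmi_cap,
                )
                forage = dmi - suppl
                intake = dmi
                nemi = forage * nem_d + suppl * cfg.supplement_diet.nem_density
                neg_pool = forage * neg_d + suppl * cfg.supplement_diet.neg_density
                herd_forage += float(forage.sum())
            else:
                nem_b = cfg.base_diet.nem_density
                neg_b = cfg.base_diet.neg_density
                dmi = np.where(
                    young,
                    nutrition.dmi_young(h.csbw[adults], nem_b, cfg.dmi_pct_cap),
                    nutrition.dmi_cow(h.csbw[adults], nem_b, lact, t_dmi),
                )
                base_need = nemr / nem_b
                growing = age_yr <= 3
                # growing stock fed ad libitum; mature cows fed to requirement
                intake = np.where(growing, dmi, np.minimum(base_need, dmi))
                restricted = h.bcs[adults] > cfg.bcs_target + 1
                intake = np.where(
                    restricted, cfg.overcondition_intake_restriction * base_need, intake
                )
                nemi = intake * nem_b
                neg_pool = intake * neg_b
                lp = (h.bcs[adults] < cfg.bcs_target) & (nemi < nemr + regain) & ~restricted
                if lp.any():
                    x, y_s, _, _ = solve_ration_batch(
                        (nemr + regain)[lp], np.zeros(int(lp.sum())), dmi[lp],
                        dmi[lp] / h.csbw[adults][lp], h.csbw[adults][lp],
                        cfg.available_base_kg, cfg.base_diet, cfg.supplement_diet,
                    )
                    intake[lp] = x + y_s
                    nemi[lp] = x * nem_b + y_s * cfg.supplement_diet.nem_density
                    neg_pool[lp] = x * neg_b + y_s * cfg.supplement_diet.neg_density

            safe_intake = np.maximum(intake, 1e-9)
            negi = nutrition.neg_intake(safe_intake, nemi / safe_intake, neg_pool / safe_intake, nemr)
            ebl = nutrition.energy_balance_loss(nemi, nemr, self._loss_tbl[bcs_idx])
            mature = age_yr >= 4
            sbg = np.where(
                mature,
                nutrition.grow_mature(nemi, nemr, self._gain_tbl[bcs_idx], self._loss_tbl[bcs_idx]),
                nutrition.grow_young(h.csbw[adults], h.mw[adults], negi, ebl),
            )
            fat_chg = nutrition.body_fat_gain(negi, ebl, nemi > nemr)
            h.csbw[adults] = np.maximum(h.csbw[adults] + sbg, 30.0)
            h.fat[adults] = np.clip(
                h.fat[adults] + np.where(mature, 0.0, fat_chg), 0.0, 0.45 * h.csbw[adults]
            )
            h.bcs[adults] = nutrition.assign_bcs(
                age_yr, h.fat[adults], h.csbw[adults], h.mw[adults],
                cfg.fat_frac_by_bcs, cfg.csbw_ratio_by_bcs,
            ).astype(np.int8)

        if calves.size:
            age_c = h.age_days(abs_day, calves)
            milk = np.zeros(calves.size)
            if adults.size:
                dam = h.dam[calves]
                pos = np.searchsorted(adults, dam)
                pos_c = np.minimum(pos, adults.size - 1)
                ok = (dam >= 0) & (adults[pos_c] == dam)
                milk[ok] = lact[pos_c[ok]]
            if self.grazing_on:
                cnem = self.env.forage_nem[year_idx, month - 1]
                cneg = self.env.forage_neg[year_idx, month - 1]
            else:
                cnem = cfg.supplement_diet.nem_density
                cneg = cfg.supplement_diet.neg_density
            forage_c = self.calf_forage_fn(
                age_c, h.csbw[calves], milk, cnem, cfg.dmi_pct_cap, cfg.milk_only_age
            )
            nemr_c = nutrition.nemr(
                h.csbw[calves], temp, 0.0,
                np.where(h.dam_pl[calves] < cfg.low_milk_threshold, cfg.calf_low_milk_factor, 1.0),
            )
            nemi_c = milk * cfg.milk_nem_mcal_kg + forage_c * cnem
            neg_c = milk * cfg.milk_neg_mcal_kg + forage_c * cneg
            intake_c = np.maximum(milk + forage_c, 1e-9)
            negi_c = nutrition.neg_intake(intake_c, nemi_c / intake_c, neg_c / intake_c, nemr_c)
            bcs_c = np.clip(h.bcs[calves], 1, 9) - 1
            ebl_c = nutrition.energy_balance_loss(nemi_c, nemr_c, self._loss_tbl[bcs_c])
            sbg_c = nutrition.grow_young(h.csbw[calves], h.mw[calves], negi_c, ebl_c)
            capped = (age_c >= cfg.calf_growth_cap_age) & (h.wean[calves] >= 0)
            if capped.any():
                wa = (h.wean[calves] - h.birth[calves]).astype(float)
                cap = np.maximum(
                    (h.baww[calves] - h.csbw[calves]) / np.maximum(wa - age_c, 1.0), 0.0
                )
                sbg_c = np.where(capped, np.minimum(sbg_c, cap), sbg_c)
            new_w = h.csbw[calves] + sbg_c
            new_w = np.where(capped, np.minimum(new_w, h.baww[calves]), new_w)
            h.csbw[calves] = np.maximum(new_w, 0.5 * h.abw[calves])
            h.fat[calves] = np.clip(
                h.fat[calves] + nutrition.body_fat_gain(negi_c, ebl_c, nemi_c > nemr_c),
                0.0, 0.45 * h.csbw[calves],
            )
            herd_forage += float(forage_c.sum())

        if self.grazing_on and self.ledger is not None:
            if update_grazing_ledger(self.ledger, herd_forage):
                self._end_grazing()

    # ------------------------------------------------------------------
    def _reproduction(self, abs_day: int, year: int, doy: int) -> None:
        cfg, rng, h = self.cfg, self.rng, self.herd
        in_season = self._doy_season_start <= doy <= self._doy_season_end

        # heifer puberty: later of the drawn age and the 40%-of-MW day
        heif = np.nonzero(
            h.alive[: h.n] & (h.role[: h.n] == ROLE_HEIFER)
            & ~h.cycling[: h.n] & ~h.pregnant[: h.n]
        )[0]
        if heif.size:
            ready = (abs_day >= h.estrus_draw[heif]) & (
                h.csbw[heif] >= cfg.puberty_weight_fraction * h.mw[heif]
            )
            start = heif[ready]
            h.cycling[start] = True
            h.next_estrus[start] = abs_day

        # estrus events
        est = np.nonzero(
            h.alive[: h.n] & h.cycling[: h.n] & ~h.pregnant[: h.n]
            & (h.next_estrus[: h.n] <= abs_day)
        )[0]
        if est.size:
            if in_season:
                conceive = h.exposed[est] & reproduction.attempt_conception(
                    cfg.conception_prob_per_estrus, rng, est.size
                )
            else:
                conceive = np.zeros(est.size, dtype=bool)
            ci = est[conceive]
            if ci.size:
                h.pregnant[ci] = True
                h.ever_preg[ci] = True
                h.cycling[ci] = False
                h.conc[ci] = abs_day
                h.cohort[ci] = np.int16(year - self.env.start_year)
                h.gest[ci] = reproduction.draw_gestation_length(
                    rng, ci.size, cfg.gestation_mean, cfg.gestation_sd, cfg.gestation_bounds
                )
                h.ccbw[ci] = 0.0
            miss = est[~conceive]
            if miss.size:
                h.next_estrus[miss] = reproduction.next_estrus(
                    abs_day, rng, cfg.estrus_interval, miss.size
                )

        # daily abortion
        preg = np.nonzero(h.alive[: h.n] & h.pregnant[: h.n])[0]
        if preg.size:
            ab = preg[reproduction.daily_abortion(cfg.daily_abortion_hazard, rng, preg.size)]
            for i in ab:
                h.pregnant[i] = False
                cohort_year = self.env.start_year + int(h.cohort[i])
                stats = self.acc.cohorts.get(cohort_year)
                if h.diag[i] and stats is not None and abs_day > stats.diag_day:
                    stats.lost_post_diag += 1
                    # a post-cull-date abortion culls the female that day
                    h.alive[i] = False
                    self.losses_counter += 1
                    self._orphan(i)
                elif in_season and h.exposed[i] and not h.aborted_season[i]:
                    h.aborted_season[i] = True
                    h.cycling[i] = True
                    h.next_estrus[i] = reproduction.next_estrus(abs_day, rng, cfg.estrus_interval)
                h.diag[i] = False

        # calving
        due = np.nonzero(
            h.alive[: h.n] & h.pregnant[: h.n]
            & ((abs_day - h.conc[: h.n]) >= h.gest[: h.n])
        )[0]
        if due.size:
            self._calve(due, abs_day, year)

    def _calve(self, dams: np.ndarray, abs_day: int, year: int) -> None:
        cfg, rng, h = self.cfg, self.rng, self.herd
        n = dams.size
        primiparous = h.parity[dams] == 0
        dyst = np.atleast_1d(
            reproduction.assign_dystocia(
                primiparous, h.ccbw[dams] * LB_PER_KG, self.dyst_risks, rng,
                cfg.dystocia_heavy_bw_lb,
            )
        )
        dam_age = h.age_years(abs_day, dams)
        idx = h.add(n)
        h.alive[idx] = True
        h.role[idx] = ROLE_CALF
        h.birth[idx] = abs_day
        h.dam[idx] = dams
        h.dam_birth[idx] = h.birth[dams]
        h.dam_pl[idx] = h.pl[dams]
        h.female[idx] = h.cfem[dams]
        h.mw[idx] = h.cmw[dams]
        h.pl[idx] = h.cpl[dams]
        h.ww_lb[idx] = h.cww[dams]
        h.bwgp_lb[idx] = h.cbwgp[dams]
        h.wwgp_sexed[idx] = np.where(
            h.cfem[dams], cfg.female_ww_factor * h.cww[dams], h.cww[dams]
        )
        h.bwgp_sexed[idx] = np.where(
            h.cfem[dams], cfg.female_bw_factor * h.cbwgp[dams], h.cbwgp[dams]
        )
        h.ww_adj_lb[idx] = lookup_age_table(cfg.ww_dam_age_adj_lb, dam_age)
        h.bw_adj_lb[idx] = lookup_age_table(cfg.bw_dam_age_adj_lb, dam_age)
        h.abw[idx] = h.ccbw[dams]
        h.csbw[idx] = h.ccbw[dams]
        h.fat[idx] = 0.12 * h.ccbw[dams]
        h.bcs[idx] = 4
        h.dyst[idx] = dyst
        # dam state updates
        h.pregnant[dams] = False
        h.diag[dams] = False
        h.lact[dams] = True
        h.calved[dams] = abs_day
        h.calf[dams] = idx
        h.parity[dams] += 1
        h.role[dams] = ROLE_COW
        for k, dam in enumerate(dams):
            ppi = reproduction.draw_ppi(
                int(h.parity[dam]), int(h.bcs[dam]), bool(dyst[k]), cfg.ppi_pert, rng,
                cfg.dystocia_ppi_addon,
            )
            h.cycling[dam] = True
            h.next_estrus[dam] = abs_day + ppi
        crop = self.acc.crops.setdefault(year, _CropStats())
        crop.born += n
        crop.abw_sum += float(h.ccbw[dams].sum())
        crop.first_birth = min(crop.first_birth, abs_day)

    # ------------------------------------------------------------------
    def _health(self, abs_day: int, year: int, doy: int) -> None:
        h, rng = self.herd, self.rng
        calves = np.nonzero(h.alive[: h.n] & (h.role[: h.n] == ROLE_CALF))[0]
        if calves.size:
            new_morbid, dead = daily_calf_health(
                h.age_days(abs_day, calves), h.dyst[calves], h.morbid[calves], self.profile, rng
            )
            h.morbid[calves] |= new_morbid
            di = calves[dead]
            if di.size:
                h.alive[di] = False
                crop = self.acc.crops.setdefault(year, _CropStats())
                crop.deaths += int(di.size)
                dams = h.dam[di]
                dams = dams[dams >= 0]
                dams = dams[h.alive[dams]]
                h.lact[dams] = False
                h.calf[dams] = -1
                # a dam losing her calf before the breeding season is culled
                if doy < self._doy_season_start:
                    h.alive[dams] = False
                    self.losses_counter += int(dams.size)

        females = np.nonzero(h.alive[: h.n] & (h.role[: h.n] != ROLE_CALF))[0]
        if females.size:
            breeding = h.ever_preg[females] | (h.parity[females] > 0)
            dead = daily_female_mortality(breeding, self.profile, rng)
            di = females[dead]
            for i in di:
                if h.diag[i] and h.pregnant[i]:
                    cohort_year = self.env.start_year + int(h.cohort[i])
                    stats = self.acc.cohorts.get(cohort_year)
                    if stats is not None and abs_day > stats.diag_day:
                        stats.lost_post_diag += 1
                self._orphan(i)
                h.alive[i] = False
                if breeding[np.searchsorted(females, i)]:
                    self.losses_counter += 1

    def _orphan(self, dam_idx: int) -> None:
        calf = int(self.herd.calf[dam_idx])
        if calf >= 0:
            self.herd.dam[calf] = -1
            self.herd.calf[dam_idx] = -1

    # ------------------------------------------------------------------
    def _management(self, abs_day: int, year: int, year_idx: int, doy: int) -> None:
        h = self.herd
        if doy == self._doy_season_start:
            self._expose(abs_day, year)
            self._start_grazing(year, year_idx)
        if doy == self._doy_season_end + 1:
            cohort = np.nonzero(
                h.alive[: h.n] & h.pregnant[: h.n]
                & (h.cohort[: h.n] == year - self.env.start_year)
            )[0]
            self._draw_conceptus(cohort, birth_year=year + 1)
        if doy == self._diag_doy:
            self._diagnose(abs_day, year)
        if doy == self._doy_graze_end and self.grazing_on:
            self._end_grazing()

        crop = self.acc.crops.get(year)
        if crop is None:
            return
        if not crop.finalized and crop.born > 0 and doy < 200:
            prev_cohort = year - 1 - self.env.start_year
            still_preg = (
                h.alive[: h.n] & h.pregnant[: h.n] & (h.cohort[: h.n] == prev_cohort)
            ).any()
            if not still_preg:
                self._finalize_crop(crop)
        if crop.finalized and not crop.weaned and abs_day == crop.wean_abs:
            self._wean(abs_day, year, crop)
        diag_abs = year_idx * DAYS_PER_YEAR + self._diag_doy
        if crop.weaned and not crop.culled and abs_day >= max(crop.wean_abs, diag_abs):
            self._cull_and_replace(abs_day, year, crop)

    def _expose(self, abs_day: int, year: int) -> None:
        cfg, h, rng = self.cfg, self.herd, self.rng
        h.exposed[: h.n] = False
        h.aborted_season[: h.n] = False
        alive = h.alive[: h.n]
        cows = np.nonzero(
            alive & ((h.role[: h.n] == ROLE_COW) | (h.role[: h.n] == ROLE_HEIFER) & h.pregnant[: h.n])
        )[0]
        heifers = np.nonzero(
            alive & (h.role[: h.n] == ROLE_HEIFER) & ~h.pregnant[: h.n]
            & (h.age_days(abs_day, slice(0, h.n)) >= 330)
        )[0]
        h.exposed[cows] = True
        need = cfg.target_exposed - cows.size
        if heifers.size:
            order = heifers[np.argsort(-h.age_days(abs_day, heifers))]
            chosen = order[: max(need, 0)]
            h.exposed[chosen] = True
            h.alive[order[max(need, 0):]] = False  # surplus open heifers sold
            need -= chosen.size
        if need > 0:
            self._purchase_heifers(need, abs_day)
        exposed_n = int(h.exposed[: h.n].sum())
        self.acc.cohorts[year] = _CohortStats(exposed=exposed_n)
        self.acc.events.append((year, "exposed", exposed_n))
        self.expected_losses = self.losses_counter
        self.losses_counter = 0

    def _purchase_heifers(self, count: int, abs_day: int) -> None:
        """Open replacement heifers bought in, traits matching the raised
        heifer population."""
        cfg, h, rng = self.cfg, self.herd, self.rng
        idx = h.add(count)
        h.alive[idx] = True
        h.female[idx] = True
        h.role[idx] = ROLE_HEIFER
        h.exposed[idx] = True
        h.birth[idx] = abs_day - 430
        mw, pl, ww, bw = self._founder_gps(count)
        h.mw[idx], h.pl[idx], h.ww_lb[idx], h.bwgp_lb[idx] = mw, pl, ww, bw
        h.csbw[idx] = 0.55 * mw
        h.fat[idx] = 0.17 * h.csbw[idx]
        h.cycling[idx] = True
        h.next_estrus[idx] = abs_day + rng.uniform(0, 21, count)
        h.estrus_draw[idx] = h.birth[idx] + cfg.first_estrus_mean
        self.acc.events.append((self.env.start_year + abs_day // DAYS_PER_YEAR,
                                "purchased_heifers", count))

    def _start_grazing(self, year: int, year_idx: int) -> None:
        cfg, h = self.cfg, self.herd
        production = forage_production(
            self.env.jan_aug_precip(year), self.prior_pct_remaining, cfg.forage_coefficients
        )
        alive = h.alive[: h.n]
        cows = alive & (h.role[: h.n] == ROLE_COW)
        heifers = alive & (h.role[: h.n] == ROLE_HEIFER)
        mean_mw = float(h.mw[: h.n][cows].mean()) if cows.any() else cfg.sire_mw_gp
        acres = cows.sum() * acreage_allocation(mean_mw, "pair") + heifers.sum() * (
            acreage_allocation(mean_mw, "yearling")
        )
        self.ledger = GrazingLedger(
            production_per_acre=production,
            acres=float(max(acres, 1.0)),
            waste_fraction=cfg.forage_waste_fraction,
            removal_threshold=cfg.forage_removal_threshold,
        )
        self.grazing_on = True

    def _end_grazing(self) -> None:
        self.grazing_on = False
        if self.ledger is not None:
            self.prior_pct_remaining = self.ledger.pct_remaining

    def _diagnose(self, abs_day: int, year: int) -> None:
        cfg, h = self.cfg, self.herd
        stats = self.acc.cohorts.setdefault(year, _CohortStats())
        stats.diag_day = abs_day
        alive = h.alive[: h.n]
        exposed = alive & h.exposed[: h.n]
        pregnant = exposed & h.pregnant[: h.n]
        stats.pregnant_at_diag = int(pregnant.sum())
        h.diag[: h.n] = pregnant
        h.tocull[: h.n] |= exposed & ~h.pregnant[: h.n]  # opens
        h.tocull[: h.n] |= alive & (h.role[: h.n] == ROLE_COW) & (
            h.age_years(abs_day, slice(0, h.n)) >= cfg.max_cow_age
        )

    def _finalize_crop(self, crop: _CropStats) -> None:
        """Fix the herd-wide weaning date (oldest calf at 220 d) and each
        calf's growth plan toward its base weaning-weight potential."""
        cfg, h = self.cfg, self.herd
        crop.finalized = True
        crop.wean_abs = crop.first_birth + cfg.weaning_trigger_age
        calves = np.nonzero(h.alive[: h.n] & (h.role[: h.n] == ROLE_CALF))[0]
        if calves.size == 0:
            return
        h.wean[calves] = crop.wean_abs
        weaning_age = (crop.wean_abs - h.birth[calves]).astype(float)
        badg, baww = genetics.badg_baww(
            h.wwgp_sexed[calves], h.bwgp_sexed[calves], h.ww_adj_lb[calves],
            h.bw_adj_lb[calves], h.abw[calves], weaning_age,
        )
        h.badg[calves] = badg
        h.baww[calves] = np.maximum(baww, h.abw[calves])

    def _wean(self, abs_day: int, year: int, crop: _CropStats) -> None:
        """Herd-wide weaning: records for every calf, steers sold, heifer
        calves held until the cull date's retention decision."""
        from cowcalfsim.summaries import adjusted_205d_ww

        cfg, h = self.cfg, self.herd
        crop.weaned = True
        calves = np.nonzero(
            h.alive[: h.n] & (h.role[: h.n] == ROLE_CALF) & (h.wean[: h.n] == abs_day)
        )[0]
        if calves.size == 0:
            return
        wage = h.age_days(abs_day, calves).astype(float)
        ww = h.csbw[calves]
        abw = h.abw[calves]
        adjww = adjusted_205d_ww(abw, ww, wage, h.ww_adj_lb[calves] / LB_PER_KG)
        cage = (abs_day - h.dam_birth[calves]) / DAYS_PER_YEAR
        for k in range(calves.size):
            self.acc.individual.append(
                (year, float(abw[k]), float(wage[k]), float(ww[k]),
                 float((ww[k] - abw[k]) / wage[k]), float(adjww[k]), float(cage[k]))
            )
        crop.mage = float(wage.mean())
        crop.madg = float(((ww - abw) / wage).mean())
        crop.mcage = float(((abs_day - h.dam_birth[calves]) // DAYS_PER_YEAR).mean())
        crop.total_weaned_kg = float(ww.sum())
        crop.n_weaned = int(calves.size)
        # steer calves sold at weaning; heifer calves become weaned heifers
        # pending the retention decision on the cull date
        steers = calves[~h.female[calves]]
        h.alive[steers] = False
        heifer_calves = calves[h.female[calves]]
        h.role[heifer_calves] = ROLE_HEIFER
        h.lact[: h.n] = False
        h.calf[: h.n] = -1

    def _cull_and_replace(self, abs_day: int, year: int, crop: _CropStats) -> None:
        cfg, h, rng = self.cfg, self.herd, self.rng
        crop.culled = True
        alive = h.alive[: h.n]

        # open exposed heifers flagged at diagnosis
        open_heifers = np.nonzero(
            alive & (h.role[: h.n] == ROLE_HEIFER) & h.tocull[: h.n]
        )[0]
        h.alive[open_heifers] = False

        cows = np.nonzero(alive & (h.role[: h.n] == ROLE_COW))[0]
        cull = h.tocull[cows].copy()
        ages = h.age_years(abs_day, cows)
        for age, frac in cfg.min_cull_fraction_by_age.items():
            grp = ages == age
            n_grp = int(grp.sum())
            if n_grp == 0:
                continue
            shortfall = int(np.rint(n_grp * frac)) - int(cull[grp].sum())
            if shortfall > 0:
                candidates = np.nonzero(grp & ~cull)[0]
                if candidates.size:
                    pick = rng.choice(candidates, min(shortfall, candidates.size), replace=False)
                    cull[pick] = True
        culled = cows[cull]
        h.alive[culled] = False
        for i in culled:
            self._orphan(i)
        h.tocull[: h.n] = False

        # heifer retention: replace culls plus last off-season's losses,
        # oldest weaned heifer calves first
        need = int(culled.size) + int(open_heifers.size) + self.expected_losses
        crop_heifers = np.nonzero(
            h.alive[: h.n] & (h.role[: h.n] == ROLE_HEIFER)
            & (h.age_days(abs_day, slice(0, h.n)) < 330)
        )[0]
        order = crop_heifers[np.argsort(h.birth[crop_heifers])]
        retained = order[:need]
        h.alive[order[need:]] = False  # surplus heifer calves sold
        h.estrus_draw[retained] = h.birth[retained] + rng.normal(
            cfg.first_estrus_mean, cfg.first_estrus_sd, retained.size
        )
        self.acc.events.append((year, "culled", int(culled.size) + int(open_heifers.size)))
        self.acc.events.append((year, "retained_heifers", int(retained.size)))

        # herd-year summary
        cohort_prev = self.acc.cohorts.get(year - 1, _CohortStats(exposed=cfg.target_exposed))
        cohort_now = self.acc.cohorts.get(year, _CohortStats())
        self.acc.herd_year.append(
            {
                "year": year,
                "exposed": cohort_now.exposed,
                "pregperc": 100.0 * cohort_now.pregnant_at_diag / max(cohort_now.exposed, 1),
                "preglp": 100.0 * cohort_prev.lost_post_diag / max(cohort_prev.exposed, 1),
                "calfl2": 100.0 * crop.deaths / max(crop.born, 1),
                "mage": crop.mage,
                "madg": crop.madg,
                "mbrtwt": crop.abw_sum / max(crop.born, 1),
                "mcage": crop.mcage,
                "kg_weaned_per_exposed": crop.total_weaned_kg / max(cohort_prev.exposed, 1),
                "n_weaned": crop.n_weaned,
            }
        )

    # ------------------------------------------------------------------
    def step_day(self, abs_day: int) -> None:
        year_idx, doy = divmod(abs_day, DAYS_PER_YEAR)
        if year_idx < 0 or year_idx >= min(self.years, self.env.n_years):
            return
        year = self.env.start_year + year_idx
        self._nutrition_growth(abs_day, year_idx, doy)
        self._reproduction(abs_day, year, doy)
        self._health(abs_day, year, doy)
        self._management(abs_day, year, year_idx, doy)

    def run(self) -> None:
        for abs_day in range(min(self.years, self.env.n_years) * DAYS_PER_YEAR):
            self.step_day(abs_day)


def run_iteration(
    cfg: HerdConfig,
    env: EnvironmentCalendar,
    seed_seq,
    years: int,
    calf_forage_fn=None,
) -> _Accumulators:
    """Run one iteration and return its raw accumulators."""
    rng = np.random.default_rng(seed_seq)
    it = _Iteration(cfg, env, rng, years, calf_forage_fn)
    it.run()
    return it.acc


def run_scenario(
    spec: ScenarioSpec,
    config: HerdConfig | None = None,
    env: EnvironmentCalendar | None = None,
    iterations: int | None = None,
    keep_burn_in: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one genetic scenario.

    Returns ``(individual, herd_year)`` DataFrames.  Individual rows are
    per-weaned-calf records (ABW, WAGE, WW, pre-weaning ADG, ADJ WW, CAGE);
    herd-year rows carry the SPA-style summary variables (MAGE, MADG,
    MBRTWT, MCAGE, PREGPERC, PREGLP, CALFL2, kg weaned per cow exposed).
    Burn-in production years are dropped unless ``keep_burn_in``.
    Deterministic per (seed, spec, config).
    """
    cfg = config if config is not None else default_config()
    cfg = dataclasses.replace(cfg, sire_mw_gp=spec.sire_mw_gp, sire_pl_gp=spec.sire_pl_gp)
    years = spec.years
    if env is None:
        env = generate_synthetic_weather(years, seed=(spec.seed ^ 0x5EED) % (2**31))
    n_iter = iterations if iterations is not None else spec.iterations
    children = np.random.SeedSequence(spec.seed).spawn(n_iter)
    ind_rows, herd_rows = [], []
    for it_num, child in enumerate(children):
        acc = run_iteration(cfg, env, child, years)
        for row in acc.individual:
            ind_rows.append((spec.sire_mw_gp, spec.sire_pl_gp, it_num) + row)
        for row in acc.herd_year:
            herd_rows.append(
                {"sire_mw": spec.sire_mw_gp, "sire_pl": spec.sire_pl_gp, "iteration": it_num}
                | row
            )
    individual = pd.DataFrame(
        ind_rows,
        columns=[
            "sire_mw", "sire_pl", "iteration", "year", "abw_kg", "wage_d", "ww_kg",
            "adg_kg_d", "adjww_kg", "cage_yr",
        ],
    )
    herd_year = pd.DataFrame(herd_rows)
    if not keep_burn_in:
        first_reported = env.start_year + cfg.burn_in_years
        if len(individual):
            individual = individual[individual["year"] >= first_reported].reset_index(drop=True)
        if len(herd_year):
            herd_year = herd_year[herd_year["year"] >= first_reported].reset_index(drop=True)
    return individual, herd_year
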