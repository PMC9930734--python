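"""SPA-style individual and herd-year output tables.

Individual records follow beef-industry Standardized Performance Analysis
conventions: actual birth weight (ABW), weaning age (WAGE), pre-weaning
ADG, BIF 205-d adjusted weaning weight (ADJ WW), cow age (CAGE) and a
mature-weight class rounded to the simulated scenario grid.  Herd-year
summaries carry the mean birth weight (MBRTWT), mean weaning age (MAGE),
mean pre-weaning ADG (MADG), mean cow age (MCAGE), percent pregnant per
cow exposed (PREGPERC), percent pregnancy loss per cow exposed (PREGLP)
and percent calf mortality per calf born (CALFL2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REFERENCE_WEANING_DAYS = 205


def adjusted_205d_ww(abw, ww, wage, dam_age_adj_kg=0.0):
    """BIF 205-d adjusted weaning weight (kg).

    ``ABW + (WW - ABW) / WAGE * 205`` plus the additive dam-age adjustment.
    Array-friendly.
    """
    wage_arr = np.asarray(wage, dtype=float)
    if np.any(wage_arr <= 0):
        raise ValueError("weaning age must be positive")
    abw_arr = np.asarray(abw, dtype=float)
    out = (
        abw_arr
        + (np.asarray(ww, dtype=float) - abw_arr) / wage_arr * REFERENCE_WEANING_DAYS
        + np.asarray(dam_age_adj_kg, dtype=float)
    )
    return out if out.ndim else float(out)


def classify_mw(cow_weight, grid) -> float | np.ndarray:
    """Round a mature-weight proxy (kg) to the nearest scenario MW class;
    exact midpoints go to the lower class."""
    grid_arr = np.sort(np.asarray(grid, dtype=float))
    if grid_arr.size == 0:
        raise ValueError("grid must be non-empty")
    w = np.asarray(cow_weight, dtype=float)
    mids = 0.5 * (grid_arr[1:] + grid_arr[:-1])
    idx = np.searchsorted(mids, w, side="left")  # ties go down
    out = grid_arr[idx]
    return out if out.ndim else float(out)


def herd_year_summary(records: pd.DataFrame, exposed: int, pregnancies_lost: int = 0,
                      pregnant_at_diag: int | None = None) -> dict:
    """SPA herd-year summary from a frame of weaned-calf records.

    ``records`` needs columns abw_kg, ww_kg, wage_d, cage_yr and (for
    CALFL2) born/died counts are taken from optional attrs; this helper is
    the small-data path — full simulations assemble the same fields inside
    the herd engine.
    """
    if exposed <= 0:
        raise ValueError("herd-year undefined without exposed females")
    born = int(records.attrs.get("born", len(records)))
    deaths = int(records.attrs.get("calf_deaths", 0))
    pregnant = pregnant_at_diag if pregnant_at_diag is not None else len(records)
    adg = (records["ww_kg"] - records["abw_kg"]) / records["wage_d"]
    return {
        "exposed": exposed,
        "pregperc": 100.0 * pregnant / exposed,
        "preglp": 100.0 * pregnancies_lost / exposed,
        "calfl2": 100.0 * deaths / max(born, 1),
        "mage": float(records["wage_d"].mean()),
        "madg": float(adg.mean()),
        "mbrtwt": float(records["abw_kg"].mean()),
        "mcage": float(np.floor(records["cage_yr"]).mean()),
        "kg_weaned_per_exposed": float(records["ww_kg"].sum()) / exposed,
        "n_weaned": len(records),
    }


def build_validation_samples(
    individual: pd.DataFrame,
    herd_year: pd.DataFrame,
    rng: np.random.Generator,
    n_individual: int = 5025,
    n_herd: int = 422,
    mature_cage: float = 4.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random validation samples mirroring the field-data filters.

    Individual records keep only calves out of mature cows (CAGE >= 4);
    herd-year records pool all scenarios.  Samples are drawn without
    replacement where possible; short tables are returned whole.
    """
    pool = individual[individual["cage_yr"] >= mature_cage]
    n_i = min(n_individual, len(pool))
    ind_sample = pool.iloc[rng.choice(len(pool), n_i, replace=False)].reset_index(drop=True)
    n_h = min(n_herd, len(herd_year))
    herd_sample = herd_year.iloc[rng.choice(len(herd_year), n_h, replace=False)].reset_index(
        drop=True
    )
    return ind_sample, herd_sample
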