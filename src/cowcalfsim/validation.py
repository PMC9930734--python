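"""Desk-scale validation runs: the pooled scenario grid and the
repeated-iteration weaned-output trial.

These assemble the simulator's outputs the way the model-validation
exercise does: one seeded iteration of each of the 32 MW x PL genetic
scenarios pooled over production years 2000-2017, sampled down to 422
herd-year and 5,025 individual records; and repeated iterations of the
590 kg MW / 11.3 kg/d PL scenario for the final-year kg-weaned-per-cow-
exposed summary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cowcalfsim.config_environment import HerdConfig, generate_synthetic_weather
from cowcalfsim.herd_engine import MW_GRID, PL_GRID, ScenarioSpec, run_scenario
from cowcalfsim.summaries import build_validation_samples

FIRST_REPORTED_YEAR = 2000
LAST_POOLED_YEAR = 2017


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % (2**31 - 1)


def run_validation_grid(
    seed: int,
    years: int = 24,
    config: HerdConfig | None = None,
    iterations_per_scenario: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One seeded iteration of every MW x PL scenario, pooled.

    Returns ``(individual, herd_year)`` frames restricted to production
    years 2000-2017.  All scenarios share one synthetic weather series, as
    a single region's history would be shared by real herds.
    """
    env = generate_synthetic_weather(years, seed=_sub_seed(seed, 0))
    ind_frames, hy_frames = [], []
    k = 1
    for mw in MW_GRID:
        for pl in PL_GRID:
            spec = ScenarioSpec(
                mw, pl, years=years, iterations=iterations_per_scenario,
                seed=_sub_seed(seed, k),
            )
            ind, hy = run_scenario(spec, config=config, env=env)
            ind_frames.append(ind)
            hy_frames.append(hy)
            k += 1
    individual = pd.concat(ind_frames, ignore_index=True)
    herd_year = pd.concat(hy_frames, ignore_index=True)
    individual = individual[individual["year"].between(FIRST_REPORTED_YEAR, LAST_POOLED_YEAR)]
    herd_year = herd_year[herd_year["year"].between(FIRST_REPORTED_YEAR, LAST_POOLED_YEAR)]
    return individual.reset_index(drop=True), herd_year.reset_index(drop=True)


def pooled_medians(
    individual: pd.DataFrame,
    herd_year: pd.DataFrame,
    seed: int,
    n_individual: int = 5025,
    n_herd: int = 422,
) -> dict[str, float]:
    """Medians of the sampled validation tables (the HERD MOD / IND MOD
    style summaries)."""
    rng = np.random.default_rng(_sub_seed(seed, 999))
    ind_sample, herd_sample = build_validation_samples(
        individual, herd_year, rng, n_individual=n_individual, n_herd=n_herd
    )
    return {
        "mage_d": float(herd_sample["mage"].median()),
        "mcage_yr": float(herd_sample["mcage"].median()),
        "pregperc": float(herd_sample["pregperc"].median()),
        "preglp": float(herd_sample["preglp"].median()),
        "calfl2": float(herd_sample["calfl2"].median()),
        "abw_kg": float(ind_sample["abw_kg"].median()),
        "adjww_kg": float(ind_sample["adjww_kg"].median()),
        "n_individual": len(ind_sample),
        "n_herd": len(herd_sample),
    }


def kg_weaned_trial(
    seed: int,
    iterations: int = 10,
    years: int = 24,
    sire_mw: float = 590.0,
    sire_pl: float = 11.3,
    config: HerdConfig | None = None,
) -> tuple[float, int]:
    """Mean kg of calf weaned per cow exposed in the final simulated year
    of the reference scenario, across repeated iterations."""
    spec = ScenarioSpec(sire_mw, sire_pl, years=years, iterations=iterations,
                        seed=_sub_seed(seed, 77))
    _, hy = run_scenario(spec)
    final_year = 1995 + years - 1
    final = hy[hy["year"] == final_year]
    return float(final["kg_weaned_per_exposed"].mean()), len(final)
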