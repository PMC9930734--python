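"""Daily binary morbidity and mortality outcomes.

A single :class:`HealthRiskProfile` is drawn per simulation iteration:
every hazard is one truncated-normal draw (bounded below at zero) that then
applies uniformly to all animals in its category for the whole iteration.
Calf mortality has eight cells — (neonatal <= 3 d vs older) x (dystocia at
birth) x (prior morbidity) — calf morbidity four, and female mortality two
(post-weaning replacement vs breeding herd).  A calf can be morbid at most
once; morbidity's only effect is to move the calf to the higher mortality
cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cowcalfsim.config_environment import HealthHazardConfig
from cowcalfsim.reproduction import truncated_normal

NEONATAL_MAX_AGE = 3  # d


@dataclass
class HealthRiskProfile:
    """Daily hazards for one simulation iteration."""

    calf_morbidity: dict[str, float]
    calf_mortality: dict[str, float]
    female_mortality: dict[str, float]

    def morbidity_array(self) -> np.ndarray:
        """Morbidity hazards indexed by 2*is_post + dystocia."""
        m = self.calf_morbidity
        return np.array(
            [m["neonatal"], m["neonatal_dystocia"], m["post"], m["post_dystocia"]]
        )

    def mortality_array(self) -> np.ndarray:
        """Mortality hazards indexed by 4*is_post + 2*dystocia + morbid."""
        m = self.calf_mortality
        return np.array(
            [
                m["neonatal"],
                m["neonatal_morbid"],
                m["neonatal_dystocia"],
                m["neonatal_dystocia_morbid"],
                m["post"],
                m["post_morbid"],
                m["post_dystocia"],
                m["post_dystocia_morbid"],
            ]
        )


def draw_risk_profile(config: HealthHazardConfig, rng: np.random.Generator) -> HealthRiskProfile:
    """One truncated-normal hazard draw per category (lower bound zero)."""

    def draw(table: dict[str, tuple[float, float]]) -> dict[str, float]:
        return {
            key: float(min(truncated_normal(mean, sd, lower=0.0, rng=rng), 1.0))
            for key, (mean, sd) in table.items()
        }

    return HealthRiskProfile(
        calf_morbidity=draw(config.calf_morbidity),
        calf_mortality=draw(config.calf_mortality),
        female_mortality=draw(config.female_mortality),
    )


def daily_calf_health(
    age_days,
    dystocia,
    morbid_ever,
    profile: HealthRiskProfile,
    rng: np.random.Generator,
):
    """Daily (new morbidity, death) flags for pre-weaning calves.

    Morbidity can strike only calves never previously morbid; mortality is
    drawn from the (age class, dystocia, morbidity-including-today) cell.
    Array-friendly.
    """
    age = np.asarray(age_days)
    dystocia = np.asarray(dystocia, dtype=bool)
    morbid_ever = np.asarray(morbid_ever, dtype=bool)
    is_post = (age > NEONATAL_MAX_AGE).astype(np.intp)

    morb_p = profile.morbidity_array()[2 * is_post + dystocia.astype(np.intp)]
    new_morbid = (rng.random(age.shape) < morb_p) & ~morbid_ever

    morbid_now = morbid_ever | new_morbid
    cell = 4 * is_post + 2 * dystocia.astype(np.intp) + morbid_now.astype(np.intp)
    dead = rng.random(age.shape) < profile.mortality_array()[cell]
    if np.ndim(age_days):
        return new_morbid, dead
    return bool(new_morbid), bool(dead)


def daily_female_mortality(
    in_breeding_herd,
    profile: HealthRiskProfile,
    rng: np.random.Generator,
):
    """Daily death flags for replacement heifers (pre-first-pregnancy) and
    breeding-herd females.  Array-friendly."""
    breeding = np.asarray(in_breeding_herd, dtype=bool)
    hazard = np.where(
        breeding,
        profile.female_mortality["breeding"],
        profile.female_mortality["replacement"],
    )
    out = rng.random(breeding.shape) < hazard
    return out if out.ndim else bool(out)
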