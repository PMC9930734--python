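"""Puberty, postpartum interval, estrous cycling, conception, gestation,
abortion and dystocia.

Biological intervals come from bounded stochastic draws: beta-PERT for the
postpartum interval (parity x BCS cells, with a truncated-normal dystocia
add-on), truncated normals for estrous-cycle length and gestation, and
Bernoulli daily hazards for conception per estrus and abortion.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

PERT_LAMBDA = 4.0


def truncated_normal(
    mean: float,
    sd: float,
    lower: float = -np.inf,
    upper: float = np.inf,
    rng: np.random.Generator | None = None,
    size=None,
):
    """Truncated-normal draws; degenerate SD returns the (clipped) mean."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        value = float(np.clip(mean, lower, upper))
        return value if size is None else np.full(size, value)
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def beta_pert(
    minimum: float,
    mode: float,
    maximum: float,
    rng: np.random.Generator,
    size=None,
    lamb: float = PERT_LAMBDA,
):
    """Beta-PERT draws on [minimum, maximum] with the given mode."""
    if not (minimum <= mode <= maximum):
        raise ValueError("need minimum <= mode <= maximum")
    span = maximum - minimum
    if span == 0:
        return minimum if size is None else np.full(size, float(minimum))
    alpha = 1.0 + lamb * (mode - minimum) / span
    beta = 1.0 + lamb * (maximum - mode) / span
    return minimum + span * rng.beta(alpha, beta, size=size)


def first_estrus_age(
    normal_draw_day: float,
    puberty_weight_day: float,
) -> float:
    """Age (d) at first estrus for a replacement heifer: the later of the
    drawn physiological age and the day she reaches the puberty weight
    threshold (40% of mature weight)."""
    return max(normal_draw_day, puberty_weight_day)


def bcs_class(bcs) -> np.ndarray:
    """Map BCS to the PPI table classes low (<=4) / moderate (5) / high (>=6)."""
    bcs = np.asarray(bcs)
    return np.where(bcs <= 4, "low", np.where(bcs == 5, "moderate", "high"))


def draw_ppi(
    parity: int,
    bcs: int,
    dystocia: bool,
    ppi_pert: dict[str, tuple[float, float, float]],
    rng: np.random.Generator,
    dystocia_addon: tuple[float, float] = (10.0, 3.0),
) -> float:
    """Postpartum interval (d) from the (parity class, BCS class) PERT cell,
    plus a non-negative truncated-normal extension after dystocia."""
    parity_class = "primiparous" if parity <= 1 else "multiparous"
    key = f"{parity_class}_{bcs_class(bcs)}"
    try:
        lo, mode, hi = ppi_pert[key]
    except KeyError:
        raise KeyError(f"no PPI PERT cell for {key}") from None
    ppi = float(beta_pert(lo, mode, hi, rng))
    if dystocia:
        mean, sd = dystocia_addon
        ppi += float(truncated_normal(mean, sd, lower=0.0, rng=rng))
    return ppi


def next_estrus(
    current_day: float,
    rng: np.random.Generator,
    interval: tuple[float, float, float, float] = (21.0, 0.75, 18.0, 24.0),
    size=None,
):
    """Day of the next estrus: current day plus a truncated-normal cycle
    length (mean 21 d, bounded to [18, 24])."""
    mean, sd, lower, upper = interval
    return current_day + truncated_normal(mean, sd, lower, upper, rng=rng, size=size)


def attempt_conception(p: float, rng: np.random.Generator, size=None):
    """Bernoulli conception at one in-season estrus."""
    if size is None:
        return bool(rng.random() < p)
    return rng.random(size) < p


def daily_abortion(hazard: float, rng: np.random.Generator, size=None):
    """Bernoulli daily abortion event for a pregnant female."""
    if size is None:
        return bool(rng.random() < hazard)
    return rng.random(size) < hazard


def draw_gestation_length(
    rng: np.random.Generator,
    size=None,
    mean: float = 285.0,
    sd: float = 5.0,
    bounds: tuple[float, float] = (260.0, 310.0),
):
    """Preliminary gestation length draws, N(285, 5) truncated to bounds;
    the herd engine subsequently enforces the +0.30 correlation with calf
    birth weight within each conception cohort."""
    return truncated_normal(mean, sd, bounds[0], bounds[1], rng=rng, size=size)


def draw_dystocia_risks(
    rng: np.random.Generator,
    base: tuple[float, float] = (0.05, 0.01),
    primiparous_heavy: tuple[float, float] = (0.08, 0.01),
) -> tuple[float, float]:
    """Herd-level dystocia probabilities for one simulation iteration:
    (multiparous or light-calf primiparous, heavy-calf primiparous), each a
    truncated-normal draw bounded below at zero."""
    p_base = float(truncated_normal(base[0], base[1], lower=0.0, rng=rng))
    p_heavy = float(
        truncated_normal(primiparous_heavy[0], primiparous_heavy[1], lower=0.0, rng=rng)
    )
    return min(p_base, 1.0), min(p_heavy, 1.0)


def assign_dystocia(
    primiparous,
    calf_bw_lb,
    risks: tuple[float, float],
    rng: np.random.Generator,
    heavy_bw_lb: float = 90.0,
):
    """Per-calving dystocia flags: heavy-calf primiparous dams carry the
    elevated risk, everyone else the base risk.  Array-friendly."""
    primiparous = np.asarray(primiparous, dtype=bool)
    heavy = np.asarray(calf_bw_lb, dtype=float) >= heavy_bw_lb
    p = np.where(primiparous & heavy, risks[1], risks[0])
    out = rng.random(p.shape) < p
    return out if out.ndim else bool(out)
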