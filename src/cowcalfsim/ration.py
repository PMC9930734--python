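"""Least-cost ration formulation and the surrounding feeding-policy rules.

The drylot ration is a two-feed blend (an alfalfa-based base diet and a
higher-energy alfalfa/corn supplement) chosen to minimize daily feed cost
subject to net-energy and intake constraints:

    minimize   x * BRP + y * SRP
    subject to x*NEgBR + y*NEgSR >= NEgR + NEgBR * NEmR / NEmBR
               x*NEgBR + y*NEgSR >= NEgR + NEgSR * NEmR / NEmSR
               x*NEmBR + y*NEmSR >= NEmR
               x + y >= DMI_PCT * CSBW
               x + y <= DMI
               x <= Available BR
               x, y >= 0

with x/y the base/supplement intake (kg DM).  When the program is
infeasible the supplement replaces 40% of the base ration.

Two solver paths are provided: :func:`solve_ration` wraps
``scipy.optimize.linprog`` (HiGHS) for single problems, and
:func:`solve_ration_batch` enumerates constraint-boundary intersections of
the two-variable program across many problems at once; the herd engine uses
the batch path in its daily loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

FALLBACK_SUPPLEMENT_SHARE = 0.40


@dataclass(frozen=True)
class DietSpec:
    """A feed with net-energy densities (Mcal/kg DM), digestible energy
    (Mcal/kg) and price (currency/kg DM)."""

    name: str
    nem_density: float
    neg_density: float
    de: float
    price: float

    def __post_init__(self) -> None:
        if self.nem_density < 0 or self.neg_density < 0:
            raise ValueError("energy densities must be non-negative")
        if self.neg_density > self.nem_density:
            raise ValueError("NEg density cannot exceed NEm density")


@dataclass
class RationProblem:
    """One animal-day's ration formulation inputs."""

    nemr: float  # Mcal
    negr: float  # Mcal
    dmi: float  # kg DM, upper intake bound
    dmi_pct: float  # fraction of CSBW, lower intake bound via cstr 4
    csbw: float  # kg
    available_base: float  # kg
    base: DietSpec
    supplement: DietSpec

    def __post_init__(self) -> None:
        for name in ("nemr", "negr", "dmi", "dmi_pct", "csbw", "available_base"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class RationSolution:
    x: float  # kg base diet
    y: float  # kg supplement diet
    cost: float
    status: str  # "optimal" or "fallback"


def _constraint_rows(problem: RationProblem):
    """All constraints as rows of A x <= b (x = [base, supplement])."""
    b_, s_ = problem.base, problem.supplement
    g1 = problem.negr + b_.neg_density * problem.nemr / b_.nem_density
    g2 = problem.negr + s_.neg_density * problem.nemr / s_.nem_density
    min_intake = problem.dmi_pct * problem.csbw
    a = np.array(
        [
            [-b_.neg_density, -s_.neg_density],
            [-b_.neg_density, -s_.neg_density],
            [-b_.nem_density, -s_.nem_density],
            [-1.0, -1.0],
            [1.0, 1.0],
            [1.0, 0.0],
            [-1.0, 0.0],
            [0.0, -1.0],
        ]
    )
    ub = np.array(
        [-g1, -g2, -problem.nemr, -min_intake, problem.dmi, problem.available_base, 0.0, 0.0]
    )
    return a, ub


def _fallback(problem: RationProblem) -> RationSolution:
    base_ration = problem.dmi  # what the animal would otherwise eat as base diet
    x = (1.0 - FALLBACK_SUPPLEMENT_SHARE) * base_ration
    y = FALLBACK_SUPPLEMENT_SHARE * base_ration
    cost = x * problem.base.price + y * problem.supplement.price
    return RationSolution(x=x, y=y, cost=cost, status="fallback")


def solve_ration(problem: RationProblem) -> RationSolution:
    """Solve one ration LP; on infeasibility return the 60/40 fallback mix."""
    a, ub = _constraint_rows(problem)
    res = linprog(
        c=[problem.base.price, problem.supplement.price],
        A_ub=a,
        b_ub=ub,
        bounds=[(0, None), (0, None)],
        method="highs",
    )
    if not res.success:
        return _fallback(problem)
    x, y = res.x
    return RationSolution(x=float(x), y=float(y), cost=float(res.fun), status="optimal")


def solve_ration_batch(
    nemr: np.ndarray,
    negr: np.ndarray,
    dmi: np.ndarray,
    dmi_pct: np.ndarray,
    csbw: np.ndarray,
    available_base: np.ndarray | float,
    base: DietSpec,
    supplement: DietSpec,
    tol: float = 1e-9,
):
    """Vectorized exact solver for the two-variable ration LP.

    Enumerates all pairwise intersections of constraint boundaries, keeps the
    feasible ones and picks the cheapest.  Returns ``(x, y, cost, fallback)``
    arrays; infeasible problems carry the 60/40 fallback mix with
    ``fallback = True``.
    """
    nemr, negr, dmi, dmi_pct, csbw = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (nemr, negr, dmi, dmi_pct, csbw))
    )
    avail = np.broadcast_to(np.asarray(available_base, dtype=float), nemr.shape)
    n = nemr.shape[0] if nemr.ndim else 1

    g1 = negr + base.neg_density * nemr / base.nem_density
    g2 = negr + supplement.neg_density * nemr / supplement.nem_density
    min_intake = dmi_pct * csbw

    # rows of A x <= b; coefficient rows are problem-independent here
    a_rows = np.array(
        [
            [-base.neg_density, -supplement.neg_density],
            [-base.nem_density, -supplement.nem_density],
            [-1.0, -1.0],
            [1.0, 1.0],
            [1.0, 0.0],
            [-1.0, 0.0],
            [0.0, -1.0],
        ]
    )  # (7, 2)
    b_rows = np.stack(
        [
            -np.maximum(g1, g2),
            -nemr,
            -min_intake,
            dmi,
            avail,
            np.zeros_like(dmi),
            np.zeros_like(dmi),
        ],
        axis=0,
    )  # (7, n)

    m = a_rows.shape[0]
    ii, jj = np.triu_indices(m, k=1)
    a1, a2 = a_rows[ii], a_rows[jj]  # (p, 2)
    det = a1[:, 0] * a2[:, 1] - a1[:, 1] * a2[:, 0]  # (p,)
    nonpar = np.abs(det) > 1e-12
    b1, b2 = b_rows[ii], b_rows[jj]  # (p, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        vx = (b1 * a2[:, 1][:, None] - b2 * a1[:, 1][:, None]) / det[:, None]
        vy = (b2 * a1[:, 0][:, None] - b1 * a2[:, 0][:, None]) / det[:, None]
    vx = np.where(nonpar[:, None], vx, np.nan)
    vy = np.where(nonpar[:, None], vy, np.nan)

    # feasibility of each candidate vertex against every constraint
    lhs = a_rows[:, 0][None, :, None] * vx[:, None, :] + a_rows[:, 1][None, :, None] * vy[:, None, :]
    feas = np.all(lhs <= b_rows[None, :, :] + tol, axis=1)  # (p, n)
    feas &= np.isfinite(vx) & np.isfinite(vy)

    cost = base.price * vx + supplement.price * vy
    cost = np.where(feas, cost, np.inf)
    best = np.argmin(cost, axis=0)
    idx = np.arange(vx.shape[1])
    x = vx[best, idx]
    y = vy[best, idx]
    c = cost[best, idx]
    fallback = ~np.isfinite(c)
    x = np.where(fallback, (1.0 - FALLBACK_SUPPLEMENT_SHARE) * dmi, np.maximum(x, 0.0))
    y = np.where(fallback, FALLBACK_SUPPLEMENT_SHARE * dmi, np.maximum(y, 0.0))
    c = np.where(fallback, base.price * x + supplement.price * y, c)
    return x, y, c, fallback


def grazing_supplement_policy(
    bcs,
    nemr,
    forage_dmi,
    forage_nem,
    dmi,
    supplement: DietSpec,
    cap_fraction: float = 0.20,
):
    """Supplement (kg DM) offered to a grazing female.

    Only animals below BCS 5 with a negative energy balance on forage alone
    are supplemented.  Supplement substitutes for forage kg-for-kg within
    the intake envelope, so each kg closes ``NEm_suppl - NEm_forage`` Mcal of
    deficit; the offer is what closes the NEm deficit, capped at
    ``cap_fraction`` of daily DMI.  Array-friendly.
    """
    bcs, nemr, forage_dmi, forage_nem, dmi = (
        np.asarray(v, dtype=float) for v in (bcs, nemr, forage_dmi, forage_nem, dmi)
    )
    deficit = nemr - forage_dmi * forage_nem
    gain_per_kg = np.maximum(supplement.nem_density - forage_nem, 1e-9)
    need = np.clip(deficit / gain_per_kg, 0.0, None)
    offer = np.minimum(need, cap_fraction * dmi)
    eligible = (bcs < 5) & (deficit > 0)
    return np.where(eligible, offer, 0.0)


def drylot_feeding_policy(
    bcs: float,
    nemr: float,
    negr: float,
    dmi: float,
    dmi_pct: float,
    csbw: float,
    base: DietSpec,
    supplement: DietSpec,
    available_base: float = 1.0e6,
):
    """Drylot feeding decision for one animal-day.

    Returns ``("restricted", kg_base)`` for over-conditioned animals
    (BCS > 6: intake held at 70% of the base-diet amount meeting NEmR),
    ``("base", kg_base)`` when the base diet alone meets requirements within
    the intake bound, or ``("lp", RationSolution)`` for thin animals in
    negative energy balance, solved with the cost-minimizing LP.
    """
    base_for_nemr = nemr / base.nem_density
    if bcs > 6:
        return "restricted", 0.70 * base_for_nemr
    base_feed = min(base_for_nemr, dmi)
    balance = base_feed * base.nem_density - nemr
    if bcs < 5 and balance < 0:
        problem = RationProblem(
            nemr=nemr,
            negr=negr,
            dmi=dmi,
            dmi_pct=dmi_pct,
            csbw=csbw,
            available_base=available_base,
            base=base,
            supplement=supplement,
        )
        return "lp", solve_ration(problem)
    return "base", base_feed
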