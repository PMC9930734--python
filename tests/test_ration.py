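import numpy as np
import pytest

from cowcalfsim.ration import (
    DietSpec,
    RationProblem,
    drylot_feeding_policy,
    grazing_supplement_policy,
    solve_ration,
    solve_ration_batch,
)

BASE = DietSpec("base", 1.20, 0.64, 3.08, 0.13)
SUPPL = DietSpec("suppl", 1.63, 1.02, 3.08, 0.18)


def brute_force(problem: RationProblem, coarse=0.05, fine=0.002):
    """Grid-search oracle: coarse scan of (x, y), then local refinement."""

    def feasible(x, y):
        g1 = problem.negr + BASE.neg_density * problem.nemr / BASE.nem_density
        g2 = problem.negr + SUPPL.neg_density * problem.nemr / SUPPL.nem_density
        return (
            x * BASE.neg_density + y * SUPPL.neg_density >= max(g1, g2) - 1e-9
            and x * BASE.nem_density + y * SUPPL.nem_density >= problem.nemr - 1e-9
            and x + y >= problem.dmi_pct * problem.csbw - 1e-9
            and x + y <= problem.dmi + 1e-9
            and x <= problem.available_base + 1e-9
        )

    def scan(x0, x1, y0, y1, step):
        xs = np.arange(x0, x1 + step, step)
        ys = np.arange(y0, y1 + step, step)
        xx, yy = np.meshgrid(xs, ys)
        g1 = problem.negr + BASE.neg_density * problem.nemr / BASE.nem_density
        g2 = problem.negr + SUPPL.neg_density * problem.nemr / SUPPL.nem_density
        ok = (
            (xx * BASE.neg_density + yy * SUPPL.neg_density >= max(g1, g2) - 1e-9)
            & (xx * BASE.nem_density + yy * SUPPL.nem_density >= problem.nemr - 1e-9)
            & (xx + yy >= problem.dmi_pct * problem.csbw - 1e-9)
            & (xx + yy <= problem.dmi + 1e-9)
            & (xx <= problem.available_base + 1e-9)
        )
        cost = xx * BASE.price + yy * SUPPL.price
        cost = np.where(ok, cost, np.inf)
        k = np.argmin(cost)
        return xx.ravel()[k], yy.ravel()[k], cost.ravel()[k]

    hi = problem.dmi
    x, y, c = scan(0, hi, 0, hi, coarse)
    if not np.isfinite(c):
        return None
    x, y, c = scan(max(x - coarse, 0), x + coarse, max(y - coarse, 0), y + coarse, fine)
    return x, y, c


def random_problem(rng) -> RationProblem:
    csbw = rng.uniform(200, 700)
    dmi = csbw * rng.uniform(0.018, 0.028)
    return RationProblem(
        nemr=rng.uniform(0.4, 1.25) * dmi,  # spans easy to near-infeasible
        negr=rng.uniform(0.0, 1.5),
        dmi=dmi,
        dmi_pct=dmi / csbw * rng.uniform(0.7, 1.0),
        csbw=csbw,
        available_base=rng.uniform(0.3, 2.0) * dmi,
        base=BASE,
        supplement=SUPPL,
    )


class TestSolveRation:
    def test_base_alone_when_cheap_and_sufficient(self):
        p = RationProblem(6.0, 0.0, 12.0, 0.3, 20.0, 100.0, BASE, SUPPL)
        sol = solve_ration(p)
        assert sol.status == "optimal"
        assert sol.y == pytest.approx(0.0, abs=1e-8)

    def test_supplement_only_when_no_base_available(self):
        p = RationProblem(6.0, 0.0, 12.0, 0.3, 20.0, 0.0, BASE, SUPPL)
        sol = solve_ration(p)
        assert sol.status == "optimal"
        assert sol.x == pytest.approx(0.0, abs=1e-8)
        assert sol.y * SUPPL.nem_density >= 6.0 - 1e-6

    def test_fallback_is_60_40_of_dmi(self):
        # requirement impossible within the intake bound -> fallback mix
        p = RationProblem(40.0, 0.0, 10.0, 0.5, 18.0, 100.0, BASE, SUPPL)
        sol = solve_ration(p)
        assert sol.status == "fallback"
        assert sol.x == pytest.approx(6.0)
        assert sol.y == pytest.approx(4.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            RationProblem(-1.0, 0.0, 10.0, 0.5, 18.0, 100.0, BASE, SUPPL)

    def test_matches_brute_force_on_random_problems(self, rng):
        checked = 0
        for _ in range(20):
            p = random_problem(rng)
            sol = solve_ration(p)
            oracle = brute_force(p)
            if oracle is None or sol.status != "optimal":
                continue
            checked += 1
            assert sol.cost <= oracle[2] + 0.005 * max(abs(oracle[2]), 0.01)
        assert checked >= 10


class TestBatchSolver:
    def test_agrees_with_linprog_on_1000_problems(self, rng):
        problems = [random_problem(rng) for _ in range(1000)]
        x, y, cost, fb = solve_ration_batch(
            np.array([p.nemr for p in problems]),
            np.array([p.negr for p in problems]),
            np.array([p.dmi for p in problems]),
            np.array([p.dmi_pct for p in problems]),
            np.array([p.csbw for p in problems]),
            np.array([p.available_base for p in problems]),
            BASE,
            SUPPL,
        )
        n_optimal = 0
        for k, p in enumerate(problems):
            ref = solve_ration(p)
            assert fb[k] == (ref.status == "fallback")
            if ref.status == "optimal":
                n_optimal += 1
                assert cost[k] == pytest.approx(ref.cost, rel=5e-3, abs=1e-6)
        assert n_optimal > 500  # both regimes exercised

    def test_constraints_satisfied_to_tolerance(self, rng):
        problems = [random_problem(rng) for _ in range(200)]
        x, y, cost, fb = solve_ration_batch(
            np.array([p.nemr for p in problems]),
            np.array([p.negr for p in problems]),
            np.array([p.dmi for p in problems]),
            np.array([p.dmi_pct for p in problems]),
            np.array([p.csbw for p in problems]),
            np.array([p.available_base for p in problems]),
            BASE,
            SUPPL,
        )
        for k, p in enumerate(problems):
            if fb[k]:
                continue
            assert x[k] * BASE.nem_density + y[k] * SUPPL.nem_density >= p.nemr - 1e-6
            assert x[k] + y[k] <= p.dmi + 1e-6
            assert x[k] <= p.available_base + 1e-6
            assert x[k] >= -1e-9 and y[k] >= -1e-9


class TestFeedingPolicies:
    def test_no_supplement_at_bcs5(self):
        out = grazing_supplement_policy(5, 12.0, 10.0, 0.71, 10.0, SUPPL)
        assert out == 0.0

    def test_small_deficit_closed_exactly(self):
        # thin cow, deficit closable within the 20% cap
        nemr = 10.0
        forage_dmi, forage_nem, dmi = 10.0, 0.9, 10.0
        out = grazing_supplement_policy(4, nemr, forage_dmi, forage_nem, dmi, SUPPL)
        deficit = nemr - forage_dmi * forage_nem
        assert float(out) == pytest.approx(deficit / (SUPPL.nem_density - forage_nem))
        assert float(out) < 0.2 * dmi

    def test_huge_deficit_hits_cap(self):
        out = grazing_supplement_policy(3, 20.0, 9.0, 0.71, 9.0, SUPPL)
        assert float(out) == pytest.approx(0.2 * 9.0)

    def test_drylot_overconditioned_restricted(self):
        kind, amount = drylot_feeding_policy(7, 10.0, 0.0, 12.0, 0.02, 600.0, BASE, SUPPL)
        assert kind == "restricted"
        assert amount == pytest.approx(0.7 * 10.0 / BASE.nem_density)

    def test_drylot_base_only_when_adequate(self):
        kind, amount = drylot_feeding_policy(5, 10.0, 0.0, 12.0, 0.02, 600.0, BASE, SUPPL)
        assert kind == "base"
        assert amount == pytest.approx(10.0 / BASE.nem_density)

    def test_drylot_thin_negative_balance_invokes_lp(self):
        kind, sol = drylot_feeding_policy(4, 14.0, 0.0, 10.0, 10.0 / 600.0, 600.0, BASE, SUPPL)
        assert kind == "lp"
        assert sol.x * BASE.nem_density + sol.y * SUPPL.nem_density >= 14.0 - 1e-6

    def test_policy_idempotent_within_day(self):
        first = drylot_feeding_policy(4, 14.0, 0.0, 10.0, 0.02, 600.0, BASE, SUPPL)
        second = drylot_feeding_policy(4, 14.0, 0.0, 10.0, 0.02, 600.0, BASE, SUPPL)
        assert first[0] == second[0]
        assert first[1].x == second[1].x and first[1].y == second[1].y
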