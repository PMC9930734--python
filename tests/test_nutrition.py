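import numpy as np
import pytest

from cowcalfsim import nutrition as nu
import nutrition_oracle as oracle


class TestLactation:
    def test_zero_weeks_zero_yield(self):
        assert nu.lactation_yield(10.0, 5, 0.0) == 0.0

    def test_peak_equals_pl_at_one_over_k(self):
        assert nu.lactation_yield(10.0, 5, 1.0 / nu.LACTATION_K) == pytest.approx(10.0)

    def test_peak_identity_by_grid_search(self):
        weeks = np.linspace(0.1, 45, 3000)
        yields = nu.lactation_yield(11.3, 6, weeks)
        assert yields.max() == pytest.approx(11.3, abs=1e-4)
        assert weeks[np.argmax(yields)] == pytest.approx(1.0 / nu.LACTATION_K, abs=0.05)

    def test_hand_value_week4(self):
        assert nu.lactation_yield(10.0, 5, 4.0) == pytest.approx(7.985, abs=1e-3)

    @pytest.mark.parametrize("age,af", [(2, 0.74), (3, 0.88), (4, 1.0), (9, 1.0)])
    def test_age_factor_scaling(self, age, af):
        base = nu.lactation_yield(10.0, 5, 6.0)
        assert nu.lactation_yield(10.0, age, 6.0) == pytest.approx(af * base)

    def test_weeks_rounding(self):
        assert nu.weeks_postpartum(10) == 1.0
        assert nu.weeks_postpartum(11) == 2.0


class TestRequirements:
    def test_nemr_reference_values(self):
        assert nu.nemr(600.0, 20.0, 0.0) == pytest.approx(9.334, abs=1e-3)
        assert nu.nemr(600.0, 30.0, 0.0) == pytest.approx(8.486, abs=1e-3)

    def test_low_milk_reductions(self):
        base = nu.nemr(600.0, 20.0, 3.0)
        assert nu.nemr(600.0, 20.0, 3.0, factor=0.88) == pytest.approx(0.88 * base)
        assert nu.nemr(40.0, 20.0, 0.0, factor=0.89) == pytest.approx(
            0.89 * nu.nemr(40.0, 20.0, 0.0)
        )

    def test_gestation_energy_t0(self):
        nepreg, mepreg, nemg = nu.gestation_energy(36.0, 0.0)
        assert nepreg == pytest.approx(36.0 * 0.05855 / 1000.0)
        assert nemg / mepreg == pytest.approx(0.576)

    def test_gestation_ratio_constant_over_t(self):
        for t in (0.0, 100.0, 280.0):
            _, mepreg, nemg = nu.gestation_energy(36.0, t)
            assert nemg / mepreg == pytest.approx(0.576)

    def test_gestation_matches_oracle_at_term(self):
        nepreg, _, _ = nu.gestation_energy(36.0, 280.0)
        assert nepreg == pytest.approx(oracle.oracle_nepreg(36.0, 280.0), abs=1e-12)

    def test_gestation_day_out_of_range(self):
        with pytest.raises(ValueError):
            nu.gestation_energy(36.0, 311.0)


class TestIntake:
    def test_dmi_cow_hand_value(self):
        assert nu.dmi_cow(600.0, 1.2, 0.0, 200.0) == pytest.approx(11.948, abs=1e-3)

    def test_lactation_adds_point2_per_kg(self):
        dry = nu.dmi_cow(600.0, 1.2, 0.0, 200.0)
        wet = nu.dmi_cow(600.0, 1.2, 10.0, 200.0)
        assert wet - dry == pytest.approx(2.0)

    def test_low_density_denominator_floor(self):
        # NEmA = 0.95 when diet density < 1 Mcal/kg
        v = nu.dmi_cow(600.0, 0.9, 0.0, 200.0)
        expected = 600.0**0.75 * (0.04631 + 0.04997 * 0.81) / 0.95
        assert v == pytest.approx(expected)

    def test_gestation_branch(self):
        early = nu.dmi_cow(600.0, 1.2, 0.0, 93.0)
        late = nu.dmi_cow(600.0, 1.2, 0.0, 94.0)
        assert late > early

    def test_dmi_young_hand_values(self):
        assert nu.dmi_pct_young(1.2) == pytest.approx(0.025034, abs=1e-6)
        assert nu.dmi_young(300.0, 1.2, 0.03) == pytest.approx(7.51, abs=0.01)
        assert nu.dmi_young(300.0, 1.2, 0.02) == pytest.approx(6.0)  # cap binds


class TestGrowth:
    def test_no_energy_no_gain(self):
        assert nu.grow_young(300.0, 600.0, 0.0, 0.0) == 0.0

    def test_eqsbw_identity_at_reference_mw(self):
        # MW = 478 means EQSBW == CSBW
        v478 = nu.grow_young(300.0, 478.0, 3.0, 0.0)
        expected = 12.341 * (0.891 * 300.0) ** -0.6837 * 3.0**0.9116
        assert v478 == pytest.approx(expected)

    def test_energy_balance_loss(self):
        assert nu.energy_balance_loss(10.0, 10.0, 5.0) == 0.0
        assert nu.energy_balance_loss(5.0, 10.0, 5.0) == pytest.approx(-1.0)
        assert nu.energy_balance_loss(12.0, 10.0, 5.0) == 0.0

    def test_body_fat_gain_branches(self):
        assert nu.body_fat_gain(0.0, 0.0, True) == 0.0  # floor
        assert nu.body_fat_gain(2.0, 0.0, True) == pytest.approx(0.1152)
        assert nu.body_fat_gain(2.0, -0.4, False) == pytest.approx(-0.4)

    def test_grow_mature_symmetric_hand_values(self):
        assert nu.grow_mature(16.0, 10.0, 6.0, 6.0) == pytest.approx(1.0 / 0.956)
        assert nu.grow_mature(4.0, 10.0, 6.0, 6.0) == pytest.approx(-1.0 / 0.956)
        assert nu.grow_mature(10.0, 10.0, 6.0, 6.0) == 0.0

    def test_maintenance_day_is_weight_neutral(self):
        # a cow held exactly at requirements neither gains nor loses
        nemr = nu.nemr(600.0, 10.0, 0.0)
        assert nu.grow_mature(nemr, nemr, 6.4, 5.2) == 0.0
        assert nu.energy_balance_loss(nemr, nemr, 5.2) == 0.0


class TestBCSAssignment:
    def test_mature_cow_at_msbw_is_bcs5(self, cfg):
        bcs = nu.assign_bcs(6, 0.0, 600.0, 600.0, cfg.fat_frac_by_bcs, cfg.csbw_ratio_by_bcs)
        assert bcs == 5

    def test_young_at_anchor_fat_is_bcs5(self, cfg):
        bcs = nu.assign_bcs(2, 0.1889 * 300.0, 300.0, 600.0, cfg.fat_frac_by_bcs,
                            cfg.csbw_ratio_by_bcs)
        assert bcs == 5

    def test_three_year_old_takes_maximum(self, cfg):
        # fat method says thin, weight method says moderate: max wins
        fat = 0.10 * 520.0
        young = nu.assign_bcs(2, fat, 520.0, 600.0, cfg.fat_frac_by_bcs, cfg.csbw_ratio_by_bcs)
        mature = nu.assign_bcs(6, fat, 520.0, 600.0, cfg.fat_frac_by_bcs, cfg.csbw_ratio_by_bcs)
        three = nu.assign_bcs(3, fat, 520.0, 600.0, cfg.fat_frac_by_bcs, cfg.csbw_ratio_by_bcs)
        assert three == max(young, mature)


class TestCalfIntake:
    def test_milk_only_before_50d(self):
        milk, forage = nu.calf_daily_intake(30, 60.0, 8.0, 1.48)
        assert milk == 8.0 and forage == 0.0

    def test_forage_non_increasing_in_milk(self):
        ages = 120
        lo = nu.calf_daily_intake(ages, 120.0, 4.0, 1.1)[1]
        hi = nu.calf_daily_intake(ages, 120.0, 10.0, 1.1)[1]
        assert hi <= lo

    def test_daily_milk_form_exceeds_peak_milk_form_late(self):
        # substituting the declining daily milk for the static peak raises
        # late-season forage intake
        peak = 11.3
        late_milk = 5.0  # well past peak
        modified = nu.calf_forage_intake(180, 160.0, late_milk, 0.71)
        original = nu.calf_forage_intake(180, 160.0, peak, 0.71)
        assert modified > original


class TestOracleAgreement:
    """Every energy equation matches the independent straight-line
    re-evaluation to 1e-9 on 100 random physiological states."""

    def test_full_suite_on_random_states(self):
        local = np.random.default_rng(2024)
        for _ in range(100):
            csbw = local.uniform(40, 800)
            temp = local.uniform(-15, 35)
            pl = local.uniform(5, 14)
            age = int(local.integers(1, 12))
            n_wk = float(local.integers(0, 40))
            nemd = local.uniform(0.6, 1.7)
            negd = local.uniform(0.1, nemd)
            lact = local.uniform(0, 12)
            t = float(local.integers(0, 300))
            cbw = local.uniform(25, 50)
            mw = local.uniform(400, 800)
            negi = local.uniform(0, 5)
            nemi = local.uniform(3, 20)
            nemr_v = local.uniform(3, 20)
            mcal_loss = local.uniform(4, 6)
            mcal_gain = local.uniform(5, 7)
            ebl = oracle.oracle_ebl(nemi, nemr_v, mcal_loss)
            nemlg = local.uniform(0, 8)

            assert nu.lactation_yield(pl, age, n_wk) == pytest.approx(
                oracle.oracle_lactation(pl, age, n_wk), abs=1e-9
            )
            assert nu.nemr(csbw, temp, nemlg) == pytest.approx(
                oracle.oracle_nemr(csbw, temp, nemlg), abs=1e-9
            )
            nep, mep, nemg = nu.gestation_energy(cbw, t)
            assert nep == pytest.approx(oracle.oracle_nepreg(cbw, t), abs=1e-9)
            assert mep == pytest.approx(oracle.oracle_mepreg(cbw, t), abs=1e-9)
            assert nemg == pytest.approx(oracle.oracle_nemg(cbw, t), abs=1e-9)
            assert nu.dmi_cow(csbw, nemd, lact, t) == pytest.approx(
                oracle.oracle_dmi_cow(csbw, nemd, lact, t), abs=1e-9
            )
            assert nu.dmi_pct_young(nemd) == pytest.approx(
                oracle.oracle_dmi_pct_young(nemd), abs=1e-9
            )
            assert nu.neg_intake(10.0, nemd, negd, nemr_v) == pytest.approx(
                oracle.oracle_negi(10.0, nemd, negd, nemr_v), abs=1e-9
            )
            assert nu.grow_young(csbw, mw, negi, ebl) == pytest.approx(
                oracle.oracle_sbg_young(csbw, mw, negi, ebl), abs=1e-9
            )
            assert nu.energy_balance_loss(nemi, nemr_v, mcal_loss) == pytest.approx(
                ebl, abs=1e-9
            )
            assert nu.body_fat_gain(negi, ebl, nemi > nemr_v) == pytest.approx(
                oracle.oracle_bfg(negi, ebl, nemi, nemr_v), abs=1e-9
            )
            assert nu.grow_mature(nemi, nemr_v, mcal_gain, mcal_loss) == pytest.approx(
                oracle.oracle_sbg_mature(nemi, nemr_v, mcal_gain, mcal_loss), abs=1e-9
            )
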