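"""Simulator: hazard construction, life-cycle bookkeeping, dilution
round trips and the protective Zn-on-Cd signature."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nemamix.doseresponse import MG_PER_L, Concentration, effect_at
from nemamix.endpoints import (
    DilutionSchedule,
    PopulationSeries,
    cumulative_dilution_factor,
    endpoint_summary,
    standard_schedule,
)
from nemamix.experiments import (
    main_experiment_configs,
    mortality_assay,
    recovery_study,
    zncd_series,
)
from nemamix.mixtures import predict_ia
from nemamix.simulate import (
    HazardModel,
    ProtectiveZnCd,
    SimConfig,
    StageParams,
    combined_hazard,
    generate_experiment,
    hazard_from_lc,
    simulate,
)


class TestHazards:
    def test_lc20_dose_gives_closed_form_hazard(self, curves):
        c = Concentration(7.110)  # the Cd LC20
        h = hazard_from_lc(curves["Cd"], c)
        assert h == pytest.approx(-math.log(0.8) / 24.0, rel=1e-9)

    def test_zero_dose_zero_hazard(self, curves):
        assert hazard_from_lc(curves["Zn"], Concentration(0.0)) == 0.0

    def test_hazard_increases_with_dose(self, curves):
        doses = [0.5, 2.0, 10.0, 50.0]
        hs = [hazard_from_lc(curves["Zn"], Concentration(d)) for d in doses]
        assert all(b > a for a, b in zip(hs, hs[1:]))

    def test_single_component_same_in_all_modes(self, curves):
        exposure = {"Cd": 7.110}
        expected = hazard_from_lc(curves["Cd"], Concentration(7.110))
        for mode in ("IA", "CA", "protective_zn_cd"):
            hm = HazardModel(curves=curves, mode=mode)
            assert combined_hazard(hm, exposure) == pytest.approx(expected, rel=1e-9)

    def test_ia_mode_reproduces_survival_product(self, curves):
        """24 h survival under summed hazards equals the IA prediction."""
        exposure = {"Zn": 9.501, "Cd": 7.110}
        hm = HazardModel(curves=curves, mode="IA")
        h = combined_hazard(hm, exposure)
        from nemamix.mixtures import MixtureExposure

        mix = MixtureExposure.of(
            (curves["Zn"], Concentration(9.501)), (curves["Cd"], Concentration(7.110))
        )
        assert 100.0 * (1 - math.exp(-24 * h)) == pytest.approx(predict_ia(mix), rel=1e-9)

    def test_protective_factor_shape(self):
        g = ProtectiveZnCd()
        assert g.factor(0.0) == 1.0
        # deep protection through the mid-range, recovery at overload
        mids = [g.factor(c) for c in (1.416, 9.501, 31.495)]
        assert all(m < 0.1 for m in mids)
        assert g.factor(84.823) > 0.5
        assert g.factor(31.495) < g.factor(84.823)

    def test_protective_zero_zn_leaves_cd_unchanged(self, curves):
        hm = HazardModel(curves=curves, mode="protective_zn_cd")
        assert combined_hazard(hm, {"Cd": 7.110}) == pytest.approx(
            hazard_from_lc(curves["Cd"], Concentration(7.110))
        )

    def test_unknown_mode_rejected(self, curves):
        with pytest.raises(ValueError):
            HazardModel(curves=curves, mode="magic")


class TestStageParams:
    def test_defaults_are_anchored_to_life_history(self):
        p = StageParams()
        # egg-to-adult about 3 days; first molt at 0.37 mm; adults over 1 mm
        total = sum(p.durations_h[s] for s in ("egg", "L1", "L2", "L3", "L4"))
        assert 60 <= total <= 96
        assert p.lengths_mm["L2"] == pytest.approx(0.37)
        assert 1.0 <= p.lengths_mm["adult"] <= 1.5

    def test_non_increasing_lengths_rejected(self):
        with pytest.raises(ValueError):
            StageParams(lengths_mm={"L1": 0.5, "L2": 0.4, "L3": 0.6, "L4": 0.8, "adult": 1.2})


class TestSimulate:
    def test_closed_form_bookkeeping(self, ia_model):
        """10 founders laying 5 eggs/day for 4 days, no deaths: exactly
        10 + 10*5*4 = 210 individuals at day 4."""
        config = SimConfig(
            hazards=ia_model,
            exposure={},
            n_start_adults=10,
            duration_days=4.0,
            fecundity=5.0,
            deterministic=True,
        )
        out = simulate(config)
        last = out.hourly.iloc[-1]
        total = sum(last[s] for s in ("egg", "L1", "L2", "L3", "L4", "adult"))
        assert total == pytest.approx(210.0, rel=1e-9)

    def test_no_hazard_no_founder_deaths(self, ia_model):
        config = SimConfig(
            hazards=ia_model, exposure={}, duration_days=2.0, seed=5
        )
        out = simulate(config)
        assert all(rec.n_alive == 10 for rec in out.mortality)

    def test_founder_mortality_matches_binomial(self, ia_model):
        """1000 founders at the Cd LC20 for 24 h: the dead fraction stays
        inside the exact binomial 99% interval around 20% in almost all
        seeded runs."""
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.2)
        inside = 0
        n_seeds = 50
        for seed in range(n_seeds):
            y = mortality_assay(ia_model, {"Cd": 7.110}, 1000, seed=seed)
            inside += lo <= y * 10 <= hi
        assert inside >= n_seeds - 3

    def test_conservation_no_spontaneous_individuals(self, ia_model):
        """alive(t+1) <= alive(t) + births(t): splits and deaths never
        create individuals."""
        config = SimConfig(
            hazards=ia_model,
            exposure={"Zn": 9.501},
            duration_days=4.0,
            schedule=standard_schedule(96.0),
            seed=11,
        )
        out = simulate(config)
        hourly = out.hourly
        totals = hourly[["egg", "L1", "L2", "L3", "L4", "adult"]].sum(axis=1).to_numpy()
        eggs = hourly["egg"].to_numpy()
        for t in range(1, len(totals)):
            new_eggs_upper = eggs[t]  # eggs laid this hour are a subset
            assert totals[t] <= totals[t - 1] + new_eggs_upper + 1e-9

    def test_seeded_reproducibility(self, ia_model):
        config = SimConfig(hazards=ia_model, exposure={"Cd": 7.110}, duration_days=3.0, seed=42)
        a, b = simulate(config), simulate(config)
        pd.testing.assert_frame_equal(a.hourly, b.hourly)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_expectation_mode_matches_sampling_mean(self, ia_model):
        """Deterministic propagation equals the across-seed mean of the
        sampling mode within Monte-Carlo error (total population, day 4)."""
        base = dict(
            hazards=ia_model, exposure={"Zn": 1.416}, duration_days=4.0, fecundity=20.0
        )
        det = simulate(SimConfig(**base, deterministic=True))
        expected = det.counts.iloc[-1]["counted_n"]
        n_seeds = 200
        totals = np.array(
            [
                simulate(SimConfig(**base, seed=s)).counts.iloc[-1]["counted_n"]
                for s in range(n_seeds)
            ],
            dtype=float,
        )
        se = totals.std(ddof=1) / math.sqrt(n_seeds)
        assert abs(totals.mean() - expected) <= 4 * se

    def test_dilution_round_trip_deterministic(self, ia_model):
        """Reconstruction exactly undoes the splits in expectation mode."""
        sched = standard_schedule(96.0)
        with_splits = simulate(
            SimConfig(hazards=ia_model, exposure={}, duration_days=4.0,
                      schedule=sched, deterministic=True)
        )
        without = simulate(
            SimConfig(hazards=ia_model, exposure={}, duration_days=4.0,
                      deterministic=True)
        )
        for row_s, row_p in zip(
            with_splits.counts.itertuples(), without.counts.itertuples()
        ):
            factor = cumulative_dilution_factor(sched, 24.0 * row_s.day)
            assert row_s.counted_n * factor == pytest.approx(row_p.counted_n, rel=1e-9)

    def test_dilution_round_trip_sampling(self, ia_model):
        """Stochastic splits reconstruct the undiluted expectation within
        sampling error (averaged over seeds)."""
        sched = DilutionSchedule(((36.0, 2), (72.0, 2)))
        without = simulate(
            SimConfig(hazards=ia_model, exposure={}, duration_days=4.0,
                      fecundity=20.0, deterministic=True)
        )
        expected = without.counts.iloc[-1]["counted_n"]
        recon = []
        for seed in range(60):
            out = simulate(
                SimConfig(hazards=ia_model, exposure={}, duration_days=4.0,
                          fecundity=20.0, schedule=sched, seed=seed)
            )
            series = PopulationSeries(
                "t", seed,
                days=tuple(out.counts["day"]),
                counted_n=tuple(int(n) for n in out.counts["counted_n"]),
                schedule=sched,
            )
            from nemamix.endpoints import reconstruct_population

            recon.append(reconstruct_population(series)["true_n"].iloc[-1])
        recon = np.asarray(recon, dtype=float)
        se = recon.std(ddof=1) / math.sqrt(len(recon))
        assert abs(recon.mean() - expected) <= 4 * se

    def test_collapse_scenario_reaches_zero(self, curves):
        """A Cd-LC20-like exposure wipes the well before day 10."""
        hm = HazardModel(curves=curves, mode="IA")
        out = simulate(
            SimConfig(
                hazards=hm,
                exposure={"Cd": 7.110},
                duration_days=10.0,
                schedule=standard_schedule(240.0),
                seed=3,
            )
        )
        series = PopulationSeries(
            "Cd", 1,
            days=tuple(out.counts["day"]),
            counted_n=tuple(int(n) for n in out.counts["counted_n"]),
            schedule=standard_schedule(240.0),
        )
        summary = endpoint_summary(series)
        assert summary.end_n == 0
        assert summary.max_day < 10.0

    def test_body_lengths_track_development(self, ia_model):
        out = simulate(
            SimConfig(
                hazards=ia_model, exposure={}, duration_days=1.0,
                length_sample_days=(0.0, 1.0), seed=9,
            )
        )
        day0 = out.lengths[out.lengths["day"] == 0.0]["length_mm"]
        # only founder adults present at day 0: adult-sized worms
        assert len(day0) == 10
        assert day0.between(0.9, 1.5).all()


class TestGenerateExperiment:
    def test_fixed_seed_byte_identical_csvs(self, ia_model, tmp_path):
        configs = [
            SimConfig(
                hazards=ia_model, treatment="control", replicate=r, exposure={},
                duration_days=2.0, length_sample_days=(0.0, 1.0), seed=100 + r,
            )
            for r in (1, 2)
        ]
        a = generate_experiment(configs, tmp_path / "a")
        b = generate_experiment(configs, tmp_path / "b")
        for key in ("counts", "schedule", "lengths", "mortality"):
            assert a[key].read_bytes() == b[key].read_bytes()

    def test_output_tables_feed_endpoint_pipeline(self, ia_model, tmp_path):
        from nemamix import io as nio
        from nemamix.endpoints import endpoint_table

        configs = [
            SimConfig(
                hazards=ia_model, treatment=t, replicate=r,
                exposure={} if t == "control" else {"Cd": 7.110},
                duration_days=2.0, seed=7 * r,
            )
            for t in ("control", "Cd")
            for r in (1, 2, 3)
        ]
        paths = generate_experiment(configs, tmp_path)
        series = nio.series_from_tables(
            nio.read_counts(paths["counts"]), nio.read_schedules(paths["schedule"])
        )
        table = endpoint_table(series)
        assert len(table) == 6
        mort = nio.read_mortality(paths["mortality"])
        assert set(mort["treatment"]) == {"control", "Cd"}

    def test_main_experiment_has_eight_treatments(self):
        configs = main_experiment_configs(seed=1, level=20.0)
        treatments = {c.treatment for c in configs}
        assert treatments == {
            "control", "Zn", "Cu", "Cd", "ZnCu", "ZnCd", "CuCd", "ZnCuCd",
        }
        control = next(c for c in configs if c.treatment == "control")
        assert cumulative_dilution_factor(control.schedule, 240.0) == 2048
        zn = next(c for c in configs if c.treatment == "Zn")
        assert cumulative_dilution_factor(zn.schedule, 240.0) == 64


class TestProtectiveSignature:
    def test_expected_mortality_below_both_models_at_mid_zn(self):
        """In expectation, Zn+Cd-LC20 founder mortality sits below the CA
        and IA predictions for Zn at LC5-LC40 and the deficit shrinks
        (here reverses) at the LC60 overload level."""
        result = zncd_series(seed=0, n_replicates=3)
        exp = result.expected[result.expected["time_h"] == 24.0].set_index("zn_level")
        for level in (5.0, 20.0, 40.0):
            row = exp.loc[level]
            assert row["expected_mixture"] < row["y_ca"]
            assert row["expected_mixture"] < row["y_ia"]
        deficit = (exp["y_ia"] - exp["expected_mixture"])
        assert deficit.loc[60.0] < deficit.loc[[5.0, 20.0, 40.0]].min()

    def test_mortality_ratio_profile_is_u_shaped(self):
        """Mixture/Cd-only mortality ratio dips below 1 at low Zn and
        rises above 1 toward the overload level."""
        result = zncd_series(seed=0, n_replicates=3)
        ratios = result.expected_ratios(24.0)
        assert ratios.loc[5.0] < 1.0
        assert ratios.loc[5.0] < ratios.loc[2.0]  # falling limb
        assert ratios.loc[60.0] > ratios.loc[40.0] > ratios.loc[5.0]  # rising limb

    def test_parameter_recovery_smoke(self):
        """Small-scale version of the recovery study: most replicates
        land within tolerance."""
        result = recovery_study(seed=2, n_replicates=10)
        assert result.success_rate >= 0.7
        assert result.true_ec50 == pytest.approx(51.7, rel=0.01)
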