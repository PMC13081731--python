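"""Volume formula, TGI, ANCOVA/ANOVA, events, KM, log-rank, 4PL."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from biodscore import (
    GrowthSimConfig,
    ancova_log_tgi,
    anova_interaction,
    compare_slopes,
    compute_tgi,
    derive_events,
    fit_4pl,
    km_curve,
    logrank,
    simulate_growth,
    tumor_volume,
)
from biodscore.growth import _logrank_z, four_pl


def study_from_volumes(volumes: dict, days, genotype=None) -> pd.DataFrame:
    """Build a GrowthStudy table from {group: [per-animal volume series]}."""
    rows = []
    for group, series in volumes.items():
        for j, vs in enumerate(series):
            for d, v in zip(days, vs):
                w = np.cbrt(2 * v / 1.3)
                rows.append((f"{group}_{j}", group,
                             (genotype or {}).get(group, "wildtype"),
                             d, 1.3 * w, w, v))
    return pd.DataFrame(rows, columns=["animal", "group", "genotype", "day",
                                       "length_mm", "width_mm", "volume_mm3"])


class TestTumorVolume:
    @pytest.mark.parametrize("L,W,v", [(10, 10, 500.0), (12, 5, 150.0)])
    def test_formula(self, L, W, v):
        assert tumor_volume(L, W) == v

    def test_width_exceeding_length_rejected(self):
        with pytest.raises(ValueError, match="longest"):
            tumor_volume(5, 12)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            tumor_volume(5, 0)


class TestTGI:
    def test_identical_groups_zero(self):
        # per-animal baselines and rates differ (non-degenerate residuals),
        # but the two groups are copies of each other
        rng = np.random.default_rng(17)
        vols = [[v0 * np.exp(r * d) for d in (0, 7, 14)]
                for v0, r in zip(rng.uniform(75, 150, 6),
                                 rng.uniform(0.15, 0.25, 6))]
        study = study_from_volumes({"control": vols, "treated": vols}, (0, 7, 14))
        res = compute_tgi(study, "treated", "control")
        assert res.tgi_percent == pytest.approx(0.0, abs=1e-9)
        assert res.p_one_sided == pytest.approx(0.5, abs=1e-9)
        assert res.reference_day == 14

    def test_half_volume_is_fifty_percent(self):
        base = [90.0, 95.0, 100.0, 105.0, 110.0]
        c = [[b, 200.0] for b in base]
        t = [[b, 100.0] for b in base]
        study = study_from_volumes({"control": c, "treated": t}, (0, 10))
        res = compute_tgi(study, "treated", "control")
        assert res.tgi_percent == pytest.approx(50.0)

    def test_noise_free_exponential_closed_form(self):
        """Control rate 0.23/day vs treated rate 0 over 10 days:
        TGI = 100·(1 − e^(−2.3))."""
        cfg = GrowthSimConfig(seed=5, n_per_group=8,
                              groups={"control": 0.23, "treated": 0.0},
                              residual_sd=0.0, days=(0, 5, 10),
                              baseline_range_mm3=(100.0, 100.0))  # equal baselines
        with pytest.warns(UserWarning):  # degenerate noise-free ANCOVA flagged
            res = compute_tgi(simulate_growth(cfg), "treated", "control")
        assert res.tgi_percent == pytest.approx(100 * (1 - np.exp(-2.3)), abs=0.5)

    def test_scale_invariance(self):
        cfg = GrowthSimConfig(seed=7, n_per_group=6, residual_sd=0.1)
        study = simulate_growth(cfg)
        scaled = study.assign(volume_mm3=study["volume_mm3"] * 1000.0)
        a = compute_tgi(study, "treated", "control")
        b = compute_tgi(scaled, "treated", "control")
        assert a.tgi_percent == pytest.approx(b.tgi_percent)
        assert a.p_one_sided == pytest.approx(b.p_one_sided)

    def test_geometric_variant(self):
        base = [90.0, 100.0, 110.0, 120.0]
        c = [[b, 400.0] for b in base]
        t = [[b, 100.0] for b in base]
        study = study_from_volumes({"control": c, "treated": t}, (0, 10))
        res = compute_tgi(study, "treated", "control", method="geometric")
        assert res.tgi_percent == pytest.approx(75.0)

    def test_negative_tgi_allowed(self):
        base = [90.0, 100.0, 110.0, 120.0]
        c = [[b, 100.0] for b in base]
        t = [[b, 120.0] for b in base]
        study = study_from_volumes({"control": c, "treated": t}, (0, 10))
        assert compute_tgi(study, "treated", "control").tgi_percent < 0


class TestAncova:
    def test_strong_effect_detected_across_seeds(self):
        hits = 0
        for seed in range(100):
            cfg = GrowthSimConfig(seed=seed, n_per_group=10,
                                  groups={"control": 0.23, "treated": 0.115},
                                  residual_sd=0.10, days=(0, 3, 7, 10, 14))
            p = ancova_log_tgi(simulate_growth(cfg), "treated", "control")
            hits += p < 0.001
        assert hits >= 95

    def test_one_sided_is_half_two_sided_in_hypothesized_direction(self):
        import statsmodels.api as sm

        cfg = GrowthSimConfig(seed=3, n_per_group=8,
                              groups={"control": 0.23, "treated": 0.15},
                              residual_sd=0.15)
        study = simulate_growth(cfg)
        p1 = ancova_log_tgi(study, "treated", "control")
        ref_day = study["day"].max()
        ref = study[study["day"] == ref_day].set_index("animal")
        base = study[study["day"] == 0].set_index("animal")
        X = sm.add_constant(np.column_stack([
            (ref["group"] == "treated").to_numpy(float),
            np.log(base.loc[ref.index, "volume_mm3"]),
        ]))
        p2 = sm.OLS(np.log(ref["volume_mm3"].to_numpy()), X).fit().pvalues[1]
        assert p1 == pytest.approx(p2 / 2)

    def test_wrong_direction_gives_large_p(self):
        cfg = GrowthSimConfig(seed=1, n_per_group=8,
                              groups={"control": 0.10, "treated": 0.25},
                              residual_sd=0.05)
        assert ancova_log_tgi(simulate_growth(cfg), "treated", "control") > 0.5

    def test_unit_invariance(self):
        cfg = GrowthSimConfig(seed=9, n_per_group=6, residual_sd=0.1)
        study = simulate_growth(cfg)
        scaled = study.assign(volume_mm3=study["volume_mm3"] / 1000.0)  # cm³
        assert ancova_log_tgi(study, "treated", "control") == pytest.approx(
            ancova_log_tgi(scaled, "treated", "control")
        )


class TestInteractionAnova:
    @staticmethod
    def _sim(seed, wt_treat_effect, ko_treat_effect, n=8, sd=0.2):
        rng = np.random.default_rng(seed)
        rows = []
        for geno, eff in (("wildtype", wt_treat_effect), ("knockout", ko_treat_effect)):
            base = 6.0 + (0.3 if geno == "knockout" else 0.0)
            for group, treat in (("control", 0.0), ("treated", 1.0)):
                for j in range(n):
                    logv = base + treat * eff + rng.normal(0, sd)
                    v = np.exp(logv)
                    w = np.cbrt(2 * v / 1.3)
                    rows.append((f"{geno}_{group}_{j}", group, geno, 14,
                                 1.3 * w, w, v))
        df = pd.DataFrame(rows, columns=["animal", "group", "genotype", "day",
                                         "length_mm", "width_mm", "volume_mm3"])
        # add a baseline day so the reference-day logic has >1 day
        base_rows = df.assign(day=0, volume_mm3=100.0)
        return pd.concat([base_rows, df], ignore_index=True)

    def test_null_p_uniform(self):
        """No interaction → one-sided p uniform on [0,1] (KS, α = 0.01)."""
        ps = [anova_interaction(self._sim(seed, -0.5, -0.5), "treated", "control")
              for seed in range(1000)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_additive_effects_give_near_zero_interaction(self):
        ps = [anova_interaction(self._sim(seed, -0.5, -0.5, sd=0.01),
                                "treated", "control") for seed in range(20)]
        assert 0.1 < np.mean(ps) < 0.9

    def test_power_for_hypothesized_direction(self):
        """Stronger inhibition in wildtype → small one-sided p."""
        hits = sum(
            anova_interaction(self._sim(seed, -1.0, -0.2), "treated", "control") < 0.05
            for seed in range(100)
        )
        assert hits > 80

    def test_wrong_direction_large_p(self):
        ps = [anova_interaction(self._sim(seed, -0.2, -1.0), "treated", "control")
              for seed in range(20)]
        assert np.mean(ps) > 0.5


class TestEvents:
    def test_monotone_crossing(self):
        study = study_from_volumes(
            {"g": [[200, 900, 1600, 2100]]}, (0, 7, 14, 21))
        tbl = derive_events(study)
        assert tbl.iloc[0]["time_days"] == 14 and tbl.iloc[0]["event"]

    def test_never_crossing_censored_at_last_day(self):
        study = study_from_volumes({"g": [[200, 400, 800]]}, (0, 15, 30))
        tbl = derive_events(study)
        assert tbl.iloc[0]["time_days"] == 30 and not tbl.iloc[0]["event"]

    def test_non_monotone_first_crossing_wins(self):
        study = study_from_volumes(
            {"g": [[200, 1600, 900, 1700]]}, (0, 7, 14, 21))
        tbl = derive_events(study)
        assert tbl.iloc[0]["time_days"] == 7 and tbl.iloc[0]["event"]

    def test_noise_free_exponential_matches_closed_form_crossing(self):
        """V₀e^{rt} ≥ 1500 first at the first measured day ≥ ln(1500/V₀)/r."""
        cfg = GrowthSimConfig(seed=11, n_per_group=5,
                              groups={"g": 0.23}, residual_sd=0.0,
                              days=tuple(range(0, 29, 2)))
        study = simulate_growth(cfg)
        tbl = derive_events(study).set_index("animal")
        v0 = study[study["day"] == 0].set_index("animal")["volume_mm3"]
        for animal, row in tbl.iterrows():
            t_cross = np.log(1500.0 / v0[animal]) / 0.23
            expected = next(d for d in range(0, 29, 2) if d >= t_cross)
            assert row["time_days"] == expected and row["event"]


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        tbl = pd.DataFrame({"animal": list("abcd"), "group": "g",
                            "time_days": [1, 2, 3, 4], "event": True})
        km = km_curve(tbl)
        s = km.set_index("time_days")["survival"]
        assert s[2.0] == pytest.approx(0.5)  # S(2.5) on the step = S at t=2
        assert s[4.0] == pytest.approx(0.0)

    def test_all_censored_flat_one(self):
        tbl = pd.DataFrame({"animal": list("abc"), "group": "g",
                            "time_days": [5, 6, 7], "event": False})
        km = km_curve(tbl)
        assert (km["survival"] == 1.0).all()

    def test_mixed_hand_computed_product_limit(self):
        """events at 2 (4 at risk) and 5 (2 at risk), censor at 3:
        S = 3/4 then 3/4 · 1/2 = 3/8."""
        tbl = pd.DataFrame({"animal": list("abcd"), "group": "g",
                            "time_days": [2, 3, 5, 6],
                            "event": [True, False, True, False]})
        s = km_curve(tbl).set_index("time_days")["survival"]
        assert s[2.0] == pytest.approx(0.75)
        assert s[5.0] == pytest.approx(0.375)

    def test_starts_at_one(self):
        tbl = pd.DataFrame({"animal": list("ab"), "group": "g",
                            "time_days": [3, 8], "event": [True, True]})
        km = km_curve(tbl)
        assert km.iloc[0]["time_days"] == 0.0 and km.iloc[0]["survival"] == 1.0


class TestLogrank:
    @staticmethod
    def _tbl(t_treated, t_control, e_treated=None, e_control=None):
        times = list(t_treated) + list(t_control)
        events = list(e_treated or [True] * len(t_treated)) + \
            list(e_control or [True] * len(t_control))
        groups = ["rt"] * len(t_treated) + ["ctrl"] * len(t_control)
        return pd.DataFrame({"animal": [f"a{i}" for i in range(len(times))],
                             "group": groups, "time_days": times, "event": events})

    def test_identical_groups_p_half(self):
        tbl = self._tbl([3, 5, 8], [3, 5, 8])
        assert logrank(tbl, "rt", "ctrl", method="asymptotic") == pytest.approx(0.5)

    def test_exact_matches_enumeration_oracle(self):
        """Exhaustive group-label permutation oracle on 6 animals."""
        tbl = self._tbl([9, 12, 15], [3, 5, 14])
        p = logrank(tbl, "rt", "ctrl", method="exact")
        times = tbl["time_days"].to_numpy(float)
        events = tbl["event"].to_numpy(bool)
        z_obs = _logrank_z(times, events, (tbl["group"] == "rt").to_numpy())
        zs = []
        for idx in itertools.combinations(range(6), 3):
            lab = np.zeros(6, dtype=bool)
            lab[list(idx)] = True
            zs.append(_logrank_z(times, events, lab))
        assert p == pytest.approx(np.mean(np.asarray(zs) <= z_obs + 1e-12))

    def test_asymptotic_within_permutation_bracket(self):
        """On a small example the normal-deviate p lies inside the coarse
        permutation bracket [P(Z < z), P(Z ≤ z)] (continuity slack one
        permutation atom)."""
        tbl = self._tbl([8, 10, 15], [3, 6, 9])
        times = tbl["time_days"].to_numpy(float)
        events = tbl["event"].to_numpy(bool)
        z_obs = _logrank_z(times, events, (tbl["group"] == "rt").to_numpy())
        zs = np.array([
            _logrank_z(times, events,
                       np.isin(np.arange(6), idx))
            for idx in itertools.combinations(range(6), 3)
        ])
        lo = np.mean(zs < z_obs - 1e-12)
        hi = np.mean(zs <= z_obs + 1e-12)
        p_asym = logrank(tbl, "rt", "ctrl", method="asymptotic")
        atom = 1.0 / len(zs)
        assert lo - atom <= p_asym <= hi + atom

    def test_squared_deviate_equals_lifelines_chi2(self):
        from lifelines.statistics import logrank_test

        tbl = self._tbl([9, 12, 15, 20, 22, 30], [3, 5, 8, 11, 14, 18],
                        e_treated=[True, True, False, True, True, False])
        times = tbl["time_days"].to_numpy(float)
        events = tbl["event"].to_numpy(bool)
        z = _logrank_z(times, events, (tbl["group"] == "rt").to_numpy())
        ref = logrank_test(
            tbl[tbl["group"] == "rt"]["time_days"],
            tbl[tbl["group"] == "ctrl"]["time_days"],
            event_observed_A=tbl[tbl["group"] == "rt"]["event"],
            event_observed_B=tbl[tbl["group"] == "ctrl"]["event"],
        )
        assert z**2 == pytest.approx(ref.test_statistic)

    def test_null_p_uniform_by_simulation(self):
        """Exchangeable groups → asymptotic one-sided p roughly uniform."""
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(300):
            t = rng.exponential(10, size=24)
            cens = rng.uniform(5, 30, size=24)
            tbl = pd.DataFrame({
                "animal": [f"a{i}" for i in range(24)],
                "group": ["rt"] * 12 + ["ctrl"] * 12,
                "time_days": np.minimum(t, cens),
                "event": t <= cens,
            })
            ps.append(logrank(tbl, "rt", "ctrl", method="asymptotic"))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestFourPL:
    def test_noise_free_recovery(self):
        t = np.linspace(1, 96, 40)
        truth = dict(bottom=5.0, top=88.0, slope=2.5, inflection=40.0)
        c = four_pl(t, **truth)
        fit = fit_4pl(t, c)
        assert fit.converged
        for k, v in truth.items():
            assert getattr(fit, k) == pytest.approx(v, rel=1e-4)

    def test_constant_series_flagged_degenerate(self):
        fit = fit_4pl(np.arange(10.0), np.full(10, 42.0))
        assert not fit.converged

    def test_decreasing_series_negative_slope(self):
        t = np.linspace(1, 96, 40)
        c = four_pl(t, bottom=10.0, top=90.0, slope=-1.8, inflection=30.0)
        fit = fit_4pl(t, c)
        assert fit.converged and fit.slope == pytest.approx(-1.8, rel=1e-3)
        assert fit.top >= fit.bottom

    def test_compare_identical_slope_sets_p_half(self):
        p = compare_slopes([2.0, 2.1, 1.9], [2.0, 2.1, 1.9])
        assert p == pytest.approx(0.5, abs=0.01)

    def test_two_replicate_arms_have_bounded_p(self):
        """Separated slopes at n = 2 + 2: significant but p bounded away
        from zero by the tiny df."""
        p = compare_slopes([1.0, 1.01], [2.0, 2.01])
        assert p < 0.05
        assert p > 1e-6

    def test_simulated_shift_power(self):
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            treated = rng.normal(1.5, 0.3, 6)
            control = rng.normal(2.5, 0.3, 6)
            hits += compare_slopes(treated, control) < 0.05
        assert hits / n_rep > 0.9
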