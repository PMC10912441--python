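"""Synthetic registry generator tests (determinism, rates, competing risks)."""

import numpy as np
import pandas as pd
import pytest

from pseudocohort import (
    ConfigurationError,
    SimConfig,
    calibrate_hazards,
    generate_health_events,
    generate_outcomes,
    generate_population,
    simulate_cohort,
    simulate_registry,
    true_params,
)
from pseudocohort.synth import _cif_const, calendar_period


class TestConfig:
    def test_invalid_rates_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(baseline_abuse_hazard=-1)
        with pytest.raises(ConfigurationError):
            SimConfig(category_diagnosis_rates={"Hypertension": -0.1})
        with pytest.raises(ConfigurationError):
            SimConfig(study_start="2000-01-01", study_end="1999-01-01")
        with pytest.raises(ConfigurationError):
            SimConfig(true_log_rr={"Hypertension": np.inf})

    def test_yaml_round_trip(self, tmp_path, small_sim_config):
        path = tmp_path / "cfg.yaml"
        small_sim_config.to_yaml(path)
        again = SimConfig.from_yaml(path)
        assert again.to_dict() == small_sim_config.to_dict()
        pd.testing.assert_frame_equal(true_params(again), true_params(small_sim_config))

    def test_true_params_values(self):
        cfg = SimConfig(true_log_rr={"A": 0.0, "B": float(np.log(1.5))})
        tab = true_params(cfg).set_index("category")
        assert tab.loc["A", "true_rr"] == pytest.approx(1.0)
        assert tab.loc["B", "true_rr"] == pytest.approx(1.5)


class TestGeneratePopulation:
    def test_empty(self):
        snap = generate_population(SimConfig(n_families=0))
        assert len(snap.persons) == 0

    def test_negative_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_families=-1)

    def test_determinism_byte_identical(self, tmp_path, small_sim_config):
        a = generate_population(small_sim_config)
        b = generate_population(small_sim_config)
        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        for name in ("persons", "links", "covariates"):
            assert (tmp_path / "a" / f"{name}.tsv").read_bytes() == (
                tmp_path / "b" / f"{name}.tsv"
            ).read_bytes()

    def test_every_child_linked(self, small_sim_config):
        snap = generate_population(small_sim_config)
        snap.validate()
        linked = set(snap.links["child_id"])
        assert set(snap.children["person_id"]) <= linked

    def test_family_size_distribution(self):
        # DERIVED oracle: direct count of families with >= 2 children vs the
        # configured probability, within binomial MC error
        probs = [0.46, 0.37, 0.164, 0.006]
        cfg = SimConfig(n_families=1000, family_size_probs=probs, seed=5)
        snap = generate_population(cfg)
        sizes = snap.children.groupby("family_id").size()
        frac = float((sizes >= 2).mean())
        p = 1 - probs[0]
        se = np.sqrt(p * (1 - p) / 1000)
        assert abs(frac - p) < 4 * se

    def test_covariate_levels(self, small_sim_config):
        cov = generate_population(small_sim_config).covariates
        assert set(cov["reconstituted_family"].dropna().unique()) <= {0, 1, 2}
        assert set(cov["n_children_category"].unique()) <= {0, 1, 2, 3}
        assert set(cov["calendar_period"].unique()) <= {0, 1, 2}

    def test_missingness_only_on_allowed_fields(self):
        cfg = SimConfig(n_families=200, seed=3)
        cfg.covariate_distributions["missing_rates"] = {
            "neighborhood_resources": 0.3,
            "income": 0.2,
        }
        cov = generate_population(cfg).covariates
        assert cov["neighborhood_resources"].isna().mean() > 0.2
        assert cov["income"].isna().mean() > 0.1
        assert cov["mean_parental_age"].notna().all()
        assert cov["psychiatric_disease"].notna().all()


class TestGenerateHealthEvents:
    def test_zero_rates_no_events(self, small_sim_config):
        cfg = SimConfig.from_dict(
            {**small_sim_config.to_dict(), "category_diagnosis_rates": {}, "prescription_rates": {}}
        )
        snap = generate_population(cfg)
        dx, rx = generate_health_events(snap, cfg)
        assert len(dx) == 0 and len(rx) == 0

    def test_unknown_category_key(self, small_sim_config):
        cfg = SimConfig.from_dict(
            {**small_sim_config.to_dict(), "category_diagnosis_rates": {"No Such Category": 1.0}}
        )
        snap = generate_population(cfg)
        with pytest.raises(ConfigurationError, match="unknown category"):
            generate_health_events(snap, cfg)

    def test_unknown_atc_key(self, small_sim_config):
        cfg = SimConfig.from_dict(
            {**small_sim_config.to_dict(), "prescription_rates": {"ZZ99": 1.0}}
        )
        snap = generate_population(cfg)
        with pytest.raises(ConfigurationError, match="ATC"):
            generate_health_events(snap, cfg)

    def test_poisson_mean(self):
        # DERIVED oracle: one parent, rate r over T years -> mean count rT
        r = 2.0
        cfg = SimConfig(
            n_families=1,
            p_two_parents=0.0,
            family_size_probs=[1.0, 0, 0, 0],
            study_start="1997-01-01",
            study_end="2001-12-31",
            category_diagnosis_rates={"Hypertension": r},
        )
        T = (np.datetime64("2001-12-31") - np.datetime64("1994-01-01")) / np.timedelta64(1, "D") / 365.25
        counts = []
        for seed in range(60):
            cfg.seed = seed
            snap = generate_population(cfg)
            dx, _ = generate_health_events(snap, cfg)
            counts.append(len(dx))
        mean = np.mean(counts)
        se = np.sqrt(r * T / 60)
        assert abs(mean - r * T) < 4 * se

    def test_no_event_before_readin(self, small_sim_config):
        snap = generate_population(small_sim_config)
        dx, rx = generate_health_events(snap, small_sim_config)
        read_in = np.datetime64("1997-01-01") - np.timedelta64(int(round(3 * 365.25)), "D")
        assert (dx["date"].values.astype("datetime64[D]") >= read_in).all()
        assert (rx["date"].values.astype("datetime64[D]") >= read_in).all()

    def test_codes_classifiable(self, small_sim_config, taxonomy):
        from pseudocohort import classify_code

        snap = generate_population(small_sim_config)
        dx, _ = generate_health_events(snap, small_sim_config)
        some = dx[dx["code"].str.startswith("I1")]
        assert len(some) and all(classify_code(taxonomy, c) == "Hypertension" for c in some["code"])


class TestGenerateOutcomes:
    def _no_censor_config(self, **overrides):
        base = dict(
            n_families=800,
            study_start="1997-01-01",
            study_end="2016-12-31",
            baseline_abuse_hazard=0.05,
            death_hazard=0.05,
            censoring_hazards_by_period=[0.0, 0.0, 0.0],
            seed=9,
        )
        base.update(overrides)
        return SimConfig(**base)

    def test_competing_race_probability(self):
        # DERIVED closed form: equal hazards a = d -> P(first event abuse
        # | abuse or death) = a / (a + d) = 1/2, independent of truncation
        cfg = self._no_censor_config()
        snap = generate_population(cfg)
        out = generate_outcomes(snap, None, cfg)
        n_abuse = (out["type"] == "abuse").sum()
        n_death = (out["type"] == "death").sum()
        frac = n_abuse / (n_abuse + n_death)
        se = np.sqrt(0.25 / (n_abuse + n_death))
        assert abs(frac - 0.5) < 4 * se

    def test_every_child_one_record(self):
        cfg = self._no_censor_config()
        snap = generate_population(cfg)
        out = generate_outcomes(snap, None, cfg)
        assert not out["child_id"].duplicated().any()
        in_study = snap.children[
            (snap.children["birth_date"].values.astype("datetime64[D]") <= np.datetime64("2016-12-31"))
        ]
        # children aging out before study start get no record
        assert set(out["child_id"]) <= set(in_study["person_id"])

    def test_all_abuse_when_only_abuse_hazard(self):
        cfg = self._no_censor_config(baseline_abuse_hazard=5.0, death_hazard=0.0)
        snap = generate_population(cfg)
        out = generate_outcomes(snap, None, cfg)
        # hazard 5/yr: essentially every child followed >1y is abused
        followed = out[out["date"] - pd.to_datetime(
            snap.children.set_index("person_id").loc[out["child_id"], "birth_date"]
        ).values > np.timedelta64(365, "D")]
        assert (followed["type"] == "abuse").mean() > 0.98

    def test_no_outcome_before_birth(self):
        cfg = self._no_censor_config()
        snap = generate_population(cfg)
        out = generate_outcomes(snap, None, cfg)
        birth = snap.children.set_index("person_id")["birth_date"]
        assert (
            out["date"].values.astype("datetime64[D]")
            >= pd.to_datetime(birth.loc[out["child_id"]]).values.astype("datetime64[D]")
        ).all()

    def test_child_born_after_study_end_absent(self):
        cfg = self._no_censor_config(n_families=50, study_end="1998-12-31")
        snap = generate_population(cfg)
        late = snap.children[
            snap.children["birth_date"].values.astype("datetime64[D]") > np.datetime64("1998-12-31")
        ]
        out = generate_outcomes(snap, None, cfg)
        assert set(out["child_id"]).isdisjoint(set(late["person_id"]))

    def test_calendar_dependent_censoring_rates(self):
        # DERIVED oracle: per-period emigration incidence rate, person-years
        # allocated across period boundaries by hand, vs configured hazards
        rates = [0.02, 0.05, 0.10]
        cfg = SimConfig(
            n_families=1500,
            study_start="1997-01-01",
            study_end="2014-12-31",
            baseline_abuse_hazard=0.0,
            death_hazard=0.0,
            censoring_hazards_by_period=rates,
            seed=13,
        )
        snap = generate_population(cfg)
        out = generate_outcomes(snap, None, cfg)
        start, end = np.datetime64("1997-01-01"), np.datetime64("2014-12-31")
        span = (end - start) / np.timedelta64(1, "D")
        bounds = [start, start + np.timedelta64(int(span / 3), "D"),
                  start + np.timedelta64(int(2 * span / 3), "D"), end]
        birth = pd.to_datetime(
            snap.children.set_index("person_id").loc[out["child_id"], "birth_date"]
        ).values.astype("datetime64[D]")
        entry = np.maximum(birth, start)
        exit_ = out["date"].values.astype("datetime64[D]")
        events = out["type"].values == "emigration"
        for p in range(3):
            lo, hi = bounds[p], bounds[p + 1]
            t0 = np.maximum(entry, lo)
            t1 = np.minimum(exit_, hi)
            py = np.maximum((t1 - t0) / np.timedelta64(1, "D"), 0).sum() / 365.25
            ev = (events & (exit_ > lo) & (exit_ <= hi)).sum()
            rate = ev / py
            se = np.sqrt(ev) / py
            assert abs(rate - rates[p]) < 4 * max(se, 1e-6), (p, rate)

    def test_exposure_raises_abuse_rate(self, taxonomy):
        cfg = SimConfig(
            n_families=1200,
            study_start="1997-01-01",
            study_end="2010-12-31",
            category_diagnosis_rates={"Hypertension": 0.05},
            true_log_rr={"Hypertension": np.log(4.0)},
            baseline_abuse_hazard=0.01,
            death_hazard=0.0,
            censoring_hazards_by_period=[0, 0, 0],
            seed=21,
        )
        snap, timeline = simulate_registry(cfg)
        out = snap.outcomes
        abuse = out[out["type"] == "abuse"]
        fam = snap.children.set_index("person_id")["family_id"]
        exposed_fams = {
            f for f, row in zip(timeline.family_ids, timeline.exposed_matrix("Hypertension"))
            if row.any()
        }
        abused_exposed = abuse["child_id"].map(fam).isin(exposed_fams).mean()
        all_exposed = out["child_id"].map(fam).isin(exposed_fams).mean()
        assert abused_exposed > all_exposed  # enrichment under RR 4


class TestSimulateCohort:
    def test_calibration_closed_form(self):
        lam0, lam1 = calibrate_hazards(0.10, 1.5, 0.002, 8.0)
        assert _cif_const(lam0, 0.002, 8.0) == pytest.approx(0.10, abs=1e-10)
        assert _cif_const(lam1, 0.002, 8.0) == pytest.approx(0.15, abs=1e-10)

    def test_cohort_shape_and_ratio(self, rng):
        df = simulate_cohort(100, 1.5, rng, ratio=5)
        assert len(df) == 600
        assert df["exposed"].sum() == 100
        assert set(df["event"].unique()) <= {0, 1, 2}

    def test_exposed_have_higher_incidence(self, rng):
        df = simulate_cohort(4000, 2.0, rng)
        inc = df.groupby("exposed").apply(
            lambda g: ((g["event"] == 1) & (g["time"] <= 8.0)).mean(), include_groups=False
        )
        assert inc[1] > 1.5 * inc[0]

    def test_calendar_period_helper(self):
        dates = ["1997-06-01", "2005-01-01", "2017-01-01"]
        assert list(calendar_period(dates, "1997-01-01", "2018-12-31")) == [0, 1, 2]
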