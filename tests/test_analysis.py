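"""Stratification, quadrant response, survival comparisons and meta-analysis."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from conftest import fisher_exact_enumeration
from csgtools.analysis import (
    StratifiedCohort,
    SurvivalModelSpec,
    cox_model,
    km_compare,
    meta_by_type,
    pool_fixed_effect,
    quadrant_response,
    stratify,
)
from csgtools.types import CohortTable, ValidationError


def _clinical(n, rng=None, **cols):
    rng = rng or np.random.default_rng(0)
    base = {
        "sample_id": [f"s{i}" for i in range(n)],
        "os_months": rng.exponential(10, n),
        "os_event": np.ones(n, dtype=bool),
        "response": ["PD"] * n,
        "neoantigen_burden": rng.gamma(2.0, 1.0, n),
        "cancer_type": ["BLCA"] * n,
        "stage": rng.choice([1, 2, 3, 4], n),
    }
    base.update(cols)
    return CohortTable(pd.DataFrame(base))


def _metrics(n, values=None, rng=None):
    rng = rng or np.random.default_rng(1)
    wg = values if values is not None else rng.uniform(0, 1, n)
    return pd.DataFrame({"wgii": wg}, index=[f"s{i}" for i in range(n)])


def _labels(n, csg="CSG3"):
    return pd.Series(csg, index=[f"s{i}" for i in range(n)])


class TestStratify:
    def test_median_split_values_1234(self):
        cohort = _clinical(4, neoantigen_burden=np.array([5.0, 6.0, 7.0, 8.0]))
        strat = stratify(cohort, _metrics(4, np.array([1.0, 2.0, 3.0, 4.0])), _labels(4))
        assert strat.wgii_median == 2.5
        assert strat.data["wgii_high"].tolist() == [False, False, True, True]

    def test_value_at_median_counts_as_high(self):
        cohort = _clinical(3, neoantigen_burden=np.array([1.0, 2.0, 3.0]))
        strat = stratify(cohort, _metrics(3, np.array([1.0, 2.0, 3.0])), _labels(3))
        assert strat.data.set_index("sample_id").loc["s1", "wgii_high"]

    def test_constant_metric_warns_all_high(self):
        cohort = _clinical(4)
        with pytest.warns(UserWarning, match="constant"):
            strat = stratify(cohort, _metrics(4, np.full(4, 0.5)), _labels(4))
        assert strat.data["wgii_high"].all()

    def test_responder_definition(self):
        cohort = _clinical(4, response=["CR", "PR", "SD", "PD"])
        strat = stratify(cohort, _metrics(4), _labels(4))
        assert strat.data["responder"].tolist() == [True, True, False, False]

    def test_missing_csg_rejected(self):
        cohort = _clinical(3)
        labels = pd.Series({"s0": "CSG1", "s1": "CSG2"})  # s2 missing
        with pytest.raises(ValidationError):
            stratify(cohort, _metrics(3), labels)


class TestQuadrantResponse:
    def _strat(self, wgii_high, neo_high, responder, csg=None):
        n = len(wgii_high)
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "wgii_high": wgii_high,
                "neo_high": neo_high,
                "responder": responder,
                "csg": csg if csg is not None else ["CSG3"] * n,
            }
        )
        return StratifiedCohort(df, 0.5, 2.0)

    def test_printed_size_table_matches_enumeration_oracle(self):
        """Fisher p for the 2x2 table [[9,11],[10,70]] agrees with exhaustive
        hypergeometric enumeration."""
        wgii_high = [True] * 20 + [False] * 80
        neo_high = [True] * 20 + [False] * 80
        responder = [True] * 9 + [False] * 11 + [True] * 10 + [False] * 70
        res = quadrant_response(self._strat(wgii_high, neo_high, responder))
        assert res.table.to_numpy().tolist() == [[9, 11], [10, 70]]
        assert res.p_value == pytest.approx(
            fisher_exact_enumeration([[9, 11], [10, 70]]), rel=1e-9
        )

    def test_extreme_association_significant(self):
        wgii_high = [True] * 30 + [False] * 70
        neo_high = [True] * 30 + [False] * 70
        responder = [True] * 30 + [False] * 70
        res = quadrant_response(self._strat(wgii_high, neo_high, responder))
        assert res.p_value < 0.01

    def test_identical_rates_give_p_one(self):
        wgii_high = ([True] * 10 + [False] * 10) * 2
        neo_high = ([True] * 10 + [False] * 10) * 2
        responder = [True] * 5 + [False] * 5 + [True] * 5 + [False] * 5 + [
            True
        ] * 5 + [False] * 5 + [True] * 5 + [False] * 5
        res = quadrant_response(self._strat(wgii_high, neo_high, responder))
        assert res.p_value == pytest.approx(1.0)

    def test_counts_sum_to_cohort_and_quadrants_complete(self):
        rng = np.random.default_rng(5)
        n = 60
        strat = self._strat(
            rng.random(n) < 0.5, rng.random(n) < 0.5, rng.random(n) < 0.3
        )
        res = quadrant_response(strat)
        assert res.table.to_numpy().sum() == n
        assert res.quadrant_counts["n"].sum() == n

    def test_empty_filter_rejected(self):
        strat = self._strat([True], [True], [True], csg=["CSG1"])
        with pytest.raises(ValidationError):
            quadrant_response(strat, csg_filter="CSG3")


class TestKM:
    def _strat(self, months, events, group):
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(months))],
                "os_months": months,
                "os_event": events,
                "group": group,
            }
        )
        return StratifiedCohort(df, 0.5, 2.0)

    def test_all_events_at_t5_median_five(self):
        strat = self._strat([5.0] * 10, [True] * 10, ["a"] * 10)
        res = km_compare(strat, "group")
        assert res.medians["a"] == 5.0

    def test_identical_groups_logrank_near_one(self):
        months = list(np.linspace(1, 20, 20)) * 2
        events = [True] * 40
        group = ["a"] * 20 + ["b"] * 20
        res = km_compare(self._strat(months, events, group), "group")
        assert res.logrank_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.logrank_p == pytest.approx(1.0, abs=1e-6)

    def test_zero_event_group_has_na_median(self):
        months = [5.0] * 10 + [8.0] * 10
        events = [True] * 10 + [False] * 10
        group = ["a"] * 10 + ["b"] * 10
        res = km_compare(self._strat(months, events, group), "group")
        assert np.isnan(res.medians["b"])

    def test_curves_are_non_increasing_from_one(self):
        rng = np.random.default_rng(6)
        months = rng.exponential(10, 30)
        events = rng.random(30) < 0.7
        res = km_compare(self._strat(months, events, ["a"] * 30), "group")
        surv = res.curves["a"]["survival"].to_numpy()
        assert surv[0] == 1.0
        assert (np.diff(surv) <= 1e-12).all()

    def test_triple_high_group_longest_survival(self, small_cohort):
        truth = small_cohort.truth.set_index("sample_id")
        df = small_cohort.clinical.data.set_index("sample_id")
        df["group"] = np.where(
            (truth["true_csg"] == "CSG3")
            & (truth["true_wgii_regime"] == "high")
            & (truth["true_neo_regime"] == "high"),
            "triple_high",
            "rest",
        )
        strat = StratifiedCohort(df.reset_index(), 0.5, 2.0)
        res = km_compare(strat, "group")
        assert res.medians["triple_high"] > res.medians["rest"]


class TestCox:
    def _strat_from(self, df):
        return StratifiedCohort(df, 0.5, 2.0)

    def test_null_covariate_hr_near_one_with_coverage(self):
        """A binary covariate with no true effect: CI covers HR=1 in >=90%
        of 100 simulated datasets."""
        rng = np.random.default_rng(7)
        covered = 0
        for _ in range(100):
            n = 120
            x = rng.random(n) < 0.5
            df = pd.DataFrame(
                {
                    "sample_id": range(n),
                    "os_months": rng.exponential(10, n),
                    "os_event": True,
                    "x": x.astype(float),
                    "csg": "CSG1",
                }
            )
            res = cox_model(self._strat_from(df), SurvivalModelSpec(covariates=["x"]))
            row = res.summary.loc["x"]
            covered += row["hr_lower95"] <= 1.0 <= row["hr_upper95"]
        assert covered >= 90

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(8)
        n = 50
        x = rng.random(n)
        df = pd.DataFrame(
            {
                "sample_id": range(n),
                "os_months": rng.exponential(10, n),
                "os_event": True,
                "x1": x,
                "x2": x,
                "csg": "CSG1",
            }
        )
        with pytest.raises(ValidationError, match="collinear"):
            cox_model(self._strat_from(df), SurvivalModelSpec(covariates=["x1", "x2"]))

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame(
            {
                "sample_id": range(20),
                "os_months": np.linspace(1, 20, 20),
                "os_event": True,
                "x": 1.0,
                "csg": "CSG1",
            }
        )
        with pytest.raises(ValidationError, match="constant"):
            cox_model(self._strat_from(df), SurvivalModelSpec(covariates=["x"]))

    def test_interaction_recovered_from_synthetic_cohort(self):
        """n=800 with interaction log-HR -1.5: fitted three-way interaction
        HR < 1 at p < 0.05."""
        from csgtools.simulate import SimConfig, simulate_clinical, simulate_expression

        cfg = dataclasses.replace(SimConfig(), n_background_genes=0, seed=13)
        sim = simulate_expression(cfg)
        clin = simulate_clinical(cfg, sim.truth)
        truth = sim.truth.set_index("sample_id")
        df = clin.data.set_index("sample_id")
        df["csg"] = truth["true_csg"]
        df["wgii_high"] = (truth["true_wgii_regime"] == "high").astype(float)
        df["neo_high"] = (truth["true_neo_regime"] == "high").astype(float)
        spec = SurvivalModelSpec(
            covariates=["csg", "wgii_high", "neo_high"],
            interaction_terms=[("csg3", "wgii_high", "neo_high")],
        )
        res = cox_model(self._strat_from(df.reset_index()), spec)
        row = res.summary.loc["csg3_x_wgii_high_x_neo_high"]
        assert row["hr"] < 1
        assert row["p_value"] < 0.05


class TestMeta:
    def test_identical_types_pool_to_same_loghr(self):
        assert pool_fixed_effect([-1.0, -1.0], [0.5, 0.5]) == (
            pytest.approx(-1.0),
            pytest.approx(0.5 / np.sqrt(2)),
        )

    def test_tiny_se_type_dominates(self):
        pooled, _ = pool_fixed_effect([-2.0, 0.0], [0.001, 10.0])
        assert pooled == pytest.approx(-2.0, abs=1e-4)

    def test_pooled_variance_closed_form_three_types(self):
        log_hrs = np.array([-0.5, -1.2, 0.3])
        ses = np.array([0.4, 0.6, 0.8])
        pooled, se = pool_fixed_effect(log_hrs, ses)
        w = 1 / ses**2
        assert pooled == pytest.approx(float((w * log_hrs).sum() / w.sum()))
        assert se**2 == pytest.approx(1.0 / w.sum())

    def test_meta_by_type_on_synthetic_cohort(self, small_cohort):
        truth = small_cohort.truth.set_index("sample_id")
        df = small_cohort.clinical.data.set_index("sample_id")
        df["csg"] = truth["true_csg"]
        df["wgii_high"] = truth["true_wgii_regime"] == "high"
        df["neo_high"] = truth["true_neo_regime"] == "high"
        strat = StratifiedCohort(df.reset_index(), 0.5, 2.0)
        res = meta_by_type(strat, SurvivalModelSpec(covariates=["csg"]))
        assert set(res.pooled.index) == {"csg_CSG2", "csg_CSG3", "csg_CSG4"}
        # pooled estimates reproduce the closed form over the per-type fits
        for term, row in res.pooled.iterrows():
            grp = res.per_type[res.per_type["term"] == term]
            manual, _ = pool_fixed_effect(grp["log_hr"].to_numpy(), grp["se"].to_numpy())
            assert row["log_hr"] == pytest.approx(manual)
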