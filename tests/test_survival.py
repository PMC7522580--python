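"""Cox engine, Kaplan-Meier/log-rank, cohort splitting and the risk model."""

import numpy as np
import pandas as pd
import pytest

from lncsyn import survival as lsurv
from lncsyn.datatypes import ClinicalTable, ExpressionMatrix
from oracles import breslow_partial_loglik, logrank_oe


def _clinical(times, events, prefix="S"):
    return ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": [f"{prefix}{i}" for i in range(len(times))],
                "time": times,
                "event": events,
                "tissue": "tumor",
            }
        )
    )


class TestCoxUnivariate:
    def test_symmetric_groups_give_zero_coefficient(self):
        res = lsurv.cox_univariate(
            [1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1], [1, 1, 1, 0, 0, 0]
        )
        assert res.converged
        assert res.coef == pytest.approx(0.0, abs=1e-8)

    def test_six_subject_worked_set_matches_grid_search(self):
        # interleaved covariate keeps the partial likelihood concave with a
        # finite maximizer (a block covariate here would separate completely)
        time = [1, 2, 3, 4, 5, 6]
        event = [1] * 6
        x = [1, 0, 1, 0, 1, 0]
        res = lsurv.cox_univariate(time, event, x)
        grid = np.arange(-5, 5, 1e-4)
        lls = [breslow_partial_loglik(b, time, event, x) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert res.coef == pytest.approx(best, abs=1e-4)

    def test_parameter_recovery_from_exponential_survival(self):
        rng = np.random.default_rng(7)
        n = 500
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-1.0 * x))
        res = lsurv.cox_univariate(t, np.ones(n, dtype=int), x)
        assert res.converged
        assert res.coef == pytest.approx(1.0, abs=0.15)

    def test_matches_lifelines_on_seeded_datasets(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(0)
        for _ in range(5):
            n = int(rng.integers(40, 200))
            x = rng.normal(size=n)
            t = rng.exponential(np.exp(-0.7 * x))
            c = rng.exponential(np.median(t) * 2, n)
            time = np.minimum(t, c)
            event = (t <= c).astype(int)
            if event.sum() < 5:
                continue
            res = lsurv.cox_univariate(time, event, x)
            cph = CoxPHFitter().fit(
                pd.DataFrame({"t": time, "e": event, "x": x}), "t", "e",
                fit_options={"precision": 1e-9},
            )
            assert res.coef == pytest.approx(cph.params_["x"], abs=1e-4)
            assert res.se == pytest.approx(cph.standard_errors_["x"], rel=1e-3)

    def test_monotone_likelihood_reported_not_converged(self):
        # perfectly separating covariate: earliest deaths all have x = 1
        res = lsurv.cox_univariate(
            [1, 2, 3, 10, 11, 12], [1, 1, 1, 1, 1, 1], [1, 1, 1, 0, 0, 0], max_iter=200
        )
        assert not res.converged

    def test_too_few_events_raises(self):
        with pytest.raises(ValueError):
            lsurv.cox_univariate([1, 2, 3], [1, 0, 0], [1.0, 2.0, 3.0])


class TestKaplanMeierLogrank:
    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(size=50)
        km = lsurv.kaplan_meier(t, np.ones(50, dtype=int))
        for row in km.itertuples():
            empirical = (t > row.time).mean()
            assert row.survival == pytest.approx(empirical, abs=1e-12)

    def test_identical_groups_give_zero_chi2(self):
        chi2, p = lsurv.logrank_test(
            [1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1], list("aaabbb")
        )
        assert chi2 == 0.0
        assert p == 1.0

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(size=40)
        e = rng.integers(0, 2, 40)
        e[:4] = 1
        g = np.array(["a"] * 20 + ["b"] * 20)
        chi2_ab, _ = lsurv.logrank_test(t, e, g)
        chi2_ba, _ = lsurv.logrank_test(t, e, np.where(g == "a", "b", "a"))
        assert chi2_ab == pytest.approx(chi2_ba, abs=1e-12)

    def test_hand_computed_six_subject_example(self):
        """Separated groups: observed-minus-expected sums match a literal
        O-E loop to near machine precision."""
        time = [1, 2, 3, 4, 5, 6]
        event = [1] * 6
        group = ["a", "a", "a", "b", "b", "b"]
        chi2, _ = lsurv.logrank_test(time, event, group)
        oe, var = logrank_oe(time, event, [g == "a" for g in group])
        assert chi2 == pytest.approx(oe**2 / var, abs=1e-10)


class TestSplit:
    def test_hundred_samples_split_70_30(self):
        clin = _clinical(np.arange(1, 101, dtype=float), [1, 0] * 50)
        train, test = lsurv.split_train_test(clin, 0.7, seed=0)
        assert len(train) == 70 and len(test) == 30

    def test_same_seed_identical_partition(self):
        clin = _clinical(np.arange(1, 51, dtype=float), [1, 0] * 25)
        assert lsurv.split_train_test(clin, seed=5) == lsurv.split_train_test(clin, seed=5)

    def test_disjoint_and_exhaustive(self):
        clin = _clinical(np.arange(1, 44, dtype=float), ([1] * 30 + [0] * 13))
        train, test = lsurv.split_train_test(clin, 0.7, seed=1)
        assert set(train) & set(test) == set()
        assert set(train) | set(test) == set(clin.data["sample_id"])

    def test_stratification_preserves_event_balance(self):
        clin = _clinical(np.arange(1, 101, dtype=float), [1] * 40 + [0] * 60)
        train, _ = lsurv.split_train_test(clin, 0.7, seed=3)
        events = clin.data.set_index("sample_id").loc[train, "event"]
        assert events.sum() == 28  # 70% of the 40 events


class TestRiskModel:
    @staticmethod
    def _expr(values: dict, samples):
        df = pd.DataFrame(values, index=samples).T
        return ExpressionMatrix(df.astype(float), "lncRNA", log_scale=True)

    def test_published_style_coefficient_arithmetic(self):
        model = lsurv.RiskModel(
            terms=[("MEG3", 0.4933), ("ZEB1-AS1", 1.1077)], cutoff=0.0,
            training_sample_ids=[],
        )
        samples = ["s1", "s2"]
        expr = self._expr({"MEG3": [0.0, 1.0], "ZEB1-AS1": [0.0, 1.0]}, samples)
        scores = model.score(expr)
        assert scores["s1"] == pytest.approx(0.0)
        assert scores["s2"] == pytest.approx(1.6010, abs=1e-9)

    def test_affine_equivariance_of_scores(self):
        rng = np.random.default_rng(4)
        samples = [f"s{i}" for i in range(30)]
        expr = self._expr(
            {"A": rng.normal(5, 1, 30), "B": rng.normal(5, 1, 30)}, samples
        )
        model = lsurv.RiskModel(terms=[("A", 0.5), ("B", 1.1)], cutoff=0.0,
                                training_sample_ids=samples)
        base = model.score(expr)
        shifted = self._expr(
            {"A": expr.data.loc["A"] + 3.0, "B": expr.data.loc["B"]}, samples
        )
        np.testing.assert_allclose(model.score(shifted), base + 0.5 * 3.0)
        # median recomputed on shifted data leaves membership unchanged
        assert (base > base.median()).equals(
            model.score(shifted) > model.score(shifted).median()
        )

    def test_cutoff_is_training_median_and_boundary_is_low_risk(self):
        rng = np.random.default_rng(9)
        samples = [f"s{i}" for i in range(20)]
        x = rng.normal(5, 1, 20)
        expr = self._expr({"A": x, "B": rng.normal(5, 1, 20)}, samples)
        t = rng.exponential(np.exp(-(x - x.mean())), 20) * 100
        clin = _clinical(t, [1] * 20, prefix="s")
        clin.data["sample_id"] = samples
        clin = ClinicalTable(clin.data)
        model, fits = lsurv.build_risk_model(expr, clin, ["A", "B"], samples)
        scores = model.score(expr, samples)
        assert model.cutoff == pytest.approx(float(scores.median()))
        comp = lsurv.score_and_stratify(model, expr, clin, samples)
        at_cutoff = scores[scores == model.cutoff]
        for s in at_cutoff.index:
            assert comp.labels[s] == "low"

    def test_coefficient_recovery_on_synthetic_cohort(self):
        """Univariate coefficients on a large simulated cohort recover the
        generating betas."""
        from lncsyn.simulate import generate_dataset

        ds = generate_dataset(
            seed=21, n_samples=500, n_normal=0, missing_frac=0.0,
            n_lnc=10, n_mir=10, n_mrna=60, n_modules=3, module_size=5,
        )
        clin = ClinicalTable(ds.clinical.tumor())
        expr = ExpressionMatrix(
            ds.log_expression["lncRNA"], "lncRNA", log_scale=True
        )
        samples = list(clin.data["sample_id"])
        model, fits = lsurv.build_risk_model(expr, clin, list(ds.truth.risk_lnc_ids), samples)
        coefs = dict(model.terms)
        assert coefs[ds.truth.risk_lnc_ids[0]] == pytest.approx(ds.truth.betas[0], abs=0.2)
        assert coefs[ds.truth.risk_lnc_ids[1]] == pytest.approx(ds.truth.betas[1], abs=0.2)


class TestStratification:
    def test_planted_risk_model_separates_test_set(self, pipeline_products):
        ds = pipeline_products["dataset"]
        expr = pipeline_products["expr_lnc"]
        clin = ClinicalTable(ds.clinical.tumor())
        train, test = lsurv.split_train_test(clin, 0.7, seed=1)
        model, _ = lsurv.build_risk_model(expr, clin, list(ds.truth.risk_lnc_ids), train)
        comp = lsurv.score_and_stratify(model, expr, clin, test)
        assert comp.logrank_p < 0.05
        assert set(comp.labels.unique()) == {"high", "low"}

    def test_km_curves_non_increasing(self, pipeline_products):
        ds = pipeline_products["dataset"]
        expr = pipeline_products["expr_lnc"]
        clin = ClinicalTable(ds.clinical.tumor())
        train, _ = lsurv.split_train_test(clin, 0.7, seed=1)
        model, _ = lsurv.build_risk_model(expr, clin, list(ds.truth.risk_lnc_ids), train)
        comp = lsurv.score_and_stratify(model, expr, clin, train)
        for curve in comp.km_curves.values():
            assert (np.diff(curve["survival"]) <= 1e-12).all()


class TestExpressionGroups:
    def test_disjoint_supports_exact_p(self):
        samples = [f"s{i}" for i in range(6)]
        expr = ExpressionMatrix(
            pd.DataFrame({"G": [1, 2, 3, 10, 11, 12]}, index=samples).T.astype(float),
            "lncRNA",
        )
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=samples)
        _, p, med = lsurv.compare_expression_groups(expr, labels, "G")
        assert p == pytest.approx(2 / 20)  # 2 / C(6,3)
        assert med == {"a": 2.0, "b": 11.0}

    def test_identical_distributions_large_n(self):
        rng = np.random.default_rng(6)
        samples = [f"s{i}" for i in range(400)]
        expr = ExpressionMatrix(
            pd.DataFrame({"G": rng.normal(size=400)}, index=samples).T, "lncRNA"
        )
        labels = pd.Series(["a", "b"] * 200, index=samples)
        _, p, _ = lsurv.compare_expression_groups(expr, labels, "G")
        assert p > 0.2

    def test_tumor_shift_detected_in_simulated_data(self, pipeline_products):
        """The generator up-regulates the second risk lncRNA in tumors."""
        ds = pipeline_products["dataset"]
        expr = pipeline_products["expr_lnc"]
        labels = pd.Series(
            ds.clinical.data.set_index("sample_id")["tissue"]
        ).loc[expr.sample_ids]
        _, p_shift, med = lsurv.compare_expression_groups(
            expr, labels, ds.truth.risk_lnc_ids[1]
        )
        assert p_shift < 0.01
        assert med["tumor"] > med["normal"]
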