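"""MRP engine: poststratification algebra, HDI summaries, recovery, party
extension, error contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import mrpsup as m
from mrpsup.models import (
    ConvergenceError,
    FormulaSpec,
    PosteriorFit,
    PriorSpec,
    SamplerConfig,
    _build_design,
    load_fit,
    save_fit,
)


def _manual_ordinal_fit(beta, cutpoints, n_draws=200):
    """A deterministic single-coefficient probit 'posterior' (point mass),
    for checking the poststratification algebra in closed form."""
    formula = FormulaSpec(fixed=("x",), varying=(), interactions=())
    priors = PriorSpec()
    df = pd.DataFrame({"x": [0.0], "count": [1]})
    _, info, _ = _build_design(df, formula, {}, priors, False, check_levels=False)
    k = len(cutpoints) + 1
    return PosteriorFit(
        family="ordinal-probit", formula=formula, priors=priors,
        sampler=SamplerConfig(chains=1, draws=n_draws, seed=0),
        info=info, levels_map={}, outcome="item", k=k, categories=None,
        theta=np.full((1, n_draws, 1), beta),
        group_sd=np.empty((1, n_draws, 0)),
        cutpoints=np.tile(np.asarray(cutpoints, float), (1, n_draws, 1)),
        diagnostics={"rhat_max": 1.0, "ess_min": np.inf, "divergences": 0},
    )


def _expected_mean(beta, x, cutpoints):
    eta = beta * x
    cdf = norm.cdf(np.asarray(cutpoints) - eta)
    probs = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
    return probs @ np.arange(1, len(probs) + 1)


class TestPoststratifyAlgebra:
    def test_count_weighted_mean_of_cell_predictions(self):
        fit = _manual_ordinal_fit(beta=1.0, cutpoints=[-0.5, 0.5])
        table = m.PoststratTable(
            df=pd.DataFrame({"x": [-1.0, 1.0], "count": [100, 300]}),
            demographics=["x"],
        )
        est = m.poststratify(fit, table, estimand="mean_response")
        m1 = _expected_mean(1.0, -1.0, [-0.5, 0.5])
        m2 = _expected_mean(1.0, 1.0, [-0.5, 0.5])
        assert est.mean == pytest.approx((100 * m1 + 300 * m2) / 400, abs=1e-12)

    def test_uniform_counts_equal_unweighted_mean(self):
        fit = _manual_ordinal_fit(beta=0.7, cutpoints=[-1.0, 0.0, 1.0])
        xs = np.array([-1.5, -0.5, 0.5, 1.5])
        table = m.PoststratTable(
            df=pd.DataFrame({"x": xs, "count": [50, 50, 50, 50]}),
            demographics=["x"],
        )
        est = m.poststratify(fit, table, estimand="mean_response")
        expected = np.mean([_expected_mean(0.7, x, [-1.0, 0.0, 1.0]) for x in xs])
        assert est.mean == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_latent_effects(self):
        table = m.PoststratTable(
            df=pd.DataFrame({"x": [0.5, 1.0], "count": [10, 20]}),
            demographics=["x"],
        )
        means = [
            m.poststratify(
                _manual_ordinal_fit(beta=b, cutpoints=[-0.5, 0.5]), table,
                estimand="mean_response",
            ).mean
            for b in (0.0, 0.4, 0.8, 1.5)
        ]
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_category_probs_sum_to_one_per_draw(self):
        fit = _manual_ordinal_fit(beta=0.3, cutpoints=[-1.0, 0.2, 0.9])
        table = m.PoststratTable(
            df=pd.DataFrame({"x": [-1.0, 0.0, 2.0], "count": [5, 2, 3]}),
            demographics=["x"],
        )
        est = m.poststratify(fit, table)
        np.testing.assert_allclose(est.draws.sum(axis=1), 1.0, atol=1e-9)
        assert ((est.draws >= 0) & (est.draws <= 1)).all()

    def test_empty_table_rejected(self):
        fit = _manual_ordinal_fit(beta=0.0, cutpoints=[0.0])
        with pytest.raises(ValueError, match="empty"):
            m.poststratify(
                fit,
                m.PoststratTable(
                    df=pd.DataFrame({"x": [], "count": []}), demographics=["x"]
                ),
            )


class TestSummarizePosterior:
    def test_standard_normal_hdi(self):
        rng = np.random.default_rng(0)
        mean, (lo, hi) = m.summarize_posterior(rng.standard_normal(100_000))
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_symmetric_draws_match_equal_tail(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(2.0, 0.5, 50_000)
        _, (lo, hi) = m.summarize_posterior(draws)
        qlo, qhi = np.quantile(draws, [0.025, 0.975])
        assert lo == pytest.approx(qlo, abs=0.03)
        assert hi == pytest.approx(qhi, abs=0.03)

    def test_point_mass_zero_width(self):
        mean, (lo, hi) = m.summarize_posterior(np.full(500, 0.42))
        assert mean == lo == hi == 0.42

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            m.summarize_posterior(np.arange(50))


class TestFitContracts:
    def test_single_observed_level_rejected(self, small_table):
        roster = m.sample_respondents(small_table, 200, seed=0)
        roster["sex"] = "Female"
        ds = m.simulate_ordinal_responses(
            roster, m.TruthSpec(cutpoints=[-0.5, 0.5]), 3, seed=1
        )
        with pytest.raises(ValueError, match="single observed level"):
            m.fit_ordinal_mrp(ds, "item")

    def test_binary_scale_rejected(self, small_table):
        roster = m.sample_respondents(small_table, 100, seed=0)
        ds = m.simulate_ordinal_responses(roster, m.TruthSpec(cutpoints=[0.0]), 2,
                                          seed=1)
        with pytest.raises(ValueError, match="K >= 3"):
            m.fit_ordinal_mrp(ds, "item")

    def test_convergence_gate_raises(self, small_table):
        roster = m.sample_respondents(small_table, 200, seed=0)
        ds = m.simulate_ordinal_responses(
            roster, m.TruthSpec(cutpoints=[-0.5, 0.5]), 3, seed=1
        )
        strict = SamplerConfig(chains=2, draws=120, warmup=50, seed=0,
                               rhat_max=0.999)  # unattainable threshold
        with pytest.raises(ConvergenceError):
            m.fit_ordinal_mrp(ds, "item", sampler=strict)

    def test_degenerate_single_category_data(self, small_table, fast_sampler):
        roster = m.sample_respondents(small_table, 500, seed=2)
        ds = m.simulate_ordinal_responses(
            roster, m.TruthSpec(cutpoints=[-12.0, 12.0]), 3, seed=3
        )
        assert (ds.df["item"] == 2).all()
        fit = m.fit_ordinal_mrp(ds, "item", sampler=fast_sampler)
        est = m.poststratify(fit, small_table)
        assert est.mean[1] > 0.9


class TestNullRecovery:
    def test_poststratified_hdis_cover_closed_form_null(
        self, small_table, fast_sampler
    ):
        cuts = norm.ppf([0.2, 0.5, 0.8])
        truth = m.TruthSpec(cutpoints=cuts)
        roster = m.sample_respondents(small_table, 2000, seed=5)
        ds = m.simulate_ordinal_responses(roster, truth, 4, seed=6)
        fit = m.fit_ordinal_mrp(ds, "item", sampler=fast_sampler)
        est = m.poststratify(fit, small_table)
        true_probs = m.true_population_value(small_table, truth, "category_probs")
        covered = sum(
            lo <= p <= hi for (lo, hi), p in zip(est.hdi, true_probs)
        )
        assert covered >= 3  # at most one of four categories may miss

    def test_self_representative_table_matches_sample_mean(
        self, small_table, fast_sampler
    ):
        truth = m.default_truth(5, seed=77)
        roster = m.sample_respondents(small_table, 1500, seed=8)
        ds = m.simulate_ordinal_responses(roster, truth, 5, seed=9)
        fit = m.fit_ordinal_mrp(ds, "item", sampler=fast_sampler)
        demo = [c for c in roster.columns if c != "respondent_id"]
        sample_cells = (
            ds.df.groupby(demo, as_index=False, observed=True)
            .size().rename(columns={"size": "count"})
        )
        table = m.PoststratTable(
            df=sample_cells,
            demographics=small_table.demographics,
            cell_covariates=small_table.cell_covariates,
        )
        est = m.poststratify(fit, table, estimand="mean_response")
        sd = est.draws.std()
        assert abs(est.mean - ds.df["item"].mean()) <= max(3 * sd, 0.05)


class TestCategoricalFit:
    def test_balanced_null_three_categories(self, small_table, fast_sampler):
        roster = m.sample_respondents(small_table, 1200, seed=10)
        rng = np.random.default_rng(11)
        df = roster.copy()
        df["choice"] = rng.choice(["x", "y", "z"], len(df))
        ds = m.SurveyDataset(
            df=df, items={}, demographics=[], levels={"choice": ["x", "y", "z"]}
        )
        fit = m.fit_categorical_mrp(ds, "choice", sampler=fast_sampler)
        est = m.poststratify(fit, small_table)
        np.testing.assert_allclose(est.draws.sum(axis=1), 1.0, atol=1e-9)
        for (lo, hi), emp in zip(
            est.hdi, df["choice"].value_counts(normalize=True).sort_index()
        ):
            assert lo - 0.02 <= emp <= hi + 0.02
        for mu in est.mean:
            assert 0.28 < mu < 0.39


class TestPartyExtension:
    def _constant_party_fit(self, probs, formula=None, n_draws=150):
        """Intercept-only categorical 'posterior' with fixed probabilities."""
        probs = np.asarray(probs, float)
        formula = formula or FormulaSpec(fixed=(), varying=(), interactions=())
        priors = PriorSpec()
        df = pd.DataFrame({"count": [1]})
        _, info, _ = _build_design(df, formula, {}, priors, True,
                                   check_levels=False)
        intercepts = np.log(probs / probs[0])
        theta = np.zeros((1, n_draws, 1, len(probs)))
        theta[0, :, 0, :] = intercepts
        return PosteriorFit(
            family="categorical-logit", formula=formula, priors=priors,
            sampler=SamplerConfig(chains=1, draws=n_draws, seed=0),
            info=info, levels_map={}, outcome="party",
            k=len(probs), categories=["D", "I", "R"],
            theta=theta, group_sd=np.empty((1, n_draws, 0, len(probs) - 1)),
            cutpoints=None,
            diagnostics={"rhat_max": 1.0, "ess_min": np.inf, "divergences": 0},
        )

    def test_proportional_split_hand_example(self):
        fit = self._constant_party_fit([0.5, 0.3, 0.2])
        table = m.PoststratTable(
            df=pd.DataFrame({"cellid": ["c1"], "count": [100]}),
            demographics=["cellid"],
        )
        out = m.extend_table_with_party(table, fit)
        np.testing.assert_allclose(
            out.df["count"].to_numpy(), [50.0, 30.0, 20.0], atol=1e-9
        )

    def test_total_count_conserved(self, small_table):
        base = small_table.marginalize("party")
        fit = self._constant_party_fit([0.4, 0.35, 0.25])
        out = m.extend_table_with_party(base, fit)
        assert out.total == pytest.approx(base.total, rel=1e-9)
        assert len(out) == 3 * len(base)

    def test_synthetic_election_study_extension(
        self, small_spec, small_table, fast_sampler
    ):
        """End to end: learn party | demographics from an auxiliary sample
        drawn from the same truth, extend the party-less table, and check
        the implied party margin against the true table's margin."""
        aux = m.sample_respondents(small_table, 3000, seed=12)
        ds = m.SurveyDataset(
            df=aux.rename(columns={"party": "party_obs"}),
            items={}, demographics=[],
            levels={"party_obs": list(small_spec.party_model.parties)},
        )
        formula = FormulaSpec(
            fixed=("sex",), varying=("age_band", "education"), interactions=()
        )
        fit = m.fit_categorical_mrp(ds, "party_obs", formula=formula,
                                    sampler=fast_sampler)
        base = small_table.marginalize("party")
        out = m.extend_table_with_party(base, fit)
        assert out.total == pytest.approx(base.total, rel=1e-6)
        true_margin = (
            small_table.df.groupby("party")["count"].sum() / small_table.total
        )
        got_margin = out.df.groupby("party")["count"].sum() / out.total
        for p in true_margin.index:
            assert got_margin[p] == pytest.approx(true_margin[p], abs=0.04)

    def test_missing_factor_rejected(self, small_table):
        fit = self._constant_party_fit([0.5, 0.3, 0.2])
        fit.formula = FormulaSpec(
            fixed=("sex",), varying=("occupation",), interactions=()
        )
        base = small_table.marginalize("party")
        with pytest.raises(ValueError, match="occupation"):
            m.extend_table_with_party(base, fit)


class TestSerialization:
    def test_fit_roundtrip(self, tmp_path, small_table, fast_sampler):
        roster = m.sample_respondents(small_table, 300, seed=13)
        ds = m.simulate_ordinal_responses(
            roster, m.TruthSpec(cutpoints=[-0.6, 0.6]), 3, seed=14
        )
        fit = m.fit_ordinal_mrp(ds, "item", sampler=fast_sampler)
        save_fit(fit, str(tmp_path / "fit"))
        back = load_fit(str(tmp_path / "fit"))
        np.testing.assert_array_equal(back.theta, fit.theta)
        np.testing.assert_array_equal(back.cutpoints, fit.cutpoints)
        e1 = m.poststratify(fit, small_table, estimand="mean_response")
        e2 = m.poststratify(back, small_table, estimand="mean_response")
        assert e1.mean == pytest.approx(e2.mean)
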