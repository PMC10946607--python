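"""Quasi-GLMs, model selection, interaction models, median split,
correlation and assortative-mating ANOVA."""

import numpy as np
import pandas as pd
import pytest

from polyprec import (
    SimulationParams,
    assortative_test,
    fit_order_glm,
    fit_repeat_glm,
    interaction_models,
    median_split,
    order_repeat_correlation,
    pairwise_contrasts,
    score_dataset,
    select_model,
    simulate_experiment,
)
from polyprec.errors import DegenerateInputError, FittingError


def make_scores(order, ps, repeat=None, social=None, size=None, fec=None, exp="M"):
    n = len(order)
    return pd.DataFrame(
        {
            "vial": [f"v{i}" for i in range(n)],
            "order_index": order,
            "paternity_share": ps,
            "repetitive_count": repeat if repeat is not None else np.arange(n) % 4 + 1,
            "n_female_days": [6] * n,
            "group_mean_fecundity": fec if fec is not None else np.full(n, 50.0),
            "mate_mean_fecundity": fec if fec is not None else np.full(n, 50.0),
            "social": social if social is not None else ["Het", "Hom"] * (n // 2),
            "focal_size": size if size is not None else ["large", "small"] * (n // 2),
            "experiment": exp,
        }
    )


@pytest.fixture(scope="module")
def m_scores():
    ds = simulate_experiment("M", n_het=20, n_hom=10, rng=np.random.default_rng(17))
    return score_dataset(ds)


class TestQuasiGLMs:
    def test_order_glm_table_shape(self, m_scores):
        table = fit_order_glm(m_scores)
        assert set(table.terms["term"]) == {
            "C(social)",
            "C(focal_size)",
            "C(social):C(focal_size)",
            "group_mean_fecundity",
        }
        assert table.dispersion > 0
        assert ((table.terms["p"] >= 0) & (table.terms["p"] <= 1)).all()
        assert (table.terms["F"] >= 0).all()
        assert "quasi-binomial" in table.family

    def test_repeat_glm_runs(self, m_scores):
        table = fit_repeat_glm(m_scores)
        assert table.family == "quasi-Poisson"
        assert table.dispersion > 0

    def test_size_effect_recovered_under_strong_advantage(self):
        """A 2:1 large-male courtship advantage shows up as a lower order
        index for small focal males where sizes compete within vials (Het
        groups): the model coefficient and the cell means agree in direction.
        """
        params = SimulationParams(male_weight_large=2.0, male_weight_small=1.0)
        ds = simulate_experiment("M", n_het=40, n_hom=20,
                                 params=params, rng=np.random.default_rng(5))
        scores = score_dataset(ds)
        het = scores[scores["social"] == "Het"]
        assert (
            het[het["focal_size"] == "large"]["order_index"].mean()
            > het[het["focal_size"] == "small"]["order_index"].mean()
        )
        table = fit_order_glm(scores)
        # treatment coding with Het as reference: the focal-size coefficient
        # is the within-Het simple effect, negative for small focal males
        assert table.coef("focal_size") < 0

    def test_constant_response_raises(self, m_scores):
        const = m_scores.copy()
        const["order_index"] = 0.5
        with pytest.raises(FittingError):
            fit_order_glm(const)

    def test_weighted_fit_runs(self, m_scores):
        table = fit_order_glm(m_scores, weight_by_days=True)
        assert table.dispersion > 0


class TestSelectModel:
    TERMS = ["C(social)", "C(focal_size)", "C(social):C(focal_size)",
             "group_mean_fecundity"]

    def test_single_term_model_unchanged(self, m_scores):
        final, trace = select_model(
            m_scores, "order_index", ["C(social)"], family="binomial"
        )
        assert final == ["C(social)"]
        assert len(trace) == 1

    def test_hierarchy_respected(self, m_scores):
        final, trace = select_model(
            m_scores, "order_index", self.TERMS, family="binomial"
        )
        # a main effect is never dropped while its interaction is retained
        for step in trace:
            if step["dropped"] in ("C(social)", "C(focal_size)"):
                assert "C(social):C(focal_size)" not in step["terms"] + [step["dropped"]]
        if "C(social):C(focal_size)" in final:
            assert {"C(social)", "C(focal_size)"} <= set(final)

    def test_criterion_decreases_along_trace(self, m_scores):
        _, trace = select_model(
            m_scores, "repetitive_count", self.TERMS, family="poisson",
            criterion="qaic",
        )
        crits = [s["criterion"] for s in trace]
        assert all(b < a for a, b in zip(crits, crits[1:]))


class TestInteractionModels:
    def test_tables_per_experiment(self, m_scores):
        out = interaction_models(m_scores)
        assert set(out) == {("M", "order"), ("M", "repeat")}
        order_table = out[("M", "order")]
        assert "order_std" in set(order_table.terms["term"])
        assert "order_std:C(social)" in set(order_table.terms["term"])

    def test_order_main_effect_is_strong(self, m_scores):
        out = interaction_models(m_scores)
        assert out[("M", "order")].p_of("order_std") < 0.001

    def test_single_social_level_raises(self, m_scores):
        sub = m_scores[m_scores["social"] == "Het"]
        with pytest.raises(DegenerateInputError):
            interaction_models(sub)


class TestMedianSplit:
    def test_arithmetic_oracle(self):
        scores = make_scores(
            order=[0.2, 0.4, 0.6, 0.8], ps=[0.1, 0.3, 0.7, 0.9],
            social=["Hom"] * 4, size=["large"] * 4,
        )
        out = median_split(scores, by=["social"])
        low = out[out["side"] == "<= median"].iloc[0]
        high = out[out["side"] == "> median"].iloc[0]
        assert low["mean_paternity_share"] == pytest.approx(0.2)
        assert high["mean_paternity_share"] == pytest.approx(0.8)
        assert low["n"] == high["n"] == 2
        assert low["se"] == pytest.approx(np.std([0.1, 0.3], ddof=1) / np.sqrt(2))

    def test_ties_go_to_lower_side(self):
        scores = make_scores(
            order=[0.4, 0.4, 0.4, 0.8], ps=[0.2, 0.2, 0.2, 0.9],
            social=["Hom"] * 4, size=["large"] * 4,
        )
        out = median_split(scores, by=["social"])
        assert out[out["side"] == "<= median"]["n"].iloc[0] == 3

    def test_pooled_mean_reconstructs_grand_mean(self, m_scores):
        out = median_split(m_scores)
        for (exp, soc), grp in out.groupby(["experiment", "social"]):
            sub = m_scores.dropna(subset=["order_index", "paternity_share"])
            sub = sub[(sub["experiment"] == exp) & (sub["social"] == soc)]
            pooled = (grp["mean_paternity_share"] * grp["n"]).sum() / grp["n"].sum()
            assert pooled == pytest.approx(sub["paternity_share"].mean(), abs=1e-12)

    def test_constant_index_yields_one_sided_output(self):
        scores = make_scores(
            order=[0.5] * 4, ps=[0.2, 0.4, 0.6, 0.8],
            social=["Hom"] * 4, size=["large"] * 4,
        )
        out = median_split(scores, by=["social"])
        assert list(out["side"]) == ["<= median"]
        assert out["n"].iloc[0] == 4


class TestCorrelation:
    def test_identical_vectors(self):
        scores = make_scores(order=[0.1, 0.2, 0.3, 0.4], ps=[0.5] * 4,
                             repeat=[1, 2, 3, 4])
        r, p = order_repeat_correlation(scores)
        assert r == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        scores = make_scores(order=[0.1, 0.1, 0.3, 0.3], ps=[0.5] * 4,
                             repeat=[1, 2, 2, 1])
        r, _ = order_repeat_correlation(scores)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form(self, m_scores):
        r, _ = order_repeat_correlation(m_scores)
        sub = m_scores.dropna(subset=["order_index", "repetitive_count"])
        x = sub["order_index"].to_numpy()
        y = sub["repetitive_count"].to_numpy(dtype=float)
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_raises(self):
        scores = make_scores(order=[0.5] * 4, ps=[0.5] * 4, repeat=[2, 3, 1, 4])
        with pytest.raises(DegenerateInputError):
            order_repeat_correlation(scores)


class TestAssortative:
    def test_m_experiment_is_degenerate(self):
        ds = simulate_experiment("M", n_het=2, n_hom=1, rng=np.random.default_rng(0))
        with pytest.raises(DegenerateInputError):
            assortative_test(ds, "M")

    def test_f_and_fm_tables(self):
        rng = np.random.default_rng(14)
        ds_f = simulate_experiment("F", n_het=6, n_hom=4, rng=rng)
        table_f = assortative_test(ds_f, "F")
        assert "C(female_size)" in set(table_f.terms["term"])
        ds_fm = simulate_experiment("FM", n_het=8, n_hom=4, rng=rng)
        table_fm = assortative_test(ds_fm, "FM")
        assert "C(female_size):C(focal_size)" in set(table_fm.terms["term"])
        assert ((table_fm.terms["p"] >= 0) & (table_fm.terms["p"] <= 1)).all()


class TestPairwise:
    def test_holm_correction_monotone(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(
            {
                "y": np.concatenate(
                    [rng.normal(0, 1, 10), rng.normal(2, 1, 10), rng.normal(0.2, 1, 10)]
                ),
                "g": ["a"] * 10 + ["b"] * 10 + ["c"] * 10,
            }
        )
        out = pairwise_contrasts(data, "y", "g")
        assert len(out) == 3
        assert (out["p_holm"] >= out["p_raw"] - 1e-12).all()

    def test_single_level_raises(self):
        data = pd.DataFrame({"y": [1.0, 2.0], "g": ["a", "a"]})
        with pytest.raises(DegenerateInputError):
            pairwise_contrasts(data, "y", "g")
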