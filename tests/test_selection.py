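"""Candidate enumeration, AIC ranking and conditional model averaging."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from nectarweb.formula import interaction, linear, quadratic
from nectarweb.glmm import fit_glmm
from nectarweb.selection import (
    build_term_sets,
    community_term_pool,
    conditional_average,
    rank_by_aic,
)
from nectarweb.multithreshold import multithreshold_term_pool


class TestEnumeration:
    def test_single_predictor_linear_quadratic(self):
        pool = [linear("a"), quadratic("a")]
        sets = build_term_sets(pool, marginality=True)
        assert [tuple(t.name for t in s) for s in sets] == [(), ("a",), ("a", "a^2")]

    def test_three_linear_predictors_power_set(self):
        pool = community_term_pool(include_quadratic=False, include_interactions=False)
        assert len(build_term_sets(pool)) == 8

    def test_full_nine_predictor_pool(self):
        # quadratics need their linear term; interactions need both mains
        assert len(build_term_sets(community_term_pool())) == 95

    def test_marginality_off_gives_full_power_set(self):
        pool = [linear("a"), quadratic("a")]
        assert len(build_term_sets(pool, marginality=False)) == 4

    def test_cap_excludes_large_models(self):
        pool = community_term_pool()
        capped = build_term_sets(pool, max_terms=5)
        assert all(len(s) <= 5 for s in capped)
        assert max(len(s) for s in build_term_sets(pool)) == 9

    def test_threshold_pool_interactions_require_constituents(self):
        pool = multithreshold_term_pool()
        sets = build_term_sets(pool, max_terms=5)
        for s in sets:
            names = {t.name for t in s}
            if "fdis^2:threshold" in names:
                assert {"threshold", "fdis", "fdis^2"} <= names


def _toy_entries(aics):
    """Fabricate ranked entries by refitting intercept models is overkill;
    instead fit once and patch AICs to the requested values."""
    rng = np.random.default_rng(0)
    n, strips = 12, np.repeat([1, 2, 3], 4)
    m = np.full(n, 30)
    y = rng.binomial(m, 0.4, n)
    entries = []
    for i, a in enumerate(aics):
        terms = () if i == 0 else tuple(linear(f"v{j}") for j in range(i))
        X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in terms])
        f = fit_glmm(X, y, strips, trials=m, names=["(Intercept)"] + [t.name for t in terms],
                     terms=terms, restarts=1)
        f.aic = a
        entries.append((terms, f))
    return entries


class TestRanking:
    def test_equal_aic_half_weights(self):
        ranked = rank_by_aic(_toy_entries([100.0, 100.0]))
        assert np.allclose(ranked["weight"], 0.5)

    def test_strict_delta_boundary(self):
        ranked = rank_by_aic(_toy_entries([10.0, 12.0]))
        assert ranked["selected"].tolist() == [True, False]  # delta == 2 excluded

    def test_weights_sum_to_one(self):
        ranked = rank_by_aic(_toy_entries([10.0, 11.0, 13.5, 20.0]))
        assert ranked["weight"].sum() == pytest.approx(1.0)


def _fit_sets(d, y, m, strips, term_sets):
    from nectarweb.formula import design_matrix

    entries = []
    for terms in term_sets:
        X, names = design_matrix(d, list(terms))
        entries.append(
            (terms, fit_glmm(X, y, strips, trials=m, names=names, terms=terms, restarts=1))
        )
    return entries


@pytest.fixture(scope="module")
def sim():
    rng = np.random.default_rng(21)
    n, strips = 27, np.repeat([1, 2, 3], 9)
    d = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    m = rng.integers(30, 120, n)
    y = rng.binomial(m, expit(-1 + 0.8 * d["a"].to_numpy()))
    return d, y, m, strips


class TestAveraging:

    def test_single_model_averaging_is_identity(self, sim):
        d, y, m, strips = sim
        entries = _fit_sets(d, y, m, strips, [(linear("a"),)])
        avg = conditional_average(rank_by_aic(entries))
        f = entries[0][1]
        assert avg.terms.loc["a", "estimate"] == pytest.approx(f.beta[1])
        assert avg.terms.loc["a", "se"] == pytest.approx(f.se[1])
        assert avg.terms.loc["a", "importance"] == pytest.approx(1.0)
        assert avg.terms.loc["(Intercept)", "estimate"] == pytest.approx(f.beta[0])

    def test_hand_average_two_members(self):
        entries = _toy_entries([10.0, 10.0])
        # both models share no term except the intercept; patch in a shared
        # coefficient by hand on copies of the fits
        ranked = rank_by_aic(entries)
        avg = conditional_average(ranked)
        # weights renormalize to 0.5/0.5 and the intercept averages across both
        assert np.allclose(avg.members["weight"], 0.5)
        b0s = [f.beta[0] for _, f in entries]
        assert avg.terms.loc["(Intercept)", "estimate"] == pytest.approx(np.mean(b0s))

    def test_conditional_rule_and_importance(self, sim):
        d, y, m, strips = sim
        term_sets = build_term_sets([linear("a"), linear("b")])
        entries = _fit_sets(d, y, m, strips, term_sets)
        ranked = rank_by_aic(entries)
        avg = conditional_average(ranked)
        fits = ranked.attrs["fits"]
        sel = ranked[ranked["selected"]]
        w = (sel["weight"] / sel["weight"].sum()).to_numpy()
        # recompute the conditional average for 'a' independently
        est, wts = [], []
        for wm, mid in zip(w, sel["model_id"]):
            terms, f = fits[mid]
            names = [t.name for t in terms]
            if "a" in names:
                est.append(f.beta[f.names.index("a")])
                wts.append(wm)
        expected = np.average(est, weights=wts)
        assert avg.terms.loc["a", "estimate"] == pytest.approx(expected)
        assert avg.terms.loc["a", "importance"] == pytest.approx(np.sum(wts))

    def test_adjusted_se_formula(self, sim):
        d, y, m, strips = sim
        term_sets = build_term_sets([linear("a"), linear("b")])
        entries = _fit_sets(d, y, m, strips, term_sets)
        ranked = rank_by_aic(entries)
        avg = conditional_average(ranked)
        fits = ranked.attrs["fits"]
        sel = ranked[ranked["selected"]]
        w = (sel["weight"] / sel["weight"].sum()).to_numpy()
        est, ses, wts = [], [], []
        for wm, mid in zip(w, sel["model_id"]):
            terms, f = fits[mid]
            names = [t.name for t in terms]
            if "a" in names:
                j = f.names.index("a")
                est.append(f.beta[j]); ses.append(f.se[j]); wts.append(wm)
        est, ses, wts = map(np.asarray, (est, ses, wts))
        wc = wts / wts.sum()
        bbar = wc @ est
        se_exp = wc @ np.sqrt(ses**2 + (est - bbar) ** 2)
        assert avg.terms.loc["a", "se"] == pytest.approx(se_exp)

    def test_enumeration_order_invariance(self, sim):
        d, y, m, strips = sim
        term_sets = build_term_sets([linear("a"), linear("b")])
        e1 = _fit_sets(d, y, m, strips, term_sets)
        e2 = _fit_sets(d, y, m, strips, term_sets[::-1])
        a1 = conditional_average(rank_by_aic(e1)).terms.sort_index()
        a2 = conditional_average(rank_by_aic(e2)).terms.sort_index()
        pd.testing.assert_frame_equal(a1, a2, atol=1e-10, rtol=0)

    def test_empty_selection_raises(self):
        ranked = rank_by_aic(_toy_entries([10.0, 11.0]))
        ranked["selected"] = False
        with pytest.raises(ValueError, match="empty confidence set"):
            conditional_average(ranked)


def test_full_set_importance_option(sim):
    d, y, m, strips = sim
    term_sets = build_term_sets([linear("a"), linear("b")])
    entries = _fit_sets(d, y, m, strips, term_sets)
    ranked = rank_by_aic(entries)
    avg_full = conditional_average(ranked, importance_full_set=True)
    fits = ranked.attrs["fits"]
    expected = sum(
        row["weight"]
        for _, row in ranked.iterrows()
        if "a" in [t.name for t in fits[row["model_id"]][0]]
    )
    assert avg_full.terms.loc["a", "importance"] == pytest.approx(expected)
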