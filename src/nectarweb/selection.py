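"""All-subsets candidate models, AIC ranking and conditional model averaging.

The candidate set for the community analyses is every admissible additive
combination of nine predictors: linear and quadratic terms of the three
community descriptors (accessible-nectar cover, species richness, functional
dispersion) plus the three pairwise interactions of the linear terms.  With
marginality enforced (a quadratic requires its linear term, an interaction
requires both mains) this yields 95 candidate models.

Models are ranked by AIC; Akaike weights are
``w_m = exp(-delta_m / 2) / sum exp(-delta / 2)``.  Models with
``delta AIC < 2`` (strictly) form the confidence set; coefficients are
conditionally averaged over the members containing each term with weights
renormalized within those members, using the revised unconditional-variance
estimator for the adjusted SE.  A term's importance is the summed
(renormalized) weight of the selected models that contain it.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .formula import (
    INTERCEPT_NAME,
    Term,
    dominates,
    formula_label,
    interaction,
    linear,
    quadratic,
)
from .glmm import GlmmFit

__all__ = [
    "community_term_pool",
    "build_term_sets",
    "rank_by_aic",
    "conditional_average",
    "AveragedModel",
]

logger = logging.getLogger(__name__)


def community_term_pool(
    predictors: tuple[str, ...] = ("nectar", "richness", "fdis"),
    include_quadratic: bool = True,
    include_interactions: bool = True,
) -> list[Term]:
    """The standard nine-term pool over the three community predictors."""
    pool: list[Term] = [linear(v) for v in predictors]
    if include_quadratic:
        pool += [quadratic(v) for v in predictors]
    if include_interactions:
        pool += [interaction(a, b) for a, b in itertools.combinations(predictors, 2)]
    return pool


def build_term_sets(
    pool: list[Term],
    marginality: bool = True,
    max_terms: int | None = None,
) -> list[tuple[Term, ...]]:
    """Enumerate admissible term combinations from a pool, in a
    deterministic order (by size, then pool order).

    With ``marginality`` on, a combination containing a term must contain
    every lower-order pool term it dominates (quadratic needs its linear
    term, interactions need their constituents).  ``max_terms`` caps the
    number of fixed-effect terms per model (the intercept-only model is
    always included).
    """
    requires = {
        t: frozenset(s for s in pool if dominates(t, s)) for t in pool
    }
    out: list[tuple[Term, ...]] = []
    npool = len(pool)
    for size in range(0, npool + 1):
        if max_terms is not None and size > max_terms:
            break
        for combo in itertools.combinations(range(npool), size):
            terms = tuple(pool[i] for i in combo)
            if marginality:
                have = frozenset(terms)
                if any(not requires[t] <= have for t in terms):
                    continue
            out.append(terms)
    return out


def rank_by_aic(
    entries: list[tuple[tuple[Term, ...], GlmmFit]],
    delta_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Rank fitted candidate models by AIC and attach Akaike weights.

    Non-converged fits are dropped (logged).  The confidence set is
    ``delta AIC < delta_cutoff`` with a strict inequality.
    """
    dropped = sum(1 for _, f in entries if not f.converged)
    if dropped:
        logger.warning("dropping %d non-converged candidate models", dropped)
    entries = [(t, f) for t, f in entries if f.converged]
    if not entries:
        raise ValueError("no converged candidate models to rank")
    rows = []
    for idx, (terms, f) in enumerate(entries):
        rows.append(
            {
                "model_id": idx,
                "formula": formula_label(terms),
                "n_terms": len(terms),
                "k": f.k,
                "loglik": f.loglik,
                "aic": f.aic,
            }
        )
    table = pd.DataFrame(rows)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    rel = np.exp(-0.5 * table["delta_aic"].to_numpy())
    table["weight"] = rel / rel.sum()
    table["selected"] = table["delta_aic"] < delta_cutoff
    table = table.sort_values(["aic", "model_id"], kind="stable").reset_index(drop=True)
    table.attrs["fits"] = {row.model_id: entries[row.model_id] for row in table.itertuples()}
    return table


@dataclass
class AveragedModel:
    """Conditional model-averaged coefficients over the AIC confidence set."""

    terms: pd.DataFrame  # index term name: estimate, se, z, p, importance
    members: pd.DataFrame  # formula, aic, delta_aic, weight (renormalized)
    best_terms: tuple[Term, ...]
    best_fit: GlmmFit

    def coefficient(self, name: str) -> float:
        return float(self.terms.loc[name, "estimate"])


def conditional_average(ranked: pd.DataFrame, importance_full_set: bool = False) -> AveragedModel:
    """Average the ``delta AIC < 2`` confidence set conditionally per term.

    Per term: the estimate averages member-model estimates with weights
    renormalized over members containing the term; the adjusted SE is the
    revised unconditional-variance estimator
    ``sum_m w_m * sqrt(se_m^2 + (b_m - b_avg)^2)``; importance is the summed
    renormalized weight of selected members containing the term, or — with
    ``importance_full_set`` — the summed raw Akaike weight of *all* ranked
    models containing it.
    """
    fits: dict[int, tuple[tuple[Term, ...], GlmmFit]] = ranked.attrs["fits"]
    sel = ranked[ranked["selected"]]
    if len(sel) == 0:
        raise ValueError("empty confidence set")
    w = sel["weight"].to_numpy()
    w = w / w.sum()  # renormalize within the selected set
    members = sel[["formula", "k", "loglik", "aic", "delta_aic"]].copy()
    members["weight"] = w
    members = members.reset_index(drop=True)

    sel_models = [fits[mid] for mid in sel["model_id"]]
    # the intercept is present in every member and averages like any term
    term_names: list[str] = [INTERCEPT_NAME]
    for terms, _ in sel_models:
        for t in terms:
            if t.name not in term_names:
                term_names.append(t.name)

    rows = []
    for name in term_names:
        est, ses, wts = [], [], []
        for (terms, f), wm in zip(sel_models, w):
            tnames = [t.name for t in terms] + [INTERCEPT_NAME]
            if name in tnames:
                j = f.names.index(name)
                est.append(f.beta[j])
                ses.append(f.se[j])
                wts.append(wm)
        est = np.asarray(est)
        ses = np.asarray(ses)
        wts = np.asarray(wts)
        if importance_full_set:
            importance = 0.0
            for _, row in ranked.iterrows():
                terms, _f = fits[row["model_id"]]
                if name in [t.name for t in terms] + [INTERCEPT_NAME]:
                    importance += float(row["weight"])
        else:
            importance = float(wts.sum())
        wc = wts / wts.sum()
        b_avg = float(wc @ est)
        se_adj = float(wc @ np.sqrt(ses**2 + (est - b_avg) ** 2))
        z = abs(b_avg) / se_adj if se_adj > 0 else np.inf
        p = 2.0 * float(special.ndtr(-z))
        rows.append((name, b_avg, se_adj, z, p, importance))
    terms_df = pd.DataFrame(
        rows, columns=["term", "estimate", "se", "z", "p", "importance"]
    ).set_index("term")
    best_terms, best_fit = sel_models[0]
    return AveragedModel(terms_df, members, best_terms, best_fit)
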