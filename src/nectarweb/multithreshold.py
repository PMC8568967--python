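"""Multi-threshold multi-species parasitism.

Rather than averaging non-substitutable parasitism rates across herbivores,
multi-species parasitism counts, per plot, how many herbivores' parasitism
rates exceed a threshold fraction tau of that herbivore's reference maximum
(mean of its three highest recorded plot-level rates), with tau swept from
0.10 to 0.90 in steps of 0.10.  The resulting plot x threshold counts are
modelled as Poisson GLMMs (strip random intercept) whose candidate fixed
effects combine the community predictors with the threshold and
threshold-by-predictor interactions, capped at five fixed-effect variables
per model.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .formula import Term, interaction, linear, quadratic
from .glmm import fit_glmm_terms
from .selection import AveragedModel, build_term_sets, conditional_average, rank_by_aic

__all__ = [
    "DEFAULT_THRESHOLDS",
    "herbivore_maxima",
    "multispecies_counts",
    "multithreshold_term_pool",
    "fit_multithreshold",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.1, 0.91, 0.1), 10))


def _plot_rates(table: pd.DataFrame, distance: float) -> pd.DataFrame:
    """Plot x herbivore parasitism rates at one distance (counts pooled)."""
    sub = table[table["distance_m"] == distance]
    if len(sub) == 0:
        raise ValueError(f"no parasitism records at distance {distance}")
    agg = sub.groupby(["plot", "herbivore"], sort=True)[
        ["n_parasitized", "n_examined"]
    ].sum()
    bad = agg["n_parasitized"] > agg["n_examined"]
    if bad.any():
        raise ValueError("n_parasitized exceeds n_examined")
    agg = agg[agg["n_examined"] > 0]
    rates = (agg["n_parasitized"] / agg["n_examined"]).rename("rate")
    return rates.reset_index()


def herbivore_maxima(table: pd.DataFrame, distance: float) -> pd.Series:
    """Per-herbivore reference maximum: mean of the 3 highest plot rates.

    Computed per herbivore at one distance.  With fewer than three recorded
    rates the mean of what exists is used, with a warning.
    """
    rates = _plot_rates(table, distance)
    out = {}
    for herb, grp in rates.groupby("herbivore", sort=True):
        vals = np.sort(grp["rate"].to_numpy())[::-1]
        if len(vals) < 3:
            warnings.warn(
                f"herbivore {herb!r} has only {len(vals)} rates at {distance} m; "
                "reference maximum uses all of them"
            )
        out[herb] = float(vals[:3].mean())
    return pd.Series(out, name="reference_max")


def multispecies_counts(
    table: pd.DataFrame,
    distance: float,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    complete_only: bool = True,
    maxima: pd.Series | None = None,
) -> pd.DataFrame:
    """Long plot x threshold table of multi-species parasitism counts.

    ``count(plot, tau)`` is the number of herbivores whose local rate is
    strictly greater than ``tau * reference_max``.  By default only plots
    with a rate recorded for every herbivore contribute
    (``complete_only=False`` counts over the available herbivores instead).
    Ties with the threshold value are logged.
    """
    rates = _plot_rates(table, distance)
    herbivores = sorted(rates["herbivore"].unique())
    if maxima is None:
        maxima = herbivore_maxima(table, distance)
    wide = rates.pivot(index="plot", columns="herbivore", values="rate")
    if complete_only:
        complete = wide.dropna()
        dropped = len(wide) - len(complete)
        if dropped:
            logger.info("dropping %d incomplete plots at %s m", dropped, distance)
        wide = complete
    strip_of = (
        table[table["distance_m"] == distance]
        .drop_duplicates("plot")
        .set_index("plot")["strip"]
        if "strip" in table.columns
        else None
    )
    rows = []
    n_ties = 0
    ref = maxima.reindex(wide.columns).to_numpy()
    for plot, r in wide.iterrows():
        rv = r.to_numpy(dtype=float)
        present = ~np.isnan(rv)
        for tau in thresholds:
            cut = tau * ref
            n_ties += int(np.sum(rv[present] == cut[present]))
            count = int(np.sum(rv[present] > cut[present]))
            rows.append(
                {
                    "plot": plot,
                    "strip": None if strip_of is None else strip_of.get(plot),
                    "threshold": float(tau),
                    "count": count,
                }
            )
    if n_ties:
        logger.info("%d rate values tied exactly with a threshold cut", n_ties)
    out = pd.DataFrame(rows)
    out.attrs["herbivores"] = herbivores
    out.attrs["reference_maxima"] = maxima
    return out


def multithreshold_term_pool(
    predictors: tuple[str, ...] = ("nectar", "richness", "fdis"),
    threshold_var: str = "threshold",
) -> list[Term]:
    """Community predictors (linear + quadratic), threshold, and
    threshold-by-predictor interactions (with linear and quadratic terms)."""
    pool: list[Term] = [linear(v) for v in predictors]
    pool += [quadratic(v) for v in predictors]
    pool.append(linear(threshold_var))
    pool += [interaction(threshold_var, v) for v in predictors]
    pool += [Term(tuple(sorted(((threshold_var, 1), (v, 2))))) for v in predictors]
    return pool


def fit_multithreshold(
    dataset: pd.DataFrame,
    covariates: pd.DataFrame,
    predictors: tuple[str, ...] = ("nectar", "richness", "fdis"),
    max_terms: int = 5,
    restarts: int = 1,
    standardize: bool = True,
) -> tuple[AveragedModel, pd.DataFrame]:
    """Model the multi-species counts against community structure.

    Merges the plot-level covariates into the plot x threshold dataset,
    z-scores every explanatory variable (threshold included), enumerates the
    candidate term sets (marginality on, at most ``max_terms`` fixed-effect
    variables), fits Poisson GLMMs with the strip as random intercept, and
    returns the conditional averaged model together with the ranked table.
    """
    if len(dataset) == 0:
        raise ValueError("empty multi-threshold dataset")
    data = dataset.merge(covariates, left_on="plot", right_index=True, how="inner")
    if len(data) == 0:
        raise ValueError("no overlap between dataset plots and covariates")
    data = data.sort_values(["plot", "threshold"], kind="stable").reset_index(drop=True)
    cols = list(predictors) + ["threshold"]
    if standardize:
        for c in cols:
            v = data[c].to_numpy(dtype=float)
            sd = v.std()
            data[c] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    pool = multithreshold_term_pool(predictors)
    term_sets = build_term_sets(pool, marginality=True, max_terms=max_terms)
    entries = []
    for terms in term_sets:
        try:
            f = fit_glmm_terms(
                data, terms, response="count", group="strip", family="poisson",
                restarts=restarts,
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("candidate %s failed: %s", terms, exc)
            continue
        entries.append((terms, f))
    ranked = rank_by_aic(entries)
    return conditional_average(ranked), ranked
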