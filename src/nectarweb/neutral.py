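"""Neutral randomization of plant-parasitoid interactions.

Validates the mechanistic trait-matching covariate by rebuilding the
accessible-nectar cover from randomly chosen plant species instead of the
trait-matched set, keeping the number of interacting species constant.  Two
pools are supported: species in flower during the parasitoid's activity
(tests the morphological match only) and all species present in the
community (tests the temporal and morphological match together).  Per
iteration the covariate is recomputed, re-standardized and the reference
model formula refitted; the observed model's AIC is compared with the mean
AIC of the neutral models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .formula import Term, design_matrix
from .glmm import GlmmFit, fit_glmm

__all__ = ["NeutralConfig", "NeutralReport", "neutral_draw", "neutral_aic_comparison"]

logger = logging.getLogger(__name__)

MODES = ("flowering_pool", "all_species_pool")


@dataclass
class NeutralConfig:
    mode: str = "flowering_pool"
    iterations: int = 1000
    seed: int = 0
    max_failure_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class NeutralReport:
    mode: str
    iterations: int
    k: int
    pool_size: int
    observed_aic: float
    mean_neutral_aic: float
    sd_neutral_aic: float
    empirical_quantile: float  # fraction of neutral AICs <= observed
    neutral_aics: np.ndarray = field(repr=False)
    n_failures: int = 0

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "iterations": self.iterations,
            "k": self.k,
            "pool_size": self.pool_size,
            "observed_aic": self.observed_aic,
            "mean_neutral_aic": self.mean_neutral_aic,
            "sd_neutral_aic": self.sd_neutral_aic,
            "empirical_quantile": self.empirical_quantile,
            "n_failures": self.n_failures,
        }


def neutral_draw(pool: Sequence[str], k: int, rng: np.random.Generator) -> list[str]:
    """Uniform sample of ``k`` species without replacement (sorted pool for
    reproducibility across input orderings)."""
    pool = sorted(pool)
    if k > len(pool):
        raise ValueError(f"k={k} exceeds pool size {len(pool)}")
    if k == 0:
        return []
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(idx)]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def neutral_aic_comparison(
    terms: tuple[Term, ...],
    data: pd.DataFrame,
    covers: pd.DataFrame,
    pool: Sequence[str],
    k: int,
    config: NeutralConfig,
    nectar_var: str = "nectar",
    response: str = "n_parasitized",
    trials: str | None = "n_examined",
    group: str = "strip",
    family: str = "binomial",
    observed_fit: GlmmFit | None = None,
) -> NeutralReport:
    """Compare the trait-matching model's AIC against neutral re-draws.

    Parameters
    ----------
    terms : fixed-effect terms of the reference (top-ranked) model; the
        ``nectar_var`` column of ``data`` is replaced per iteration.
    data : analysis table (one row per plot) holding the response, trials,
        grouping factor and standardized covariates.
    covers : plot x species percent-cover matrix used to rebuild the
        covariate from each random species set.
    pool : candidate species for the random draws (flowering or all
        present, per the configured mode).
    k : number of species per draw (= size of the trait-matched set).
    """
    data = data.reset_index(drop=True)
    if observed_fit is None:
        X, names = design_matrix(data, list(terms))
        observed_fit = fit_glmm(
            X, data[response].to_numpy(), data[group].to_numpy(),
            trials=None if trials is None else data[trials].to_numpy(),
            family=family, names=names, terms=tuple(terms), restarts=1,
        )
    observed_aic = observed_fit.aic
    warm = np.append(observed_fit.beta, np.log(max(observed_fit.sigma_u, 0.05)))

    ss = np.random.SeedSequence(entropy=config.seed)
    child = ss.spawn(config.iterations)
    uses_nectar = any(nectar_var in dict(t.powers) for t in terms)

    # precompute everything that does not change across iterations: the
    # design matrix, the plot x pool cover matrix aligned to the data rows,
    # and the indices of the design columns that involve the nectar covariate
    X0, names = design_matrix(data, list(terms))
    y = data[response].to_numpy()
    g = data[group].to_numpy()
    tr = None if trials is None else data[trials].to_numpy()
    pool_sorted = sorted(pool)
    covmat = (
        covers.reindex(index=data["plot"], columns=pool_sorted)
        .fillna(0.0)
        .to_numpy(dtype=float)
    )
    base_vars = {
        var: data[var].to_numpy(dtype=float)
        for t in terms
        for var, _ in t.powers
        if var != nectar_var
    }
    nectar_cols = [
        (1 + i, t)
        for i, t in enumerate(terms)
        if nectar_var in dict(t.powers)
    ]

    aics = []
    failures = 0
    for it in range(config.iterations):
        rng = np.random.default_rng(child[it])
        if k == 0:
            idx = np.array([], dtype=int)
        else:
            idx = rng.choice(len(pool_sorted), size=k, replace=False)
        zn = _zscore(covmat[:, np.sort(idx)].sum(axis=1)) if k else np.zeros(len(data))
        X = X0.copy()
        vals = dict(base_vars)
        vals[nectar_var] = zn
        for j, t in nectar_cols:
            X[:, j] = t.column(vals)
        try:
            f = fit_glmm(
                X, y, g, trials=tr, family=family, names=names,
                terms=tuple(terms), restarts=1,
                start=warm if uses_nectar else None, compute_cov=False,
            )
            if not f.converged:
                raise RuntimeError("non-convergence")
            aics.append(f.aic)
        except Exception as exc:
            failures += 1
            logger.warning("neutral iteration %d failed: %s", it, exc)
    if failures > config.max_failure_fraction * config.iterations:
        raise RuntimeError(
            f"{failures}/{config.iterations} neutral iterations failed to fit"
        )
    aics = np.asarray(aics)
    return NeutralReport(
        mode=config.mode,
        iterations=config.iterations,
        k=k,
        pool_size=len(pool),
        observed_aic=float(observed_aic),
        mean_neutral_aic=float(aics.mean()),
        sd_neutral_aic=float(aics.std(ddof=1)) if len(aics) > 1 else 0.0,
        empirical_quantile=float(np.mean(aics <= observed_aic)),
        neutral_aics=aics,
        n_failures=failures,
    )
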