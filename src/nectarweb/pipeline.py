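"""End-to-end analysis tracks over one dataset (synthetic or loaded).

Two tracks, mirroring the study design they emulate:

* per-herbivore parasitism: assemblage-factor GLMMs (random effect chosen by
  AIC among plot / strip / block), then all-subsets multimodel inference over
  the three standardized community covariates (accessible-nectar cover for
  the herbivore's parasitoid, species richness, functional dispersion), with
  an optional neutral-randomization validation of the nectar covariate;
* multi-species parasitism: the multi-threshold count statistic against the
  same covariates averaged over parasitoids, with threshold interactions.

Distances are analyzed strictly separately.  Everything is deterministic
under the scenario master seed plus the analysis seed; artifacts embed the
configuration hash.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .covariates import build_covariates, plot_cover_matrix
from .glmm import fit_glmm_terms, pseudo_r2, select_random_effect, wald_joint
from .multithreshold import (
    fit_multithreshold,
    herbivore_maxima,
    multispecies_counts,
)
from .neutral import NeutralConfig, neutral_aic_comparison
from .selection import build_term_sets, community_term_pool, conditional_average, rank_by_aic
from .simulate import (
    ScenarioConfig,
    simulate_flora,
    simulate_parasitism,
    simulate_parasitoids,
)
from .traits import accessible_species, nectar_available

__all__ = [
    "RunConfig",
    "Dataset",
    "prepare_dataset",
    "run_assemblage_analysis",
    "run_covariate_analysis",
    "run_multithreshold_analysis",
    "run_all",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    distances: tuple[float, ...] | None = None  # default: scenario distances
    run_assemblage: bool = True
    run_covariates: bool = True
    run_neutral: bool = True
    run_multithreshold: bool = True
    neutral_iterations: int = 1000
    neutral_modes: tuple[str, ...] = ("flowering_pool", "all_species_pool")
    neutral_distances: tuple[float, ...] = (5.0,)
    analysis_seed: int = 1
    outdir: str | Path | None = None


@dataclass
class Dataset:
    """One analyzable dataset: flora, parasitoids, parasitism, covariates."""

    flora: object  # SyntheticFlora-like: traits, morphology, surveys, plots
    parasitoids: list
    parasitism: pd.DataFrame
    covariates: pd.DataFrame
    herbivore_taxa: dict[str, str]


def prepare_dataset(scenario: ScenarioConfig) -> Dataset:
    """Simulate flora + parasitoids, derive covariates, draw parasitism."""
    flora = simulate_flora(scenario)
    parasitoids = simulate_parasitoids(scenario)
    cov = build_covariates(flora.surveys, flora.traits, flora.morphology, parasitoids)
    parasitism = simulate_parasitism(scenario, cov, parasitoids)
    herb_taxa = {
        h: parasitoids[i % len(parasitoids)].taxon
        for i, h in enumerate(scenario.herbivores)
    }
    return Dataset(flora, parasitoids, parasitism, cov, herb_taxa)


def _herbivore_frame(ds: Dataset, herbivore: str, distance: float) -> pd.DataFrame:
    sub = ds.parasitism[
        (ds.parasitism["herbivore"] == herbivore)
        & (ds.parasitism["distance_m"] == distance)
    ]
    cov = ds.covariates.drop(columns=["strip"], errors="ignore")
    data = sub.merge(cov, left_on="plot", right_index=True, how="inner")
    meta = ds.flora.plots.set_index("plot") if hasattr(ds.flora, "plots") else None
    if meta is not None:
        for col in ("treatment", "block"):
            if col in meta.columns and col not in data.columns:
                data[col] = data["plot"].map(meta[col]).to_numpy()
    return data.sort_values("plot", kind="stable").reset_index(drop=True)


def _zscore_cols(data: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    data = data.copy()
    for c in cols:
        v = data[c].to_numpy(dtype=float)
        sd = v.std()
        data[c] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    return data


def run_assemblage_analysis(ds: Dataset, distances: tuple[float, ...]) -> pd.DataFrame:
    """Treatment-as-factor binomial GLMMs per herbivore and distance.

    The random effect is chosen by AIC among plot, strip and block; the
    treatment factor is tested with a type-II Wald chi-square (joint test of
    the treatment contrasts).
    """
    herbs = sorted(ds.parasitism["herbivore"].unique())
    rows = []
    for dist in distances:
        for herb in herbs:
            data = _herbivore_frame(ds, herb, dist)
            if len(data) == 0:
                continue
            treatments = sorted(data["treatment"].unique())
            dummies = pd.get_dummies(data["treatment"], drop_first=True, dtype=float)
            X = np.column_stack([np.ones(len(data)), dummies.to_numpy()])
            names = ["(Intercept)"] + [f"treatment[{t}]" for t in dummies.columns]
            candidates = {
                "plot": data["plot"].to_numpy(),
                "strip": data["strip"].to_numpy(),
                "block": data["block"].to_numpy(),
            }
            best_name, fits = select_random_effect(
                X, data["n_parasitized"].to_numpy(), candidates,
                trials=data["n_examined"].to_numpy(), family="binomial",
                names=names, restarts=1,
            )
            fit = fits[best_name]
            chisq, dfree, p = wald_joint(fit, names[1:])
            r2m, r2c = pseudo_r2(fit)
            rows.append(
                {
                    "distance_m": dist,
                    "herbivore": herb,
                    "n_treatments": len(treatments),
                    "random_effect": best_name,
                    "aic": fit.aic,
                    "chisq": chisq,
                    "df": dfree,
                    "p": p,
                    "r2_marginal": r2m,
                    "r2_conditional": r2c,
                }
            )
    return pd.DataFrame(rows)


def _fit_candidates(
    data: pd.DataFrame,
    term_sets,
    response: str,
    trials: str | None,
    group: str,
    family: str,
    restarts: int = 1,
):
    entries = []
    for terms in term_sets:
        try:
            f = fit_glmm_terms(
                data, terms, response=response, group=group, trials=trials,
                family=family, restarts=restarts,
            )
            entries.append((terms, f))
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("candidate %s failed: %s", terms, exc)
    return entries


def run_covariate_analysis(
    ds: Dataset,
    distances: tuple[float, ...],
    max_terms: int | None = None,
) -> dict:
    """All-subsets multimodel inference per herbivore and distance.

    Returns ``{(distance, herbivore): {"averaged", "ranked", "data",
    "r2"}}``; ``data`` holds the standardized analysis frame (columns
    ``nectar``, ``richness``, ``fdis``).
    """
    pool = community_term_pool()
    term_sets = build_term_sets(pool, marginality=True, max_terms=max_terms)
    herbs = sorted(ds.parasitism["herbivore"].unique())
    out = {}
    for dist in distances:
        for herb in herbs:
            data = _herbivore_frame(ds, herb, dist)
            if len(data) == 0:
                continue
            taxon = ds.herbivore_taxa.get(herb)
            data["nectar"] = data[f"nectar_{taxon}"] if taxon else data["nectar"]
            data = _zscore_cols(data, ["nectar", "richness", "fdis"])
            entries = _fit_candidates(
                data, term_sets, "n_parasitized", "n_examined", "strip", "binomial"
            )
            ranked = rank_by_aic(entries)
            avg = conditional_average(ranked)
            out[(dist, herb)] = {
                "averaged": avg,
                "ranked": ranked,
                "data": data,
                "r2": pseudo_r2(avg.best_fit),
            }
    return out


def run_neutral_analysis(
    ds: Dataset,
    covariate_results: dict,
    config: RunConfig,
) -> dict:
    """Neutral-randomization AIC comparison per herbivore / distance / mode."""
    covers = plot_cover_matrix(ds.flora.surveys)
    present_species = sorted(covers.columns[(covers.sum(axis=0) > 0)])
    taxa = {i.taxon: i for i in ds.parasitoids}
    out = {}
    for (dist, herb), res in covariate_results.items():
        if dist not in config.neutral_distances:
            continue
        insect = taxa[ds.herbivore_taxa[herb]]
        matched = accessible_species(
            {s: ds.flora.morphology[s] for s in present_species if s in ds.flora.morphology},
            insect,
        )
        k = len(matched)
        flowering = sorted(
            s
            for s in present_species
            if s in ds.flora.morphology
            and nectar_available(ds.flora.morphology[s], insect, "window")
        )
        pools = {"flowering_pool": flowering, "all_species_pool": present_species}
        for mode in config.neutral_modes:
            pool = pools[mode]
            key = zlib.crc32(f"{dist}|{herb}|{mode}".encode())
            cfg = NeutralConfig(
                mode=mode,
                iterations=config.neutral_iterations,
                seed=int(
                    np.random.SeedSequence(
                        entropy=config.analysis_seed, spawn_key=(key,)
                    ).generate_state(1)[0]
                    % (2**31)
                ),
            )
            report = neutral_aic_comparison(
                res["averaged"].best_terms,
                res["data"],
                covers,
                pool,
                min(k, len(pool)),
                cfg,
                observed_fit=res["averaged"].best_fit,
            )
            out[(dist, herb, mode)] = report
    return out


def run_multithreshold_analysis(
    ds: Dataset,
    distances: tuple[float, ...],
    fdis_grid: int = 25,
) -> dict:
    """Multi-threshold track: counts, averaged Poisson model, partial curves.

    Covariates enter averaged over parasitoids (the ``nectar`` mean column);
    predicted count-vs-functional-dispersion curves are emitted per
    threshold from the conditional averaged coefficients, holding the other
    covariates at their mean.
    """
    out = {}
    for dist in distances:
        counts = multispecies_counts(ds.parasitism, dist)
        cov = ds.covariates[["nectar", "richness", "fdis"]]
        avg, ranked = fit_multithreshold(counts, cov)
        curves = _partial_curves(avg, counts, ds.covariates, fdis_grid)
        out[dist] = {
            "counts": counts,
            "averaged": avg,
            "ranked": ranked,
            "curves": curves,
            "maxima": herbivore_maxima(ds.parasitism, dist),
            "r2": pseudo_r2(avg.best_fit),
        }
    return out


def _partial_curves(
    avg, counts: pd.DataFrame, covariates: pd.DataFrame, n_grid: int
) -> pd.DataFrame:
    """Predicted multi-species count vs functional dispersion per threshold."""
    coefs = avg.terms["estimate"]
    fdis_raw = covariates["fdis"].to_numpy(dtype=float)
    f_mu, f_sd = fdis_raw.mean(), fdis_raw.std() or 1.0
    thresholds = sorted(counts["threshold"].unique())
    t_arr = counts["threshold"].to_numpy(dtype=float)
    t_mu, t_sd = t_arr.mean(), t_arr.std() or 1.0
    grid = np.linspace(fdis_raw.min(), fdis_raw.max(), n_grid)
    rows = []
    for tau in thresholds:
        zt = (tau - t_mu) / t_sd
        for f in grid:
            zf = (f - f_mu) / f_sd
            vals = {"threshold": zt, "fdis": zf, "nectar": 0.0, "richness": 0.0}
            eta = 0.0
            for name, b in coefs.items():
                if name == "(Intercept)":
                    eta += b
                    continue
                contrib = b
                for part in name.split(":"):
                    var, _, pw = part.partition("^")
                    contrib *= vals[var] ** (int(pw) if pw else 1)
                eta += contrib
            rows.append(
                {
                    "threshold": tau,
                    "fdis": f,
                    "fdis_z": zf,
                    "predicted_count": float(np.exp(eta)),
                }
            )
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """Run every enabled stage on the configured scenario.

    Returns a results dictionary; when ``config.outdir`` is set, writes the
    full set of CSV / JSON artifacts (byte-stable under fixed seeds).
    """
    distances = config.distances or config.scenario.distances
    ds = prepare_dataset(config.scenario)
    results: dict = {"dataset": ds}
    if config.run_assemblage:
        results["assemblage"] = run_assemblage_analysis(ds, distances)
    if config.run_covariates:
        results["covariate"] = run_covariate_analysis(ds, distances)
        if config.run_neutral:
            results["neutral"] = run_neutral_analysis(ds, results["covariate"], config)
    if config.run_multithreshold:
        results["multithreshold"] = run_multithreshold_analysis(ds, distances)
    if config.outdir is not None:
        _write_artifacts(config, results)
    return results


def _averaged_to_json(avg) -> dict:
    return {
        "terms": avg.terms,
        "members": avg.members[["formula", "aic", "delta_aic", "weight"]],
        "best_formula": "~ 1 + " + " + ".join(t.name for t in avg.best_terms)
        if avg.best_terms
        else "~ 1",
    }


def _write_artifacts(config: RunConfig, results: dict) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds: Dataset = results["dataset"]
    nio.write_table(ds.flora.surveys, out / "surveys.csv")
    nio.write_table(ds.parasitism, out / "parasitism.csv")
    nio.write_table(ds.covariates.reset_index(), out / "covariates.csv")
    nio.write_flora_csv(ds.flora.morphology, out / "flora_traits.csv")
    nio.write_parasitoid_csv(ds.parasitoids, out / "parasitoids.csv")
    if "assemblage" in results:
        nio.write_table(results["assemblage"], out / "assemblage_wald.csv")
    if "covariate" in results:
        for (dist, herb), res in results["covariate"].items():
            tag = f"{herb.replace(' ', '_')}_{int(dist)}m"
            nio.write_table(
                res["ranked"].drop(columns="model_id"), out / f"ranked_{tag}.csv"
            )
            nio.write_json(_averaged_to_json(res["averaged"]), out / f"averaged_{tag}.json")
    if "neutral" in results:
        neutral = {
            f"{herb.replace(' ', '_')}_{int(dist)}m_{mode}": rep.to_dict()
            for (dist, herb, mode), rep in results["neutral"].items()
        }
        nio.write_json(neutral, out / "neutral_reports.json")
        audit = pd.concat(
            [
                pd.DataFrame(
                    {
                        "herbivore": herb, "distance_m": dist, "mode": mode,
                        "iteration": np.arange(len(rep.neutral_aics)),
                        "aic": rep.neutral_aics,
                    }
                )
                for (dist, herb, mode), rep in results["neutral"].items()
            ],
            ignore_index=True,
        )
        nio.write_table(audit, out / "neutral_iteration_aics.csv")
    if "multithreshold" in results:
        for dist, res in results["multithreshold"].items():
            tag = f"{int(dist)}m"
            nio.write_table(res["counts"], out / f"multithreshold_counts_{tag}.csv")
            nio.write_table(res["curves"], out / f"multithreshold_curves_{tag}.csv")
            nio.write_json(
                _averaged_to_json(res["averaged"]), out / f"multithreshold_averaged_{tag}.json"
            )
    summary = {
        "config_hash": nio.config_hash(config.scenario),
        "master_seed": config.scenario.master_seed,
        "analysis_seed": config.analysis_seed,
        "n_plots": int(len(ds.covariates)),
        "n_parasitism_rows": int(len(ds.parasitism)),
    }
    nio.write_json(summary, out / "run_summary.json")
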