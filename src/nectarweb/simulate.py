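"""Synthetic field-experiment generator.

Emulates the structure of a wildflower-strip factorial experiment: eight
sown assemblages (two identity sets crossed with low/high functional
diversity and three sown-richness levels: LFMS 14 species, HFLS 9, HFMS 14,
HFHS 29) plus an unsown control, replicated in three strips (27 plots);
botanical surveys over a pool of ~85 plant species with mixed-type traits;
seven parasitoid taxa with measured mouthpart morphologies and staggered
activity windows; and binomial parasitism records for five herbivores at two
distances from the strip.

Parasitism is generated from the same model family the analysis fits:
``logit(rate) = b0_h + decay_d * (bn * Z_nectar + br * Z_richness +
bf * Z_fdis + bf2 * Z_fdis^2) + u_strip`` with ``u ~ N(0, sigma_strip^2)``,
so that parameter-recovery and power properties can be checked by
construction.  All draws are reproducible from the master seed through
independent named substreams (flora / parasitoids / parasitism).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .diversity import TraitMatrix, gower_dissimilarity
from .traits import FlowerMorphology, InsectMorphology, NectarType

__all__ = [
    "ScenarioConfig",
    "SyntheticFlora",
    "simulate_flora",
    "simulate_parasitoids",
    "simulate_parasitism",
    "fixture_small",
    "HERBIVORES",
]

HERBIVORES: tuple[str, ...] = (
    "Bruchus rufimanus",
    "Psylliodes chrysocephala",
    "Ceutorhynchus pallidactylus",
    "Brassicogethes aeneus",
    "Dasineura brassicae",
)

# assemblage code -> sown species richness
ASSEMBLAGE_RICHNESS = {"LFMS": 14, "HFLS": 9, "HFMS": 14, "HFHS": 29}


@dataclass
class ScenarioConfig:
    """Design, flora, parasitoid and effect-size settings of one scenario.

    Effect sizes act on the latent logit scale on z-scored covariates; the
    default scenario carries a positive accessible-nectar effect and a
    negative quadratic functional-dispersion effect with effects attenuated
    at the far distance, plus a strip-level random intercept.
    """

    # experimental design
    n_strips: int = 3
    distances: tuple[float, ...] = (5.0, 20.0)
    herbivores: tuple[str, ...] = HERBIVORES
    # flora
    pool_size: int = 85
    n_sown_pool: int = 55
    survey_doy: int = 150
    sown_cover_range: tuple[float, float] = (60.0, 90.0)
    spontaneous_cover_range: tuple[float, float] = (3.0, 10.0)
    control_cover_range: tuple[float, float] = (15.0, 30.0)
    # parasitoids
    n_parasitoids: int = 7
    season: tuple[int, int] = (60, 240)
    # latent effects (logit scale, z-scored covariates)
    beta0: tuple[float, ...] = (-0.2, -1.2, -1.4, -2.1, -0.9)
    beta_nectar: float = 0.5
    beta_richness: float = 0.0
    beta_fdis: float = 0.0
    beta_fdis2: float = -0.4
    sigma_strip: float = 0.3
    distance_decay: Mapping[float, float] = field(
        default_factory=lambda: {5.0: 1.0, 20.0: 0.4}
    )
    trials_range: tuple[int, int] = (20, 200)
    master_seed: int = 20210

    def rng(self, stream: int) -> np.random.Generator:
        """Independent named substream of the master seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.master_seed, spawn_key=(stream,))
        )

    @property
    def treatments(self) -> list[str]:
        out = []
        for code in ("LFMS", "HFLS", "HFMS", "HFHS"):
            out += [f"{code}-A", f"{code}-B"]
        out.append("control")
        return out


@dataclass
class SyntheticFlora:
    traits: TraitMatrix
    morphology: dict[str, FlowerMorphology]
    surveys: pd.DataFrame  # plot, treatment, strip, block, species, cover, stage
    plots: pd.DataFrame  # plot, treatment, strip, block


def _draw_species_traits(rng: np.random.Generator, n: int) -> pd.DataFrame:
    names = [f"sp{i + 1:03d}" for i in range(n)]
    ntype = rng.choice(
        ["floral", "extrafloral", "both", "none"], size=n, p=[0.65, 0.08, 0.05, 0.22]
    )
    df = pd.DataFrame(
        {
            "opening_width": np.round(rng.lognormal(np.log(3.0), 0.6, n), 3),
            "corolla_height": np.round(rng.lognormal(np.log(2.5), 0.7, n), 3),
            "nectar_depth": np.round(rng.lognormal(np.log(1.5), 0.7, n), 3),
            "tube_diameter": np.round(rng.lognormal(np.log(1.0), 0.5, n), 3),
            "has_tube": rng.random(n) < 0.6,
            "nectar_type": ntype,
            "nectar_quantity": rng.integers(0, 4, n),
            "flower_start": rng.integers(60, 201, n),
            "duration": rng.integers(20, 91, n),
            "color": rng.choice(["white", "yellow", "blue", "purple", "pink"], n),
            "uv_pattern": rng.choice(["present", "absent"], n),
            "height_cm": np.round(rng.lognormal(np.log(40.0), 0.5, n), 1),
            "leaf_distribution": rng.choice(["rosette", "semi-rosette", "regular"], n),
        },
        index=names,
    )
    df["flower_end"] = df["flower_start"] + df["duration"]
    return df


#: trait kinds used for the functional-diversity trait matrix (covering
#: trophic resources, temporal availability, attractiveness, accessibility
#: and physical habitat)
FD_TRAIT_KINDS = {
    "nectar_type": "categorical",
    "nectar_quantity": "quantitative",
    "flower_start": "quantitative",
    "duration": "quantitative",
    "opening_width": "quantitative",
    "corolla_height": "quantitative",
    "nectar_depth": "quantitative",
    "color": "categorical",
    "uv_pattern": "binary",
    "height_cm": "quantitative",
    "leaf_distribution": "categorical",
}


def _morphology_from_row(name: str, row: pd.Series) -> FlowerMorphology:
    return FlowerMorphology(
        species=name,
        opening_width=float(row["opening_width"]),
        corolla_height=float(row["corolla_height"]),
        nectar_depth=float(row["nectar_depth"]),
        tube_diameter=float(row["tube_diameter"]) if row["has_tube"] else None,
        nectar_type=str(row["nectar_type"]),
        flower_start=int(row["flower_start"]),
        flower_end=int(row["flower_end"]),
        nectar_quantity=int(row["nectar_quantity"]),
    )


def _pick_low_fd(dism: pd.DataFrame, candidates: list[str], k: int, rng) -> list[str]:
    """Trait-clustered set: a seed species and its k-1 nearest neighbours."""
    seed = candidates[rng.integers(len(candidates))]
    order = dism.loc[seed, candidates].sort_values(kind="stable")
    return sorted(order.index[:k])


def _pick_high_fd(dism: pd.DataFrame, candidates: list[str], k: int, rng) -> list[str]:
    """Trait-dispersed set by greedy max-min selection."""
    chosen = [candidates[rng.integers(len(candidates))]]
    rest = [c for c in candidates if c != chosen[0]]
    while len(chosen) < k:
        mind = dism.loc[rest, chosen].min(axis=1)
        nxt = mind.idxmax()
        chosen.append(nxt)
        rest.remove(nxt)
    return sorted(chosen)


def _stage_at(doy: int, start: int, end: int) -> int:
    """Phenological stage on the 0-10 scale at one survey date."""
    if doy < start:
        return 2 if start - doy <= 20 else 1
    if doy > end:
        return 10 if doy - end > 20 else 9
    frac = (doy - start) / max(end - start, 1)
    return 5 + min(int(frac * 4), 3)  # 5..8 while in flower


def simulate_flora(config: ScenarioConfig) -> SyntheticFlora:
    """Draw the plant pool, assemblage compositions and botanical surveys."""
    rng = config.rng(0)
    df = _draw_species_traits(rng, config.pool_size)
    traits = TraitMatrix(df[list(FD_TRAIT_KINDS)].copy(), FD_TRAIT_KINDS)
    morphology = {name: _morphology_from_row(name, row) for name, row in df.iterrows()}
    dism = gower_dissimilarity(traits)

    sown = list(df.index[: config.n_sown_pool])
    half = len(sown) // 2 + 2
    identity_sets = {"A": sown[:half], "B": sown[-half:]}

    compositions: dict[str, list[str]] = {}
    for code, richness in ASSEMBLAGE_RICHNESS.items():
        for ident, candidates in identity_sets.items():
            if code.startswith("LF"):
                comp = _pick_low_fd(dism, candidates, richness, rng)
            else:
                comp = _pick_high_fd(dism, candidates, richness, rng)
            compositions[f"{code}-{ident}"] = comp
    compositions["control"] = []

    spontaneous_pool = list(df.index[config.n_sown_pool :])
    records = []
    plot_rows = []
    for treatment in config.treatments:
        for strip in range(1, config.n_strips + 1):
            plot = f"{treatment}-s{strip}"
            block = strip  # one replicate of each assemblage per block
            plot_rows.append(
                {"plot": plot, "treatment": treatment, "strip": strip, "block": block}
            )
            comp = compositions[treatment]
            if comp:
                total = rng.uniform(*config.sown_cover_range)
                covers = rng.dirichlet(np.ones(len(comp))) * total
                for sp, c in zip(comp, covers):
                    records.append((plot, treatment, strip, block, sp, float(c)))
                spo_total = rng.uniform(*config.spontaneous_cover_range)
            else:
                spo_total = rng.uniform(*config.control_cover_range)
            n_spo = int(rng.integers(5, 13))
            spo = rng.choice(spontaneous_pool, size=n_spo, replace=False)
            spo_cov = rng.dirichlet(np.ones(n_spo)) * spo_total
            for sp, c in zip(spo, spo_cov):
                records.append((plot, treatment, strip, block, sp, float(c)))
    surveys = pd.DataFrame(
        records, columns=["plot", "treatment", "strip", "block", "species", "cover"]
    )
    surveys["stage"] = [
        _stage_at(
            config.survey_doy,
            morphology[sp].flower_start,
            morphology[sp].flower_end,
        )
        for sp in surveys["species"]
    ]
    plots = pd.DataFrame(plot_rows)
    return SyntheticFlora(traits, morphology, surveys, plots)


def simulate_parasitoids(config: ScenarioConfig) -> list[InsectMorphology]:
    """Seven parasitoid taxa with positive morphologies and staggered
    activity windows inside the season."""
    rng = config.rng(1)
    lo, hi = config.season
    taxa = []
    span = (hi - lo - 70) / max(config.n_parasitoids - 1, 1)
    for i in range(config.n_parasitoids):
        start = int(np.clip(lo + 5 + i * span + rng.integers(-8, 9), lo, hi - 30))
        length = int(rng.integers(30, 61))
        taxa.append(
            InsectMorphology(
                taxon=f"wasp_{i + 1}",
                head_width=float(np.round(rng.lognormal(np.log(0.7), 0.25), 4)),
                proboscis_length=float(np.round(rng.lognormal(np.log(0.35), 0.35), 4)),
                proboscis_width=float(np.round(rng.lognormal(np.log(0.06), 0.25), 4)),
                activity_start=start,
                activity_end=min(start + length, hi),
            )
        )
    return taxa


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def simulate_parasitism(
    config: ScenarioConfig,
    covariates: pd.DataFrame,
    parasitoids: list[InsectMorphology],
) -> pd.DataFrame:
    """Binomial parasitism records per plot x distance x herbivore.

    ``covariates`` must be indexed by plot with ``richness``, ``fdis``,
    ``strip`` and one ``nectar_<taxon>`` column per parasitoid; herbivore
    ``h`` is driven by the accessible-nectar cover of parasitoid taxon ``h``
    (taxa beyond the herbivore count provide no parasitism pressure).
    """
    rng = config.rng(2)
    plots = covariates.index.to_numpy()
    strips = covariates["strip"].to_numpy()
    zr = _zscore(covariates["richness"].to_numpy(dtype=float))
    zf = _zscore(covariates["fdis"].to_numpy(dtype=float))
    rows = []
    for hi_, herb in enumerate(config.herbivores):
        taxon = parasitoids[hi_ % len(parasitoids)].taxon
        zn = _zscore(covariates[f"nectar_{taxon}"].to_numpy(dtype=float))
        b0 = config.beta0[hi_ % len(config.beta0)]
        for dist in config.distances:
            decay = config.distance_decay.get(dist, 1.0)
            u = rng.normal(0.0, config.sigma_strip, size=config.n_strips)
            strip_levels = {s: u[i] for i, s in enumerate(sorted(set(strips)))}
            eta = b0 + decay * (
                config.beta_nectar * zn
                + config.beta_richness * zr
                + config.beta_fdis * zf
                + config.beta_fdis2 * zf**2
            ) + np.array([strip_levels[s] for s in strips])
            n_exam = rng.integers(config.trials_range[0], config.trials_range[1] + 1, len(plots))
            y = rng.binomial(n_exam, expit(eta))
            for p, s, n, yy in zip(plots, strips, n_exam, y):
                rows.append(
                    {
                        "plot": p,
                        "strip": s,
                        "distance_m": dist,
                        "herbivore": herb,
                        "n_examined": int(n),
                        "n_parasitized": int(yy),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# deterministic miniature fixture
# ---------------------------------------------------------------------------

def fixture_small() -> dict:
    """Deterministic 4-species x 2-parasitoid x 6-plot miniature dataset.

    Hand-computable accessible covers (window mode):

    * wasp_a (head 1.0 mm -> r 0.5, proboscis 0.8 x 0.15 mm, active
      [120, 160]): plant_a accessible (head enters w=2.0 >= 1.0; 0.8 >= p=0.5;
      no tube), plant_b available for a single day (flowering ends day 120)
      but unreachable (head excluded, 0.8 < h+p = 3.5), plant_c extrafloral,
      plant_d nectarless.  Accessible set {plant_a, plant_c}: cover
      30 + 10 = 40 in treatment T1 plots and 10 + 0 = 10 in T2 plots.
    * wasp_b (head 3.0 -> r 1.5, proboscis 4.0 x 0.05, active [60, 110]):
      head excluded everywhere but the long proboscis spans h+p for plant_a
      (4.0 >= 1.5) and plant_b (4.0 >= 3.5, tube 0.05 <= 0.1).  Accessible
      set {plant_a, plant_b, plant_c}: cover 60 (T1) and 15 (T2).
    """
    morphology = {
        "plant_a": FlowerMorphology(
            "plant_a", 2.0, 1.0, 0.5, None, NectarType.FLORAL, 100, 180, nectar_quantity=2
        ),
        "plant_b": FlowerMorphology(
            "plant_b", 0.5, 2.0, 1.5, 0.1, NectarType.FLORAL, 60, 120, nectar_quantity=3
        ),
        "plant_c": FlowerMorphology(
            "plant_c", 1.0, 0.5, 0.2, None, NectarType.EXTRAFLORAL, 90, 150, nectar_quantity=1
        ),
        "plant_d": FlowerMorphology(
            "plant_d", 3.0, 1.0, 0.5, None, NectarType.NONE, 80, 140, nectar_quantity=0
        ),
    }
    traits = TraitMatrix(
        pd.DataFrame(
            {
                "opening_width": [2.0, 0.5, 1.0, 3.0],
                "corolla_height": [1.0, 2.0, 0.5, 1.0],
                "nectar_depth": [0.5, 1.5, 0.2, 0.5],
                "flower_start": [100, 60, 90, 80],
                "nectar_type": ["floral", "floral", "extrafloral", "none"],
                "color": ["white", "blue", "yellow", "white"],
            },
            index=list(morphology),
        ),
        {
            "opening_width": "quantitative",
            "corolla_height": "quantitative",
            "nectar_depth": "quantitative",
            "flower_start": "quantitative",
            "nectar_type": "categorical",
            "color": "categorical",
        },
    )
    parasitoids = [
        InsectMorphology("wasp_a", 1.0, 0.8, 0.15, 120, 160),
        InsectMorphology("wasp_b", 3.0, 4.0, 0.05, 60, 110),
    ]
    base_covers = {
        "T1": {"plant_a": 30.0, "plant_b": 20.0, "plant_c": 10.0, "plant_d": 5.0},
        "T2": {"plant_a": 10.0, "plant_b": 5.0, "plant_c": 0.0, "plant_d": 40.0},
    }
    stages = {"plant_a": 6, "plant_b": 8, "plant_c": 5, "plant_d": 2}
    records = []
    plot_rows = []
    for treatment in ("T1", "T2"):
        for strip in (1, 2, 3):
            plot = f"{treatment}-s{strip}"
            plot_rows.append(
                {"plot": plot, "treatment": treatment, "strip": strip, "block": strip}
            )
            for sp, c in base_covers[treatment].items():
                if c > 0:
                    records.append(
                        {
                            "plot": plot,
                            "treatment": treatment,
                            "strip": strip,
                            "block": strip,
                            "species": sp,
                            "cover": c,
                            "stage": stages[sp],
                        }
                    )
    surveys = pd.DataFrame(records)
    parasitized = {
        ("herb_a", "T1"): (20, 22, 18),
        ("herb_a", "T2"): (8, 10, 6),
        ("herb_b", "T1"): (30, 28, 32),
        ("herb_b", "T2"): (15, 12, 14),
    }
    prows = []
    for herb in ("herb_a", "herb_b"):
        for treatment in ("T1", "T2"):
            for strip in (1, 2, 3):
                prows.append(
                    {
                        "plot": f"{treatment}-s{strip}",
                        "strip": strip,
                        "distance_m": 5.0,
                        "herbivore": herb,
                        "n_examined": 50,
                        "n_parasitized": parasitized[(herb, treatment)][strip - 1],
                    }
                )
    return {
        "morphology": morphology,
        "traits": traits,
        "parasitoids": parasitoids,
        "surveys": surveys,
        "plots": pd.DataFrame(plot_rows),
        "parasitism": pd.DataFrame(prows),
    }
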