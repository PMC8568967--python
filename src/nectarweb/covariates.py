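"""Plot-level community covariates for the parasitism analyses.

From the botanical surveys (plot x species percent cover), the flower trait
matrix and the parasitoid morphologies this module derives, per plot:
species richness, functional dispersion (and Rao Q) of the plant community,
and the percent cover providing available and accessible nectar for each
parasitoid taxon plus its across-taxa mean.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .diversity import TraitMatrix, fdis, gower_dissimilarity, rao_q, species_richness
from .traits import FlowerMorphology, InsectMorphology, accessible_cover

__all__ = ["plot_cover_matrix", "build_covariates"]


def plot_cover_matrix(surveys: pd.DataFrame) -> pd.DataFrame:
    """Pivot long surveys (plot, species, cover) to a plot x species matrix."""
    return (
        surveys.pivot_table(index="plot", columns="species", values="cover", aggfunc="sum")
        .fillna(0.0)
        .sort_index()
    )


def build_covariates(
    surveys: pd.DataFrame,
    traits: TraitMatrix,
    morphology: Mapping[str, FlowerMorphology],
    parasitoids: Iterable[InsectMorphology],
    dism: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-plot community covariates.

    Returns a DataFrame indexed by plot with columns ``richness``, ``fdis``,
    ``rao_q``, one ``nectar_<taxon>`` column per parasitoid, their mean
    ``nectar``, and the plot's ``strip``/``treatment`` labels when present in
    the surveys.
    """
    parasitoids = list(parasitoids)
    covers = plot_cover_matrix(surveys)
    if dism is None:
        dism = gower_dissimilarity(traits)
    dism = dism.loc[
        [s for s in dism.index if s in covers.columns],
        [s for s in dism.index if s in covers.columns],
    ]
    rows = []
    for plot, ab in covers.iterrows():
        ab_d = ab[ab > 0]
        row: dict = {
            "plot": plot,
            "richness": species_richness(ab),
            "fdis": fdis(ab_d.reindex(dism.index).fillna(0.0), dism),
            "rao_q": rao_q(ab_d.reindex(dism.index).fillna(0.0), dism),
        }
        vals = []
        for ins in parasitoids:
            c = accessible_cover(ab_d.to_dict(), morphology, ins, mode="window")
            row[f"nectar_{ins.taxon}"] = c
            vals.append(c)
        row["nectar"] = float(np.mean(vals)) if vals else np.nan
        rows.append(row)
    out = pd.DataFrame(rows).set_index("plot").sort_index()
    meta_cols = [c for c in ("treatment", "strip", "block") if c in surveys.columns]
    if meta_cols:
        meta = surveys.drop_duplicates("plot").set_index("plot")[meta_cols]
        out = out.join(meta)
    return out
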