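"""Mixed-trait dissimilarity and abundance-weighted functional diversity.

Implements Gower dissimilarity over mixed quantitative / categorical / binary
trait matrices, functional dispersion (FDis: abundance-weighted mean distance
of species to the abundance-weighted centroid of the community in trait
space) and Rao quadratic entropy (expected pairwise dissimilarity between two
random draws).  FDis embeds the dissimilarity matrix by principal-coordinates
analysis with a Cailliez correction when the matrix is not Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitMatrix",
    "gower_dissimilarity",
    "pcoa_embedding",
    "fdis",
    "rao_q",
    "species_richness",
]

TRAIT_KINDS = ("quantitative", "categorical", "binary")


@dataclass
class TraitMatrix:
    """Species x traits table with per-trait kind declarations.

    ``values`` holds one row per species; quantitative traits are numeric
    (NaN = missing), categorical/binary traits are labels (None/NaN =
    missing).  Traits are equally weighted in the Gower computation.
    """

    values: pd.DataFrame
    kinds: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError("TraitMatrix needs at least one species")
        unknown = set(self.kinds) - set(self.values.columns)
        if unknown:
            raise ValueError(f"kinds declared for unknown traits: {sorted(unknown)}")
        for col in self.values.columns:
            k = self.kinds.get(col)
            if k not in TRAIT_KINDS:
                raise ValueError(f"trait {col!r} has invalid kind {k!r}")

    @property
    def species(self) -> list[str]:
        return list(self.values.index)


def gower_dissimilarity(traits: TraitMatrix) -> pd.DataFrame:
    """Symmetric Gower dissimilarity matrix in [0, 1].

    Quantitative traits contribute ``|x_i - x_j| / range`` (a constant trait
    contributes 0), categorical and binary traits contribute 0/1 mismatch.
    Missing values are handled by pairwise deletion: each pair is averaged
    over the traits observed for both species.  A pair sharing no observed
    trait raises, naming the pair.
    """
    df = traits.values
    n = len(df)
    if n < 2:
        raise ValueError("Gower dissimilarity needs at least two species")
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for col in df.columns:
        kind = traits.kinds[col]
        if kind == "quantitative":
            x = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
            valid = ~np.isnan(x)
            rng = np.nanmax(x) - np.nanmin(x) if valid.any() else 0.0
            diff = np.abs(x[:, None] - x[None, :])
            contrib = diff / rng if rng > 0 else np.zeros_like(diff)
        else:
            x = df[col].to_numpy(dtype=object)
            valid = np.array([v is not None and v == v for v in x])
            contrib = (x[:, None] != x[None, :]).astype(float)
        both = valid[:, None] & valid[None, :]
        num += np.where(both, np.nan_to_num(contrib), 0.0)
        den += both.astype(float)
    if (den == 0).any():
        i, j = np.argwhere(den == 0)[0]
        raise ValueError(
            f"species pair ({df.index[i]!r}, {df.index[j]!r}) shares no observed trait"
        )
    d = num / den
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float noise
    return pd.DataFrame(d, index=df.index, columns=df.index)


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest c such that d_ij + c (i != j) has a Euclidean embedding."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    delta1 = -0.5 * j @ (d**2) @ j
    delta2 = -0.5 * j @ d @ j
    upper = np.block([[np.zeros((n, n)), 2.0 * delta1], [-np.eye(n), -4.0 * delta2]])
    ev = np.linalg.eigvals(upper)
    return float(np.max(ev.real))


def pcoa_embedding(dism: pd.DataFrame | np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Principal-coordinates embedding of a dissimilarity matrix.

    Double-centers the squared dissimilarities and keeps axes with positive
    eigenvalues.  When negative eigenvalues exceed ``tol`` times the largest
    positive one, the Cailliez constant is added to the off-diagonal
    dissimilarities first so that all pairwise distances are representable.
    """
    d = np.asarray(dism, dtype=float)
    n = d.shape[0]
    if n == 1:
        return np.zeros((1, 1))

    def _embed(dd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (dd**2) @ j
        evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
        return evals[::-1], evecs[:, ::-1]

    evals, evecs = _embed(d)
    top = max(evals.max(), 0.0)
    if evals.min() < -tol * max(top, 1.0):
        c = _cailliez_constant(d)
        if c > 0:
            d = d + c * (1.0 - np.eye(n))
            evals, evecs = _embed(d)
    keep = evals > tol * max(abs(evals).max(), 1.0)
    if not keep.any():
        return np.zeros((n, 1))
    return evecs[:, keep] * np.sqrt(evals[keep])


def _weights(abund: Mapping[str, float] | pd.Series, species: Sequence[str]) -> np.ndarray:
    if isinstance(abund, pd.Series):
        w = abund.reindex(species).fillna(0.0).to_numpy(dtype=float)
    else:
        w = np.array([float(abund.get(s, 0.0)) for s in species])
    if (w < 0).any():
        raise ValueError("abundances must be non-negative")
    tot = w.sum()
    if tot <= 0:
        raise ValueError("at least one species must have positive abundance")
    return w / tot


def fdis(abund: Mapping[str, float] | pd.Series, dism: pd.DataFrame) -> float:
    """Functional dispersion of one community.

    Species with zero cover are dropped; the remaining dissimilarity
    submatrix is embedded by PCoA and FDis is the abundance-weighted mean
    distance to the abundance-weighted centroid.  A single-species community
    has FDis 0.
    """
    species = list(dism.index)
    w = _weights(abund, species)
    present = w > 0
    if present.sum() <= 1:
        return 0.0
    sub = dism.loc[np.array(species)[present], np.array(species)[present]]
    coords = pcoa_embedding(sub)
    ww = w[present] / w[present].sum()
    centroid = ww @ coords
    dist = np.sqrt(((coords - centroid) ** 2).sum(axis=1))
    return float(ww @ dist)


def rao_q(abund: Mapping[str, float] | pd.Series, dism: pd.DataFrame) -> float:
    """Rao quadratic entropy Q = sum_ij w_i w_j d_ij (d, not d^2)."""
    species = list(dism.index)
    w = _weights(abund, species)
    d = dism.to_numpy(dtype=float)
    return float(w @ d @ w)


def species_richness(abund: Mapping[str, float] | pd.Series) -> int:
    """Number of species with strictly positive cover."""
    if isinstance(abund, pd.Series):
        return int((abund > 0).sum())
    return sum(1 for v in abund.values() if v > 0)
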