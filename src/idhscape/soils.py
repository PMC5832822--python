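"""Soil field-description encoding, PCA and the within-site diversity index.

Auger profiles are described in the field over seven fixed depth layers
(0-10, 10-20 cm, then every 20 cm to 1.2 m) by ordinal scores (moisture,
texture by touch, root abundance, coarse fragments, redox features) and a
nominal colour class.  Descriptors are encoded numerically (ordinal codes,
one-hot colours), standardized, and projected on the first seven principal
axes; the mean Euclidean distance between a site's samples in that score
space is its soil-diversity index - a proxy for habitat (niche) diversity.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .synth import N_SOIL_LAYERS, SOIL_COLOURS, SOIL_ORDINALS

__all__ = [
    "encode_soil_descriptors",
    "soil_pca",
    "soil_diversity_index",
    "soil_groups",
    "SoilPCA",
]


def encode_soil_descriptors(samples: pd.DataFrame) -> pd.DataFrame:
    """Numeric sample-by-variable matrix from long-format field descriptions.

    Each sample must describe all seven layers.  Ordinal descriptors keep
    their integer codes; colour is one-hot encoded; every column is then
    standardized to zero mean and unit variance.  Zero-variance columns are
    dropped with a warning (they carry no information for the PCA).

    Returns a DataFrame indexed by ``sample_id`` with columns like
    ``L3_moisture`` and ``L3_colour_red``.
    """
    required = {"sample_id", "layer", *SOIL_ORDINALS, "colour"}
    missing_cols = required - set(samples.columns)
    if missing_cols:
        raise ValueError(f"missing columns: {sorted(missing_cols)}")

    layers = set(range(1, N_SOIL_LAYERS + 1))
    per_sample = samples.groupby("sample_id")["layer"].agg(set)
    problems = [(sid, sorted(layers - got))
                for sid, got in per_sample.items() if layers - got]
    if problems:
        msg = "; ".join(f"sample {sid} missing layer(s) {lay}"
                        for sid, lay in problems[:10])
        raise ValueError("incomplete soil profiles: " + msg)

    wide = {}
    for layer in sorted(layers):
        sub = samples[samples["layer"] == layer].set_index("sample_id")
        for var in SOIL_ORDINALS:
            wide[f"L{layer}_{var}"] = sub[var].astype(float)
        for colour in SOIL_COLOURS:
            wide[f"L{layer}_colour_{colour}"] = (
                sub["colour"] == colour).astype(float)
    X = pd.DataFrame(wide)

    sd = X.std(ddof=0)
    dead = sd[sd == 0].index
    if len(dead):
        warnings.warn(f"dropping {len(dead)} zero-variance descriptor column(s)",
                      stacklevel=2)
        X = X.drop(columns=dead)
        sd = sd.drop(dead)
    return (X - X.mean()) / sd


@dataclasses.dataclass
class SoilPCA:
    """Loadings, per-sample scores and explained variance of the soil PCA."""

    loadings: pd.DataFrame          # variables x axes
    scores: pd.DataFrame            # samples x axes
    explained_variance_ratio: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


def soil_pca(matrix: pd.DataFrame, n_axes: int = 7) -> SoilPCA:
    """PCA of the standardized descriptor matrix (correlation PCA).

    Returns scores on the top ``n_axes`` axes.  If the matrix rank is lower
    than requested, the available axes are returned with a warning.
    """
    if len(matrix) < n_axes + 1:
        raise ValueError(
            f"need at least {n_axes + 1} samples for {n_axes} axes, "
            f"got {len(matrix)}")
    X = np.asarray(matrix, dtype=float)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    k = min(n_axes, rank)
    if k < n_axes:
        warnings.warn(f"matrix rank {rank} < requested {n_axes} axes; "
                      f"returning {k}", stacklevel=2)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    axes = [f"PC{i + 1}" for i in range(k)]
    return SoilPCA(
        loadings=pd.DataFrame(pca.components_.T, index=matrix.columns,
                              columns=axes),
        scores=pd.DataFrame(scores, index=matrix.index, columns=axes),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def soil_diversity_index(scores: pd.DataFrame,
                         site_of_sample: pd.Series) -> pd.Series:
    """Mean pairwise Euclidean distance between a site's samples in PCA
    score space.

    Sites with a single sample get NaN (the index is undefined there); the
    index is zero iff all of a site's samples coincide.
    """
    site_of_sample = site_of_sample.reindex(scores.index)
    if site_of_sample.isna().any():
        raise ValueError("site_of_sample must cover every scored sample")
    out = {}
    for site, idx in scores.groupby(site_of_sample).groups.items():
        pts = scores.loc[idx].to_numpy()
        out[site] = float(pdist(pts).mean()) if len(pts) >= 2 else np.nan
    return pd.Series(out, name="soil_diversity").sort_index()


def soil_groups(scores: pd.DataFrame, k: int = 6) -> pd.Series:
    """Ward-linkage clustering of PCA scores into ``k`` soil groups.

    A purely numerical stand-in for expert soil-type assignment: group
    labels are arbitrary integers, not pedological classes.
    """
    if len(scores) < k:
        raise ValueError(f"cannot form {k} groups from {len(scores)} samples")
    Z = hierarchy.ward(scores.to_numpy())
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=scores.index, name="soil_group")
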