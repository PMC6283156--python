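"""Trait reduction: per-condition PCA with a 90%-variance rule, trait clustering,
and representative-trait selection for validation assays."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class PCSet:
    """Principal components of the standardized trait matrix for one condition.

    ``n_selected`` is the smallest number of leading components whose
    cumulative variance fraction reaches ``variance_threshold``.
    """

    condition: str
    trait_names: list[str]
    loadings: np.ndarray  # traits x components, orthonormal columns
    scores: pd.DataFrame  # strains x components
    variance_fractions: np.ndarray
    n_selected: int
    variance_threshold: float


@dataclass
class TraitClustering:
    condition: str
    trait_names: list[str]
    correlation: pd.DataFrame
    linkage: np.ndarray
    groups: pd.Series  # trait -> group label (1..k)
    k: int


def pca_select(
    pheno: pd.DataFrame,
    variance_threshold: float = 0.90,
    condition: str = "",
) -> PCSet:
    """PCA of the strain x trait matrix after scaling each trait to mean 0, SD 1.

    Strains with any missing trait are dropped; constant traits are dropped
    with a warning (their SD is 0 and they carry no variance to decompose).
    PC signs are fixed so each component's largest-magnitude loading is
    positive.
    """
    X = pheno.dropna(axis=0, how="any")
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 complete strains and 2 traits")
    sd = X.std(ddof=1)
    const = sd[sd == 0].index
    if len(const):
        warnings.warn(f"dropping constant traits: {list(const)}")
        X = X.drop(columns=const)
        sd = sd.drop(const)
    Z = (X - X.mean()) / sd
    # SVD of the standardized matrix == eigendecomposition of the correlation matrix
    U, svals, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    var = svals**2 / (Z.shape[0] - 1)
    frac = var / var.sum()
    load = Vt.T
    sign = np.sign(load[np.argmax(np.abs(load), axis=0), np.arange(load.shape[1])])
    sign[sign == 0] = 1.0
    load = load * sign
    scores = Z.to_numpy() @ load
    cum = np.cumsum(frac)
    n_selected = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    cols = [f"PC{i+1}" for i in range(load.shape[1])]
    return PCSet(
        condition=condition,
        trait_names=list(X.columns),
        loadings=load,
        scores=pd.DataFrame(scores, index=X.index, columns=cols),
        variance_fractions=frac,
        n_selected=n_selected,
        variance_threshold=variance_threshold,
    )


def cluster_traits(pheno: pd.DataFrame, k: int, condition: str = "") -> TraitClustering:
    """Hierarchical clustering of traits cut into exactly ``k`` groups.

    Distance is 1 - |Pearson correlation| (pairwise-complete observations),
    with complete linkage; the dendrogram is cut to ``k`` clusters.
    """
    if not 1 <= k <= pheno.shape[1]:
        raise ValueError(f"k={k} outside 1..{pheno.shape[1]}")
    corr = pheno.corr(method="pearson", min_periods=2)
    dist = 1.0 - corr.abs()
    np.fill_diagonal(dist.values, 0.0)
    condensed = squareform(dist.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return TraitClustering(
        condition=condition,
        trait_names=list(pheno.columns),
        correlation=corr,
        linkage=Z,
        groups=pd.Series(labels, index=pheno.columns),
        k=k,
    )


def representative_traits(
    pc_scores: pd.Series,
    pheno: pd.DataFrame,
    clustering: TraitClustering,
) -> tuple[list[str], tuple[float, float]]:
    """Traits to carry into a validation assay for one principal component.

    Picks the trait with the highest |correlation| to the PC scores (ties
    broken by trait-name order), then returns every trait in that trait's
    cluster, ordered by decreasing |correlation|, together with the (min, max)
    range of the absolute correlations across the returned traits.
    """
    common = pheno.index.intersection(pc_scores.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared strains")
    cors = {}
    for t in pheno.columns:
        sub = pd.concat([pc_scores[common], pheno.loc[common, t]], axis=1).dropna()
        cors[t] = float(np.corrcoef(sub.iloc[:, 0], sub.iloc[:, 1])[0, 1])
    abs_cors = pd.Series({t: abs(c) for t, c in cors.items()})
    # ties broken deterministically by trait name
    best = abs_cors.sort_index().sort_values(kind="stable", ascending=False).index[0]
    grp = clustering.groups[best]
    members = [t for t in clustering.trait_names if clustering.groups[t] == grp]
    members = sorted(members, key=lambda t: (-abs_cors[t], t))
    rng = (float(abs_cors[members].min()), float(abs_cors[members].max()))
    return members, rng
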