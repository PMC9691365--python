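"""Sample-structure diagnostics on enrichment matrices.

PCA and average-linkage hierarchical clustering of samples, computed on
log2(RPM+1), region-centered signal at a chosen region subset (typically
the CAF-activated enhancers).  Both are deterministic: PCA signs follow a
fixed convention and clustering ties resolve by sample order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .intervals import RegionSet
from .quant import EnrichmentMatrix

__all__ = ["SampleEmbedding", "pca_on_regions", "hierarchical_clusters"]


@dataclass
class SampleEmbedding:
    """Sample coordinates in component space plus the transform record."""

    coordinates: pd.DataFrame        # samples x components
    explained_variance_ratio: np.ndarray
    transform: str

    def __post_init__(self) -> None:
        evr = self.explained_variance_ratio
        if np.any(evr < -1e-12) or np.any(evr > 1 + 1e-12):
            raise ValueError("explained-variance fractions must lie in [0, 1]")
        if np.any(np.diff(evr) > 1e-12):
            raise ValueError("explained-variance fractions must be non-increasing")


def _transformed_sample_matrix(
    matrix: EnrichmentMatrix, region_subset: RegionSet | None
) -> pd.DataFrame:
    """samples x regions array of log2(x+1), region-centered signal."""
    values = matrix.values
    if region_subset is not None:
        if len(region_subset) == 0:
            raise ValueError("region subset is empty")
        ids = region_subset.region_ids
        missing = [r for r in ids if r not in values.index]
        if missing:
            raise KeyError(f"regions not in matrix: {missing[:3]}...")
        values = values.loc[ids]
    x = np.log2(values.to_numpy(dtype=float) + 1.0)
    x = x - x.mean(axis=1, keepdims=True)  # center each region across samples
    return pd.DataFrame(x.T, index=values.columns, columns=values.index)


def pca_on_regions(
    matrix: EnrichmentMatrix,
    region_subset: RegionSet | None = None,
    n_components: int = 2,
) -> SampleEmbedding:
    """PCA of samples on enrichment at a region subset.

    Signal is log2(RPM+1)-transformed and centered per region.  Component
    signs are fixed by making the largest-magnitude region loading of each
    component positive, so the embedding is fully deterministic.
    """
    x = _transformed_sample_matrix(matrix, region_subset)
    n_samples, n_regions = x.shape
    if n_components > min(n_samples, n_regions):
        raise ValueError("n_components exceeds matrix dimensions")
    arr = x.to_numpy()
    if np.allclose(arr, arr[0], atol=1e-12) or np.allclose(arr.std(axis=0), 0):
        raise ValueError("matrix has zero variance across samples")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(arr)
    loadings = pca.components_
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1
            coords[:, k] *= -1
    return SampleEmbedding(
        coordinates=pd.DataFrame(
            coords,
            index=x.index,
            columns=[f"PC{k + 1}" for k in range(n_components)],
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
        transform="log2(x+1), region-centered",
    )


def hierarchical_clusters(
    matrix: EnrichmentMatrix,
    region_subset: RegionSet | None = None,
    k: int = 2,
    method: str = "average",
    metric: str = "euclidean",
) -> dict[str, int]:
    """Agglomerative clustering of samples cut at k clusters.

    Average linkage on Euclidean distances of the transformed sample
    profiles by default.  Returns sample -> 1-based cluster label.
    """
    x = _transformed_sample_matrix(matrix, region_subset)
    if k > len(x):
        raise ValueError(f"k={k} exceeds the {len(x)} samples")
    z = linkage(x.to_numpy(), method=method, metric=metric)
    labels = fcluster(z, t=k, criterion="maxclust")
    return {sample: int(lab) for sample, lab in zip(x.index, labels)}
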