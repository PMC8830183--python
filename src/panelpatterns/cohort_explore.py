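"""Unsupervised structure discovery on the genotype matrix.

PCA (samples as observations, variants as mean-centered features) with
contributor ranking, Jaccard-distance embedding via t-SNE, average-linkage
hierarchical clustering, tag-SNP haplotype labelling (e.g. the MAPT H1/H2
system from rs1052553 and rs1800547), and concordance between discovered
clusters and external labels.

Features are mean-centered but never variance-scaled: on binary/ternary
dosages, unit-variance scaling would inflate rare variants. PCA signs are
canonicalized so that the largest-|loading| entry of each component is
positive, making loadings tables reproducible across runs and libraries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score

from .variant_matrix import GenotypeMatrix, VariantKey

__all__ = [
    "Embedding",
    "HaplotypeCall",
    "pca_embed",
    "top_contributors",
    "jaccard_distance_matrix",
    "tsne_embed",
    "hierarchical_clusters",
    "assign_tag_haplotype",
    "cluster_label_concordance",
]

HAPLOTYPE_LABELS = ("H1/H1", "H1/H2", "H2/H2", "inconsistent", "uncallable")


@dataclass
class Embedding:
    """PCA decomposition of a genotype matrix.

    ``scores`` is samples × components (projections of the centered
    data), ``loadings`` is variants × components with unit-norm columns,
    and ``explained_variance_ratio`` is non-increasing.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    variants: list[VariantKey]
    samples: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class HaplotypeCall:
    sample_id: str
    haplotype: str

    def __post_init__(self) -> None:
        # labels may be caller-supplied (e.g. "H1/H2" or NOTCH3 names); no fixed set
        if not self.haplotype:
            raise ValueError("empty haplotype label")


def pca_embed(matrix: GenotypeMatrix, n_components: int) -> Embedding:
    """Principal component analysis of samples by their variant profile.

    Samples (columns of the matrix) are the observations and variants
    the features. Features are mean-centered only. Signs are fixed per
    component so the entry of largest absolute loading is positive.
    """
    n_var, n_samp = matrix.shape
    if not 1 <= n_components <= min(n_var, n_samp):
        raise ValueError(
            f"n_components must be in [1, {min(n_var, n_samp)}], got {n_components}")
    X = matrix.values.T.astype(float)  # samples x variants
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("matrix has zero variance (all samples identical)")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()  # variants x components, unit columns
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return Embedding(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        variants=list(matrix.variants),
        samples=list(matrix.samples),
    )


def top_contributors(embedding: Embedding, component: int, k: int
                     ) -> list[tuple[VariantKey, float]]:
    """Variants ranked by |loading| on one component, ties by row order."""
    if not 0 <= component < embedding.n_components:
        raise ValueError(f"component {component} out of range "
                         f"[0, {embedding.n_components})")
    if k < 1:
        raise ValueError("k must be positive")
    load = embedding.loadings[:, component]
    order = np.argsort(-np.abs(load), kind="stable")
    return [(embedding.variants[i], float(load[i])) for i in order[:k]]


def jaccard_distance_matrix(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise Jaccard distance between samples' variant presence sets.

    ``d(a, b) = 1 − |a ∩ b| / |a ∪ b|``; two samples with no variants at
    all get distance 0 by convention.
    """
    if matrix.mode != "binary":
        raise ValueError("Jaccard distance requires a binary matrix; "
                         "call .binarize() first")
    B = matrix.values.astype(np.int64)
    inter = B.T @ B
    sizes = B.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    d[union == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.samples, columns=matrix.samples)


def tsne_embed(distances: pd.DataFrame | np.ndarray, seed: int,
               perplexity: float = 30.0) -> np.ndarray:
    """2-D t-SNE of a precomputed distance matrix; deterministic per seed.

    Perplexity is clamped below ``(n − 1) / 3`` with a warning so small
    cohorts still embed.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 samples for t-SNE, got {n}")
    max_perp = (n - 1) / 3
    if perplexity >= max_perp:
        clamped = max(1.0, max_perp - 1e-9)
        warnings.warn(f"perplexity {perplexity} clamped to {clamped:.2f} "
                      f"for n={n} samples")
        perplexity = clamped
    tsne = TSNE(n_components=2, metric="precomputed", init="random",
                random_state=int(seed), perplexity=perplexity)
    return tsne.fit_transform(D)


def hierarchical_clusters(distances: pd.DataFrame | np.ndarray, k: int
                          ) -> np.ndarray:
    """Average-linkage clustering of a distance matrix, cut at k clusters."""
    D = np.asarray(distances, dtype=float)
    Z = linkage(squareform(D, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust")


def assign_tag_haplotype(
    matrix: GenotypeMatrix,
    tag_keys: Sequence[VariantKey | str],
    names: tuple[str, str] = ("H1", "H2"),
) -> list[HaplotypeCall]:
    """Diplotype labels from tag-SNP zygosities (e.g. MAPT H1/H2).

    Each tag SNP contributes the sample's zygosity for its minor
    (haplotype-tagging) allele; a tag absent from the matrix counts as
    zygosity 0 everywhere. Samples whose tags all agree are labelled
    ``major/major`` (0), ``major/minor`` (1) or ``minor/minor`` (2);
    any disagreement yields ``"inconsistent"``.
    """
    if matrix.mode != "ternary":
        raise ValueError("haplotype assignment needs zygosity (ternary matrix)")
    if not tag_keys:
        raise ValueError("empty tag-SNP list")
    major, minor = names
    n = len(matrix.samples)
    rows = []
    for tag in tag_keys:
        try:
            rows.append(matrix.values[matrix.index_of(tag), :])
        except KeyError:
            rows.append(np.zeros(n, dtype=np.int8))  # absent tag: all zygosity 0
    Z = np.vstack(rows)
    label_for = {0: f"{major}/{major}", 1: f"{major}/{minor}", 2: f"{minor}/{minor}"}
    calls = []
    for j, sid in enumerate(matrix.samples):
        z = Z[:, j]
        calls.append(HaplotypeCall(
            sid, label_for[int(z[0])] if (z == z[0]).all() else "inconsistent"))
    return calls


def cluster_label_concordance(
    cluster_labels: Mapping[str, object],
    annotation: Mapping[str, object],
) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate two labelings of the same samples and score agreement.

    Returns the contingency table (clusters × annotation) and the
    adjusted Rand index.
    """
    if set(cluster_labels) != set(annotation):
        raise ValueError("cluster labels and annotation cover different samples")
    samples = sorted(cluster_labels)
    a = [cluster_labels[s] for s in samples]
    b = [annotation[s] for s in samples]
    table = pd.crosstab(pd.Series(a, name="cluster"),
                        pd.Series(b, name="annotation"))
    ari = float(adjusted_rand_score(
        pd.factorize(np.asarray(a, dtype=object))[0],
        pd.factorize(np.asarray(b, dtype=object))[0]))
    return table, ari
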