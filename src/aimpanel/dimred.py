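"""Low-dimensional views of genotype matrices: PCA and classical MDS.

PCA follows the normalization conventional for population-structure
analysis of SNP data: each locus is centered by twice its posterior allele
frequency p_hat = (1 + counted-allele count) / (2 + 2n) and scaled by
sqrt(p_hat (1 - p_hat)), the binomial standard deviation expected under
drift; missing entries are set to 0 after centering (i.e. to the locus
mean). Monomorphic loci are dropped. Components come from the SVD of the
normalized matrix, with eigenvalues of the sample covariance and the
proportion of variance each explains.

MDS operates on identity-by-state (IBS) distances: the similarity of two
individuals is the fraction of allele copies they share across mutually
non-missing loci, and distance = 1 - similarity. Classical (Torgerson)
scaling double-centers the squared distances and embeds the top
non-negative eigenpairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DataError, GenotypeDataset, SampleMetadata


@dataclass
class PCAResult:
    scores: np.ndarray
    eigenvalues: np.ndarray
    proportion_variance: np.ndarray
    locus_ids: list[str]
    sample_ids: list[str]
    center: np.ndarray
    scale: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            columns=[f"PC{i + 1}" for i in range(self.scores.shape[1])],
        )
        df.insert(0, "sample_id", self.sample_ids)
        return df


def pca(dataset: GenotypeDataset, n_components: int | None = None) -> PCAResult:
    """Genotype PCA with drift-scaled normalization and missing->mean."""
    g = dataset.dosages
    n, L = g.shape
    if n < 2 or L < 2:
        raise DataError("PCA needs >= 2 samples and >= 2 loci")
    obs = ~np.isnan(g)
    count = np.nansum(g, axis=0)
    n_obs = obs.sum(axis=0)
    phat = (1.0 + count) / (2.0 + 2.0 * n_obs)
    raw_freq = np.where(n_obs > 0, count / np.maximum(2.0 * n_obs, 1), np.nan)
    poly = (n_obs > 0) & (raw_freq > 0) & (raw_freq < 1)
    if not poly.any():
        raise DataError("all loci monomorphic; PCA undefined")
    if not poly.all():
        warnings.warn(f"dropping {int((~poly).sum())} monomorphic loci")
    keep = np.where(poly)[0]
    center = 2.0 * phat[keep]
    scale = np.sqrt(phat[keep] * (1.0 - phat[keep]))
    x = np.where(obs[:, keep], g[:, keep], center) - center
    x /= scale
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    total = eigenvalues.sum()
    k = min(n_components or len(eigenvalues), len(eigenvalues))
    scores = u[:, :k] * s[:k]
    # deterministic sign: orient each component so its largest-|.| loading is positive
    for j in range(k):
        i_max = int(np.argmax(np.abs(vt[j])))
        if vt[j, i_max] < 0:
            scores[:, j] = -scores[:, j]
    return PCAResult(
        scores,
        eigenvalues[:k],
        eigenvalues[:k] / total,
        [dataset.loci[j].locus_id for j in keep],
        list(dataset.sample_ids),
        center,
        scale,
    )


def population_centroids(
    result: PCAResult, metadata: Sequence[SampleMetadata]
) -> pd.DataFrame:
    """Mean component scores per population (for population-level plots)."""
    pop = {m.sample_id: m.population for m in metadata}
    missing = [s for s in result.sample_ids if s not in pop]
    if missing:
        raise DataError(f"samples without metadata: {missing[:5]}")
    df = result.to_frame()
    df["population"] = [pop[s] for s in result.sample_ids]
    return df.groupby("population", sort=True).mean(numeric_only=True).reset_index()


def ibs_distance(dataset: GenotypeDataset) -> np.ndarray:
    """1 - identity-by-state similarity for every sample pair.

    s_ij = sum_l (2 - |g_il - g_jl|) / (2 L_ij) over mutually non-missing
    loci; a pair sharing no locus is an error.
    """
    g = dataset.dosages
    n = g.shape[0]
    obs = ~np.isnan(g)
    d = np.zeros((n, n))
    for i in range(n):
        both = obs[i] & obs
        shared = both.sum(axis=1)
        diff = np.where(both, np.abs(g[i] - np.where(obs, g, 0.0)), 0.0).sum(axis=1)
        zero = shared == 0
        zero[i] = False
        if zero.any():
            j = int(np.where(zero)[0][0])
            raise DataError(
                f"samples {dataset.sample_ids[i]!r} and {dataset.sample_ids[j]!r} "
                "share no non-missing locus"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = (2.0 * shared - diff) / (2.0 * shared)
        d[i] = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return d


def classical_mds(distance: np.ndarray, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson scaling of a distance matrix; returns (scores, eigenvalues).

    Negative eigenvalues (non-Euclidean distances) are dropped with a
    warning; k is truncated to the positive-eigenvalue count.
    """
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise DataError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise DataError("distance matrix must be symmetric with zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    if (~pos[: min(k, n)]).any():
        warnings.warn("negative/zero eigenvalues dropped from MDS embedding")
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(f"k={k} exceeds {n_pos} positive eigenvalues; truncating")
        k = n_pos
    if k == 0:
        return np.zeros((n, 0)), vals[:0]
    scores = vecs[:, :k] * np.sqrt(vals[:k])
    for jcol in range(k):
        i_max = int(np.argmax(np.abs(scores[:, jcol])))
        if scores[i_max, jcol] < 0:
            scores[:, jcol] = -scores[:, jcol]
    return scores, vals[:k]
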