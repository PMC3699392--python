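"""Population-differentiation statistics.

Pairwise F_ST between groups of individuals is estimated with the
Weir–Cockerham (1984) theta: per locus, the allele-frequency variance is
decomposed into components *a* (among groups), *b* (among individuals
within groups) and *c* (within individuals, driven by observed
heterozygosity), and the multi-locus estimate is the ratio of sums
sum(a) / sum(a + b + c) over loci with defined components. Negative
estimates are reported as computed (they are valid draws of an unbiased
estimator around 0) unless ``floor_at_zero`` is requested.

Significance is assessed by permuting individuals between the two groups,
holding group sizes fixed, with the add-one rule
p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1), which can never return
an exact zero.

The Mantel test correlates two distance matrices over their lower-triangle
entries, with significance from jointly permuting the rows and columns of
the second matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .io import DataError, GenotypeDataset


# ---------------------------------------------------------------------------
# Weir–Cockerham variance components


def _wc_components(dosages_by_group: list[np.ndarray]) -> tuple[np.ndarray, ...]:
    """Per-locus (a, b, c) for r groups given each group's dosage matrix.

    Works on counted-allele dosages with NaN missingness; loci where any
    group has < 1 observed genotype, or where the pooled locus is
    monomorphic, yield NaN components and are dropped from the ratio of
    sums by the caller.
    """
    r = len(dosages_by_group)
    n_i = np.stack([np.sum(~np.isnan(g), axis=0) for g in dosages_by_group])  # r x L
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.stack([np.nansum(g, axis=0) for g in dosages_by_group]) / (2.0 * n_i)
        h_i = np.stack(
            [np.sum(g == 1, axis=0) for g in dosages_by_group]
        ) / n_i  # observed heterozygote fraction

    valid = (n_i >= 1).all(axis=0)
    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
    # degenerate loci: monomorphic pooled sample or nbar == 1
    degenerate = ~valid | (nbar <= 1) | np.isclose(pbar * (1 - pbar) + s2, 0.0)
    for arr in (a, b, c):
        arr[degenerate] = np.nan
    return a, b, c


def wc_fst(
    dataset: GenotypeDataset,
    labels: Sequence[str],
    pair: tuple[str, str],
    floor_at_zero: bool = False,
) -> float:
    """Multi-locus Weir–Cockerham F_ST between two labelled groups."""
    lab = np.asarray(labels)
    groups = [dataset.dosages[lab == g] for g in pair]
    for g, name in zip(groups, pair):
        if g.shape[0] < 2:
            raise DataError(f"group {name!r} needs >= 2 individuals")
    a, b, c = _wc_components(groups)
    ok = ~np.isnan(a)
    if not ok.any():
        raise DataError("no locus with defined variance components for this pair")
    theta = float(np.sum(a[ok]) / np.sum(a[ok] + b[ok] + c[ok]))
    return max(theta, 0.0) if floor_at_zero else theta


def _theta_from_matrix(x1: np.ndarray, x2: np.ndarray) -> float:
    a, b, c = _wc_components([x1, x2])
    ok = ~np.isnan(a)
    if not ok.any():
        return np.nan
    return float(np.sum(a[ok]) / np.sum(a[ok] + b[ok] + c[ok]))


def fst_permutation_test(
    dataset: GenotypeDataset,
    labels: Sequence[str],
    pair: tuple[str, str],
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Permutation p-value for pairwise F_ST; returns (theta_obs, p).

    Individuals are shuffled between the two groups preserving group sizes.
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    lab = np.asarray(labels)
    mask = np.isin(lab, pair)
    sub = dataset.dosages[mask]
    sub_lab = lab[mask]
    n1 = int(np.sum(sub_lab == pair[0]))
    if n1 < 2 or sub.shape[0] - n1 < 2:
        raise DataError("both groups need >= 2 individuals")
    obs = _theta_from_matrix(sub[sub_lab == pair[0]], sub[sub_lab == pair[1]])
    exceed = 0
    idx = np.arange(sub.shape[0])
    for _ in range(n_perm):
        rng.shuffle(idx)
        t = _theta_from_matrix(sub[idx[:n1]], sub[idx[n1:]])
        if not np.isnan(t) and t >= obs - 1e-15:
            exceed += 1
    return obs, (1.0 + exceed) / (n_perm + 1.0)


@dataclass
class FstMatrix:
    """Symmetric group x group F_ST matrix with permutation p-values."""

    groups: list[str]
    fst: np.ndarray
    pvalues: np.ndarray | None
    n_permutations: int

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.groups.index(pair[0]), self.groups.index(pair[1])
        return float(self.fst[i, j])


def pairwise_fst_matrix(
    dataset: GenotypeDataset,
    labels: Sequence[str],
    n_perm: int = 0,
    seed: int = 0,
    exclude_groups: Sequence[str] = (),
) -> FstMatrix:
    """All pairwise F_ST values (and permutation p-values when n_perm > 0)."""
    groups = sorted(set(labels) - set(exclude_groups))
    if len(groups) < 2:
        raise DataError("need >= 2 groups after exclusions")
    G = len(groups)
    fst = np.zeros((G, G))
    pvals = np.ones((G, G)) if n_perm else None
    rng = np.random.default_rng(seed)
    for i, j in combinations(range(G), 2):
        pair = (groups[i], groups[j])
        if n_perm:
            theta, p = fst_permutation_test(dataset, labels, pair, n_perm, rng)
            pvals[i, j] = pvals[j, i] = p
        else:
            theta = wc_fst(dataset, labels, pair)
        fst[i, j] = fst[j, i] = theta
    return FstMatrix(groups, fst, pvals, n_perm)


# ---------------------------------------------------------------------------
# Mantel test


def mantel(
    d1: np.ndarray,
    d2: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation between two square distance matrices.

    r is the Pearson correlation of the strict lower triangles; p comes
    from jointly permuting the rows and columns of ``d2``, two-sided on |r|.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape or d1.ndim != 2 or d1.shape[0] != d1.shape[1]:
        raise DataError("matrices must be square and of identical shape")
    if not (np.allclose(d1, d1.T) and np.allclose(d2, d2.T)):
        raise DataError("matrices must be symmetric")
    il = np.tril_indices_from(d1, k=-1)
    v1, v2 = d1[il], d2[il]
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise DataError("zero variance in a lower triangle; r undefined")
    r = float(np.corrcoef(v1, v2)[0, 1])
    rng = np.random.default_rng(seed)
    n = d1.shape[0]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        v2p = d2[np.ix_(perm, perm)][il]
        rp = float(np.corrcoef(v1, v2p)[0, 1])
        if abs(rp) >= abs(r) - 1e-15:
            exceed += 1
    return r, (1.0 + exceed) / (n_perm + 1.0)
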