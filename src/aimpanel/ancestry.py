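"""Likelihood-based estimation of individual admixture proportions.

Model: individual i carries, at each biallelic locus l, two allele copies
drawn independently; each copy originates from ancestral cluster k with
probability q_ik (the admixture proportions, a point on the K-simplex) and
is then the counted allele with probability p_lk, the cluster's allele
frequency. With dosage g_il and loci treated as independent (appropriate
for an LD-pruned panel), the log-likelihood of one individual is

    l(q) = sum_l [ g_l ln(sum_k q_k p_lk) + (2 - g_l) ln(sum_k q_k (1 - p_lk)) ]

over non-missing loci. *Supervised* estimation fixes p from labelled
reference individuals and maximises over q per sample by EM. *Unsupervised*
estimation alternates the q-step with a frequency update from the
allele-origin responsibilities, from random Dirichlet starts, keeping the
best of several restarts. Both updates monotonically increase the
likelihood.

This is a deterministic maximum-likelihood replacement for MCMC-based
clustering: the quantity produced (the Q matrix of ancestry proportions)
is the same, without posterior uncertainty.

Cluster labels of independent runs are arbitrary (label switching); runs
are aligned by exhaustive search over column permutations maximising the
summed inner product of membership rows, the same criterion used by
replicate-alignment tools in this field.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DataError, GenotypeDataset, SampleMetadata

UNASSIGNED = "unassigned"


@dataclass
class ReferenceFreqs:
    """Loci x K cluster allele frequencies, clamped away from 0 and 1."""

    freqs: np.ndarray
    clusters: list[str]
    locus_ids: list[str]
    eps: float = 1e-6

    def __post_init__(self) -> None:
        self.freqs = np.clip(np.asarray(self.freqs, dtype=float), self.eps, 1 - self.eps)
        if len(set(self.clusters)) != len(self.clusters):
            raise DataError("cluster labels must be unique")
        if self.freqs.shape != (len(self.locus_ids), len(self.clusters)):
            raise DataError("frequency matrix does not match registries")

    @property
    def k(self) -> int:
        return len(self.clusters)


@dataclass
class AdmixtureMatrix:
    """Samples x K ancestry proportions with per-sample log-likelihood."""

    q: np.ndarray
    clusters: list[str]
    sample_ids: list[str]
    loglik: np.ndarray
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        rows = self.q.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8) or (self.q < -1e-12).any():
            raise DataError("each q row must be non-negative and sum to 1")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.q, columns=self.clusters)
        df.insert(0, "sample_id", self.sample_ids)
        df["loglik"] = self.loglik
        return df


def estimate_ref_freqs(
    dataset: GenotypeDataset,
    labels: Sequence[str],
    pseudocount: float = 0.5,
    eps: float = 1e-6,
) -> ReferenceFreqs:
    """Cluster allele frequencies from labelled individuals.

    p_lk = (counted-allele copies + pseudocount) / (chromosomes + 2 x
    pseudocount); the default pseudocount 0.5 is a Jeffreys-style shrinkage
    that keeps rare reference alleles off the likelihood boundary. Cells
    with zero observations fall back to the pseudocount prior mean (0.5).
    """
    lab = np.asarray(labels)
    clusters = sorted(set(labels))
    freqs = np.empty((dataset.n_loci, len(clusters)))
    for k, name in enumerate(clusters):
        sub = dataset.dosages[lab == name]
        if sub.shape[0] == 0:
            raise DataError(f"cluster {name!r} has no labelled individuals")
        chrom = 2.0 * np.sum(~np.isnan(sub), axis=0)
        count = np.nansum(sub, axis=0)
        if (chrom == 0).any():
            warnings.warn(
                f"cluster {name!r}: {int((chrom == 0).sum())} loci with no calls; "
                "frequency from pseudocount alone"
            )
        freqs[:, k] = (count + pseudocount) / (chrom + 2.0 * pseudocount)
    return ReferenceFreqs(freqs, clusters, dataset.locus_ids, eps)


# ---------------------------------------------------------------------------
# supervised EM


def _em_q_step(g: np.ndarray, obs: np.ndarray, q: np.ndarray, p: np.ndarray) -> np.ndarray:
    """One EM sweep updating q for all samples at once.

    g: N x L dosages (NaN -> 0 with obs mask), q: N x K, p: L x K.
    """
    # mixture means per sample x locus
    fa = q @ p.T  # N x L: P(counted allele)
    fb = q @ (1 - p).T
    # responsibilities summed over loci
    # a_ilk = q_ik p_lk / fa_il ; contribution g_il * a_ilk
    wa = np.where(obs, g / fa, 0.0)  # N x L
    wb = np.where(obs, (2 - g) / fb, 0.0)
    num = q * (wa @ p + wb @ (1 - p))  # N x K
    denom = 2.0 * obs.sum(axis=1, keepdims=True)
    return num / denom


def _loglik(g: np.ndarray, obs: np.ndarray, q: np.ndarray, p: np.ndarray) -> np.ndarray:
    fa = q @ p.T
    fb = q @ (1 - p).T
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs, g * np.log(fa) + (2 - g) * np.log(fb), 0.0)
    return terms.sum(axis=1)


def supervised_em(
    genotypes: np.ndarray,
    ref: ReferenceFreqs,
    tol: float = 1e-7,
    max_iter: int = 2000,
) -> tuple[np.ndarray, float]:
    """ML admixture proportions of one sample against fixed cluster frequencies.

    Returns (q on the simplex, final log-likelihood). Missing loci are
    dropped from the likelihood; an all-missing sample is an error.
    """
    g = np.asarray(genotypes, dtype=float)[None, :]
    res = supervised_admixture_matrix(g, ref, ["s"], tol, max_iter)
    return res.q[0], float(res.loglik[0])


def supervised_admixture_matrix(
    dosages: np.ndarray,
    ref: ReferenceFreqs,
    sample_ids: Sequence[str],
    tol: float = 1e-7,
    max_iter: int = 2000,
) -> AdmixtureMatrix:
    """Vectorised supervised EM over a whole dosage matrix."""
    g = np.asarray(dosages, dtype=float)
    if g.shape[1] != len(ref.locus_ids):
        raise DataError("dosage columns do not match reference loci")
    obs = ~np.isnan(g)
    if (~obs).all(axis=1).any():
        bad = [sample_ids[i] for i in np.where((~obs).all(axis=1))[0]]
        raise DataError(f"samples with no non-missing locus: {bad[:5]}")
    g = np.where(obs, g, 0.0)
    n, k = g.shape[0], ref.k
    q = np.full((n, k), 1.0 / k)
    ll = _loglik(g, obs, q, ref.freqs)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        q = _em_q_step(g, obs, q, ref.freqs)
        new_ll = _loglik(g, obs, q, ref.freqs)
        if np.max(np.abs(new_ll - ll)) < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll
    q = q / q.sum(axis=1, keepdims=True)  # guard round-off
    return AdmixtureMatrix(q, list(ref.clusters), list(sample_ids), ll, it, converged)


def supervised_admixture(
    dataset: GenotypeDataset,
    ref: ReferenceFreqs,
    tol: float = 1e-7,
    max_iter: int = 2000,
) -> AdmixtureMatrix:
    """Supervised EM for every sample of a dataset (loci matched by id)."""
    data = dataset.subset_loci(ref.locus_ids)
    return supervised_admixture_matrix(
        data.dosages, ref, data.sample_ids, tol, max_iter
    )


# ---------------------------------------------------------------------------
# unsupervised EM


def unsupervised_em(
    dataset: GenotypeDataset,
    k: int,
    seed: int = 0,
    restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    eps: float = 1e-6,
) -> tuple[AdmixtureMatrix, ReferenceFreqs]:
    """Joint ML estimation of Q and cluster frequencies at a given K.

    Alternates an EM sweep over every sample's q with the closed-form
    frequency update from the allele-origin responsibilities. Each restart
    draws q from Dirichlet(1, ..., 1); the restart with the best final
    log-likelihood is returned. Clusters are labelled "K1".."Kk".
    """
    if k < 1:
        raise DataError("k must be >= 1")
    if k > dataset.n_samples:
        raise DataError("k exceeds sample count")
    if restarts < 1:
        raise DataError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    g_raw = dataset.dosages
    obs = ~np.isnan(g_raw)
    g = np.where(obs, g_raw, 0.0)
    n, L = g.shape
    best: tuple[float, np.ndarray, np.ndarray, int, bool] | None = None
    for _ in range(restarts):
        q = rng.dirichlet(np.ones(k), size=n)
        # frequency init: responsibility-weighted pooled frequencies
        p = np.clip(
            (q.T @ g) / np.maximum((q.T @ (2.0 * obs)), 1e-12), eps, 1 - eps
        ).T  # L x K
        ll_total = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            q = _em_q_step(g, obs, q, p)
            # responsibilities for the frequency update
            fa = q @ p.T  # N x L
            fb = q @ (1 - p).T
            wa = np.where(obs, g / fa, 0.0)
            wb = np.where(obs, (2 - g) / fb, 0.0)
            num = (wa.T @ q) * p  # L x K: sum_i g_il a_ilk
            den = num + (wb.T @ q) * (1 - p)
            p = np.clip(num / np.maximum(den, 1e-300), eps, 1 - eps)
            new_ll = float(_loglik(g, obs, q, p).sum())
            if abs(new_ll - ll_total) < tol * max(1.0, abs(new_ll)):
                ll_total = new_ll
                converged = True
                break
            ll_total = new_ll
        if best is None or ll_total > best[0]:
            best = (ll_total, q, p, it, converged)
    ll_total, q, p, it, converged = best
    clusters = [f"K{i + 1}" for i in range(k)]
    q = q / q.sum(axis=1, keepdims=True)
    per_sample_ll = _loglik(g, obs, q, p)
    qm = AdmixtureMatrix(q, clusters, list(dataset.sample_ids), per_sample_ll, it, converged)
    return qm, ReferenceFreqs(p, clusters, dataset.locus_ids, eps)


# ---------------------------------------------------------------------------
# replicate alignment and assignment


def align_replicates(
    q_list: Sequence[np.ndarray | AdmixtureMatrix],
) -> tuple[list[np.ndarray], list[tuple[int, ...]], float]:
    """Align cluster columns of replicate runs to the first run.

    Exhaustive search over all K! column permutations, maximising the summed
    elementwise product with the first run's matrix. Returns (aligned
    matrices, permutations, mean pairwise similarity). K is capped at 10;
    beyond that the factorial search is infeasible and a greedy matcher
    should be used instead.
    """
    mats = [m.q if isinstance(m, AdmixtureMatrix) else np.asarray(m) for m in q_list]
    if not mats:
        raise DataError("no replicates supplied")
    k = mats[0].shape[1]
    if k > 10:
        raise DataError("K > 10: exhaustive alignment infeasible; use a greedy matcher")
    if any(m.shape != mats[0].shape for m in mats):
        raise DataError("replicates must share samples and K")
    ref = mats[0]
    aligned = [ref]
    perms: list[tuple[int, ...]] = [tuple(range(k))]
    for m in mats[1:]:
        best_perm, best_score = None, -np.inf
        for perm in itertools.permutations(range(k)):
            score = float(np.sum(ref * m[:, perm]))
            if score > best_score:
                best_perm, best_score = perm, score
        aligned.append(m[:, best_perm])
        perms.append(best_perm)
    sims = []
    for i in range(len(aligned)):
        for j in range(i + 1, len(aligned)):
            sims.append(
                1.0
                - np.abs(aligned[i] - aligned[j]).sum()
                / (2.0 * aligned[i].shape[0])
            )
    similarity = float(np.mean(sims)) if sims else 1.0
    return aligned, perms, similarity


def assign_clusters(
    admixture: AdmixtureMatrix | np.ndarray,
    threshold: float,
    clusters: Sequence[str] | None = None,
) -> list[str]:
    """Assign each sample to the cluster with membership strictly above
    ``threshold``, else "unassigned"."""
    if not 0 < threshold <= 1:
        raise DataError("threshold must be in (0, 1]")
    if isinstance(admixture, AdmixtureMatrix):
        q, clusters = admixture.q, admixture.clusters
    else:
        q = np.asarray(admixture)
        if clusters is None:
            raise DataError("cluster names required with a bare matrix")
    out = []
    for row in q:
        j = int(np.argmax(row))
        out.append(clusters[j] if row[j] > threshold else UNASSIGNED)
    return out


def population_summary(
    admixture: AdmixtureMatrix,
    metadata: Sequence[SampleMetadata],
    thresholds: Sequence[float] = (0.85, 0.5),
    expected_region_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-population mean cluster membership and correct-assignment rates.

    For each threshold t, the column ``assigned:{t}`` is the fraction of the
    population's samples assigned (strictly above t) to its expected
    cluster; blank when the population has no entry in
    ``expected_region_map``.
    """
    meta_by_id = {m.sample_id: m for m in metadata}
    missing = [s for s in admixture.sample_ids if s not in meta_by_id]
    if missing:
        raise DataError(f"samples without metadata: {missing[:5]}")
    pops = [meta_by_id[s].population for s in admixture.sample_ids]
    df = pd.DataFrame(admixture.q, columns=admixture.clusters)
    df["population"] = pops
    rows = []
    for pop, grp in df.groupby("population", sort=True):
        row: dict[str, object] = {"population": pop, "n": len(grp)}
        for c in admixture.clusters:
            row[c] = grp[c].mean()
        expected = (expected_region_map or {}).get(pop)
        qsub = grp[admixture.clusters].to_numpy()
        for t in thresholds:
            if expected is None or expected not in admixture.clusters:
                row[f"assigned:{t:g}"] = np.nan
            else:
                calls = assign_clusters(qsub, t, admixture.clusters)
                row[f"assigned:{t:g}"] = float(
                    np.mean([c == expected for c in calls])
                )
        rows.append(row)
    return pd.DataFrame(rows)


def compare_admixture(
    q_hat_a: np.ndarray, q_hat_b: np.ndarray
) -> tuple[float, float, float]:
    """Pearson r plus least-squares slope/intercept between two estimate
    vectors of the same ancestry component over the same samples."""
    a = np.asarray(q_hat_a, dtype=float)
    b = np.asarray(q_hat_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("inputs must be equal-length vectors")
    if a.size < 3:
        raise DataError("need >= 3 samples")
    if np.std(a) == 0 or np.std(b) == 0:
        raise DataError("constant estimate vector; correlation undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    slope, intercept = np.polyfit(a, b, 1)
    return r, float(slope), float(intercept)
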