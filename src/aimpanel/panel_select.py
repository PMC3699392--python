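"""Multi-stage construction of a small ancestry-informative marker panel.

The pipeline mirrors how compact continental-ancestry panels are designed
from a genome-wide candidate pool:

1. *candidate filtering* — keep autosomal, strand-unambiguous SNPs (allele
   pairs A/C, A/G, T/C, T/G; A/T and C/G are excluded because their strand
   cannot be resolved from frequency data) that are present on the
   genotyping array of interest;
2. *informativeness capping* — keep the top-N loci by I_n (default 5000);
3. *LD pruning* — sliding-window removal of loci whose dosage is too
   predictable from their neighbours, thresholded on the variance inflation
   factor VIF = 1/(1 - R^2) (default 1.5, window 50 SNPs, step 5);
4. *per-pair delta selection* — for each of the K(K-1)/2 group pairs, claim
   the top ``per_pair`` remaining markers by that pair's delta (default 10,
   giving 210 markers for 7 regions);
5. *iterative reduction* — greedy backward elimination to a multiplex-sized
   target (default 41), maximising at each step the minimum over pairs of
   the sum of that pair's three best retained deltas, after removing loci
   on an assay-infeasibility exclusion list.

Stage 5's objective is this package's own surrogate for assay-chemistry
constraints that cannot be modelled generically: it preserves the design
intent that every group pair keeps several high-delta markers. All ties are
broken deterministically by (score, locus_id).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DataError, GenotypeDataset, LocusInfo
from .aim_stats import MarkerScores, group_pairs, rank_markers, score_markers

logger = logging.getLogger("aimpanel")

AUTOSOMES = {str(c) for c in range(1, 23)}
UNAMBIGUOUS_PAIRS = {
    frozenset(p) for p in (("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"))
}


@dataclass
class SelectionConfig:
    """Tunable parameters of the panel-selection pipeline."""

    top_n_by_in: int = 5000
    vif_threshold: float = 1.5
    window_size: int = 50
    window_step: int = 5
    per_pair: int = 10
    target_size: int = 41
    exclusion_list: tuple[str, ...] = ()
    require_autosomal: bool = True
    require_unambiguous: bool = True
    require_on_array: bool = True

    def __post_init__(self) -> None:
        if self.vif_threshold <= 1:
            raise DataError("vif_threshold must exceed 1")
        if self.window_step > self.window_size:
            raise DataError("window_step must be <= window_size")


@dataclass
class PanelEntry:
    locus_id: str
    stage: str
    pair: tuple[str, str] | None = None
    delta: float | None = None
    i_n: float | None = None


@dataclass
class PanelSpec:
    """An ordered marker panel with per-locus selection provenance."""

    entries: list[PanelEntry]
    config: SelectionConfig | None = None
    stage_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.locus_ids
        if len(set(ids)) != len(ids):
            raise DataError("duplicate loci in panel")

    @property
    def locus_ids(self) -> list[str]:
        return [e.locus_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "locus_id": e.locus_id,
                    "stage": e.stage,
                    "pair": "-".join(e.pair) if e.pair else "",
                    "delta": e.delta,
                    "I_n": e.i_n,
                }
                for e in self.entries
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# stage 1: candidate filtering


def filter_candidates(
    loci: Sequence[LocusInfo],
    require_autosomal: bool = True,
    require_unambiguous: bool = True,
    require_on_array: bool = True,
) -> tuple[list[LocusInfo], dict[str, int]]:
    """Apply the candidate-marker criteria; returns (kept, rejection counts)."""
    kept: list[LocusInfo] = []
    reasons = {"non_autosomal": 0, "ambiguous_alleles": 0, "not_on_array": 0}
    for l in loci:
        chrom = l.chromosome.removeprefix("chr")
        if require_autosomal and chrom not in AUTOSOMES:
            reasons["non_autosomal"] += 1
            continue
        if (
            require_unambiguous
            and frozenset((l.allele_a.upper(), l.allele_b.upper()))
            not in UNAMBIGUOUS_PAIRS
        ):
            reasons["ambiguous_alleles"] += 1
            continue
        if require_on_array and not l.on_array:
            reasons["not_on_array"] += 1
            continue
        kept.append(l)
    return kept, reasons


# ---------------------------------------------------------------------------
# stage 3: VIF-based LD pruning


def _vifs_regression(xc: np.ndarray, norm: np.ndarray) -> np.ndarray:
    """Per-column VIF by explicit regression on the remaining columns.

    Fallback for singular windows; pseudoinverse-based, so a perfectly
    predictable column gets VIF = inf.
    """
    m = xc.shape[1]
    out = np.empty(m)
    for j in range(m):
        if norm[j] <= 1e-12:  # monomorphic after imputation
            out[j] = 1.0
            continue
        y = xc[:, j]
        others = np.delete(xc, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        r2 = 1.0 - float(resid @ resid) / float(y @ y)
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def _vifs(x: np.ndarray) -> np.ndarray:
    """VIF of each column of a dosage matrix regressed on the others.

    Fast path: VIF_j is the j-th diagonal entry of the inverse correlation
    matrix. Near-singular windows (collinear loci) fall back to explicit
    pseudoinverse regressions so that perfectly predictable columns report
    an infinite VIF rather than a numerical artefact.
    """
    xc = x - x.mean(axis=0)
    norm = np.sqrt(np.sum(xc**2, axis=0))
    ok = norm > 1e-12
    out = np.ones(x.shape[1])
    if ok.sum() < 2:
        return out
    z = xc[:, ok] / norm[ok]
    r = z.T @ z
    # guard: eigenvalue near zero means some column is (almost) perfectly
    # predictable, where the inverse is unreliable
    if np.linalg.eigvalsh(r)[0] < 1e-8:
        out[ok] = _vifs_regression(xc[:, ok], norm[ok])
        return out
    out[ok] = np.maximum(np.diag(np.linalg.inv(r)), 1.0)
    return out


def vif_prune(
    dataset: GenotypeDataset,
    window_size: int = 50,
    window_step: int = 5,
    vif_threshold: float = 1.5,
) -> list[str]:
    """Sliding-window VIF pruning; returns retained locus ids in map order.

    Loci must be ordered by chromosome and position. Missing dosages are
    mean-imputed per locus for the regressions only. Within each window the
    locus with the highest VIF is removed (ties: the later locus in map
    order) until all VIFs are at or below the threshold; removals are
    permanent and the window then advances by ``window_step``. Windows never
    span chromosomes, and the sliding pass over each chromosome repeats
    until no further locus is removed, so that on output *every* window of
    retained loci satisfies the threshold (directly assertable).
    """
    x = dataset.dosages.copy()
    col_mean = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(x))
    x[inds] = col_mean[inds[1]]

    chroms = [l.chromosome for l in dataset.loci]
    removed: set[int] = set()
    for chrom in dict.fromkeys(chroms):  # preserve first-appearance order
        retained = [j for j, c in enumerate(chroms) if c == chrom]
        changed = True
        while changed:
            changed = False
            for start in window_starts(len(retained), window_size, window_step):
                window = retained[start : start + window_size]
                while len(window) >= 2:
                    vifs = _vifs(x[:, window])
                    worst = np.max(vifs)
                    if worst <= vif_threshold:
                        break
                    # tie-break: later locus in map order among maximal VIFs
                    candidates = np.where(vifs >= worst - 1e-12)[0]
                    drop = window[int(candidates[-1])]
                    removed.add(drop)
                    retained.remove(drop)
                    window.remove(drop)
                    changed = True
    return [l.locus_id for j, l in enumerate(dataset.loci) if j not in removed]


def window_starts(n_loci: int, window_size: int, window_step: int) -> list[int]:
    """Start offsets of the sliding windows over ``n_loci`` ordered loci."""
    if n_loci <= window_size:
        return [0]
    starts = list(range(0, n_loci - window_size + 1, window_step))
    if starts[-1] != n_loci - window_size:  # cover the chromosome tail
        starts.append(n_loci - window_size)
    return starts


# ---------------------------------------------------------------------------
# stage 4: top-delta-per-pair claiming


def select_top_delta_per_pair(
    scores: Sequence[MarkerScores],
    per_pair: int = 10,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> PanelSpec:
    """Claim the top ``per_pair`` unclaimed markers per group pair.

    Pairs are processed in ascending min-group-index order (the order of
    :func:`aim_stats.group_pairs`); within a pair, markers are walked in
    delta-descending order (ties by locus_id) and claimed if no earlier pair
    already took them, so the union has per_pair x n_pairs distinct loci
    whenever enough markers exist.
    """
    if not scores:
        raise DataError("no scores supplied")
    if pairs is None:
        groups = sorted({g for s in scores for p in s.delta for g in p})
        pairs = group_pairs(groups)
    by_id = {s.locus_id: s for s in scores}
    claimed: dict[str, PanelEntry] = {}
    for pair in pairs:
        ranking = rank_markers(list(scores), by=pair)
        taken = 0
        for locus_id in ranking:
            if taken == per_pair:
                break
            if locus_id in claimed:
                continue
            s = by_id[locus_id]
            claimed[locus_id] = PanelEntry(
                locus_id, "top_delta", tuple(pair), s.delta_for(pair), s.i_n
            )
            taken += 1
        if taken < per_pair:
            warnings.warn(
                f"pair {pair}: only {taken}/{per_pair} unclaimed markers available"
            )
    return PanelSpec(list(claimed.values()))


# ---------------------------------------------------------------------------
# stage 5: iterative reduction


def _delta_matrix(
    locus_ids: Sequence[str], scores_by_id: dict[str, MarkerScores]
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    pairs = sorted({tuple(sorted(p)) for i in locus_ids for p in scores_by_id[i].delta})
    mat = np.array(
        [[scores_by_id[i].delta_for(p) for p in pairs] for i in locus_ids]
    )
    return mat, pairs


def panel_objective(deltas: np.ndarray, top: int = 3) -> float:
    """min over pairs (columns) of the sum of the ``top`` best deltas (rows)."""
    k = min(top, deltas.shape[0])
    part = np.partition(deltas, deltas.shape[0] - k, axis=0)[-k:]
    return float(part.sum(axis=0).min())


#: Exhaustive search is used whenever the subset count is at most this.
_EXACT_SEARCH_BUDGET = 20000


def reduce_panel(
    panel: PanelSpec,
    scores: Sequence[MarkerScores],
    target_size: int = 41,
    exclusion_list: Sequence[str] = (),
) -> PanelSpec:
    """Reduce a panel to ``target_size`` loci, maximising the objective.

    Excluded loci (assay-infeasible) are removed first. Small instances
    (subset count within a fixed budget, which covers every panel of eight
    or fewer loci) are solved exactly by enumeration, taking the
    lexicographically-first optimal subset; larger panels use greedy
    backward elimination — repeatedly deleting the locus whose removal
    leaves the highest objective, ties broken by lower I_n then locus_id.
    Deterministic either way.
    """
    scores_by_id = {s.locus_id: s for s in scores}
    current = [
        e.locus_id for e in panel.entries if e.locus_id not in set(exclusion_list)
    ]
    if len(current) < target_size:
        raise DataError(
            f"exclusions leave {len(current)} loci, below target {target_size}"
        )
    from math import comb

    if comb(len(current), target_size) <= _EXACT_SEARCH_BUDGET:
        trimmed = PanelSpec(
            [e for e in panel.entries if e.locus_id in set(current)]
        )
        _, subset = exhaustive_reduce(trimmed, scores, target_size)
        keep = set(subset)
        kept = [e for e in panel.entries if e.locus_id in keep]
        for e in kept:
            e.stage = "reduced"
        return PanelSpec(kept)

    deltas, _ = _delta_matrix(current, scores_by_id)
    while len(current) > target_size:
        best = None  # key = (-objective_after, i_n, locus_id) minimised
        for row, locus_id in enumerate(current):
            obj = panel_objective(np.delete(deltas, row, axis=0))
            key = (-obj, scores_by_id[locus_id].i_n, locus_id)
            if best is None or key < best[0]:
                best = (key, row)
        deltas = np.delete(deltas, best[1], axis=0)
        del current[best[1]]
    keep = set(current)
    kept = [e for e in panel.entries if e.locus_id in keep]
    for e in kept:
        e.stage = "reduced"
    return PanelSpec(kept)


def exhaustive_reduce(
    panel: PanelSpec,
    scores: Sequence[MarkerScores],
    target_size: int,
) -> tuple[float, tuple[str, ...]]:
    """Brute-force best subset under the reduction objective (small panels).

    Returns (objective, lexicographically-first optimal subset). Used as the
    oracle the greedy reduction is checked against.
    """
    scores_by_id = {s.locus_id: s for s in scores}
    ids = sorted(panel.locus_ids)
    deltas, _ = _delta_matrix(ids, scores_by_id)
    best: tuple[float, tuple[str, ...]] | None = None
    for subset in combinations(range(len(ids)), target_size):
        obj = panel_objective(deltas[list(subset)])
        if best is None or obj > best[0] + 1e-12:
            best = (obj, tuple(ids[j] for j in subset))
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# end-to-end pipeline


def run_pipeline(
    dataset: GenotypeDataset,
    labels: Sequence[str],
    config: SelectionConfig | None = None,
) -> PanelSpec:
    """filter -> score -> top-I_n -> VIF prune -> per-pair delta -> reduce."""
    cfg = config or SelectionConfig()
    counts: dict[str, int] = {"input": dataset.n_loci}

    kept, reasons = filter_candidates(
        dataset.loci,
        cfg.require_autosomal,
        cfg.require_unambiguous,
        cfg.require_on_array,
    )
    data = dataset.subset_loci([l.locus_id for l in kept])
    counts["candidates"] = data.n_loci
    logger.info("candidate filter: %d -> %d (%s)", dataset.n_loci, data.n_loci, reasons)

    scores, excluded = score_markers(data, labels)
    counts["scored"] = len(scores)
    top = rank_markers(scores, by="I_n", top_n=min(cfg.top_n_by_in, len(scores)))
    if cfg.top_n_by_in > len(scores):
        warnings.warn(
            f"top_n_by_in={cfg.top_n_by_in} exceeds {len(scores)} scored loci"
        )
    # restore map order for windowed pruning
    top_set = set(top)
    data = data.subset_loci([i for i in data.locus_ids if i in top_set])
    counts["top_in"] = data.n_loci

    retained = vif_prune(data, cfg.window_size, cfg.window_step, cfg.vif_threshold)
    counts["ld_pruned"] = len(retained)
    logger.info("VIF pruning: %d -> %d", data.n_loci, len(retained))
    retained_set = set(retained)
    pool = [s for s in scores if s.locus_id in retained_set]

    panel = select_top_delta_per_pair(pool, cfg.per_pair)
    counts["per_pair_pool"] = len(panel)
    panel = reduce_panel(panel, pool, cfg.target_size, cfg.exclusion_list)
    counts["final"] = len(panel)
    panel.config = cfg
    panel.stage_counts = counts
    logger.info("pipeline stage counts: %s", counts)
    return panel
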