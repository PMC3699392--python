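"""Per-marker ancestry informativeness: I_n and pairwise delta.

I_n is Rosenberg's *informativeness for assignment* for a biallelic locus
across K predefined groups. Writing p_i for the counted-allele frequency in
group i, p_bar = mean_i(p_i), and summing the expression over the two
alleles (frequencies p and 1 - p),

    I_n = sum_alleles( -p_bar ln p_bar + (1/K) sum_i p_i ln p_i ),

with 0 ln 0 := 0. It is 0 iff all group frequencies are equal and bounded
above by ln K. Natural logarithms throughout; rescale by 1/ln(b) to convert
to base b. Groups enter unweighted — region sample sizes do not weight the
mean.

delta for a group pair is the absolute counted-allele frequency difference
|p_i - p_k|, which for a biallelic locus equals half the L1 distance over
both alleles — the classic two-population criterion for ancestry-informative
markers.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AlleleFrequencyTable, DataError, GenotypeDataset, group_allele_freqs


def _xlogx(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = p * np.log(p)
    return np.where(p > 0, out, 0.0)


def informativeness(freqs: Sequence[float] | np.ndarray) -> float:
    """I_n of one biallelic locus given its K per-group frequencies."""
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise DataError("informativeness requires K >= 2 group frequencies")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("group frequencies must be defined and in [0, 1]")
    return float(informativeness_matrix(p[None, :])[0])


def informativeness_matrix(freqs: np.ndarray) -> np.ndarray:
    """Vectorised I_n for an L x K frequency matrix (NaN rows give NaN)."""
    p = np.asarray(freqs, dtype=float)
    K = p.shape[1]
    out = np.full(p.shape[0], np.nan)
    ok = ~np.isnan(p).any(axis=1)
    for q in (p[ok], 1.0 - p[ok]):  # both alleles
        qbar = q.mean(axis=1)
        term = -_xlogx(qbar) + _xlogx(q).mean(axis=1)
        out[ok] = np.where(np.isnan(out[ok]), term, out[ok] + term)
    # clip tiny negative round-off at the I_n = 0 boundary
    out[ok] = np.where(np.abs(out[ok]) < 1e-15, 0.0, out[ok])
    return out


def pairwise_delta(
    freqs: Sequence[float] | np.ndarray, groups: Sequence[str]
) -> dict[tuple[str, str], float]:
    """|p_i - p_k| for every unordered group pair; NaN where undefined."""
    p = np.asarray(freqs, dtype=float)
    if len(groups) != p.size:
        raise DataError("group names do not match frequency vector")
    out: dict[tuple[str, str], float] = {}
    for i in range(p.size):
        for k in range(i + 1, p.size):
            out[(groups[i], groups[k])] = float(abs(p[i] - p[k]))
    return out


def group_pairs(groups: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered pairs in ascending group-index order (fixed, documented)."""
    return [
        (groups[i], groups[k])
        for i in range(len(groups))
        for k in range(i + 1, len(groups))
    ]


@dataclass
class MarkerScores:
    """I_n and the pairwise deltas of one locus across K groups."""

    locus_id: str
    i_n: float
    delta: dict[tuple[str, str], float]
    k: int

    def delta_for(self, pair: tuple[str, str]) -> float:
        if pair in self.delta:
            return self.delta[pair]
        return self.delta[(pair[1], pair[0])]


def score_markers(
    dataset: GenotypeDataset | AlleleFrequencyTable,
    labels: Sequence[str] | None = None,
) -> tuple[list[MarkerScores], list[str]]:
    """Score every locus; returns (scores, excluded locus ids).

    Accepts either a genotype dataset plus per-sample group labels, or a
    precomputed frequency table. Loci with an undefined frequency in any
    group are excluded from scoring (not mean-imputed) and reported.
    """
    if isinstance(dataset, AlleleFrequencyTable):
        table = dataset
    else:
        if labels is None:
            raise DataError("labels required when scoring from genotypes")
        table = group_allele_freqs(dataset, labels)
    if len(table.groups) < 2:
        raise DataError("scoring requires >= 2 groups")
    i_n = informativeness_matrix(table.freqs)
    scores: list[MarkerScores] = []
    excluded: list[str] = []
    for l, locus_id in enumerate(table.locus_ids):
        if np.isnan(table.freqs[l]).any():
            excluded.append(locus_id)
            continue
        scores.append(
            MarkerScores(
                locus_id,
                float(i_n[l]),
                pairwise_delta(table.freqs[l], table.groups),
                len(table.groups),
            )
        )
    if excluded:
        warnings.warn(f"{len(excluded)} loci excluded (undefined group frequency)")
    return scores, excluded


def rank_markers(
    scores: Sequence[MarkerScores],
    by: str | tuple[str, str] = "I_n",
    top_n: int | None = None,
) -> list[str]:
    """Locus ids sorted by descending score; ties broken by locus_id.

    ``by`` is "I_n" or a group pair (ranks by that pair's delta).
    """
    if top_n is not None and top_n < 1:
        raise DataError("top_n must be >= 1")
    if by == "I_n":
        key = [(-s.i_n, s.locus_id) for s in scores]
    else:
        key = [(-s.delta_for(by), s.locus_id) for s in scores]
    order = sorted(range(len(scores)), key=lambda i: key[i])
    ids = [scores[i].locus_id for i in order]
    if top_n is not None and top_n > len(ids):
        warnings.warn(f"top_n={top_n} exceeds {len(ids)} scored loci; returning all")
    return ids[:top_n] if top_n is not None else ids


# ---------------------------------------------------------------------------
# score-table TSV (layout: locus_id, I_n, delta column per pair code)


def scores_to_frame(scores: Sequence[MarkerScores]) -> pd.DataFrame:
    rows = []
    for s in scores:
        row = {"locus_id": s.locus_id, "I_n": s.i_n}
        for (a, b), d in s.delta.items():
            row[f"{a}-{b}"] = d
        rows.append(row)
    return pd.DataFrame(rows)


def write_scores_tsv(scores: Sequence[MarkerScores], path: str | Path) -> None:
    scores_to_frame(scores).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_scores_tsv(path: str | Path) -> list[MarkerScores]:
    """Read a marker-score TSV (locus_id, I_n, delta columns "A-B", extras ignored)."""
    df = pd.read_csv(path, sep="\t")
    if "locus_id" not in df.columns or "I_n" not in df.columns:
        raise DataError(f"{path}: expected locus_id and I_n columns")
    pair_cols = [c for c in df.columns if "-" in c]
    groups = sorted({g for c in pair_cols for g in c.split("-", 1)})
    return [
        MarkerScores(
            str(row["locus_id"]),
            float(row["I_n"]),
            {tuple(c.split("-", 1)): float(row[c]) for c in pair_cols},
            len(groups),
        )
        for _, row in df.iterrows()
    ]


def load_published_panel_scores() -> pd.DataFrame:
    """Published score table of a 41-SNP continental-ancestry panel.

    Columns: locus_id, I_n, in31 (1 if the marker is also in the reduced
    31-SNP subset) and the 21 pairwise deltas among the seven continental
    regions. Shipped as package data for worked examples and summaries.
    """
    with importlib.resources.files("aimpanel.data").joinpath(
        "panel41_scores.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def published_panel_scores() -> list[MarkerScores]:
    """The published 41-SNP panel as :class:`MarkerScores` objects."""
    df = load_published_panel_scores()
    pair_cols = [c for c in df.columns if "-" in c]
    groups = sorted({g for c in pair_cols for g in c.split("-", 1)})
    return [
        MarkerScores(
            str(row["locus_id"]),
            float(row["I_n"]),
            {tuple(c.split("-", 1)): float(row[c]) for c in pair_cols},
            len(groups),
        )
        for _, row in df.iterrows()
    ]
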