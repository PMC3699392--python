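"""Synthetic multi-region SNP data with known truth.

Populations diverge from a shared ancestral pool under the Balding–Nichols
model: for each locus with ancestral counted-allele frequency p, region k's
frequency is drawn Beta(p (1 - F_k) / F_k, (1 - p)(1 - F_k) / F_k), so that
E[freq] = p and the expected fixation index of region k against the
ancestor is F_k. Genotypes follow the admixture model generatively: each of
an individual's two allele copies at a locus first draws its region of
origin from the individual's ancestry vector q, then the allele from that
region's frequency. Loci are unlinked (no LD is simulated — the panels this
package designs are LD-pruned by construction and the admixture likelihood
assumes independent loci) and missingness is i.i.d.

The packaged default scenario mimics a seven-continental-region reference
collection: divergences chosen so Eurasian regions (Middle East, Europe,
Central/South Asia) are closest and Africa/Americas/Oceania most distinct,
50 samples per region, plus two admixed cohorts (Africa–Europe and
Americas–Europe gradients spanning ancestry fractions 0.05-0.95) that
emulate admixed test populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    DEFAULT_REGIONS,
    DataError,
    GenotypeDataset,
    LocusInfo,
    SampleMetadata,
    write_metadata,
    write_ped_map,
)

#: Region divergences of the default scenario, ordered as DEFAULT_REGIONS
#: (Africa, Middle East, Europe, CS Asia, E Asia, Americas, Oceania).
DEFAULT_REGION_F = (0.15, 0.03, 0.03, 0.05, 0.10, 0.20, 0.18)

_UNAMBIGUOUS = (("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"))


@dataclass
class SimulationConfig:
    """Parameters of one synthetic scenario."""

    n_loci: int = 1000
    regions: tuple[str, ...] = DEFAULT_REGIONS
    region_f: tuple[float, ...] = DEFAULT_REGION_F
    ancestral_range: tuple[float, float] = (0.1, 0.9)
    samples_per_region: int = 50
    admixed: tuple[tuple[tuple[float, ...], int], ...] = ()
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.region_f) != len(self.regions):
            raise DataError("region_f must match regions")
        if not all(0 < f < 1 for f in self.region_f):
            raise DataError("each F must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise DataError("missing_rate must be in [0, 1)")
        for q, _count in self.admixed:
            if len(q) != len(self.regions) or abs(sum(q) - 1.0) > 1e-8 or min(q) < 0:
                raise DataError("admixed q vectors must be simplex points over regions")


@dataclass
class SimulationTruth:
    """Ground truth emitted beside every simulated dataset."""

    ancestral_freqs: np.ndarray
    region_freqs: np.ndarray  # loci x regions
    regions: list[str]
    q: np.ndarray  # samples x regions
    labels: list[str]  # source label per sample ("Admixed1", ... for mixtures)


def balding_nichols_freqs(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(region frequency matrix loci x K, ancestral frequencies)."""
    rng = rng or np.random.default_rng(config.seed)
    lo, hi = config.ancestral_range
    p = rng.uniform(lo, hi, size=config.n_loci)
    freqs = np.empty((config.n_loci, len(config.regions)))
    for k, f in enumerate(config.region_f):
        a = p * (1.0 - f) / f
        b = (1.0 - p) * (1.0 - f) / f
        freqs[:, k] = rng.beta(a, b)
    return freqs, p


def sample_genotypes(
    region_freqs: np.ndarray,
    q: np.ndarray,
    missing_rate: float = 0.0,
    rng: np.random.Generator | int = 0,
    loci: Sequence[LocusInfo] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> GenotypeDataset:
    """Draw genotypes under the admixture model.

    Each allele copy independently picks an origin region from its sample's
    q, then is the counted allele with that region's frequency.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    q = np.asarray(q, dtype=float)
    if np.any(np.abs(q.sum(axis=1) - 1.0) > 1e-8) or (q < 0).any():
        raise DataError("q rows must be simplex points")
    n, k = q.shape
    L = region_freqs.shape[0]
    dosages = np.zeros((n, L))
    for copy in range(2):
        origins = np.stack([rng.choice(k, size=L, p=qi) for qi in q])  # n x L
        p_copy = region_freqs.T[origins, np.arange(L)]  # n x L
        dosages += rng.random((n, L)) < p_copy
    if missing_rate > 0:
        dosages[rng.random((n, L)) < missing_rate] = np.nan
    if loci is None:
        loci = default_loci(L, rng=None)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]
    return GenotypeDataset(dosages, list(loci), list(sample_ids))


def default_loci(
    n_loci: int, rng: np.random.Generator | None = None, n_chrom: int = 22
) -> list[LocusInfo]:
    """Evenly spaced autosomal loci with unambiguous allele pairs."""
    loci = []
    per_chrom = -(-n_loci // n_chrom)
    for j in range(n_loci):
        chrom = str(j // per_chrom + 1)
        pos = (j % per_chrom + 1) * 10000
        a, b = _UNAMBIGUOUS[j % len(_UNAMBIGUOUS)]
        loci.append(LocusInfo(f"sim{j:05d}", chrom, pos, a, b))
    return loci


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeDataset, list[SampleMetadata], SimulationTruth]:
    """Full scenario: reference regions plus optional admixed cohorts."""
    rng = np.random.default_rng(config.seed)
    region_freqs, ancestral = balding_nichols_freqs(config, rng)
    K = len(config.regions)
    q_rows, labels, pops = [], [], []
    for k, region in enumerate(config.regions):
        qk = np.zeros(K)
        qk[k] = 1.0
        for _ in range(config.samples_per_region):
            q_rows.append(qk)
            labels.append(region)
            pops.append(region.replace(" ", "") + "Pop")
    for idx, (qv, count) in enumerate(config.admixed, start=1):
        for _ in range(count):
            q_rows.append(np.asarray(qv, dtype=float))
            labels.append(f"Admixed{idx}")
            pops.append(f"Admixed{idx}")
    q = np.vstack(q_rows)
    sample_ids = [f"S{i:04d}" for i in range(len(q_rows))]
    dataset = sample_genotypes(
        region_freqs,
        q,
        config.missing_rate,
        rng,
        default_loci(config.n_loci),
        sample_ids,
    )
    # admixed cohorts keep their cohort name as "region" is not meaningful;
    # metadata regions must come from the declared set, so map them to the
    # region of their largest ancestry fraction for the metadata table.
    meta = []
    for sid, lab, qi in zip(sample_ids, labels, q):
        region = config.regions[int(np.argmax(qi))]
        meta.append(SampleMetadata(sid, lab if lab.startswith("Admixed") else lab + "Pop", region))
    truth = SimulationTruth(ancestral, region_freqs, list(config.regions), q, labels)
    return dataset, meta, truth


def admixture_gradient(
    region_a: int, region_b: int, k: int, fractions: Sequence[float]
) -> tuple[tuple[tuple[float, ...], int], ...]:
    """Admixed-cohort spec with one individual per ancestry fraction."""
    spec = []
    for f in fractions:
        q = [0.0] * k
        q[region_a] = f
        q[region_b] = 1.0 - f
        spec.append((tuple(q), 1))
    return tuple(spec)


def default_scenario_config(
    n_loci: int = 5000, seed: int = 0, missing_rate: float = 0.01
) -> SimulationConfig:
    """The packaged seven-region scenario with two admixed gradients."""
    K = len(DEFAULT_REGIONS)
    gradient = tuple(np.round(np.linspace(0.05, 0.95, 19), 4))
    admixed = admixture_gradient(0, 2, K, gradient) + admixture_gradient(
        5, 2, K, gradient
    )
    return SimulationConfig(
        n_loci=n_loci,
        samples_per_region=50,
        admixed=admixed,
        missing_rate=missing_rate,
        seed=seed,
    )


def make_reference_scenario(
    config: SimulationConfig, outdir: str | Path
) -> dict[str, Path]:
    """Write a complete scenario (PED/MAP, metadata TSV, truth TSV) to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset, meta, truth = simulate_dataset(config)
    paths = {
        "ped": outdir / "scenario.ped",
        "map": outdir / "scenario.map",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth_q.tsv",
        "region_freqs": outdir / "truth_region_freqs.tsv",
    }
    write_ped_map(dataset, paths["ped"], paths["map"])
    write_metadata(meta, paths["metadata"])
    with open(paths["truth"], "w") as fh:
        fh.write("sample_id\tsource\t" + "\t".join(truth.regions) + "\n")
        for sid, lab, qi in zip(dataset.sample_ids, truth.labels, truth.q):
            fh.write(sid + "\t" + lab + "\t" + "\t".join(f"{v:.6f}" for v in qi) + "\n")
    with open(paths["region_freqs"], "w") as fh:
        fh.write("locus_id\t" + "\t".join(truth.regions) + "\n")
        for l, locus in enumerate(dataset.loci):
            fh.write(
                locus.locus_id
                + "\t"
                + "\t".join(f"{v:.6f}" for v in truth.region_freqs[l])
                + "\n"
            )
    return paths
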