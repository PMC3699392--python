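"""Genotype, metadata and allele-frequency I/O.

Establishes the *counted-allele* convention used by every downstream
statistic: each locus records the dosage (0, 1 or 2 copies) of a single
designated allele, by default ``allele_a`` — the first allele observed in
file order — unless an explicit reference-allele table is supplied. The
convention is written into every output header so that panels and frequency
tables from different sources can be reconciled.

Supported formats are whitespace-delimited PED/MAP pedigree files, biallelic
SNP VCF, a three-column sample-metadata TSV (sample_id, population, region)
and labelled TSV allele-frequency tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The seven continental regions used for panel design by default.
DEFAULT_REGIONS: tuple[str, ...] = (
    "Africa",
    "Middle East",
    "Europe",
    "CS Asia",
    "E Asia",
    "Americas",
    "Oceania",
)

#: Optional eighth region for northern-Asian populations (e.g. the Khanty)
#: that fit none of the seven continental clusters.
REGIONS_WITH_SIBERIA: tuple[str, ...] = DEFAULT_REGIONS + ("Siberia",)

MISSING = np.nan


class ParseError(ValueError):
    """Malformed input file."""


class DataError(ValueError):
    """Structurally valid file with inadmissible content."""


@dataclass(frozen=True)
class LocusInfo:
    """A biallelic autosomal-or-sex-chromosome SNP locus.

    ``allele_a`` is the counted allele; ``on_array`` flags membership on the
    genotyping array from which candidates may be drawn.
    """

    locus_id: str
    chromosome: str
    position: int
    allele_a: str
    allele_b: str
    on_array: bool = True

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise DataError(f"{self.locus_id}: alleles must differ")
        if self.position < 1:
            raise DataError(f"{self.locus_id}: position must be >= 1 (1-based)")


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    population: str
    region: str


@dataclass
class GenotypeDataset:
    """Samples x loci matrix of counted-allele dosages.

    ``dosages`` is a float array with entries in {0, 1, 2} and NaN for
    missing genotypes. Row ``i`` is sample ``sample_ids[i]``; column ``j``
    is locus ``loci[j]`` and counts copies of ``loci[j].allele_a``.
    """

    dosages: np.ndarray
    loci: list[LocusInfo]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.loci)):
            raise DataError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )
        finite = self.dosages[~np.isnan(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise DataError("non-missing dosages must be 0, 1 or 2")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate locus_id in dataset")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample_id in dataset")

    # -- registry helpers -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def locus_index(self, locus_ids: Iterable[str]) -> np.ndarray:
        lookup = {l.locus_id: j for j, l in enumerate(self.loci)}
        try:
            return np.array([lookup[i] for i in locus_ids], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"locus {e.args[0]!r} not in dataset") from None

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeDataset":
        idx = self.locus_index(locus_ids)
        return GenotypeDataset(
            self.dosages[:, idx], [self.loci[j] for j in idx], list(self.sample_ids)
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeDataset":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in sample_ids], dtype=int)
        return GenotypeDataset(self.dosages[idx], list(self.loci), list(sample_ids))


@dataclass
class AlleleFrequencyTable:
    """Loci x groups counted-allele frequencies with observation counts.

    ``freqs[l, g]`` is the counted-allele frequency of locus ``l`` in group
    ``g``; NaN where the group has zero non-missing chromosomes there (an
    *undefined* cell, deliberately distinct from frequency 0).
    ``counts[l, g]`` is the number of observed chromosomes (2 x non-missing
    genotypes).
    """

    freqs: np.ndarray
    counts: np.ndarray
    locus_ids: list[str]
    groups: list[str]
    counted_alleles: list[str]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        shape = (len(self.locus_ids), len(self.groups))
        if self.freqs.shape != shape or self.counts.shape != shape:
            raise DataError("frequency/count matrices do not match registries")
        defined = self.counts > 0
        bad = defined & ((self.freqs < 0) | (self.freqs > 1) | np.isnan(self.freqs))
        if bad.any():
            raise DataError("frequencies must lie in [0, 1] where counts > 0")
        if not np.isnan(self.freqs[~defined]).all():
            raise DataError("zero-count cells must carry NaN (undefined) frequency")


# ---------------------------------------------------------------------------
# PED/MAP


def read_ped_map(
    ped_path: str | Path,
    map_path: str | Path,
    counted_alleles: Mapping[str, str] | None = None,
) -> GenotypeDataset:
    """Read a whitespace-delimited PED + 4-column MAP pair.

    The counted allele of each locus defaults to the first allele character
    observed in file order; pass ``counted_alleles`` (locus_id -> allele) to
    fix the convention explicitly. A half-missing genotype (exactly one "0"
    allele) is treated as fully missing.
    """
    map_rows = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{map_path}: line {ln}: expected 4 MAP columns")
        map_rows.append((parts[0], parts[1], int(parts[3])))
    n_loci = len(map_rows)

    sample_ids: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_loci:
            raise ParseError(
                f"{ped_path}: row {ln}: {len(parts)} columns, expected "
                f"{6 + 2 * n_loci} for {n_loci} MAP loci"
            )
        sample_ids.append(parts[1])
        allele_rows.append(
            [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_loci)]
        )

    loci: list[LocusInfo] = []
    dosages = np.full((len(sample_ids), n_loci), np.nan)
    for j, (chrom, locus_id, pos) in enumerate(map_rows):
        observed: list[str] = []
        for row in allele_rows:
            for a in row[j]:
                if a != "0" and a not in observed:
                    observed.append(a)
        if counted_alleles and locus_id in counted_alleles:
            counted = counted_alleles[locus_id]
            others = [a for a in observed if a != counted]
            other = others[0] if others else _complementary(counted)
        else:
            counted = observed[0] if observed else "A"
            other = observed[1] if len(observed) > 1 else _complementary(counted)
        loci.append(LocusInfo(locus_id, chrom, pos, counted, other))
        for i, row in enumerate(allele_rows):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                continue  # half-missing treated as missing
            for a in (a1, a2):
                if a not in (counted, other):
                    raise DataError(
                        f"{ped_path}: sample {sample_ids[i]}, locus {locus_id}: "
                        f"unexpected allele {a!r}"
                    )
            dosages[i, j] = (a1 == counted) + (a2 == counted)
    return GenotypeDataset(dosages, loci, sample_ids)


def _complementary(allele: str) -> str:
    # placeholder partner for monomorphic loci: any base differing from counted
    return "A" if allele != "A" else "G"


def write_ped_map(
    dataset: GenotypeDataset, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write the dataset as PED/MAP; inverse of :func:`read_ped_map`."""
    with open(map_path, "w") as fh:
        for l in dataset.loci:
            fh.write(f"{l.chromosome}\t{l.locus_id}\t0\t{l.position}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(dataset.sample_ids):
            cols = [sid, sid, "0", "0", "0", "-9"]
            for j, l in enumerate(dataset.loci):
                d = dataset.dosages[i, j]
                if np.isnan(d):
                    cols += ["0", "0"]
                else:
                    n_counted = int(d)
                    cols += [l.allele_a] * n_counted + [l.allele_b] * (2 - n_counted)
            fh.write(" ".join(cols) + "\n")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(vcf_path: str | Path, skip_multiallelic: bool = True) -> GenotypeDataset:
    """Read biallelic SNP records from a VCF; counted allele = REF.

    Multiallelic records are skipped with a warning, or rejected with
    :class:`DataError` when ``skip_multiallelic`` is false.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    loci: list[LocusInfo] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            if skip_multiallelic:
                warnings.warn(f"skipping non-biallelic-SNP record {rec.ID or rec.POS}")
                continue
            raise DataError(f"non-biallelic-SNP record {rec.ID or rec.POS}")
        gts = np.asarray(rec.genotype.array())[:, :2].astype(float)
        gts[gts < 0] = np.nan
        ref_dosage = 2.0 - np.nansum(np.where(np.isnan(gts), np.nan, gts), axis=1)
        ref_dosage[np.isnan(gts).any(axis=1)] = np.nan
        loci.append(
            LocusInfo(
                rec.ID or f"{rec.CHROM}:{rec.POS}",
                str(rec.CHROM),
                rec.POS,
                rec.REF,
                rec.ALT[0],
            )
        )
        rows.append(ref_dosage)
    if not rows:
        raise DataError(f"{vcf_path}: no usable biallelic SNP records")
    return GenotypeDataset(np.column_stack(rows), loci, sample_ids)


# ---------------------------------------------------------------------------
# metadata


def read_metadata(
    tsv_path: str | Path, region_set: Sequence[str] = DEFAULT_REGIONS
) -> list[SampleMetadata]:
    """Read a sample_id / population / region TSV, validating region labels."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = {"sample_id", "population", "region"}
    if not required.issubset(df.columns):
        raise ParseError(f"{tsv_path}: header must contain {sorted(required)}")
    if df.empty:
        warnings.warn(f"{tsv_path}: empty metadata file")
        return []
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise DataError(f"duplicate sample_id: {sorted(set(dup))}")
    bad = sorted(set(df["region"]) - set(region_set))
    if bad:
        raise DataError(f"unknown region labels: {bad} (declared: {list(region_set)})")
    return [
        SampleMetadata(r.sample_id, r.population, r.region)
        for r in df.itertuples(index=False)
    ]


def write_metadata(meta: Sequence[SampleMetadata], tsv_path: str | Path) -> None:
    pd.DataFrame(
        [(m.sample_id, m.population, m.region) for m in meta],
        columns=["sample_id", "population", "region"],
    ).to_csv(tsv_path, sep="\t", index=False)


def metadata_labels(
    meta: Sequence[SampleMetadata],
    sample_ids: Sequence[str],
    by: str = "region",
) -> list[str]:
    """Group label per sample in dataset order (``by`` = region|population)."""
    attr = {"region": "region", "population": "population"}[by]
    lookup = {m.sample_id: getattr(m, attr) for m in meta}
    missing = [s for s in sample_ids if s not in lookup]
    if missing:
        raise DataError(f"samples without metadata: {missing[:5]}")
    return [lookup[s] for s in sample_ids]


# ---------------------------------------------------------------------------
# group allele frequencies


def group_allele_freqs(
    dataset: GenotypeDataset, labels: Sequence[str]
) -> AlleleFrequencyTable:
    """Counted-allele frequency per locus per group, pooling individuals.

    p = (counted-allele copies among non-missing genotypes) / (2 x
    non-missing genotype count). Groups with zero non-missing calls at a
    locus get an undefined (NaN) frequency, never 0.
    """
    if len(labels) != dataset.n_samples:
        raise DataError("labels length does not match sample count")
    groups = sorted(set(labels))
    lab = np.asarray(labels)
    freqs = np.full((dataset.n_loci, len(groups)), np.nan)
    counts = np.zeros((dataset.n_loci, len(groups)))
    for g, name in enumerate(groups):
        sub = dataset.dosages[lab == name]
        obs = 2.0 * np.sum(~np.isnan(sub), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.nansum(sub, axis=0) / obs
        counts[:, g] = obs
        freqs[:, g] = np.where(obs > 0, f, np.nan)
    return AlleleFrequencyTable(
        freqs, counts, dataset.locus_ids, groups, [l.allele_a for l in dataset.loci]
    )


# ---------------------------------------------------------------------------
# frequency-table TSV round trip

_FREQ_HEADER = "# aimpanel allele-frequency table; counted allele per locus in column 'counted_allele'"


def write_freq_table(table: AlleleFrequencyTable, path: str | Path) -> None:
    """Write a frequency table as TSV, lossless to 6 decimal places."""
    with open(path, "w") as fh:
        fh.write(_FREQ_HEADER + "\n")
        cols = ["locus_id", "counted_allele"]
        for g in table.groups:
            cols += [f"freq:{g}", f"count:{g}"]
        fh.write("\t".join(cols) + "\n")
        for l in range(len(table.locus_ids)):
            row = [table.locus_ids[l], table.counted_alleles[l]]
            for g in range(len(table.groups)):
                f, c = table.freqs[l, g], table.counts[l, g]
                row.append("NA" if np.isnan(f) else f"{f:.6f}")
                row.append(f"{c:g}")
            fh.write("\t".join(row) + "\n")


def read_freq_table(path: str | Path) -> AlleleFrequencyTable:
    lines = Path(path).read_text().splitlines()
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty frequency table")
    header = lines[0].split("\t")
    if header[:2] != ["locus_id", "counted_allele"] or len(header) < 4:
        raise ParseError(f"{path}: malformed frequency-table header")
    groups = [c.split(":", 1)[1] for c in header[2::2]]
    expected = ["locus_id", "counted_allele"]
    for g in groups:
        expected += [f"freq:{g}", f"count:{g}"]
    if header != expected:
        raise ParseError(f"{path}: malformed frequency-table header")
    locus_ids, counted, freq_rows, count_rows = [], [], [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        locus_ids.append(parts[0])
        counted.append(parts[1])
        fr, cr = [], []
        for f, c in zip(parts[2::2], parts[3::2]):
            val = np.nan if f == "NA" else float(f)
            if not np.isnan(val) and not 0 <= val <= 1:
                raise DataError(f"{path}: frequency {f} outside [0, 1]")
            fr.append(val)
            cr.append(float(c))
        freq_rows.append(fr)
        count_rows.append(cr)
    return AlleleFrequencyTable(
        np.array(freq_rows), np.array(count_rows), locus_ids, groups, counted
    )
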