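"""Core data types, genotype/climate readers and writers, and variant filters.

Genotypes are stored as alternate-allele dosages (0, 1 or 2 copies of the
alternate allele per diploid individual); the orientation "alternate allele"
is used consistently throughout the package, including the polygenic-score
construction, where only a consistent per-locus orientation matters.

Missing genotypes are encoded as -1 in the integer matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("landgea")

MISSING = -1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusInfo:
    """A biallelic SNP locus: VCF-style 1-based position, single-char alleles."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"locus {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"locus {self.id}: ref and alt alleles are identical")


@dataclass
class GenotypeMatrix:
    """Individuals x loci alternate-allele dosage matrix with population labels.

    Attributes
    ----------
    genotypes : (n_individuals, n_loci) int8/int16 array with values in
        {0, 1, 2} or MISSING (-1).
    individual_ids : sample identifiers, one per row.
    population_of : mapping from individual id to population label.
    loci : per-column LocusInfo.
    """

    genotypes: np.ndarray
    individual_ids: list[str]
    population_of: dict[str, str]
    loci: list[LocusInfo]

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if g.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x loci)")
        valid = np.isin(g, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(g[~valid])
            raise ValueError(f"invalid genotype codes {bad}; allowed 0/1/2/{MISSING}")
        if g.shape[0] != len(self.individual_ids):
            raise ValueError("row count does not match individual_ids")
        if g.shape[1] != len(self.loci):
            raise ValueError("column count does not match loci list")
        missing_pop = [i for i in self.individual_ids if i not in self.population_of]
        if missing_pop:
            raise ValueError(f"individuals without population label: {missing_pop[:5]}")
        self.genotypes = g

    # -- convenience -------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for ind in self.individual_ids:
            seen.setdefault(self.population_of[ind], None)
        return list(seen)

    def population_labels(self) -> np.ndarray:
        """Per-individual population label array aligned with matrix rows."""
        return np.array([self.population_of[i] for i in self.individual_ids])

    def population_masks(self) -> dict[str, np.ndarray]:
        labels = self.population_labels()
        return {p: labels == p for p in self.populations}

    def subset_loci(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            genotypes=self.genotypes[:, idx],
            individual_ids=list(self.individual_ids),
            population_of=dict(self.population_of),
            loci=[self.loci[int(j)] for j in idx],
        )

    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]


@dataclass
class FrequencyTable:
    """Populations x loci alternate-allele frequencies with allele counts.

    ``counts[k, j]`` is the number of called *alleles* (2 x called genotypes)
    of population k at locus j; ``freqs[k, j]`` is alt-allele count divided by
    ``counts[k, j]``, NaN where the count is zero.
    """

    freqs: np.ndarray
    counts: np.ndarray
    populations: list[str]
    locus_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        f, c = np.asarray(self.freqs, float), np.asarray(self.counts)
        if f.shape != c.shape:
            raise ValueError("freqs and counts must have the same shape")
        if f.shape[0] != len(self.populations):
            raise ValueError("row count does not match populations")
        ok = c > 0
        if np.any((f[ok] < 0) | (f[ok] > 1)):
            raise ValueError("frequencies outside [0, 1]")
        self.freqs, self.counts = f, c

    @property
    def n_populations(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_loci(self) -> int:
        return self.freqs.shape[1]

    def imputed(self) -> np.ndarray:
        """Frequencies with empty (population, locus) cells mean-imputed.

        Empty cells get the across-population mean frequency of the locus,
        keeping the matrix complete for ordination without dropping loci.
        """
        f = self.freqs.copy()
        empty = self.counts == 0
        if empty.any():
            col_mean = np.nanmean(np.where(empty, np.nan, f), axis=0)
            f = np.where(empty, col_mean[None, :], f)
            logger.info("mean-imputed %d empty (population, locus) cells", int(empty.sum()))
        return f

    def subset_loci(self, index: np.ndarray | Sequence[int]) -> "FrequencyTable":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return FrequencyTable(
            freqs=self.freqs[:, idx],
            counts=self.counts[:, idx],
            populations=list(self.populations),
            locus_ids=[self.locus_ids[int(j)] for j in idx] if self.locus_ids else [],
        )


@dataclass
class ClimateTable:
    """Per-site climate values plus site coordinates (decimal degrees)."""

    values: np.ndarray               # (n_populations, n_variables)
    variables: list[str]
    populations: list[str]
    longitude: np.ndarray
    latitude: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape != (len(self.populations), len(self.variables)):
            raise ValueError("values must be (n_populations, n_variables)")
        if np.isnan(v).any():
            raise ValueError("climate table contains missing values")
        self.values = v
        self.longitude = np.asarray(self.longitude, float)
        self.latitude = np.asarray(self.latitude, float)

    def valid_variables(self) -> list[str]:
        """Variables with nonzero variance across sites (analysable)."""
        sd = self.values.std(axis=0)
        return [v for v, s in zip(self.variables, sd) if s > 0]

    def standardized(self, variables: Sequence[str] | None = None) -> np.ndarray:
        """Zero-mean/unit-variance columns for the selected variables."""
        names = list(variables) if variables is not None else self.valid_variables()
        idx = [self.variables.index(n) for n in names]
        x = self.values[:, idx]
        sd = x.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = [names[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"zero-variance climate variables: {bad}")
        return (x - x.mean(axis=0)) / sd


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_population_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping sample id -> population label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("population table needs columns: sample_id, population")
    col_s, col_p = df.columns[:2]
    return dict(zip(df[col_s], df[col_p]))


def read_climate_table(path: str | Path) -> ClimateTable:
    """Read a climate TSV: ``population  longitude  latitude  var1 ...``."""
    df = pd.read_csv(path, sep="\t")
    required = {"population", "longitude", "latitude"}
    if not required.issubset(df.columns):
        raise ValueError(f"climate table must contain columns {sorted(required)}")
    varcols = [c for c in df.columns if c not in required]
    return ClimateTable(
        values=df[varcols].to_numpy(float),
        variables=varcols,
        populations=df["population"].astype(str).tolist(),
        longitude=df["longitude"].to_numpy(float),
        latitude=df["latitude"].to_numpy(float),
    )


def _load_vcf(path: str | Path, pop_of: dict[str, str]) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in pop_of]
    if unknown:
        raise ValueError(
            f"sample(s) {unknown} present in VCF but absent from the population table"
        )
    cols: list[np.ndarray] = []
    loci: list[LocusInfo] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_multi += 1
            continue
        # gts012: 0/1/2 = alt dosage, 3 = unknown; phased and unphased alike
        gt = np.asarray(rec.gt_types, dtype=np.int16).copy()
        gt[gt == 3] = MISSING
        cols.append(gt)
        rid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        loci.append(LocusInfo(rec.CHROM, rec.POS, rid, rec.REF, rec.ALT[0]))
    if n_multi:
        logger.info("skipped %d multiallelic/non-SNP records", n_multi)
    if not cols:
        raise ValueError("no biallelic SNP records in VCF")
    geno = np.stack(cols, axis=1)
    return GenotypeMatrix(geno, samples, {s: pop_of[s] for s in samples}, loci)


def _load_tsv(path: str | Path, pop_of: dict[str, str]) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta = ["chrom", "pos", "id", "ref", "alt"]
    if list(df.columns[:5]) != meta:
        raise ValueError(f"genotype TSV must start with columns {meta}")
    samples = list(df.columns[5:])
    unknown = [s for s in samples if s not in pop_of]
    if unknown:
        raise ValueError(
            f"sample(s) {unknown} present in genotype table but absent from the "
            "population table"
        )
    loci = [
        LocusInfo(str(r.chrom), int(r.pos), str(r.id), str(r.ref), str(r.alt))
        for r in df.itertuples()
    ]
    raw = df[samples].to_numpy()
    geno = np.where(pd.isna(raw) | (raw == "NA"), MISSING, raw).astype(np.int16).T
    return GenotypeMatrix(geno, samples, {s: pop_of[s] for s in samples}, loci)


def load_genotypes(
    path: str | Path,
    format: str = "vcf",
    pop_table: str | Path | dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Load genotypes from a VCF (GT field) or the package's TSV dialect.

    Biallelic SNP records only; multiallelic records are skipped with a logged
    count. Genotypes become alternate-allele dosages; ``./.`` becomes MISSING.
    """
    if pop_table is None:
        raise ValueError("a population table (path or mapping) is required")
    pop_of = pop_table if isinstance(pop_table, dict) else read_population_table(pop_table)
    if format == "vcf":
        return _load_vcf(path, pop_of)
    if format == "tsv":
        return _load_tsv(path, pop_of)
    raise ValueError(f"unknown genotype format {format!r}; expected 'vcf' or 'tsv'")


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV genotype dialect (header of sample ids, NA = missing)."""
    df = pd.DataFrame(
        {
            "chrom": [l.chrom for l in g.loci],
            "pos": [l.pos for l in g.loci],
            "id": [l.id for l in g.loci],
            "ref": [l.ref for l in g.loci],
            "alt": [l.alt for l in g.loci],
        }
    )
    geno = g.genotypes.T.astype(object)
    geno[geno == MISSING] = "NA"
    for i, s in enumerate(g.individual_ids):
        df[s] = geno[:, i]
    df.to_csv(path, sep="\t", index=False)


def write_population_table(g: GenotypeMatrix, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": g.individual_ids,
         "population": [g.population_of[i] for i in g.individual_ids]}
    ).to_csv(path, sep="\t", index=False)


def write_climate_table(c: ClimateTable, path: str | Path) -> None:
    df = pd.DataFrame({"population": c.populations,
                       "longitude": c.longitude, "latitude": c.latitude})
    for j, v in enumerate(c.variables):
        df[v] = c.values[:, j]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant filters
# ---------------------------------------------------------------------------

@dataclass
class FilterLog:
    n_input: int
    n_removed_maf: int
    n_removed_presence: int
    n_retained: int


def apply_variant_filters(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    min_ind_per_pop: int = 12,
) -> tuple[GenotypeMatrix, FilterLog]:
    """Retain loci with overall MAF > ``maf_min`` and adequate per-population calls.

    A locus is kept iff its minor-allele frequency across all called genotypes
    exceeds ``maf_min`` AND it is called in at least ``min_ind_per_pop``
    individuals in EVERY population. Returns the filtered matrix and a removal
    log. Both rules are evaluated on the input matrix, so the filter is
    idempotent.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    if min_ind_per_pop < 0:
        raise ValueError("min_ind_per_pop must be >= 0")

    geno = g.genotypes
    called = geno != MISSING
    alt = np.where(called, geno, 0).sum(axis=0)
    n_alleles = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    pass_maf = (maf > maf_min) & (n_alleles > 0)

    pass_presence = np.ones(g.n_loci, bool)
    for mask in g.population_masks().values():
        pass_presence &= called[mask].sum(axis=0) >= min_ind_per_pop

    keep = pass_maf & pass_presence
    log = FilterLog(
        n_input=g.n_loci,
        n_removed_maf=int((~pass_maf).sum()),
        n_removed_presence=int((~pass_presence).sum()),
        n_retained=int(keep.sum()),
    )
    logger.info(
        "variant filters: %d in, %d fail MAF<=%g, %d fail presence>=%d, %d retained",
        log.n_input, log.n_removed_maf, maf_min, log.n_removed_presence,
        min_ind_per_pop, log.n_retained,
    )
    if log.n_retained == 0:
        raise ValueError(
            "all loci removed by variant filters; review the maf_min and "
            "min_ind_per_pop thresholds"
        )
    return g.subset_loci(keep), log


def population_allele_frequencies(g: GenotypeMatrix) -> FrequencyTable:
    """Per-population alternate-allele frequencies and called allele counts.

    ``freq[k, j]`` = (sum of dosages over called individuals of population k at
    locus j) / (2 x number called); cells with zero called individuals are NaN
    with count 0 and are mean-imputed downstream via ``FrequencyTable.imputed``.
    """
    if g.n_loci == 0 or g.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    pops = g.populations
    called = g.genotypes != MISSING
    freqs = np.empty((len(pops), g.n_loci))
    counts = np.empty((len(pops), g.n_loci), dtype=np.int64)
    masks = g.population_masks()
    for k, p in enumerate(pops):
        m = masks[p]
        c = called[m]
        alt = np.where(c, g.genotypes[m], 0).sum(axis=0)
        n = 2 * c.sum(axis=0)
        counts[k] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[k] = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return FrequencyTable(freqs, counts, pops, g.locus_ids())
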