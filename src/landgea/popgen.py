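"""Within-population diversity statistics and pairwise Hudson F_ST.

Diversity per population: Watterson's theta (segregating sites scaled by the
harmonic number and the number of assayed sites), nucleotide diversity pi
(unbiased average pairwise difference per site), Tajima's D with the standard
variance constants, observed heterozygosity, and a method-of-moments F_IS
(1 - H_obs/H_exp over polymorphic loci).

Differentiation: the Hudson (1992) estimator computed from called allele
frequencies with the ratio-of-averages combination across loci — the standard
hard-call analogue of SFS-based estimators. Negative pair estimates are
retained, not truncated; the linearized transform f/(1-f) is available for
isolation-by-distance regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, FrequencyTable, GenotypeMatrix


@dataclass
class PopulationDiversity:
    population: str
    n_individuals: int
    s_segregating: int
    theta_w: float          # per site
    theta_w_sd: float       # per-locus SD of the per-site contribution
    pi: float               # per site
    pi_sd: float
    tajimas_d: float
    het_obs: float
    f_is: float
    defined: bool = True


@dataclass
class DiversityStats:
    per_population: list[PopulationDiversity]
    total_sites: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.per_population])


def _tajima_constants(n: int) -> dict[str, float]:
    """Variance constants for Tajima's D at sample size n (alleles)."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return {"a1": a1, "a2": a2, "e1": c1 / a1, "e2": c2 / (a1**2 + a2)}


def diversity_stats(g: GenotypeMatrix, total_sites: int | None = None) -> DiversityStats:
    """Per-population diversity statistics from called genotypes.

    ``total_sites`` is the denominator for per-site scaling (the number of
    assayed sites); it defaults to the number of loci in ``g``. The sample
    size n entering the harmonic number is twice the median number of called
    individuals per locus (loci differ in missingness).
    """
    L = int(total_sites) if total_sites is not None else g.n_loci
    if L <= 0:
        raise ValueError("total_sites must be positive")
    out: list[PopulationDiversity] = []
    for pop, mask in g.population_masks().items():
        sub = g.genotypes[mask]
        called = sub != MISSING
        n_called = called.sum(axis=0)
        if (n_called >= 2).sum() == 0:
            out.append(PopulationDiversity(pop, int(mask.sum()), 0, np.nan, np.nan,
                                           np.nan, np.nan, np.nan, np.nan, np.nan,
                                           defined=False))
            continue
        alt = np.where(called, sub, 0).sum(axis=0)
        n_alleles = 2 * n_called
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        poly = (n_alleles > 0) & (alt > 0) & (alt < n_alleles)
        S = int(poly.sum())

        n = 2 * int(np.median(n_called[n_called > 0]))
        n = max(n, 2)
        k = _tajima_constants(n)

        # per-locus unbiased heterozygosity; zero where monomorphic/uncalled
        nl = np.maximum(n_alleles, 2)
        pi_locus = np.where(n_alleles >= 2,
                            2.0 * p * (1 - p) * nl / (nl - 1.0), 0.0)
        pi_locus = np.nan_to_num(pi_locus)
        pi_sum = float(pi_locus.sum())
        theta_sum = S / k["a1"]

        if S > 0:
            var_d = k["e1"] * S + k["e2"] * S * (S - 1)
            taj_d = (pi_sum - theta_sum) / np.sqrt(var_d) if var_d > 0 else 0.0
        else:
            taj_d = np.nan

        het_obs = float((sub == 1).sum() / max(called.sum(), 1))
        if S > 0:
            het_exp = float(np.mean(2.0 * p[poly] * (1 - p[poly])))
            f_is = 1.0 - het_obs / het_exp if het_exp > 0 else np.nan
        else:
            f_is = np.nan

        theta_locus = np.where(poly, 1.0 / k["a1"], 0.0)
        out.append(PopulationDiversity(
            population=pop,
            n_individuals=int(mask.sum()),
            s_segregating=S,
            theta_w=theta_sum / L,
            theta_w_sd=float(theta_locus.std(ddof=1)) if g.n_loci > 1 else 0.0,
            pi=pi_sum / L,
            pi_sd=float(pi_locus.std(ddof=1)) if g.n_loci > 1 else 0.0,
            tajimas_d=float(taj_d),
            het_obs=het_obs,
            f_is=float(f_is),
        ))
    return DiversityStats(out, L)


@dataclass
class FstMatrix:
    """Pairwise Hudson F_ST (ratio of averages); optionally linearized."""

    values: np.ndarray
    populations: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("F_ST matrix must be square and symmetric")
        np.fill_diagonal(v, 0.0)
        self.values = v

    def linearized(self) -> np.ndarray:
        """Rousset's transform f/(1-f), entry-wise; diagonal stays zero."""
        return self.values / (1.0 - self.values)

    def to_frame(self, linearize: bool = False) -> pd.DataFrame:
        rows = []
        lin = self.linearized()
        n = len(self.populations)
        for a in range(n):
            for b in range(a + 1, n):
                rows.append((self.populations[a], self.populations[b],
                             self.values[a, b], lin[a, b]))
        return pd.DataFrame(rows, columns=["popA", "popB", "fst", "fst_linearized"])


def hudson_fst_components(
    p1: np.ndarray, p2: np.ndarray, n1: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Hudson numerator and denominator from sample frequencies.

    n1/n2 are called *allele* counts. Loci with fewer than 2 alleles in
    either population contribute NaN and are dropped by the caller.
    """
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / (n1 - 1)
               - p2 * (1 - p2) / (n2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    bad = (n1 < 2) | (n2 < 2) | np.isnan(p1) | np.isnan(p2)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def pairwise_fst(f: FrequencyTable, linearize: bool = False) -> FstMatrix:
    """Pairwise Hudson F_ST across all loci (ratio of averages).

    ``linearize`` is accepted for interface symmetry; the returned FstMatrix
    always exposes ``linearized()`` regardless.
    """
    K = f.n_populations
    if K < 2:
        raise ValueError("need at least 2 populations")
    vals = np.zeros((K, K))
    for a in range(K):
        for b in range(a + 1, K):
            num, den = hudson_fst_components(
                f.freqs[a], f.freqs[b], f.counts[a], f.counts[b])
            ok = ~np.isnan(num) & ~np.isnan(den)
            dsum = np.nansum(den[ok])
            if not ok.any() or dsum == 0:
                raise ValueError(
                    f"F_ST undefined for pair ({f.populations[a]}, "
                    f"{f.populations[b]}): zero denominator at all loci")
            vals[a, b] = vals[b, a] = np.nansum(num[ok]) / dsum
    return FstMatrix(vals, list(f.populations))
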