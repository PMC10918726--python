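"""Population structure axes, distance matrices, and IBD/IBE Mantel tests.

Structure covariates come from a Patterson-scaled PCA of the individual
dosage matrix (loci centered by 2*p and scaled by sqrt(p(1-p)), missing cells
mean-imputed); climate dimensionality reduction is a correlation-matrix PCA
over sites. Isolation by distance is tested by a one-sided Mantel test of
linearized F_ST against log great-circle distance; isolation by environment
by partial Mantel tests of linearized F_ST against environmental distance
controlling for geography, with Benjamini–Hochberg FDR across variables.

Mantel permutation scheme: simultaneous row/column permutation of the
dependent matrix; for the partial test the dependent matrix is permuted
before residualization on the control (Legendre's method), which controls
type-I error better than residual permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _iterperms

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io import MISSING, ClimateTable, GenotypeMatrix
from .popgen import FstMatrix

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class StructureAxes:
    individual_scores: np.ndarray        # (n_individuals, K)
    population_scores: np.ndarray        # (n_populations, K)
    explained: np.ndarray                # fraction per retained axis
    populations: list[str]
    n_loci_used: int
    n_loci_dropped: int


def genotype_pca(
    g: GenotypeMatrix, n_axes: int = 4, patterson_scaling: bool = True
) -> StructureAxes:
    """Principal components of the individual dosage matrix.

    Loci are centered by twice their observed allele frequency and, under
    Patterson scaling, divided by sqrt(p(1-p)); missing dosages are imputed
    with the locus mean (hence contribute zero after centering). Monomorphic
    loci are dropped. Population scores are the means of member individuals.
    """
    if n_axes >= g.n_individuals:
        raise ValueError("n_axes must be smaller than the number of individuals")
    geno = g.genotypes.astype(float)
    called = g.genotypes != MISSING
    n_alleles = 2 * called.sum(axis=0)
    alt = np.where(called, g.genotypes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    poly = (n_alleles > 0) & (p > 0) & (p < 1)
    n_dropped = int((~poly).sum())
    geno = np.where(called, geno, (2 * p)[None, :])[:, poly]
    pj = p[poly]
    x = geno - 2 * pj[None, :]
    if patterson_scaling:
        x = x / np.sqrt(pj * (1 - pj))[None, :]
    if x.shape[1] == 0 or not np.any(x):
        raise ValueError("no polymorphic variation: covariance has rank 0")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum())
    if n_axes > rank:
        raise ValueError(f"n_axes={n_axes} exceeds matrix rank {rank}")
    scores = u[:, :n_axes] * s[:n_axes]
    explained = (s[:n_axes] ** 2) / np.sum(s**2)
    pops = g.populations
    masks = g.population_masks()
    pop_scores = np.stack([scores[masks[p]].mean(axis=0) for p in pops])
    return StructureAxes(scores, pop_scores, explained, pops, int(poly.sum()), n_dropped)


@dataclass
class ClimatePCA:
    site_scores: np.ndarray              # (n_populations, K)
    loadings: np.ndarray                 # (n_variables_used, K)
    explained: np.ndarray                # per retained axis
    explained_all: np.ndarray            # full spectrum (sums to 1)
    variables: list[str]


def climate_pca(c: ClimateTable, n_axes: int = 2) -> ClimatePCA:
    """Correlation-matrix PCA of the site climate table."""
    names = c.valid_variables()
    if len(names) < len(c.variables):
        import warnings

        dropped = sorted(set(c.variables) - set(names))
        warnings.warn(f"excluding zero-variance climate variables: {dropped}",
                      stacklevel=2)
    if len(names) < 2:
        raise ValueError("need at least 2 climate variables with nonzero variance")
    z = c.standardized(names)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    explained_all = s**2 / np.sum(s**2)
    n_axes = min(n_axes, len(s))
    return ClimatePCA(
        site_scores=u[:, :n_axes] * s[:n_axes],
        loadings=vt.T[:, :n_axes],
        explained=explained_all[:n_axes],
        explained_all=explained_all,
        variables=names,
    )


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    values: np.ndarray
    labels: list[str]
    kind: str                            # geographic | environmental | genetic

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T):
            raise ValueError("distance matrix must be square and symmetric")
        np.fill_diagonal(v, 0.0)
        if (v < 0).any():
            raise ValueError("distance matrix must be non-negative")
        self.values = v

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.values.shape[0], 1)
        return self.values[iu]


def haversine_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix (km) from decimal-degree coordinates."""
    lam, phi = np.radians(lon), np.radians(lat)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = (np.sin(dphi / 2) ** 2
         + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def distance_matrices(
    c: ClimateTable,
    fst: FstMatrix | None = None,
    variables: list[str] | None = None,
    log_geographic: bool = True,
) -> dict[str, DistanceMatrix]:
    """Geographic (log great-circle), environmental and genetic distances.

    The genetic matrix is linearized F_ST with slightly negative entries
    clamped to zero. The geographic matrix is log-transformed (natural log)
    for isolation-by-distance regression; duplicate coordinates make the log
    undefined and raise.
    """
    import logging

    logger = logging.getLogger("landgea")
    out: dict[str, DistanceMatrix] = {}
    geo = haversine_km(c.longitude, c.latitude)
    off = ~np.eye(len(c.populations), dtype=bool)
    if log_geographic:
        if np.any(geo[off] <= 0):
            raise ValueError(
                "zero geographic distance between distinct sites; jitter "
                "coordinates or merge the sites")
        lg = np.zeros_like(geo)
        lg[off] = np.log(geo[off])
        out["geographic"] = DistanceMatrix(lg, list(c.populations), "geographic")
    else:
        out["geographic"] = DistanceMatrix(geo, list(c.populations), "geographic")

    z = c.standardized(variables)
    d2 = np.sqrt(((z[:, None, :] - z[None, :, :]) ** 2).sum(-1))
    out["environmental"] = DistanceMatrix(d2, list(c.populations), "environmental")

    if fst is not None:
        lin = fst.linearized()
        n_neg = int((lin < 0).sum() // 2)
        if n_neg:
            logger.info("clamped %d negative linearized F_ST entries to 0", n_neg)
        out["genetic"] = DistanceMatrix(np.maximum(lin, 0.0), fst.populations,
                                        "genetic")
    return out


def environmental_distance(c: ClimateTable, variable: str) -> DistanceMatrix:
    """Euclidean distance on a single standardized climate variable."""
    z = c.standardized([variable])[:, 0]
    return DistanceMatrix(np.abs(z[:, None] - z[None, :]), list(c.populations),
                          "environmental")


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    partial: bool = False
    control: str | None = None


def _check_conformable(*mats: DistanceMatrix) -> int:
    n = mats[0].values.shape[0]
    for m in mats[1:]:
        if m.values.shape[0] != n or m.labels != mats[0].labels:
            raise ValueError("distance matrices must share dimension and site order")
    return n


def _permuted_vectors(
    m: np.ndarray, perms: np.ndarray, iu: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Unrolled upper triangles of simultaneously row/col permuted matrices."""
    return m[perms[:, :, None], perms[:, None, :]][:, iu[0], iu[1]]


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of x with the matching row of y."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    return (xc * yc).sum(axis=1) / denom


def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(_iterperms(range(n))), dtype=np.intp)


def mantel_test(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
) -> MantelResult:
    """One-sided (positive) Mantel test of matrix correlation.

    r is the Pearson correlation over the n(n-1)/2 off-diagonal pairs; the
    null is generated by simultaneous row/column permutation of ``b``;
    p = (#{r_perm >= r_obs} + 1) / (n_perm + 1). With ``exhaustive`` all n!
    permutations are enumerated and p is the exact exceedance fraction
    (the identity permutation counts, so p >= 1/n!).
    """
    n = _check_conformable(a, b)
    if not exhaustive and n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    iu = np.triu_indices(n, 1)
    av, bv = a.values[iu], b.values[iu]
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(av, bv)[0, 1])
    if exhaustive:
        perms = _all_permutations(n)
        r_perm = _pearson_rows(np.broadcast_to(av, (len(perms), av.size)),
                               _permuted_vectors(b.values, perms, iu))
        p = float(np.sum(r_perm >= r_obs - 1e-12) / len(perms))
        return MantelResult(r_obs, p, len(perms))
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)]).astype(np.intp)
    r_perm = _pearson_rows(np.broadcast_to(av, (n_perm, av.size)),
                           _permuted_vectors(b.values, perms, iu))
    p = float((np.sum(r_perm >= r_obs - 1e-12) + 1) / (n_perm + 1))
    return MantelResult(r_obs, p, n_perm)


def partial_mantel_test(
    a: DistanceMatrix,
    b: DistanceMatrix,
    control: DistanceMatrix,
    n_perm: int = 1000,
    seed: int = 0,
) -> MantelResult:
    """One-sided partial Mantel test of a ~ b controlling for ``control``.

    The unrolled a and b are residualized on the unrolled control by least
    squares; r is the correlation of residuals. The null permutes rows and
    columns of ``a`` before residualization.
    """
    import warnings

    n = _check_conformable(a, b, control)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    iu = np.triu_indices(n, 1)
    av, bv, cv = a.values[iu], b.values[iu], control.values[iu]
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("constant distance matrix: partial Mantel r undefined")
    x = np.column_stack([np.ones_like(cv), cv])
    pinv = np.linalg.pinv(x)
    res_b = bv - x @ (pinv @ bv)
    if res_b.std() < 1e-12 * max(bv.std(), 1.0):
        warnings.warn("control is collinear with b: partial r near 0 by "
                      "construction", stacklevel=2)
    res_a = av - x @ (pinv @ av)
    if res_a.std() < 1e-12 * max(av.std(), 1.0):
        r_obs = 0.0          # a fully explained by the control
    else:
        denom = np.sqrt((res_a**2).sum() * (res_b**2).sum())
        r_obs = float((res_a * res_b).sum() / denom) if denom > 0 else 0.0

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)]).astype(np.intp)
    a_perm = _permuted_vectors(a.values, perms, iu)          # (n_perm, pairs)
    res_ap = a_perm - (a_perm @ pinv.T) @ x.T
    r_perm = _pearson_rows(res_ap, np.broadcast_to(res_b, res_ap.shape))
    # residuals are centered, so Pearson of residuals == the statistic above
    p = float((np.sum(r_perm >= r_obs - 1e-12) + 1) / (n_perm + 1))
    return MantelResult(r_obs, p, n_perm, partial=True, control=control.kind)


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (rejection flags, adjusted p-values)."""
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adjusted
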