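"""Structure-corrected genotype–environment association scans and consensus.

Three complementary scans, mirroring the standard landscape-genomics toolkit:

* ``latent_factor_scan`` — a univariate individual-level scan in the spirit of
  latent-factor mixed models: population structure is absorbed by the top-k
  left singular vectors of the dosage matrix, each locus is regressed on the
  environmental variable plus the factors, and the squared z-scores are
  recalibrated by the genomic inflation factor (median z^2 over the chi^2_1
  median) before conversion to p-values.
* ``covariance_scan`` — a population-level generalized least squares scan:
  standardized population allele frequencies are regressed on the environment
  with the among-population frequency covariance (estimated on a neutral
  locus set) as the error covariance, the same statistical design as
  Bayes-factor environmental-correlation methods but deterministic.
* ``fit_rda``/``rda_outliers`` — multivariate redundancy analysis of the
  population frequency matrix on climate, optionally conditioned on structure
  covariates (partial RDA); outliers are loci whose loadings on the leading
  constrained axes lie more than ``sd_mult`` SDs from the axis mean.

Candidate loci are those flagged by at least ``min_methods`` scans.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, FrequencyTable, GenotypeMatrix
from .structure import bh_fdr

logger = logging.getLogger("landgea")

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))   # 0.4549...


# ---------------------------------------------------------------------------
# Redundancy analysis
# ---------------------------------------------------------------------------

@dataclass
class RDAResult:
    eigenvalues: np.ndarray              # constrained, non-increasing
    site_scores: np.ndarray              # (n_rows, n_axes) fitted site scores
    locus_scores: np.ndarray             # (n_loci, n_axes), scaled by sqrt(eig)
    biplot_scores: np.ndarray            # (n_predictors, n_axes)
    r2: float
    adj_r2: float
    total_variance: float
    constrained_variance: float
    residual_variance: float
    n_rows: int
    n_predictors: int
    conditioned: bool = False
    n_conditioning: int = 0
    global_p: float | None = None
    axis_p: np.ndarray | None = None
    locus_ids: list[str] = field(default_factory=list)


def _center(m: np.ndarray) -> np.ndarray:
    return m - m.mean(axis=0, keepdims=True)


def _residualize(m: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Residuals of (column-centered) m on centered z, intercept included."""
    coef, *_ = np.linalg.lstsq(z, m, rcond=None)
    return m - z @ coef


def _drop_collinear(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedily drop columns that add no rank; returns (reduced x, kept mask)."""
    keep = np.zeros(x.shape[1], bool)
    rank = 0
    cols: list[int] = []
    for j in range(x.shape[1]):
        trial = x[:, cols + [j]]
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            cols.append(j)
            rank = r
            keep[j] = True
    return x[:, cols], keep


def fit_rda(
    y: np.ndarray,
    x: np.ndarray,
    z: np.ndarray | None = None,
    locus_ids: list[str] | None = None,
) -> RDAResult:
    """Redundancy analysis of response y on predictors x, conditioning on z.

    y, x (and z) are column-centered internally; when z is given both y and x
    are first replaced by their least-squares residuals on z (partial RDA).
    Eigen-decomposition of the fitted-value covariance yields the constrained
    axes; r2 is constrained variance over the total variance of the (possibly
    z-residualized) response; adj_r2 is the Ezekiel adjustment with
    p = rank(x) predictors.
    """
    y = _center(np.asarray(y, float))
    x = _center(np.atleast_2d(np.asarray(x, float).T).T
                if np.asarray(x).ndim == 1 else np.asarray(x, float))
    if x.ndim == 1:
        x = x[:, None]
    n = y.shape[0]
    if x.shape[0] != n:
        raise ValueError("rows of y and x must align")
    if z is not None and np.asarray(z).size == 0:
        z = None
    q = 0
    if z is not None:
        z = _center(np.asarray(z, float))
        if z.ndim == 1:
            z = z[:, None]
        if z.shape[0] != n:
            raise ValueError("rows of y and z must align")
        q = int(np.linalg.matrix_rank(z))
        y = _residualize(y, z)
        x = _residualize(x, z)

    if n <= x.shape[1]:
        raise ValueError(
            f"cannot fit RDA: n={n} rows <= p={x.shape[1]} predictors")
    rank_x = int(np.linalg.matrix_rank(x)) if x.size else 0
    if rank_x < x.shape[1]:
        warnings.warn(
            f"rank-deficient predictor matrix: dropping "
            f"{x.shape[1] - rank_x} collinear column(s)", stacklevel=2)
        x, _ = _drop_collinear(x)
    p = x.shape[1]

    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ coef
    dof = n - 1
    total = float((y**2).sum()) / dof
    if total == 0:
        raise ValueError("response matrix has zero variance")
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    n_axes = min(p, n - 1, y.shape[1])
    s = s[:n_axes]
    eig = s**2 / dof
    constrained = float((fitted**2).sum()) / dof
    r2 = constrained / total
    if n - p - 1 > 0:
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    else:
        adj = np.nan
    site = u[:, :n_axes] * s
    locus = vt[:n_axes].T * np.sqrt(eig)          # "species" scaling by sqrt(eig)
    with np.errstate(invalid="ignore", divide="ignore"):
        xs = x / np.linalg.norm(x, axis=0, keepdims=True)
        ss = site / np.where(np.linalg.norm(site, axis=0) > 0,
                             np.linalg.norm(site, axis=0), 1.0)
        biplot = xs.T @ ss
    return RDAResult(
        eigenvalues=eig,
        site_scores=site,
        locus_scores=locus,
        biplot_scores=biplot,
        r2=r2,
        adj_r2=adj,
        total_variance=total,
        constrained_variance=constrained,
        residual_variance=total - constrained,
        n_rows=n,
        n_predictors=p,
        conditioned=z is not None,
        n_conditioning=q,
        locus_ids=list(locus_ids) if locus_ids else [],
    )


def permutation_anova(
    y: np.ndarray,
    x: np.ndarray,
    z: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int = 0,
    per_axis: bool = False,
) -> tuple[float, np.ndarray | None]:
    """Permutation test of the (partial) RDA via the pseudo-F statistic.

    pseudo-F = (constrained variance / p) / (residual variance / (n-p-q-1)).
    The null permutes the residuals of the reduced model: residuals of y on z
    when z is present, free row permutation of the centered response
    otherwise. p = (exceedances + 1)/(n_perm + 1). Per-axis p-values use the
    marginal scheme (exceedance of the i-th constrained eigenvalue).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    y = _center(np.asarray(y, float))
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[:, None]
    x = _center(x)
    n = y.shape[0]
    if z is not None and np.asarray(z).size == 0:
        z = None
    q = 0
    if z is not None:
        z = _center(np.asarray(z, float))
        if z.ndim == 1:
            z = z[:, None]
        q = int(np.linalg.matrix_rank(z))
        y_res = _residualize(y, z)
        x_res = _residualize(x, z)
    else:
        y_res, x_res = y, x
    if np.linalg.matrix_rank(x_res) < x_res.shape[1]:
        x_res, _ = _drop_collinear(x_res)
    p = x_res.shape[1]
    df_resid = n - p - q - 1
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom for the pseudo-F test")

    qx, _ = np.linalg.qr(x_res)
    n_axes = min(p, n - 1, y_res.shape[1])

    def pseudo_f(resp: np.ndarray) -> float:
        ss_c = float(((qx.T @ resp) ** 2).sum())
        ss_t = float((resp**2).sum())
        # rounding can push an exact fit's residual slightly negative
        ss_resid = max(ss_t - ss_c, 0.0)
        if ss_resid == 0.0:
            return np.inf
        return (ss_c / p) / (ss_resid / df_resid)

    def axis_eigs(resp: np.ndarray) -> np.ndarray:
        s = np.linalg.svd(qx @ (qx.T @ resp), compute_uv=False)[:n_axes]
        return s**2

    f_obs = pseudo_f(y_res)
    eig_obs = axis_eigs(y_res) if per_axis else None
    f_cut = f_obs * (1 - 1e-12) if np.isfinite(f_obs) else np.inf

    rng = np.random.default_rng(seed)
    exceed = 0
    axis_exceed = np.zeros(n_axes)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        resp = y_res[perm]
        if z is not None:
            resp = _residualize(resp, z)
        if pseudo_f(resp) >= f_cut:
            exceed += 1
        if per_axis:
            eig_p = axis_eigs(resp)
            k = min(eig_p.size, eig_obs.size)
            axis_exceed[:k] += eig_p[:k] >= eig_obs[:k] - 1e-12
    global_p = (exceed + 1) / (n_perm + 1)
    axis_p = (axis_exceed + 1) / (n_perm + 1) if per_axis else None
    return float(global_p), axis_p


# ---------------------------------------------------------------------------
# Outlier sets
# ---------------------------------------------------------------------------

@dataclass
class OutlierSet:
    method: str
    locus_ids: list[str]
    threshold: str

    def __len__(self) -> int:
        return len(self.locus_ids)


@dataclass
class CandidateSet:
    locus_ids: list[str]
    support: dict[str, int]              # locus -> number of supporting methods
    methods_of: dict[str, list[str]]
    min_methods: int
    overlap: pd.DataFrame                # pairwise overlap fractions

    def __len__(self) -> int:
        return len(self.locus_ids)


def rda_outliers(res: RDAResult, n_axes: int = 2, sd_mult: float = 3.0) -> OutlierSet:
    """Loci whose loadings lie > sd_mult SDs from the mean on any retained axis."""
    if n_axes > res.locus_scores.shape[1]:
        raise ValueError(
            f"n_axes={n_axes} exceeds the {res.locus_scores.shape[1]} "
            "available constrained axes")
    flags = np.zeros(res.locus_scores.shape[0], bool)
    for i in range(n_axes):
        sc = res.locus_scores[:, i]
        sd = sc.std()
        if sd == 0:
            continue
        flags |= np.abs(sc - sc.mean()) > sd_mult * sd
    ids = res.locus_ids or [str(j) for j in range(flags.size)]
    return OutlierSet(
        method="rda",
        locus_ids=[ids[j] for j in np.flatnonzero(flags)],
        threshold=f"|score - mean| > {sd_mult} SD on first {n_axes} axes",
    )


# ---------------------------------------------------------------------------
# Univariate latent-factor scan (individual level)
# ---------------------------------------------------------------------------

@dataclass
class GEAScanResult:
    method: str
    environment: str
    locus_ids: list[str]
    statistic: np.ndarray                # per-locus signed statistic
    p: np.ndarray
    q: np.ndarray                        # BH-adjusted
    outlier: np.ndarray                  # bool flags
    inflation_lambda: float | None = None
    k: int | None = None

    def outlier_set(self) -> OutlierSet:
        return OutlierSet(
            method=self.method,
            locus_ids=[self.locus_ids[j] for j in np.flatnonzero(self.outlier)],
            threshold=f"BH FDR on calibrated p ({self.environment})",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "locus_id": self.locus_ids,
            "statistic": self.statistic,
            "p": self.p,
            "q": self.q,
            "outlier": self.outlier.astype(int),
        })


def latent_factor_scan(
    g: GenotypeMatrix,
    env: np.ndarray,
    k: int = 10,
    fdr_q: float = 0.05,
    env_name: str = "env",
    factor_mode: str = "env_orthogonal",
) -> GEAScanResult:
    """Univariate scan of individual dosages on an environmental variable.

    The environment value of each individual is that of its site. Latent
    factors absorbing population structure are the top-k left singular
    vectors of the centered/scaled dosage matrix; per-locus OLS of dosage on
    environment + factors yields t statistics, squared into z^2 and
    recalibrated by the genomic inflation factor
    lambda = median(z^2) / median(chi^2_1) before conversion to chi^2_1
    p-values and BH FDR outlier calling.

    ``factor_mode`` controls the under/over-correction trade-off inherent to
    two-stage latent-factor scans:

    * ``"env_orthogonal"`` (default): factors are estimated on the data
      projected onto the orthogonal complement of the environment, the
      behaviour of the ridge latent-factor estimator in the small-penalty
      limit. Environment-aligned genetic variation is kept out of the
      correction, preserving power when structure and environment are
      collinear; the price is a raw inflation factor well above 1, which the
      genomic-control recalibration absorbs.
    * ``"svd"``: factors from the plain SVD. With k spanning the full
      between-population space (k >= n_pops - 1) the raw lambda sits near 1,
      but any environment effect that is constant within populations is
      absorbed by the factors, costing most of the power.
    """
    env = np.asarray(env, float)
    if env.shape[0] != g.n_individuals:
        raise ValueError("env must provide one value per individual")
    if env.std() == 0:
        raise ValueError("environmental variable is constant across individuals")
    if k >= g.n_individuals:
        raise ValueError("k must be smaller than the number of individuals")
    if k == 0:
        warnings.warn("k=0: no structure correction applied", stacklevel=2)

    geno = g.genotypes.astype(float)
    called = g.genotypes != MISSING
    col_mean = np.where(called, geno, 0).sum(0) / np.maximum(called.sum(0), 1)
    geno = np.where(called, geno, col_mean[None, :])
    gc = geno - geno.mean(axis=0, keepdims=True)
    sd = gc.std(axis=0)
    gs = gc / np.where(sd > 0, sd, 1.0)

    if factor_mode not in ("env_orthogonal", "svd"):
        raise ValueError("factor_mode must be 'env_orthogonal' or 'svd'")
    env_z = (env - env.mean()) / env.std()
    cols = [np.ones(g.n_individuals), env_z]
    if k > 0:
        if factor_mode == "env_orthogonal":
            ex = env_z / np.linalg.norm(env_z)
            basis = gs - np.outer(ex, ex @ gs)
        else:
            basis = gs
        u, _, _ = np.linalg.svd(basis, full_matrices=False)
        cols.append(u[:, :k])
    d = np.column_stack(cols)
    dtd_inv = np.linalg.inv(d.T @ d)
    coef = dtd_inv @ d.T @ gc
    resid = gc - d @ coef
    df = g.n_individuals - d.shape[1]
    if df <= 0:
        raise ValueError("no residual degrees of freedom in the locus regressions")
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * dtd_inv[1, 1], 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, coef[1] / se, 0.0)
    z2 = t**2
    lam = float(np.median(z2) / CHI2_1_MEDIAN)
    lam = max(lam, 1e-12)
    p = stats.chi2.sf(z2 / lam, df=1)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    reject, adj = bh_fdr(p, fdr_q)
    return GEAScanResult(
        method="latent_factor",
        environment=env_name,
        locus_ids=g.locus_ids(),
        statistic=t,
        p=p,
        q=adj,
        outlier=reject,
        inflation_lambda=lam,
        k=k,
    )


# ---------------------------------------------------------------------------
# Population-covariance GLS scan
# ---------------------------------------------------------------------------

@dataclass
class PopCovariance:
    omega: np.ndarray
    populations: list[str]
    epsilon: float
    n_loci: int


def _standardize_freqs(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(p_k - pbar)/sqrt(pbar(1-pbar)) per locus; mask of usable loci."""
    pbar = freqs.mean(axis=0)
    usable = (pbar > 0) & (pbar < 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = (freqs - pbar[None, :]) / np.sqrt(pbar * (1 - pbar))[None, :]
    return x, usable


def estimate_pop_covariance(
    f: FrequencyTable,
    neutral_loci: np.ndarray | list[int] | None = None,
    epsilon: float | None = None,
) -> PopCovariance:
    """Among-population covariance of standardized allele frequencies.

    Estimated across a designated neutral locus set; a ridge term eps*I
    (default 1e-4 * trace/n) guarantees invertibility of the (rank-deficient,
    since standardized frequencies are population-centered) sample covariance.
    """
    if f.n_populations < 2:
        raise ValueError("need at least 2 populations")
    freqs = f.imputed()
    if neutral_loci is not None:
        idx = np.asarray(neutral_loci)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        freqs = freqs[:, idx]
    if freqs.shape[1] < 50:
        warnings.warn(
            f"only {freqs.shape[1]} neutral loci for covariance estimation; "
            ">= 50 recommended", stacklevel=2)
    x, usable = _standardize_freqs(freqs)
    x = x[:, usable]
    if x.shape[1] == 0:
        raise ValueError("no polymorphic neutral loci for covariance estimation")
    omega = x @ x.T / max(x.shape[1] - 1, 1)
    if epsilon is None:
        epsilon = 1e-4 * float(np.trace(omega)) / f.n_populations
    omega = omega + epsilon * np.eye(f.n_populations)
    return PopCovariance(omega, list(f.populations), float(epsilon), x.shape[1])


def covariance_scan(
    f: FrequencyTable,
    env: np.ndarray,
    omega: PopCovariance,
    fdr_q: float = 0.05,
    env_name: str = "env",
    outlier_rule: str = "top_quantile",
    top_quantile: float = 0.025,
    p_gate: float = 0.005,
) -> GEAScanResult:
    """GLS scan of standardized population frequencies on the environment.

    Per locus, generalized least squares of the standardized frequency vector
    on (intercept, standardized env) with error covariance omega; the
    statistic is effect/SE with a two-sided t p-value on n_pops - 2 df.

    Outlier calling: ``"top_quantile"`` (default) flags loci in the upper
    ``top_quantile`` tail of |statistic| that are also nominally significant
    (p < ``p_gate``) — the hard-call analogue of calling outliers from the
    upper tail of Bayes factors, appropriate because a t test on n_pops - 2
    degrees of freedom has little per-locus resolution; the significance gate
    keeps the rule from force-flagging a fixed fraction when there is no
    signal. ``"bh"`` applies Benjamini-Hochberg FDR to the t p-values.
    """
    k = f.n_populations
    env = np.asarray(env, float)
    if env.shape[0] != k:
        raise ValueError("env must provide one value per population")
    if env.std() == 0:
        raise ValueError("environmental variable is constant across populations")
    env_z = (env - env.mean()) / env.std()
    try:
        chol = np.linalg.cholesky(omega.omega)
    except np.linalg.LinAlgError as exc:
        raise ValueError("omega is not positive definite; regularize first") from exc
    freqs = f.imputed()
    y, usable = _standardize_freqs(freqs)
    y = np.where(usable[None, :], y, 0.0)
    x = np.column_stack([np.ones(k), env_z])
    xw = np.linalg.solve(chol, x)
    yw = np.linalg.solve(chol, y)
    xtx_inv = np.linalg.inv(xw.T @ xw)
    coef = xtx_inv @ xw.T @ yw
    resid = yw - xw @ coef
    df = k - 2
    if df <= 0:
        raise ValueError("need more than 2 populations for the GLS scan")
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, coef[1] / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p = np.where(usable, p, 1.0)
    if outlier_rule == "bh":
        reject, adj = bh_fdr(p, fdr_q)
    elif outlier_rule == "top_quantile":
        _, adj = bh_fdr(p, fdr_q)
        cut = np.quantile(np.abs(t), 1.0 - top_quantile)
        reject = (np.abs(t) > cut) & (p < p_gate)
    else:
        raise ValueError("outlier_rule must be 'top_quantile' or 'bh'")
    return GEAScanResult(
        method="covariance_gls",
        environment=env_name,
        locus_ids=list(f.locus_ids) or [str(j) for j in range(f.n_loci)],
        statistic=t,
        p=p,
        q=adj,
        outlier=reject,
    )


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def consensus_candidates(sets: list[OutlierSet], min_methods: int = 2) -> CandidateSet:
    """Loci flagged by at least ``min_methods`` scans, with overlap report.

    The pairwise overlap table reports the Jaccard fraction
    |A∩B|/|A∪B| as well as the per-method fractions |A∩B|/|A| and |A∩B|/|B|.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 outlier sets")
    if min_methods < 2:
        raise ValueError("min_methods must be >= 2")
    methods_of: dict[str, list[str]] = {}
    for s in sets:
        for lid in set(s.locus_ids):
            methods_of.setdefault(lid, []).append(s.method)
    support = {lid: len(ms) for lid, ms in methods_of.items()}
    cand = sorted(lid for lid, n in support.items() if n >= min_methods)
    rows = []
    for i, a in enumerate(sets):
        for b in sets[i + 1:]:
            sa, sb = set(a.locus_ids), set(b.locus_ids)
            inter, union = len(sa & sb), len(sa | sb)
            rows.append({
                "method_a": a.method, "method_b": b.method,
                "n_a": len(sa), "n_b": len(sb), "n_intersection": inter,
                "jaccard": inter / union if union else 0.0,
                "frac_of_a": inter / len(sa) if sa else 0.0,
                "frac_of_b": inter / len(sb) if sb else 0.0,
            })
    return CandidateSet(
        locus_ids=cand,
        support={lid: support[lid] for lid in cand},
        methods_of={lid: methods_of[lid] for lid in cand},
        min_methods=min_methods,
        overlap=pd.DataFrame(rows),
    )
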