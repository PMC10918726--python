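"""Variance partitioning, climate-variable attribution, and polygenic scores.

Variance partitioning decomposes the explained variance of the population
frequency matrix into a component exclusive to climate, a component exclusive
to population structure, and their joint (confounded) share, via the standard
series of RDA/pRDA fits; components are assembled as differences of
full-model R² values so that the decomposition is exactly additive, and both
"fraction of total variance" and "fraction of explained variance"
normalizations are reported.

Per-locus attribution fits one partial RDA per climate variable (conditioned
on the remaining variables and structure), z-normalizes the axis-1 locus
loadings across loci, and assigns each locus to the variable with the largest
absolute normalized loading.

Polygenic climate scores are unweighted sums of orientation-corrected
dosages: per variable, each assigned locus contributes its dosage if its
population frequency rises with the variable and (2 - dosage) otherwise;
linear vs quadratic score-environment models are compared by AIC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, ClimateTable, FrequencyTable, GenotypeMatrix
from .scan import CandidateSet, RDAResult, fit_rda, permutation_anova

logger = logging.getLogger("landgea")


# ---------------------------------------------------------------------------
# Variance partitioning
# ---------------------------------------------------------------------------

@dataclass
class VariancePartition:
    total: float                          # unadjusted R2 of climate ∪ structure
    exclusive_climate: float
    exclusive_structure: float
    joint: float
    unexplained: float
    total_adj: float
    exclusive_climate_adj: float
    exclusive_structure_adj: float
    joint_adj: float
    unexplained_adj: float
    climate_alone: float                  # marginal (unconditioned) fits
    structure_alone: float
    climate_alone_adj: float
    structure_alone_adj: float
    p_total: float | None = None
    p_exclusive_climate: float | None = None
    p_exclusive_structure: float | None = None

    def of_explained(self) -> dict[str, float]:
        """Components renormalized as fractions of the explained variance."""
        t = self.total if self.total > 0 else np.nan
        return {
            "exclusive_climate": self.exclusive_climate / t,
            "exclusive_structure": self.exclusive_structure / t,
            "joint": self.joint / t,
        }

    def to_frame(self) -> pd.DataFrame:
        shares = self.of_explained()
        rows = [
            ("total_explained", self.total, self.total_adj, 1.0, self.p_total),
            ("exclusive_climate", self.exclusive_climate,
             self.exclusive_climate_adj, shares["exclusive_climate"],
             self.p_exclusive_climate),
            ("exclusive_structure", self.exclusive_structure,
             self.exclusive_structure_adj, shares["exclusive_structure"],
             self.p_exclusive_structure),
            ("joint", self.joint, self.joint_adj, shares["joint"], None),
            ("unexplained", self.unexplained, self.unexplained_adj, None, None),
        ]
        return pd.DataFrame(
            rows, columns=["component", "r2", "adj_r2", "share_of_explained", "p"])


def partition_variance(
    y: np.ndarray | FrequencyTable,
    climate: np.ndarray,
    structure: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> VariancePartition:
    """Partition response variance between climate and structure predictors.

    Five fits: y ~ climate, y ~ structure, y ~ climate|structure,
    y ~ structure|climate and y ~ climate ∪ structure. Unadjusted components
    are differences of full-model R² (exactly additive); adjusted components
    are the analogous differences of Ezekiel-adjusted R². Permutation
    p-values come from the pseudo-F tests of the full and the two partial
    models.
    """
    ymat = y.imputed() if isinstance(y, FrequencyTable) else np.asarray(y, float)
    c = np.asarray(climate, float)
    s = np.asarray(structure, float)
    if c.ndim == 1:
        c = c[:, None]
    if s.ndim == 1:
        s = s[:, None]
    n = ymat.shape[0]
    p_comb = np.linalg.matrix_rank(np.column_stack([c, s]))
    if p_comb >= n - 1:
        raise ValueError(
            f"combined predictor count {p_comb} >= n-1 ({n - 1}); use fewer "
            "structure axes or climate variables")

    fit_c = fit_rda(ymat, c)
    fit_s = fit_rda(ymat, s)
    fit_b = fit_rda(ymat, np.column_stack([c, s]))

    total = fit_b.r2
    excl_c = fit_b.r2 - fit_s.r2
    excl_s = fit_b.r2 - fit_c.r2
    joint = fit_c.r2 + fit_s.r2 - fit_b.r2
    total_adj = fit_b.adj_r2
    excl_c_adj = fit_b.adj_r2 - fit_s.adj_r2
    excl_s_adj = fit_b.adj_r2 - fit_c.adj_r2
    joint_adj = fit_c.adj_r2 + fit_s.adj_r2 - fit_b.adj_r2

    p_total, _ = permutation_anova(ymat, np.column_stack([c, s]),
                                   n_perm=n_perm, seed=seed)
    p_exc_c, _ = permutation_anova(ymat, c, s, n_perm=n_perm, seed=seed + 1)
    p_exc_s, _ = permutation_anova(ymat, s, c, n_perm=n_perm, seed=seed + 2)

    return VariancePartition(
        total=total,
        exclusive_climate=excl_c,
        exclusive_structure=excl_s,
        joint=joint,
        unexplained=1.0 - total,
        total_adj=total_adj,
        exclusive_climate_adj=excl_c_adj,
        exclusive_structure_adj=excl_s_adj,
        joint_adj=joint_adj,
        unexplained_adj=1.0 - total_adj,
        climate_alone=fit_c.r2,
        structure_alone=fit_s.r2,
        climate_alone_adj=fit_c.adj_r2,
        structure_alone_adj=fit_s.adj_r2,
        p_total=p_total,
        p_exclusive_climate=p_exc_c,
        p_exclusive_structure=p_exc_s,
    )


# ---------------------------------------------------------------------------
# Per-variable marginal effects and per-locus attribution
# ---------------------------------------------------------------------------

def marginal_climate_effects(
    y: np.ndarray | FrequencyTable,
    climate: np.ndarray,
    variable_names: list[str],
    structure: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-variable marginal (semipartial) effects on the response.

    For each climate variable v: a pRDA of y on v conditioned on all other
    variables (plus structure covariates, when given). Reported per variable:
    the semipartial R² (full-model R² minus the model without v), the
    matching difference of adjusted R², and the permutation p of the
    conditional pseudo-F test.
    """
    ymat = y.imputed() if isinstance(y, FrequencyTable) else np.asarray(y, float)
    c = np.asarray(climate, float)
    s = _structure_block(structure, ymat.shape[0])
    nv = c.shape[1]
    if nv < 2:
        raise ValueError("need at least 2 climate variables")
    n = ymat.shape[0]
    full_cols = np.column_stack([c, s])
    if np.linalg.matrix_rank(full_cols) >= n - 1:
        raise ValueError("conditioning matrix rank too high for marginal effects")
    fit_full = fit_rda(ymat, full_cols)
    rows = []
    for v in range(nv):
        others = np.delete(c, v, axis=1)
        cond = np.column_stack([others, s])
        fit_red = fit_rda(ymat, cond)
        p_val, _ = permutation_anova(ymat, c[:, [v]], cond,
                                     n_perm=n_perm, seed=seed + v)
        rows.append({
            "variable": variable_names[v],
            "r2": fit_full.r2 - fit_red.r2,
            "adj_r2": fit_full.adj_r2 - fit_red.adj_r2,
            "p": p_val,
        })
    return pd.DataFrame(rows)


@dataclass
class LocusAttribution:
    locus_ids: list[str]
    assigned: list[str]                   # per-locus climate variable
    scores: np.ndarray                    # (n_loci, n_variables) normalized
    variables: list[str]
    reliable: bool = True
    n_ties: int = 0

    def counts(self) -> pd.Series:
        return pd.Series(self.assigned).value_counts()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.variables)
        df.insert(0, "locus_id", self.locus_ids)
        df["assigned"] = self.assigned
        return df


def _structure_block(structure: np.ndarray | None, n_rows: int) -> np.ndarray:
    if structure is None:
        return np.zeros((n_rows, 0))
    s = np.asarray(structure, float)
    return s[:, None] if s.ndim == 1 else s


def assign_strongest_variable(
    y: np.ndarray | FrequencyTable,
    climate: np.ndarray,
    variable_names: list[str],
    structure: np.ndarray | None = None,
    locus_ids: list[str] | None = None,
) -> LocusAttribution:
    """Assign each locus to its most strongly associated climate variable.

    One single-variable pRDA per variable, conditioned on the other climate
    variables (plus structure covariates, when given — note that structure
    axes estimated from genotype data can absorb the very gradient being
    attributed when selection shapes the leading axes, so conditioning on
    them is optional and off in the pipeline default); axis-1 locus loadings
    are normalized to zero mean / unit variance across loci, and each locus
    is assigned the variable with the largest absolute normalized loading.
    The response should include the neutral locus background, not only the
    outliers, so that the normalization has an absolute reference: with the
    outliers alone, loci sharing a single driving variable cannot stand out
    relative to one another. Ties break to the first variable in order, with
    a logged warning.
    """
    ymat = y.imputed() if isinstance(y, FrequencyTable) else np.asarray(y, float)
    if isinstance(y, FrequencyTable) and locus_ids is None:
        locus_ids = list(y.locus_ids)
    c = np.asarray(climate, float)
    s = _structure_block(structure, ymat.shape[0])
    n_loci = ymat.shape[1]
    if n_loci < 1:
        raise ValueError("need at least one locus to attribute")
    ids = locus_ids or [str(j) for j in range(n_loci)]
    nv = c.shape[1]
    scores = np.zeros((n_loci, nv))
    reliable = n_loci > 1
    for v in range(nv):
        cond = np.column_stack([np.delete(c, v, axis=1), s])
        res = fit_rda(ymat, c[:, [v]], cond)
        if res.locus_scores.shape[1] == 0:
            # variable fully collinear with the conditioning set
            scores[:, v] = 0.0
            continue
        sc = res.locus_scores[:, 0]
        sd = sc.std()
        if n_loci == 1 or sd == 0:
            scores[:, v] = 0.0
            reliable = False
        else:
            scores[:, v] = (sc - sc.mean()) / sd
    if not reliable:
        warnings.warn("degenerate locus-score normalization; attribution "
                      "flagged unreliable", stacklevel=2)
    absA = np.abs(scores)
    best = absA.argmax(axis=1)
    ties = (absA == absA.max(axis=1, keepdims=True)).sum(axis=1) > 1
    n_ties = int(ties.sum())
    if n_ties:
        logger.warning("%d loci with tied attribution scores; tie-break to "
                       "first variable in order", n_ties)
    return LocusAttribution(
        locus_ids=list(ids),
        assigned=[variable_names[b] for b in best],
        scores=scores,
        variables=list(variable_names),
        reliable=reliable,
        n_ties=n_ties,
    )


# ---------------------------------------------------------------------------
# Polygenic scores
# ---------------------------------------------------------------------------

@dataclass
class ScoreModelFit:
    variable: str
    n: int
    aic_linear: float
    aic_quadratic: float | None
    selected: str                          # "linear" | "quadratic"
    coef_linear: np.ndarray
    coef_quadratic: np.ndarray | None
    adj_r2: float


@dataclass
class PolygenicResult:
    individual_ids: list[str]
    variables: list[str]
    scores: dict[str, np.ndarray]          # variable -> per-individual int score
    orientation: dict[str, np.ndarray]     # variable -> per-locus sign
    loci_used: dict[str, list[str]]
    models: dict[str, ScoreModelFit] = field(default_factory=dict)
    n_imputed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.variables:
            for ind, s in zip(self.individual_ids, self.scores[v]):
                rows.append((ind, v, int(s)))
        return pd.DataFrame(rows, columns=["individual", "variable", "score"])


def _aic_ols(x: np.ndarray, y: np.ndarray, k_extra: int = 0):
    """Gaussian AIC = n log(RSS/n) + 2k, k counting coefficients + variance."""
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    n = y.size
    rss = float((resid**2).sum())
    rss_floor = max(rss, 1e-12)
    k = x.shape[1] + 1 + k_extra
    aic = n * np.log(rss_floor / n) + 2 * k
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    p = x.shape[1] - 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else np.nan
    return coef, aic, adj


def fit_score_models(scores: np.ndarray, env: np.ndarray,
                     variable: str = "env") -> ScoreModelFit:
    """Compare linear vs quadratic score-environment models by AIC."""
    scores = np.asarray(scores, float)
    env = np.asarray(env, float)
    n = scores.size
    x_lin = np.column_stack([np.ones(n), env])
    coef_l, aic_l, adj_l = _aic_ols(x_lin, scores)
    if np.unique(env).size < 3:
        warnings.warn("fewer than 3 distinct environment values: quadratic "
                      "model skipped", stacklevel=2)
        return ScoreModelFit(variable, n, aic_l, None, "linear", coef_l, None, adj_l)
    x_quad = np.column_stack([np.ones(n), env, env**2])
    coef_q, aic_q, adj_q = _aic_ols(x_quad, scores)
    if aic_q < aic_l:
        return ScoreModelFit(variable, n, aic_l, aic_q, "quadratic",
                             coef_l, coef_q, adj_q)
    return ScoreModelFit(variable, n, aic_l, aic_q, "linear", coef_l, coef_q, adj_l)


def polygenic_scores(
    g: GenotypeMatrix,
    candidates: CandidateSet,
    attribution: LocusAttribution,
    f: FrequencyTable,
    climate: ClimateTable,
    fit_models: bool = True,
) -> PolygenicResult:
    """Additive polygenic climate scores over candidate loci.

    Per climate variable V, using the candidate loci assigned to V: the
    orientation sign of a locus is the sign of the across-population Pearson
    correlation between its allele frequency and V; each individual
    contributes its dosage when the sign is positive and (2 - dosage)
    otherwise; missing dosages are imputed by the rounded doubled population
    frequency (logged). Scores therefore lie in [0, 2 * n_loci_used].
    """
    id_to_col = {lid: j for j, lid in enumerate(f.locus_ids)}
    g_col = {lid: j for j, lid in enumerate(g.locus_ids())}
    missing_in_g = [lid for lid in candidates.locus_ids if lid not in g_col]
    if missing_in_g:
        raise ValueError(f"candidate loci absent from genotypes: {missing_in_g[:5]}")
    assigned_of = dict(zip(attribution.locus_ids, attribution.assigned))
    freqs = f.imputed()
    pop_index = {p: k for k, p in enumerate(f.populations)}
    ind_pop = np.array([pop_index[g.population_of[i]] for i in g.individual_ids])

    scores: dict[str, np.ndarray] = {}
    orientation: dict[str, np.ndarray] = {}
    loci_used: dict[str, list[str]] = {}
    models: dict[str, ScoreModelFit] = {}
    n_imputed = 0
    for vi, var in enumerate(climate.variables):
        loci = [lid for lid in candidates.locus_ids if assigned_of.get(lid) == var]
        if not loci:
            warnings.warn(f"no candidate loci assigned to {var}; score skipped",
                          stacklevel=2)
            continue
        env = climate.values[:, vi]
        env_c = env - env.mean()
        signs = np.empty(len(loci))
        total = np.zeros(g.n_individuals)
        for i, lid in enumerate(loci):
            fr = freqs[:, id_to_col[lid]]
            cov = float(((fr - fr.mean()) * env_c).sum())
            signs[i] = 1.0 if cov > 0 else -1.0
            dos = g.genotypes[:, g_col[lid]].astype(float)
            miss = dos == MISSING
            if miss.any():
                imput = np.rint(2.0 * fr[ind_pop])
                dos = np.where(miss, imput, dos)
                n_imputed += int(miss.sum())
            total += dos if signs[i] > 0 else (2.0 - dos)
        scores[var] = np.rint(total).astype(int)
        orientation[var] = signs
        loci_used[var] = loci
        if fit_models:
            env_ind = env[ind_pop]
            models[var] = fit_score_models(scores[var], env_ind, var)
    if n_imputed:
        logger.info("imputed %d missing dosages in polygenic scores", n_imputed)
    return PolygenicResult(
        individual_ids=list(g.individual_ids),
        variables=[v for v in climate.variables if v in scores],
        scores=scores,
        orientation=orientation,
        loci_used=loci_used,
        models=models,
        n_imputed=n_imputed,
    )
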