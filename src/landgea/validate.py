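"""Reusable validation experiments: calibration, recovery and power.

These functions run the package's own machinery on synthetic data under
controlled conditions (star-tree drift at F = 0.1 for the scan experiments,
so the expected differentiation is known in closed form) and measure the
operating characteristics a user should care about: F_ST recovery against
the Balding–Nichols expectation, permutation-test type-I error, genomic
inflation under the null, consensus sensitivity and false discovery under
clinal selection, attribution accuracy, and polygenic-score recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import attribution as attr
from . import popgen, scan, structure
from .io import apply_variant_filters, population_allele_frequencies
from .simulate import SimConfig, simulate_metapopulation


def fst_recovery(seed: int = 0, n_loci: int = 5000, drift_f: float = 0.1) -> float:
    """Mean pairwise Hudson F_ST on a star tree; expectation ~ drift_f."""
    cfg = SimConfig(n_loci=n_loci, n_selected=0, beta=0.0, tree="star",
                    drift_F=drift_f, missing_rate=0.0, fis=0.0, seed=seed)
    g, _, _ = simulate_metapopulation(cfg)
    f = population_allele_frequencies(g)
    fst = popgen.pairwise_fst(f)
    iu = np.triu_indices(f.n_populations, 1)
    return float(fst.values[iu].mean())


@dataclass
class ScanExperiment:
    """Outcome of one seeded scan/consensus/attribution/polygenic run."""

    seed: int
    beta: float
    n_true: int
    n_candidates: int
    sensitivity: float
    fdr: float
    lambda_svd: float            # latent-factor scan, svd mode, k = n_pops - 1
    lambda_default: float        # pipeline default (env-orthogonal factors)
    attribution_accuracy: float  # among detected true loci; NaN if none
    n_detected_true: int
    polygenic_adj_r2: float      # score vs driving variable; NaN if undefined
    n_variables: int


def run_scan_experiment(seed: int, beta: float = 1.5, n_loci: int = 2000,
                        n_selected: int = 50) -> ScanExperiment:
    """One seeded end-to-end recovery run at the controlled drift condition.

    Star tree at drift F = 0.1, 12 populations x 24 individuals; selection of
    ``n_selected`` loci on the first climate variable with effect ``beta`` on
    the logit scale per SD of environment. Runs the three scans with the
    pipeline defaults, the >= 2-method consensus, full-background locus
    attribution and polygenic scoring, and measures recovery against the
    simulation truth.
    """
    cfg = SimConfig(n_loci=n_loci, n_selected=n_selected if beta else 0,
                    beta=beta, tree="star", drift_F=0.1, seed=seed)
    g, clim, truth = simulate_metapopulation(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g, _ = apply_variant_filters(g)
        f = population_allele_frequencies(g)
        ids = np.array(g.locus_ids())
        true_ids = set(truth.selected_locus_ids) & set(ids)
        cpca = structure.climate_pca(clim, 2)
        pop_index = {p: j for j, p in enumerate(clim.populations)}
        ind_pop = np.array([pop_index[g.population_of[i]]
                            for i in g.individual_ids])

        # latent-factor scan (both factor modes; default drives the consensus)
        lf_flags = np.zeros(g.n_loci, bool)
        lams_default, lams_svd = [], []
        for i in range(cpca.site_scores.shape[1]):
            env_i = cpca.site_scores[ind_pop, i]
            r = scan.latent_factor_scan(g, env_i, k=10)
            lf_flags |= r.outlier
            lams_default.append(r.inflation_lambda)
            r_svd = scan.latent_factor_scan(g, env_i, k=cfg.n_pops - 1,
                                            factor_mode="svd")
            lams_svd.append(r_svd.inflation_lambda)

        # covariance GLS scan with one-step neutral refinement of omega
        omega = scan.estimate_pop_covariance(f)
        first = np.zeros(f.n_loci)
        for i in range(cpca.site_scores.shape[1]):
            r0 = scan.covariance_scan(f, cpca.site_scores[:, i], omega)
            first = np.maximum(first, np.abs(r0.statistic))
        omega = scan.estimate_pop_covariance(
            f, neutral_loci=first <= np.quantile(first, 0.95))
        cov_flags = np.zeros(f.n_loci, bool)
        for i in range(cpca.site_scores.shape[1]):
            cov_flags |= scan.covariance_scan(
                f, cpca.site_scores[:, i], omega).outlier

        # structure-conditioned RDA scan
        axes = structure.genotype_pca(g, 4)
        rda = scan.fit_rda(f.imputed(), clim.standardized(),
                           axes.population_scores, locus_ids=list(f.locus_ids))
        rda_set = scan.rda_outliers(rda, 2, 3.0)

        sets = [
            scan.OutlierSet("latent_factor", list(ids[lf_flags]), ""),
            scan.OutlierSet("covariance_gls", list(ids[cov_flags]), ""),
            rda_set,
        ]
        cand = scan.consensus_candidates(sets, 2)
        tp = len(set(cand.locus_ids) & true_ids)
        sens = tp / len(true_ids) if true_ids else np.nan
        fdr = (len(cand) - tp) / len(cand) if len(cand) else 0.0

        attr_acc, n_det_true, poly_r2 = np.nan, 0, np.nan
        if beta and len(cand) > 1:
            cstd = clim.standardized()
            names = clim.valid_variables()
            la_full = attr.assign_strongest_variable(f, cstd, names)
            a_of = dict(zip(la_full.locus_ids, la_full.assigned))
            det_true = [l for l in cand.locus_ids if l in true_ids]
            n_det_true = len(det_true)
            driving = names[cfg.driving_variable]
            if det_true:
                attr_acc = float(np.mean([a_of[l] == driving for l in det_true]))
            keep = [i for i, l in enumerate(la_full.locus_ids)
                    if l in set(cand.locus_ids)]
            la = attr.LocusAttribution(
                locus_ids=[la_full.locus_ids[i] for i in keep],
                assigned=[la_full.assigned[i] for i in keep],
                scores=la_full.scores[keep], variables=la_full.variables)
            poly = attr.polygenic_scores(g, cand, la, f, clim)
            if driving in poly.models:
                poly_r2 = float(poly.models[driving].adj_r2)

    return ScanExperiment(
        seed=seed, beta=beta, n_true=len(true_ids), n_candidates=len(cand),
        sensitivity=float(sens), fdr=float(fdr),
        lambda_svd=float(np.median(lams_svd)),
        lambda_default=float(np.median(lams_default)),
        attribution_accuracy=attr_acc, n_detected_true=n_det_true,
        polygenic_adj_r2=poly_r2, n_variables=len(clim.variables),
    )


def scan_experiment_batch(seeds, beta: float = 1.5) -> list[ScanExperiment]:
    return [run_scan_experiment(s, beta) for s in seeds]


def median_over(runs: list[ScanExperiment], field: str) -> float:
    vals = [getattr(r, field) for r in runs]
    vals = [v for v in vals if np.isfinite(v)]
    return float(np.median(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# Permutation-test calibration
# ---------------------------------------------------------------------------

def mantel_null_pvalues(n_replicates: int = 500, n_sites: int = 8,
                        n_perm: int = 999, seed: int = 0,
                        partial: bool = False) -> np.ndarray:
    """Null p-values of the (partial) Mantel test on independent matrices."""
    rng = np.random.default_rng(seed)
    labels = [f"s{i}" for i in range(n_sites)]

    def random_dist() -> structure.DistanceMatrix:
        pts = rng.normal(size=(n_sites, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        return structure.DistanceMatrix(d, labels, "environmental")

    ps = np.empty(n_replicates)
    for r in range(n_replicates):
        a, b = random_dist(), random_dist()
        if partial:
            c = random_dist()
            res = structure.partial_mantel_test(a, b, c, n_perm=n_perm,
                                                seed=int(rng.integers(2**31)))
        else:
            res = structure.mantel_test(a, b, n_perm=n_perm,
                                        seed=int(rng.integers(2**31)))
        ps[r] = res.p
    return ps


def rda_anova_null_pvalues(n_replicates: int = 500, n_rows: int = 12,
                           n_loci: int = 30, n_pred: int = 3,
                           n_perm: int = 999, seed: int = 0) -> np.ndarray:
    """Null p-values of the RDA permutation ANOVA with noise predictors."""
    rng = np.random.default_rng(seed)
    ps = np.empty(n_replicates)
    for r in range(n_replicates):
        y = rng.normal(size=(n_rows, n_loci))
        x = rng.normal(size=(n_rows, n_pred))
        p, _ = scan.permutation_anova(y, x, n_perm=n_perm,
                                      seed=int(rng.integers(2**31)))
        ps[r] = p
    return ps
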