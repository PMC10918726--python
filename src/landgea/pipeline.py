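"""Configuration-driven orchestration of the full landscape-genomics analysis.

Stage order: variant filters -> population allele frequencies -> diversity
and pairwise F_ST -> structure PCA -> climate PCA -> IBD/IBE Mantel tests ->
three GEA scans -> consensus candidates -> variance partitioning -> marginal
climate effects -> per-locus attribution -> polygenic scores -> report.
Every stage writes a TSV artifact into the output directory; the resolved
configuration and a run report are written alongside so each run is fully
auditable and reproducible from its seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribution as attr
from . import io as lio
from . import popgen, scan, simulate, structure

logger = logging.getLogger("landgea")


@dataclass
class PipelineConfig:
    """Resolved settings of one pipeline run.

    Defaults follow the package's reference analysis: MAF > 0.05, presence in
    >= 12 individuals per population, 4 structure axes, 2 climate principal
    components for the univariate scans, BH FDR q = 0.05, RDA outliers at 3
    SD on 2 axes, 1000 permutations, >= 2-method consensus.
    """

    # input: either file paths or a simulate block
    genotypes: str | None = None
    genotype_format: str = "vcf"
    pop_table: str | None = None
    climate_table: str | None = None
    simulate: simulate.SimConfig | None = None
    # filters
    maf_min: float = 0.05
    min_ind_per_pop: int = 12
    # structure / climate
    structure_axes: int = 4
    climate_pcs: int = 2
    # scans
    k_latent: int = 10
    lf_factor_mode: str = "env_orthogonal"
    fdr_q: float = 0.05
    cov_outlier_rule: str = "top_quantile"
    cov_top_quantile: float = 0.025
    cov_refine_omega: bool = True
    rda_axes: int = 2
    rda_sd_mult: float = 3.0
    n_perm: int = 1000
    min_methods: int = 2
    # attribution: condition per-variable RDAs on structure axes as well
    attr_condition_structure: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d.get("simulate") is not None:
            d["simulate"]["ancestral_freq_range"] = list(
                d["simulate"]["ancestral_freq_range"])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = simulate.SimConfig(**sim)
        return cfg

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class PipelineResult:
    outdir: Path
    config: PipelineConfig
    filter_log: lio.FilterLog | None = None
    fst: popgen.FstMatrix | None = None
    mantel: pd.DataFrame | None = None
    scans: dict[str, scan.GEAScanResult] = field(default_factory=dict)
    outlier_sets: list[scan.OutlierSet] = field(default_factory=list)
    candidates: scan.CandidateSet | None = None
    partition: attr.VariancePartition | None = None
    marginal: pd.DataFrame | None = None
    attribution: attr.LocusAttribution | None = None
    polygenic: attr.PolygenicResult | None = None
    report: dict = field(default_factory=dict)


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    for h in [h for h in logger.handlers if isinstance(h, logging.FileHandler)]:
        h.close()
        logger.removeHandler(h)
    fh = logging.FileHandler(outdir / "run.log", mode="a")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler) for h in logger.handlers):
        logger.addHandler(logging.StreamHandler())


def _write_matrix_tsv(m: np.ndarray, labels: list[str], path: Path) -> None:
    pd.DataFrame(m, index=labels, columns=labels).to_csv(path, sep="\t")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute every analysis stage and write all artifacts to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    config.dump(outdir / "config_resolved.yaml")
    result = PipelineResult(outdir, config)
    report: dict = {"seed": config.seed, "warnings": {}}

    # ---- stage: input ----------------------------------------------------
    truth = None
    if config.simulate is not None:
        logger.info("stage input: simulating metapopulation (seed=%d)",
                    config.simulate.seed)
        g, climate, truth = simulate.simulate_metapopulation(config.simulate)
        lio.write_genotypes_tsv(g, outdir / "genotypes.tsv")
        lio.write_population_table(g, outdir / "populations.tsv")
        lio.write_climate_table(climate, outdir / "climate.tsv")
        simulate.write_truth_tsv(truth, config.simulate.n_loci, outdir / "truth.tsv")
        report["warnings"]["clipped_frequencies"] = truth.n_clipped
    else:
        if not (config.genotypes and config.pop_table and config.climate_table):
            raise ValueError(
                "stage input: provide genotypes, pop_table and climate_table "
                "paths, or a simulate block")
        logger.info("stage input: loading %s", config.genotypes)
        g = lio.load_genotypes(config.genotypes, config.genotype_format,
                               config.pop_table)
        climate = lio.read_climate_table(config.climate_table)
    report["n_individuals"] = g.n_individuals
    report["n_loci_input"] = g.n_loci

    # ---- stage: filters --------------------------------------------------
    g, flog = lio.apply_variant_filters(g, config.maf_min, config.min_ind_per_pop)
    result.filter_log = flog
    report["filters"] = dataclasses.asdict(flog)
    logger.info("stage filters: %d -> %d loci", flog.n_input, flog.n_retained)

    # ---- stage: frequencies ----------------------------------------------
    f = lio.population_allele_frequencies(g)
    report["n_populations"] = f.n_populations

    # ---- stage: diversity and F_ST ---------------------------------------
    div = popgen.diversity_stats(g)
    div.to_frame().to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    fst = popgen.pairwise_fst(f)
    fst.to_frame().to_csv(outdir / "fst.tsv", sep="\t", index=False)
    result.fst = fst
    iu = np.triu_indices(f.n_populations, 1)
    report["mean_pairwise_fst"] = float(fst.values[iu].mean())
    logger.info("stage fst: mean pairwise Hudson F_ST = %.4f",
                report["mean_pairwise_fst"])

    # ---- stage: structure and climate PCA --------------------------------
    axes = structure.genotype_pca(g, config.structure_axes)
    pd.DataFrame(
        axes.population_scores,
        index=axes.populations,
        columns=[f"Ps{i + 1}" for i in range(config.structure_axes)],
    ).to_csv(outdir / "structure_axes.tsv", sep="\t")
    cpca = structure.climate_pca(climate, config.climate_pcs)
    report["structure_explained"] = [float(e) for e in axes.explained]
    report["climate_pc_explained"] = [float(e) for e in cpca.explained]

    # ---- stage: IBD / IBE ------------------------------------------------
    dists = structure.distance_matrices(climate, fst)
    _write_matrix_tsv(dists["geographic"].values, climate.populations,
                      outdir / "distance_geographic_log.tsv")
    _write_matrix_tsv(dists["genetic"].values, climate.populations,
                      outdir / "distance_genetic.tsv")
    rows = []
    ibd = structure.mantel_test(dists["genetic"], dists["geographic"],
                                config.n_perm, seed=config.seed)
    rows.append(("IBD_log_geographic", ibd.r, ibd.p, ibd.n_perm))
    ibe_ps = []
    ibe_names = []
    env_tests: list[tuple[str, structure.DistanceMatrix]] = [
        (v, structure.environmental_distance(climate, v))
        for v in climate.valid_variables()
    ]
    for i in range(cpca.site_scores.shape[1]):
        z = cpca.site_scores[:, i]
        m = structure.DistanceMatrix(np.abs(z[:, None] - z[None, :]),
                                     list(climate.populations), "environmental")
        env_tests.append((f"climatePC{i + 1}", m))
    for name, mat in env_tests:
        r = structure.partial_mantel_test(dists["genetic"], mat,
                                          dists["geographic"], config.n_perm,
                                          seed=config.seed)
        ibe_ps.append(r.p)
        ibe_names.append(name)
        rows.append((f"IBE_{name}", r.r, r.p, r.n_perm))
    _, q_adj = structure.bh_fdr(ibe_ps, config.fdr_q)
    mantel_df = pd.DataFrame(rows, columns=["test", "r", "p", "n_perm"])
    qcol = {f"IBE_{n}": qv for n, qv in zip(ibe_names, q_adj)}
    mantel_df["q"] = [qcol.get(t, np.nan) for t in mantel_df["test"]]
    mantel_df.to_csv(outdir / "mantel.tsv", sep="\t", index=False)
    result.mantel = mantel_df
    report["ibd_mantel_r"] = float(ibd.r)
    report["ibd_mantel_p"] = float(ibd.p)

    # ---- stage: GEA scans ------------------------------------------------
    pop_index = {p: k for k, p in enumerate(climate.populations)}
    ind_pop = np.array([pop_index[g.population_of[i]] for i in g.individual_ids])
    k_latent = min(config.k_latent, g.n_individuals - 3)
    lf_flags = np.zeros(g.n_loci, bool)
    lf_stat = np.zeros(g.n_loci)
    lams = []
    for i in range(cpca.site_scores.shape[1]):
        env_ind = cpca.site_scores[ind_pop, i]
        res = scan.latent_factor_scan(g, env_ind, k_latent, config.fdr_q,
                                      env_name=f"climatePC{i + 1}",
                                      factor_mode=config.lf_factor_mode)
        res.to_frame().to_csv(outdir / f"scan_latent_factor_PC{i + 1}.tsv",
                              sep="\t", index=False)
        lf_flags |= res.outlier
        lf_stat = np.where(np.abs(res.statistic) > np.abs(lf_stat),
                           res.statistic, lf_stat)
        lams.append(res.inflation_lambda)
        result.scans[f"latent_factor_PC{i + 1}"] = res
    lf_set = scan.OutlierSet("latent_factor",
                             [g.locus_ids()[j] for j in np.flatnonzero(lf_flags)],
                             f"BH q={config.fdr_q} on any climate PC")
    report["lambda_latent_factor"] = [float(l) for l in lams]

    omega = scan.estimate_pop_covariance(f)
    if config.cov_refine_omega:
        # one-step refinement: re-estimate the neutral covariance excluding
        # the first-pass upper tail, the standard practice for this design
        first = np.zeros(f.n_loci)
        for i in range(cpca.site_scores.shape[1]):
            r0 = scan.covariance_scan(f, cpca.site_scores[:, i], omega)
            first = np.maximum(first, np.abs(r0.statistic))
        omega = scan.estimate_pop_covariance(
            f, neutral_loci=first <= np.quantile(first, 0.95))
    cov_flags = np.zeros(f.n_loci, bool)
    for i in range(cpca.site_scores.shape[1]):
        res = scan.covariance_scan(f, cpca.site_scores[:, i], omega,
                                   config.fdr_q, env_name=f"climatePC{i + 1}",
                                   outlier_rule=config.cov_outlier_rule,
                                   top_quantile=config.cov_top_quantile)
        res.to_frame().to_csv(outdir / f"scan_covariance_gls_PC{i + 1}.tsv",
                              sep="\t", index=False)
        cov_flags |= res.outlier
        result.scans[f"covariance_gls_PC{i + 1}"] = res
    cov_set = scan.OutlierSet("covariance_gls",
                              [f.locus_ids[j] for j in np.flatnonzero(cov_flags)],
                              f"BH q={config.fdr_q} on any climate PC")

    climate_std = climate.standardized()
    rda_fit = scan.fit_rda(f.imputed(), climate_std, axes.population_scores,
                           locus_ids=list(f.locus_ids))
    rda_axes = min(config.rda_axes, rda_fit.locus_scores.shape[1])
    rda_set = scan.rda_outliers(rda_fit, rda_axes, config.rda_sd_mult)
    pd.DataFrame({
        "locus_id": f.locus_ids,
        **{f"axis{i + 1}": rda_fit.locus_scores[:, i] for i in range(rda_axes)},
        "outlier": [int(l in set(rda_set.locus_ids)) for l in f.locus_ids],
    }).to_csv(outdir / "scan_rda.tsv", sep="\t", index=False)

    result.outlier_sets = [lf_set, cov_set, rda_set]
    report["n_outliers"] = {s.method: len(s) for s in result.outlier_sets}

    # ---- stage: consensus ------------------------------------------------
    candidates = scan.consensus_candidates(result.outlier_sets, config.min_methods)
    result.candidates = candidates
    pd.DataFrame({
        "locus_id": candidates.locus_ids,
        "support": [candidates.support[l] for l in candidates.locus_ids],
        "methods": [",".join(candidates.methods_of[l])
                    for l in candidates.locus_ids],
    }).to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    candidates.overlap.to_csv(outdir / "method_overlap.tsv", sep="\t", index=False)
    report["n_candidates"] = len(candidates)
    logger.info("stage consensus: %d candidate loci (>=%d methods)",
                len(candidates), config.min_methods)

    # ---- stage: variance partitioning (neutral loci) ---------------------
    all_outliers = set().union(*(set(s.locus_ids) for s in result.outlier_sets))
    neutral_mask = np.array([l not in all_outliers for l in f.locus_ids])
    report["n_neutral"] = int(neutral_mask.sum())
    part = attr.partition_variance(f.subset_loci(neutral_mask), climate_std,
                                   axes.population_scores,
                                   n_perm=config.n_perm, seed=config.seed)
    part.to_frame().to_csv(outdir / "variance_partition.tsv", sep="\t",
                           index=False)
    result.partition = part

    # ---- stage: attribution + polygenic scores (candidate loci) ----------
    if len(candidates) == 0:
        logger.info("stage attribution: no consensus candidates; downstream "
                    "polygenic stage skipped")
        report["polygenic"] = "skipped (no candidates)"
    else:
        cand_mask = np.array([l in set(candidates.locus_ids) for l in f.locus_ids])
        f_cand = f.subset_loci(cand_mask)
        cond = axes.population_scores if config.attr_condition_structure else None
        marg = attr.marginal_climate_effects(
            f_cand, climate_std, climate.valid_variables(), cond,
            n_perm=config.n_perm, seed=config.seed)
        marg.to_csv(outdir / "marginal_effects.tsv", sep="\t", index=False)
        result.marginal = marg
        # attribution scores computed against the full locus background so
        # the per-variable normalization has a neutral reference
        la_full = attr.assign_strongest_variable(
            f, climate_std, climate.valid_variables(), cond)
        keep = [i for i, l in enumerate(la_full.locus_ids)
                if l in set(candidates.locus_ids)]
        la = attr.LocusAttribution(
            locus_ids=[la_full.locus_ids[i] for i in keep],
            assigned=[la_full.assigned[i] for i in keep],
            scores=la_full.scores[keep],
            variables=la_full.variables,
            reliable=la_full.reliable,
            n_ties=la_full.n_ties,
        )
        la.to_frame().to_csv(outdir / "locus_attribution.tsv", sep="\t",
                             index=False)
        result.attribution = la
        poly = attr.polygenic_scores(g, candidates, la, f, climate)
        poly.to_frame().to_csv(outdir / "polygenic_scores.tsv", sep="\t",
                               index=False)
        pd.DataFrame([
            {"variable": v, "n_loci": len(poly.loci_used[v]),
             "aic_linear": m.aic_linear, "aic_quadratic": m.aic_quadratic,
             "selected": m.selected, "adj_r2": m.adj_r2}
            for v, m in poly.models.items()
        ]).to_csv(outdir / "score_models.tsv", sep="\t", index=False)
        result.polygenic = poly
        report["polygenic_adj_r2"] = {v: float(m.adj_r2)
                                      for v, m in poly.models.items()}

    # ---- stage: report ---------------------------------------------------
    if truth is not None and len(candidates) > 0:
        true_ids = set(truth.selected_locus_ids)
        called = set(candidates.locus_ids)
        tp = len(true_ids & called)
        report["recovery"] = {
            "sensitivity": tp / len(true_ids) if true_ids else np.nan,
            "fdr": (len(called) - tp) / len(called) if called else 0.0,
        }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    result.report = report
    logger.info("pipeline complete: artifacts in %s", outdir)
    return result
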