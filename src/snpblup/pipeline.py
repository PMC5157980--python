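"""End-to-end orchestration of the genomic-prediction workflow.

``run_all`` reproduces the full analysis design on a synthetic cohort:
simulate -> genotype/sample QC -> PCA ancestry filtering -> relatedness
split -> REML + SNP-BLUP on the unrelated training core -> polygenic
scoring of the held-out, related, ancestry-outlier and diverged-ancestry
groups (within- and across-population accuracy tables) -> effect-size
two-component, MAF-stratified and multivariate refits -> clump+threshold
GWAS comparison profile -> subsampling series with 1/r^2 extrapolation to
a target cohort size.

Every stage writes its artifacts plus a JSON provenance block (input
hashes, seed, package version); the same config and seed reproduce every
numeric output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .extrapolate import fit_inverse_r2, fraction_of_maximum, project_accuracy
from .gwas_ct import clump, gwas_scan, threshold_profile
from .io_formats import write_effects, write_phenotypes, write_plink
from .kinship import compute_grm, ld_prune, pca_from_grm, standardize
from .mlm import (effect_outlier_groups, maf_groups, reml_fit,
                  reml_fit_multivariate, snp_blup, snp_blup_multivariate)
from .qc import (ancestry_filter, phenotype_outlier_filter, relatedness_split,
                 sample_qc, variant_qc)
from .scoring import accuracy, adjust_phenotype, polygenic_score
from .simdata import generate_cohort


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def run_all(config: PipelineConfig, outdir, *, write_genotypes: bool = True,
            log=print) -> dict:
    """Run the whole workflow; returns (and writes) the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    provenance = {"version": __version__, "seed": config.seed,
                  "sim_seed": config.sim.seed, "stages": {}}

    def stage(name):
        log(f"[{time.time() - t0:7.1f}s] {name}")
        provenance["stages"][name] = {"t": round(time.time() - t0, 2)}

    rng = np.random.default_rng(config.seed)
    traits = config.sim.trait_names
    covars = ["sex", "age"]

    # ------------------------------------------------------------- simulate
    stage("simulate")
    gm, pheno, truth = generate_cohort(config.sim)
    config.to_yaml(outdir / "config.yaml")
    if write_genotypes:
        write_plink(gm, outdir / "cohort")
        write_phenotypes(pheno, outdir / "phenotypes.tsv")
        provenance["stages"]["simulate"]["sha256"] = {
            f"cohort{ext}": _sha256(outdir / f"cohort{ext}")
            for ext in (".bed", ".bim", ".fam")}
    _json_dump({"realized_h2": truth.realized_h2,
                "n_samples": gm.n_samples, "n_variants": gm.n_variants},
               outdir / "truth_summary.json")

    # ------------------------------------------------------- genotype QC (1)
    stage("variant_qc_pass1")
    gm, vrep1 = variant_qc(gm, max_missing=config.variant_max_missing,
                           platform_log10p=config.platform_log10p,
                           min_maf=0.0, hwe_log10p=-np.inf)

    stage("sample_qc")
    keep, srep = sample_qc(gm, max_missing=config.sample_max_missing,
                           het_sd=config.het_sd,
                           sex_check=config.sim.x_variants > 0,
                           x_chrom=config.sim.x_chrom)
    gm = gm.subset(samples=keep)
    srep.to_json(outdir / "qc_samples.json")

    # ------------------------------------------------- PCA ancestry filtering
    stage("pca_ancestry")
    autosomal = (gm.variants["chrom"].astype(str) != str(config.sim.x_chrom)
                 ).to_numpy()
    pruned_mask = np.zeros(gm.n_variants, dtype=bool)
    pruned_mask[autosomal] = ld_prune(gm.subset(variants=autosomal),
                                      window=config.prune_window,
                                      step=config.prune_step,
                                      r2_max=config.prune_r2)
    z_pruned, _ = standardize(gm.subset(variants=pruned_mask),
                              dtype=np.float32)
    kin_pca = compute_grm(z_pruned.astype(np.float64),
                          ids=gm.samples["iid"])
    pcs = pca_from_grm(kin_pca, k=config.n_pcs)
    pd.DataFrame(pcs.projections,
                 index=pcs.ids).to_csv(outdir / "pca_projections.tsv",
                                       sep="\t", header=False)

    pops = gm.samples["population"]
    keep_anc, anc_summary = ancestry_filter(
        pcs.projections, pops, k=config.n_pcs, z=config.pca_z,
        min_group_size=config.min_group_size)
    anc_summary.to_csv(outdir / "ancestry_summary.tsv", sep="\t", index=False)
    ref_pop = config.sim.reference_population
    is_ref = (pops == ref_pop).to_numpy()
    pca_outlier_ids = gm.samples.loc[is_ref & ~keep_anc, "iid"].to_numpy()

    # ---------------------------------------------------- relatedness split
    # relatedness needs the full marker set: pruned-GRM noise (SD ~ 1/sqrt(M))
    # would push unrelated pairs over the 0.0625 cut at desk scale
    stage("relatedness_split")
    z_auto, _ = standardize(gm.subset(variants=autosomal), dtype=np.float32)
    kin_rel = compute_grm(z_auto.astype(np.float32),
                          ids=gm.samples["iid"])
    del z_auto
    ref_ids = gm.samples.loc[is_ref & keep_anc, "iid"].to_numpy()
    kin_ref = kin_rel.submatrix(ref_ids)
    unrelated, related = relatedness_split(
        kin_ref, threshold=config.relatedness_threshold)
    n_hold = max(4, int(round(config.holdout_fraction * len(unrelated))))
    holdout = np.sort(rng.choice(unrelated, size=n_hold, replace=False))
    training = np.setdiff1d(unrelated, holdout)
    groups = {"holdout": holdout, "related": np.sort(related),
              "pca_outlier": np.sort(pca_outlier_ids)}
    for pop in config.sim.n_samples:
        if pop == ref_pop:
            continue
        ids = gm.samples.loc[(pops == pop).to_numpy() & keep_anc,
                             "iid"].to_numpy()
        if len(ids) >= 4:
            groups[pop] = np.sort(ids)
    _json_dump({"training": training.tolist(),
                **{k: v.tolist() for k, v in groups.items()}},
               outdir / "groups.json")

    # -------------------------------------------------- genotype QC (2: MAF/HWE)
    stage("variant_qc_pass2")
    gm_common, vrep2 = variant_qc(
        gm, max_missing=config.variant_max_missing,
        platform_log10p=config.platform_log10p, min_maf=config.min_maf,
        hwe_log10p=config.hwe_log10p, training_samples=training)
    vrep1.stages.extend(vrep2.stages)
    vrep1.to_json(outdir / "qc_variants.json")
    # keep autosomes only for modelling
    gm_common = gm_common.subset(
        variants=(gm_common.variants["chrom"].astype(str)
                  != str(config.sim.x_chrom)).to_numpy())

    # ------------------------------------------------------ phenotype QC
    stage("phenotype_qc")
    for trait in traits:
        pheno = phenotype_outlier_filter(pheno, trait, z=config.phenotype_z)

    # -------------------------------------------------------- main model fit
    stage("fit_main")
    gm_train = gm_common.select_samples(training)
    z_train, stats = standardize(gm_train, dtype=np.float32)
    kin_train = compute_grm(z_train.astype(np.float64),
                            ids=gm_train.samples["iid"])
    data_train = pheno.data.loc[gm_train.samples["iid"]]
    X_train = data_train[covars].to_numpy()

    vc_report, effects_by_model, rows = {}, {}, []
    est_main = {}
    for trait in traits:
        y = data_train[trait].to_numpy()
        est = reml_fit(y, X_train, kin_train)
        est_main[trait] = est
        eff = snp_blup(z_train.astype(np.float64), X_train, y, est,
                       stats=stats, kinships=kin_train.values,
                       description=f"single-component blup, {trait}")
        effects_by_model[("main", trait)] = eff
        write_effects(eff, outdir / f"effects_main_{trait}.tsv")
        vc_report[trait] = {
            "model": "single_component", "sigma2_g": est.sigma2_g,
            "sigma2_e": est.sigma2_e, "h2": est.h2, "se_h2": est.se_h2,
            "loglik": est.loglik, "converged": est.converged,
        }
    _json_dump(vc_report, outdir / "variance_components_main.json")

    # ------------------------------------------------------------- scoring
    stage("score_groups")

    def score_groups(model: str, trait: str, eff) -> None:
        for gname, ids in groups.items():
            if len(ids) < 4:
                continue
            gm_g = gm_common.select_samples(ids)
            scores = polygenic_score(gm_g, eff)
            data_g = pheno.data.loc[gm_g.samples["iid"]]
            mask = data_g[trait].notna().to_numpy()
            if mask.sum() < 4:
                continue
            adj = adjust_phenotype(data_g.loc[mask, trait],
                                   data_g.loc[mask, covars])
            res = accuracy(scores.to_numpy()[mask], adj, trait=trait,
                           group=gname)
            rows.append({"model": model, **res.as_row()})

    for trait in traits:
        score_groups("main", trait, effects_by_model[("main", trait)])

    # ------------------------------------- two-component (effect-size) refit
    gwas_by_trait = {}
    if config.run_two_component:
        stage("fit_two_component")
        for trait in traits:
            y = data_train[trait].to_numpy()
            ok = np.isfinite(y)
            summary = gwas_scan(y[ok], X_train[ok], gm_train.subset(samples=ok))
            gwas_by_trait[trait] = summary
            labels = effect_outlier_groups(summary.beta)
            tail = labels == "tail"
            if tail.sum() == 0 or (~tail).sum() == 0:
                continue
            Zt = z_train[:, tail].astype(np.float64)
            Kt = (Zt @ Zt.T) / tail.sum()
            m_all = z_train.shape[1]
            Km = (m_all * kin_train.values - Zt @ Zt.T) / (~tail).sum()
            est2 = reml_fit(y, X_train, {"main": Km, "tail": Kt})
            stats_tab = stats.table
            from .kinship import StandardizationStats
            eff2 = snp_blup(
                {"main": z_train[:, ~tail].astype(np.float64), "tail": Zt},
                X_train, y, est2,
                stats={"main": StandardizationStats(
                           stats_tab.loc[~tail].reset_index(drop=True)),
                       "tail": StandardizationStats(
                           stats_tab.loc[tail].reset_index(drop=True))},
                kinships={"main": Km, "tail": Kt},
                description=f"two-component blup, {trait}")
            write_effects(eff2, outdir / f"effects_two_component_{trait}.tsv")
            vc_report[trait + "_two_component"] = {
                "model": "two_component", "sigma2_g": est2.sigma2_g,
                "sigma2_e": est2.sigma2_e, "h2": est2.h2,
                "n_tail": int(tail.sum()), "converged": est2.converged,
            }
            score_groups("two_component", trait, eff2)

    # --------------------------------------------------- MAF-stratified refit
    if config.run_maf_stratified:
        stage("fit_maf_stratified")
        gm_rare, _ = variant_qc(
            gm, max_missing=config.variant_max_missing,
            platform_log10p=config.platform_log10p,
            min_maf=config.rare_min_maf, hwe_log10p=config.hwe_log10p,
            training_samples=training)
        gm_rare = gm_rare.subset(
            variants=(gm_rare.variants["chrom"].astype(str)
                      != str(config.sim.x_chrom)).to_numpy())
        gm_rare_train = gm_rare.select_samples(training)
        labels = maf_groups(gm_rare_train.maf())
        assigned = labels != "unassigned"
        gm_rare_train = gm_rare_train.subset(variants=assigned)
        labels = labels[assigned]
        zr, stats_r = standardize(gm_rare_train, dtype=np.float32)
        comp_z, comp_k, comp_stats = {}, {}, {}
        from .kinship import StandardizationStats
        common_ids = stats_r.table.loc[labels == "common", "id"]
        reuse_common = common_ids.tolist() == stats.table["id"].tolist()
        for name in ("common", "low_freq", "rare"):
            sel = labels == name
            if sel.sum() < 2:
                continue
            Zc = zr[:, sel].astype(np.float64)
            comp_z[name] = Zc
            if name == "common" and reuse_common:
                comp_k[name] = kin_train.values  # identical variant set
            else:
                comp_k[name] = (Zc @ Zc.T) / sel.sum()
            comp_stats[name] = StandardizationStats(
                stats_r.table.loc[sel].reset_index(drop=True))
        for trait in traits:
            y = data_train[trait].to_numpy()
            est3 = reml_fit(y, X_train, comp_k)
            eff3 = snp_blup(comp_z, X_train, y, est3, stats=comp_stats,
                            kinships=comp_k,
                            description=f"maf-stratified blup, {trait}")
            write_effects(eff3, outdir / f"effects_maf_{trait}.tsv")
            vc_report[trait + "_maf"] = {
                "model": "maf_stratified", "sigma2_g": est3.sigma2_g,
                "sigma2_e": est3.sigma2_e, "h2": est3.h2,
                "m_per_group": {k: int(z.shape[1]) for k, z in comp_z.items()},
                "converged": est3.converged,
            }
            # score with the rare-inclusive variant set
            for gname, ids in groups.items():
                if len(ids) < 4:
                    continue
                gm_g = gm_rare.select_samples(ids)
                scores = polygenic_score(gm_g, eff3)
                data_g = pheno.data.loc[gm_g.samples["iid"]]
                mask = data_g[trait].notna().to_numpy()
                if mask.sum() < 4:
                    continue
                adj = adjust_phenotype(data_g.loc[mask, trait],
                                       data_g.loc[mask, covars])
                res = accuracy(scores.to_numpy()[mask], adj, trait=trait,
                               group=gname)
                rows.append({"model": "maf_stratified", **res.as_row()})

    # ------------------------------------------------------ multivariate refit
    if config.run_multivariate and len(traits) >= 2:
        stage("fit_multivariate")
        pair = traits[:2]
        Y = data_train[pair].to_numpy()
        mest = reml_fit_multivariate(Y, X_train, kin_train, traits=pair)
        effs = snp_blup_multivariate(z_train.astype(np.float64), X_train, Y,
                                     mest, stats=stats)
        vc_report["multivariate"] = {
            "model": "bivariate", "traits": pair,
            "sigma_g": mest.sigma_g.tolist(),
            "sigma_e": mest.sigma_e.tolist(),
            "genetic_correlation": float(mest.genetic_correlation[0, 1]),
            "se_genetic_correlation": float(mest.se_genetic_correlation[0, 1]),
            "h2": mest.h2.tolist(), "converged": mest.converged,
        }
        for trait in pair:
            write_effects(effs[trait],
                          outdir / f"effects_multivariate_{trait}.tsv")
            score_groups("multivariate", trait, effs[trait])

    _json_dump(vc_report, outdir / "variance_components.json")
    pred = pd.DataFrame(rows)
    pred.to_csv(outdir / "predictions.tsv", sep="\t", index=False)
    within = pred[pred["group"].isin(["holdout", "related", "pca_outlier"])]
    across = pred[~pred["group"].isin(["holdout", "related", "pca_outlier"])]
    within.to_csv(outdir / "table1_analogue.tsv", sep="\t", index=False)
    across.to_csv(outdir / "table2_analogue.tsv", sep="\t", index=False)

    # --------------------------------------------------------- C+T profile
    stage("ct_profile")
    gm_hold = gm_common.select_samples(holdout)
    profiles = {}
    for trait in traits:
        summary = gwas_by_trait.get(trait)
        if summary is None:
            y = data_train[trait].to_numpy()
            ok = np.isfinite(y)
            summary = gwas_scan(y[ok], X_train[ok], gm_train.subset(samples=ok))
        summary.table.drop(columns=["flagged"]).to_csv(
            outdir / f"gwas_{trait}.tsv", sep="\t", index=False)
        clumps = clump(summary, gm_train, r2=config.clump_r2,
                       window_bp=config.clump_window_bp)
        prof = threshold_profile(clumps, summary, gm_hold, pheno, trait,
                                 covariates=covars,
                                 thresholds=config.thresholds)
        prof.to_csv(outdir / f"ct_profile_{trait}.tsv", sep="\t", index=False)
        profiles[trait] = prof

    # ----------------------------------------------- subsample + extrapolate
    stage("extrapolate")
    trait = traits[0]
    data_hold = pheno.data.loc[gm_hold.samples["iid"]]
    mask_h = data_hold[trait].notna().to_numpy()
    adj_hold = adjust_phenotype(data_hold.loc[mask_h, trait],
                                data_hold.loc[mask_h, covars])
    sizes = sorted({int(round(f * len(training)))
                    for f in config.subsample_fractions})
    sub_rows = []
    iid_train = gm_train.samples["iid"].to_numpy()
    y_full = data_train[trait].to_numpy()
    for size in sizes:
        for rep in range(config.subsample_seeds):
            sub_rng = np.random.default_rng(
                [config.seed % (2 ** 31), size, rep])
            pick = np.sort(sub_rng.choice(len(iid_train), size=size,
                                          replace=False))
            K_sub = kin_train.values[np.ix_(pick, pick)]
            est = reml_fit(y_full[pick], X_train[pick], K_sub)
            eff = snp_blup(z_train[pick].astype(np.float64), X_train[pick],
                           y_full[pick], est, stats=stats, kinships=K_sub)
            scores = polygenic_score(gm_hold, eff)
            res = accuracy(scores.to_numpy()[mask_h], adj_hold, trait=trait)
            sub_rows.append({"n": size, "seed": rep, "r": res.r})
            if size == sizes[-1]:
                break  # full-size fit is deterministic; one rep suffices
    sub = pd.DataFrame(sub_rows)
    sub.to_csv(outdir / f"subsample_{trait}.tsv", sep="\t", index=False)

    extrap = {"trait": trait, "points": sub.to_dict("records")}
    try:
        fit = fit_inverse_r2(sub[["n", "r"]])
        fit.points.to_csv(outdir / f"inverse_r2_points_{trait}.tsv",
                          sep="\t", index=False)
        extrap.update({
            "intercept": fit.intercept, "slope": fit.slope,
            "se_intercept": fit.se_intercept, "se_slope": fit.se_slope,
            "max_accuracy": fit.max_accuracy,
            "se_max_accuracy": fit.se_max_accuracy,
        })
        if fit.valid:
            r_proj, se_proj = project_accuracy(fit, config.n_target)
            h2_hat = est_main[trait].h2
            pct = fraction_of_maximum(min(r_proj, 1.0), h2_hat, ci_slack=1.0)
            extrap.update({
                "n_target": config.n_target, "projected_r": r_proj,
                "se_projected_r": se_proj, "h2_hat": h2_hat,
                "percent_of_maximum": int(round(pct)),
            })
    except ValueError as exc:
        extrap["flagged"] = str(exc)
    _json_dump(extrap, outdir / f"extrapolation_{trait}.json")

    # ------------------------------------------------------------- summary
    stage("summary")
    summary = {
        "n_samples_simulated": int(sum(config.sim.n_samples.values())
                                   + 2 * config.sim.n_sib_pairs),
        "n_variants_common": int(gm_common.n_variants),
        "n_training": int(len(training)),
        "groups": {k: int(len(v)) for k, v in groups.items()},
        "h2_estimates": {t: est_main[t].h2 for t in traits},
        "realized_h2": truth.realized_h2,
        "extrapolation": {k: v for k, v in extrap.items() if k != "points"},
    }
    _json_dump(summary, outdir / "summary.json")
    provenance["runtime_s"] = round(time.time() - t0, 1)
    _json_dump(provenance, outdir / "provenance.json")
    log(f"[{time.time() - t0:7.1f}s] done")
    return summary
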