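"""End-to-end orchestration: simulate -> prep -> OPNMF -> overlap -> statistics.

``run_pipeline`` executes the stages in order under one :class:`RunConfig`,
writes all artifacts under the output directory, and returns (and serializes)
a machine-readable JSON report containing every statistic, the selected
granularity and the Dice-kappa table.  All randomness is seeded from the
config, so identical config implies an identical report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from . import nifti_io as io
from . import overlap as ov
from . import synthetic as syn
from .config import RunConfig
from .opnmf import opnmf, select_k, stability_analysis
from .prep import assemble_matrix, gaussian_blur, stack_images
from .voxelstats import fit_voxelwise_lme, subject_weight_glm

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "simulate_stage"]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

        return wrapper

    return deco


@_stage("simulate")
def simulate_stage(config: RunConfig, outdir: Path):
    spec = syn.CohortSpec(
        n_per_cell=config.n_per_cell,
        timepoints_dpi=config.timepoints_dpi,
        grid_shape=config.grid_shape,
        voxel_size_mm=config.voxel_size_mm,
        seed=config.seed,
    )
    truth = syn.default_truth(spec, k0=config.k0)
    mask = syn.brain_mask(spec)
    cohort = syn.generate_cohort(spec, truth)
    behavior = syn.generate_behavior(cohort, truth, spec)
    rel = syn.generate_jacobians(cohort, truth, spec, flavor="relative")
    abso = syn.generate_jacobians(cohort, truth, spec, flavor="absolute")
    cohort.to_csv(outdir / "cohort.csv", index=False)
    behavior.to_csv(outdir / "behavior.csv", index=False)
    if config.write_images:
        img_dir = outdir / "images"
        affine = rel[0].affine
        io.write_nifti((mask.astype(float), affine), img_dir / "mask.nii.gz")
        for img in rel:
            io.write_nifti(img, img_dir / "relative" / io.scan_filename(img.subject_id, img.dpi))
        for img in abso:
            io.write_nifti(img, img_dir / "absolute" / io.scan_filename(img.subject_id, img.dpi))
    return mask, cohort, behavior, rel, abso


@_stage("load")
def _load_stage(config: RunConfig):
    if not config.mask_path or not config.cohort_csv:
        raise FileNotFoundError(
            f"simulate=false requires mask_path and cohort_csv (got "
            f"mask_path={config.mask_path!r})"
        )
    cohort = pd.read_csv(config.cohort_csv)
    behavior = pd.read_csv(config.behavior_csv) if config.behavior_csv else None
    img_dir = Path(config.image_dir)
    rel, abso = [], []
    for flavor, store in (("relative", rel), ("absolute", abso)):
        for _, row in cohort.iterrows():
            for tp in config.timepoints_dpi:
                p = img_dir / flavor / io.scan_filename(row["subject_id"], tp)
                if p.exists():
                    store.append(
                        io.read_nifti(p, flavor=flavor, subject_id=row["subject_id"], dpi=float(tp))
                    )
    mask = io.read_mask(config.mask_path, reference_affine=rel[0].affine if rel else None)
    return mask, cohort, behavior, rel, abso


def _select_component(H: np.ndarray, meta: pd.DataFrame) -> tuple[int, dict]:
    """Component whose subject-weight GLM injection-group effect is strongest."""
    best, best_p, glms = 0, np.inf, {}
    for c in range(H.shape[0]):
        res = subject_weight_glm(H, c, meta)
        p = float(res.pvalues.get("group[PFF]", np.nan))
        glms[c] = res
        if np.isfinite(p) and p < best_p:
            best, best_p = c, p
    return best, glms


@_stage("opnmf")
def _opnmf_stage(config: RunConfig, abso, mask, outdir: Path, report: dict):
    at_tp = [im for im in abso if im.dpi == config.analysis_dpi]
    runs = {}
    sub_meta = {}
    for name, images in (
        ("all", at_tp),
        ("male", [im for im in at_tp if im.subject_id in report["_male_ids"]]),
        ("female", [im for im in at_tp if im.subject_id in report["_female_ids"]]),
    ):
        dm = assemble_matrix(images, mask, invert=True, zscore=True)
        runs[name] = dm
        sub_meta[name] = dm.column_meta

    dm_all = runs["all"]
    strata = report["_strata"].loc[dm_all.column_meta["subject_id"]].to_numpy()
    profile = stability_analysis(
        dm_all,
        k_list=config.k_list,
        n_splits=config.n_splits,
        seed=config.seed,
        strata=strata,
        max_iter=config.opnmf_max_iter,
        tol=config.opnmf_tol,
    )
    k = select_k(profile)
    report["selected_k"] = int(k)
    report["stability"] = {
        "k": list(profile.k_list),
        "stability": [round(float(v), 6) for v in profile.stability],
        "error": [round(float(v), 6) for v in profile.errors],
        "error_gradient": [None if np.isnan(v) else round(float(v), 6) for v in profile.error_gradient],
    }
    pd.DataFrame(
        {
            "k": profile.k_list,
            "stability": profile.stability,
            "error": profile.errors,
            "error_gradient": profile.error_gradient,
        }
    ).to_csv(outdir / "stability_profile.csv", index=False)

    results, selected, weight_glms = {}, {}, {}
    for name, dm in runs.items():
        res = opnmf(dm, k, max_iter=config.opnmf_max_iter, tol=config.opnmf_tol)
        meta = dm.column_meta.merge(report["_covars"], on="subject_id", how="left")
        comp, glms = _select_component(res.H, meta)
        results[name] = res
        selected[name] = comp
        weight_glms[name] = glms[comp]
        pd.DataFrame(res.H.T, columns=[f"comp{c}" for c in range(k)]).assign(
            subject_id=dm.column_meta["subject_id"].to_numpy()
        ).to_csv(outdir / f"weights_{name}.csv", index=False)
        if config.write_images:
            labels = ov.label_map(res.W).labels
            io.write_map(
                labels.astype(float),
                dm.voxel_index,
                dm.grid_shape,
                dm.affine,
                outdir / f"components_{name}_labels.nii.gz",
                fill=-1,
            )
        report.setdefault("weight_glm", {})[name] = {
            "selected_component": int(comp),
            "p": {t: round(float(p), 6) for t, p in weight_glms[name].pvalues.items()},
            "cohens_d": {t: round(float(d), 4) for t, d in weight_glms[name].cohens_d.items()},
            "d_variant": weight_glms[name].d_variant,
            "n": weight_glms[name].n_obs,
        }

    # the sex-specific matrices share the voxel space only if no rows were
    # dropped differently; re-binarize on the intersection of kept voxels
    common = np.intersect1d(
        np.intersect1d(runs["all"].voxel_index, runs["male"].voxel_index),
        runs["female"].voxel_index,
    )
    Ws = {}
    for name in ("all", "male", "female"):
        keep = np.isin(runs[name].voxel_index, common)
        Ws[name] = results[name].W[keep]
    kappa = ov.sex_overlap_report(Ws["all"], Ws["male"], Ws["female"], selected)
    kappa.to_csv(outdir / "dice_kappa.csv", index=False)
    report["dice_kappa"] = {
        f"{r.pattern_a}-{r.pattern_b}": round(float(r.kappa), 4) for r in kappa.itertuples()
    }
    return results, selected


@_stage("voxelstats")
def _voxelstats_stage(config: RunConfig, rel, mask, outdir: Path, report: dict):
    matrix, voxel_index, meta = stack_images(rel, mask)
    meta = meta.merge(report["_covars"], on="subject_id", how="left")
    maps = fit_voxelwise_lme(matrix, meta, q_level=config.q_level)
    summary = {}
    for term, vmap in maps.items():
        summary[term] = {
            "n_significant": int(np.nansum(vmap.significant)),
            "n_voxels": int(vmap.p.size),
            "n_failed": int(vmap.n_failed),
            "q_level": config.q_level,
        }
        if config.write_images:
            safe = term.replace("[", "").replace("]", "").replace(":", "_")
            io.write_map(vmap.t, voxel_index, config.grid_shape,
                         rel[0].affine, outdir / f"tmap_{safe}.nii.gz")
    report["voxelwise"] = {"formula": next(iter(maps.values())).formula, "terms": summary}
    return maps


@_stage("behavior")
def _behavior_stage(config: RunConfig, cohort, behavior, outdir: Path, report: dict):
    surv = bh.fit_survival(cohort)
    surv.km_curves.to_csv(outdir / "km_curves.csv", index=False)
    report["survival"] = {
        "coef": {t: round(float(v), 4) for t, v in surv.coefs.items()},
        "hazard_ratio": {t: round(float(v), 4) for t, v in surv.hazard_ratios.items()},
        "p": {t: round(float(v), 6) for t, v in surv.pvalues.items()},
        "n_events": surv.n_events,
        "event_direction": surv.event_direction,
    }
    onset = bh.motor_onset_glm(cohort)
    report["motor_onset"] = {
        "coef": {t: round(float(v), 4) for t, v in onset.params.items()},
        "p": {t: round(float(v), 6) for t, v in onset.pvalues.items()},
        "n": onset.n_obs,
        "notes": onset.notes,
    }
    for measure, quad in (("weight", True), ("rotarod", False)):
        res = bh.fit_longitudinal_lme(measure, cohort, behavior, quadratic_time=quad)
        report[f"{measure}_lme"] = {
            "formula": res.formula,
            "coef": {t: round(float(v), 4) for t, v in res.params.items()},
            "p": {t: round(float(v), 6) for t, v in res.pvalues.items()},
            "n": res.n_obs,
        }
    cox_rows = []
    for task in ("wirehang", "pole"):
        records = bh.encode_task(behavior, task)
        for tp in config.timepoints_dpi:
            sub = records[records["dpi"] == tp]
            if sub.empty:
                continue
            try:
                fit = bh.fit_cox(
                    sub,
                    covariates=["group", "sex", "group:sex", "trial", "weight_g"],
                    event_direction=bh.EVENT_DIRECTION[task],
                )
                cox_rows.append(
                    {
                        "task": task,
                        "dpi": float(tp),
                        "coef_group": float(fit.coefs.get("group[PFF]", np.nan)),
                        "hr_group": float(fit.hazard_ratios.get("group[PFF]", np.nan)),
                        "p_group": float(fit.pvalues.get("group[PFF]", np.nan)),
                        "n_events": fit.n_events,
                        "n_records": fit.n_records,
                        "note": "",
                    }
                )
            except (ValueError, RuntimeError) as err:
                cox_rows.append(
                    {"task": task, "dpi": float(tp), "coef_group": np.nan,
                     "hr_group": np.nan, "p_group": np.nan, "n_events": 0,
                     "n_records": len(sub), "note": str(err)}
                )
    cox_df = pd.DataFrame(cox_rows)
    ok = cox_df["p_group"].notna()
    adj = bh.bonferroni(cox_df.loc[ok, "p_group"].to_numpy(), m=config.bonferroni_m)
    cox_df.loc[ok, "p_group_bonferroni"] = adj["p_adjusted"].to_numpy()
    cox_df.loc[ok, "significant"] = adj["significant"].to_numpy()
    cox_df.to_csv(outdir / "motor_cox.csv", index=False)
    report["motor_cox"] = json.loads(cox_df.round(6).to_json(orient="records"))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write ``report.json`` to the outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.save(outdir / "config.yaml")
    report: dict = {"config_hash": config.config_hash()}

    if config.simulate:
        mask, cohort, behavior, rel, abso = simulate_stage(config, outdir)
    else:
        mask, cohort, behavior, rel, abso = _load_stage(config)

    report["cohort"] = {
        "n_subjects": int(len(cohort)),
        "n_events": int(cohort["event_flag"].sum()),
        "n_relative_scans": len(rel),
        "n_absolute_scans": len(abso),
    }
    # stash covariate lookups for later stages (stripped before writing)
    report["_covars"] = cohort[["subject_id", "sex", "group"]]
    report["_male_ids"] = set(cohort.loc[cohort["sex"] == "M", "subject_id"])
    report["_female_ids"] = set(cohort.loc[cohort["sex"] == "F", "subject_id"])
    report["_strata"] = (cohort["group"] + "/" + cohort["sex"]).set_axis(cohort["subject_id"])

    rel = [gaussian_blur(im, config.fwhm_mm) for im in rel]
    abso = [gaussian_blur(im, config.fwhm_mm) for im in abso]

    if config.run_opnmf:
        _opnmf_stage(config, abso, mask, outdir, report)
    if config.run_voxelstats:
        _voxelstats_stage(config, rel, mask, outdir, report)
    if config.run_behavior and behavior is not None:
        _behavior_stage(config, cohort, behavior, outdir, report)

    report = {k: v for k, v in report.items() if not k.startswith("_")}
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
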