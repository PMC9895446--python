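"""Config-driven end-to-end orchestration of the analysis stages.

A single mapping (usually loaded from YAML) declares input paths, filter
settings, ladder specifications, evidence-map thresholds and the seed; the
three entry points — :func:`run_synth`, :func:`run_behavioral`,
:func:`run_neuro` — each write a self-contained report bundle into the
output directory, with the resolved config serialized alongside so every
file is reproducible from (config, seed).
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .evidence import (
    VoxelEvidenceModel,
    partial_correlation,
    residualize,
    roi_percent_signal_change,
)
from .exposure import (
    bilingual_subsample_filter,
    english_majority_filter,
    index_table,
    read_exposure_csv,
)
from .ladder import outlier_filter, run_h2_ladder, run_h3_ladder
from .lexdist import distance_matrix, read_wordlists, write_wordlists
from .synth import (
    CohortConfig,
    synth_cohort,
    synth_contrast_maps,
    synth_lexicons,
    synth_outcomes,
)
from .threshold import segmented_fit, smooth_vs_linear, two_stage_cluster

__all__ = ["run_synth", "run_behavioral", "run_neuro", "DEFAULT_CONFIG"]

log = logging.getLogger("langexp")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "langexp_run",
    "synth": {
        "n_children": 160,
        "language_pool_size": 37,
        "receptive": {"index": "exposure_english", "f2": 0.10},
        "expressive": {"index": "typological_diversity_qe", "f2": 0.063},
        "volumes": {"coupling_beta": 1.0, "noise_sd": 1.0},
    },
    "paths": {},
    "filters": {"outlier_sd": 3.0},
    "covariates": ["age_years", "gender", "ses_years", "nonverbal_score"],
    "neuro_covariates": [
        "age_years", "gender", "ses_years", "nonverbal_score",
        "handedness", "dprime", "headphone_model",
    ],
    "thresholds": {"lbf": 3.0, "lbf_fallback": 1.5, "min_cluster": 10},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(
            base.get(k), dict) else v
    return out


def _stage(name):
    log.info("stage %s", name)
    return time.time()


def run_synth(config: dict | None = None) -> dict:
    """Generate a full synthetic input bundle; returns the written paths."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(cfg["out_dir"]) / "inputs"
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    sc = cfg["synth"]
    t0 = _stage("synth lexicons")
    ccfg = CohortConfig(
        n_children=int(sc["n_children"]),
        language_pool_size=int(sc["language_pool_size"]),
        seed=seed,
    )
    wordlists, D, _ = synth_lexicons(ccfg)
    write_wordlists(wordlists, out / "wordlists.tsv")
    _stage("synth cohort")
    profiles = synth_cohort(ccfg)
    f2_rec = synth_outcomes(
        profiles, D, outcome="receptive_score", seed=seed,
        index=sc["receptive"]["index"], f2=float(sc["receptive"]["f2"]),
    )
    f2_exp = synth_outcomes(
        profiles, D, outcome="expressive_score", seed=seed + 1,
        index=sc["expressive"]["index"], f2=float(sc["expressive"]["f2"]),
    )
    _stage("synth volumes")
    dataset, roi = synth_contrast_maps(
        profiles, D, seed=seed,
        coupling_beta=float(sc["volumes"]["coupling_beta"]),
        noise_sd=float(sc["volumes"]["noise_sd"]),
    )
    rows = [
        {"child_id": p.child_id, "age_years": p.age_years,
         "language_id": lang, "exposure_years": years}
        for p in profiles for lang, years in sorted(p.exposure_years.items())
    ]
    pd.DataFrame(rows).to_csv(out / "exposure.csv", index=False)
    cov = pd.DataFrame(
        [
            {
                "child_id": p.child_id, "gender": p.gender,
                "ses_years": p.ses_years,
                "nonverbal_score": p.nonverbal_score,
                "english_from_birth": p.english_from_birth,
                "receptive_score": p.receptive_score,
                "expressive_score": p.expressive_score,
                "handedness": p.handedness, "dprime": p.dprime,
                "headphone_model": p.headphone_model,
            }
            for p in profiles
        ]
    )
    cov.to_csv(out / "covariates.csv", index=False)
    lio.write_group_dataset(dataset, out / "volumes")
    lio.save_volume(out / "volumes" / "roi.nii.gz", roi.astype(np.float32))
    manifest = {
        "seed": seed, "config": cfg,
        "realized_f2": {"receptive": f2_rec, "expressive": f2_exp},
        "n_children": len(profiles),
    }
    lio.write_json(manifest, out / "manifest.json")
    log.info("synth bundle complete in %.1fs", time.time() - t0)
    return {"inputs": str(out), "manifest": manifest}


def _load_behavioral(cfg: dict):
    paths = cfg["paths"]
    base = Path(cfg["out_dir"]) / "inputs"
    wl_path = paths.get("wordlists", base / "wordlists.tsv")
    exp_path = paths.get("exposure", base / "exposure.csv")
    cov_path = paths.get("covariates", base / "covariates.csv")
    for p in (wl_path, exp_path, cov_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file missing: {p}")
    D = distance_matrix(read_wordlists(wl_path))
    profiles = read_exposure_csv(exp_path, cov_path)
    return D, profiles


def run_behavioral(config: dict | None = None) -> dict:
    """Indices, threshold report, and both model ladders; writes tables."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(cfg["out_dir"]) / "behavioral"
    out.mkdir(parents=True, exist_ok=True)
    covariates = list(cfg["covariates"])
    t0 = _stage("load inputs")
    D, profiles = _load_behavioral(cfg)
    audit: dict = {"n_input": len(profiles)}
    profiles = [p for p in profiles if p.english_from_birth]
    audit["n_english_from_birth"] = len(profiles)

    _stage("indices")
    D.to_long_frame().to_csv(out / "distances.tsv", sep="\t", index=False)
    D.to_frame().to_csv(out / "distances_matrix.csv")
    table_all = index_table(profiles, D)
    table_all[
        ["exposure_english", "diversity_h", "typological_diversity_qe"]
    ].to_csv(out / "indices.csv")

    _stage("majority-English filter")
    kept, removed = english_majority_filter(profiles)
    audit["majority_english_removed"] = removed

    reports: dict = {}
    k_sd = float(cfg["filters"]["outlier_sd"])
    for outcome in ("receptive_score", "expressive_score"):
        tbl = index_table(kept, D).dropna(subset=[outcome])
        mask = outlier_filter(tbl[outcome].to_numpy(), k_sd=k_sd)
        audit[f"{outcome}_outliers_removed"] = int((~mask).sum())
        tbl = tbl.loc[mask]
        audit[f"{outcome}_n_analyzed"] = len(tbl)

        _stage(f"threshold discovery ({outcome})")
        adjusted = residualize(
            tbl[outcome].to_numpy(),
            np.column_stack(
                [
                    tbl["age_years"], tbl["ses_years"],
                    tbl["nonverbal_score"],
                    (tbl["gender"] == "f").astype(float),
                ]
            ),
        )
        x = tbl["exposure_english"].to_numpy()
        seg = segmented_fit(x, adjusted)
        smooth = smooth_vs_linear(x, adjusted)
        clus = two_stage_cluster(x, adjusted)
        reports[f"h1_{outcome}"] = {
            "breakpoint": seg.breakpoint,
            "bf_segmented_vs_linear": seg.bf_vs_linear,
            "bf_smooth_vs_linear": smooth.bf_smooth_vs_linear,
            "cluster_has_structure": clus.has_structure,
            "cluster_k": clus.k,
            "cluster_silhouette": clus.silhouette,
            "cluster_threshold": clus.threshold,
        }

        _stage(f"index ladder ({outcome})")
        res = run_h2_ladder(tbl, outcome, covariates=covariates)
        res.to_frame().to_csv(
            out / f"h2_ladder_{outcome}.tsv", sep="\t", index=False
        )
        reports[f"h2_{outcome}"] = {
            f"{c.model_a}_vs_{c.model_b}": c.bf10 for c in res.comparisons
        }

    _stage("bilingual filter + ladder")
    bil, removed = bilingual_subsample_filter(profiles, D)
    audit["bilingual_removed"] = removed
    audit["bilingual_n"] = len(bil)
    for outcome in ("receptive_score", "expressive_score"):
        tbl = index_table(bil, D).dropna(subset=[outcome, "l2_distance"])
        mask = outlier_filter(tbl[outcome].to_numpy(), k_sd=k_sd)
        tbl = tbl.loc[mask]
        res = run_h3_ladder(tbl, outcome, covariates=covariates)
        res.to_frame().to_csv(
            out / f"h3_ladder_{outcome}.tsv", sep="\t", index=False
        )
        reports[f"h3_{outcome}"] = {
            f"{c.model_a}_vs_{c.model_b}": c.bf10 for c in res.comparisons
        }

    reports["filter_audit"] = audit
    reports["config"] = cfg
    lio.write_json(reports, out / "report.json")
    log.info("behavioral pipeline complete in %.1fs", time.time() - t0)
    return reports


def run_neuro(config: dict | None = None) -> dict:
    """cvLME maps, pairwise LBF maps, voxel counts, clusters, ROI follow-up."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(cfg["out_dir"]) / "neuro"
    out.mkdir(parents=True, exist_ok=True)
    thr = float(cfg["thresholds"]["lbf"])
    thr_fb = float(cfg["thresholds"]["lbf_fallback"])
    min_cluster = int(cfg["thresholds"]["min_cluster"])
    t0 = _stage("load volumes")
    vol_dir = cfg["paths"].get(
        "volumes", Path(cfg["out_dir"]) / "inputs" / "volumes"
    )
    if not Path(vol_dir).exists():
        raise FileNotFoundError(f"volume bundle missing: {vol_dir}")
    dataset = lio.read_group_dataset(vol_dir)

    # majority-English rule applies to the fMRI sample too
    keep = dataset.design["exposure_english"].to_numpy(float) >= 0.5
    audit = {"n_input": len(dataset.subjects),
             "majority_english_removed": int((~keep).sum())}
    if keep.sum() < len(dataset.subjects):
        from .evidence import GroupDataset

        dataset = GroupDataset(
            subjects=[s for s, k in zip(dataset.subjects, keep) if k],
            grid=dataset.grid,
            contrast=dataset.contrast[keep],
            design=dataset.design.loc[keep].reset_index(drop=True),
            baseline=None if dataset.baseline is None
            else dataset.baseline[keep],
            affine=dataset.affine,
        )

    _stage("cvLME maps")
    model = VoxelEvidenceModel.index_ladder(
        dataset, covariates=list(cfg["neuro_covariates"])
    )
    results = model.fit()
    for name, emap in results.maps.items():
        lio.save_map(emap, out / f"cvlme_{name}.nii.gz",
                     affine=dataset.affine)

    _stage("LBF maps + clusters")
    names = list(results.maps)
    counts = results.preference_counts(thresholds=(thr, thr_fb))
    counts.to_csv(out / "voxel_counts.tsv", sep="\t", index=False)
    cluster_report = {}
    for a in names:
        for b in names:
            if a == b:
                continue
            m = results.lbf(a, b)
            lio.save_map(m, out / f"lbf_{a}_gt_{b}.nii.gz",
                         affine=dataset.affine)
            table = results.cluster_table(
                a, b, thr=thr, fallback_thr=thr_fb, min_size=min_cluster
            )
            table.rows.to_csv(
                out / f"clusters_{a}_gt_{b}.tsv", sep="\t", index=False
            )
            if table.threshold != thr:
                log.info("comparison %s>%s empty at LBF>%g; fell back to %g",
                         a, b, thr, table.threshold)
            cluster_report[f"{a}_gt_{b}"] = {
                "threshold_used": table.threshold,
                "n_clusters": len(table),
                "sizes": table.rows["size"].tolist(),
            }

    _stage("ROI follow-up")
    roi_report = {}
    roi_path = Path(vol_dir) / "roi.nii.gz"
    if dataset.baseline is not None and roi_path.exists():
        roi_mask, _ = lio.load_volume(roi_path)
        psc = roi_percent_signal_change(
            dataset.contrast, dataset.baseline, dataset.grid, roi_mask > 0.5
        )
        typo_resid = residualize(
            dataset.design["typological_diversity_qe"].to_numpy(float),
            dataset.design["diversity_h"].to_numpy(float),
        )
        from .evidence import build_design

        covs = build_design(
            dataset.design,
            [c for c in cfg["neuro_covariates"]],
        )[:, 1:]
        r = partial_correlation(psc, typo_resid, covs)
        roi_report = {"roi_psc_partial_r": r, "n": len(psc)}
        pd.DataFrame(
            {"subject_id": dataset.subjects, "psc": psc,
             "typology_residual": typo_resid}
        ).to_csv(out / "roi_psc.csv", index=False)

    report = {
        "filter_audit": audit,
        "clusters": cluster_report,
        "roi": roi_report,
        "config": cfg,
    }
    lio.write_json(report, out / "report.json")
    log.info("neuro pipeline complete in %.1fs", time.time() - t0)
    return report
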