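"""End-to-end driver: simulate -> clinical -> morphometry -> SCN -> CaSCN
-> dynamic connectivity -> outcome prediction, with a reproducibility
manifest.

Every stage derives its seed deterministically from the config seed, so two
runs with the same config produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cascn import build_pseudotime, export_causal_network, roi_network_gc, seed_to_map_gc
from .clinical import assign_subgroups, classify_subtype, dichotomize_efficacy
from .dfnc import cluster_states, compare_dwell, dwell_statistics, sliding_window_fc
from .io import PipelineConfig, default_atlas, write_gmv_matrix, write_reports, write_subjects
from .morphostats import fdr_bh, fit_group_glm, permutation_cluster_fwe
from .prediction import residualize_vta, svm_ensemble_auc
from .scn import covariance_group_difference
from .synthetic import (GroundTruth, gen_component_timeseries, gen_dbs_outcomes,
                        gen_gmv_parcels, gen_gmv_volumes, gen_subject_table)

__all__ = ["run_pipeline"]


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.__dict__, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, truth: GroundTruth | None = None) -> dict:
    """Execute enabled stages in dependency order; write reports + manifest.

    Returns a dict of in-memory stage results keyed by stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.stages
    results: dict = {}
    truth = truth if truth is not None else GroundTruth.paper_like(seed=config.seed)

    if not stages.get("simulate", True):
        raise ValueError("pipeline currently starts from the simulate stage")
    subjects = gen_subject_table(config.n_patient, config.n_control, seed=config.seed)
    gmv = gen_gmv_parcels(subjects, truth)
    write_subjects(subjects, out / "subjects.tsv")
    write_gmv_matrix(gmv, out / "gmv.tsv")
    truth.to_json(out / "ground_truth.json")
    results["simulate"] = {"subjects": subjects, "gmv": gmv, "truth": truth}

    if stages.get("clinical", True):
        pats = subjects[subjects["group"] == "patient"]
        subtypes = pats.apply(
            lambda r: classify_subtype(r["tremor_mean"], r["pigd_mean"]), axis=1)
        sub = assign_subgroups(pats)
        sub["subtype"] = subtypes.to_numpy()
        write_reports({"clinical_subgroups": sub.set_index("id")}, out)
        results["clinical"] = sub

    if stages.get("morphometry", True):
        stat = fit_group_glm(gmv, subjects=subjects)
        _, qv = fdr_bh(stat.p)
        stat.corrected = qv
        atlas = default_atlas(parcels=list(gmv.columns))
        stack = gen_gmv_volumes(gmv, atlas, noise_sd=truth.noise_sd,
                                seed=config.seed + 101)
        clusters = permutation_cluster_fwe(
            stack, subjects=subjects, forming_p=config.forming_p,
            n_perm=config.n_perm, alpha=config.alpha, seed=config.seed + 102)
        write_reports({"morphometry_parcels": stat.to_frame(),
                       "morphometry_clusters": clusters.to_frame()}, out)
        results["morphometry"] = {"statmap": stat, "clusters": clusters, "atlas": atlas}

    if stages.get("scn", True):
        scn_map = covariance_group_difference(gmv, config.scn_seed_parcel, subjects)
        write_reports({"scn_interaction": scn_map}, out)
        results["scn"] = scn_map

    if stages.get("cascn", True):
        pseudo = build_pseudotime(gmv, subjects)
        seed_map = seed_to_map_gc(pseudo, config.scn_seed_parcel,
                                  q=config.q, lag=config.lag)
        net = roi_network_gc(pseudo, pseudo.parcels, q=config.q, lag=config.lag)
        atlas = results.get("morphometry", {}).get("atlas") or default_atlas(
            parcels=list(gmv.columns))
        export_causal_network(net, atlas.centroids(),
                              out / "cascn.node", out / "cascn.edge")
        degrees = pd.DataFrame({"out_degree": net.out_degree,
                                "in_degree": net.in_degree})
        seed_df = pd.DataFrame([r._asdict() for r in seed_map])
        write_reports({"cascn_seed_map": seed_df, "cascn_degrees": degrees}, out)
        results["cascn"] = {"pseudotime": pseudo, "seed_map": seed_map, "network": net}

    if stages.get("dfnc", True):
        series, paths = gen_component_timeseries(
            len(subjects), config.n_timepoints, truth)
        wins = [sliding_window_fc(s, window_length=config.window_length,
                                  step=config.window_step,
                                  taper_sd=config.taper_sd,
                                  subject=sid)
                for s, sid in zip(series, subjects["id"])]
        model = cluster_states(wins, k=config.k_states, n_init=config.n_init,
                               seed=config.seed + 103)
        dwell = dwell_statistics(model)
        groups = dict(zip(subjects["id"], subjects["group"]))
        comparison = compare_dwell(dwell, groups)
        write_reports({"dfnc_dwell": dwell.set_index(["subject", "state"]),
                       "dfnc_dwell_comparison": comparison,
                       "dfnc_centroids": pd.DataFrame(model.centroids)}, out)
        results["dfnc"] = {"model": model, "dwell": dwell,
                           "comparison": comparison, "true_paths": paths}

    if stages.get("predict", True):
        feat, outcomes = gen_dbs_outcomes(subjects, truth, features=gmv)
        vta_cols = [c for c in outcomes.columns if c.startswith("vta_")]
        resid = residualize_vta(outcomes["improvement"], outcomes[vta_cols])
        labels = np.where(resid < 30.0, "poor", "good")
        if np.unique(labels).size < 2:
            labels = outcomes["efficacy"].to_numpy()
        report = svm_ensemble_auc(feat, labels,
                                  n_iterations=config.n_iterations,
                                  seed=config.seed + 104,
                                  selection="per-split",
                                  retain_fraction=config.retain_fraction,
                                  lasso_repeats=min(config.n_lasso_repeats, 25))
        eff = pd.Series(labels, index=outcomes.index, name="efficacy_residualized")
        write_reports({"prediction_report": report.to_dict(),
                       "prediction_labels": eff.to_frame()}, out)
        results["predict"] = {"report": report, "outcomes": outcomes,
                              "features": feat}

    manifest = {
        "package": "morphnet",
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in config.__dict__.items()},
        "config_hash": _config_hash(config),
        "stages_run": [s for s, on in stages.items() if on],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    results["manifest"] = manifest
    return results
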