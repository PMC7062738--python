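"""End-to-end study orchestration.

``run_study`` executes the full workflow on a (synthetic) cohort:
responder labeling from CRS-R change, per-subject preprocessing and
marker/ERP/decoding computation, the four group-contrast families
(marker topographies, wSMI pairs, ERP space-time, decoding matrices)
through cluster permutation, the multivariate-prediction ART ANOVA, and
exclusion bookkeeping.  Every random choice flows from the config seeds,
so a rerun with the same config reproduces the report payload.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import erp as erp_mod
from . import markers as markers_mod
from . import mvpa as mvpa_mod
from . import preprocess as pp
from . import stats as stats_mod
from .core import POST, PRE, REST, TASK
from .synth import Cohort, CohortSpec, posterior_channels, simulate_reference_database


def classify_response(crsr_pre: int, crsr_post: int) -> str:
    """Responder label from the CRS-R change: R+ iff the score increased."""
    for s in (crsr_pre, crsr_post):
        if not 0 <= s <= 23:
            raise ValueError("CRS-R scores must lie in [0, 23]")
    return "R+" if crsr_post > crsr_pre else "R-"


@dataclass
class StudyConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    seed: int = 0
    n_rest_iterations: int = 100
    n_perm: int = 10000
    erp_decim: int = 1
    decode_decim: int = 1
    decode_iterations: int = 10
    decode_folds: int = 5
    reference_n_vs: int = 75
    reference_n_mcs: int = 68
    reference_separation: float = 1.0
    marker_contrasts: tuple = ("theta_norm", "alpha_norm", "wsmi_theta_alpha_degree")
    run_erp: bool = True
    run_decoding: bool = True


@dataclass
class StudyReport:
    behavioral: pd.DataFrame
    marker_clusters: dict  # marker -> ClusterResult
    pair_cluster: object
    erp_cluster: object
    decoding_cluster: object
    delta_predictions: pd.DataFrame
    art: dict
    exclusions: dict
    provenance: dict

    def to_json_dict(self) -> dict:
        def _cl(c):
            return None if c is None else c.to_json_dict()

        return {
            "behavioral": self.behavioral.to_dict(orient="records"),
            "marker_clusters": {k: _cl(v) for k, v in self.marker_clusters.items()},
            "pair_cluster": _cl(self.pair_cluster),
            "erp_cluster": _cl(self.erp_cluster),
            "decoding_cluster": _cl(self.decoding_cluster),
            "delta_predictions": self.delta_predictions.to_dict(orient="records"),
            "art": self.art,
            "exclusions": self.exclusions,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=1, sort_keys=True)


def _rest_markers(cohort: Cohort, idx: int, session: str, cfg: StudyConfig):
    rec = cohort.recording(idx, REST, session)
    sets, reports = pp.preprocess_resting(
        rec, seed=cfg.seed * 1000 + idx * 2 + (session == POST), n_iterations=cfg.n_rest_iterations
    )
    usable = [s for s in sets if not s.failed]
    if not usable:
        return None
    topo = markers_mod.compute_topographies(usable)
    pairs = markers_mod.compute_pair_topography(usable)
    features = mvpa_mod.features_from_epoch_sets(usable)
    return {"topo": topo, "pairs": pairs, "features": features}


def run_study(cfg: StudyConfig) -> StudyReport:
    """Execute the full pipeline and assemble the study report."""
    cohort = Cohort(cfg.cohort)
    layout = cohort.layout
    exclusions = {"rest": [], "task": []}

    behavioral = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "diagnosis": s.diagnosis,
                "crsr_pre": s.crsr_pre,
                "crsr_post": s.crsr_post,
                "crsr_delta": s.crsr_post - s.crsr_pre,
                "response": classify_response(s.crsr_pre, s.crsr_post),
            }
            for s in cohort.subjects
        ]
    )
    responder = behavioral["response"].to_numpy() == "R+"

    # --- reference classifier ---------------------------------------------
    ref = simulate_reference_database(
        cfg.reference_n_vs,
        cfg.reference_n_mcs,
        separation=cfg.reference_separation,
        seed=cfg.seed + 101,
        base_spec=cfg.cohort.null(),
    )
    ref_feats, ref_labels = [], []
    for sid, label, rec in ref:
        sets, _ = pp.preprocess_resting(rec, seed=cfg.seed + 7, n_iterations=1)
        usable = [s for s in sets if not s.failed]
        if not usable:
            continue
        ref_feats.append(mvpa_mod.features_from_epoch_sets(usable))
        ref_labels.append(label)
    ref_df = pd.DataFrame(ref_feats)
    clf = mvpa_mod.train(ref_df, np.array(ref_labels), seed=cfg.seed)

    # --- per-subject resting markers and predictions ----------------------
    rest_results = {}
    for i, sub in enumerate(cohort.subjects):
        pre = _rest_markers(cohort, i, PRE, cfg)
        post = _rest_markers(cohort, i, POST, cfg)
        if pre is None or post is None:
            exclusions["rest"].append(sub.subject_id)
            continue
        rest_results[i] = (pre, post)

    marker_clusters = {}
    rp = [i for i in rest_results if responder[i]]
    rm = [i for i in rest_results if not responder[i]]
    for marker in cfg.marker_contrasts:
        if marker == "wsmi_theta_alpha_degree":
            continue  # covered by both topography and pair families below
        da = np.stack(
            [rest_results[i][1]["topo"][marker] - rest_results[i][0]["topo"][marker] for i in rp]
        )
        db = np.stack(
            [rest_results[i][1]["topo"][marker] - rest_results[i][0]["topo"][marker] for i in rm]
        )
        marker_clusters[marker] = stats_mod.cluster_perm(
            da, db, layout.adjacency, "welch_t", n_perm=cfg.n_perm, seed=cfg.seed + 11
        )
    # degree topography contrast
    da = np.stack(
        [
            rest_results[i][1]["topo"]["wsmi_theta_alpha_degree"]
            - rest_results[i][0]["topo"]["wsmi_theta_alpha_degree"]
            for i in rp
        ]
    )
    db = np.stack(
        [
            rest_results[i][1]["topo"]["wsmi_theta_alpha_degree"]
            - rest_results[i][0]["topo"]["wsmi_theta_alpha_degree"]
            for i in rm
        ]
    )
    marker_clusters["wsmi_theta_alpha_degree"] = stats_mod.cluster_perm(
        da, db, layout.adjacency, "welch_t", n_perm=cfg.n_perm, seed=cfg.seed + 12
    )

    # wSMI pair-space contrast
    _, pair_adj = stats_mod.pair_adjacency(layout)
    da = np.stack([rest_results[i][1]["pairs"] - rest_results[i][0]["pairs"] for i in rp])
    db = np.stack([rest_results[i][1]["pairs"] - rest_results[i][0]["pairs"] for i in rm])
    pair_cluster = stats_mod.cluster_perm(
        da, db, pair_adj, "welch_t", n_perm=cfg.n_perm, seed=cfg.seed + 13
    )

    # --- MVPA deltas and ART ANOVA ----------------------------------------
    rows = []
    for i in rest_results:
        pre, post = rest_results[i]
        p_pre = mvpa_mod.predict_mcs(clf, pre["features"])
        p_post = mvpa_mod.predict_mcs(clf, post["features"])
        rows.append(
            {
                "subject_id": cohort.subjects[i].subject_id,
                "response": "R+" if responder[i] else "R-",
                "p_pre": p_pre,
                "p_post": p_post,
                "delta": p_post - p_pre,
            }
        )
    delta_predictions = pd.DataFrame(rows)
    long = pd.concat(
        [
            delta_predictions.rename(columns={"p_pre": "value"}).assign(session=PRE)[
                ["subject_id", "response", "session", "value"]
            ],
            delta_predictions.rename(columns={"p_post": "value"}).assign(session=POST)[
                ["subject_id", "response", "session", "value"]
            ],
        ]
    )
    art = stats_mod.art_anova(
        long, dv="value", between="response", within="session", subject="subject_id"
    )

    # --- task: ERP interaction and decoding -------------------------------
    erp_cluster = None
    decoding_cluster = None
    if cfg.run_erp or cfg.run_decoding:
        task_sets = {}
        for i, sub in enumerate(cohort.subjects):
            eps = {}
            ok = True
            for session in (PRE, POST):
                ep, _ = pp.preprocess_task(cohort.recording(i, TASK, session))
                if ep.failed:
                    ok = False
                    break
                eps[session] = ep
            if not ok:
                exclusions["task"].append(sub.subject_id)
                continue
            task_sets[i] = eps

        if cfg.run_erp:
            subjects = [
                {
                    "subject_id": cohort.subjects[i].subject_id,
                    "responder": bool(responder[i]),
                    "pre": task_sets[i][PRE],
                    "post": task_sets[i][POST],
                }
                for i in task_sets
            ]
            arr_p, arr_m, excluded = erp_mod.interaction_contrast(subjects)
            exclusions["task"] += [e for e in excluded if e not in exclusions["task"]]
            if cfg.erp_decim > 1 and arr_p.ndim == 3:
                arr_p = arr_p[:, :, :: cfg.erp_decim]
                arr_m = arr_m[:, :, :: cfg.erp_decim]
            if len(arr_p) >= 2 and len(arr_m) >= 2:
                n_t = arr_p.shape[2]
                adj = stats_mod.spatiotemporal_adjacency(layout, n_t)
                erp_cluster = stats_mod.cluster_perm(
                    arr_p.reshape(len(arr_p), -1),
                    arr_m.reshape(len(arr_m), -1),
                    adj,
                    "welch_t",
                    n_perm=cfg.n_perm,
                    seed=cfg.seed + 14,
                )

        if cfg.run_decoding:
            mats = {}
            for i, eps in task_sets.items():
                ms = {}
                for session in (PRE, POST):
                    gm = erp_mod.tg_decode(
                        eps[session],
                        seed=cfg.seed + i,
                        n_iterations=cfg.decode_iterations,
                        n_folds=cfg.decode_folds,
                        decim=cfg.decode_decim,
                    )
                    if gm.flagged:
                        ms = None
                        break
                    ms[session] = gm
                if ms is not None:
                    mats[i] = ms[POST].auc - ms[PRE].auc
            dp = [mats[i] for i in mats if responder[i]]
            dm = [mats[i] for i in mats if not responder[i]]
            if len(dp) >= 2 and len(dm) >= 2:
                shape = dp[0].shape
                adj = stats_mod.lattice_adjacency(shape)
                decoding_cluster = stats_mod.cluster_perm(
                    np.stack(dp).reshape(len(dp), -1),
                    np.stack(dm).reshape(len(dm), -1),
                    adj,
                    "mann_whitney_z",
                    n_perm=cfg.n_perm,
                    seed=cfg.seed + 15,
                )

    provenance = {
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "n_rest_iterations": cfg.n_rest_iterations,
        "cohort": {k: v for k, v in asdict(cfg.cohort).items()},
        "planted_channels": [int(c) for c in posterior_channels(layout)],
        "n_subjects_rest": len(rest_results),
    }
    return StudyReport(
        behavioral=behavioral,
        marker_clusters=marker_clusters,
        pair_cluster=pair_cluster,
        erp_cluster=erp_cluster,
        decoding_cluster=decoding_cluster,
        delta_predictions=delta_predictions,
        art=art,
        exclusions=exclusions,
        provenance=provenance,
    )
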