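"""End-to-end study orchestration.

``run_trial`` processes one trial bundle with both foot models (filtering
-> anatomical frames -> cluster poses -> joint angles and angular
velocities -> inertial parameters -> GRF assignment -> Newton-Euler ->
power and work), on the identical input.  ``run_study`` aggregates
stance-normalised series across subjects (averaging multiple trials per
subject first) and runs the statistical comparison: paired Hotelling's
T^2 fields on the 3-component ankle angle / angular-velocity / moment
series with Sidak-gated post-hoc component t fields, paired t fields on
ankle power (between models) and on ankle vs midfoot power (within the
multi-segment model), and Bonferroni-corrected scalar paired t tests on
the work summaries.

Moments and angular velocities enter the statistics as clinical
components (dorsiflexion+, inversion+, abduction+) resolved in the
proximal anatomical frame; power is a frame-invariant scalar.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anthropometry import foot_segment_inertia
from .config import PipelineConfig, DEFAULT_CONFIG
from .errors import DataError, PairingError, StageError
from .foot_models import (
    COMPONENTS,
    JointAngleSeries,
    compute_joint_angles,
    compute_trial_kinematics,
    make_model,
    time_normalize,
)
from .inverse_dynamics import compute_joint_kinetics
from .io_formats import TrialBundle
from .spm_stats import (
    FieldSample,
    normality_check,
    scalar_paired_t,
    sidak_alpha,
    spm_paired_hotelling,
    spm_paired_t,
)

log = logging.getLogger("footmech")


# ---------------------------------------------------------------------------
# per-trial results

@dataclass
class ModelTrialResult:
    model_id: str
    angles: dict               # joint -> JointAngleSeries
    moments: dict              # joint -> (nodes, 3) N*m/kg, clinical components
    powers: dict               # joint -> (nodes,) W/kg
    works: dict                # joint -> WorkSummary (J/kg)
    assignment_counts: dict


@dataclass
class TrialResult:
    subject_mass: float
    stance_duration: float
    models: dict               # 'SINGLE'/'MULTI' -> ModelTrialResult


def _clinical_components(series_lab, prox_R_anat, signs):
    """Express lab-frame vectors in the proximal anatomical frame and
    reorder to clinical components (sagittal z, frontal x, transverse y)."""
    v = np.einsum("tji,tj->ti", prox_R_anat, series_lab)
    return np.stack([v[:, 2], v[:, 0], v[:, 1]], axis=1) * signs


def run_trial(bundle: TrialBundle, config: PipelineConfig | None = None) -> TrialResult:
    """Process one trial with both the SINGLE and MULTI foot models."""
    config = config or DEFAULT_CONFIG
    if bundle.forces is None:
        raise StageError("inverse_dynamics", DataError("force record missing"))
    signs = np.asarray(config.lab.angle_signs())
    nodes = config.stance.nodes
    out = {}
    stance_duration = None
    for model_id in ("SINGLE", "MULTI"):
        model = make_model(model_id, config)
        try:
            kin = compute_trial_kinematics(bundle, model, config)
        except Exception as exc:  # noqa: BLE001 - stage attribution
            raise StageError("kinematics", exc) from exc
        log.info("model %s: stance %d-%d (%.3f s)", model_id, kin.stance.first,
                 kin.stance.last, kin.stance.duration)
        try:
            angles = compute_joint_angles(kin, config=config)
        except Exception as exc:  # noqa: BLE001
            raise StageError("angles", exc) from exc
        try:
            inertial = foot_segment_inertia(bundle.subject, config.anthropometry)
        except Exception as exc:  # noqa: BLE001
            raise StageError("anthropometry", exc) from exc
        try:
            kinetics, works, assignment = compute_joint_kinetics(
                kin, inertial, bundle.subject.mass, config)
        except Exception as exc:  # noqa: BLE001
            raise StageError("inverse_dynamics", exc) from exc
        moments = {}
        powers = {}
        w = kin.stance
        for j in model.joints:
            jk = kinetics[j.name]
            prox_R = kin.segments[j.proximal].R_anat[w.first:w.last + 1]
            m_cl = _clinical_components(jk.moment, prox_R, signs)
            stub = type("W", (), {"first": 0, "last": len(m_cl) - 1,
                                  "rate": kin.rate})()
            moments[j.name] = time_normalize(m_cl, stub, nodes)
            powers[j.name] = time_normalize(jk.power, stub, nodes)
        out[model_id] = ModelTrialResult(model_id, angles, moments, powers,
                                         works, assignment.counts())
        stance_duration = kin.stance.duration
    return TrialResult(bundle.subject.mass, stance_duration, out)


# ---------------------------------------------------------------------------
# study aggregation

@dataclass
class StudyResult:
    """Cross-subject aggregate: per-subject node series, SPM results and
    scalar work contrasts."""

    n_subjects: int
    nodes: int
    fields: dict = field(default_factory=dict)    # name -> (n, nodes[, 3])
    spm: dict = field(default_factory=dict)       # name -> SPMResult
    posthoc: dict = field(default_factory=dict)   # name -> [SPMResult x3]
    work_tests: dict = field(default_factory=dict)
    work_values: dict = field(default_factory=dict)
    normality: dict = field(default_factory=dict)
    work_partition: dict = field(default_factory=dict)

    def to_json(self, path=None):
        payload = {
            "n_subjects": self.n_subjects,
            "nodes": self.nodes,
            "spm": {k: v.to_dict() for k, v in self.spm.items()},
            "posthoc": {k: [r.to_dict() for r in v] for k, v in self.posthoc.items()},
            "work_tests": self.work_tests,
            "work_values": {k: list(map(float, v)) for k, v in self.work_values.items()},
            "normality": self.normality,
            "work_partition": self.work_partition,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=1)
        return payload

    def tidy_frame(self) -> pd.DataFrame:
        """Long-format per-node summary (mean and SD across subjects)."""
        rows = []
        for name, arr in self.fields.items():
            arr = np.asarray(arr)
            if arr.ndim == 2:
                comps = {"value": arr}
            else:
                comps = {COMPONENTS[k]: arr[..., k] for k in range(arr.shape[2])}
            for comp, a in comps.items():
                mean = a.mean(axis=0)
                sd = a.std(axis=0, ddof=1)
                for node in range(a.shape[1]):
                    rows.append({"variable": name, "component": comp,
                                 "pct_stance": node, "mean": mean[node],
                                 "sd": sd[node]})
        return pd.DataFrame(rows)


def _average_trials(results):
    """Average node series across a subject's trials (1..k allowed)."""
    if len(results) == 1:
        return results[0]
    base = results[0]
    for model_id, mres in base.models.items():
        for j, jas in mres.angles.items():
            jas.angles = np.mean([r.models[model_id].angles[j].angles for r in results], axis=0)
            jas.omega = np.mean([r.models[model_id].angles[j].omega for r in results], axis=0)
        for j in mres.moments:
            mres.moments[j] = np.mean([r.models[model_id].moments[j] for r in results], axis=0)
            mres.powers[j] = np.mean([r.models[model_id].powers[j] for r in results], axis=0)
        for j, wk in mres.works.items():
            wk.positive = float(np.mean([r.models[model_id].works[j].positive for r in results]))
            wk.negative = float(np.mean([r.models[model_id].works[j].negative for r in results]))
            wk.net = float(np.mean([r.models[model_id].works[j].net for r in results]))
    return base


def run_study(bundles, config: PipelineConfig | None = None, alpha=0.05,
              seed=0) -> StudyResult:
    """Run the full SINGLE-vs-MULTI comparison across subjects.

    ``bundles``: one entry per subject, each a TrialBundle or a list of
    TrialBundles (trials are averaged per subject before statistics).
    """
    config = config or DEFAULT_CONFIG
    if len(bundles) < 2:
        raise PairingError("paired statistics need at least 2 subjects")
    per_subject = []
    for i, entry in enumerate(bundles):
        trials = entry if isinstance(entry, (list, tuple)) else [entry]
        results = [run_trial(b, config) for b in trials]
        per_subject.append(_average_trials(results))
        log.info("subject %d: %d trial(s) processed", i + 1, len(results))
    nodes = config.stance.nodes
    res = StudyResult(len(per_subject), nodes)

    def gather(fn):
        return np.stack([fn(r) for r in per_subject])

    f = res.fields
    f["ankle_angle_SINGLE"] = gather(lambda r: r.models["SINGLE"].angles["ankle"].angles)
    f["ankle_angle_MULTI"] = gather(lambda r: r.models["MULTI"].angles["ankle"].angles)
    f["ankle_omega_SINGLE"] = gather(lambda r: r.models["SINGLE"].angles["ankle"].omega)
    f["ankle_omega_MULTI"] = gather(lambda r: r.models["MULTI"].angles["ankle"].omega)
    f["ankle_moment_SINGLE"] = gather(lambda r: r.models["SINGLE"].moments["ankle"])
    f["ankle_moment_MULTI"] = gather(lambda r: r.models["MULTI"].moments["ankle"])
    f["ankle_power_SINGLE"] = gather(lambda r: r.models["SINGLE"].powers["ankle"])
    f["ankle_power_MULTI"] = gather(lambda r: r.models["MULTI"].powers["ankle"])
    f["midfoot_power_MULTI"] = gather(lambda r: r.models["MULTI"].powers["midtarsal"])
    f["midfoot_moment_MULTI"] = gather(lambda r: r.models["MULTI"].moments["midtarsal"])

    # vector fields: Hotelling T^2 with gated post-hoc component t fields
    a_sidak = sidak_alpha(alpha, 3)
    for name in ("angle", "omega", "moment"):
        sa = FieldSample(f[f"ankle_{name}_SINGLE"])
        sb = FieldSample(f[f"ankle_{name}_MULTI"])
        h = spm_paired_hotelling(sa, sb, alpha=alpha, seed=seed)
        res.spm[f"ankle_{name}_T2"] = h
        if h.significant:
            res.posthoc[f"ankle_{name}"] = [
                spm_paired_t(sa.values[..., k], sb.values[..., k],
                             alpha=a_sidak, seed=seed)
                for k in range(3)]

    res.spm["ankle_power_t"] = spm_paired_t(
        f["ankle_power_SINGLE"], f["ankle_power_MULTI"], alpha=alpha, seed=seed)
    res.spm["ankle_vs_midfoot_power_t"] = spm_paired_t(
        f["ankle_power_MULTI"], f["midfoot_power_MULTI"], alpha=alpha, seed=seed)

    # scalar work contrasts (Bonferroni over the 3 planned comparisons)
    pos_s = gather(lambda r: r.models["SINGLE"].works["ankle"].positive)
    pos_m = gather(lambda r: r.models["MULTI"].works["ankle"].positive)
    neg_s = gather(lambda r: r.models["SINGLE"].works["ankle"].negative)
    neg_m = gather(lambda r: r.models["MULTI"].works["ankle"].negative)
    pos_mid = gather(lambda r: r.models["MULTI"].works["midtarsal"].positive)
    res.work_values = {
        "ankle_positive_SINGLE": pos_s, "ankle_positive_MULTI": pos_m,
        "ankle_negative_SINGLE": neg_s, "ankle_negative_MULTI": neg_m,
        "midfoot_positive_MULTI": pos_mid,
    }
    contrasts = {
        "positive_work_single_vs_multi": (pos_s, pos_m),
        "negative_work_single_vs_multi": (neg_s, neg_m),
        "multi_ankle_vs_midfoot_positive": (pos_m, pos_mid),
    }
    for name, (x, y) in contrasts.items():
        t, p, thr = scalar_paired_t(x, y, corrections=len(contrasts), alpha=alpha)
        res.work_tests[name] = {"t": t, "p": p, "corrected_alpha": thr,
                                "significant": bool(p < thr),
                                "mean_difference": float(np.mean(x - y))}
        w, pn, ok = normality_check(x - y)
        res.normality[name] = {"W": None if np.isnan(w) else w, "p": pn, "passed": ok}

    combined = pos_m + pos_mid
    denom = float(np.mean(pos_s))
    res.work_partition = {
        "single_ankle_positive": denom,
        "multi_ankle_positive": float(np.mean(pos_m)),
        "multi_midfoot_positive": float(np.mean(pos_mid)),
        "multi_ankle_plus_midfoot": float(np.mean(combined)),
        "relative_discrepancy": float(abs(np.mean(pos_s) - np.mean(combined))
                                      / denom) if denom else np.nan,
    }
    return res


def write_report(result: StudyResult, out_dir):
    """Write the tidy per-node CSV and the JSON results summary."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.tidy_frame().to_csv(out / "study_nodes.csv", index=False)
    result.to_json(out / "study_results.json")
    return out
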