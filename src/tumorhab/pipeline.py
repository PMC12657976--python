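"""End-to-end study orchestration at desk scale.

Phantom cohort -> feature maps -> cohort habitat clustering (per perfusion
quantity, sweeping the habitat count) -> model calibration under the chosen
parameterization schemes -> V3 prediction -> error metrics, optimal habitat
number, scheme comparisons, calibration-efficiency table, and ROC analysis of
response classification.  Stage outputs are cached on disk keyed by a hash of
the configuration so re-runs are incremental.
"""

from __future__ import annotations

import hashlib
import json
import pickle
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration, evaluation, features, habitats, phantom
from .calibration import CalibrationProblem

METRICS = ("ttc", "ttv", "mse_tc")


@dataclass
class StudyConfig:
    phantom: phantom.PhantomConfig = field(
        default_factory=phantom.PhantomConfig)
    n_patients: int = 10
    qois: tuple = ("msi",)
    h_range: tuple = (2, 3, 4)
    schemes: tuple = ("global", "habitat", "local")
    seed: int = 0
    dt: float = 0.25
    stress_interval: float = 7.0
    max_iter: int = 40
    local_max_iter: int | None = None   # defaults to max_iter
    ttv_threshold: float = 0.25
    responder_fraction: float = 0.05
    cache_dir: str | None = None

    def __post_init__(self) -> None:
        if not all(2 <= h <= 16 for h in self.h_range):
            raise ValueError("habitat counts must lie in 2..16")
        if not self.schemes:
            raise ValueError("at least one calibration scheme required")


def recovery_study_config(seed: int = 7, n_patients: int = 10) -> StudyConfig:
    """Noiseless parameter-recovery conditions.

    Full default grid (32x32x16), three regions with constant per-region
    proliferation, no measurement noise; desk-scale numerics (dt 1 d,
    stress refresh every 14 d, identical in generation and calibration so the
    inverse problem is exactly self-consistent).
    """
    pcfg = phantom.PhantomConfig(dwi_noise_sd=0.0, dce_noise_sd=0.0,
                                 k_voxel_jitter=0.0,
                                 stress_interval_days=14.0, dt_days=1.0,
                                 seed=seed)
    return StudyConfig(phantom=pcfg, n_patients=n_patients, qois=("msi",),
                       h_range=(2, 3), schemes=("habitat",), seed=seed,
                       dt=1.0, stress_interval=14.0, max_iter=20)


def extend_labels_to_roi(labels: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Give unlabeled ROI voxels their own 'new growth' habitat.

    The modeling ROI is the union of the V1 and V2 segmentations, so voxels
    the tumor invaded after V1 carry no generative region label.  Their true
    proliferation rate is the background's (zero), not any region's, so they
    form an additional habitat rather than inheriting a neighbor's label —
    otherwise the true parameters are no longer the optimum of the noiseless
    inverse problem.
    """
    roi = np.asarray(roi, bool)
    out = np.asarray(labels).copy()
    missing = roi & (out == 0)
    if missing.any():
        out[missing] = int(labels.max()) + 1
    return out


def run_recovery_experiment(cfg: StudyConfig) -> pd.DataFrame:
    """Fit the habitat scheme with the *true* region map on a noiseless cohort.

    Returns one row per patient with the relative recovery error of each
    per-region proliferation rate and of the drug efficacy.
    """
    cohort = phantom.generate_cohort(cfg.n_patients, cfg.phantom, cfg.seed)
    rows = []
    for i, patient in enumerate(cohort):
        pf = compute_patient_features(patient)
        true_map = extend_labels_to_roi(
            patient.ground_truth["region_labels"], pf["roi"])
        problem = build_problem(patient, pf, "habitat", cfg,
                                habitat_map=true_map)
        result = calibration.levenberg_marquardt(problem)
        # compare only the generative regions' rates; a possible extra
        # 'new growth' habitat has true rate 0 and is not scored
        n_reg = patient.config.n_regions
        true_k = np.array([a.k for a in patient.config.region_archetypes
                           [:n_reg]])
        rel_k = np.abs(result.k[:n_reg] - true_k) / true_k
        rel_a = abs(result.alpha - patient.config.alpha) \
            / patient.config.alpha
        row = dict(patient=i, alpha_rel_err=rel_a,
                   converged=result.converged,
                   n_simulations=result.n_simulations)
        for j, e in enumerate(rel_k):
            row[f"k{j + 1}_rel_err"] = e
        rows.append(row)
    return pd.DataFrame(rows)


def noisy_study_config(seed: int = 11, n_patients: int = 12) -> StudyConfig:
    """Noisy-cohort conditions for scheme comparison and habitat-count choice.

    Reduced grid (20x20x10, ~120 tumor voxels) so the voxelwise calibration
    stays desk-scale; DWI noise at a clinical SNR (~12), additive DCE noise,
    and mild within-region proliferative heterogeneity.
    """
    pcfg = phantom.PhantomConfig(grid_shape=(20, 20, 10),
                                 tumor_semiaxes_mm=(4.0, 4.0, 3.5),
                                 breast_semiaxes_mm=(8.5, 8.5, 6.0),
                                 dwi_noise_sd=0.08, dce_noise_sd=4.0,
                                 k_voxel_jitter=0.15,
                                 stress_interval_days=7.0, dt_days=0.5,
                                 seed=seed)
    return StudyConfig(phantom=pcfg, n_patients=n_patients, qois=("msi",),
                       h_range=(2, 3, 4),
                       schemes=("global", "habitat", "local"), seed=seed,
                       dt=0.5, stress_interval=7.0, max_iter=25,
                       local_max_iter=80)


def _key(*parts) -> str:
    blob = repr(parts).encode()
    return hashlib.sha256(blob).hexdigest()[:20]


class _Cache:
    def __init__(self, root: str | None):
        self.root = Path(root) if root else None
        if self.root:
            self.root.mkdir(parents=True, exist_ok=True)

    def get_or(self, key, fn):
        if self.root is None:
            return fn()
        path = self.root / f"{key}.pkl"
        if path.exists():
            with open(path, "rb") as fh:
                return pickle.load(fh)
        val = fn()
        with open(path, "wb") as fh:
            pickle.dump(val, fh)
        return val


# ---------------------------------------------------------------------------
# per-patient feature extraction

def compute_patient_features(patient: phantom.VirtualPatient) -> dict:
    """ADC, cellularity, and perfusion maps per visit, plus C(x) and ROI."""
    roi = patient.modeling_roi
    adc_maps, valid = {}, {}
    for visit in ("V1", "V2", "V3"):
        s_lo, s_hi = patient.dwi[visit]
        amap = features.fit_adc(s_lo, s_hi, visit=visit)
        adc_maps[visit] = amap
    adc_min = min(float(amap.values[roi & amap.valid].min())
                  for amap in adc_maps.values())
    adc_min = min(adc_min, features.ADC_WATER - 1e-6)
    cell = {v: features.cellularity_map(a, adc_min, patient.theta)
            for v, a in adc_maps.items()}
    perf = {v: features.perfusion_maps(patient.dce[v], visit=v)
            for v in ("V1", "V2", "V3")}
    drug = features.drug_concentration(
        features.normalize_dce(patient.dce["V1"]), patient.breast_mask)
    out = {
        "roi": roi,
        "adc": {v: adc_maps[v].values for v in adc_maps},
        "cell": cell,
        "msi": {v: perf[v].msi for v in perf},
        "pei": {v: perf[v].pei for v in perf},
        "ser": {v: perf[v].ser for v in perf},
        "drug_map": drug,
        "adc_min": adc_min,
    }
    return out


def build_problem(patient: phantom.VirtualPatient, pf: dict, scheme: str,
                  cfg: StudyConfig, habitat_map: np.ndarray | None = None,
                  solver=None) -> CalibrationProblem:
    days = patient.config.visit_days
    problem = CalibrationProblem(
        cell_v1=pf["cell"]["V1"].values, cell_v2=pf["cell"]["V2"].values,
        roi=pf["roi"], breast_mask=patient.breast_mask, theta=patient.theta,
        drug_map=pf["drug_map"], schedule=patient.schedule, scheme=scheme,
        t_v2=days[1], t_v3=days[2], habitat_map=habitat_map,
        d0=patient.config.d0, mech=patient.mechanical_params(),
        spacing=patient.spacing, dt=cfg.dt,
        stress_interval=cfg.stress_interval,
        max_iter=(cfg.local_max_iter or cfg.max_iter) if scheme == "local"
        else cfg.max_iter)
    if solver is not None:
        problem.set_solver(solver)
    return problem


def patient_metrics(problem: CalibrationProblem, model_v2: np.ndarray,
                    model_v3: np.ndarray, pf: dict, theta: float,
                    voxel_volume: float, ttv_threshold: float) -> dict:
    """The three error metrics at V2 (calibration) and V3 (prediction)."""
    roi = problem.roi
    data = {v: pf["cell"][v].values[roi] for v in ("V1", "V2", "V3")}
    out = {}
    for visit, model in (("V2", model_v2), ("V3", model_v3)):
        model_roi = model[roi]
        d_ttc = evaluation.pct_delta_ttc(data["V1"], data[visit])
        m_ttc = evaluation.pct_delta_ttc(data["V1"], model_roi)
        d_ttv = evaluation.pct_delta_ttv(data["V1"], data[visit], theta,
                                         voxel_volume, ttv_threshold)
        m_ttv = evaluation.pct_delta_ttv(data["V1"], model_roi, theta,
                                         voxel_volume, ttv_threshold)
        mse = evaluation.mse_pct_delta_tc(
            pf["cell"]["V1"].values, model, pf["cell"]["V1"].values,
            pf["cell"][visit].values, roi)
        out[visit] = {"ttc": abs(m_ttc - d_ttc), "ttv": abs(m_ttv - d_ttv),
                      "mse_tc": mse}
    return out


# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    config: StudyConfig
    metrics: pd.DataFrame          # patient x scheme x H x visit x metric
    optimal_h: dict                # qoi -> evaluation.OptimalH
    scheme_tests: pd.DataFrame     # KS p-values between schemes at optimal H
    efficiency: pd.DataFrame       # parameter counts and wall times
    roc: pd.DataFrame              # AUC/CI/sens/spec per predictor
    delong: pd.DataFrame           # pairwise AUC comparisons
    connectivity: dict             # per qoi: unneighbored %, shuffle p
    responders: np.ndarray


def run_study(cfg: StudyConfig) -> StudyReport:
    cache = _Cache(cfg.cache_dir)
    cohort = cache.get_or(_key("cohort", asdict_safe(cfg)), lambda:
                          phantom.generate_cohort(cfg.n_patients, cfg.phantom,
                                                  cfg.seed))
    pfs = cache.get_or(_key("features", asdict_safe(cfg)), lambda: [
        compute_patient_features(p) for p in cohort])
    shape = cfg.phantom.grid_shape
    voxvol = cfg.phantom.voxel_volume

    # cohort habitat maps per qoi and H
    hab_maps: dict = {}
    connectivity: dict = {}
    for qoi in cfg.qois:
        fm = habitats.build_feature_matrix(pfs, qoi)
        hab_maps[qoi] = {}
        for H in cfg.h_range:
            ha = habitats.cluster_habitats(fm, H, seed=cfg.seed)
            habitats.assign_semantic_labels(ha, fm)
            hab_maps[qoi][H] = ha.per_patient_maps(fm, shape)
        # connectivity diagnostics at the smallest H
        H0 = cfg.h_range[0]
        maps0 = hab_maps[qoi][H0]
        rois = [pf["roi"] for pf in pfs]
        pct = [habitats.pct_unneighbored(m, r) for m, r in zip(maps0, rois)]
        p_shuf, true_d, null_d = habitats.shuffled_connectivity_test(
            maps0, rois, H0, n_shuffles=5, seed=cfg.seed + 1)
        connectivity[qoi] = {"pct_unneighbored": pct, "shuffle_p": p_shuf,
                             "diag_true": true_d, "diag_null": null_d}

    # calibrations
    rows, eff_rows = [], []
    predictions: dict = {}
    for i, (patient, pf) in enumerate(zip(cohort, pfs)):
        # one prefactorized elasticity operator per patient, shared by all
        # calibration variants (the stiffness depends only on E and the mask)
        patient_solver = None
        if patient.config.mech["gamma"] > 0 and patient.config.d0 > 0:
            from .mechanics import ElasticitySolver
            patient_solver = ElasticitySolver(
                patient.mechanical_params(), patient.breast_mask,
                patient.spacing)
        # run global before local: the local fit warm-starts from the global
        # optimum (deterministic staged initialization)
        order = {"global": 0, "habitat": 1, "local": 2}
        global_fit = None
        for scheme in sorted(cfg.schemes, key=lambda s: order[s]):
            variants = []
            if scheme == "habitat":
                for qoi in cfg.qois:
                    for H in cfg.h_range:
                        variants.append((qoi, H, hab_maps[qoi][H][i]))
            else:
                variants.append((None, 0, None))
            for qoi, H, hmap in variants:
                key = _key("cal", asdict_safe(cfg), i, scheme, qoi, H)
                problem = build_problem(patient, pf, scheme, cfg,
                                        habitat_map=hmap,
                                        solver=patient_solver)
                init = None
                if scheme == "local" and global_fit is not None:
                    # keep warm-start k's off the bound so their sensitivity
                    # does not vanish under the logistic transform
                    k0 = max(float(global_fit.k[0]), 0.01)
                    init = np.r_[np.full(problem.n_voxels, k0),
                                 global_fit.alpha]

                def run(problem=problem, init=init):
                    t0 = time.perf_counter()
                    result = calibration.levenberg_marquardt(
                        problem, init_vector=init)
                    v2 = calibration._simulate_to(problem, result.params,
                                                  problem.t_v2)
                    v3 = calibration.predict_v3(problem, result)
                    return result, v2, v3, time.perf_counter() - t0

                result, v2, v3, wall = cache.get_or(key, run)
                if scheme == "global":
                    global_fit = result
                predictions[(i, scheme, qoi, H)] = (v2, v3)
                m = patient_metrics(problem, v2, v3, pf, patient.theta,
                                    voxvol, cfg.ttv_threshold)
                for visit in ("V2", "V3"):
                    for metric in METRICS:
                        rows.append(dict(patient=i, scheme=scheme, qoi=qoi,
                                         H=H, visit=visit, metric=metric,
                                         error=m[visit][metric]))
                eff_rows.append(dict(patient=i, scheme=scheme, qoi=qoi, H=H,
                                     n_params=result.parameter_count,
                                     wall_time_s=wall,
                                     n_simulations=result.n_simulations,
                                     converged=result.converged))
    metrics = pd.DataFrame(rows)
    efficiency = pd.DataFrame(eff_rows)

    # optimal habitat count per qoi: per-patient average of V2+V3 errors
    optimal_h = {}
    if "habitat" in cfg.schemes and len(cfg.h_range) >= 2:
        for qoi in cfg.qois:
            tables = {}
            sub = metrics[(metrics.scheme == "habitat")
                          & (metrics.qoi == qoi)]
            for H in cfg.h_range:
                tab = {}
                for metric in METRICS:
                    s = sub[(sub.H == H) & (sub.metric == metric)]
                    tab[metric] = (s.groupby("patient")["error"].mean()
                                   .to_numpy())
                tables[H] = tab
            optimal_h[qoi] = evaluation.select_optimal_H(tables)

    # scheme comparison (KS) at the optimal habitat count
    test_rows = []
    for qoi in cfg.qois:
        h_opt = optimal_h[qoi].H if qoi in optimal_h else cfg.h_range[0]
        for visit in ("V2", "V3"):
            for metric in METRICS:
                dists = {}
                for scheme in cfg.schemes:
                    sel = ((metrics.scheme == scheme)
                           & (metrics.visit == visit)
                           & (metrics.metric == metric))
                    if scheme == "habitat":
                        sel &= (metrics.qoi == qoi) & (metrics.H == h_opt)
                    d = metrics[sel].sort_values("patient")["error"]
                    dists[scheme] = d.to_numpy()
                names = list(dists)
                for a in range(len(names)):
                    for b in range(a + 1, len(names)):
                        stat, p = evaluation.ks_two_sample(dists[names[a]],
                                                           dists[names[b]])
                        test_rows.append(dict(
                            qoi=qoi, visit=visit, metric=metric,
                            scheme_a=names[a], scheme_b=names[b],
                            median_a=float(np.median(dists[names[a]])),
                            median_b=float(np.median(dists[names[b]])),
                            ks_stat=stat, p=p))
    scheme_tests = pd.DataFrame(test_rows)

    # ROC: V3 totals (measured and per-scheme predicted) as pCR-surrogate
    # predictors; lower residual tumor indicates response.
    responders = evaluation.responder_labels(cohort, cfg.responder_fraction)
    roc_rows, scores_by_pred = [], {}
    if responders.any() and not responders.all():
        qoi0 = cfg.qois[0]
        h_opt = optimal_h[qoi0].H if qoi0 in optimal_h else cfg.h_range[0]
        preds = {"data": None}
        for scheme in cfg.schemes:
            preds[scheme] = (scheme, qoi0 if scheme == "habitat" else None,
                             h_opt if scheme == "habitat" else 0)
        for quantity in ("ttc", "ttv"):
            for name, spec_ in preds.items():
                scores = []
                for i in range(len(cohort)):
                    if name == "data":
                        field3 = pfs[i]["cell"]["V3"].values
                    else:
                        scheme, qoi, H = spec_
                        field3 = predictions[(i, scheme, qoi, H)][1]
                    vals = field3[pfs[i]["roi"]]
                    if quantity == "ttc":
                        scores.append(float(vals.sum()))
                    else:
                        scores.append(evaluation.tumor_volume(
                            vals, cohort[i].theta, voxvol,
                            cfg.ttv_threshold))
                scores = np.asarray(scores)
                scores_by_pred[(quantity, name)] = scores
                rr = evaluation.roc_auc(scores, responders,
                                        orientation="less")
                roc_rows.append(dict(quantity=quantity, predictor=name,
                                     auc=rr.auc, ci_lo=rr.ci95[0],
                                     ci_hi=rr.ci95[1],
                                     sensitivity=rr.sensitivity,
                                     specificity=rr.specificity))
    roc = pd.DataFrame(roc_rows)
    delong_rows = []
    for quantity in ("ttc", "ttv"):
        keys = [k for k in scores_by_pred if k[0] == quantity]
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                try:
                    p = evaluation.delong_test(-scores_by_pred[keys[a]],
                                               -scores_by_pred[keys[b]],
                                               responders)
                except ValueError:
                    p = np.nan
                delong_rows.append(dict(quantity=quantity,
                                        pred_a=keys[a][1], pred_b=keys[b][1],
                                        p=p))
    delong = pd.DataFrame(delong_rows)

    return StudyReport(config=cfg, metrics=metrics, optimal_h=optimal_h,
                       scheme_tests=scheme_tests, efficiency=efficiency,
                       roc=roc, delong=delong, connectivity=connectivity,
                       responders=responders)


def asdict_safe(cfg) -> str:
    """Stable textual key for a (nested-dataclass) config."""
    def conv(x):
        if hasattr(x, "__dataclass_fields__"):
            return {k: conv(v) for k, v in asdict(x).items()}
        if isinstance(x, (list, tuple)):
            return [conv(v) for v in x]
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        return x
    return json.dumps(conv(cfg), sort_keys=True, default=str)


def write_report(report: StudyReport, out_dir) -> None:
    """Persist the study tables as CSV/JSON plus a Markdown summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.metrics.to_csv(out / "metrics.csv", index=False)
    report.scheme_tests.to_csv(out / "scheme_tests.csv", index=False)
    report.efficiency.to_csv(out / "efficiency.csv", index=False)
    if len(report.roc):
        report.roc.to_csv(out / "roc.csv", index=False)
        report.delong.to_csv(out / "delong.csv", index=False)
    opt = {q: {"H": int(o.H), "qualified": bool(o.qualified)}
           for q, o in report.optimal_h.items()}
    (out / "optimal_h.json").write_text(json.dumps(opt, indent=2))
    lines = ["# Study summary", ""]
    for q, o in report.optimal_h.items():
        lines.append(f"- optimal habitat count ({q.upper()}): {o.H}"
                     f"{'' if o.qualified else ' (no H qualified)'}")
    med = (report.metrics.groupby(["scheme", "visit", "metric"])["error"]
           .median().reset_index())
    lines.append("")
    lines.append(med.to_string(index=False))
    (out / "summary.md").write_text("\n".join(lines) + "\n")
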