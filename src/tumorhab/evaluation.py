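"""Error metrics, optimal-habitat-number selection, and ROC machinery.

Calibration and prediction accuracy are judged by three metrics: absolute
error in the percent change of total tumor cellularity (%dTTC) and of total
tumor volume (%dTTV) between visits, and the mean squared error of the
voxelwise fractional cellularity change, MSE(%dTC(x)).  Cohort distributions
are compared with the two-sample Kolmogorov-Smirnov test; pCR-style
classification performance uses ROC/AUC with DeLong confidence intervals and
the paired DeLong test for AUC differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats


def _values(cell) -> np.ndarray:
    return np.asarray(getattr(cell, "values", cell), dtype=float)


def pct_delta_ttc(cell_a, cell_b) -> float:
    """Percent change in total tumor cellularity, 100 (Σb − Σa)/Σa."""
    a = _values(cell_a).sum()
    b = _values(cell_b).sum()
    if a == 0:
        raise ValueError("total cellularity at the reference visit is zero")
    return 100.0 * (b - a) / a


def tumor_volume(cell, theta: float, voxel_volume: float,
                 threshold_fraction: float = 0.25) -> float:
    """Total tumor volume: count of tumor-bearing voxels × voxel volume."""
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold fraction must be in (0, 1)")
    n = _values(cell)
    return float((n >= threshold_fraction * theta).sum()) * voxel_volume


def pct_delta_ttv(cell_a, cell_b, theta: float, voxel_volume: float = 1.0,
                  threshold_fraction: float = 0.25) -> float:
    """Percent change in total tumor volume between two cellularity fields."""
    va = tumor_volume(cell_a, theta, voxel_volume, threshold_fraction)
    vb = tumor_volume(cell_b, theta, voxel_volume, threshold_fraction)
    if va == 0:
        raise ValueError("no tumor-bearing voxels at the reference visit")
    return 100.0 * (vb - va) / va


def mse_pct_delta_tc(model_a, model_b, data_a, data_b, roi,
                     eps: float = 1.0) -> float:
    """MSE between modeled and measured voxelwise fractional change.

    The per-voxel change (N_b − N_a)/max(N_a, eps) is expressed as a fraction
    (values ~0.1, not percent); ``eps`` of one cell guards voxels empty at the
    reference visit.
    """
    roi = np.asarray(roi, bool)
    if not roi.any():
        raise ValueError("empty ROI")

    def frac_change(a, b):
        a = _values(a)[roi]
        b = _values(b)[roi]
        return (b - a) / np.maximum(a, eps)

    diff = frac_change(model_a, model_b) - frac_change(data_a, data_b)
    return float(np.mean(diff ** 2))


def ks_two_sample(x, y):
    """Two-sample Kolmogorov-Smirnov: sup-norm ECDF distance, asymptotic p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p (normal approximation, tie-corrected)."""
    res = stats.mannwhitneyu(np.asarray(x, float), np.asarray(y, float),
                             alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


class OptimalH(NamedTuple):
    H: int
    qualified: bool           # False: no H passed, H_max returned
    pvalues: dict             # (H, H_prime, metric) -> p


def select_optimal_H(error_tables: dict, alpha: float = 0.05) -> OptimalH:
    """Smallest habitat count whose errors match all larger counts.

    ``error_tables`` maps H -> {metric -> per-patient averaged error array}.
    For each candidate H the distribution of every metric is compared (KS,
    two-sample) against each larger H'; the smallest H with no significant
    difference anywhere (all p >= alpha) wins.  If none qualifies the largest
    H is returned with ``qualified=False``.
    """
    hs = sorted(error_tables)
    if len(hs) < 2:
        raise ValueError("need error tables for at least two habitat counts")
    metrics = sorted(error_tables[hs[0]])
    for h in hs:
        for m in metrics:
            if len(np.atleast_1d(error_tables[h][m])) < 2:
                raise ValueError("KS comparison needs >= 2 patients per cell")
    pvals = {}
    chosen, qualified = hs[-1], False
    for h in hs[:-1]:
        ok = True
        for hp in (x for x in hs if x > h):
            for m in metrics:
                _, p = ks_two_sample(error_tables[h][m], error_tables[hp][m])
                pvals[(h, hp, m)] = p
                ok &= p >= alpha
        if ok:
            chosen, qualified = h, True
            break
    return OptimalH(H=chosen, qualified=qualified, pvalues=pvals)


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong

@dataclass
class RocResult:
    auc: float
    ci95: tuple
    sensitivity: float
    specificity: float
    threshold: float
    orientation: str


def _placements(scores, labels):
    """Placement values: per-positive and per-negative mid-rank comparisons."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("ROC needs both classes present")
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)          # one per positive
    v01 = cmp.mean(axis=0)          # one per negative
    return v10, v01


def roc_auc(scores, labels, orientation: str = "greater") -> RocResult:
    """AUC (Mann-Whitney form), Youden-optimal operating point, DeLong CI.

    ``orientation='greater'`` means larger scores indicate the positive
    class; 'less' flips the predictor.
    """
    s = np.asarray(scores, dtype=float)
    if orientation == "less":
        s = -s
    elif orientation != "greater":
        raise ValueError("orientation must be 'greater' or 'less'")
    y = np.asarray(labels).astype(bool)
    v10, v01 = _placements(s, y)
    auc = float(v10.mean())
    m, n = v10.size, v01.size
    var = (v10.var(ddof=1) / m if m > 1 else 0.0) \
        + (v01.var(ddof=1) / n if n > 1 else 0.0)
    se = np.sqrt(var)
    ci = (max(0.0, auc - 1.959963984540054 * se),
          min(1.0, auc + 1.959963984540054 * se))
    # Youden J over candidate thresholds (each observed score)
    pos, neg = s[y], s[~y]
    cand = np.unique(s)
    best_j, best = -np.inf, (cand[0], 0.0, 0.0)
    for thr in cand:
        sens = float((pos >= thr).mean())
        spec = float((neg < thr).mean())
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best = j, (thr, sens, spec)
    thr, sens, spec = best
    if orientation == "less":
        thr = -thr
    return RocResult(auc=auc, ci95=ci, sensitivity=sens, specificity=spec,
                     threshold=float(thr), orientation=orientation)


def delong_test(scores1, scores2, labels) -> float:
    """Paired DeLong z-test for the difference of two correlated AUCs."""
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("paired scores must have identical shape")
    v10 = np.column_stack([_placements(s, labels)[0] for s in (s1, s2)])
    v01 = np.column_stack([_placements(s, labels)[1] for s in (s1, s2)])
    auc = v10.mean(axis=0)
    d_auc = auc[0] - auc[1]
    m, n = v10.shape[0], v01.shape[0]
    if m < 2 or n < 2:
        raise ValueError("DeLong test needs >= 2 cases per class")
    s10 = np.cov(v10, rowvar=False)
    s01 = np.cov(v01, rowvar=False)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        if abs(d_auc) < 1e-12:
            return 1.0
        raise ValueError("degenerate variance with nonzero AUC difference")
    z = d_auc / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def responder_labels(patients, fraction: float = 0.05) -> np.ndarray:
    """Surrogate pCR labels for phantoms.

    A virtual patient responds when the true V3 total cellularity falls below
    ``fraction`` of the V1 total.  The clinical pCR label cannot be
    synthesized mechanistically; this surrogate gives the ROC machinery a
    ground-truth-linked target.
    """
    out = []
    for p in patients:
        c = p.ground_truth["cellularity"]
        roi = p.ground_truth["region_labels"] > 0
        out.append(c["V3"][roi].sum() < fraction * c["V1"][roi].sum())
    return np.asarray(out, dtype=bool)
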