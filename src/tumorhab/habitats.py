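"""Cohort-level longitudinal habitat analysis.

Every tumor voxel contributes a 4-vector {ADC(V1), ADC(V2), Q(V1), Q(V2)}
with Q one of the perfusion summaries (MSI, PEI, or SER).  Vectors are pooled
over all patients, columns standardized, and k-means splits the pool into H
habitats (H = 2..16).  Habitat indices are re-ordered by increasing mean V1
ADC so the numbering is deterministic, and each habitat receives a high/low
semantic label per feature by comparison with the pooled feature mean.
Spatial-connectivity diagnostics (unneighbored-voxel percentage and a
26-neighborhood interaction matrix) quantify how contiguous the habitats are
even though no spatial information enters the clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

FEATURE_COLUMNS = ("adc_v1", "adc_v2", "q_v1", "q_v2")

_NEIGHBOR_OFFSETS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
     if (i, j, k) != (0, 0, 0)], dtype=np.int64)


@dataclass
class FeatureMatrix:
    """Standardized pooled voxel-feature matrix with row provenance."""

    values: np.ndarray                 # (n_voxels_total, 4), standardized
    raw: np.ndarray                    # same shape, unstandardized
    col_mean: np.ndarray
    col_sd: np.ndarray
    zero_variance: np.ndarray          # per-column guard flags
    patient_ids: np.ndarray            # (n,) int
    voxel_index: list                  # per patient: (n_i, 3) voxel coords
    qoi: str = ""


@dataclass
class HabitatAssignment:
    H: int
    labels: np.ndarray                 # (n,) int in 1..H, pooled row order
    centers: np.ndarray                # (H, 4) standardized space
    semantic_labels: list | None = None
    qoi: str = ""

    def per_patient_maps(self, fm: FeatureMatrix, shape) -> list:
        """Rebuild 3D integer label maps (0 outside ROI) per patient."""
        maps = []
        for pid in np.unique(fm.patient_ids):
            sel = fm.patient_ids == pid
            vol = np.zeros(shape, dtype=np.int32)
            coords = fm.voxel_index[int(pid)]
            vol[coords[:, 0], coords[:, 1], coords[:, 2]] = self.labels[sel]
            maps.append(vol)
        return maps


def build_feature_matrix(patient_features: list, qoi: str) -> FeatureMatrix:
    """Pool per-patient voxel features into one standardized matrix.

    ``patient_features`` holds dicts with keys 'adc' and the chosen qoi, each
    mapping visit ('V1'/'V2') to a 3D map, plus 'roi' (bool volume).  Columns
    with zero variance are flagged and left at zero rather than divided.
    """
    rows, pids, coords_all = [], [], []
    for pid, pf in enumerate(patient_features):
        roi = np.asarray(pf["roi"], bool)
        try:
            block = np.column_stack([
                pf["adc"]["V1"][roi], pf["adc"]["V2"][roi],
                pf[qoi]["V1"][roi], pf[qoi]["V2"][roi]])
        except KeyError as err:
            raise ValueError(
                f"patient {pid}: missing map for {err.args[0]!r}") from None
        rows.append(block)
        pids.append(np.full(block.shape[0], pid))
        coords_all.append(np.argwhere(roi))
    raw = np.vstack(rows)
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)
    # tolerance absorbs accumulation rounding on a truly constant column
    zero_var = sd <= 1e-10 * (np.abs(mean) + 1e-30)
    safe_sd = np.where(zero_var, 1.0, sd)
    std = (raw - mean) / safe_sd
    std[:, zero_var] = 0.0
    return FeatureMatrix(values=std, raw=raw, col_mean=mean, col_sd=sd,
                         zero_variance=zero_var,
                         patient_ids=np.concatenate(pids),
                         voxel_index=coords_all, qoi=qoi)


def cluster_habitats(fm: FeatureMatrix, H: int, seed: int,
                     n_init: int = 10) -> HabitatAssignment:
    """Pooled k-means into H habitats, re-indexed by increasing mean V1 ADC."""
    if not 2 <= H <= 16:
        raise ValueError("H must be in 2..16")
    if fm.values.shape[0] < H:
        raise ValueError("fewer rows than habitats")
    km = KMeans(n_clusters=H, init="k-means++", n_init=n_init, max_iter=300,
                tol=1e-6, random_state=seed)
    raw_labels = km.fit_predict(fm.values)
    if np.unique(raw_labels).size < H:
        raise RuntimeError("k-means produced an empty cluster")
    # order habitats by increasing mean V1 ADC (unstandardized column 0)
    means = np.array([fm.raw[raw_labels == c, 0].mean() for c in range(H)])
    order = np.argsort(means, kind="stable")
    remap = np.empty(H, dtype=np.int64)
    remap[order] = np.arange(1, H + 1)
    labels = remap[raw_labels]
    centers = km.cluster_centers_[order]
    return HabitatAssignment(H=H, labels=labels, centers=centers, qoi=fm.qoi)


def assign_semantic_labels(ha: HabitatAssignment,
                           fm: FeatureMatrix) -> list:
    """Per habitat, 'high'/'low' for each feature vs the pooled mean.

    Strictly greater than the overall mean maps to 'high'; ties go to 'low'.
    """
    overall = fm.raw.mean(axis=0)
    out = []
    for h in range(1, ha.H + 1):
        sel = ha.labels == h
        hab_mean = fm.raw[sel].mean(axis=0)
        out.append(tuple("high" if m > o else "low"
                         for m, o in zip(hab_mean, overall)))
    ha.semantic_labels = out
    return out


def n_label_combinations(n_features: int = 4) -> int:
    """Number of distinct high/low semantic label combinations."""
    return 2 ** n_features


def _neighbor_pairs(labels: np.ndarray, roi: np.ndarray):
    """Ordered (center_label, neighbor_label) pairs over 26-neighborhoods."""
    roi = np.asarray(roi, bool)
    coords = np.argwhere(roi)
    shape = labels.shape
    lab_c, lab_n = [], []
    for off in _NEIGHBOR_OFFSETS:
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < np.array(shape)), axis=1)
        c, n = coords[ok], nb[ok]
        inroi = roi[n[:, 0], n[:, 1], n[:, 2]]
        c, n = c[inroi], n[inroi]
        lab_c.append(labels[c[:, 0], c[:, 1], c[:, 2]])
        lab_n.append(labels[n[:, 0], n[:, 1], n[:, 2]])
    return np.concatenate(lab_c), np.concatenate(lab_n)


def pct_unneighbored(labels: np.ndarray, roi: np.ndarray) -> dict:
    """Percentage of each habitat's voxels with no same-habitat 26-neighbor.

    Neighbors outside the ROI are ignored; empty habitats report NaN.
    """
    roi = np.asarray(roi, bool)
    coords = np.argwhere(roi)
    shape = labels.shape
    has_mate = np.zeros(coords.shape[0], dtype=bool)
    center_lab = labels[coords[:, 0], coords[:, 1], coords[:, 2]]
    for off in _NEIGHBOR_OFFSETS:
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < np.array(shape)), axis=1)
        same = np.zeros(coords.shape[0], dtype=bool)
        c_ok = coords[ok]
        n_ok = nb[ok]
        inroi = roi[n_ok[:, 0], n_ok[:, 1], n_ok[:, 2]]
        idx = np.nonzero(ok)[0][inroi]
        same[idx] = (labels[n_ok[inroi, 0], n_ok[inroi, 1], n_ok[inroi, 2]]
                     == center_lab[idx])
        has_mate |= same
    out = {}
    for h in np.unique(center_lab):
        sel = center_lab == h
        out[int(h)] = 100.0 * float((~has_mate[sel]).sum()) / float(sel.sum())
    return out


def spatial_interaction_matrix(labels: np.ndarray, roi: np.ndarray,
                               H: int) -> np.ndarray:
    """Row-normalized 26-neighbor co-occurrence of habitat labels.

    Entry (a, b) is the fraction of ordered neighbor pairs whose center lies
    in habitat a and neighbor in habitat b; the diagonal measures
    within-habitat spatial connectivity.  Absent habitats yield NaN rows.
    """
    lab_c, lab_n = _neighbor_pairs(labels, roi)
    mat = np.zeros((H, H))
    np.add.at(mat, (lab_c - 1, lab_n - 1), 1.0)
    sums = mat.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = mat / sums
    out[sums[:, 0] == 0] = np.nan
    return out


def diagonal_index(labels: np.ndarray, roi: np.ndarray, H: int) -> float:
    """Mean diagonal of the spatial interaction matrix over present habitats."""
    mat = spatial_interaction_matrix(labels, roi, H)
    d = np.diag(mat)
    return float(np.nanmean(d))


def shuffled_connectivity_test(label_maps: list, rois: list, H: int,
                               n_shuffles: int, seed: int):
    """Cohort test: are habitats more contiguous than size-matched shuffles?

    For each patient the diagonal interaction index of the true habitat map is
    compared against the average index over ``n_shuffles`` random permutations
    of labels within the ROI (habitat sizes preserved).  The two cohort
    samples are compared with a two-sided Wilcoxon rank-sum test.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    rng = np.random.default_rng(seed)
    true_idx, null_idx = [], []
    for labels, roi in zip(label_maps, rois):
        roi = np.asarray(roi, bool)
        true_idx.append(diagonal_index(labels, roi, H))
        vals = labels[roi]
        acc = []
        for _ in range(n_shuffles):
            shuf = np.zeros_like(labels)
            shuf[roi] = rng.permutation(vals)
            acc.append(diagonal_index(shuf, roi, H))
        null_idx.append(float(np.mean(acc)))
    from .evaluation import wilcoxon_rank_sum
    p = wilcoxon_rank_sum(true_idx, null_idx)
    return p, np.asarray(true_idx), np.asarray(null_idx)
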