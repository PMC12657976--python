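"""Synthetic multi-visit breast-MRI phantoms with known ground truth.

A virtual patient carries a baseline (V1) cellularity field partitioned into
spatially contiguous subregions of distinct proliferation and perfusion
character, DW-MRI signal pairs consistent with the mono-exponential decay and
the ADC-cellularity inversion, DCE curves whose semi-quantitative summaries
(MSI/PEI/SER) separate the subregions, and follow-up visits (V2, V3) produced
by the forward model from known parameters under an A/C dosing schedule.
The clinical study conditions being emulated: visits at baseline, after two,
and after four 21-day chemotherapy cycles (days 0 / 42 / 84).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import features
from .features import DCETimecourse, ADC_WATER, DCE_FRAME_TIMES
from .forward_model import ModelParameterSet, TherapySchedule, simulate
from .mechanics import MechanicalParams, two_tissue_modulus


@dataclass
class RegionArchetype:
    """Per-subregion generative parameters.

    adc_range brackets the true ADC draw (mm²/s); the DCE curve is a
    piecewise-linear bolus: baseline until ``onset_s``, linear wash-in to
    ``baseline + amplitude`` at ``peak_s``, then linear wash-out to
    ``baseline + plateau_frac * amplitude`` at 360 s.
    """

    name: str
    k: float                      # proliferation rate, day^-1
    adc_range: tuple              # (lo, hi) mm^2/s
    dce_baseline: float = 100.0
    dce_amplitude: float = 120.0
    dce_onset_s: float = 30.0
    dce_peak_s: float = 60.0
    dce_plateau_frac: float = 1.0


DEFAULT_ARCHETYPES = (
    # dense, well-perfused, fast-proliferating: sharp early bolus w/ washout;
    # drug reaches it readily, so it responds strongly
    RegionArchetype("perfused-dense", k=0.15, adc_range=(0.8e-3, 1.2e-3),
                    dce_amplitude=160.0, dce_onset_s=30.0, dce_peak_s=40.0,
                    dce_plateau_frac=0.85),
    # dense, aggressive, poorly perfused core: late weak enhancement means
    # little drug arrives, and the region regrows between doses
    RegionArchetype("hypoperfused-dense", k=0.14, adc_range=(1.1e-3, 1.5e-3),
                    dce_amplitude=60.0, dce_onset_s=190.0, dce_peak_s=330.0,
                    dce_plateau_frac=1.0),
    # sparse, indolent, similarly poorly perfused rim: low cellularity and
    # near-zero proliferation
    RegionArchetype("sparse-rim", k=0.002, adc_range=(1.6e-3, 2.2e-3),
                    dce_amplitude=45.0, dce_onset_s=180.0, dce_peak_s=340.0,
                    dce_plateau_frac=1.0),
)

#: normal fibroglandular tissue outside the tumor ROI.  Its ADC sits below
#: free water, so the inversion assigns it a nonzero apparent cellularity —
#: as in vivo — but below the tumor-bearing threshold (0.25 theta).
BACKGROUND_ARCHETYPE = RegionArchetype(
    "background", k=0.0, adc_range=(2.3e-3, 2.45e-3), dce_amplitude=30.0,
    dce_onset_s=60.0, dce_peak_s=350.0, dce_plateau_frac=1.0)


@dataclass
class PhantomConfig:
    grid_shape: tuple = (32, 32, 16)
    voxel_size_mm: tuple = (1.0, 1.0, 1.5)
    n_regions: int = 3
    region_archetypes: tuple = DEFAULT_ARCHETYPES
    dwi_noise_sd: float = 0.0       # multiplicative, fraction of signal
    dce_noise_sd: float = 0.0       # additive, signal units
    dce_voxel_jitter: float = 0.2   # fractional within-region timing spread
    dce_depth_delay_s_per_mm: float = 12.0  # wash-in delay with tumor depth
    k_voxel_jitter: float = 0.0     # lognormal sigma of within-region k spread
    visit_days: tuple = (0.0, 42.0, 84.0)
    seed: int = 0
    alpha: float = 2.8              # true drug efficacy, day^-1
    d0: float = 0.05                # mm^2/day
    s0_dwi: float = 1000.0
    tumor_semiaxes_mm: tuple = (7.0, 7.0, 6.0)
    breast_semiaxes_mm: tuple = (14.0, 14.0, 10.0)
    mech: dict = field(default_factory=lambda: dict(
        e_tumor=20.0, e_background=2.0, nu=0.45, kappa=1.0, gamma=2.0e-2))
    stress_interval_days: float = 1.0
    dt_days: float = 0.25
    seg_threshold: float = 0.4      # follow-up segmentation level, fraction of theta

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        days = tuple(self.visit_days)
        if days[0] != 0 or any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("visit_days must start at 0, strictly increasing")
        if self.dwi_noise_sd < 0 or self.dce_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.n_regions < 1:
            raise ValueError("need at least one region")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def theta(self) -> float:
        return features.carrying_capacity(self.voxel_volume)

    @property
    def adc_min(self) -> float:
        return min(a.adc_range[0]
                   for a in self.region_archetypes[:self.n_regions])


@dataclass
class VirtualPatient:
    config: PhantomConfig
    dwi: dict                  # visit -> (S_b100, S_b800)
    dce: dict                  # visit -> DCETimecourse (raw)
    roi_masks: dict            # visit -> bool volume
    breast_mask: np.ndarray
    schedule: TherapySchedule
    theta: float
    ground_truth: dict         # labels, k_field, alpha, cellularity, drug_map

    @property
    def modeling_roi(self) -> np.ndarray:
        """Union of the V1 and V2 tumor segmentations."""
        return self.roi_masks["V1"] | self.roi_masks["V2"]

    @property
    def spacing(self) -> tuple:
        return self.config.voxel_size_mm

    def mechanical_params(self) -> MechanicalParams:
        m = self.config.mech
        E = two_tissue_modulus(self.breast_mask, self.roi_masks["V1"],
                               m["e_tumor"], m["e_background"])
        return MechanicalParams(E=E, nu=m["nu"], kappa=m["kappa"],
                                gamma=m["gamma"])


def _ellipsoid_mask(shape, spacing, center_mm, semiaxes_mm):
    grids = np.meshgrid(*[np.arange(s) * h for s, h in zip(shape, spacing)],
                        indexing="ij")
    r2 = sum(((g - c) / a) ** 2
             for g, c, a in zip(grids, center_mm, semiaxes_mm))
    return r2 <= 1.0


def generate_cellularity_field(config: PhantomConfig, seed: int,
                               background: RegionArchetype = BACKGROUND_ARCHETYPE):
    """Baseline cellularity with contiguous Voronoi subregions.

    Returns (cellularity, region_labels) where labels are 1..n_regions inside
    the tumor ROI and 0 elsewhere.  Breast tissue outside the tumor carries a
    low apparent cellularity drawn from the background archetype (normal
    tissue ADC sits below free water).  The lowest-ADC voxel is pinned to the
    carrying capacity so the observed minimum ADC equals the generative one.
    """
    rng = np.random.default_rng(seed)
    shape = config.grid_shape
    spacing = config.voxel_size_mm
    center = [0.5 * (s - 1) * h for s, h in zip(shape, spacing)]
    roi = _ellipsoid_mask(shape, spacing, center, config.tumor_semiaxes_mm)
    breast = _ellipsoid_mask(shape, spacing, center, config.breast_semiaxes_mm)
    coords = np.argwhere(roi)
    if config.n_regions > coords.shape[0]:
        raise ValueError(
            f"{config.n_regions} regions exceed ROI size {coords.shape[0]}")
    pos_mm = coords * np.asarray(spacing)
    # seeded Voronoi growth: pick distinct seed voxels, label by nearest seed
    seed_idx = rng.choice(coords.shape[0], size=config.n_regions,
                          replace=False)
    seeds_mm = pos_mm[seed_idx]
    d2 = ((pos_mm[:, None, :] - seeds_mm[None, :, :]) ** 2).sum(axis=2)
    owner = d2.argmin(axis=1)
    labels = np.zeros(shape, dtype=np.int32)
    labels[roi] = owner + 1

    theta = config.theta
    adc_min = config.adc_min
    cell = np.zeros(shape, dtype=float)
    bg = breast & ~roi
    adc_bg = rng.uniform(background.adc_range[0], background.adc_range[1],
                         size=int(bg.sum()))
    cell[bg] = theta * (ADC_WATER - adc_bg) / (ADC_WATER - adc_min)
    for i in range(config.n_regions):
        arch = config.region_archetypes[i]
        m = labels == (i + 1)
        adc = rng.uniform(arch.adc_range[0], arch.adc_range[1],
                          size=int(m.sum()))
        cell[m] = theta * (ADC_WATER - adc) / (ADC_WATER - adc_min)
    cell = np.clip(cell, 0.0, theta)
    # anchor: densest voxel sits exactly at theta (observed ADC_min == adc_min)
    dense = np.unravel_index(np.argmax(cell), shape)
    cell[dense] = theta
    return cell, labels


def synthesize_dwi(cellularity: np.ndarray, theta: float, adc_min: float,
                   noise_sd: float, seed: int, s0: float = 1000.0,
                   b_values=(100.0, 800.0)):
    """DWI signal pair from cellularity via the inverted ADC relationship."""
    n = np.asarray(cellularity, dtype=float)
    if np.any(n < -1e-9) or np.any(n > theta * (1 + 1e-9)):
        raise ValueError("cellularity outside [0, theta]")
    if adc_min >= ADC_WATER:
        raise ValueError("adc_min must be below the free-water ADC")
    adc = ADC_WATER - (n / theta) * (ADC_WATER - adc_min)
    rng = np.random.default_rng(seed)
    out = []
    for b in b_values:
        sig = s0 * np.exp(-b * adc)
        if noise_sd > 0:
            sig = sig * (1.0 + noise_sd * rng.standard_normal(sig.shape))
        out.append(sig)
    return tuple(out)


def _bolus_curves(t: np.ndarray, baseline, amplitude, onset, peak,
                  plateau_frac) -> np.ndarray:
    """Vectorized piecewise-linear bolus curves, one row per voxel."""
    b = np.atleast_1d(baseline)[:, None]
    a = np.atleast_1d(amplitude)[:, None]
    t0 = np.atleast_1d(onset)[:, None]
    tp = np.atleast_1d(peak)[:, None]
    pl = np.atleast_1d(plateau_frac)[:, None]
    tt = t[None, :]
    rise = np.clip((tt - t0) / np.maximum(tp - t0, 1e-9), 0.0, 1.0)
    fall = np.clip((tt - tp) / np.maximum(t[-1] - tp, 1e-9), 0.0, 1.0)
    # linear rise 0 -> 1 until the peak, then linear fall 1 -> plateau_frac
    frac = np.where(tt <= tp, rise, 1.0 - fall * (1.0 - pl))
    return b + a * frac


def synthesize_dce(region_labels: np.ndarray, archetypes, frame_times,
                   noise_sd: float, seed: int,
                   background: RegionArchetype = BACKGROUND_ARCHETYPE,
                   visit: str = "", voxel_jitter: float = 0.2,
                   jitter_seed: int | None = None,
                   depth_delay: np.ndarray | None = None) -> DCETimecourse:
    """4D DCE signal: archetypal bolus curves with per-voxel timing jitter.

    Each voxel draws its wash-in onset and peak time within ``voxel_jitter``
    (fractional) of its region archetype, emulating smooth within-habitat
    perfusion variation; ``depth_delay`` (seconds per voxel) additionally
    postpones wash-in toward the tumor core, where contrast arrives late.
    ``jitter_seed`` fixes the per-voxel curve shapes independently of the
    additive noise seed, so repeated visits image the same underlying
    perfusion pattern.
    """
    t = np.asarray(frame_times, dtype=float)
    labels = np.asarray(region_labels)
    nvox = labels.size
    flat = labels.reshape(-1)
    jrng = np.random.default_rng(seed if jitter_seed is None else jitter_seed)
    base = np.empty(nvox)
    amp = np.empty(nvox)
    onset = np.empty(nvox)
    peak = np.empty(nvox)
    plateau = np.empty(nvox)
    for lab in np.unique(flat):
        arch = background if lab == 0 else archetypes[lab - 1]
        m = flat == lab
        n = int(m.sum())
        base[m] = arch.dce_baseline
        amp[m] = arch.dce_amplitude
        onset[m] = arch.dce_onset_s * (1 + voxel_jitter
                                       * jrng.uniform(-1, 1, n))
        peak[m] = arch.dce_peak_s * (1 + voxel_jitter
                                     * jrng.uniform(-1, 1, n))
        plateau[m] = np.clip(arch.dce_plateau_frac
                             + 0.5 * voxel_jitter * jrng.uniform(-1, 1, n),
                             0.0, 1.0)
    if depth_delay is not None:
        shift = np.asarray(depth_delay, dtype=float).reshape(-1)
        onset = onset + shift
        peak = peak + shift
    onset = np.clip(onset, 0.0, t[-1] - 20.0)
    peak = np.clip(peak, onset + 10.0, t[-1] - 2.0)
    sig = _bolus_curves(t, base, amp, onset, peak, plateau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + noise_sd * rng.standard_normal(sig.shape)
    return DCETimecourse(signal=sig.reshape(labels.shape + (t.size,)),
                         frame_times=t, visit=visit)


def generate_virtual_patient(config: PhantomConfig) -> VirtualPatient:
    """Full multi-visit phantom: V1 drawn, V2/V3 run forward from truth."""
    shape = config.grid_shape
    spacing = config.voxel_size_mm
    center = [0.5 * (s - 1) * h for s, h in zip(shape, spacing)]
    breast = _ellipsoid_mask(shape, spacing, center, config.breast_semiaxes_mm)

    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(8)
    cell_v1, labels = generate_cellularity_field(config, int(seeds[0]))
    roi_v1 = labels > 0
    theta = config.theta

    archetypes = config.region_archetypes[:config.n_regions]
    jitter_seed = int(seeds[7])
    # contrast wash-in is delayed with depth into the tumor
    from scipy.ndimage import distance_transform_edt
    depth_mm = distance_transform_edt(roi_v1, sampling=spacing)
    depth_delay = config.dce_depth_delay_s_per_mm * depth_mm
    # noiseless V1 DCE defines the ground-truth drug-delivery map C(x)
    dce_clean = synthesize_dce(labels, archetypes, DCE_FRAME_TIMES, 0.0, 0,
                               visit="V1",
                               voxel_jitter=config.dce_voxel_jitter,
                               jitter_seed=jitter_seed,
                               depth_delay=depth_delay)
    drug_map = features.drug_concentration(features.normalize_dce(dce_clean),
                                           breast)

    n_cycles = int(np.ceil(config.visit_days[-1] / 21.0))
    schedule = TherapySchedule.ac_schedule(n_cycles=n_cycles)

    k_field = np.zeros(shape, dtype=float)
    for i, arch in enumerate(archetypes):
        k_field[labels == (i + 1)] = arch.k
    if config.k_voxel_jitter > 0:
        # within-region proliferative heterogeneity (mean-one lognormal)
        krng = np.random.default_rng(int(seeds[7]) ^ 0x5f5f)
        sig = config.k_voxel_jitter
        mult = np.exp(sig * krng.standard_normal(shape) - 0.5 * sig ** 2)
        k_field = np.clip(k_field * mult, 0.0, 0.5)

    m = config.mech
    E = two_tissue_modulus(breast, roi_v1, m["e_tumor"], m["e_background"])
    mech = MechanicalParams(E=E, nu=m["nu"], kappa=m["kappa"],
                            gamma=m["gamma"])
    params = ModelParameterSet(scheme="local", k=k_field, alpha=config.alpha,
                               d0=config.d0)
    sim = simulate(params, cell_v1, theta, schedule, roi_v1, breast,
                   drug_map, t_end=config.visit_days[-1],
                   output_times=list(config.visit_days[1:]),
                   dt=config.dt_days, spacing=spacing, mech=mech,
                   stress_interval=config.stress_interval_days)
    cell = {"V1": cell_v1}
    for name, snap in zip(("V2", "V3"), sim.snapshots):
        cell[name] = snap

    dwi, dce = {}, {}
    for j, visit in enumerate(("V1", "V2", "V3")):
        dwi[visit] = synthesize_dwi(cell[visit], theta, config.adc_min,
                                    config.dwi_noise_sd, int(seeds[1 + j]),
                                    s0=config.s0_dwi)
        dce[visit] = synthesize_dce(labels, archetypes, DCE_FRAME_TIMES,
                                    config.dce_noise_sd, int(seeds[4 + j]),
                                    visit=visit,
                                    voxel_jitter=config.dce_voxel_jitter,
                                    jitter_seed=jitter_seed,
                                    depth_delay=depth_delay)

    # follow-up segmentation: appreciable residual disease, above any
    # background-tissue apparent cellularity
    roi_masks = {"V1": roi_v1}
    for visit in ("V2", "V3"):
        roi_masks[visit] = cell[visit] >= config.seg_threshold * theta

    gt = dict(region_labels=labels, k_field=k_field, alpha=config.alpha,
              cellularity=cell, drug_map=drug_map, adc_min=config.adc_min)
    return VirtualPatient(config=config, dwi=dwi, dce=dce,
                          roi_masks=roi_masks, breast_mask=breast,
                          schedule=schedule, theta=theta, ground_truth=gt)


def generate_cohort(n_patients: int, config: PhantomConfig,
                    seed: int) -> list:
    """Deterministic cohort with per-patient archetype jitter."""
    if n_patients < 1:
        raise ValueError("need at least one patient")
    master = np.random.SeedSequence(seed)
    cohort = []
    for child in master.spawn(n_patients):
        state = child.generate_state(2)
        rng = np.random.default_rng(int(state[0]))
        archs = []
        for arch in config.region_archetypes[:config.n_regions]:
            lo, hi = arch.adc_range
            shift = rng.uniform(-0.03e-3, 0.03e-3)
            archs.append(RegionArchetype(
                name=arch.name,
                k=arch.k * rng.uniform(0.85, 1.15),
                adc_range=(max(lo + shift, 0.5e-3), hi + shift),
                dce_baseline=arch.dce_baseline,
                dce_amplitude=arch.dce_amplitude * rng.uniform(0.9, 1.1),
                dce_onset_s=arch.dce_onset_s,
                dce_peak_s=float(np.clip(
                    arch.dce_peak_s * rng.uniform(0.95, 1.05), 35.0, 355.0)),
                dce_plateau_frac=arch.dce_plateau_frac,
            ))
        cfg = dataclasses.replace(
            config,
            region_archetypes=tuple(archs),
            seed=int(state[1]),
            alpha=config.alpha * rng.uniform(0.8, 1.2),
            tumor_semiaxes_mm=tuple(
                a * rng.uniform(0.85, 1.1) for a in config.tumor_semiaxes_mm),
            mech=dict(config.mech),
        )
        cohort.append(generate_virtual_patient(cfg))
    return cohort


# ---------------------------------------------------------------------------
# on-disk representation (NIfTI volumes + JSON sidecars)

def write_patient(patient: VirtualPatient, out_dir) -> None:
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(patient.spacing) + [1.0])

    def save(name, arr):
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine),
                 str(out / f"{name}.nii.gz"))

    for visit, (s_lo, s_hi) in patient.dwi.items():
        save(f"dwi_b100_{visit}", s_lo)
        save(f"dwi_b800_{visit}", s_hi)
    for visit, tc in patient.dce.items():
        save(f"dce_{visit}", tc.signal)
    for visit, m in patient.roi_masks.items():
        save(f"roi_{visit}", m.astype(np.uint8))
    save("breast_mask", patient.breast_mask.astype(np.uint8))
    save("gt_region_labels", patient.ground_truth["region_labels"])
    save("gt_k_field", patient.ground_truth["k_field"])
    save("gt_drug_map", patient.ground_truth["drug_map"])
    for visit, c in patient.ground_truth["cellularity"].items():
        save(f"gt_cellularity_{visit}", c)
    meta = dict(theta=patient.theta, alpha=patient.ground_truth["alpha"],
                adc_min=patient.ground_truth["adc_min"],
                visit_days=list(patient.config.visit_days),
                schedule=patient.schedule.to_dict())
    (out / "patient.json").write_text(json.dumps(meta, indent=2))
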