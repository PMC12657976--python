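"""Mechanically coupled reaction-diffusion model of tumor response to therapy.

The tumor cell number N_TC(x, t) evolves as

    dN/dt = div( D(x,t) grad N ) + k(x) N (1 - N/theta)
            - alpha N C(x) * sum_{i,j} exp(-beta_j (t - tau_ij))

with diffusion damped by von Mises stress (D = D0 exp(-gamma sigma_vm)),
logistic proliferation at rate k(x), and exponential drug kill driven by the
normalized delivery map C(x) and the post-dose decay of each drug.

Integration is explicit Euler in flux-conservative form with a no-flux
condition at the breast-mask boundary; the therapy factor is evaluated at the
step midpoint (the term is a known function of time, so midpoint quadrature
removes the dominant O(dt) error of left-endpoint sampling).  The stress
field, hence D, is refreshed on a configurable interval (default daily)
rather than every transport step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mechanics import ElasticitySolver, MechanicalParams, damped_diffusivity

_AXES = (0, 1, 2)


@dataclass
class TherapySchedule:
    """Drug decay rates beta_j (day^-1) and dose times tau_ij (days)."""

    drugs: dict  # name -> {"beta": float, "dose_days": list[float]}

    def __post_init__(self) -> None:
        for name, d in self.drugs.items():
            if d["beta"] <= 0:
                raise ValueError(f"beta for {name} must be positive")
            days = sorted(float(t) for t in d["dose_days"])
            if days and days[0] < 0:
                raise ValueError("dose times must be nonnegative")
            d["dose_days"] = days

    def to_dict(self) -> dict:
        return {k: {"beta": v["beta"], "dose_days": list(v["dose_days"])}
                for k, v in self.drugs.items()}

    @classmethod
    def ac_schedule(cls, n_cycles: int = 4, cycle_days: float = 21.0,
                    beta_adriamycin: float = 1.0,
                    beta_cytoxan: float = 2.0) -> "TherapySchedule":
        """Standard A/C regimen: both drugs at the start of each 21-day cycle."""
        days = [i * cycle_days for i in range(n_cycles)]
        return cls({
            "adriamycin": {"beta": beta_adriamycin, "dose_days": list(days)},
            "cytoxan": {"beta": beta_cytoxan, "dose_days": list(days)},
        })


def therapy_factor(schedule: TherapySchedule, t: float) -> float:
    """Sum over past doses of exp(-beta_j (t - tau_ij)); future doses are 0."""
    total = 0.0
    for d in schedule.drugs.values():
        beta = d["beta"]
        for tau in d["dose_days"]:
            if tau <= t:
                total += np.exp(-beta * (t - tau))
    return total


@dataclass
class ModelParameterSet:
    """Proliferation/efficacy parameterization for one patient.

    scheme : 'global' (one k), 'habitat' (one k per habitat), or 'local'
    (one k per ROI voxel).  alpha is always global.
    """

    scheme: str
    k: np.ndarray            # scalar-like, (H,), or full 3D field
    alpha: float
    d0: float = 0.05         # mm^2/day, stress-free diffusivity
    habitat_map: np.ndarray | None = None   # int labels 1..H inside ROI

    def __post_init__(self) -> None:
        if self.scheme not in ("global", "habitat", "local"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")


def expand_k(params: ModelParameterSet, roi: np.ndarray) -> np.ndarray:
    """Broadcast the scheme's k parameterization to a voxel field (0 off-ROI)."""
    roi = np.asarray(roi, bool)
    out = np.zeros(roi.shape, dtype=float)
    if params.scheme == "global":
        out[roi] = float(np.asarray(params.k).reshape(-1)[0])
    elif params.scheme == "habitat":
        if params.habitat_map is None:
            raise ValueError("habitat scheme requires a habitat map")
        kvals = np.asarray(params.k, dtype=float).reshape(-1)
        labels = params.habitat_map[roi]
        present = np.unique(labels)
        if present.min() < 1 or present.max() > kvals.size:
            raise ValueError("habitat label without a k value")
        out[roi] = kvals[labels - 1]
    else:  # local
        kf = np.asarray(params.k, dtype=float)
        if kf.shape == roi.shape:
            out[roi] = kf[roi]
        else:
            vals = kf.reshape(-1)
            if vals.size != int(roi.sum()):
                raise ValueError("local k vector does not match ROI size")
            out[roi] = vals
    return out


@dataclass
class SimulationResult:
    times: np.ndarray
    snapshots: np.ndarray        # (n_times, nx, ny, nz)
    total_cells: np.ndarray      # per snapshot
    dt_used: float
    n_steps: int


def _face_masks(mask):
    """Per-axis boolean arrays marking interior faces (both sides in mask)."""
    faces = []
    for ax in _AXES:
        sl_lo = [slice(None)] * 3
        sl_lo[ax] = slice(0, -1)
        sl_hi = [slice(None)] * 3
        sl_hi[ax] = slice(1, None)
        faces.append(mask[tuple(sl_lo)] & mask[tuple(sl_hi)])
    return faces


def _diffusion_term(n_tc, d_field, mask, faces, spacing):
    """Flux-form div(D grad N) with zero flux across the mask boundary."""
    out = np.zeros_like(n_tc)
    for ax in _AXES:
        h = spacing[ax]
        sl_lo = [slice(None)] * 3
        sl_lo[ax] = slice(0, -1)
        sl_hi = [slice(None)] * 3
        sl_hi[ax] = slice(1, None)
        sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)
        d_face = 0.5 * (d_field[sl_lo] + d_field[sl_hi])
        flux = np.where(faces[ax], d_face * (n_tc[sl_hi] - n_tc[sl_lo]) / h, 0.0)
        div = np.zeros_like(n_tc)
        div[sl_lo] += flux / h
        div[sl_hi] -= flux / h
        out += div
    return out


def stable_dt(d_max: float, spacing, margin: float = 0.9) -> float:
    """Explicit-Euler diffusion stability bound dt <= h_min^2 / (6 D_max)."""
    if d_max <= 0:
        return np.inf
    h_min = min(spacing)
    return margin * h_min ** 2 / (6.0 * d_max)


def simulate(params: ModelParameterSet,
             init: np.ndarray,
             theta: float,
             schedule: TherapySchedule,
             roi: np.ndarray,
             breast_mask: np.ndarray,
             drug_map: np.ndarray,
             t_end: float,
             output_times,
             dt: float = 0.25,
             spacing=(1.0, 1.0, 1.0),
             mech: MechanicalParams | None = None,
             solver: ElasticitySolver | None = None,
             stress_interval: float = 1.0,
             clip: bool = True) -> SimulationResult:
    """Integrate the model from t=0 to t_end, returning snapshots.

    ``solver`` may be passed to reuse a prefactorized elasticity operator
    (it must have been built with ``mech`` and ``breast_mask``).  When both
    ``mech`` and ``solver`` are None, or gamma == 0, diffusion is unmixed
    (D = D0 everywhere).
    """
    n = np.asarray(init, dtype=float).copy()
    if np.any(n < -1e-9) or np.any(n > theta * (1 + 1e-9)):
        raise ValueError("initial cellularity outside [0, theta]")
    n = np.clip(n, 0.0, theta)
    mask = np.asarray(breast_mask, bool)
    faces = _face_masks(mask)
    k_field = expand_k(params, roi)
    c_field = np.asarray(drug_map, dtype=float)

    gamma = mech.gamma if mech is not None else 0.0
    use_mech = params.d0 > 0 and gamma > 0 and mech is not None
    if use_mech and solver is None:
        solver = ElasticitySolver(mech, mask, spacing)

    output_times = np.sort(np.asarray(output_times, dtype=float))
    if output_times.size == 0 or output_times[-1] > t_end + 1e-9:
        raise ValueError("output_times must be nonempty and within t_end")

    d_field = np.full(n.shape, params.d0, dtype=float)
    if use_mech:
        svm = solver.solve(n, theta).von_mises
        d_field = damped_diffusivity(params.d0, gamma, svm)

    dt_use = min(dt, stable_dt(params.d0, spacing))
    snaps, totals = [], []
    t = 0.0
    next_stress = stress_interval
    n_steps = 0
    checkpoints = list(output_times)
    for t_target in checkpoints:
        while t < t_target - 1e-12:
            sub = min(dt_use, t_target - t)
            if use_mech:
                sub = min(sub, max(next_stress - t, 1e-9))
            rate = (_diffusion_term(n, d_field, mask, faces, spacing)
                    + k_field * n * (1.0 - n / theta)
                    - params.alpha * n * c_field
                    * therapy_factor(schedule, t + sub / 2))
            n = n + sub * rate
            if not np.all(np.isfinite(n)):
                raise FloatingPointError(
                    f"non-finite cellularity at t={t + sub:.4f} d "
                    f"(dt={sub:.4g}); reduce dt")
            if clip:
                np.clip(n, 0.0, theta, out=n)
            t += sub
            n_steps += 1
            if use_mech and t >= next_stress - 1e-9:
                svm = solver.solve(n, theta).von_mises
                d_field = damped_diffusivity(params.d0, gamma, svm)
                next_stress += stress_interval
        snaps.append(n.copy())
        totals.append(float(n.sum()))
    return SimulationResult(times=output_times,
                            snapshots=np.stack(snaps),
                            total_cells=np.asarray(totals),
                            dt_used=dt_use, n_steps=n_steps)
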