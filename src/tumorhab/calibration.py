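"""Patient-specific calibration of proliferation and drug efficacy.

The forward model is fit to the V1 -> V2 cellularity data with a
Levenberg-Marquardt optimizer; the proliferation rate k(x) is parameterized
globally (one value), per habitat (one per habitat), or locally (one per ROI
voxel), and the drug efficacy alpha is always global.  Box bounds are
enforced through a logistic reparameterization so LM itself is unconstrained.
The fitted parameters then drive the model to V3 for prediction.

Jacobians are forward finite differences.  For the local scheme, where one
simulation per voxel parameter would be prohibitive, voxels are grouped into
lattice color classes (2-voxel spacing per axis, 8 classes) and perturbed
together; each perturbed voxel's sensitivity is read off the residual rows
within its 1-voxel neighborhood.  This structured differencing is accurate
because the cell diffusion length between visits is about a voxel; LM
accepts or rejects steps on exact residuals, so the grouping affects cost,
not the objective.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .forward_model import ModelParameterSet, TherapySchedule, simulate
from .mechanics import ElasticitySolver, MechanicalParams

K_BOUNDS = (0.0, 0.5)       # day^-1, physiologic doubling times
ALPHA_BOUNDS = (0.0, 5.0)   # day^-1, exponential drug-kill scale
K_INIT = 0.05
ALPHA_INIT = 0.1


@dataclass
class CalibrationProblem:
    cell_v1: np.ndarray
    cell_v2: np.ndarray
    roi: np.ndarray
    breast_mask: np.ndarray
    theta: float
    drug_map: np.ndarray
    schedule: TherapySchedule
    scheme: str
    t_v2: float = 42.0
    t_v3: float = 84.0
    habitat_map: np.ndarray | None = None
    d0: float = 0.05
    mech: MechanicalParams | None = None
    spacing: tuple = (1.0, 1.0, 1.0)
    dt: float = 0.25
    stress_interval: float = 1.0
    k_bounds: tuple = K_BOUNDS
    alpha_bounds: tuple = ALPHA_BOUNDS
    max_iter: int = 100
    tol: float = 1e-6
    fd_step: float = 1e-3

    def __post_init__(self) -> None:
        self.roi = np.asarray(self.roi, bool)
        self.breast_mask = np.asarray(self.breast_mask, bool)
        if self.cell_v1.shape != self.cell_v2.shape:
            raise ValueError("V1/V2 grids differ")
        if self.k_bounds[0] >= self.k_bounds[1] \
                or self.alpha_bounds[0] >= self.alpha_bounds[1]:
            raise ValueError("bounds must satisfy min < max")
        if self.scheme == "habitat" and self.habitat_map is None:
            raise ValueError("habitat scheme needs a habitat map")
        self._solver = None
        self._roi_coords = np.argwhere(self.roi)

    def set_solver(self, solver: ElasticitySolver) -> None:
        """Attach a prefactorized elasticity solver (shared across problems)."""
        self._solver = solver

    @property
    def n_voxels(self) -> int:
        return int(self.roi.sum())

    @property
    def n_habitats(self) -> int:
        if self.habitat_map is None:
            return 0
        return int(self.habitat_map[self.roi].max())

    @property
    def n_k(self) -> int:
        return {"global": 1, "habitat": self.n_habitats,
                "local": self.n_voxels}[self.scheme]

    def solver(self) -> ElasticitySolver | None:
        """Prefactorized elasticity operator, shared across simulations."""
        if self.mech is None or self.mech.gamma == 0 or self.d0 == 0:
            return None
        if self._solver is None:
            self._solver = ElasticitySolver(self.mech, self.breast_mask,
                                            self.spacing)
        return self._solver

    def bounds_vector(self):
        nk = self.n_k
        lo = np.r_[np.full(nk, self.k_bounds[0]), self.alpha_bounds[0]]
        hi = np.r_[np.full(nk, self.k_bounds[1]), self.alpha_bounds[1]]
        return lo, hi

    def initial_vector(self) -> np.ndarray:
        return np.r_[np.full(self.n_k, K_INIT), ALPHA_INIT]


def count_parameters(scheme: str, H: int = 0, n_voxels: int = 0) -> int:
    """2 for global, H+1 for habitat, n_voxels+1 for local."""
    if scheme == "global":
        return 2
    if scheme == "habitat":
        return H + 1
    if scheme == "local":
        return n_voxels + 1
    raise ValueError(f"unknown scheme {scheme!r}")


def _simulate_to(problem: CalibrationProblem, vec: np.ndarray,
                 t_end: float) -> np.ndarray:
    params = ModelParameterSet(scheme=problem.scheme, k=vec[:-1],
                               alpha=float(vec[-1]), d0=problem.d0,
                               habitat_map=problem.habitat_map)
    res = simulate(params, problem.cell_v1, problem.theta, problem.schedule,
                   problem.roi, problem.breast_mask, problem.drug_map,
                   t_end=t_end, output_times=[t_end], dt=problem.dt,
                   spacing=problem.spacing, mech=problem.mech,
                   solver=problem.solver(),
                   stress_interval=problem.stress_interval)
    return res.snapshots[-1]


def residuals(problem: CalibrationProblem, vec: np.ndarray) -> np.ndarray:
    """Unit-free V2 misfit: (model − data)/theta per ROI voxel."""
    lo, hi = problem.bounds_vector()
    if np.any(vec < lo - 1e-9) or np.any(vec > hi + 1e-9):
        raise ValueError("parameter vector outside bounds")
    model_v2 = _simulate_to(problem, vec, problem.t_v2)
    return (model_v2[problem.roi] - problem.cell_v2[problem.roi]) \
        / problem.theta


# -- bound transform ---------------------------------------------------------
# The transformed coordinate is clamped to +/- Z_MAX: at the clamp a parameter
# sits within 3.4e-4 of its bound but its gradient never vanishes entirely, so
# the iteration can pull it back off the bound later.

Z_MAX = 8.0


def _to_z(p, lo, hi):
    frac = np.clip((p - lo) / (hi - lo), 1e-9, 1 - 1e-9)
    return np.clip(np.log(frac / (1 - frac)), -Z_MAX, Z_MAX)


def _to_p(z, lo, hi):
    return lo + (hi - lo) / (1.0 + np.exp(-np.clip(z, -Z_MAX, Z_MAX)))


@dataclass
class CalibrationResult:
    params: np.ndarray            # natural units, [k..., alpha]
    scheme: str
    residual_trace: list          # residual norms at accepted iterates
    converged: bool
    n_iterations: int
    n_simulations: int
    wall_time_s: float
    parameter_count: int

    @property
    def k(self) -> np.ndarray:
        return self.params[:-1]

    @property
    def alpha(self) -> float:
        return float(self.params[-1])


def _color_groups(problem: CalibrationProblem, spacing: int = 2):
    """Lattice color classes and, per voxel, its residual-row neighborhood.

    Voxels whose lattice coordinates agree modulo ``spacing`` share a color
    and are perturbed together; a perturbed voxel's sensitivity is read off
    the residual rows in its 26-neighborhood.  Cached on the problem.
    """
    cached = getattr(problem, "_color_cache", None)
    if cached is not None:
        return cached
    coords = problem._roi_coords
    s = spacing
    colors = ((coords[:, 0] % s) * s + coords[:, 1] % s) * s + coords[:, 2] % s
    # map voxel coordinate -> residual row
    row_of = {tuple(c): i for i, c in enumerate(coords)}
    nbr_rows = []
    for c in coords:
        rows = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    r = row_of.get((c[0] + dx, c[1] + dy, c[2] + dz))
                    if r is not None:
                        rows.append(r)
        nbr_rows.append(np.asarray(rows))
    groups = [np.nonzero(colors == c)[0] for c in range(s ** 3)]
    out = ([g for g in groups if g.size], nbr_rows)
    problem._color_cache = out
    return out


def _jacobian(problem, z, r0, res_of):
    """Forward-difference Jacobian in transformed space."""
    n = z.size
    m = r0.size
    J = np.zeros((m, n))
    h = problem.fd_step * np.maximum(np.abs(z), 1.0)
    if problem.scheme == "local":
        groups, nbr_rows = _color_groups(problem)
        for g in groups:
            zp = z.copy()
            zp[g] += h[g]
            rp = res_of(zp)
            dr = rp - r0
            for j in g:
                rows = nbr_rows[j]
                J[rows, j] = dr[rows] / h[j]
        # alpha column (last)
        zp = z.copy()
        zp[-1] += h[-1]
        rp = res_of(zp)
        J[:, -1] = (rp - r0) / h[-1]
    else:
        for j in range(n):
            zp = z.copy()
            zp[j] += h[j]
            rp = res_of(zp)
            J[:, j] = (rp - r0) / h[j]
    return J


def lm_core(res_of, z0, jac_of, max_iter: int = 100, tol: float = 1e-6,
            step_cap: float = 2.0):
    """Levenberg-Marquardt on an unconstrained residual function.

    Damping starts at 1e-3, multiplied by 10 on a rejected step and divided
    by 10 on an accepted one; iteration stops when the relative change of the
    residual norm falls below ``tol``, when no step can be accepted, or at
    ``max_iter``.  Returns (z, trace, converged, n_iterations).

    ``step_cap`` bounds the infinity norm of each step in the transformed
    space.  Growth and drug kill compensate each other strongly, so the
    misfit surface has a curved valley; uncapped Gauss-Newton steps overshoot
    along it and pin parameters against their bounds, where the logistic
    bound transform has vanishing gradient and the iteration stalls in a
    spurious minimum.  Capping the step keeps the iterates in the responsive
    region (the cap plays the role of a trust region; acceptance still uses
    exact residuals).
    """
    z = np.asarray(z0, dtype=float).copy()
    r = res_of(z)
    if not np.all(np.isfinite(r)):
        raise FloatingPointError("non-finite residual at initial guess")
    norm = float(np.linalg.norm(r))
    trace = [norm]
    lam = 1e-3
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        J = jac_of(z, r)
        A = J.T @ J
        g = J.T @ r
        diag = np.maximum(np.diag(A), 1e-12)
        accepted = False
        for _ in range(25):
            try:
                step = np.linalg.solve(A + lam * np.diag(diag), -g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            step = np.clip(step, -step_cap, step_cap)
            # keep iterates inside the transform's live range: past +/-Z_MAX
            # the parameter saturates and forward differences read zero,
            # freezing the coordinate permanently
            z_new = np.clip(z + step, -Z_MAX, Z_MAX)
            r_new = res_of(z_new)
            norm_new = float(np.linalg.norm(r_new))
            if np.isfinite(norm_new) and norm_new < norm:
                z, r = z_new, r_new
                rel_change = (norm - norm_new) / max(norm, 1e-300)
                norm = norm_new
                trace.append(norm)
                lam = max(lam / 10, 1e-12)
                accepted = True
                # a tiny relative improvement only counts as convergence when
                # the damping is small: heavily damped micro-steps can make
                # negligible progress while a good full step still exists
                if rel_change < tol and lam <= 1e-2:
                    converged = True
                break
            lam *= 10
        if not accepted or converged:
            # a stall (no acceptable step) also terminates as converged
            converged = True
            break
    return z, trace, converged, it


def levenberg_marquardt(problem: CalibrationProblem,
                        init_vector: np.ndarray | None = None
                        ) -> CalibrationResult:
    """Bound-constrained LM fit of the V1 -> V2 misfit.

    Bounds are enforced by a logistic reparameterization; the optimizer
    itself runs unconstrained in the transformed space.
    """
    t0 = time.perf_counter()
    lo, hi = problem.bounds_vector()
    p0 = problem.initial_vector() if init_vector is None \
        else np.asarray(init_vector, dtype=float)
    counter = [0]

    def res_of(zv):
        counter[0] += 1
        return residuals(problem, _to_p(zv, lo, hi))

    def jac_of(zv, rv):
        return _jacobian(problem, zv, rv, res_of)

    z0 = _to_z(p0, lo, hi)
    z, trace, converged, it = lm_core(res_of, z0, jac_of,
                                      max_iter=problem.max_iter,
                                      tol=problem.tol)
    params = _to_p(z, lo, hi)
    n_params = count_parameters(problem.scheme, H=problem.n_habitats,
                                n_voxels=problem.n_voxels)
    assert params.size == n_params
    return CalibrationResult(params=params, scheme=problem.scheme,
                             residual_trace=trace, converged=converged,
                             n_iterations=it, n_simulations=counter[0],
                             wall_time_s=time.perf_counter() - t0,
                             parameter_count=n_params)


def predict_v3(problem: CalibrationProblem,
               result: CalibrationResult | np.ndarray) -> np.ndarray:
    """Run the fitted model forward from V1 through the full schedule to V3."""
    vec = result.params if isinstance(result, CalibrationResult) else \
        np.asarray(result, dtype=float)
    return _simulate_to(problem, vec, problem.t_v3)
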