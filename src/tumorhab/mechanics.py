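"""Mechanical coupling: linear-elastic equilibrium and stress-damped diffusivity.

Tumor cell load enters the Cauchy stress as an isotropic expansion term
−κ N_TC/θ · I.  Mechanical equilibrium ∇·σ = 0 with zero displacement on the
breast-mask boundary is discretized by finite differences on the image grid
and solved for the displacement; the von Mises stress of the reassembled
stress tensor then damps the tumor-cell diffusivity, D = D0 exp(−γ σ_vm).

The stiffness operator depends only on the elastic fields and the mask, so it
is factorized once (sparse LU) and reused across time steps and calibration
iterations; only the right-hand side (the cellularity gradient) changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

_AXES = (0, 1, 2)


@dataclass
class MechanicalParams:
    """Linear-elastic material description.

    E : Young's modulus field (kPa); nu : Poisson ratio; kappa : cell-force
    coupling (kPa); gamma : stress-diffusion coupling (kPa⁻¹).
    """

    E: np.ndarray
    nu: float = 0.45
    kappa: float = 1.0
    gamma: float = 2.0e-2

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if np.any(self.E <= 0):
            raise ValueError("Young's modulus must be positive")
        if not 0.0 < self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")

    @property
    def lame_lambda(self) -> np.ndarray:
        return self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))

    @property
    def lame_mu(self) -> np.ndarray:
        return self.E / (2 * (1 + self.nu))


@dataclass
class StressState:
    displacement: np.ndarray          # (3, nx, ny, nz), mm
    sigma: dict                       # keys 'xx','yy','zz','xy','xz','yz'
    von_mises: np.ndarray             # (nx, ny, nz), kPa


def von_mises(sigma: dict) -> np.ndarray:
    """Scalar von Mises stress from the symmetric Cauchy tensor components."""
    sxx, syy, szz = sigma["xx"], sigma["yy"], sigma["zz"]
    sxy, sxz, syz = sigma["xy"], sigma["xz"], sigma["yz"]
    return np.sqrt(0.5 * ((sxx - syy) ** 2 + (sxx - szz) ** 2
                          + (szz - syy) ** 2
                          + 6.0 * (sxy ** 2 + sxz ** 2 + syz ** 2)))


def damped_diffusivity(d0: float, gamma: float,
                       svm: np.ndarray) -> np.ndarray:
    """D = D0 · exp(−γ σ_vm): stress shields cell motility."""
    if d0 < 0 or gamma < 0:
        raise ValueError("d0 and gamma must be nonnegative")
    return d0 * np.exp(-gamma * svm)


def _masked_gradient(f: np.ndarray, mask: np.ndarray, axis: int,
                     h: float) -> np.ndarray:
    """Central-difference gradient using only in-mask neighbors.

    At mask edges the stencil degrades to one-sided; voxels with no in-mask
    neighbor along the axis get zero.  A field constant on the mask therefore
    has exactly zero gradient everywhere on the mask.
    """
    fp = np.roll(f, -1, axis=axis)
    fm = np.roll(f, 1, axis=axis)
    mp = np.roll(mask, -1, axis=axis)
    mm = np.roll(mask, 1, axis=axis)
    # roll wraps around; kill wrapped entries
    sl_hi = [slice(None)] * 3
    sl_hi[axis] = slice(-1, None)
    sl_lo = [slice(None)] * 3
    sl_lo[axis] = slice(0, 1)
    mp = mp.copy(); mp[tuple(sl_hi)] = False
    mm = mm.copy(); mm[tuple(sl_lo)] = False
    both = mp & mm
    out = np.zeros_like(f, dtype=float)
    out[both] = (fp[both] - fm[both]) / (2 * h)
    fwd = mp & ~mm
    out[fwd] = (fp[fwd] - f[fwd]) / h
    bwd = mm & ~mp
    out[bwd] = (f[bwd] - fm[bwd]) / h
    out[~mask] = 0.0
    return out


class ElasticitySolver:
    """Prefactorized finite-difference solver for ∇·σ(u) = ∇(κ N/θ).

    Unknowns are the three displacement components on interior mask voxels;
    u = 0 on and outside the mask boundary (Dirichlet).  Diagonal
    second-derivative terms use compact conservative 3-point stencils with
    face-averaged coefficients; mixed derivatives use composed central
    differences.
    """

    def __init__(self, params: MechanicalParams, mask: np.ndarray,
                 spacing=(1.0, 1.0, 1.0)):
        self.params = params
        self.mask = np.asarray(mask, bool)
        self.spacing = tuple(float(s) for s in spacing)
        self.shape = self.mask.shape
        if params.E.shape != self.shape:
            raise ValueError("E field must match mask shape")
        self._build()

    # -- assembly -------------------------------------------------------
    def _build(self) -> None:
        mask = self.mask
        # interior = mask voxels whose 6-neighbors are all inside the mask;
        # boundary layer carries the u=0 condition.
        interior = mask.copy()
        for ax in _AXES:
            for shift in (1, -1):
                nb = np.roll(mask, shift, axis=ax)
                sl = [slice(None)] * 3
                sl[ax] = slice(0, 1) if shift == 1 else slice(-1, None)
                nb = nb.copy(); nb[tuple(sl)] = False
                interior &= nb
        self.interior = interior
        n = int(interior.sum())
        if n == 0:
            raise ValueError("mask has no interior voxels")
        self.n = n
        idx = -np.ones(self.shape, dtype=np.int64)
        idx[interior] = np.arange(n)
        self.idx = idx
        lam = self.params.lame_lambda
        mu = self.params.lame_mu
        h = self.spacing

        coords = np.argwhere(interior)
        rows_of = lambda c: idx[c[:, 0], c[:, 1], c[:, 2]]
        base_rows = np.arange(n)

        def neighbor(coords_, ax, step):
            c = coords_.copy()
            c[:, ax] += step
            inb = (c[:, ax] >= 0) & (c[:, ax] < self.shape[ax])
            cols = -np.ones(len(c), dtype=np.int64)
            cc = c[inb]
            cols[inb] = idx[cc[:, 0], cc[:, 1], cc[:, 2]]
            return cols  # -1 where neighbor is not an unknown (u=0 there)

        def compact_block(wfield, ax):
            """Sparse n×n matrix for ∂_ax( w ∂_ax u ) with face-avg w."""
            w = wfield[interior]
            cp = neighbor(coords, ax, +1)
            cm = neighbor(coords, ax, -1)
            wp = 0.5 * (w + self._at(wfield, coords, ax, +1))
            wm = 0.5 * (w + self._at(wfield, coords, ax, -1))
            h2 = h[ax] ** 2
            data, ri, ci = [], [], []
            # diagonal
            data.append(-(wp + wm) / h2); ri.append(base_rows); ci.append(base_rows)
            ok = cp >= 0
            data.append(wp[ok] / h2); ri.append(base_rows[ok]); ci.append(cp[ok])
            ok = cm >= 0
            data.append(wm[ok] / h2); ri.append(base_rows[ok]); ci.append(cm[ok])
            return sp.csr_matrix((np.concatenate(data),
                                  (np.concatenate(ri), np.concatenate(ci))),
                                 shape=(n, n))

        def central_diff_op(ax):
            """Sparse n×n central difference along ax (Dirichlet outside)."""
            cp = neighbor(coords, ax, +1)
            cm = neighbor(coords, ax, -1)
            data, ri, ci = [], [], []
            ok = cp >= 0
            data.append(np.full(ok.sum(), 1.0 / (2 * h[ax])))
            ri.append(base_rows[ok]); ci.append(cp[ok])
            ok = cm >= 0
            data.append(np.full(ok.sum(), -1.0 / (2 * h[ax])))
            ri.append(base_rows[ok]); ci.append(cm[ok])
            return sp.csr_matrix((np.concatenate(data),
                                  (np.concatenate(ri), np.concatenate(ci))),
                                 shape=(n, n))

        G = [central_diff_op(ax) for ax in _AXES]
        lam_d = sp.diags(lam[interior])
        mu_d = sp.diags(mu[interior])

        blocks = [[None] * 3 for _ in range(3)]
        for a in _AXES:
            diag = compact_block(lam + 2 * mu, a)
            for c in _AXES:
                if c != a:
                    diag = diag + compact_block(mu, c)
            blocks[a][a] = diag
            for b in _AXES:
                if b == a:
                    continue
                blocks[a][b] = G[a] @ lam_d @ G[b] + G[b] @ mu_d @ G[a]
        K = sp.bmat(blocks, format="csc")
        self._G = G
        self._lu = splu(K)

    def _at(self, field, coords, ax, step):
        c = coords.copy()
        c[:, ax] = np.clip(c[:, ax] + step, 0, self.shape[ax] - 1)
        return field[c[:, 0], c[:, 1], c[:, 2]]

    # -- solve ----------------------------------------------------------
    def solve(self, cellularity: np.ndarray, theta: float) -> StressState:
        """Displacement and stress for a given tumor cell field."""
        n_tc = np.asarray(cellularity, dtype=float)
        if np.any(n_tc < -1e-9) or np.any(n_tc > theta * (1 + 1e-9)):
            raise ValueError("cellularity outside [0, theta]")
        load = self.params.kappa * n_tc / theta
        # forcing f_a = ∂_a (κ N/θ), mask-aware so constant load ⇒ zero force
        f = np.concatenate([
            _masked_gradient(load, self.mask, ax, self.spacing[ax])[self.interior]
            for ax in _AXES])
        u_flat = self._lu.solve(f)
        if not np.all(np.isfinite(u_flat)):
            raise np.linalg.LinAlgError(
                "elasticity solve produced non-finite displacement "
                "(ill-conditioned stiffness)")
        u = np.zeros((3,) + self.shape)
        for a in _AXES:
            comp = np.zeros(self.shape)
            comp[self.interior] = u_flat[a * self.n:(a + 1) * self.n]
            u[a] = comp
        # strain from masked central differences of u
        grad = [[_masked_gradient(u[a], self.mask, b, self.spacing[b])
                 for b in _AXES] for a in _AXES]
        lam = self.params.lame_lambda
        mu = self.params.lame_mu
        div = grad[0][0] + grad[1][1] + grad[2][2]
        sigma = {
            "xx": lam * div + 2 * mu * grad[0][0] - load,
            "yy": lam * div + 2 * mu * grad[1][1] - load,
            "zz": lam * div + 2 * mu * grad[2][2] - load,
            "xy": mu * (grad[0][1] + grad[1][0]),
            "xz": mu * (grad[0][2] + grad[2][0]),
            "yz": mu * (grad[1][2] + grad[2][1]),
        }
        for k in sigma:
            sigma[k] = np.where(self.mask, sigma[k], 0.0)
        svm = von_mises(sigma)
        return StressState(displacement=u, sigma=sigma, von_mises=svm)


def solve_equilibrium(params: MechanicalParams, cellularity: np.ndarray,
                      theta: float, breast_mask: np.ndarray,
                      spacing=(1.0, 1.0, 1.0)) -> StressState:
    """One-shot equilibrium solve (factorizes, solves, discards)."""
    return ElasticitySolver(params, breast_mask, spacing).solve(
        cellularity, theta)


def two_tissue_modulus(breast_mask: np.ndarray, roi_mask: np.ndarray,
                       e_tumor: float = 20.0,
                       e_background: float = 2.0) -> np.ndarray:
    """Young's modulus field: stiff tumor in softer fibroglandular background."""
    E = np.full(breast_mask.shape, e_background, dtype=float)
    E[np.asarray(roi_mask, bool)] = e_tumor
    E[~np.asarray(breast_mask, bool)] = e_background
    return E
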