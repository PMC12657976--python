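"""Quantitative maps from multiparametric breast MRI.

Diffusion-weighted MRI at two b-values yields the apparent diffusion
coefficient (ADC), which is converted to a tumor-cell-number map through the
inverse linear relationship between ADC and cellularity.  The dynamic
contrast-enhanced (DCE) timecourse yields three semi-quantitative perfusion
summaries — maximum slope of increase (MSI), positive enhancement integral
(PEI), and signal enhancement ratio (SER) — plus a normalized
drug-concentration surrogate used by the treatment-response model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: ADC of free water at 37 °C, mm²/s.
ADC_WATER = 3.0e-3

#: DCE resampling grid: 0..360 s at 10 s resolution (37 frames).
DCE_FRAME_TIMES = np.arange(0.0, 361.0, 10.0)


@dataclass
class ADCMap:
    """Apparent diffusion coefficient volume (mm²/s) with a validity mask."""

    values: np.ndarray
    valid: np.ndarray
    visit: str = ""


@dataclass
class CellularityField:
    """Voxelwise tumor cell number N_TC with carrying capacity theta."""

    values: np.ndarray
    theta: float
    adc_min: float
    visit: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if np.any(v < -1e-9) or np.any(v > self.theta * (1 + 1e-9)):
            raise ValueError("cellularity outside [0, theta]")


@dataclass
class DCETimecourse:
    """4D DCE signal (x, y, z, frame) with frame times in seconds."""

    signal: np.ndarray
    frame_times: np.ndarray
    visit: str = ""
    normalized: bool = False
    flat_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.frame_times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        self.frame_times = t
        if self.signal.shape[-1] != t.size:
            raise ValueError("signal/frame_times length mismatch")


@dataclass
class PerfusionMaps:
    msi: np.ndarray
    pei: np.ndarray
    ser: np.ndarray
    visit: str = ""


def fit_adc(s_low: np.ndarray, s_high: np.ndarray,
            b_values: tuple[float, float] = (100.0, 800.0),
            visit: str = "") -> ADCMap:
    """Two-point ADC from the mono-exponential signal decay S_b = S0 e^{-b ADC}.

    With exactly two b-values the log-linear fit reduces to the closed form
    ``ADC = ln(S_b1/S_b2) / (b2 - b1)``.  Voxels with nonpositive signal are
    flagged invalid (value 0, excluded downstream); negative ADC (S_high >
    S_low) is returned but flagged.
    """
    b1, b2 = float(b_values[0]), float(b_values[1])
    if b2 == b1:
        raise ValueError("b-values must differ")
    s_low = np.asarray(s_low, dtype=float)
    s_high = np.asarray(s_high, dtype=float)
    ok = (s_low > 0) & (s_high > 0)
    adc = np.zeros_like(s_low)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc[ok] = np.log(s_low[ok] / s_high[ok]) / (b2 - b1)
    valid = ok & (adc >= 0)
    return ADCMap(values=adc, valid=valid, visit=visit)


def carrying_capacity(voxel_volume: float, cell_radius: float = 0.01,
                      packing: float = 0.7405) -> float:
    """Cells per voxel: packed spheres of radius ``cell_radius`` (mm).

    Default radius 10 μm and packing density 0.7405 give θ ≈ 1.768e5 for a
    1 mm³ voxel.
    """
    if voxel_volume <= 0 or cell_radius <= 0 or packing < 0:
        raise ValueError("arguments must be positive (packing >= 0)")
    return packing * voxel_volume / ((4.0 / 3.0) * np.pi * cell_radius ** 3)


def cellularity_map(adc: ADCMap, adc_min: float, theta: float,
                    adc_w: float = ADC_WATER) -> CellularityField:
    """Cell number from ADC: N = θ (ADC_w − ADC) / (ADC_w − ADC_min).

    ``adc_min`` is the minimum ADC over the patient's tumor across all
    visits.  Values are clipped to [0, θ].
    """
    if adc_min >= adc_w:
        raise ValueError("adc_min must be below the free-water ADC")
    n = theta * (adc_w - adc.values) / (adc_w - adc_min)
    n = np.clip(n, 0.0, theta)
    n[~adc.valid] = 0.0
    return CellularityField(values=n, theta=theta, adc_min=adc_min,
                            visit=adc.visit)


def resample_dce(raw: DCETimecourse) -> DCETimecourse:
    """Linearly resample a DCE timecourse onto 0..360 s at 10 s resolution."""
    t = raw.frame_times
    if t[0] > 0 or t[-1] < 360.0:
        raise ValueError(
            f"timecourse covers [{t[0]:g}, {t[-1]:g}] s; need [0, 360] s")
    target = DCE_FRAME_TIMES
    sig = raw.signal
    # np.interp per voxel, vectorized over the flattened spatial axes
    flat = sig.reshape(-1, t.size)
    out = np.empty((flat.shape[0], target.size), dtype=float)
    for j, tt in enumerate(target):
        # piecewise-linear weights for one target time
        idx = np.searchsorted(t, tt, side="right") - 1
        idx = min(max(idx, 0), t.size - 2)
        w = (tt - t[idx]) / (t[idx + 1] - t[idx])
        out[:, j] = (1 - w) * flat[:, idx] + w * flat[:, idx + 1]
    return DCETimecourse(signal=out.reshape(sig.shape[:-1] + (target.size,)),
                         frame_times=target.copy(), visit=raw.visit)


def normalize_dce(dce: DCETimecourse) -> DCETimecourse:
    """Per-voxel min-max normalization of the DCE signal to [0, 1].

    Flat curves (max == min) are set to all-zero and flagged.
    """
    sig = np.asarray(dce.signal, dtype=float)
    lo = sig.min(axis=-1, keepdims=True)
    hi = sig.max(axis=-1, keepdims=True)
    rng = hi - lo
    flat = rng[..., 0] == 0
    rng = np.where(rng == 0, 1.0, rng)
    out = (sig - lo) / rng
    out[flat] = 0.0
    return DCETimecourse(signal=out, frame_times=dce.frame_times.copy(),
                         visit=dce.visit, normalized=True, flat_mask=flat)


def _require_uniform_dt(dce: DCETimecourse) -> float:
    dt = np.diff(dce.frame_times)
    if not np.allclose(dt, dt[0]):
        raise ValueError("frame spacing must be uniform")
    return float(dt[0])


def compute_msi(dce_n: DCETimecourse) -> np.ndarray:
    """Maximum slope of increase (s⁻¹): max forward difference of DCE_N."""
    if dce_n.frame_times.size < 2:
        raise ValueError("need at least 2 frames")
    dt = _require_uniform_dt(dce_n)
    return np.diff(dce_n.signal, axis=-1).max(axis=-1) / dt


def compute_pei(dce_n: DCETimecourse) -> np.ndarray:
    """Positive enhancement integral (s): Δτ · Σ_τ DCE_N over all frames."""
    dt = _require_uniform_dt(dce_n)
    return dt * dce_n.signal.sum(axis=-1)


def compute_ser(dce: DCETimecourse, rel_tol: float = 1e-6) -> np.ndarray:
    """Signal enhancement ratio from the *raw* DCE signal.

    SER = (S1 − S0)/(S2 − S0), with S0 the mean of the 0/10/20 s frames
    (pre-contrast), S1 the mean of 110/120/130 s (early post-contrast), and
    S2 the mean of 340/350/360 s (late post-contrast).  Where the washout
    denominator is below ``rel_tol * S0`` the ratio is set to 0.
    """
    t = dce.frame_times

    def frame_mean(times):
        cols = []
        for tt in times:
            hit = np.nonzero(np.isclose(t, tt))[0]
            if hit.size == 0:
                raise ValueError(f"required DCE frame at {tt:g} s missing")
            cols.append(hit[0])
        return dce.signal[..., cols].mean(axis=-1)

    s0 = frame_mean([0.0, 10.0, 20.0])
    s1 = frame_mean([110.0, 120.0, 130.0])
    s2 = frame_mean([340.0, 350.0, 360.0])
    denom = s2 - s0
    guard = np.abs(denom) <= rel_tol * np.abs(s0)
    denom = np.where(guard, 1.0, denom)
    ser = (s1 - s0) / denom
    ser[guard] = 0.0
    return ser


def perfusion_maps(dce_raw: DCETimecourse, visit: str = "") -> PerfusionMaps:
    """MSI/PEI (from the normalized signal) and SER (from the raw signal)."""
    dce_n = normalize_dce(dce_raw)
    return PerfusionMaps(msi=compute_msi(dce_n), pei=compute_pei(dce_n),
                         ser=compute_ser(dce_raw), visit=visit)


def drug_concentration(dce_n: DCETimecourse,
                       breast_mask: np.ndarray) -> np.ndarray:
    """Normalized drug-delivery map C(x) ∈ [0, 1].

    The positive enhancement integral of the normalized baseline (V1) DCE
    curve, rescaled by its maximum over the breast mask, stands in for the
    relative drug concentration reaching each voxel.
    """
    pei = compute_pei(dce_n)
    m = pei[np.asarray(breast_mask, bool)]
    peak = m.max() if m.size else 0.0
    if peak <= 0:
        raise ValueError("all-zero enhancement; cannot form C(x)")
    return np.clip(pei / peak, 0.0, 1.0)
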