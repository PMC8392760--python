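"""One-tissue-compartment modelling of 15O-water: CBF estimation.

The tissue compartment obeys dC_T/dt = K1*C_A(t) - k2*C_T(t), whose
solution is the convolution C_T(t) = K1 * C_A(t) (x) exp(-k2*t).  The
measured PET signal mixes in fractional arterial blood volume V_A:

    C_PET(t) = (1 - V_A) * C_T(t) + V_A * C_A(t)

Water is freely diffusible with near-complete first-pass extraction, so
K1 equals cerebral blood flow; K1 is reported in mL/min/g (tissue
density taken as 1 g/mL) and k2 in 1/min, while all curves live on a
1-s grid — unit conversion is internal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .carotid_segmentation import DynamicImage, VoiMask
from .curves import TimeActivityCurve, resample_to_1s, window_0_to_6min

__all__ = [
    "KineticParams",
    "KineticFitResult",
    "simulate_tissue",
    "fit_1tcm",
    "mean_region_tac",
    "region_cbf",
    "DEFAULT_INIT",
    "DEFAULT_BOUNDS",
]

#: (K1 mL/min/g, k2 1/min, V_A) starting point for the fit.
DEFAULT_INIT = (0.5, 1.0, 0.05)
#: Physiologic box constraints for (K1, k2, V_A).
DEFAULT_BOUNDS = ((0.0, 0.0, 0.0), (5.0, 10.0, 1.0))


@dataclass(frozen=True)
class KineticParams:
    """One-tissue model parameters; K1 is CBF for 15O-water."""

    K1: float  # mL/min/g
    k2: float  # 1/min
    V_A: float = 0.0  # unitless fraction

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.k2 < 0:
            raise ValueError("rate constants must be non-negative")
        if not 0.0 <= self.V_A <= 1.0:
            raise ValueError("V_A must lie in [0, 1]")


@dataclass(frozen=True)
class KineticFitResult:
    params: KineticParams
    residual_norm: float
    converged: bool
    n_iter: int

    @property
    def cbf(self) -> float:
        """CBF in mL/min/g (= K1 for water)."""
        return self.params.K1


def _conv_exp(ca: np.ndarray, k2_per_s: float, dt: float) -> np.ndarray:
    """Trapezoid-rule discrete convolution of C_A with exp(-k2*t).

    Exactly the cumulative trapezoidal integral when k2 = 0.
    """
    n = len(ca)
    kern = np.exp(-k2_per_s * dt * np.arange(n))
    full = np.convolve(ca, kern)[:n]
    # trapezoid end-corrections: half weight on both convolution ends
    full = full - 0.5 * (ca * kern[0] + ca[0] * kern)
    return full * dt


def simulate_tissue(aif: TimeActivityCurve, p: KineticParams) -> TimeActivityCurve:
    """Forward model: C_PET(t) from an input function and parameters."""
    dt = aif.dt
    k1_s = p.K1 / 60.0  # mL/min/g -> 1/s (density 1 g/mL)
    k2_s = p.k2 / 60.0
    ct = k1_s * _conv_exp(aif.value, k2_s, dt)
    cpet = (1.0 - p.V_A) * ct + p.V_A * aif.value
    return aif.with_values(cpet)


def fit_1tcm(
    c_pet: TimeActivityCurve,
    c_a: TimeActivityCurve,
    init: tuple[float, float, float] = DEFAULT_INIT,
    bounds: tuple = DEFAULT_BOUNDS,
    weights: np.ndarray | None = None,
) -> KineticFitResult:
    """Nonlinear least-squares fit of (K1, k2, V_A) to a tissue curve.

    Uniform weighting over the 1-s grid by default; pass ``weights`` to
    emphasize e.g. frame durations.  Trust-region-reflective with
    physiologic bounds; failure to converge is reported via the
    ``converged`` flag, never silently.
    """
    if len(c_pet) != len(c_a) or not np.allclose(c_pet.t, c_a.t):
        raise ValueError("tissue and input curves must share a grid")
    if not (np.all(np.isfinite(c_pet.value)) and np.all(np.isfinite(c_a.value))):
        raise ValueError("non-finite input curves")
    w = np.ones(len(c_pet)) if weights is None else np.asarray(weights, dtype=float)

    def resid(x):
        model = simulate_tissue(c_a, KineticParams(*x))
        return w * (model.value - c_pet.value)

    res = least_squares(
        resid,
        x0=np.asarray(init, dtype=float),
        bounds=bounds,
        method="trf",
        xtol=1e-10,
        ftol=1e-10,
        gtol=1e-10,
    )
    return KineticFitResult(
        params=KineticParams(*res.x),
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=bool(res.success),
        n_iter=int(res.nfev),
    )


def mean_region_tac(img: DynamicImage, mask: VoiMask) -> TimeActivityCurve:
    """Mean TAC over a voxel region, resampled to 1 s and windowed to
    the 0-6 min analysis interval."""
    if mask.n_voxels == 0:
        raise ValueError("region mask is empty")
    tac = TimeActivityCurve(
        img.schedule.frame_mid,
        img.voxels[mask.mask, :].mean(axis=0),
        grid_kind="frame-based",
    )
    return window_0_to_6min(resample_to_1s(tac, img.schedule))


def region_cbf(
    img: DynamicImage,
    gm_mask: VoiMask,
    input_fn: TimeActivityCurve,
    **fit_kwargs,
) -> KineticFitResult:
    """Whole-region CBF: mean grey-matter TAC fitted against the given
    input function."""
    tac_1s = mean_region_tac(img, gm_mask)
    if len(input_fn) != len(tac_1s):
        raise ValueError("input function must be on the 0-360 s 1-s grid")
    return fit_1tcm(tac_1s, input_fn, **fit_kwargs)
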