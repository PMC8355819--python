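"""Jacobian determinants, specific air volume change, and gas-volume dynamics.

The Jacobian determinant J_{n→0} of the registration transform gives the
ratiometric total volume change of a voxel between ventilation phase ``n``
and the end-inspiratory reference phase.  Combining it with the intensity
change under the two-compartment assumption (gas at -1000 HU, tissue at
0 HU) yields the specific air volume change by corrected Jacobian,

    SACJ_n = J_{n→0} * (I_n / I_0) - 1,

the relative change in voxel *gas* volume since end-inspiration: zero at the
reference phase, negative when gas volume is lost.  SACJ series are fit with
the same exponential model and F-filter as density, giving gas-volume time
constants tau_SACJ for paired comparison with the density tau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .breath_timing import BreathPhaseGrid
from .expfit import (
    VoxelFitMaps,
    exp_model,
    f_significance,
    fit_series_stack,
    _scatter,
    _scatter_bool,
)
from .io import AlignedSequence, DeformationSet, InputError

__all__ = [
    "GAS_HU",
    "TISSUE_HU",
    "jacobian_from_displacement",
    "compute_sacj",
    "sacj_series",
    "fit_sacj_time_constants",
    "relative_gas_volume_trajectory",
]

GAS_HU = -1000.0
TISSUE_HU = 0.0


def jacobian_from_displacement(
    displacement: np.ndarray, spacing_mm, mask: np.ndarray | None = None, log=None
) -> np.ndarray:
    """Jacobian determinant of (identity + displacement) per voxel.

    ``displacement`` is an (X, Y, Z, 3) field in mm on the sequence grid.
    Gradients use central differences in the interior and one-sided
    differences at the grid boundary; both are exact for affine fields.
    Non-positive determinants (grid folding) are retained but counted.
    """
    u = np.asarray(displacement, dtype=float)
    if u.ndim != 4 or u.shape[-1] != 3:
        raise InputError(f"displacement must be (X,Y,Z,3), got {u.shape}")
    spacing = np.asarray(spacing_mm, dtype=float)
    grad = np.empty(u.shape[:3] + (3, 3))
    for comp in range(3):
        gx, gy, gz = np.gradient(u[..., comp], *spacing)
        grad[..., comp, 0] = gx
        grad[..., comp, 1] = gy
        grad[..., comp, 2] = gz
    F = grad + np.eye(3)
    J = np.linalg.det(F)
    if log is not None:
        region = J[mask] if mask is not None else J
        n_fold = int((region <= 0).sum())
        if n_fold:
            log(f"warning: {n_fold} voxels with non-positive Jacobian (folding)")
    return J


def compute_sacj(jacobian, intensity_n, intensity_0, mask=None):
    """Specific air volume change by corrected Jacobian for one phase.

    Intensities are clamped to the physical [-1000, 0] HU range implied by
    the gas/tissue two-compartment assumption before use.  Voxels with no
    gas at the reference phase (clamped I_0 >= 0 HU) have undefined SACJ and
    are returned as NaN.

    Returns
    -------
    sacj : ndarray
    valid : boolean ndarray marking voxels where SACJ is defined.
    """
    J = np.asarray(jacobian, dtype=float)
    In = np.clip(np.asarray(intensity_n, dtype=float), GAS_HU, TISSUE_HU)
    I0 = np.clip(np.asarray(intensity_0, dtype=float), GAS_HU, TISSUE_HU)
    valid = I0 < 0.0
    if mask is not None:
        valid = valid & np.asarray(mask, bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        sacj = J * (In / I0) - 1.0
    sacj = np.where(valid, sacj, np.nan)
    return sacj, valid


def sacj_series(
    seq: AlignedSequence,
    deformation: DeformationSet,
    grid: BreathPhaseGrid,
    log=None,
):
    """Per-voxel SACJ at every expiratory phase.

    Returns (sacj, valid): ``sacj`` has shape (V, n_exp_samples) over masked
    voxels, exactly 0 in the reference-phase column; ``valid`` (V,) marks
    voxels with gas at the reference phase.  Jacobians are taken from the
    deformation set (computed from displacements when necessary).
    """
    if deformation.jacobian is not None:
        jac = deformation.jacobian
    else:
        jac = np.stack(
            [
                jacobian_from_displacement(
                    deformation.displacement[..., p, :], seq.spacing_mm, seq.mask
                )
                for p in range(deformation.n_phases)
            ],
            axis=-1,
        )
    if jac.shape != seq.intensity.shape:
        raise InputError(
            f"Jacobian stack shape {jac.shape} does not match sequence "
            f"{seq.intensity.shape}"
        )
    phases = grid.expiratory_phase_indices
    mask = seq.mask
    I0 = seq.intensity[..., grid.end_insp_index][mask]
    cols = []
    valid_all = None
    for p in phases:
        s, valid = compute_sacj(jac[..., p][mask], seq.intensity[..., p][mask], I0)
        cols.append(s)
        valid_all = valid if valid_all is None else (valid_all & valid)
    sacj = np.stack(cols, axis=1)
    # the reference phase is the definition's zero point; enforce exactly
    sacj[:, 0] = 0.0
    if log is not None:
        n_bad = int((~valid_all).sum())
        if n_bad:
            log(f"{n_bad} gas-free voxels excluded from SACJ analyses")
    return sacj, valid_all


def fit_sacj_time_constants(
    sacj: np.ndarray,
    valid: np.ndarray,
    grid: BreathPhaseGrid,
    seq: AlignedSequence,
    alpha: float = 0.05,
) -> VoxelFitMaps:
    """Exponential fit of SACJ vs. expiratory time with the density F-filter.

    The intercept (SACJ at t = 0) is estimated freely rather than pinned at
    its defined value of 0, mirroring the density regression.  Output maps
    align with the density-fit geometry for paired voxel-wise comparison;
    gas-free voxels are non-significant by construction.
    """
    times = grid.expiratory_times_s
    filled = np.where(np.isfinite(sacj), sacj, 0.0)
    res = fit_series_stack(times, filled)
    f, p = f_significance(res["sse_mean"], res["sse_model"], times.size)
    sig = (p <= alpha) & valid
    shape = seq.grid_shape
    mask = seq.mask
    return VoxelFitMaps(
        mask=mask.copy(),
        d0=_scatter(res["d0"], mask, shape),
        dinf=_scatter(res["dinf"], mask, shape),
        tau_s=_scatter(res["tau_s"], mask, shape),
        sse_model=_scatter(res["sse_model"], mask, shape),
        sse_mean=_scatter(res["sse_mean"], mask, shape),
        f_stat=_scatter(f, mask, shape),
        p_value=_scatter(p, mask, shape),
        significant=_scatter_bool(sig, mask, shape),
        at_bound=_scatter_bool(res["at_bound"], mask, shape),
        t_exp_s=grid.t_exp_s,
        spacing_mm=seq.spacing_mm.copy(),
        alpha=alpha,
        summary={
            "n_masked_voxels": int(mask.sum()),
            "n_gas_free": int((~valid).sum()),
            "n_excluded": int((~sig).sum()),
        },
    )


def relative_gas_volume_trajectory(
    d0: float, dinf: float, tau_s: float, times_s, t_exp_s: float | None = None
):
    """Model-predicted relative gas-volume change at requested times.

    Evaluates the fitted exponential SACJ model; times beyond ``t_exp_s``
    are allowed (extrapolation) and flagged in the returned mask.
    """
    times = np.asarray(times_s, dtype=float)
    values = exp_model(times, d0, dinf, tau_s)
    extrapolated = (
        np.zeros_like(times, dtype=bool)
        if t_exp_s is None
        else (times < 0) | (times > t_exp_s)
    )
    return values, extrapolated
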