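"""Per-voxel exponential regression of expiratory deaeration.

During passive exhalation under pressure-controlled ventilation the CT
density of an aligned lung voxel relaxes from its end-inspiratory value
``D0`` toward an equilibrium ``Dinf`` as

    I(t) = D0 + (Dinf - D0) * (1 - exp(-t / tau))

where ``tau`` is the regional deaeration time constant.  The model is
linear in (D0, Dinf) once ``tau`` is fixed, so the least-squares problem is
solved by profiling: an exact 2x2 linear solve at each ``tau`` on a dense
log-spaced grid, followed by golden-section refinement of the profiled SSE
in log-tau.  This is deterministic, has no data-dependent initialization,
and attains the global optimum of the profile to machine tolerance.

An F test against the mean-only model decides, per voxel, whether the
exponential significantly contributes to predicting the observed
variability; voxels with p > alpha (default 0.05) are excluded from
regional analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .breath_timing import BreathPhaseGrid
from .io import AlignedSequence, VentilatorTrace, InputError

__all__ = [
    "VoxelExpFit",
    "VoxelFitMaps",
    "GlobalMechanics",
    "exp_model",
    "block_downsample",
    "fit_exponential",
    "fit_series_stack",
    "f_significance",
    "fit_all_voxels",
    "fit_volume_time_constant",
    "dynamic_elastance",
]

TAU_BOUNDS_S = (1e-3, 1e2)
#: tau grid density used when profiling (points per decade of tau)
TAU_GRID_PER_DECADE = 100
_GOLDEN_ITERS = 60
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def exp_model(t, d0, dinf, tau_s):
    """Single-exponential approach from ``d0`` toward ``dinf``."""
    t = np.asarray(t, dtype=float)
    return d0 + (dinf - d0) * (1.0 - np.exp(-t / tau_s))


# ---------------------------------------------------------------------------
# Containers


@dataclass
class VoxelExpFit:
    """Exponential fit of one voxel's expiratory series, with diagnostics.

    ``d_ee`` is the model-predicted end-expiratory density at ``t_exp_s``;
    ``intratidal_change`` = D_EE - D_EI and ``nonequilibrated_change`` =
    Dinf - D_EE quantify the realized and the still-outstanding density
    change at end-expiration.
    """

    d0: float
    dinf: float
    tau_s: float
    sse_model: float
    sse_mean: float
    f_stat: float
    p_value: float
    significant: bool
    at_bound: bool
    t_exp_s: float

    @property
    def d_ee(self) -> float:
        if not np.isfinite(self.tau_s):
            return self.d0
        return float(exp_model(self.t_exp_s, self.d0, self.dinf, self.tau_s))

    @property
    def intratidal_change(self) -> float:
        return self.d_ee - self.d0

    @property
    def nonequilibrated_change(self) -> float:
        return self.dinf - self.d_ee


@dataclass
class VoxelFitMaps:
    """Per-voxel fit parameters over a 3D grid (NaN outside the lung mask)."""

    mask: np.ndarray
    d0: np.ndarray
    dinf: np.ndarray
    tau_s: np.ndarray
    sse_model: np.ndarray
    sse_mean: np.ndarray
    f_stat: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    at_bound: np.ndarray
    t_exp_s: float
    spacing_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    alpha: float = 0.05
    summary: dict = field(default_factory=dict)

    @property
    def d_ee(self) -> np.ndarray:
        with np.errstate(invalid="ignore", over="ignore"):
            out = exp_model(self.t_exp_s, self.d0, self.dinf, self.tau_s)
        flat = ~np.isfinite(self.tau_s) & self.mask
        out[flat] = self.d0[flat]
        return out

    @property
    def intratidal_change(self) -> np.ndarray:
        return self.d_ee - self.d0

    @property
    def nonequilibrated_change(self) -> np.ndarray:
        return self.dinf - self.d_ee


@dataclass
class GlobalMechanics:
    """Whole-lung mechanics from the ventilator trace."""

    tau_volume_s: float
    driving_pressure_cmh2o: float
    tidal_volume_l: float

    @property
    def dynamic_elastance_cmh2o_per_l(self) -> float:
        return dynamic_elastance(self.driving_pressure_cmh2o, self.tidal_volume_l)


# ---------------------------------------------------------------------------
# Downsampling


def block_downsample(seq: AlignedSequence, factor: int) -> AlignedSequence:
    """Block-mean downsample a sequence to coarser isotropic resolution.

    Intensities are averaged per block and phase, which lowers the additive
    noise SD (by ``factor**-1.5`` for fully masked cubic blocks).  The mask
    downsamples by majority vote (a coarse voxel is lung if at least half
    of its children are), and the average for an in-mask coarse voxel uses
    only in-mask children, so boundary voxels are not diluted with airway
    or extra-pulmonary signal.  Trailing voxels that do not fill a block
    are dropped.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"downsample factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return seq
    shape = seq.grid_shape
    if any(factor > s for s in shape):
        raise ValueError(f"factor {factor} exceeds grid shape {shape}")
    nx, ny, nz = (s // factor for s in shape)
    inten = seq.intensity[: nx * factor, : ny * factor, : nz * factor, :]
    p = inten.shape[-1]
    blocks = inten.reshape(nx, factor, ny, factor, nz, factor, p)
    plain = blocks.mean(axis=(1, 3, 5))
    m = seq.mask[: nx * factor, : ny * factor, : nz * factor]
    mblocks = m.reshape(nx, factor, ny, factor, nz, factor)
    nchild = mblocks.sum(axis=(1, 3, 5)).astype(float)
    cmask = nchild >= factor**3 / 2
    masked_sum = (blocks * mblocks[..., None].astype(float)).sum(axis=(1, 3, 5))
    coarse = np.where(
        nchild[..., None] > 0, masked_sum / np.maximum(nchild, 1.0)[..., None], plain
    )
    return AlignedSequence(
        intensity=coarse,
        mask=cmask,
        spacing_mm=seq.spacing_mm * factor,
        affine=None,
        timing=seq.timing,
    )


def block_downsample_volume(vol: np.ndarray, factor: int, mask: np.ndarray | None = None):
    """Block-mean a 3D (or 4D, leading 3 spatial) array; optionally restrict
    the average to in-mask children (NaN where a block has none)."""
    factor = int(factor)
    if factor == 1:
        return np.array(vol, dtype=float)
    nx, ny, nz = (s // factor for s in vol.shape[:3])
    v = np.asarray(vol, dtype=float)[: nx * factor, : ny * factor, : nz * factor]
    trailing = v.shape[3:]
    blocks = v.reshape((nx, factor, ny, factor, nz, factor) + trailing)
    if mask is None:
        return blocks.mean(axis=(1, 3, 5))
    m = np.asarray(mask, bool)[: nx * factor, : ny * factor, : nz * factor]
    mb = m.reshape(nx, factor, ny, factor, nz, factor).astype(float)
    if trailing:
        mb = mb.reshape(mb.shape + (1,) * len(trailing))
    num = (blocks * mb).sum(axis=(1, 3, 5))
    den = mb.sum(axis=(1, 3, 5))
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


# ---------------------------------------------------------------------------
# Profiled nonlinear least squares (vectorized over voxels)


def _linear_solve_at_tau(Y, yy, t, tau_v):
    """Exact (d0, dinf) and SSE for each row of Y at its own tau.

    Y: (V, n); tau_v: scalar or (V,).  Returns d0, dinf, sse arrays (V,).
    """
    tau_v = np.asarray(tau_v, dtype=float)
    a = np.exp(-t[None, :] / tau_v.reshape(-1, 1))  # (V, n) or (1, n)
    b = 1.0 - a
    Saa = (a * a).sum(1)
    Sab = (a * b).sum(1)
    Sbb = (b * b).sum(1)
    Sya = (Y * a).sum(1)
    Syb = (Y * b).sum(1)
    det = Saa * Sbb - Sab * Sab
    scale = Saa * Sbb + 1e-300
    good = det > 1e-12 * scale
    det_safe = np.where(good, det, 1.0)
    d0 = (Sya * Sbb - Syb * Sab) / det_safe
    dinf = (Syb * Saa - Sya * Sab) / det_safe
    sse = yy - d0 * Sya - dinf * Syb
    # ill-conditioned tau (columns collinear): fall back to the mean model
    n = Y.shape[1]
    mean = Y.mean(1)
    sse_mean = yy - n * mean * mean
    d0 = np.where(good, d0, mean)
    dinf = np.where(good, dinf, mean)
    sse = np.where(good, sse, sse_mean)
    return d0, dinf, np.maximum(sse, 0.0)


def fit_series_stack(
    times_s,
    values,
    tau_bounds_s=TAU_BOUNDS_S,
    grid_per_decade=TAU_GRID_PER_DECADE,
):
    """Fit the exponential model to many series at once.

    Parameters
    ----------
    times_s : (n,) strictly increasing sample times starting at 0.
    values : (V, n) observed series (HU, or any scalar such as SACJ).

    Returns
    -------
    dict of arrays ``d0``, ``dinf``, ``tau_s``, ``sse_model``, ``sse_mean``,
    ``at_bound`` (each (V,)).  Constant series get ``tau_s`` = NaN and
    ``sse_model`` = ``sse_mean`` (zero-amplitude fit).
    """
    t = np.asarray(times_s, dtype=float)
    Y = np.atleast_2d(np.asarray(values, dtype=float))
    if t.ndim != 1 or Y.shape[1] != t.size:
        raise ValueError("values must have shape (V, len(times_s))")
    if t.size < 4:
        raise ValueError("need at least 4 samples to fit 3 parameters")
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must start at 0 and be strictly increasing")
    lo, hi = tau_bounds_s
    if not (0 < lo < hi):
        raise ValueError(f"invalid tau bounds {tau_bounds_s}")

    V, n = Y.shape
    yy = (Y * Y).sum(1)
    mean = Y.mean(1)
    sse_mean = np.maximum(yy - n * mean * mean, 0.0)

    n_grid = int(np.ceil(np.log10(hi / lo) * grid_per_decade)) + 1
    lgrid = np.linspace(np.log10(lo), np.log10(hi), n_grid)
    best_sse = sse_mean.copy()
    best_idx = np.full(V, -1)
    for i, lg in enumerate(lgrid):
        _, _, sse = _linear_solve_at_tau(Y, yy, t, 10.0**lg)
        better = sse < best_sse
        best_sse[better] = sse[better]
        best_idx[better] = i

    constant = best_idx < 0  # no tau improved on the mean model
    idx = np.clip(best_idx, 0, n_grid - 1)
    step = lgrid[1] - lgrid[0]
    a_br = np.maximum(lgrid[idx] - step, lgrid[0])
    b_br = np.minimum(lgrid[idx] + step, lgrid[-1])

    # golden-section refinement of the profiled SSE in log10(tau),
    # vectorized over voxels (each voxel carries its own bracket)
    c = b_br - _INVPHI * (b_br - a_br)
    d = a_br + _INVPHI * (b_br - a_br)
    _, _, fc = _linear_solve_at_tau(Y, yy, t, 10.0**c)
    _, _, fd = _linear_solve_at_tau(Y, yy, t, 10.0**d)
    for _ in range(_GOLDEN_ITERS):
        left = fc < fd
        b_br = np.where(left, d, b_br)
        a_br = np.where(left, a_br, c)
        new_c = b_br - _INVPHI * (b_br - a_br)
        new_d = a_br + _INVPHI * (b_br - a_br)
        probe = np.where(left, new_c, new_d)
        _, _, fp = _linear_solve_at_tau(Y, yy, t, 10.0**probe)
        c_next = np.where(left, new_c, d)
        d_next = np.where(left, c, new_d)
        fc_next = np.where(left, fp, fd)
        fd_next = np.where(left, fc, fp)
        c, d, fc, fd = c_next, d_next, fc_next, fd_next
    ltau = (a_br + b_br) / 2.0
    d0, dinf, sse = _linear_solve_at_tau(Y, yy, t, 10.0**ltau)
    worse = sse > best_sse  # refinement must never lose to the grid
    if np.any(worse):
        g = lgrid[idx[worse]]
        d0g, dinfg, sseg = _linear_solve_at_tau(Y[worse], yy[worse], t, 10.0**g)
        d0[worse], dinf[worse], sse[worse] = d0g, dinfg, sseg
        ltau[worse] = g

    tau = 10.0**ltau
    at_bound = (idx == 0) | (idx == n_grid - 1)
    d0[constant] = mean[constant]
    dinf[constant] = mean[constant]
    tau[constant] = np.nan
    sse[constant] = sse_mean[constant]
    at_bound[constant] = False
    return {
        "d0": d0,
        "dinf": dinf,
        "tau_s": tau,
        "sse_model": np.minimum(sse, sse_mean),
        "sse_mean": sse_mean,
        "at_bound": at_bound,
    }


def fit_exponential(
    times_s, values, t_exp_s: float | None = None, alpha: float = 0.05
) -> VoxelExpFit:
    """Least-squares exponential fit of a single expiratory series."""
    res = fit_series_stack(times_s, np.atleast_2d(values))
    n = np.asarray(times_s).size
    f, p = f_significance(res["sse_mean"], res["sse_model"], n)
    if t_exp_s is None:
        t_exp_s = float(np.asarray(times_s)[-1])
    return VoxelExpFit(
        d0=float(res["d0"][0]),
        dinf=float(res["dinf"][0]),
        tau_s=float(res["tau_s"][0]),
        sse_model=float(res["sse_model"][0]),
        sse_mean=float(res["sse_mean"][0]),
        f_stat=float(f[0]),
        p_value=float(p[0]),
        significant=bool(p[0] <= alpha),
        at_bound=bool(res["at_bound"][0]),
        t_exp_s=t_exp_s,
    )


# ---------------------------------------------------------------------------
# Significance filtering


def f_significance(sse_mean, sse_model, n_samples: int):
    """F statistic and p-value of the exponential model vs. the mean model.

    F = ((SSE_mean - SSE_model) / 2) / (SSE_model / (n - 3)), referred to an
    F distribution with (2, n - 3) degrees of freedom; a perfect fit
    (SSE_model = 0) yields p = 0.
    """
    if n_samples <= 3:
        raise ValueError("F test needs more than 3 samples")
    sse_mean = np.asarray(sse_mean, dtype=float)
    sse_model = np.asarray(sse_model, dtype=float)
    dof = n_samples - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((sse_mean - sse_model) / 2.0) / (sse_model / dof)
    perfect = (sse_model <= 0) & (sse_mean > 0)
    degenerate = (sse_model <= 0) & (sse_mean <= 0)  # constant series
    f = np.where(perfect, np.inf, f)
    f = np.where(degenerate, 0.0, f)
    p = stats.f.sf(f, 2, dof)
    p = np.where(perfect, 0.0, p)
    p = np.where(degenerate, 1.0, p)
    return f, p


# ---------------------------------------------------------------------------
# Whole-map fitting


def fit_all_voxels(
    seq: AlignedSequence,
    grid: BreathPhaseGrid,
    alpha: float = 0.05,
    log=None,
) -> VoxelFitMaps:
    """Fit every masked voxel's expiratory series and apply the F-filter.

    Only expiratory phases enter the regression (the end-inspiratory t = 0
    sample included).  Returns NaN-padded 3D parameter maps plus a summary
    of the excluded fraction and its aeration-class composition.
    """
    phases = grid.expiratory_phase_indices
    times = grid.expiratory_times_s
    Y = seq.intensity[..., phases][seq.mask]
    res = fit_series_stack(times, Y)
    f, p = f_significance(res["sse_mean"], res["sse_model"], times.size)

    shape = seq.grid_shape
    maps = VoxelFitMaps(
        mask=seq.mask.copy(),
        d0=_scatter(res["d0"], seq.mask, shape),
        dinf=_scatter(res["dinf"], seq.mask, shape),
        tau_s=_scatter(res["tau_s"], seq.mask, shape),
        sse_model=_scatter(res["sse_model"], seq.mask, shape),
        sse_mean=_scatter(res["sse_mean"], seq.mask, shape),
        f_stat=_scatter(f, seq.mask, shape),
        p_value=_scatter(p, seq.mask, shape),
        significant=_scatter_bool(p <= alpha, seq.mask, shape),
        at_bound=_scatter_bool(res["at_bound"], seq.mask, shape),
        t_exp_s=grid.t_exp_s,
        spacing_mm=seq.spacing_mm.copy(),
        alpha=alpha,
    )

    from .regional import classify_aeration, AERATION_CLASSES

    excluded = ~(p <= alpha)
    n_masked = int(seq.mask.sum())
    comp = {}
    if excluded.any():
        d_ee_excl = maps.d_ee[seq.mask][excluded]
        labels = classify_aeration(d_ee_excl)
        comp = {
            c: float((labels == i).mean()) for i, c in enumerate(AERATION_CLASSES)
        }
    maps.summary = {
        "n_masked_voxels": n_masked,
        "n_excluded": int(excluded.sum()),
        "excluded_fraction": float(excluded.mean()),
        "excluded_class_composition": comp,
    }
    if log is not None:
        log(
            f"excluded {maps.summary['n_excluded']}/{n_masked} voxels "
            f"({100 * maps.summary['excluded_fraction']:.1f}%); "
            f"composition by end-expiratory aeration: {comp}"
        )
    return maps


def _scatter(vals, mask, shape):
    out = np.full(shape, np.nan)
    out[mask] = vals
    return out


def _scatter_bool(vals, mask, shape):
    out = np.zeros(shape, dtype=bool)
    out[mask] = vals
    return out


# ---------------------------------------------------------------------------
# Whole-lung mechanics


def fit_volume_time_constant(
    trace: VentilatorTrace, grid: BreathPhaseGrid | None = None
) -> GlobalMechanics:
    """Overall exhalation time constant from the exhaled-volume trace.

    The expiratory window is located from the airway-pressure square wave
    (pressure at PEEP); the exponential model is then fit to exhaled volume
    versus time within that window.  Driving pressure is the difference
    between the inspiratory and expiratory pressure plateaus, and tidal
    volume is the exhaled volume reached at end-expiration.
    """
    p = trace.pressure_cmh2o
    lo, hi = np.percentile(p, [5, 95])
    if hi - lo < 0.5:
        raise InputError("pressure trace has no identifiable expiratory window")
    mid = 0.5 * (lo + hi)
    low = p < mid
    # contiguous low-pressure runs
    edges = np.diff(low.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if low[0]:
        starts = [0] + starts
    if low[-1]:
        ends = ends + [low.size]
    runs = [(s, e) for s, e in zip(starts, ends) if e - s >= 4]
    if not runs:
        raise InputError("no expiratory window found in pressure trace")
    # prefer a window preceded by an inspiratory plateau (known-complete)
    complete = [r for r in runs if r[0] > 0]
    s, e = complete[0] if complete else runs[0]

    t = trace.time_s[s:e] - trace.time_s[s]
    v = trace.volume_ml[s:e]
    if np.ptp(v) <= 1e-9:
        raise InputError("exhaled-volume trace is flat: no expiration to fit")
    res = fit_series_stack(t, v[None, :])
    tau = float(res["tau_s"][0])
    if not np.isfinite(tau):
        raise InputError("volume trace fit did not identify a time constant")
    p_insp = float(np.median(p[~low]))
    peep = float(np.median(p[low]))
    tidal_l = float(v.max() - v.min()) / 1000.0
    return GlobalMechanics(
        tau_volume_s=tau,
        driving_pressure_cmh2o=p_insp - peep,
        tidal_volume_l=tidal_l,
    )


def dynamic_elastance(driving_pressure_cmh2o: float, tidal_volume_l: float) -> float:
    """Dynamic elastance: driving pressure over tidal volume (cmH2O / L)."""
    if tidal_volume_l <= 0:
        raise ValueError("tidal volume must be positive")
    if driving_pressure_cmh2o < 0:
        raise ValueError("driving pressure must be non-negative")
    return driving_pressure_cmh2o / tidal_volume_l
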