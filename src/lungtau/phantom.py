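"""Synthetic 4D lung phantom with known expiratory-dynamics ground truth.

The phantom emulates the statistical structure a registered, gated 4DCT
sequence of a passively exhaling lung presents to the analysis chain:

* an ellipsoidal lung mask with a cylindrical airway channel carved out
  (excluded-structure voxels for exclusion-logic tests);
* smooth spatial fields of initial density D0, equilibrium density Dinf and
  time constant tau with a gravitational gradient — dorsal (low-index) lung
  denser and faster — and, in the injured condition, patchy poorly aerated
  regions with large density swings;
* per-voxel single-exponential density decay over the expiratory phases,
  inspiratory phases filled with a time-reversed mirror, additive Gaussian
  HU noise;
* tissue-conserving analytic Jacobians J = (I0 + 1000) / (In + 1000), or a
  separable displacement field with a closed-form determinant;
* a 200 Hz ventilator trace: square airway-pressure wave between P_insp and
  PEEP and an exponentially saturating exhaled-volume curve.

Aeration-class quotas are imposed exactly by construction (rank-quantile
thresholds of a smooth latent field), so generated class fractions act as
their own bookkeeping for downstream checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import io as lio
from .breath_timing import BreathPhaseGrid, build_phase_grid
from .io import AlignedSequence, DeformationSet, VentilatorTrace

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "BASELINE_QUOTAS",
    "INJURED_QUOTAS",
    "generate_parameter_fields",
    "render_sequence",
    "render_deformation",
    "render_ventilator_trace",
    "write_phantom",
]

#: construction quotas for aeration classes at equilibrium density
BASELINE_QUOTAS = {"hyper": 0.05, "normal": 0.60, "poor": 0.25, "non": 0.10}
INJURED_QUOTAS = {"hyper": 0.05, "normal": 0.35, "poor": 0.35, "non": 0.25}

# Dinf sub-ranges per class, kept a margin inside the -900/-500/-100 HU
# thresholds so block averaging and classification agree with the quotas.
_CLASS_DINF_RANGES = {
    "hyper": (-985.0, -905.0),
    "normal": (-895.0, -505.0),
    "poor": (-495.0, -105.0),
    "non": (-95.0, 40.0),
}

# Intratidal amplitude |Dinf - D0| ranges per class (HU).  Normally and
# poorly aerated regions carry the bulk of the intratidal change; hyper- and
# non-aerated voxels are mostly near-constant with a changing minority.
_AMP_RANGES = {
    "baseline": {"normal": (60.0, 180.0), "poor": (80.0, 240.0)},
    "injured": {"normal": (80.0, 220.0), "poor": (120.0, 300.0)},
}
_QUIET_AMP_MAX = 4.0  # HU, near-constant hyper/non voxels
_QUIET_FRACTION = 0.65
_ACTIVE_QUIET_AMP = (10.0, 30.0)  # the changing minority of hyper/non


@dataclass
class PhantomSpec:
    """Parameters of the synthetic 4D study.

    ``gravity_axis`` is the dorsal-ventral axis; index 0 along it is the
    dorsal-most (gravitationally dependent, supine) side.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: float = 1.2
    n_phases: int = 21
    respiratory_rate_per_min: float = 20.0
    ie_ratio: tuple[float, float] = (1.0, 2.0)
    condition: str = "baseline"
    noise_sigma_hu: float = 15.0
    tau_range_s: tuple[float, float] = (0.2, 1.2)
    seed: int = 0
    gravity_axis: int = 2
    paradoxical_fraction: float = 0.02
    smoothness_vox: float = 3.0
    class_quotas: dict | None = None
    # ventilator trace parameters (Table-1-scale defaults)
    volume_tau_s: float = 0.3
    peep_cmh2o: float = 8.1
    p_insp_cmh2o: float = 20.8
    tidal_volume_ml: float = 90.0
    n_breaths: int = 3
    trace_sample_rate_hz: float = 200.0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ValueError(f"grid_shape axes must all be >= 4, got {self.grid_shape}")
        if self.spacing_mm <= 0:
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if self.n_phases < 3:
            raise ValueError(f"n_phases must be >= 3, got {self.n_phases}")
        if self.respiratory_rate_per_min <= 0:
            raise ValueError("respiratory_rate_per_min must be positive")
        if self.noise_sigma_hu < 0:
            raise ValueError(f"noise_sigma_hu must be >= 0, got {self.noise_sigma_hu}")
        lo, hi = self.tau_range_s
        if not (0 < lo <= hi):
            raise ValueError(f"tau_range_s must be strictly positive, got {self.tau_range_s}")
        if self.condition not in ("baseline", "injured"):
            raise ValueError(f"condition must be baseline or injured, got {self.condition!r}")
        if self.gravity_axis not in (0, 1, 2):
            raise ValueError(f"gravity_axis must be 0, 1 or 2, got {self.gravity_axis}")
        if not 0 <= self.paradoxical_fraction < 0.5:
            raise ValueError("paradoxical_fraction must be in [0, 0.5)")
        if self.class_quotas is None:
            self.class_quotas = dict(
                BASELINE_QUOTAS if self.condition == "baseline" else INJURED_QUOTAS
            )
        if abs(sum(self.class_quotas.values()) - 1.0) > 1e-9:
            raise ValueError("class_quotas must sum to 1")

    @property
    def quotas(self) -> dict:
        return self.class_quotas

    def phase_grid(self, end_insp_index: int = 0) -> BreathPhaseGrid:
        return build_phase_grid(
            self.n_phases, self.respiratory_rate_per_min, self.ie_ratio, end_insp_index
        )


@dataclass
class PhantomTruth:
    """Ground-truth parameter fields of a generated phantom.

    End-inspiration is phase 0 (the reference phase).  ``class_map`` holds
    the constructed aeration class of Dinf (codes 0..3, -1 outside the
    mask); ``quota_bookkeeping`` the realized class fractions.
    """

    mask: np.ndarray
    d0_map: np.ndarray
    dinf_map: np.ndarray
    tau_map: np.ndarray
    class_map: np.ndarray
    jac_truth: np.ndarray | None = None
    volume_trace_tau_s: float = 0.3
    quota_bookkeeping: dict = field(default_factory=dict)

    @property
    def amplitude_map(self) -> np.ndarray:
        return self.dinf_map - self.d0_map


def _lung_mask(shape) -> np.ndarray:
    """Ellipsoid interior minus a cylindrical airway channel."""
    nx, ny, nz = shape
    x, y, z = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), np.linspace(-1, 1, nz),
        indexing="ij",
    )
    ellipsoid = (x / 0.85) ** 2 + (y / 0.80) ** 2 + (z / 0.90) ** 2 <= 1.0
    airway_r = 0.12
    airway = (x**2 + y**2) <= airway_r**2  # channel along the z axis
    return ellipsoid & ~airway


def _smooth_uniform(shape, rng, sigma_vox, mask) -> np.ndarray:
    """Spatially correlated field rank-transformed to U(0,1) inside mask."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    u = np.zeros(shape)
    vals = f[mask]
    ranks = stats_rank(vals)
    u[mask] = ranks
    return u


def stats_rank(vals: np.ndarray) -> np.ndarray:
    """Fractional ranks in (0, 1), ties broken by position (deterministic)."""
    order = np.argsort(vals, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = (np.arange(vals.size) + 0.5) / vals.size
    return ranks


def generate_parameter_fields(spec: PhantomSpec) -> PhantomTruth:
    """Generate ground-truth D0 / Dinf / tau fields for the phantom.

    Deterministic for a fixed seed.  Gravitational structure: a latent
    density field mixes a dorsal-ventral trend with smooth spatial noise;
    aeration classes are assigned by latent-rank quantiles at the
    construction quotas (so realized class fractions match the quotas
    exactly, up to integer rounding), and Dinf maps monotonically from the
    latent rank into each class's HU sub-range.  Dorsal voxels are denser
    and carry faster time constants.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    mask = _lung_mask(shape)

    from .regional import relative_height

    h = relative_height(mask, spec.gravity_axis)  # 0 dorsal .. 1 ventral

    u_density = _smooth_uniform(shape, rng, spec.smoothness_vox, mask)
    u_amp = _smooth_uniform(shape, rng, spec.smoothness_vox, mask)
    u_tau = _smooth_uniform(shape, rng, spec.smoothness_vox, mask)

    # latent density: larger = denser; dorsal (h=0) denser.  The trend
    # weight keeps each height-decile step several slab-noise SDs, so the
    # imposed dorsal-ventral gradient is monotone in bin medians, not just
    # in expectation.
    w_grav = 0.75
    latent = w_grav * (1.0 - h) + (1.0 - w_grav) * u_density
    lat = latent[mask]
    r = stats_rank(lat)

    quotas = spec.quotas
    order = ["hyper", "normal", "poor", "non"]  # increasing density
    cum = np.cumsum([quotas[c] for c in order])
    codes = np.searchsorted(cum, r, side="left")
    codes = np.clip(codes, 0, 3)

    dinf_v = np.empty(r.size)
    for i, cname in enumerate(order):
        m = codes == i
        if not m.any():
            continue
        lo_q = 0.0 if i == 0 else cum[i - 1]
        hi_q = cum[i]
        within = (r[m] - lo_q) / max(hi_q - lo_q, 1e-12)
        a, b = _CLASS_DINF_RANGES[cname]
        dinf_v[m] = a + within * (b - a)

    # intratidal amplitude per class
    amp_ranges = _AMP_RANGES[spec.condition]
    ua = u_amp[mask]
    amp_v = np.zeros(r.size)
    for i, cname in enumerate(order):
        m = codes == i
        if not m.any():
            continue
        if cname in amp_ranges:
            a, b = amp_ranges[cname]
            amp_v[m] = a + ua[m] * (b - a)
        else:  # hyper / non: mostly near-constant, a changing minority
            quiet = ua[m] < _QUIET_FRACTION
            vals = np.empty(m.sum())
            vals[quiet] = ua[m][quiet] / _QUIET_FRACTION * _QUIET_AMP_MAX
            aq, bq = _ACTIVE_QUIET_AMP
            t = (ua[m][~quiet] - _QUIET_FRACTION) / (1.0 - _QUIET_FRACTION)
            vals[~quiet] = aq + t * (bq - aq)
            amp_v[m] = vals

    # paradoxical voxels: density decreases during exhalation (Dinf < D0)
    n_para = int(round(spec.paradoxical_fraction * r.size))
    if n_para:
        para_idx = rng.choice(r.size, size=n_para, replace=False)
        amp_v[para_idx] = -rng.uniform(8.0, 35.0, size=n_para)

    # keep D0 physically plausible: strictly above -1000 HU and below +100
    amp_v = np.minimum(amp_v, dinf_v + 990.0)
    d0_v = dinf_v - amp_v
    d0_v = np.clip(d0_v, -995.0, 95.0)

    # time constants: dorsal faster, plus smooth variation; the height
    # weight dominates so decile medians of tau rise monotonically even in
    # the small bins at the ellipsoid caps
    lo_t, hi_t = spec.tau_range_s
    ut = u_tau[mask]
    tau_v = lo_t + (hi_t - lo_t) * np.clip(0.8 * h[mask] + 0.2 * ut, 0.0, 1.0)

    def scatter(vals, fill=np.nan):
        out = np.full(shape, fill)
        out[mask] = vals
        return out

    class_map = np.full(shape, -1, dtype=int)
    class_map[mask] = codes
    realized = {c: float((codes == i).mean()) for i, c in enumerate(order)}

    truth = PhantomTruth(
        mask=mask,
        d0_map=scatter(d0_v),
        dinf_map=scatter(dinf_v),
        tau_map=scatter(tau_v),
        class_map=class_map,
        volume_trace_tau_s=spec.volume_tau_s,
        quota_bookkeeping={"quotas": dict(quotas), "realized": realized},
    )
    truth.jac_truth = _analytic_jacobian_stack(truth, spec)
    return truth


def _phase_equivalent_times(spec: PhantomSpec) -> np.ndarray:
    """Expiratory-equivalent time per phase (end-inspiration = phase 0).

    Expiratory phases carry their elapsed expiratory times t_n; inspiratory
    phases are a time-reversed mirror walking back toward t = 0 so the cycle
    is periodic.  Only the expiratory samples are fit downstream.
    """
    grid = spec.phase_grid(end_insp_index=0)
    K = grid.n_exp_intervals
    times = np.empty(spec.n_phases)
    times[: K + 1] = grid.expiratory_times_s
    t_last = grid.expiratory_times_s[-1]
    for m in range(K + 1, spec.n_phases):
        times[m] = t_last * (spec.n_phases - m) / (spec.n_phases - K)
    return times


def _noiseless_stack(truth: PhantomTruth, spec: PhantomSpec) -> np.ndarray:
    times = _phase_equivalent_times(spec)
    mask = truth.mask
    d0 = truth.d0_map[mask]
    amp = truth.amplitude_map[mask]
    tau = truth.tau_map[mask]
    stack = np.empty((mask.sum(), spec.n_phases))
    for p, t in enumerate(times):
        stack[:, p] = d0 + amp * (1.0 - np.exp(-t / tau))
    return stack


_BACKGROUND_HU = 20.0  # soft tissue outside the lung mask


def render_sequence(truth: PhantomTruth, spec: PhantomSpec) -> AlignedSequence:
    """Render the 4D HU sequence: exponential expiratory decay plus noise.

    Phase 0 is the end-inspiratory reference (intensity D0 + noise); the
    noise RNG is independent of the field RNG stream so the same truth can
    be rendered noiseless (sigma = 0) and noisy reproducibly.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    shape = spec.grid_shape
    stack = _noiseless_stack(truth, spec)
    inten = np.full(shape + (spec.n_phases,), _BACKGROUND_HU)
    inten[truth.mask, :] = stack
    if spec.noise_sigma_hu > 0:
        inten = inten + rng.normal(0.0, spec.noise_sigma_hu, size=inten.shape)
    return AlignedSequence(
        intensity=inten,
        mask=truth.mask.copy(),
        spacing_mm=np.full(3, spec.spacing_mm),
        timing=spec.phase_grid(end_insp_index=0),
    )


def _analytic_jacobian_stack(truth: PhantomTruth, spec: PhantomSpec) -> np.ndarray:
    """Tissue-conserving J_{n→0} = (I0 + 1000) / (In + 1000), noiseless."""
    stack = _noiseless_stack(truth, spec)
    if np.any(stack <= -1000.0):
        raise ValueError(
            "nonphysical total-gas voxel: noiseless intensity <= -1000 HU"
        )
    gas0 = stack[:, [0]] + 1000.0
    jac = np.ones(spec.grid_shape + (spec.n_phases,))
    jac[truth.mask, :] = gas0 / (stack + 1000.0)
    return jac


def render_deformation(
    truth: PhantomTruth, spec: PhantomSpec, mode: str = "analytic-jacobian"
) -> DeformationSet:
    """Per-phase deformation consistent with the rendered sequence.

    ``analytic-jacobian`` emits the tissue-conserving determinant stack
    (noiseless intensities); ``displacement`` emits a separable uniform
    compression along the gravity axis whose Jacobian has the closed form
    J = s_n, stored alongside for testing.
    """
    if mode == "analytic-jacobian":
        jac = truth.jac_truth
        if jac is None:
            jac = _analytic_jacobian_stack(truth, spec)
        return DeformationSet(jacobian=jac.copy(), frame=0)
    if mode == "displacement":
        times = _phase_equivalent_times(spec)
        # exhale compresses the lung toward the dorsal side to 0.9 scale
        s_end = 0.9
        scales = 1.0 + (s_end - 1.0) * (1.0 - np.exp(-times / spec.volume_tau_s))
        scales[0] = 1.0
        g = spec.gravity_axis
        shape = spec.grid_shape
        center = (shape[g] - 1) / 2.0
        coord = (np.arange(shape[g]) - center) * spec.spacing_mm
        bshape = [1, 1, 1]
        bshape[g] = -1
        coord = coord.reshape(bshape)
        disp = np.zeros(shape + (spec.n_phases, 3))
        for p, s in enumerate(scales):
            disp[..., p, g] = (s - 1.0) * np.broadcast_to(coord, shape)
        return DeformationSet(
            displacement=disp, frame=0, closed_form_jacobian=scales.copy()
        )
    raise ValueError(f"unknown deformation mode {mode!r}")


def render_ventilator_trace(truth: PhantomTruth, spec: PhantomSpec) -> VentilatorTrace:
    """200 Hz ventilator waveforms over ``n_breaths`` breaths.

    The trace starts at end-inspiration.  During exhalation the airway
    pressure sits at PEEP and the exhaled volume saturates exponentially
    with the ground-truth overall time constant; during inspiration the
    pressure sits at P_insp and the exhaled-volume reference ramps back to
    zero.
    """
    fs = spec.trace_sample_rate_hz
    period = 60.0 / spec.respiratory_rate_per_min
    grid = spec.phase_grid()
    n_samples = int(round(spec.n_breaths * period * fs))
    t = np.arange(n_samples) / fs
    t_in_breath = np.mod(t, period)
    exhaling = t_in_breath < grid.t_exp_s
    tau = truth.volume_trace_tau_s
    vt = spec.tidal_volume_ml
    v_ee = vt * (1.0 - np.exp(-grid.t_exp_s / tau))
    volume = np.where(
        exhaling,
        vt * (1.0 - np.exp(-t_in_breath / tau)),
        v_ee * (1.0 - (t_in_breath - grid.t_exp_s) / grid.t_insp_s),
    )
    pressure = np.where(exhaling, spec.peep_cmh2o, spec.p_insp_cmh2o)
    return VentilatorTrace(
        time_s=t,
        pressure_cmh2o=pressure,
        volume_ml=np.maximum(volume, 0.0),
        sample_rate_hz=fs,
        peep_cmh2o=spec.peep_cmh2o,
        p_insp_cmh2o=spec.p_insp_cmh2o,
    )


def write_phantom(spec: PhantomSpec, out_dir) -> dict:
    """Generate and serialize a full phantom study to ``out_dir``.

    Writes the 4D sequence, mask, Jacobian stack, truth maps, ventilator
    trace and a JSON sidecar with the spec and phase timing.  Returns the
    path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = generate_parameter_fields(spec)
    seq = render_sequence(truth, spec)
    defset = render_deformation(truth, spec, mode="analytic-jacobian")
    trace = render_ventilator_trace(truth, spec)
    grid = spec.phase_grid()

    paths = {
        "sequence": out / "sequence.nii.gz",
        "mask": out / "mask.nii.gz",
        "jacobian": out / "jacobian.nii.gz",
        "d0": out / "truth_d0.nii.gz",
        "dinf": out / "truth_dinf.nii.gz",
        "tau": out / "truth_tau.nii.gz",
        "trace": out / "trace.csv",
        "sidecar": out / "phantom.json",
    }
    lio.write_sequence(seq, paths["sequence"], paths["mask"])
    lio.write_deformation(defset, paths["jacobian"], affine=seq.affine)
    for key, vol in (("d0", truth.d0_map), ("dinf", truth.dinf_map), ("tau", truth.tau_map)):
        lio.write_volume(vol, seq.affine, paths[key])
    lio.write_trace(trace, paths["trace"])
    lio.write_json(
        {
            "spec": asdict(spec),
            "timing": {
                "n_phases": grid.n_phases,
                "phase_interval_s": grid.phase_interval_s,
                "t_insp_s": grid.t_insp_s,
                "t_exp_s": grid.t_exp_s,
                "end_insp_index": grid.end_insp_index,
                "end_exp_index": grid.end_exp_index,
                "expiratory_times_s": grid.expiratory_times_s,
            },
            "quota_bookkeeping": truth.quota_bookkeeping,
            "volume_trace_tau_s": truth.volume_trace_tau_s,
        },
        paths["sidecar"],
    )
    return {k: str(v) for k, v in paths.items()}
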