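"""File formats and validated in-memory containers.

All volumes travel as NIfTI-1 (4D stacks ordered X, Y, Z, phase), ventilator
traces as headered CSV, tabular results as TSV, and configuration/sidecars
as JSON.  Containers validate on construction so downstream analysis can
assume well-formed inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AlignedSequence",
    "DeformationSet",
    "VentilatorTrace",
    "InputError",
    "load_sequence",
    "write_sequence",
    "load_deformation",
    "write_deformation",
    "read_trace",
    "write_trace",
    "write_parameter_maps",
]

TRACE_COLUMNS = ("time_s", "pressure_cmh2o", "volume_ml")


class InputError(ValueError):
    """Malformed or inconsistent input data."""


def _default_affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


@dataclass
class AlignedSequence:
    """4D HU stack aligned to an end-inspiratory reference phase.

    ``intensity`` has shape (X, Y, Z, n_phases); ``mask`` is the lung mask in
    the reference geometry.  The sequence is assumed already registered — all
    phases sample the same material voxels.
    """

    intensity: np.ndarray
    mask: np.ndarray
    spacing_mm: np.ndarray
    affine: np.ndarray | None = None
    timing: object | None = None  # BreathPhaseGrid, attached by the pipeline

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        if self.intensity.ndim != 4:
            raise InputError(
                f"sequence must be 4D (X,Y,Z,phase), got {self.intensity.ndim}D"
            )
        if self.mask.shape != self.intensity.shape[:3]:
            raise InputError(
                f"mask shape {self.mask.shape} does not match "
                f"volume shape {self.intensity.shape[:3]}"
            )
        if self.mask.sum() == 0:
            raise InputError("lung mask is empty")
        if self.spacing_mm.shape != (3,) or np.any(self.spacing_mm <= 0):
            raise InputError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        bad = ~np.isfinite(self.intensity[self.mask])
        if bad.any():
            raise InputError(
                f"{int(bad.sum())} non-finite intensity samples inside the lung mask"
            )
        if self.affine is None:
            self.affine = _default_affine(self.spacing_mm)

    @property
    def n_phases(self) -> int:
        return self.intensity.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.intensity.shape[:3]


@dataclass
class DeformationSet:
    """Per-phase deformation relative to the reference phase.

    Either ``jacobian`` (X, Y, Z, n_phases) holds precomputed determinants
    J_{n→0}, or ``displacement`` (X, Y, Z, n_phases, 3) holds displacement
    vectors in mm from which Jacobians are derived.  ``frame`` is the
    reference phase index (J at the reference phase is identically 1).
    ``closed_form_jacobian`` optionally carries an analytic per-phase
    determinant for fields whose Jacobian is known exactly (testing aid).
    """

    jacobian: np.ndarray | None = None
    displacement: np.ndarray | None = None
    frame: int = 0
    closed_form_jacobian: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.jacobian is None and self.displacement is None:
            raise InputError("DeformationSet needs a jacobian or a displacement field")
        if self.jacobian is not None:
            self.jacobian = np.asarray(self.jacobian, dtype=float)
            if self.jacobian.ndim != 4:
                raise InputError("jacobian stack must be 4D (X,Y,Z,phase)")
        if self.displacement is not None:
            self.displacement = np.asarray(self.displacement, dtype=float)
            if self.displacement.ndim != 5 or self.displacement.shape[-1] != 3:
                raise InputError("displacement must have shape (X,Y,Z,phase,3)")

    @property
    def n_phases(self) -> int:
        src = self.jacobian if self.jacobian is not None else self.displacement
        return src.shape[3]


@dataclass
class VentilatorTrace:
    """Airway pressure and exhaled volume sampled at the endotracheal tube.

    ``volume_ml`` is the exhaled gas volume referenced to end-inspiration
    (zero at the start of each exhalation).
    """

    time_s: np.ndarray
    pressure_cmh2o: np.ndarray
    volume_ml: np.ndarray
    sample_rate_hz: float = 200.0
    peep_cmh2o: float | None = None
    p_insp_cmh2o: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.pressure_cmh2o = np.asarray(self.pressure_cmh2o, dtype=float)
        self.volume_ml = np.asarray(self.volume_ml, dtype=float)
        n = self.time_s.size
        if self.pressure_cmh2o.size != n or self.volume_ml.size != n:
            raise InputError("trace columns have mismatched lengths")
        if n < 2:
            raise InputError("trace needs at least two samples")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise InputError("trace time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise InputError("trace sampling interval must be constant")


# ---------------------------------------------------------------------------
# NIfTI round-trips


def _load_nifti(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return data, zooms, np.asarray(img.affine)


def load_sequence(path, mask_path, timing=None, log=None) -> AlignedSequence:
    """Read a 4D HU sequence plus its lung mask, validating geometry.

    Logs per-aeration-class voxel counts at the reference (first) phase when
    a ``log`` callable is given.
    """
    data, zooms, affine = _load_nifti(path)
    if data.ndim != 4:
        raise InputError(f"{path}: expected a 4D sequence, got {data.ndim}D")
    mdata, mzooms, _ = _load_nifti(mask_path)
    if mdata.ndim != 3:
        raise InputError(f"{mask_path}: expected a 3D mask, got {mdata.ndim}D")
    if mdata.shape != data.shape[:3]:
        raise InputError(
            f"mask grid {mdata.shape} does not match sequence grid {data.shape[:3]}"
        )
    if not np.allclose(mzooms, zooms, rtol=1e-5):
        raise InputError(f"mask spacing {mzooms} does not match sequence spacing {zooms}")
    seq = AlignedSequence(
        intensity=data, mask=mdata > 0.5, spacing_mm=zooms, affine=affine, timing=timing
    )
    if timing is not None and timing.n_phases != seq.n_phases:
        raise InputError(
            f"sequence has {seq.n_phases} phases but timing declares {timing.n_phases}"
        )
    if log is not None:
        from .regional import classify_aeration, AERATION_CLASSES

        ref = seq.intensity[..., 0][seq.mask]
        labels = classify_aeration(ref)
        counts = {c: int((labels == i).sum()) for i, c in enumerate(AERATION_CLASSES)}
        log(f"reference-phase aeration counts: {counts}")
    return seq


def write_sequence(seq: AlignedSequence, path, mask_path=None) -> None:
    nib.save(nib.Nifti1Image(seq.intensity.astype(np.float32), seq.affine), str(path))
    if mask_path is not None:
        nib.save(
            nib.Nifti1Image(seq.mask.astype(np.uint8), seq.affine), str(mask_path)
        )


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_deformation(jac_path=None, disp_path=None, frame: int = 0) -> DeformationSet:
    if jac_path is not None:
        data, _, _ = _load_nifti(jac_path)
        return DeformationSet(jacobian=data, frame=frame)
    if disp_path is not None:
        data, _, _ = _load_nifti(disp_path)
        return DeformationSet(displacement=data, frame=frame)
    raise InputError("provide a Jacobian or a displacement NIfTI path")


def write_deformation(defset: DeformationSet, path, affine=None) -> None:
    if affine is None:
        affine = np.eye(4)
    data = defset.jacobian if defset.jacobian is not None else defset.displacement
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))


# ---------------------------------------------------------------------------
# Ventilator traces (CSV)


def write_trace(trace: VentilatorTrace, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "pressure_cmh2o": trace.pressure_cmh2o,
            "volume_ml": trace.volume_ml,
        }
    )
    df.to_csv(path, index=False)


def read_trace(path, peep_cmh2o=None, p_insp_cmh2o=None) -> VentilatorTrace:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"trace file {path} missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy()
    rate = 1.0 / np.median(np.diff(t)) if t.size > 1 else float("nan")
    return VentilatorTrace(
        time_s=t,
        pressure_cmh2o=df["pressure_cmh2o"].to_numpy(),
        volume_ml=df["volume_ml"].to_numpy(),
        sample_rate_hz=rate,
        peep_cmh2o=peep_cmh2o,
        p_insp_cmh2o=p_insp_cmh2o,
    )


# ---------------------------------------------------------------------------
# Parameter-map products


def write_parameter_maps(fits, out_dir, affine=None) -> dict[str, Path]:
    """Serialize fitted voxel maps: NIfTI per parameter plus a TSV long table.

    Voxels excluded by the F-filter (and voxels outside the mask) are encoded
    as NaN in every float map.  The TSV holds one row per masked voxel.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = _default_affine(getattr(fits, "spacing_mm", np.ones(3)))

    sig = fits.significant & fits.mask

    def masked(arr):
        out = np.full(fits.mask.shape, np.nan)
        out[sig] = arr[sig]
        return out

    products = {
        "d0": masked(fits.d0),
        "dinf": masked(fits.dinf),
        "tau": masked(fits.tau_s),
        "intratidal_change": masked(fits.intratidal_change),
        "nonequilibrated_change": masked(fits.nonequilibrated_change),
        "p_value": np.where(fits.mask, fits.p_value, np.nan),
    }
    paths: dict[str, Path] = {}
    for name, vol in products.items():
        p = out_dir / f"{name}.nii.gz"
        write_volume(vol, affine, p)
        paths[name] = p

    idx = np.argwhere(fits.mask)
    table = pd.DataFrame(
        {
            "x": idx[:, 0],
            "y": idx[:, 1],
            "z": idx[:, 2],
            "d0_hu": fits.d0[fits.mask],
            "dinf_hu": fits.dinf[fits.mask],
            "tau_s": fits.tau_s[fits.mask],
            "d_ee_hu": fits.d_ee[fits.mask],
            "intratidal_hu": fits.intratidal_change[fits.mask],
            "nonequilibrated_hu": fits.nonequilibrated_change[fits.mask],
            "f_stat": fits.f_stat[fits.mask],
            "p_value": fits.p_value[fits.mask],
            "significant": fits.significant[fits.mask],
        }
    )
    tsv = out_dir / "voxel_fits.tsv"
    table.to_csv(tsv, sep="\t", index=False)
    paths["table"] = tsv
    return paths


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
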