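"""End-to-end orchestration: phantom → voxel fits → SACJ → regional report.

Each stage serializes its products so the next stage (and a rerun) can start
from disk; a JSON manifest records the seed, package versions, and a
checksum for every output file.  Fixed seed in, identical summary tables
out.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as lio
from .breath_timing import build_phase_grid, detect_end_inspiration
from .expfit import (
    block_downsample,
    block_downsample_volume,
    fit_all_voxels,
    fit_volume_time_constant,
)
from .io import AlignedSequence, DeformationSet, InputError
from .phantom import PhantomSpec, write_phantom
from .regional import (
    build_prm,
    class_volume_fractions,
    classify_aeration,
    group_tau_by_class,
    height_profile,
    normalized_convergence,
    tau_correlation,
    time_course_distributions,
)
from .volumetrics import fit_sacj_time_constants, sacj_series

log = logging.getLogger("lungtau")

STAGE_FAILURE = 3
VALIDATION_ERROR = 2


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_dict``)."""

    out_dir: Path
    seed: int = 0
    phantom: dict | None = None
    sequence_path: str | None = None
    mask_path: str | None = None
    jacobian_path: str | None = None
    trace_path: str | None = None
    n_phases: int | None = None
    respiratory_rate_per_min: float | None = None
    ie_ratio: tuple = (1.0, 2.0)
    end_insp_index_override: int | None = None
    downsample_factor: int = 2
    alpha: float = 0.05
    prm_bin_hu: float = 25.0
    height_bins: int = 10
    gravity_axis: int = 2

    @classmethod
    def from_dict(cls, d: dict, base_dir: Path | None = None) -> "RunConfig":
        d = dict(d)
        if "out_dir" not in d:
            raise InputError("config requires out_dir")
        cfg = cls(out_dir=Path(d.pop("out_dir")), **d)
        if not 0 < cfg.alpha < 1:
            raise InputError(f"alpha must be in (0, 1), got {cfg.alpha}")
        if cfg.phantom is None:
            for key in ("sequence_path", "mask_path"):
                p = getattr(cfg, key)
                if p is None:
                    raise InputError(f"config needs a phantom spec or {key}")
                if not Path(p).exists():
                    raise InputError(f"{key} does not exist: {p}")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(cfg: RunConfig):
    if cfg.phantom is not None:
        pdir = cfg.out_dir / "phantom"
        spec = PhantomSpec(**{**cfg.phantom, "seed": cfg.phantom.get("seed", cfg.seed)})
        paths = write_phantom(spec, pdir)
        log.info("phantom written to %s", pdir)
        grid0 = spec.phase_grid()
        seq = lio.load_sequence(paths["sequence"], paths["mask"], timing=grid0, log=log.info)
        defset = lio.load_deformation(jac_path=paths["jacobian"])
        trace = lio.read_trace(paths["trace"])
        n_phases, rate, ie = spec.n_phases, spec.respiratory_rate_per_min, spec.ie_ratio
    else:
        if cfg.n_phases is None or cfg.respiratory_rate_per_min is None:
            raise InputError("n_phases and respiratory_rate_per_min required for file inputs")
        n_phases, rate, ie = cfg.n_phases, cfg.respiratory_rate_per_min, cfg.ie_ratio
        seq = lio.load_sequence(cfg.sequence_path, cfg.mask_path, log=log.info)
        defset = (
            lio.load_deformation(jac_path=cfg.jacobian_path)
            if cfg.jacobian_path
            else None
        )
        trace = lio.read_trace(cfg.trace_path) if cfg.trace_path else None
    return seq, defset, trace, n_phases, rate, ie


def run_fit_stage(seq: AlignedSequence, cfg: RunConfig, n_phases, rate, ie):
    """Downsample, detect end-inspiration, build timing, fit all voxels."""
    ds = block_downsample(seq, cfg.downsample_factor)
    if cfg.end_insp_index_override is not None:
        end_insp = cfg.end_insp_index_override
    else:
        end_insp = detect_end_inspiration(ds)
    grid = build_phase_grid(n_phases, rate, ie, end_insp_index=end_insp)
    fits = fit_all_voxels(ds, grid, alpha=cfg.alpha, log=log.info)
    return ds, grid, fits


def run_sacj_stage(seq, defset: DeformationSet, grid, cfg: RunConfig):
    """Downsample Jacobians identically to intensities and fit SACJ."""
    ds = block_downsample(seq, cfg.downsample_factor)
    if defset.jacobian is not None:
        jac = block_downsample_volume(defset.jacobian, cfg.downsample_factor)
        defset_ds = DeformationSet(jacobian=jac, frame=defset.frame)
    else:
        defset_ds = defset
    sacj, valid = sacj_series(ds, defset_ds, grid, log=log.info)
    sfits = fit_sacj_time_constants(sacj, valid, grid, ds, alpha=cfg.alpha)
    return sfits


def run_analysis_stage(fits, sfits, mech, cfg: RunConfig, out: Path) -> dict:
    """Regional summaries: classes, heights, PRM, convergence, correlation."""
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    sel = fits.significant & fits.mask & np.isfinite(fits.tau_s)
    labels = classify_aeration(fits.d_ee[sel])
    fractions = class_volume_fractions(labels)
    fractions.to_csv(out / "class_fractions.tsv", sep="\t", header=["fraction"])
    report["class_fractions"] = fractions.to_dict()

    tau_by_class = group_tau_by_class(
        fits, tau_volume_s=None if mech is None else mech.tau_volume_s
    )
    tau_by_class.to_csv(out / "tau_by_class.tsv", sep="\t")
    report["tau_by_class"] = tau_by_class.to_dict(orient="index")

    profile = height_profile(fits, cfg.gravity_axis, n_bins=cfg.height_bins)
    profile.to_csv(out / "height_profile.tsv", sep="\t")

    prm = build_prm([fits], bin_width_hu=cfg.prm_bin_hu)
    prm_df = pd.DataFrame(
        prm.probability, index=prm.bin_centers_hu, columns=prm.bin_centers_hu
    )
    prm_df.to_csv(out / "prm_probability.tsv", sep="\t")
    pd.DataFrame(
        prm.median_tau_s, index=prm.bin_centers_hu, columns=prm.bin_centers_hu
    ).to_csv(out / "prm_median_tau.tsv", sep="\t")

    conv, n_omitted = normalized_convergence(fits)
    conv.to_csv(out / "normalized_convergence.tsv", sep="\t", index=False)
    report["convergence_voxels_omitted"] = n_omitted

    if sfits is not None:
        both = (
            fits.significant
            & sfits.significant
            & fits.mask
            & np.isfinite(fits.tau_s)
            & np.isfinite(sfits.tau_s)
        )
        corr = tau_correlation([(fits.tau_s[both], sfits.tau_s[both])], log=log.info)
        corr["per_subject"].to_csv(out / "tau_correlation.tsv", sep="\t", index=False)
        report["tau_correlation"] = {
            "fraction_significant": corr["fraction_significant"],
            "n_paired_voxels": int(both.sum()),
        }
        report["median_tau_sacj_over_tau_density"] = float(
            np.median(sfits.tau_s[both] / fits.tau_s[both])
        )

    times = np.linspace(0.0, fits.t_exp_s, 5)
    tcd = time_course_distributions(fits, times)
    report["time_course_times_s"] = list(tcd.keys())

    if mech is not None:
        report["global_mechanics"] = {
            "tau_volume_s": mech.tau_volume_s,
            "driving_pressure_cmh2o": mech.driving_pressure_cmh2o,
            "tidal_volume_l": mech.tidal_volume_l,
            "dynamic_elastance_cmh2o_per_l": mech.dynamic_elastance_cmh2o_per_l,
        }
    report["fit_summary"] = fits.summary
    return report


def _plots(fits, cfg: RunConfig, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    profile = height_profile(fits, cfg.gravity_axis, n_bins=cfg.height_bins)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    centers = (profile["height_lo"] + profile["height_hi"]) / 2
    axes[0].plot(centers, profile["d_ee_hu_median"], "o-")
    axes[0].set_xlabel("relative height (0 = dorsal)")
    axes[0].set_ylabel("median end-expiratory density (HU)")
    axes[1].plot(centers, profile["tau_s_median"], "o-")
    axes[1].set_xlabel("relative height (0 = dorsal)")
    axes[1].set_ylabel("median time constant (s)")
    fig.tight_layout()
    fig.savefig(out / "height_profile.png", dpi=110)
    plt.close(fig)

    conv, _ = normalized_convergence(fits)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(conv["tau_over_t_exp"], conv["remaining_fraction"], ".", ms=2, alpha=0.3)
    from .regional import theoretical_convergence

    x = np.linspace(1e-3, max(1.0, conv["tau_over_t_exp"].max()), 200)
    ax.plot(x, theoretical_convergence(x), "k-", lw=1.5)
    ax.set_xlabel(r"$\tau\,/\,t_{exp}$")
    ax.set_ylabel("fraction of change remaining")
    fig.tight_layout()
    fig.savefig(out / "normalized_convergence.png", dpi=110)
    plt.close(fig)


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute phantom → fit → SACJ → analyze and write the report bundle.

    Returns the report dict; all products plus a checksummed manifest land
    under the configured output directory.
    """
    if not isinstance(config, dict):
        config = lio.read_json(config)
    cfg = RunConfig.from_dict(config)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)

    stage = "inputs"
    try:
        seq, defset, trace, n_phases, rate, ie = _load_inputs(cfg)
        stage = "fit"
        ds, grid, fits = run_fit_stage(seq, cfg, n_phases, rate, ie)
        lio.write_parameter_maps(fits, cfg.out_dir / "fit")
        stage = "sacj"
        sfits = run_sacj_stage(seq, defset, grid, cfg) if defset is not None else None
        if sfits is not None:
            lio.write_parameter_maps(sfits, cfg.out_dir / "sacj")
        stage = "mechanics"
        mech = fit_volume_time_constant(trace, grid) if trace is not None else None
        stage = "analyze"
        report = run_analysis_stage(fits, sfits, mech, cfg, cfg.out_dir / "analysis")
        _plots(fits, cfg, cfg.out_dir / "analysis")
    except InputError:
        raise
    except Exception as exc:  # pragma: no cover - stage context for operators
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    lio.write_json(report, cfg.out_dir / "report.json")
    files = sorted(
        p for p in cfg.out_dir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "lungtau_version": __version__,
        "seed": cfg.seed,
        "numpy_version": np.__version__,
        "outputs": {str(p.relative_to(cfg.out_dir)): _sha256(p) for p in files},
    }
    lio.write_json(manifest, cfg.out_dir / "manifest.json")
    return report
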