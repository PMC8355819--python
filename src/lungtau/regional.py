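"""Regional groupings and summary analyses of voxel-wise fit results.

Covers aeration classification at standard HU thresholds, class volume
fractions, per-class time-constant summaries, gravitational (dorsal-ventral)
height profiles, parametric response maps (PRMs) of initial vs. equilibrium
density with median-tau overlays, nonequilibrated density change, normalized
convergence against the theoretical exponential curve, paired density/SACJ
time-constant correlation, and time-course distributions of predicted
density and gas-volume change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AERATION_CLASSES",
    "AERATION_THRESHOLDS_HU",
    "PRMGrid",
    "classify_aeration",
    "class_volume_fractions",
    "group_tau_by_class",
    "relative_height",
    "height_profile",
    "build_prm",
    "nonequilibrated_change_map",
    "normalized_convergence",
    "theoretical_convergence",
    "tau_correlation",
    "time_course_distributions",
]

#: class labels in order of increasing density
AERATION_CLASSES = ("hyper", "normal", "poor", "non")
#: hyper-aerated below -900 HU; normally aerated -900..-500; poorly aerated
#: -500..-100; non-aerated above -100.  Intervals are closed on the lower
#: (more negative) edge.
AERATION_THRESHOLDS_HU = (-900.0, -500.0, -100.0)


def classify_aeration(density_hu) -> np.ndarray:
    """Aeration class codes (0=hyper, 1=normal, 2=poor, 3=non) per voxel."""
    v = np.asarray(density_hu, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("classify_aeration requires finite HU values")
    return np.digitize(v, AERATION_THRESHOLDS_HU, right=False)


def class_volume_fractions(labels) -> pd.Series:
    """Fraction of classified voxels in each aeration class (sums to 1)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("no voxels to classify (empty mask?)")
    counts = np.bincount(labels.ravel(), minlength=4)[:4]
    return pd.Series(counts / labels.size, index=list(AERATION_CLASSES))


def _summary_frame(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for name, vals in groups.items():
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue  # empty class reported as absent, not zero
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"class": name, "n": vals.size, "median": med, "q1": q1, "q3": q3})
    return pd.DataFrame(rows).set_index("class") if rows else pd.DataFrame(
        columns=["n", "median", "q1", "q3"]
    )


def group_tau_by_class(
    fits, classify_at: str = "d_ee", tau_volume_s: float | None = None
) -> pd.DataFrame:
    """Median/IQR of the fitted time constant per aeration class.

    Only F-significant voxels enter (the exclusion rule applied upstream).
    ``classify_at`` chooses the density used for class membership:
    ``"d_ee"`` (end-expiratory prediction, the default), ``"d0"``, or
    ``"dinf"``.  The overall exhaled-volume time constant can be attached
    for reference via ``tau_volume_s``.
    """
    sel = fits.significant & fits.mask & np.isfinite(fits.tau_s)
    density = getattr(fits, {"d_ee": "d_ee", "d0": "d0", "dinf": "dinf"}[classify_at])
    labels = classify_aeration(density[sel])
    tau = fits.tau_s[sel]
    df = _summary_frame(
        {c: tau[labels == i] for i, c in enumerate(AERATION_CLASSES)}
    )
    if tau_volume_s is not None:
        df.attrs["tau_volume_s"] = tau_volume_s
    return df


# ---------------------------------------------------------------------------
# Gravitational height


def relative_height(mask: np.ndarray, gravity_axis: int) -> np.ndarray:
    """Relative height in [0, 1] along the gravity axis for every voxel.

    0 is the dorsal-most and 1 the ventral-most masked extent (supine
    convention: low index = dorsal).  Normalization uses the whole-mask
    bounding range on the gravity axis.
    """
    mask = np.asarray(mask, bool)
    idx = np.where(mask.any(axis=tuple(i for i in range(3) if i != gravity_axis)))[0]
    if idx.size == 0:
        raise ValueError("empty mask")
    lo, hi = idx.min(), idx.max()
    if hi == lo:
        raise ValueError("mask is flat along the gravity axis; height undefined")
    coords = np.arange(mask.shape[gravity_axis], dtype=float)
    h = (coords - lo) / (hi - lo)
    shape = [1, 1, 1]
    shape[gravity_axis] = -1
    return np.broadcast_to(h.reshape(shape), mask.shape).copy()


def height_profile(
    fits, gravity_axis: int, n_bins: int = 10, min_count: int = 10
) -> pd.DataFrame:
    """Median and IQR of fit quantities per relative-height bin.

    Bins partition [0, 1] along the dorsal-ventral axis; per-bin statistics
    cover end-inspiratory density, end-expiratory density, intratidal
    change, and the density time constant over F-significant voxels.  Bins
    with fewer than ``min_count`` voxels are flagged ``low_count``.
    """
    h = relative_height(fits.mask, gravity_axis)
    sel = fits.significant & fits.mask & np.isfinite(fits.tau_s)
    hv = h[sel]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(hv, edges[1:-1]), 0, n_bins - 1)
    quantities = {
        "d_ei_hu": fits.d0[sel],
        "d_ee_hu": fits.d_ee[sel],
        "intratidal_hu": fits.intratidal_change[sel],
        "tau_s": fits.tau_s[sel],
    }
    rows = []
    for b in range(n_bins):
        m = which == b
        row = {
            "bin": b,
            "height_lo": edges[b],
            "height_hi": edges[b + 1],
            "n": int(m.sum()),
            "low_count": bool(m.sum() < min_count),
        }
        for name, vals in quantities.items():
            if m.any():
                q1, med, q3 = np.percentile(vals[m], [25, 50, 75])
            else:
                q1 = med = q3 = np.nan
            row[f"{name}_median"] = med
            row[f"{name}_q1"] = q1
            row[f"{name}_q3"] = q3
        rows.append(row)
    return pd.DataFrame(rows).set_index("bin")


# ---------------------------------------------------------------------------
# Parametric response mapping


@dataclass
class PRMGrid:
    """2D histogram of (initial density, equilibrium density) across subjects.

    ``probability`` is the across-subject average probability per cell (sums
    to 1); ``median_tau_s`` and ``median_nonequilibrated_hu`` are pooled
    per-cell medians shown only where the inclusion rule holds: at least
    half of the subjects contribute at least ``min_voxels_per_subject``
    voxels to the cell.
    """

    bin_edges_hu: np.ndarray
    probability: np.ndarray
    median_tau_s: np.ndarray
    median_nonequilibrated_hu: np.ndarray
    inclusion_mask: np.ndarray
    n_subjects: int
    min_voxels_per_subject: int = 5

    @property
    def bin_centers_hu(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_hu[:-1] + self.bin_edges_hu[1:])


def _subject_table(subject) -> pd.DataFrame:
    """Accept a VoxelFitMaps or a DataFrame with d0/dinf/tau columns."""
    if isinstance(subject, pd.DataFrame):
        return subject
    sel = subject.significant & subject.mask & np.isfinite(subject.tau_s)
    return pd.DataFrame(
        {
            "d0_hu": subject.d0[sel],
            "dinf_hu": subject.dinf[sel],
            "tau_s": subject.tau_s[sel],
            "nonequilibrated_hu": subject.nonequilibrated_change[sel],
        }
    )


def build_prm(
    subjects,
    bin_width_hu: float = 25.0,
    range_hu: tuple[float, float] = (-1000.0, 100.0),
    min_voxels_per_subject: int = 5,
) -> PRMGrid:
    """Aggregate PRM of initial (end-inspiratory) vs. equilibrium density.

    Each subject contributes a probability-normalized 2D histogram over
    (D0, Dinf); histograms are averaged across subjects.  Median overlays
    (time constant, nonequilibrated change) pool voxels of all subjects but
    are reported only in cells where at least ``ceil(n_subjects / 2)``
    subjects have at least ``min_voxels_per_subject`` voxels.
    """
    tables = [_subject_table(s) for s in subjects]
    if not tables:
        raise ValueError("need at least one subject fit set")
    lo, hi = range_hu
    edges = np.arange(lo, hi + bin_width_hu / 2, bin_width_hu, dtype=float)
    nb = edges.size - 1
    n_subj = len(tables)

    prob = np.zeros((nb, nb))
    per_subject_counts = np.zeros((n_subj, nb, nb), dtype=int)
    for i, tab in enumerate(tables):
        cnt, _, _ = np.histogram2d(
            tab["d0_hu"], tab["dinf_hu"], bins=[edges, edges]
        )
        per_subject_counts[i] = cnt.astype(int)
        total = cnt.sum()
        if total > 0:
            prob += cnt / total
    prob /= n_subj

    need = int(np.ceil(n_subj / 2))
    inclusion = (per_subject_counts >= min_voxels_per_subject).sum(axis=0) >= need

    pooled = pd.concat(tables, ignore_index=True)
    ix = np.clip(np.digitize(pooled["d0_hu"], edges) - 1, 0, nb - 1)
    iy = np.clip(np.digitize(pooled["dinf_hu"], edges) - 1, 0, nb - 1)
    med_tau = np.full((nb, nb), np.nan)
    med_neq = np.full((nb, nb), np.nan)
    cell = ix * nb + iy
    order = np.argsort(cell, kind="stable")
    cell_sorted = cell.to_numpy()[order] if hasattr(cell, "to_numpy") else cell[order]
    bounds = np.searchsorted(cell_sorted, np.arange(nb * nb + 1))
    tau_sorted = pooled["tau_s"].to_numpy()[order]
    neq_sorted = pooled["nonequilibrated_hu"].to_numpy()[order]
    for flat in np.where(inclusion.ravel())[0]:
        s, e = bounds[flat], bounds[flat + 1]
        if e > s:
            med_tau.ravel()[flat] = np.median(tau_sorted[s:e])
            med_neq.ravel()[flat] = np.median(neq_sorted[s:e])
    return PRMGrid(
        bin_edges_hu=edges,
        probability=prob,
        median_tau_s=med_tau,
        median_nonequilibrated_hu=med_neq,
        inclusion_mask=inclusion,
        n_subjects=n_subj,
        min_voxels_per_subject=min_voxels_per_subject,
    )


# ---------------------------------------------------------------------------
# Nonequilibration and convergence


def nonequilibrated_change_map(fits) -> np.ndarray:
    """Dinf - D_EE per voxel (NaN where excluded or outside the mask)."""
    out = np.full(fits.mask.shape, np.nan)
    sel = fits.significant & fits.mask
    out[sel] = fits.nonequilibrated_change[sel]
    return out


def theoretical_convergence(x):
    """Fractional change remaining at end-expiration for tau/t_exp = x.

    The exponential-decay model leaves exp(-t_exp / tau) = exp(-1/x) of the
    total density change unrealized; at x = 0.2 this is e^-5 ≈ 0.674%.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.exp(-1.0 / np.where(x > 0, x, np.inf))
    return np.where(x > 0, out, 0.0)


def normalized_convergence(
    fits, amplitude_floor_hu: float = 5.0
) -> tuple[pd.DataFrame, int]:
    """Per-voxel normalized remaining change vs. normalized time constant.

    x = tau / t_exp and y = (Dinf - D_EE) / (Dinf - D0); on exact
    single-exponential voxels y equals the theoretical curve exp(-1/x).
    Voxels with |Dinf - D0| below ``amplitude_floor_hu`` are omitted (their
    normalization is ill-conditioned); the omitted count is returned.
    """
    sel = fits.significant & fits.mask & np.isfinite(fits.tau_s)
    amp = fits.dinf[sel] - fits.d0[sel]
    keep = np.abs(amp) >= amplitude_floor_hu
    n_omitted = int((~keep).sum())
    tau = fits.tau_s[sel][keep]
    y = (fits.nonequilibrated_change[sel][keep]) / amp[keep]
    df = pd.DataFrame({"tau_over_t_exp": tau / fits.t_exp_s, "remaining_fraction": y})
    return df, n_omitted


# ---------------------------------------------------------------------------
# Density vs. SACJ time constants


def tau_correlation(
    subject_pairs,
    alpha: float = 0.05,
    min_pairs: int = 10,
    n_hist_bins: int = 40,
    log=None,
) -> dict:
    """Per-subject rank correlation between density and SACJ time constants.

    ``subject_pairs`` is a list of (tau_density, tau_sacj) array pairs, one
    per subject, restricted to voxels significant in both fits.  Subjects
    with fewer than ``min_pairs`` paired voxels are skipped.  Returns
    per-subject Spearman rho/p, the fraction of evaluated subjects with a
    significant correlation, and an aggregate 2D probability density over
    (tau_density, tau_sacj) with an identity-line reference.
    """
    rows = []
    pooled_d, pooled_s = [], []
    for i, (td, ts) in enumerate(subject_pairs):
        td = np.asarray(td, float)
        ts = np.asarray(ts, float)
        ok = np.isfinite(td) & np.isfinite(ts)
        td, ts = td[ok], ts[ok]
        if td.size < min_pairs:
            if log is not None:
                log(f"subject {i}: only {td.size} paired voxels, skipped")
            continue
        rho, p = stats.spearmanr(td, ts)
        rows.append({"subject": i, "n": td.size, "rho": rho, "p": p})
        pooled_d.append(td)
        pooled_s.append(ts)
    table = pd.DataFrame(rows)
    frac_sig = float((table["p"] <= alpha).mean()) if len(table) else np.nan
    if pooled_d:
        d = np.concatenate(pooled_d)
        s = np.concatenate(pooled_s)
        hi = np.percentile(np.concatenate([d, s]), 99)
        edges = np.linspace(0, hi, n_hist_bins + 1)
        hist, _, _ = np.histogram2d(d, s, bins=[edges, edges], density=True)
    else:
        hist, edges = np.zeros((0, 0)), np.zeros(0)
    return {
        "per_subject": table,
        "fraction_significant": frac_sig,
        "density_hist": hist,
        "hist_edges_s": edges,
    }


# ---------------------------------------------------------------------------
# Time-course distributions


def time_course_distributions(
    fits, times_s, bins=60, value_range=None
) -> dict[float, dict]:
    """Distributions of model-predicted change from end-inspiration.

    For each requested expiratory time, histograms the per-voxel predicted
    change (Dinf - D0) * (1 - exp(-t/tau)) over F-significant voxels.  Works
    for density fits (change in HU) and SACJ fits (relative gas-volume
    change) alike.  Histograms are probability densities (integrate to 1).
    """
    sel = fits.significant & fits.mask & np.isfinite(fits.tau_s)
    amp = fits.dinf[sel] - fits.d0[sel]
    tau = fits.tau_s[sel]
    if value_range is None:
        lim = max(1e-6, np.percentile(np.abs(amp), 99.5))
        value_range = (-lim, lim)
    out = {}
    for t in np.atleast_1d(times_s):
        change = amp * (1.0 - np.exp(-float(t) / tau))
        hist, edges = np.histogram(
            np.clip(change, *value_range), bins=bins, range=value_range, density=True
        )
        out[float(t)] = {"density": hist, "edges": edges, "n": int(change.size)}
    return out
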