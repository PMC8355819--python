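"""Aeration classes, height profiles, PRMs, convergence, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lungtau.expfit import exp_model, fit_all_voxels
from lungtau.regional import (
    AERATION_CLASSES,
    build_prm,
    class_volume_fractions,
    classify_aeration,
    group_tau_by_class,
    height_profile,
    nonequilibrated_change_map,
    normalized_convergence,
    relative_height,
    tau_correlation,
    theoretical_convergence,
    time_course_distributions,
)


class TestClassification:
    @pytest.mark.parametrize(
        "hu,label",
        [
            (-950, "hyper"),
            (-700, "normal"),
            (-300, "poor"),
            (-50, "non"),
            (-900, "normal"),  # lower-edge-inclusive boundaries
            (-500, "poor"),
            (-100, "non"),
            (-900.0001, "hyper"),
        ],
    )
    def test_threshold_convention(self, hu, label):
        assert AERATION_CLASSES[int(classify_aeration(hu))] == label

    @given(st.lists(st.floats(-1100, 200), min_size=1, max_size=50))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_partition_is_exhaustive_and_exclusive(self, values):
        labels = classify_aeration(values)
        assert np.all((labels >= 0) & (labels <= 3))
        fr = class_volume_fractions(labels)
        assert fr.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_class_phantom(self):
        fr = class_volume_fractions(classify_aeration(np.full(100, -700.0)))
        assert fr["normal"] == 1.0
        assert fr.drop("normal").sum() == 0.0

    def test_constructed_quota_fractions(self, rng):
        vals = np.concatenate(
            [
                rng.uniform(-890, -510, 600),  # normal
                rng.uniform(-490, -110, 250),  # poor
                rng.uniform(-90, 40, 100),  # non
                rng.uniform(-980, -910, 50),  # hyper
            ]
        )
        fr = class_volume_fractions(classify_aeration(vals))
        assert fr["normal"] == pytest.approx(0.60, abs=0.05)
        assert fr["poor"] == pytest.approx(0.25, abs=0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            class_volume_fractions(np.array([], dtype=int))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_aeration([np.nan])


class TestRelativeHeight:
    def test_endpoints_and_midpoint(self):
        mask = np.zeros((5, 5, 9), bool)
        mask[:, :, 2:7] = True
        h = relative_height(mask, gravity_axis=2)
        assert h[0, 0, 2] == 0.0
        assert h[0, 0, 6] == 1.0
        assert h[0, 0, 4] == pytest.approx(0.5)

    def test_flat_mask_rejected(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[:, :, 2] = True
        with pytest.raises(ValueError, match="flat"):
            relative_height(mask, 2)


@pytest.fixture(scope="module")
def fits(small_seq, small_grid):
    return fit_all_voxels(small_seq, small_grid)


@pytest.fixture(scope="module")
def noiseless_fits(small_noiseless_seq, small_grid):
    return fit_all_voxels(small_noiseless_seq, small_grid)


class TestGroupAndProfile:
    def test_tau_ordering_matches_construction(self, fits, small_truth):
        """Dorsal (denser, poorly aerated) regions were built faster than
        ventral normally aerated ones; class medians recover that ordering."""
        df = group_tau_by_class(fits, classify_at="dinf")
        assert df.loc["poor", "median"] < df.loc["normal", "median"]

    def test_excluded_voxels_in_no_summary(self, fits):
        df = group_tau_by_class(fits)
        n_sig = int((fits.significant & fits.mask & np.isfinite(fits.tau_s)).sum())
        assert df["n"].sum() == n_sig

    def test_height_profile_partition(self, fits):
        prof = height_profile(fits, gravity_axis=2, n_bins=10)
        n_sig = int((fits.significant & fits.mask & np.isfinite(fits.tau_s)).sum())
        assert prof["n"].sum() == n_sig

    def test_height_profile_monotone_tau(self, fits):
        prof = height_profile(fits, gravity_axis=2, n_bins=8)
        med = prof["tau_s_median"].dropna()
        rho = pd.Series(med.values).corr(pd.Series(np.arange(med.size)), method="spearman")
        assert rho == 1.0

    def test_uniform_phantom_flat_profile(self):
        from lungtau.io import AlignedSequence
        from lungtau.breath_timing import build_phase_grid

        t = np.arange(10) / 5.0
        grid = build_phase_grid(15, 24)
        curve = exp_model(grid.expiratory_times_s, -600.0, -450.0, 0.6)
        inten = np.zeros((8, 8, 8, 15))
        inten[..., grid.expiratory_phase_indices] = curve
        seq = AlignedSequence(inten, np.ones((8, 8, 8), bool), np.ones(3))
        fits = fit_all_voxels(seq, grid)
        prof = height_profile(fits, gravity_axis=2, n_bins=4)
        assert prof["tau_s_median"].std() == pytest.approx(0.0, abs=1e-9)


class TestPRM:
    def _table(self, d0, dinf, tau=None, n=None):
        d0 = np.asarray(d0, float)
        if np.ndim(dinf) == 0:
            dinf = np.full_like(d0, dinf)
        tau = np.ones_like(d0) if tau is None else np.asarray(tau, float)
        return pd.DataFrame(
            {
                "d0_hu": d0,
                "dinf_hu": np.asarray(dinf, float),
                "tau_s": tau,
                "nonequilibrated_hu": np.zeros_like(d0),
            }
        )

    def test_identity_line_concentration(self, rng):
        vals = rng.uniform(-900, -200, 500)
        prm = build_prm([self._table(vals, vals)])
        centers = prm.bin_centers_hu
        ix, iy = np.nonzero(prm.probability)
        assert np.all(ix == iy)  # all mass in diagonal cells
        assert prm.probability.sum() == pytest.approx(1.0)

    def test_inclusion_rule_counterexample(self):
        """A cell fed >= 5 voxels by only 1 of 4 subjects is excluded."""
        rich = self._table(np.full(10, -712.0), -312.0)
        sparse = self._table(np.full(2, -712.0), -312.0)
        others = self._table(np.full(20, -212.0), -212.0)
        prm = build_prm([rich, sparse, others, others.copy()])
        nb = prm.bin_edges_hu.size - 1
        ix = np.digitize(-712.0, prm.bin_edges_hu) - 1
        iy = np.digitize(-312.0, prm.bin_edges_hu) - 1
        assert not prm.inclusion_mask[ix, iy]
        assert np.isnan(prm.median_tau_s[ix, iy])
        # the cell all four subjects feed with >= 5 voxels is included
        jx = np.digitize(-212.0, prm.bin_edges_hu) - 1
        assert prm.inclusion_mask[jx, jx]
        assert prm.median_tau_s[jx, jx] == 1.0

    def test_two_cluster_counts(self):
        t = self._table(
            np.concatenate([np.full(7, -612.0), np.full(3, -212.0)]),
            np.concatenate([np.full(7, -412.0), np.full(3, -112.0)]),
        )
        prm = build_prm([t])
        ix = np.digitize(-612.0, prm.bin_edges_hu) - 1
        iy = np.digitize(-412.0, prm.bin_edges_hu) - 1
        assert prm.probability[ix, iy] == pytest.approx(0.7)

    def test_inclusion_monotone_in_min_voxels(self, rng):
        d0 = rng.uniform(-900, -200, 300)
        dinf = d0 + rng.normal(50, 30, 300)
        tabs = [self._table(d0, dinf), self._table(d0[::2], dinf[::2])]
        loose = build_prm(tabs, min_voxels_per_subject=2)
        strict = build_prm(tabs, min_voxels_per_subject=8)
        assert not np.any(strict.inclusion_mask & ~loose.inclusion_mask)


class TestConvergence:
    def test_nonequilibrated_closed_form(self):
        t = np.arange(15) / 7.0
        fit_curve = exp_model(t, -400.0, -250.0, 1.0)
        from lungtau.expfit import fit_exponential

        fit = fit_exponential(t, fit_curve, t_exp_s=2.0)
        assert fit.nonequilibrated_change == pytest.approx(150.0 * np.exp(-2.0), abs=1e-3)
        assert fit.nonequilibrated_change == pytest.approx(20.30, abs=0.005)

    def test_theoretical_curve_values(self):
        assert theoretical_convergence(0.2) == pytest.approx(np.exp(-5.0))
        assert theoretical_convergence(1.0) == pytest.approx(0.3679, abs=5e-5)
        assert theoretical_convergence(0.0) == 0.0
        assert theoretical_convergence(1e9) == pytest.approx(1.0, abs=1e-6)

    def test_exact_exponential_voxels_lie_on_curve(self, noiseless_fits):
        df, _ = normalized_convergence(noiseless_fits)
        expected = theoretical_convergence(df["tau_over_t_exp"].to_numpy())
        np.testing.assert_allclose(
            df["remaining_fraction"].to_numpy(), expected, atol=1e-8
        )

    def test_amplitude_floor_omits_tiny_voxels(self, noiseless_fits):
        df_all, omitted = normalized_convergence(noiseless_fits, amplitude_floor_hu=5.0)
        sig = int(
            (
                noiseless_fits.significant
                & noiseless_fits.mask
                & np.isfinite(noiseless_fits.tau_s)
            ).sum()
        )
        assert len(df_all) + omitted == sig

    def test_nonequilibrated_map_nan_outside_significant(self, fits):
        neq = nonequilibrated_change_map(fits)
        assert np.isnan(neq[~fits.mask]).all()
        excl = fits.mask & ~fits.significant
        assert np.isnan(neq[excl]).all()


class TestTauCorrelation:
    def test_identity_gives_perfect_rank_correlation(self, rng):
        tau = rng.uniform(0.2, 1.5, 200)
        out = tau_correlation([(tau, tau)])
        assert out["per_subject"]["rho"].iloc[0] == pytest.approx(1.0)
        assert out["fraction_significant"] == 1.0

    def test_small_subjects_skipped(self, rng):
        out = tau_correlation([(np.ones(3), np.ones(3))])
        assert len(out["per_subject"]) == 0

    def test_null_pairs_significant_fraction_near_alpha(self, rng):
        subjects = [
            (rng.uniform(0.2, 1.5, 60), rng.uniform(0.2, 1.5, 60)) for _ in range(300)
        ]
        out = tau_correlation(subjects, alpha=0.05)
        assert 0.02 <= out["fraction_significant"] <= 0.09


class TestTimeCourse:
    def test_t0_all_mass_at_zero(self, noiseless_fits):
        out = time_course_distributions(
            noiseless_fits, [0.0], bins=41, value_range=(-300, 300)
        )
        hist = out[0.0]["density"]
        edges = out[0.0]["edges"]
        centers = (edges[:-1] + edges[1:]) / 2
        assert hist[np.argmin(np.abs(centers))] > 0
        assert (hist > 0).sum() == 1

    def test_distributions_integrate_to_one(self, fits):
        out = time_course_distributions(fits, [0.5, 1.0, 2.0])
        for t, d in out.items():
            widths = np.diff(d["edges"])
            assert (d["density"] * widths).sum() == pytest.approx(1.0, abs=1e-9)

    def test_end_expiration_matches_truth(self, noiseless_fits, small_truth, small_grid):
        """At t = t_exp the predicted change equals D_EE - D0 from the truth."""
        fits = noiseless_fits
        sel = fits.significant & fits.mask & np.isfinite(fits.tau_s)
        amp = fits.dinf[sel] - fits.d0[sel]
        change = amp * (1 - np.exp(-small_grid.t_exp_s / fits.tau_s[sel]))
        truth_change = small_truth.amplitude_map[sel] * (
            1 - np.exp(-small_grid.t_exp_s / small_truth.tau_map[sel])
        )
        np.testing.assert_allclose(change, truth_change, atol=1e-3)
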