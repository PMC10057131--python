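"""WHAM estimator: binning, self-consistency, invariances, bootstrap, file formats."""

import json

import numpy as np
import pytest

import chiralpmf.wham as wham_mod
from chiralpmf.core import KB_KCAL_MOL_K, WindowSpec, bias_energy
from chiralpmf.wham import (
    BiasedSeries,
    WHAMConfig,
    WHAMError,
    bootstrap_pmf,
    histogram_windows,
    read_pmf_tsv,
    read_series_file,
    solve_wham,
    write_pmf_sidecar,
    write_pmf_tsv,
    write_series_file,
)

from _oracles import mbar_pmf, naive_histogram

KBT = KB_KCAL_MOL_K * 300.0


class TestHistograms:
    def test_identical_values_fill_single_bin(self):
        s = BiasedSeries(window_index=0, values=np.full(10, 0.137))
        h = histogram_windows([s], WHAMConfig(bin_width=0.02))
        assert h.counts.sum() == 10
        assert (h.counts > 0).sum() == 1
        assert h.n_in[0] == 10 and h.n_out[0] == 0

    def test_value_on_edge_goes_to_right_bin(self):
        cfg = WHAMConfig(bin_width=0.5, rc_range=(0.0, 2.0))
        s = BiasedSeries(window_index=0, values=np.array([0.5, 0.5, 0.49]))
        h = histogram_windows([s], cfg)
        assert h.counts[0].tolist() == [1, 2, 0, 0]

    def test_matches_naive_per_sample_binning(self, rng):
        values = rng.normal(0.2, 0.6, size=500)
        cfg = WHAMConfig(bin_width=0.1, rc_range=(-1.0, 1.0))
        s = BiasedSeries(window_index=0, values=values)
        h = histogram_windows([s], cfg)
        ref_counts, ref_out = naive_histogram(values, h.bin_edges)
        assert np.array_equal(h.counts[0], ref_counts)
        assert h.n_out[0] == ref_out

    def test_window_with_no_overlap_named_in_error(self):
        s = BiasedSeries(window_index=3, values=np.array([5.0, 5.1]))
        with pytest.raises(WHAMError, match="window 3"):
            histogram_windows([s], WHAMConfig(rc_range=(0.0, 1.0)))


def _gaussian_series(rng, n, mean, sd, index=0):
    return BiasedSeries(window_index=index, values=rng.normal(mean, sd, size=n))


class TestSolve:
    def test_single_window_recovers_quadratic_pmf(self, rng):
        """Unbiased sampling from exp(-G/kBT) with quadratic G: the estimated
        PMF refits to the true curvature within 10% at 50k samples."""
        kappa = 10.0  # kcal/mol/A^2 -> Gaussian with var kBT/kappa
        sd = np.sqrt(KBT / kappa)
        s = _gaussian_series(rng, 50_000, 0.0, sd)
        windows = [WindowSpec(index=0, center=0.0, force_constant=1e-9)]
        cfg = WHAMConfig(bin_width=0.02)
        prof = solve_wham(histogram_windows([s], cfg), windows, cfg)
        m = prof.defined & (np.abs(prof.bin_centers) < 2 * sd)
        coef = np.polyfit(prof.bin_centers[m], prof.free_energy[m], 2)
        assert 2 * coef[0] == pytest.approx(kappa, rel=0.10)

    def test_duplicating_every_window_leaves_pmf_unchanged(self, small_campaign, small_schedule):
        """Duplicating the whole window set (every series fed in twice) rescales
        all the sample counts N_i by the same factor, which cancels exactly in
        the WHAM equations."""
        cfg = WHAMConfig(rc_range=(-2.3, 1.8))
        prof = solve_wham(histogram_windows(small_campaign, cfg), small_schedule, cfg)
        dup_series = list(small_campaign) + list(small_campaign)
        dup_windows = list(small_schedule) + list(small_schedule)
        prof2 = solve_wham(histogram_windows(dup_series, cfg), dup_windows, cfg)
        d = prof.free_energy - prof2.free_energy
        assert np.nanmax(np.abs(d)) < 1e-10

    def test_gauge_invariance_under_constant_bias_offset(
        self, small_campaign, small_schedule, monkeypatch
    ):
        cfg = WHAMConfig(rc_range=(-2.3, 1.8))
        hists = histogram_windows(small_campaign, cfg)
        ref = solve_wham(hists, small_schedule, cfg)
        orig = wham_mod._bias_matrix
        monkeypatch.setattr(
            wham_mod, "_bias_matrix", lambda *a, **k: orig(*a, **k) + 7.3
        )
        shifted = solve_wham(hists, small_schedule, cfg)
        assert np.nanmax(np.abs(ref.free_energy - shifted.free_energy)) < 1e-9

    def test_fixpoint_satisfies_both_wham_equations(self, small_campaign, small_schedule):
        cfg = WHAMConfig(rc_range=(-2.3, 1.8))
        hists = histogram_windows(small_campaign, cfg)
        prof = solve_wham(hists, small_schedule, cfg)
        f = prof.window_free_energies
        W = wham_mod._bias_matrix(hists.bin_centers, small_schedule, cfg.half_prefactor)
        N = hists.n_in.astype(float)
        total = hists.counts.sum(axis=0)
        denom = (N[:, None] * np.exp((f[:, None] - W) / KBT)).sum(axis=0)
        p = np.where(total > 0, total / denom, 0.0)
        f_back = -KBT * np.log((np.exp(-W / KBT) * p).sum(axis=1))
        f_back -= f_back[0]
        assert np.max(np.abs(f_back - f)) < cfg.tolerance * 10

    def test_temperature_and_energy_rescaling_leaves_reduced_pmf_unchanged(
        self, small_campaign, small_schedule
    ):
        c = 2.0
        cfg = WHAMConfig(rc_range=(-2.3, 1.8))
        prof = solve_wham(histogram_windows(small_campaign, cfg), small_schedule, cfg)
        cfg_hot = WHAMConfig(rc_range=(-2.3, 1.8), temperature=300.0 * c,
                             tolerance=cfg.tolerance * c)
        scaled_windows = [
            WindowSpec(index=w.index, center=w.center, force_constant=w.force_constant * c)
            for w in small_schedule
        ]
        prof_hot = solve_wham(
            histogram_windows(small_campaign, cfg_hot), scaled_windows, cfg_hot
        )
        d = prof.free_energy / KBT - prof_hot.free_energy / (KBT * c)
        assert np.nanmax(np.abs(d)) < 1e-6

    def test_agrees_with_unbinned_mbar_oracle(self, small_campaign, small_schedule):
        # Decimate to keep the O(K*N) oracle cheap; same windows, same bias.
        series = [
            BiasedSeries(window_index=s.window_index, values=s.values[::2])
            for s in small_campaign
        ]
        cfg = WHAMConfig(rc_range=(-2.3, 1.8))
        hists = histogram_windows(series, cfg)
        prof = solve_wham(hists, small_schedule, cfg)

        bias_fns = [
            (lambda xs, w=w: 0.5 * w.force_constant * (xs - w.center) ** 2)
            for w in small_schedule
        ]
        _, pmf_ref, _ = mbar_pmf(
            [s.values for s in series], bias_fns, KBT, hists.bin_edges
        )
        well = (hists.counts.sum(axis=0) > 100) & np.isfinite(pmf_ref) & prof.defined
        a = prof.free_energy[well]
        b = pmf_ref[well]
        # PMFs are each defined up to a constant: compare after matching means.
        assert np.max(np.abs((a - a.mean()) - (b - b.mean()))) < 0.1

    def test_all_empty_histograms_rejected(self):
        s = BiasedSeries(window_index=0, values=np.array([0.5]))
        cfg = WHAMConfig(rc_range=(0.0, 1.0), bin_width=0.5)
        h = histogram_windows([s], cfg)
        h = wham_mod.HistogramSet(
            bin_edges=h.bin_edges, counts=np.zeros_like(h.counts),
            n_in=h.n_in, n_out=h.n_out,
        )
        with pytest.raises(WHAMError):
            solve_wham(h, [WindowSpec(index=0, center=0.5)], cfg)

    def test_nonconvergence_is_flagged_not_raised(self, small_campaign, small_schedule):
        cfg = WHAMConfig(rc_range=(-2.3, 1.8), max_iterations=3)
        with pytest.warns(UserWarning, match="did not converge"):
            prof = solve_wham(histogram_windows(small_campaign, cfg), small_schedule, cfg)
        assert not prof.converged

    def test_empty_bins_marked_undefined(self, rng):
        s = _gaussian_series(rng, 1000, 0.0, 0.05)
        cfg = WHAMConfig(bin_width=0.02, rc_range=(-1.0, 1.0))
        windows = [WindowSpec(index=0, center=0.0)]
        prof = solve_wham(histogram_windows([s], cfg), windows, cfg)
        assert np.all(np.isnan(prof.free_energy[prof.counts == 0]))
        assert np.all(np.isfinite(prof.free_energy[prof.counts > 0]))


class TestBootstrap:
    def test_deterministic_given_seed(self, small_campaign, small_schedule):
        cfg = WHAMConfig(rc_range=(-2.3, 1.8))
        a = bootstrap_pmf(small_campaign, small_schedule, cfg, n_boot=2, seed=42)
        b = bootstrap_pmf(small_campaign, small_schedule, cfg, n_boot=2, seed=42)
        assert np.array_equal(a.bin_sd, b.bin_sd, equal_nan=True)
        assert np.array_equal(
            a.window_free_energy_sd, b.window_free_energy_sd
        )

    def test_block_resampling_runs(self, small_campaign, small_schedule):
        cfg = WHAMConfig(rc_range=(-2.3, 1.8))
        r = bootstrap_pmf(
            small_campaign, small_schedule, cfg, n_boot=3, seed=1, block_length=50
        )
        assert r.n_replicates == 3

    def test_single_window_gaussian_sd_near_delta_method(self):
        """Bootstrap SD of the anchored PMF one sigma off the well bottom vs the
        delta-method SEM of -kBT ln(p_b/p_anchor) for binomial bin counts:
        agreement within a factor 2."""
        rng = np.random.default_rng(314)
        n = 4000
        sd = np.sqrt(KBT / 10.0)
        s = _gaussian_series(rng, n, 0.0, sd)
        windows = [WindowSpec(index=0, center=0.0, force_constant=1e-9)]
        cfg = WHAMConfig(bin_width=0.05)
        boot = bootstrap_pmf([s], windows, cfg, n_boot=40, seed=3)
        hists = histogram_windows([s], cfg)
        i_anchor = int(np.argmax(hists.counts[0]))
        i = i_anchor + int(round(sd / cfg.bin_width))
        p_b = hists.counts[0][i] / n
        p_m = hists.counts[0][i_anchor] / n
        sem = KBT * np.sqrt((1 - p_b) / (n * p_b) + (1 - p_m) / (n * p_m))
        assert 0.5 * sem < boot.bin_sd[i] < 2.0 * sem


class TestFileFormats:
    def test_series_file_roundtrip(self, tmp_path):
        s = BiasedSeries(window_index=2, values=np.array([0.1, -0.2, 0.3]), sample_interval=5.0)
        path = tmp_path / "w.dat"
        write_series_file(s, path)
        back = read_series_file(path, window_index=2)
        assert np.allclose(back.values, s.values)
        assert back.sample_interval == 5.0
        # time column spans n * interval
        t = np.loadtxt(path)[:, 0]
        assert t[-1] == pytest.approx(15.0)

    def test_pmf_tsv_and_sidecar_roundtrip(self, tmp_path, small_campaign, small_schedule):
        cfg = WHAMConfig(rc_range=(-2.3, 1.8))
        prof = solve_wham(histogram_windows(small_campaign, cfg), small_schedule, cfg)
        boot = bootstrap_pmf(small_campaign, small_schedule, cfg, n_boot=2, seed=0)
        tsv = tmp_path / "pmf.tsv"
        write_pmf_tsv(prof, tsv, bootstrap=boot)
        back = read_pmf_tsv(tsv)
        assert np.allclose(back.bin_centers, prof.bin_centers)
        m = prof.defined
        assert np.allclose(back.free_energy[m], prof.free_energy[m], atol=1e-6)
        write_pmf_sidecar(prof, cfg, tmp_path / "pmf.json", bootstrap=boot)
        side = json.loads((tmp_path / "pmf.json").read_text())
        assert side["converged"] is True
        assert len(side["window_free_energies"]) == len(small_schedule)
        assert side["config"]["bin_width"] == cfg.bin_width
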