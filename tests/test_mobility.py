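"""Jump sequences, MSD fits, and jump-distance mixture models."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

import astigtrack as at
from astigtrack.mobility import (
    GlobalJumpDistanceFit,
    JumpDistanceMixture,
    JumpSequence,
    fit_msd,
    jump_sequence,
    mixture_cdf,
    msd,
)
from astigtrack.track import Trajectory

DT = 0.0165


def make_traj(x, y, z=None, dt=DT):
    n = len(x)
    z = np.zeros(n) if z is None else np.asarray(z)
    return Trajectory(
        frames=np.arange(n), t_s=np.arange(n) * dt, x=np.asarray(x, float),
        y=np.asarray(y, float), z_rel=z, z_abs=z,
    )


class TestJumpSequence:
    def test_static_trajectory_all_zero(self):
        t = make_traj(np.ones(10), np.ones(10))
        assert np.all(jump_sequence(t).r2 == 0.0)

    def test_unit_steps(self):
        t = make_traj(np.arange(10, dtype=float), np.zeros(10))
        assert np.allclose(jump_sequence(t).r2, 1.0)

    def test_xy_mode_mean_matches_4ddt(self):
        rng = np.random.default_rng(0)
        steps = rng.normal(0, np.sqrt(2 * 1.0 * DT), (20000, 3))
        pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        t = make_traj(pos[:, 0], pos[:, 1], pos[:, 2])
        r2 = jump_sequence(t, dims="xy").r2
        se = r2.std(ddof=1) / np.sqrt(r2.size)
        assert abs(r2.mean() - 4 * 1.0 * DT) < 3 * se

    def test_too_short_raises(self):
        t = make_traj([0.0, 1.0, 2.0], [0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            jump_sequence(t, lag=3)

    def test_negative_r2_rejected(self):
        with pytest.raises(ValueError):
            JumpSequence(r2=np.array([-1.0]), dt=DT)


class TestMsd:
    def test_ballistic_closed_form(self):
        v = 2.0
        t = make_traj(v * np.arange(50) * DT, np.zeros(50))
        tau, vals, _ = msd(t, "xy", 8)
        assert np.allclose(vals, v**2 * tau**2)

    def test_max_lag_bound(self):
        t = make_traj(np.zeros(5), np.zeros(5))
        with pytest.raises(ValueError):
            msd(t, "xy", 5)

    def test_guv_lipid_diffusion_recovery(self):
        """Membrane-lipid conditions: D = 0.82 µm²/s, 1354 steps at 16.5 ms."""
        D_true = 0.82
        fits = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            steps = rng.normal(0, np.sqrt(2 * D_true * DT), (1354, 2))
            pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
            pos = pos + rng.normal(0, 0.03, pos.shape)  # localization noise
            t = make_traj(pos[:, 0], pos[:, 1])
            tau, vals, npairs = msd(t, "xy", 10)
            D, _, _ = fit_msd(tau, vals, ndim=2, n_points=5, n_pairs=npairs)
            fits.append(D)
        fits = np.array(fits)
        se = fits.std(ddof=1) / np.sqrt(fits.size)
        # 3 s.e. over seeds, floored at 5% relative (guards against a lucky
        # underestimate of the seed-to-seed spread at small seed counts)
        assert abs(fits.mean() - D_true) < max(3 * se, 0.05 * D_true)


class TestMixtureCdf:
    def test_limits(self):
        assert mixture_cdf(0.0, [1.0], [1.0], DT) == pytest.approx(0.0)
        assert mixture_cdf(1e6, [1.0], [1.0], DT) == pytest.approx(1.0)
        assert mixture_cdf(0.0, [0.5, 2.0], [0.3, 0.7], DT) == pytest.approx(0.0)

    def test_3d_kernel_limits_and_order(self):
        assert mixture_cdf(0.0, [1.0], [1.0], DT, dims=3) == pytest.approx(0.0)
        assert mixture_cdf(1e6, [1.0], [1.0], DT, dims=3) == pytest.approx(1.0)
        x = np.linspace(0, 1, 50)
        assert np.all(np.diff(mixture_cdf(x, [1.0], [1.0], DT, dims=3)) > 0)


class TestJumpDistanceMixture:
    def test_single_component_recovery(self):
        rng = np.random.default_rng(2)
        r2 = rng.exponential(4 * 1.0 * DT, 10000)
        fit = JumpDistanceMixture(r2, DT, 1).fit()
        assert fit.converged
        assert fit.D[0] == pytest.approx(1.0, rel=0.03)
        assert fit.fractions[0] == 1.0

    def test_two_component_parameter_recovery(self):
        """Well-separated mixture: D within 5%, fractions within 0.03 at 1e4 jumps."""
        rng = np.random.default_rng(3)
        slow = rng.random(10000) < 0.4
        r2 = rng.exponential(4 * np.where(slow, 0.2, 2.0) * DT)
        fit = JumpDistanceMixture(r2, DT, 2).fit()
        assert fit.D[0] == pytest.approx(0.2, rel=0.05)
        assert fit.D[1] == pytest.approx(2.0, rel=0.05)
        assert fit.fractions[0] == pytest.approx(0.4, abs=0.03)

    def test_fractions_sum_to_one_and_sorted(self):
        rng = np.random.default_rng(4)
        slow = rng.random(2000) < 0.5
        r2 = rng.exponential(4 * np.where(slow, 0.1, 3.0) * DT)
        fit = JumpDistanceMixture(r2, DT, 2).fit()
        assert fit.fractions.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(fit.D) > 0)

    def test_mle_cross_check_agrees(self):
        rng = np.random.default_rng(5)
        slow = rng.random(8000) < 0.4
        r2 = rng.exponential(4 * np.where(slow, 0.2, 2.0) * DT)
        model = JumpDistanceMixture(r2, DT, 2)
        cdf_fit = model.fit()
        mle_fit = model.fit_mle()
        assert mle_fit.D[0] == pytest.approx(cdf_fit.D[0], rel=0.15)
        assert mle_fit.fractions[0] == pytest.approx(cdf_fit.fractions[0], abs=0.05)

    def test_histogram_fit_agrees_with_cdf_fit(self):
        # the histogram of squared jumps is an exponential density whose fit
        # is an independent route to D
        rng = np.random.default_rng(6)
        r2 = rng.exponential(4 * 1.0 * DT, 10000)
        hist, edges = np.histogram(r2, bins=50, density=True)
        ctr = 0.5 * (edges[:-1] + edges[1:])
        (D_hist,), _ = curve_fit(
            lambda x, D: np.exp(-x / (4 * D * DT)) / (4 * D * DT), ctr, hist, p0=[0.5]
        )
        D_cdf = JumpDistanceMixture(r2, DT, 1).fit().D[0]
        assert D_hist == pytest.approx(D_cdf, rel=0.05)

    def test_too_few_jumps_raises(self):
        with pytest.raises(ValueError):
            JumpDistanceMixture(np.ones(40), DT, 1)

    def test_summary_mentions_components(self):
        rng = np.random.default_rng(7)
        fit = JumpDistanceMixture(rng.exponential(4 * DT, 500), DT, 1).fit()
        s = fit.summary()
        assert "components: 1" in s and "D (um^2/s)" in s


class TestGlobalFit:
    def _seqs(self, fractions, n=400, seed=9, D=(0.85, 1.69)):
        rng = np.random.default_rng(seed)
        seqs = []
        for i, a1 in enumerate(fractions):
            slow = rng.random(n) < a1
            r2 = rng.exponential(4 * np.where(slow, D[0], D[1]) * DT)
            seqs.append(JumpSequence(r2, DT, traj_id=i))
        return seqs

    def test_identical_copies_identical_fractions(self):
        seqs = self._seqs([0.5])
        twin = [JumpSequence(seqs[0].r2.copy(), DT, traj_id=1)]
        res = GlobalJumpDistanceFit(seqs + twin, 2).fit()
        assert res.fractions_per_traj[0] == pytest.approx(res.fractions_per_traj[1], abs=1e-6)

    def test_pure_states_recovered(self):
        res = GlobalJumpDistanceFit(self._seqs([1.0, 1.0, 0.0, 0.0]), 2).fit()
        slow = res.fractions_per_traj[:, 0]
        assert slow[0] > 0.85 and slow[1] > 0.85
        assert slow[2] < 0.15 and slow[3] < 0.15

    def test_pooled_close_to_weighted_mean(self):
        res = GlobalJumpDistanceFit(self._seqs([0.2, 0.4, 0.6, 0.8], n=600, seed=12), 2).fit()
        w = res.n_jumps_per_traj / res.n_jumps_per_traj.sum()
        weighted = float((res.fractions_per_traj[:, 0] * w).sum())
        assert res.pooled_fractions[0] == pytest.approx(weighted, abs=0.02)

    def test_requires_two_trajectories(self):
        with pytest.raises(ValueError):
            GlobalJumpDistanceFit(self._seqs([0.5]), 2)

    def test_mismatched_dt_rejected(self):
        seqs = self._seqs([0.5, 0.5])
        bad = JumpSequence(seqs[1].r2, DT * 2, traj_id=1)
        with pytest.raises(ValueError):
            GlobalJumpDistanceFit([seqs[0], bad], 2)
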