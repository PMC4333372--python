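"""Diffusion analysis: MSD curves and jump-distance distribution fits.

For free 2D Brownian motion the squared frame-to-frame displacement r² is
exponentially distributed, so the cumulative distribution of jumps is

    P(r², Δt) = 1 − Σᵢ aᵢ exp(−r² / (4 Dᵢ Δt)),      Σᵢ aᵢ = 1,

where each component i is a mobility state with diffusion coefficient Dᵢ and
occupancy aᵢ.  Fitting this model to the empirical CDF of squared jumps
resolves mobility fractions that an MSD fit averages away.  The same
machinery supports a *global* fit across many trajectories: one shared set
of Dᵢ, free per-trajectory fractions.

The fitting interface follows the model/results convention: build a
:class:`JumpDistanceMixture` (or :class:`GlobalJumpDistanceFit`) from data,
call ``fit()``, and read estimates, uncertainties and a ``summary()`` table
off the returned results object.

3D note: for particles on a curved membrane, 3D Euclidean displacements may
be analysed with the 2D kernel (displacements small against the membrane
curvature radius); for genuinely free 3D motion the 3D kernel
``P(r²) = erf(x) − 2x·exp(−x²)/√π`` with ``x = sqrt(r²/(4DΔt))`` is used
(`dims=3`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.special import erf

from .track import Trajectory

__all__ = [
    "JumpSequence",
    "MobilityFit",
    "GlobalMobilityFit",
    "JumpDistanceMixture",
    "GlobalJumpDistanceFit",
    "jump_sequence",
    "msd",
    "fit_msd",
    "fit_cjdd",
    "global_fit",
    "mixture_cdf",
]

MIN_JUMPS_PER_COMPONENT = 50


@dataclass(frozen=True)
class JumpSequence:
    """Time-ordered squared displacements of one trajectory."""

    r2: np.ndarray
    dt: float
    dims: int = 2
    traj_id: int = 0

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        if np.any(r2 < 0):
            raise ValueError("squared displacements must be >= 0")
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "r2", r2)

    def __len__(self) -> int:
        return int(self.r2.size)


def jump_sequence(traj: Trajectory, dims: str = "xy", lag: int = 1) -> JumpSequence:
    """Squared displacements between frames ``i`` and ``i+lag``.

    ``dims="xy"`` uses lateral displacements only (the usual in vivo choice,
    lateral precision being the better one); ``dims="xyz"`` uses full 3D
    Euclidean displacements (membrane/GUV analysis).  The analysis
    dimensionality stored on the result is 2 in both cases by convention —
    3D Euclidean jumps on a quasi-2D surface are analysed with 2D kernels —
    unless overridden downstream.
    """
    if len(traj) < lag + 1:
        raise ValueError("trajectory too short for the requested lag")
    if dims == "xy":
        pos = np.column_stack([traj.x, traj.y])
    elif dims == "xyz":
        pos = traj.xyz
    else:
        raise ValueError("dims must be 'xy' or 'xyz'")
    d = pos[lag:] - pos[:-lag]
    dt = float(np.median(np.diff(traj.t_s))) * lag
    return JumpSequence(r2=(d**2).sum(axis=1), dt=dt, dims=2, traj_id=traj.traj_id)


def msd(traj: Trajectory, dims: str = "xy", max_lag: int = 10):
    """Time-averaged mean squared displacement for lags 1..max_lag.

    Returns ``(tau, msd_values, n_pairs)``; ``tau`` in seconds.
    """
    n = len(traj)
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the trajectory length")
    if dims == "xy":
        pos = np.column_stack([traj.x, traj.y])
    elif dims == "xyz":
        pos = traj.xyz
    else:
        raise ValueError("dims must be 'xy' or 'xyz'")
    dt = float(np.median(np.diff(traj.t_s)))
    taus = dt * np.arange(1, max_lag + 1)
    vals = np.empty(max_lag)
    npairs = np.empty(max_lag, dtype=np.int64)
    for m in range(1, max_lag + 1):
        d = pos[m:] - pos[:-m]
        vals[m - 1] = (d**2).sum(axis=1).mean()
        npairs[m - 1] = n - m
    return taus, vals, npairs


def fit_msd(taus, msd_values, ndim: int = 2, n_points: int = 5, n_pairs=None):
    """Diffusion coefficient from the first ``n_points`` MSD lags.

    Weighted linear fit of MSD = 2·ndim·D·τ + c; the intercept absorbs
    (positive or negative) localization-noise offsets.  Weights default to
    the pair counts per lag.  Returns ``(D, offset, D_stderr)``.
    """
    taus = np.asarray(taus, dtype=float)[:n_points]
    y = np.asarray(msd_values, dtype=float)[:n_points]
    w = np.ones_like(taus) if n_pairs is None else np.asarray(n_pairs, dtype=float)[:n_points]
    if taus.size < 2:
        raise ValueError("need at least 2 MSD points to fit")
    if taus.size > 2:
        coef, cov = np.polyfit(taus, y, 1, w=np.sqrt(w), cov=True)
        D_se = float(np.sqrt(cov[0, 0]) / (2.0 * ndim))
    else:
        coef = np.polyfit(taus, y, 1, w=np.sqrt(w))
        D_se = float("nan")
    slope, offset = coef
    return float(slope / (2.0 * ndim)), float(offset), D_se


def mixture_cdf(r2, D, fractions, dt: float, dims: int = 2):
    """Model CDF of squared jumps for a mobility mixture.

    2D kernel: ``1 − Σ aᵢ exp(−r²/(4DᵢΔt))``.
    3D kernel: ``Σ aᵢ (erf(xᵢ) − 2xᵢ e^{−xᵢ²}/√π)`` with ``xᵢ = sqrt(r²/(4DᵢΔt))``.
    """
    r2 = np.asarray(r2, dtype=float)
    D = np.atleast_1d(np.asarray(D, dtype=float))
    a = np.atleast_1d(np.asarray(fractions, dtype=float))
    out = np.zeros_like(r2, dtype=float)
    for Di, ai in zip(D, a):
        x2 = r2 / (4.0 * Di * dt)
        if dims == 2:
            out += ai * (1.0 - np.exp(-x2))
        else:
            x = np.sqrt(x2)
            out += ai * (erf(x) - 2.0 * x * np.exp(-x2) / np.sqrt(np.pi))
    return out


@dataclass
class MobilityFit:
    """Results of a cumulative jump-distance mixture fit.

    ``D`` ascending (µm²/s) with matching ``fractions`` (summing to one
    exactly), standard errors propagated from the least-squares Jacobian,
    and the residual sum of squares of the CDF fit.
    """

    D: np.ndarray
    fractions: np.ndarray
    D_stderr: np.ndarray
    fraction_stderr: np.ndarray
    rss: float
    n_jumps: int
    dt: float
    dims: int
    converged: bool = True

    def __post_init__(self) -> None:
        order = np.argsort(self.D)
        for name in ("D", "fractions", "D_stderr", "fraction_stderr"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float)[order])
        s = self.fractions.sum()
        if s > 0:
            self.fractions = self.fractions / s

    def summary(self) -> str:
        lines = [
            "Jump-distance mixture fit",
            f"  components: {self.D.size}   jumps: {self.n_jumps}   "
            f"dt: {self.dt * 1e3:.2f} ms   kernel: {self.dims}D",
            f"  residual SS: {self.rss:.3e}   converged: {self.converged}",
            "  comp        D (um^2/s)        fraction",
        ]
        for i, (d, ds, a, as_) in enumerate(
            zip(self.D, self.D_stderr, self.fractions, self.fraction_stderr), 1
        ):
            lines.append(f"  {i:>4}  {d:8.4f} ± {ds:.4f}   {a:6.3f} ± {as_:.3f}")
        return "\n".join(lines)


class JumpDistanceMixture:
    """Mixture-of-diffusion-states model for a set of squared jumps.

    Parameters
    ----------
    r2 : array
        Squared displacements (µm²), pooled or from one trajectory.
    dt : float
        Lag time between the positions forming each jump (s).
    n_components : int
        Number of mobility states to fit.
    dims : {2, 3}
        CDF kernel dimensionality (see :func:`mixture_cdf`).
    """

    #: log-spaced initial diffusion coefficients tried during multi-start (µm²/s)
    D_SEED_RANGE = (0.01, 20.0)
    N_STARTS = 4

    def __init__(self, r2, dt: float, n_components: int = 1, dims: int = 2,
                 weights: str = "ecdf"):
        self.r2 = np.sort(np.asarray(r2, dtype=float))
        if np.any(self.r2 < 0):
            raise ValueError("squared displacements must be >= 0")
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.r2.size < MIN_JUMPS_PER_COMPONENT * n_components:
            raise ValueError(
                f"need at least {MIN_JUMPS_PER_COMPONENT} jumps per component "
                f"({self.r2.size} given for {n_components})"
            )
        if weights not in ("ecdf", "none"):
            raise ValueError("weights must be 'ecdf' or 'none'")
        self.dt = float(dt)
        self.m = int(n_components)
        self.dims = int(dims)
        # empirical CDF evaluated at the sorted sample points
        n = self.r2.size
        self.ecdf = (np.arange(1, n + 1) - 0.5) / n
        # inverse-variance weights for the ECDF (binomial variance P(1-P)/n);
        # proper weighting noticeably reduces the small-sample bias of
        # close-component mixtures compared to an unweighted CDF fit
        if weights == "ecdf":
            self.w = 1.0 / np.sqrt(np.clip(self.ecdf * (1.0 - self.ecdf), 1e-6, None) / n)
        else:
            self.w = np.ones(n)

    # -- parameterization: theta = [log D_1..m, softmax logits for a_1..m-1] --
    def _unpack(self, theta):
        D = np.exp(theta[: self.m])
        if self.m == 1:
            return D, np.array([1.0])
        raw = np.concatenate([theta[self.m :], [0.0]])  # last component is reference
        e = np.exp(raw - raw.max())
        return D, e / e.sum()

    def _residuals(self, theta):
        D, a = self._unpack(theta)
        return self.w * (mixture_cdf(self.r2, D, a, self.dt, self.dims) - self.ecdf)

    def _starts(self):
        lo, hi = self.D_SEED_RANGE
        # deterministic ladder: D sets spread around the sample scale plus a
        # wide fallback spanning the whole seed range (fixed order)
        scale = max(np.median(self.r2) / (4.0 * self.dt), lo)
        seeds = []
        for spread in (2.0, 5.0, 10.0, 30.0):
            picks = np.geomspace(
                max(lo, scale / spread), min(hi, max(scale * spread, lo * 2)), self.m
            )
            seeds.append(np.concatenate([np.log(picks), np.zeros(self.m - 1)]))
        seeds.append(np.concatenate([np.log(np.geomspace(lo, hi, self.m)), np.zeros(self.m - 1)]))
        return seeds[: self.N_STARTS + 1]

    def fit(self) -> MobilityFit:
        """Least-squares fit of the model CDF to the empirical CDF.

        Multi-start over a fixed ladder of initial diffusion coefficients
        (deterministic given the data); the best local optimum is kept.
        Standard errors come from the Gauss–Newton covariance with the
        residual variance estimated from the fit.
        """
        best = None
        for theta0 in self._starts():
            try:
                res = least_squares(self._residuals, theta0, method="lm", max_nfev=2000)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            return MobilityFit(
                D=np.full(self.m, np.nan),
                fractions=np.full(self.m, np.nan),
                D_stderr=np.full(self.m, np.nan),
                fraction_stderr=np.full(self.m, np.nan),
                rss=float("nan"),
                n_jumps=self.r2.size,
                dt=self.dt,
                dims=self.dims,
                converged=False,
            )
        D, a = self._unpack(best.x)
        D_se, a_se = self._stderr(best)
        return MobilityFit(
            D=D,
            fractions=a,
            D_stderr=D_se,
            fraction_stderr=a_se,
            rss=float(2 * best.cost),
            n_jumps=self.r2.size,
            dt=self.dt,
            dims=self.dims,
            converged=bool(best.success),
        )

    def _stderr(self, res):
        n, p = self.r2.size, res.x.size
        dof = max(n - p, 1)
        s2 = 2 * res.cost / dof
        try:
            JTJ = res.jac.T @ res.jac
            cov_theta = s2 * np.linalg.pinv(JTJ)
            # delta method through _unpack
            eps = 1e-6
            base_D, base_a = self._unpack(res.x)
            G = np.zeros((2 * self.m, p))
            for j in range(p):
                step = np.zeros(p)
                step[j] = eps
                Dp, ap = self._unpack(res.x + step)
                G[: self.m, j] = (Dp - base_D) / eps
                G[self.m :, j] = (ap - base_a) / eps
            cov_out = G @ cov_theta @ G.T
            se = np.sqrt(np.clip(np.diag(cov_out), 0, None))
            return se[: self.m], se[self.m :]
        except Exception:
            return np.full(self.m, np.nan), np.full(self.m, np.nan)

    def fit_mle(self) -> MobilityFit:
        """Maximum-likelihood cross-check (2D kernel only).

        The 2D squared-jump density is a mixture of exponentials with means
        4DᵢΔt; MLE provides an independent route to the same parameters and
        is exposed for validation, not as the default.
        """
        if self.dims != 2:
            raise NotImplementedError("MLE cross-check implemented for the 2D kernel")
        r2 = self.r2

        def nll(theta):
            D, a = self._unpack(theta)
            mean = 4.0 * D * self.dt
            dens = (a / mean) * np.exp(-r2[:, None] / mean)
            return -np.log(np.clip(dens.sum(axis=1), 1e-300, None)).sum()

        best = None
        for theta0 in self._starts():
            res = minimize(nll, theta0, method="Nelder-Mead",
                           options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
            if best is None or res.fun < best.fun:
                best = res
        D, a = self._unpack(best.x)
        return MobilityFit(
            D=D,
            fractions=a,
            D_stderr=np.full(self.m, np.nan),
            fraction_stderr=np.full(self.m, np.nan),
            rss=float(best.fun),
            n_jumps=r2.size,
            dt=self.dt,
            dims=self.dims,
            converged=bool(best.success),
        )


@dataclass
class GlobalMobilityFit:
    """Results of a global fit: shared D, per-trajectory and pooled fractions."""

    D: np.ndarray
    D_stderr: np.ndarray
    fractions_per_traj: np.ndarray  # (n_traj, m)
    pooled_fractions: np.ndarray
    pooled_fraction_stderr: np.ndarray
    traj_ids: list
    n_jumps_per_traj: np.ndarray
    rss: float
    dt: float
    dims: int
    converged: bool = True

    def summary(self) -> str:
        lines = [
            "Global jump-distance mixture fit",
            f"  trajectories: {len(self.traj_ids)}   total jumps: {int(self.n_jumps_per_traj.sum())}",
            "  shared D (um^2/s): "
            + ", ".join(f"{d:.4f} ± {s:.4f}" for d, s in zip(self.D, self.D_stderr)),
            "  pooled fractions:  "
            + ", ".join(
                f"{a:.3f} ± {s:.3f}"
                for a, s in zip(self.pooled_fractions, self.pooled_fraction_stderr)
            ),
            "  traj   n_jumps   fractions",
        ]
        for tid, n, fr in zip(self.traj_ids, self.n_jumps_per_traj, self.fractions_per_traj):
            lines.append(f"  {tid!s:>4}  {int(n):>7}   " + ", ".join(f"{a:.3f}" for a in fr))
        return "\n".join(lines)


class GlobalJumpDistanceFit:
    """Shared-D mixture model across several jump sequences.

    One set of diffusion coefficients is estimated jointly on all
    trajectories, while each trajectory keeps its own state fractions — the
    appropriate model when particles share mobility states but occupy them
    to different degrees.
    """

    def __init__(self, sequences: list[JumpSequence], n_components: int = 2, dims: int = 2,
                 weights: str = "ecdf"):
        if len(sequences) < 2:
            raise ValueError("global fit needs at least 2 trajectories")
        if len({s.dt for s in sequences}) != 1:
            raise ValueError("all sequences must share the same lag time")
        self.sequences = sequences
        self.m = int(n_components)
        self.dims = int(dims)
        self.dt = float(sequences[0].dt)
        self.weights = weights
        self._sorted = [np.sort(s.r2) for s in sequences]
        self._ecdf = [(np.arange(1, r.size + 1) - 0.5) / r.size for r in self._sorted]
        if weights == "ecdf":
            self._w = [
                1.0 / np.sqrt(np.clip(e * (1.0 - e), 1e-6, None) / e.size) for e in self._ecdf
            ]
        else:
            self._w = [np.ones(e.size) for e in self._ecdf]

    def _unpack(self, theta):
        D = np.exp(theta[: self.m])
        fracs = []
        k = self.m
        for _ in self.sequences:
            raw = theta[k : k + self.m - 1]
            full = np.concatenate([np.exp(raw), [1.0]])
            fracs.append(full / full.sum())
            k += self.m - 1
        return D, np.array(fracs)

    def _residuals(self, theta):
        D, fracs = self._unpack(theta)
        out = []
        for r2s, ec, w, a in zip(self._sorted, self._ecdf, self._w, fracs):
            out.append(w * (mixture_cdf(r2s, D, a, self.dt, self.dims) - ec))
        return np.concatenate(out)

    def fit(self, init: MobilityFit | None = None) -> GlobalMobilityFit:
        """Joint least squares over all per-trajectory CDF residuals.

        Initialized from a pooled single fit unless ``init`` is given
        (deterministic).  Pooled fractions are additionally fitted on the
        concatenated data with the shared D fixed.
        """
        if init is None:
            pooled_r2 = np.concatenate([s.r2 for s in self.sequences])
            init = JumpDistanceMixture(pooled_r2, self.dt, self.m, self.dims, self.weights).fit()
        theta0 = np.concatenate(
            [
                np.log(np.clip(init.D, 1e-6, None)),
                np.tile(
                    np.log(np.clip(init.fractions[:-1], 1e-3, None) / max(init.fractions[-1], 1e-3)),
                    len(self.sequences),
                ),
            ]
        )
        res = least_squares(self._residuals, theta0, method="lm", max_nfev=5000)
        D, fracs = self._unpack(res.x)
        order = np.argsort(D)
        D, fracs = D[order], fracs[:, order]

        n_per = np.array([s.r2.size for s in self.sequences])
        # pooled fractions with the shared D fixed
        pooled_r2 = np.sort(np.concatenate([s.r2 for s in self.sequences]))
        pooled_ec = (np.arange(1, pooled_r2.size + 1) - 0.5) / pooled_r2.size
        if self.weights == "ecdf":
            pooled_w = 1.0 / np.sqrt(
                np.clip(pooled_ec * (1.0 - pooled_ec), 1e-6, None) / pooled_ec.size
            )
        else:
            pooled_w = np.ones(pooled_ec.size)

        def pooled_res(raw):
            full = np.concatenate([np.exp(raw), [1.0]])
            a = full / full.sum()
            return pooled_w * (mixture_cdf(pooled_r2, D, a, self.dt, self.dims) - pooled_ec)

        raw0 = np.zeros(self.m - 1)
        pres = least_squares(pooled_res, raw0, method="lm", max_nfev=2000)
        full = np.concatenate([np.exp(pres.x), [1.0]])
        pooled_a = full / full.sum()

        D_se = self._shared_D_stderr(res)
        pooled_se = self._pooled_fraction_stderr(pres, pooled_r2.size)
        return GlobalMobilityFit(
            D=D,
            D_stderr=D_se[order],
            fractions_per_traj=fracs,
            pooled_fractions=pooled_a,
            pooled_fraction_stderr=pooled_se,
            traj_ids=[s.traj_id for s in self.sequences],
            n_jumps_per_traj=n_per,
            rss=float(2 * res.cost),
            dt=self.dt,
            dims=self.dims,
            converged=bool(res.success),
        )

    def _shared_D_stderr(self, res):
        try:
            n = sum(r.size for r in self._sorted)
            dof = max(n - res.x.size, 1)
            s2 = 2 * res.cost / dof
            cov = s2 * np.linalg.pinv(res.jac.T @ res.jac)
            logD_var = np.diag(cov)[: self.m]
            return np.exp(res.x[: self.m]) * np.sqrt(np.clip(logD_var, 0, None))
        except Exception:
            return np.full(self.m, np.nan)

    def _pooled_fraction_stderr(self, pres, n):
        try:
            dof = max(n - pres.x.size, 1)
            s2 = 2 * pres.cost / dof
            cov = s2 * np.linalg.pinv(pres.jac.T @ pres.jac)
            eps = 1e-6
            full0 = np.concatenate([np.exp(pres.x), [1.0]])
            a0 = full0 / full0.sum()
            G = np.zeros((self.m, pres.x.size))
            for j in range(pres.x.size):
                step = np.zeros(pres.x.size)
                step[j] = eps
                full = np.concatenate([np.exp(pres.x + step), [1.0]])
                G[:, j] = (full / full.sum() - a0) / eps
            se = np.sqrt(np.clip(np.diag(G @ cov @ G.T), 0, None))
            return se
        except Exception:
            return np.full(self.m, np.nan)


def fit_cjdd(r2, dt: float, n_components: int = 1, dims: int = 2) -> MobilityFit:
    """Cumulative jump-distance distribution fit (functional wrapper)."""
    return JumpDistanceMixture(r2, dt, n_components, dims).fit()


def global_fit(sequences: list[JumpSequence], n_components: int = 2, dims: int = 2) -> GlobalMobilityFit:
    """Global shared-D fit across trajectories (functional wrapper)."""
    return GlobalJumpDistanceFit(sequences, n_components, dims).fit()
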