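"""Quick-look plots for calibrations, trajectories and mixture fits.

Matplotlib figures only; every function returns the Axes (or array of Axes)
so callers can restyle or save them.
"""

from __future__ import annotations

import numpy as np

from .calibrate import CalibrationCurve
from .mobility import MobilityFit, mixture_cdf
from .track import Trajectory

__all__ = ["plot_calibration", "plot_trajectory", "plot_cjdd_fit"]


def plot_calibration(curve: CalibrationCurve, z=None, metric=None, ax=None):
    """Calibration line over its valid range, optionally with measured points."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    lo, hi = curve.valid_range
    zz = np.linspace(lo, hi, 100)
    ax.plot(zz, curve.a * zz + curve.b, label=f"a={curve.a:.3f}/µm, b={curve.b:.3f}")
    if z is not None and metric is not None:
        ax.plot(z, metric, "o", ms=4, label="measured")
    ax.axvspan(*curve.fit_range, alpha=0.1)
    ax.set_xlabel("z_rel (µm)")
    ax.set_ylabel("(ξ2 − ξ1)/(ξ1 + ξ2)")
    ax.legend()
    return ax


def plot_trajectory(traj: Trajectory, ax=None):
    """xy path coloured by time plus the axial coordinate versus time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(1, 2, figsize=(9, 4))
    ax[0].scatter(traj.x, traj.y, c=traj.t_s, s=4)
    ax[0].set_xlabel("x (µm)")
    ax[0].set_ylabel("y (µm)")
    ax[0].set_aspect("equal")
    z = traj.z_abs if traj.z_abs is not None else traj.z_rel
    ax[1].plot(traj.t_s, z, lw=0.8)
    ax[1].set_xlabel("t (s)")
    ax[1].set_ylabel("z (µm)")
    return ax


def plot_cjdd_fit(fit: MobilityFit, r2, ax=None):
    """Empirical CDF of squared jumps with the fitted mixture overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    r2s = np.sort(np.asarray(r2, dtype=float))
    ecdf = (np.arange(1, r2s.size + 1) - 0.5) / r2s.size
    ax.semilogx(r2s, ecdf, ".", ms=2, label="data")
    ax.semilogx(
        r2s,
        mixture_cdf(r2s, fit.D, fit.fractions, fit.dt, fit.dims),
        label=", ".join(f"D={d:.2f} ({a:.0%})" for d, a in zip(fit.D, fit.fractions)),
    )
    ax.set_xlabel("r² (µm²)")
    ax.set_ylabel("P(r²)")
    ax.legend()
    return ax
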