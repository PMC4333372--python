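"""Mobility-state statistics on single trajectories.

A squared-displacement threshold r²_lim splits the jumps of a trajectory
into a slow state A (r² ≤ r²_lim, probability p_A given by the empirical
CDF at the threshold) and a fast state B.  If jumps were independent draws
from the observed jump-distance distribution, the state sequence would be a
Bernoulli process — so unusually long same-state runs ("dwells") and an
unusually low number of A↔B transitions both betray genuine mobility-state
kinetics (e.g. transient binding).

Two exact/analytic test statistics are provided:

* Run-length significance.  The probability that n Bernoulli trials with
  success probability p contain NO success run of length ≥ k has the closed
  form (an alternating sum over the number m of disjoint runs)

      Σ_{m=0}^{⌊(n+1)/(k+1)⌋} (−1)^m p^{mk} (1−p)^{m−1}
          [ C(n−mk, m−1) + (1−p) C(n−mk, m) ] ,

  and the significance P′ of an observed dwell of length k is the
  complement: the probability of seeing at least one such run.  P′ < 0.05
  flags a dwell as non-random.

* Transition deficit.  The expected number of state changes in n i.i.d.
  jumps is ⟨s′⟩ = 2 p_A p_B n with s.d. σ_s′ = √(p_A p_B n); an observed
  count s falling short of ⟨s′⟩ by ≥ 2σ (one-sided normal tail ≈ 0.023)
  indicates state retention without locating individual dwells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .mobility import JumpSequence

__all__ = [
    "StateSequence",
    "DwellEvent",
    "TransitionStats",
    "classify",
    "prob_no_run",
    "dwell_significance",
    "find_dwells",
    "scan_thresholds",
    "transition_stats",
]


@dataclass(frozen=True)
class StateSequence:
    """Binary state labels for a jump sequence under one threshold.

    ``labels`` is True for state A (r² ≤ r²_lim); ``p_a`` is the empirical
    CDF of r² at the threshold.
    """

    labels: np.ndarray
    r2_lim: float
    p_a: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=bool))

    @property
    def n(self) -> int:
        return int(self.labels.size)

    @property
    def p_b(self) -> float:
        return 1.0 - self.p_a


@dataclass(frozen=True)
class DwellEvent:
    """A maximal same-state run with its run-length significance."""

    start: int
    length: int
    state: str  # "A" (slow) or "B" (fast)
    r2_lim: float
    p_value: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


@dataclass(frozen=True)
class TransitionStats:
    """Observed vs expected A↔B transition counts under the i.i.d. null."""

    s_observed: int
    s_expected: float
    sigma: float
    z_deficit: float
    tail_probability: float
    degenerate: bool = False


def classify(jumps: JumpSequence, r2_lim: float) -> StateSequence:
    """Threshold a jump sequence into slow/fast states.

    p_A is the fraction of jumps at or below the threshold — i.e. the
    empirical CDF of r² evaluated at r²_lim.
    """
    if len(jumps) < 1:
        raise ValueError("need at least one jump")
    labels = jumps.r2 <= r2_lim
    return StateSequence(labels=labels, r2_lim=float(r2_lim), p_a=float(labels.mean()))


def prob_no_run(n: int, k: int, p: float) -> float:
    """Probability that n Bernoulli(p) trials contain no success run ≥ k.

    Evaluates the exact alternating sum (binomial coefficients with negative
    lower index vanish; the upper limit is ⌊(n+1)/(k+1)⌋).  Terms are
    accumulated in the log domain so large n does not overflow.  Degenerate
    probabilities are handled exactly: p = 0 → 1; p = 1 → 0 for k ≤ n.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if n < 1 or k < 1:
        raise ValueError("require n >= 1 and k >= 1")
    if k > n:
        return 1.0
    if p == 0.0:
        return 1.0
    if p == 1.0:
        return 0.0
    q = 1.0 - p
    log_p, log_q = math.log(p), math.log(q)
    upper = (n + 1) // (k + 1)
    m = np.arange(upper + 1)
    nm = n - m * k
    log_c1 = _log_comb(nm, m - 1)  # -inf where the lower index is negative/overshoots
    log_c2 = log_q + _log_comb(nm, m)
    with np.errstate(invalid="ignore"):
        log_bracket = np.logaddexp(log_c1, log_c2)
    log_term = m * k * log_p + (m - 1) * log_q + log_bracket
    # the sum alternates: when individual terms dwarf the (≤1) result, double
    # precision cannot cancel them and the equivalent recurrence is used
    if np.nanmax(log_term) > 28.0:  # terms above ~1e12
        return _prob_no_run_recurrence(n, k, p)
    terms = np.where(np.isfinite(log_term), np.exp(log_term), 0.0)
    total = float(np.sum(np.where(m % 2 == 0, terms, -terms)))
    return min(max(total, 0.0), 1.0)


def _prob_no_run_recurrence(n: int, k: int, p: float) -> float:
    """P(no success run ≥ k) via the stable linear recurrence.

    f(i) = f(i-1) - (1-p) p^k f(i-k-1) with f(i) = 1 for i < k and
    f(k) = 1 - p^k; mathematically identical to the alternating sum but
    free of cancellation, O(n) time.
    """
    if k > n:
        return 1.0
    coeff = (1.0 - p) * p**k
    f = np.ones(n + 2)  # index shifted by 1 so f[-1] ~ f(i=-1 .. not needed)
    f[: k + 1] = 1.0  # f(0..k-1) = 1 at indices 0..k-1
    f[k] = 1.0 - p**k
    for i in range(k + 1, n + 1):
        back = f[i - k - 1]
        f[i] = f[i - 1] - coeff * back
    return float(min(max(f[n], 0.0), 1.0))


def _log_comb(n, k):
    """log C(n, k), elementwise; -inf outside 0 <= k <= n."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    from scipy.special import gammaln

    with np.errstate(invalid="ignore"):
        out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where((k < 0) | (k > n), -np.inf, out)


def dwell_significance(n: int, k: int, p: float) -> float:
    """P′: probability of at least one run of ≥ k same-state jumps in n trials.

    The complement of :func:`prob_no_run`; monotone non-increasing in k and
    non-decreasing in p and n.  Small values flag an observed dwell of
    length k as incompatible with i.i.d. draws from the jump-distance
    distribution.
    """
    return 1.0 - prob_no_run(n, k, p)


def _runs(labels: np.ndarray):
    """Yield (start, length, value) for maximal constant runs."""
    n = labels.size
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            yield start, i - start, bool(labels[start])
            start = i


def find_dwells(seq: StateSequence, alpha: float = 0.05) -> list[DwellEvent]:
    """Annotate every maximal same-state run with its run-length significance.

    Each run of length k in state X gets P′ = dwell_significance(n, k, p_X),
    with p_X the empirical probability of that state over the whole
    trajectory (the candidate dwell included, which biases p_X upward and
    makes the test conservative).  Events with P′ < ``alpha`` are the
    significant dwells.
    """
    if seq.n < 2:
        raise ValueError("need at least 2 jumps")
    events = []
    for start, length, is_a in _runs(seq.labels):
        p_state = seq.p_a if is_a else seq.p_b
        p_val = dwell_significance(seq.n, length, p_state)
        events.append(
            DwellEvent(
                start=start,
                length=length,
                state="A" if is_a else "B",
                r2_lim=seq.r2_lim,
                p_value=p_val,
            )
        )
    return events


def scan_thresholds(
    jumps: JumpSequence,
    alpha: float = 0.05,
    state: str | None = "A",
    bonferroni: bool = False,
) -> list[DwellEvent]:
    """Global search for significant dwells over all possible thresholds.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted r² values.  For each threshold the trajectory is classified and
    its dwells tested; significant events are pooled over thresholds and
    deduplicated — events whose index ranges overlap (same state) are
    reduced to the one with the lowest P′.  By default only slow-state (A)
    dwells are searched, matching the usual question (transient
    immobilization); pass ``state=None`` to keep both.  Significance is raw
    (uncorrected); ``bonferroni=True`` divides alpha by the number of
    thresholds tried.
    """
    n = len(jumps)
    if n < 10:
        raise ValueError("need at least 10 jumps for a threshold scan")
    r2 = np.sort(np.unique(jumps.r2))
    if r2.size < 2:
        return []
    thresholds = 0.5 * (r2[:-1] + r2[1:])
    level = alpha / thresholds.size if bonferroni else alpha
    significant: list[DwellEvent] = []
    for lim in thresholds:
        seq = classify(jumps, lim)
        if seq.p_a in (0.0, 1.0):
            continue
        for want_a in (True, False):
            if state == "A" and not want_a:
                continue
            if state == "B" and want_a:
                continue
            p_state = seq.p_a if want_a else seq.p_b
            k_min = _min_significant_run(n, p_state, level)
            if k_min is None:
                continue
            for start, length, is_a in _runs(seq.labels):
                if is_a != want_a or length < k_min:
                    continue
                p_val = dwell_significance(n, length, p_state)
                if p_val < level:
                    significant.append(
                        DwellEvent(
                            start=start,
                            length=length,
                            state="A" if is_a else "B",
                            r2_lim=float(lim),
                            p_value=p_val,
                        )
                    )
    return _dedup_overlapping(significant)


def _min_significant_run(n: int, p: float, alpha: float):
    """Smallest k with dwell_significance(n, k, p) < alpha, or None.

    Exploits monotonicity of the significance in k (binary search), keeping
    the threshold scan at a handful of exact evaluations per threshold.
    """
    if dwell_significance(n, n, p) >= alpha:
        return None
    lo, hi = 1, n  # significance(hi) < alpha guaranteed here
    if dwell_significance(n, lo, p) < alpha:
        return lo
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if dwell_significance(n, mid, p) < alpha:
            hi = mid
        else:
            lo = mid
    return hi


def _dedup_overlapping(events: list[DwellEvent]) -> list[DwellEvent]:
    events = sorted(events, key=lambda e: e.p_value)
    kept: list[DwellEvent] = []
    for ev in events:
        lo, hi = ev.start, ev.start + ev.length
        clash = any(
            k.state == ev.state and lo < k.start + k.length and k.start < hi for k in kept
        )
        if not clash:
            kept.append(ev)
    return sorted(kept, key=lambda e: e.start)


def transition_stats(seq: StateSequence, exact_pairs: bool = False) -> TransitionStats:
    """Observed A↔B transition count against the i.i.d. expectation.

    ⟨s′⟩ = 2 p_A p_B n and σ_s′ = √(p_A p_B n) with n the number of jumps
    (the conventional form; ``exact_pairs=True`` replaces n by the exact
    number of consecutive pairs, n − 1, a O(1/n) refinement).  The z-deficit
    (⟨s′⟩ − s)/σ_s′ is converted to a one-sided normal tail probability:
    small values mean significantly fewer transitions than chance, i.e.
    state retention.
    """
    labels = seq.labels
    s = int(np.count_nonzero(labels[1:] != labels[:-1]))
    if seq.p_a in (0.0, 1.0):
        return TransitionStats(
            s_observed=s,
            s_expected=0.0,
            sigma=0.0,
            z_deficit=float("nan"),
            tail_probability=float("nan"),
            degenerate=True,
        )
    n_eff = seq.n - 1 if exact_pairs else seq.n
    s_exp = 2.0 * seq.p_a * seq.p_b * n_eff
    sigma = math.sqrt(seq.p_a * seq.p_b * n_eff)
    z = (s_exp - s) / sigma
    return TransitionStats(
        s_observed=s,
        s_expected=s_exp,
        sigma=sigma,
        z_deficit=z,
        tail_probability=float(norm.sf(z)),
    )
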