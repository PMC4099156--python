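"""Converting trial evidence into monthly transition probabilities.

Evidence arrives as medians (median months on treatment, median overall
survival) or as a fraction dead at a horizon.  Under the standard
declining-exponential assumption a median ``m`` corresponds to a
constant monthly rate ``ln 2 / m``, and a rate to a one-month
probability ``1 - exp(-rate)``.

Treatment duration additionally honours a protocol minimum: during the
first ``min_cycles`` paid months progression is forbidden (a course of
chemotherapy cannot be completed faster than its protocol allows) while
death remains possible.  After the minimum the patient exits each month
with probability ``p_death + (1 - p_death) * p_progress`` (death is
evaluated first; both are resolved from a single uniform draw).  The
resulting occupancy law is

    P(D >= t) = (1 - p_death)^(t-1)                      for t <= max(m, 1)
    P(D >= t) = (1 - p_death)^(m-1) * s^(t-m)            for t > m,

with ``s`` the per-month stay probability, and all occupancy statistics
used for calibration are evaluated in closed form from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_inputs import ModelSpec, TrialEvidence

__all__ = [
    "TransitionParams",
    "CalibrationError",
    "rate_from_median",
    "prob_from_rate",
    "prob_from_fraction",
    "occupancy_survival",
    "occupancy_mean",
    "occupancy_median",
    "progression_fraction",
    "fit_progression_to_mean",
    "calibrate_state",
    "survival_calibration",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class TransitionParams:
    state_name: str
    min_cycles: int
    p_progress: float
    p_death: float

    def __post_init__(self):
        if self.p_progress + self.p_death > 1.0 + 1e-12:
            raise ValueError("p_progress + p_death must be <= 1")
        if self.min_cycles < 0:
            raise ValueError("min_cycles must be >= 0")


class CalibrationError(ValueError):
    """No feasible calibration for the requested target."""


# ---------------------------------------------------------------------------
# elementary conversions
# ---------------------------------------------------------------------------


def rate_from_median(median: float) -> float:
    """Constant monthly event rate with the given median time, ln(2)/median."""
    if median <= 0:
        raise ValueError("median must be > 0")
    return _LN2 / median


def prob_from_rate(rate: float, t: float = 1.0) -> float:
    """Probability of the event within ``t`` months at a constant rate."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return 1.0 - math.exp(-rate * t)


def prob_from_fraction(P: float, T: float) -> float:
    """Monthly probability when a fraction ``P`` has the event by ``T`` months."""
    if not 0 < P < 1:
        raise ValueError("P must be in (0, 1)")
    if T <= 0:
        raise ValueError("T must be > 0")
    return 1.0 - (1.0 - P) ** (1.0 / T)


# ---------------------------------------------------------------------------
# occupancy law (closed form)
# ---------------------------------------------------------------------------


def occupancy_survival(t: np.ndarray | int, p_death: float, p_progress: float,
                       min_cycles: int) -> np.ndarray | float:
    """P(D >= t): probability of paying at least ``t`` months in the state."""
    t = np.asarray(t)
    m = max(min_cycles, 1)
    s = (1.0 - p_death) * (1.0 - p_progress)
    head = (1.0 - p_death) ** np.clip(t - 1, 0, None)
    tail = (1.0 - p_death) ** (m - 1) * s ** np.clip(t - m, 0, None)
    out = np.where(t <= m, head, tail)
    return out if out.ndim else float(out)


def occupancy_mean(p_death: float, p_progress: float, min_cycles: int) -> float:
    """Mean paid months in the state, E[D] = sum_t P(D >= t)."""
    m = max(min_cycles, 1)
    s = (1.0 - p_death) * (1.0 - p_progress)
    e = 1.0 - s
    if e <= 0:
        return math.inf
    if p_death > 0:
        head = (1.0 - (1.0 - p_death) ** m) / p_death
    else:
        head = float(m)
    return head + (1.0 - p_death) ** (m - 1) * s / e


def occupancy_median(p_death: float, p_progress: float, min_cycles: int,
                     q: float = 0.5) -> int:
    """The ``q``-quantile (default median) of paid months, in whole cycles."""
    s = (1.0 - p_death) * (1.0 - p_progress)
    if s >= 1.0:
        return np.iinfo(np.int64).max
    # smallest t with P(D >= t+1) <= 1-q
    t = 1
    while float(occupancy_survival(t + 1, p_death, p_progress, min_cycles)) > 1.0 - q:
        t += 1
        if t > 100000:  # pragma: no cover
            raise CalibrationError("quantile search diverged")
    return t


def progression_fraction(p_death: float, p_progress: float, min_cycles: int) -> float:
    """Probability of leaving the state by progression rather than death."""
    m = max(min_cycles, 1)
    s = (1.0 - p_death) * (1.0 - p_progress)
    e = 1.0 - s
    if e <= 0:
        return 0.0
    return (1.0 - p_death) ** m * p_progress / e


def fit_progression_to_mean(p_death: float, mean_months: float,
                            min_cycles: int) -> float:
    """Solve p_progress so the mean paid occupancy equals ``mean_months``.

    Closed-form inversion of :func:`occupancy_mean`; used to pin the
    built-in states to their reference per-line occupancy means.
    """
    m = max(min_cycles, 1)
    if p_death > 0:
        head = (1.0 - (1.0 - p_death) ** m) / p_death
    else:
        head = float(m)
    B = (1.0 - p_death) ** (m - 1)
    s_over_e = (mean_months - head) / B
    if s_over_e < 0:
        raise CalibrationError(
            f"target mean {mean_months} shorter than the minimum phase ({head:.2f})"
        )
    e = 1.0 / (1.0 + s_over_e)
    pp = (e - p_death) / (1.0 - p_death)
    if not 0.0 <= pp <= 1.0:
        raise CalibrationError(
            f"no valid p_progress for mean {mean_months} at p_death {p_death}"
        )
    return pp


# ---------------------------------------------------------------------------
# calibration against a median treatment duration
# ---------------------------------------------------------------------------


def calibrate_state(evidence: TrialEvidence, p_death: float,
                    tolerance: float = 0.5) -> TransitionParams:
    """Choose (min_cycles, p_progress) matching a median treatment duration.

    For each candidate minimum ``m`` in ``[0, floor(median)]`` the
    progression probability is the one-month conversion of the residual
    median, ``1 - exp(-ln 2 / (median - m))``, and the candidate is
    accepted if the closed-form occupancy median lands within
    ``tolerance`` cycles of the target; the smallest such minimum wins.
    """
    if evidence.median_duration is None:
        raise ValueError("evidence.median_duration is required")
    target = evidence.median_duration
    if target <= 0:
        raise ValueError("median_duration must be > 0")
    best = None
    for m in range(0, int(target) + 1):
        residual = target - m
        if residual <= 0:
            pp = 1.0
        else:
            pp = prob_from_rate(rate_from_median(residual))
        if pp + p_death > 1.0:
            pp = 1.0 - p_death
        med = occupancy_median(p_death, pp, m)
        if abs(med - target) <= tolerance:
            return TransitionParams(evidence.state_name, m, pp, p_death)
        if best is None or abs(med - target) < abs(best[0] - target):
            best = (med, m, pp)
    raise CalibrationError(
        f"no (min_cycles, p_progress) reaches median {target}; "
        f"nearest achievable median is {best[0]} at min_cycles={best[1]}"
    )


# ---------------------------------------------------------------------------
# whole-model survival calibration
# ---------------------------------------------------------------------------


def survival_calibration(spec: ModelSpec, target_median_os: float,
                         free_states: tuple[str, ...] | None = None,
                         sim_budget: int = 50_000, seed: int = 0,
                         tolerance: float = 1.0, max_iter: int = 30) -> ModelSpec:
    """Scale selected states' death probabilities to hit a median survival.

    A common multiplier on ``p_death`` of ``free_states`` (by default the
    first state, whose mortality evidence is the weakest) is searched by
    bisection until the simulated median overall survival from model
    entry matches ``target_median_os`` within ``tolerance`` months at
    ``sim_budget`` patients.  Deterministic for a fixed seed.  Raises
    :class:`CalibrationError` if every state's death probability is zero.
    """
    from .engine import simulate_cohort

    if all(s.p_death == 0.0 for s in spec.states):
        raise CalibrationError("all p_death are zero; survival is unbounded")
    if free_states is None:
        free_states = (spec.states[0].name,)

    def with_scale(k: float) -> ModelSpec:
        import dataclasses

        states = tuple(
            s if s.name not in free_states
            else dataclasses.replace(s, p_death=min(1.0 - s.p_progress, s.p_death * k))
            for s in spec.states
        )
        return spec.replace(states=states)

    def median_os(k: float) -> float:
        summ = simulate_cohort(with_scale(k), sim_budget, seed)
        return summ.os_median

    lo, hi = 0.05, 20.0
    best_k, best_err = 1.0, abs(median_os(1.0) - target_median_os)
    if best_err <= tolerance:
        return with_scale(1.0)
    k_lo, k_hi = lo, hi
    for _ in range(max_iter):
        k = math.sqrt(k_lo * k_hi)  # geometric bisection
        med = median_os(k)
        err = abs(med - target_median_os)
        if err < best_err:
            best_k, best_err = k, err
        if err <= tolerance:
            return with_scale(k)
        if med > target_median_os:  # living too long -> more mortality
            k_lo = k
        else:
            k_hi = k
    import warnings

    warnings.warn(
        f"survival calibration did not converge; best |error| = {best_err:.2f} months",
        RuntimeWarning,
    )
    return with_scale(best_k)
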