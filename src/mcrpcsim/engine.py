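"""Monte-Carlo microsimulation of individual patient histories.

Each simulated patient steps through the treatment chain in one-month
cycles.  A cycle is pay-then-draw: the patient accrues the current
state's primary cost plus the coverage-weighted castration and
bone-targeted rates, then a single uniform draw resolves the competing
exits -- death first (probability ``p_death``), then, once the state's
protocol minimum has been paid, progression to the next line
(``(1 - p_death) * p_progress``).  Death is taken to occur part-way
through the following month: the supportive therapies (the monthly
castration depot and q4w denosumab, administered at the start of the
month) are charged for that month, the primary treatment is not.  The
mCRPC period of a patient therefore spans ``paid months + 1`` months
when the patient dies, and exactly the paid months when follow-up is
censored two years after entry into the terminal OtherTx state.

Tracker variables record, per patient, the paid cycles in every state,
the last line received and the death/censoring cycle, from which every
cost category is reconstructible exactly as ``cycles x monthly rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .costing import supportive_monthly_rates
from .model_inputs import ModelSpec, TreatmentState

__all__ = [
    "step",
    "simulate_patient",
    "simulate_cohort",
    "replicate_ci",
    "PatientRecord",
    "CohortRecords",
    "CohortSummary",
    "ReplicationSummary",
]

_MAX_CYCLES = 3000  # hard stop; no plausible chain survives this long


# ---------------------------------------------------------------------------
# single-step / single-patient reference path
# ---------------------------------------------------------------------------


def step(state: TreatmentState, cycles_in_state: int, u: float) -> str:
    """Resolve one end-of-cycle draw: ``"die"``, ``"advance"`` or ``"stay"``.

    Death is evaluated first; progression only once ``cycles_in_state``
    (paid months) has reached the state's protocol minimum.  Terminal
    states never advance.
    """
    if not 0.0 <= u < 1.0:
        raise ValueError("u must be in [0, 1)")
    if u < state.p_death:
        return "die"
    if (
        not state.is_last_line
        and cycles_in_state >= state.min_cycles
        and u < state.p_death + (1.0 - state.p_death) * state.p_progress
    ):
        return "advance"
    return "stay"


@dataclass
class PatientRecord:
    """Tracker-variable history of one simulated patient."""

    cycles_in_state: dict[str, int]
    died: bool
    censored: bool
    last_line_received: str
    months_on_treatment: int  # total paid months
    mcrpc_months: int  # months from entry to death/censoring (death month included)
    primary_cost: float
    castration_cost: float
    bone_cost: float

    @property
    def total_cost(self) -> float:
        return self.primary_cost + self.castration_cost + self.bone_cost


def _routing(spec: ModelSpec) -> list[Optional[list[tuple[int, float]]]]:
    index = {s.name: i for i, s in enumerate(spec.states)}
    out: list[Optional[list[tuple[int, float]]]] = []
    for i, s in enumerate(spec.states):
        if s.is_last_line:
            out.append(None)
        elif s.goes_to is None:
            out.append([(i + 1, 1.0)])
        else:
            out.append([(index[d], w) for d, w in s.goes_to])
    return out


def simulate_patient(spec: ModelSpec, rng: np.random.Generator) -> PatientRecord:
    """Simulate one patient history (reference scalar implementation).

    The cohort path (:func:`simulate_cohort`) is vectorised and uses its
    own draw ordering; both implement the identical cycle law.
    """
    cast_rate, bone_rate = supportive_monthly_rates(spec)
    routing = _routing(spec)
    names = spec.state_names
    cycles = {n: 0 for n in names}
    si = 0
    if spec.initial_distribution is not None:
        dests, ws = zip(*spec.initial_distribution)
        si = names.index(dests[int(rng.choice(len(dests), p=np.asarray(ws)))])
    c = 0
    died = censored = False
    for _ in range(_MAX_CYCLES):
        st = spec.states[si]
        cycles[st.name] += 1
        c += 1
        cap = st.cap_cycles if st.cap_cycles is not None else (
            spec.otherx_cap if st.is_last_line else None
        )
        outcome = step(st, c, rng.random())
        if outcome == "die":
            died = True
            break
        if cap is not None and c >= cap:
            censored = True
            break
        if outcome == "advance":
            branches = routing[si]
            if len(branches) == 1:
                si = branches[0][0]
            else:
                dests, ws = zip(*branches)
                si = dests[int(rng.choice(len(dests), p=np.asarray(ws)))]
            c = 0
    months = sum(cycles.values())
    supportive_months = months + (1 if died else 0)
    last = max((n for n in names if cycles[n] > 0), key=names.index)
    return PatientRecord(
        cycles_in_state=cycles,
        died=died,
        censored=censored,
        last_line_received=last,
        months_on_treatment=months,
        mcrpc_months=supportive_months,
        primary_cost=sum(cycles[s.name] * s.primary_monthly_cost for s in spec.states),
        castration_cost=supportive_months * cast_rate,
        bone_cost=supportive_months * bone_rate,
    )


# ---------------------------------------------------------------------------
# vectorised cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortRecords:
    """Raw tracker arrays for a simulated cohort (one row per patient)."""

    spec: ModelSpec
    cycles: np.ndarray  # (n, n_states) paid months per state
    died: np.ndarray  # bool
    censored: np.ndarray  # bool
    last_state: np.ndarray  # int index of last line received

    @property
    def n(self) -> int:
        return self.cycles.shape[0]

    @property
    def months_on_treatment(self) -> np.ndarray:
        return self.cycles.sum(axis=1)

    @property
    def mcrpc_months(self) -> np.ndarray:
        """Months from mCRPC entry to death or censoring (death month included)."""
        return self.months_on_treatment + self.died

    def category_costs(self) -> dict[str, np.ndarray]:
        cast_rate, bone_rate = supportive_monthly_rates(self.spec)
        prim = self.cycles @ np.array([s.primary_monthly_cost for s in self.spec.states])
        supp_months = self.mcrpc_months
        return {
            "primary": prim,
            "castration": supp_months * cast_rate,
            "bone": supp_months * bone_rate,
            "total": prim + supp_months * (cast_rate + bone_rate),
        }


def _simulate_records(spec: ModelSpec, n: int, rng: np.random.Generator) -> CohortRecords:
    S = len(spec.states)
    pd_ = np.array([s.p_death for s in spec.states])
    pp_ = np.array([s.p_progress for s in spec.states])
    m_ = np.array([max(s.min_cycles, 1) for s in spec.states])
    adv_thresh = pd_ + (1.0 - pd_) * pp_
    cap_ = np.array(
        [
            (s.cap_cycles if s.cap_cycles is not None else
             (spec.otherx_cap if s.is_last_line else np.iinfo(np.int64).max))
            for s in spec.states
        ],
        dtype=np.int64,
    )
    terminal = np.array([s.is_last_line for s in spec.states])
    routing = _routing(spec)
    simple_next = np.array(
        [r[0][0] if (r is not None and len(r) == 1) else -1 for r in routing],
        dtype=np.int64,
    )
    branch_states = [i for i, r in enumerate(routing) if r is not None and len(r) > 1]

    state = np.zeros(n, dtype=np.int64)
    if spec.initial_distribution is not None:
        names = spec.state_names
        dests = np.array([names.index(d) for d, _ in spec.initial_distribution])
        ws = np.array([w for _, w in spec.initial_distribution])
        state = dests[rng.choice(len(dests), size=n, p=ws)]
    c = np.zeros(n, dtype=np.int64)
    cycles = np.zeros((n, S), dtype=np.int64)
    active = np.ones(n, dtype=bool)
    died = np.zeros(n, dtype=bool)
    censored = np.zeros(n, dtype=bool)

    for _ in range(_MAX_CYCLES):
        idx = np.nonzero(active)[0]
        if idx.size == 0:
            break
        st = state[idx]
        cycles[idx, st] += 1
        c[idx] += 1
        u = rng.random(idx.size)
        die = u < pd_[st]
        can_adv = (~terminal[st]) & (c[idx] >= m_[st])
        adv = (~die) & can_adv & (u < adv_thresh[st])
        capped = (~die) & (c[idx] >= cap_[st])
        died[idx[die]] = True
        censored[idx[capped]] = True
        active[idx[die | capped]] = False
        adv &= ~capped
        ai = idx[adv]
        if ai.size:
            dest = simple_next[state[ai]]
            needs_branch = dest < 0
            if needs_branch.any():
                bi = ai[needs_branch]
                v = rng.random(bi.size)
                db = dest[needs_branch]
                for si in branch_states:
                    mask = state[bi] == si
                    if not mask.any():
                        continue
                    targets, ws = zip(*routing[si])
                    edges = np.cumsum(ws)
                    pick = np.searchsorted(edges, v[mask], side="right")
                    pick = np.minimum(pick, len(targets) - 1)
                    db[mask] = np.array(targets)[pick]
                dest[needs_branch] = db
            state[ai] = dest
            c[ai] = 0
    else:  # pragma: no cover
        raise RuntimeError("simulation exceeded the cycle limit")

    entered = cycles > 0
    last_state = (entered * np.arange(S)).max(axis=1)
    return CohortRecords(spec, cycles, died, censored, last_state)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def _stats(x: np.ndarray) -> dict[str, float]:
    if x.size == 0:
        return {"mean": np.nan, "median": np.nan, "q25": np.nan, "q75": np.nan}
    return {
        "mean": float(x.mean()),
        "median": float(np.median(x)),
        "q25": float(np.percentile(x, 25)),
        "q75": float(np.percentile(x, 75)),
    }


@dataclass
class CohortSummary:
    """Aggregated outcomes of one simulated cohort."""

    n_patients: int
    variant: str
    national_cohort: int
    states: pd.DataFrame  # per-state utilization, duration, survival, costs
    totals: pd.DataFrame  # per-category cost statistics over the whole period
    mcrpc_months_mean: float
    os_median: float
    os_iqr: tuple[float, float]
    death_fraction: float
    censored_fraction: float
    monthly_cost_mean: float

    @property
    def mean_total_cost(self) -> float:
        return float(self.totals.loc["total", "mean"])


def summarize(records: CohortRecords) -> CohortSummary:
    spec = records.spec
    S = len(spec.states)
    cast_rate, bone_rate = supportive_monthly_rates(spec)
    prim_rates = np.array([s.primary_monthly_cost for s in spec.states])
    entered = records.cycles > 0
    surv_tail = records.cycles[:, ::-1].cumsum(axis=1)[:, ::-1]  # months in state s onward

    rows = []
    for s in range(S):
        e = entered[:, s]
        dur = records.cycles[e, s]
        # survival from entry into this line: remaining paid months + death month
        surv = surv_tail[e, s] + records.died[e]
        row = {"state": spec.states[s].name, "utilization": float(e.mean())}
        row.update({f"dur_{k}": v for k, v in _stats(dur).items()})
        row.update({f"surv_{k}": v for k, v in _stats(surv).items()})
        for cat, arr in {
            "primary": dur * prim_rates[s],
            "castration": dur * cast_rate,
            "bone": dur * bone_rate,
        }.items():
            row.update({f"{cat}_{k}": v for k, v in _stats(arr).items()})
        row.update(
            {f"total_{k}": v for k, v in _stats(
                dur * (prim_rates[s] + cast_rate + bone_rate)
            ).items()}
        )
        rows.append(row)
    states_df = pd.DataFrame(rows).set_index("state")

    costs = records.category_costs()
    totals = pd.DataFrame(
        {cat: _stats(arr) for cat, arr in costs.items()}
    ).T[["mean", "median", "q25", "q75"]]

    mcrpc = records.mcrpc_months
    os_stats = _stats(mcrpc)
    mean_months = float(mcrpc.mean())
    return CohortSummary(
        n_patients=records.n,
        variant=spec.variant,
        national_cohort=spec.national_cohort,
        states=states_df,
        totals=totals,
        mcrpc_months_mean=mean_months,
        os_median=os_stats["median"],
        os_iqr=(os_stats["q25"], os_stats["q75"]),
        death_fraction=float(records.died.mean()),
        censored_fraction=float(records.censored.mean()),
        monthly_cost_mean=float(costs["total"].mean()) / mean_months,
    )


def simulate_cohort(spec: ModelSpec, n: int, seed: int,
                    return_records: bool = False):
    """Simulate ``n`` patients and aggregate; deterministic for a fixed seed.

    Per-state statistics are computed among patients entering that state
    only.  Survival statistics follow each patient to death or to
    censoring at the OtherTx cap (censored times enter as recorded, i.e.
    as lower bounds).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    records = _simulate_records(spec, n, rng)
    summary = summarize(records)
    if return_records:
        return summary, records
    return summary


# ---------------------------------------------------------------------------
# replicate-sample confidence intervals
# ---------------------------------------------------------------------------


@dataclass
class ReplicationSummary:
    """Percentile CI of a cohort mean over independent replicate samples."""

    metric: str
    n_samples: int
    sample_size: int
    point: float  # mean of sample means
    ci95: tuple[float, float]  # 2.5th / 97.5th percentile of sample means
    sample_means: np.ndarray = field(repr=False)


def replicate_ci(spec: ModelSpec, sample_size: int = 10_000,
                 n_samples: int = 1000, seed: int = 0,
                 metric: str = "total") -> ReplicationSummary:
    """95% CI for a mean outcome over ``n_samples`` replicate cohorts.

    Each sample runs on an independent seeded substream.  ``metric`` is
    a cost category (``primary``, ``castration``, ``bone``, ``total``),
    ``monthly`` (total cost per mCRPC month) or ``months`` (mean mCRPC
    duration).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    streams = np.random.SeedSequence(seed).spawn(n_samples)
    means = np.empty(n_samples)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        rec = _simulate_records(spec, sample_size, rng)
        if metric == "months":
            means[i] = rec.mcrpc_months.mean()
        elif metric == "monthly":
            means[i] = rec.category_costs()["total"].mean() / rec.mcrpc_months.mean()
        else:
            means[i] = rec.category_costs()[metric].mean()
    lo, hi = np.percentile(means, [2.5, 97.5])
    return ReplicationSummary(
        metric=metric,
        n_samples=n_samples,
        sample_size=sample_size,
        point=float(means.mean()),
        ci95=(float(lo), float(hi)),
        sample_means=means,
    )
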