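"""Sensitivity scenarios as pure, declarative model transformations.

Utilization rates between mCRPC treatment lines are not observed in the
literature, so the cost estimates are stress-tested by varying the flow
of patients through the most expensive lines:

``transition_multiplier``
    Scale a named state's monthly progression probability by a factor
    (clipped so the exit probabilities stay valid).
``retreatment_fraction``
    Route a fraction of patients progressing out of docetaxel into a
    docetaxel re-treatment state (same cost and duration parameters)
    that exits directly to OtherTx, bypassing the later expensive lines.
``late_entry_fraction``
    Start a fraction of the cohort directly at the index line
    (docetaxel in the current pathway, abiraterone in the alternate),
    modelling maximal androgen blockade consumed before mCRPC.
``skip_fraction``
    Send a fraction of AA progression exits directly to the index line,
    bypassing the withdrawal period; the complement follows the base
    path.

All transformations return a new :class:`ModelSpec`; the input is never
mutated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .engine import replicate_ci, simulate_cohort
from .model_inputs import ModelSpec, TreatmentState

__all__ = ["Scenario", "apply_scenario", "paper_suite", "run_suite"]

KINDS = ("transition_multiplier", "retreatment_fraction",
         "late_entry_fraction", "skip_fraction")


@dataclass(frozen=True)
class Scenario:
    kind: str
    value: float  # multiplier or fraction, depending on kind
    state: Optional[str] = None  # for transition_multiplier
    label: str = ""

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "transition_multiplier":
            if self.value <= 0:
                raise ValueError("multiplier must be > 0")
        elif not 0.0 <= self.value <= 1.0:
            raise ValueError("fraction must be in [0, 1]")

    def name(self) -> str:
        return self.label or f"{self.kind}={self.value:g}"


def _index_line(spec: ModelSpec) -> str:
    """The expensive index line scenarios pivot on."""
    if spec.variant == "current":
        return "Docetaxel"
    if spec.variant == "alternate":
        return "Abiraterone"
    return spec.states[min(2, len(spec.states) - 1)].name


def apply_scenario(spec: ModelSpec, scenario: Scenario) -> ModelSpec:
    """Apply one scenario, returning a new spec (pure transformation)."""
    names = list(spec.state_names)

    if scenario.kind == "transition_multiplier":
        target = scenario.state or _index_line(spec)
        if target not in names:
            raise ValueError(f"state {target!r} not in the model chain")
        states = []
        for s in spec.states:
            if s.name == target:
                pp = min(s.p_progress * scenario.value, 1.0 - s.p_death)
                s = dataclasses.replace(s, p_progress=pp)
            states.append(s)
        return spec.replace(states=tuple(states))

    if scenario.kind == "retreatment_fraction":
        if "Docetaxel" not in names:
            raise ValueError("retreatment scenario requires a Docetaxel state")
        f = scenario.value
        if f == 0.0:
            return spec
        doc = spec.state("Docetaxel")
        retreat = dataclasses.replace(
            doc, name="DocetaxelRetreat", goes_to=(("OtherTx", 1.0),)
        )
        i_doc = names.index("Docetaxel")
        normal_next = (
            spec.states[i_doc + 1].name if doc.goes_to is None else doc.goes_to
        )
        if isinstance(normal_next, str):
            routed = dataclasses.replace(
                doc, goes_to=((normal_next, 1.0 - f), ("DocetaxelRetreat", f))
            )
        else:  # pre-existing branching: scale it down
            routed = dataclasses.replace(
                doc,
                goes_to=tuple((d, w * (1.0 - f)) for d, w in normal_next)
                + (("DocetaxelRetreat", f),),
            )
        states = [routed if s.name == "Docetaxel" else s for s in spec.states]
        states.insert(len(states) - 1, retreat)  # just before OtherTx
        return spec.replace(states=tuple(states), variant="custom")

    if scenario.kind == "late_entry_fraction":
        f = scenario.value
        if f == 0.0:
            return spec
        target = scenario.state or _index_line(spec)
        if target not in names:
            raise ValueError(f"state {target!r} not in the model chain")
        init = ((names[0], 1.0 - f), (target, f)) if f < 1.0 else ((target, 1.0),)
        return spec.replace(initial_distribution=init)

    # skip_fraction
    f = scenario.value
    if f == 0.0:
        return spec
    target = scenario.state or _index_line(spec)
    if target not in names:
        raise ValueError(f"state {target!r} not in the model chain")
    first = spec.states[0]
    normal = names[1] if first.goes_to is None else first.goes_to[0][0]
    routed = dataclasses.replace(
        first, goes_to=((normal, 1.0 - f), (target, f)) if f < 1.0 else ((target, 1.0),)
    )
    return spec.replace(states=(routed,) + spec.states[1:])


def paper_suite(variant: str = "current") -> list[Scenario]:
    """The published sensitivity suite: 13 scenarios in four families."""
    line = "Docetaxel"
    dest = "abiraterone" if variant == "current" else "cabazitaxel"
    idx = "docetaxel" if variant == "current" else "abiraterone"
    out = []
    for mult in (1.1, 1.2, 0.9, 0.8):
        pct = int(round(abs(mult - 1) * 100))
        direction = "increase" if mult > 1 else "decrease"
        out.append(Scenario("transition_multiplier", mult, state=line,
                            label=f"{pct}% {direction} of transition to {dest}"))
    for f in (0.2, 0.3, 0.5):
        out.append(Scenario("retreatment_fraction", f,
                            label=f"{int(f*100)}% docetaxel retreatment"))
    for f in (0.5, 0.7, 1.0):
        out.append(Scenario("late_entry_fraction", f,
                            label=f"{int(f*100)}% received AA before mCRPC"))
    for f in (0.9, 0.8, 0.7):
        out.append(Scenario("skip_fraction", f,
                            label=f"{int(f*100)}% transit directly to {idx}"))
    return out


def run_suite(base: ModelSpec, scenarios: list[Scenario], n: int, seed: int,
              ci_samples: int = 0, ci_sample_size: int = 10_000) -> pd.DataFrame:
    """Run the base model and every scenario; one row per run.

    Columns: mean and median total cost, IQR, mean monthly cost, and
    (when ``ci_samples`` > 0) replicate-sample 95% CIs for the mean.
    """
    rows = []
    for label, spec in [("base", base)] + [
        (sc.name(), apply_scenario(base, sc)) for sc in scenarios
    ]:
        summary = simulate_cohort(spec, n, seed)
        row = {
            "scenario": label,
            "mean_total": summary.totals.loc["total", "mean"],
            "median_total": summary.totals.loc["total", "median"],
            "iqr_low": summary.totals.loc["total", "q25"],
            "iqr_high": summary.totals.loc["total", "q75"],
            "monthly_mean": summary.monthly_cost_mean,
            "mcrpc_months_mean": summary.mcrpc_months_mean,
        }
        if ci_samples:
            rep = replicate_ci(spec, ci_sample_size, ci_samples, seed)
            row["ci_low"], row["ci_high"] = rep.ci95
        rows.append(row)
    return pd.DataFrame(rows).set_index("scenario")
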