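"""Monthly medication costs from unit prices and dosing schedules.

All prices are 2013 Canadian dollars from the public reimbursement list
(oral drugs, goserelin, denosumab) and a hospital pharmacy list
(i.v. chemotherapy).  A model month is 30.42 days; per-m^2 chemotherapy
doses use a 1.9 m^2 body surface area.

Two pricing dialects exist for i.v. drugs.  The price list prints
docetaxel at fractional-vial pricing ($774/month) while the simulated
per-line costs imply whole-vial charging ($868.84 drug cost/month);
``pricing_mode`` selects between them (``"table2"`` vs ``"simulation"``),
with simulation mode the default for the microsimulation.

Bicalutamide's printed $58.71/month is not derivable from its $1.61
tablet price at any day count and is carried verbatim as a fixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .model_inputs import CostingConvention, ModelSpec, PriceEntry, Regimen

__all__ = [
    "MonthlyCost",
    "PRICES",
    "REGIMENS",
    "TABLE2_PRINTED_MONTHLY",
    "dose_per_administration",
    "administration_cost",
    "monthly_cost",
    "state_primary_monthly_cost",
    "supportive_monthly_rates",
    "cost_table",
    "CASTRATION_MONTHLY",
    "BONE_MONTHLY",
    "BICALUTAMIDE_MONTHLY_PRINTED",
]


@dataclass(frozen=True)
class MonthlyCost:
    drug_name: str
    per_administration_cost: float
    administrations_per_month: float
    monthly_cost: float


# ---------------------------------------------------------------------------
# price list and regimens (2013 CAD)
# ---------------------------------------------------------------------------

PRICES = {
    "bicalutamide": PriceEntry("bicalutamide", 1.61, 50.0, "tablet"),
    "abiraterone": PriceEntry("abiraterone", 28.3333, 250.0, "tablet"),
    "cabazitaxel": PriceEntry("cabazitaxel", 5840.0, 60.0, "vial"),
    "docetaxel": PriceEntry("docetaxel", 599.79, 160.0, "vial"),
    "prednisone": PriceEntry("prednisone", 0.022, 5.0, "tablet"),
    "dexamethasone": PriceEntry("dexamethasone", 3.24, 10.0, "vial"),
    "diphenhydramine": PriceEntry("diphenhydramine", 2.98, 50.0, "vial"),
    "famotidine": PriceEntry("famotidine", 2.71, 20.0, "vial"),
    "goserelin": PriceEntry("goserelin", 1113.0, 10.8, "depot"),
    "denosumab": PriceEntry("denosumab", 538.45, 120.0, "vial"),
}

REGIMENS = {
    "bicalutamide": Regimen("bicalutamide", 1, 1, unit="tablet"),
    "abiraterone": Regimen("abiraterone", 4, 1, unit="tablet"),
    "cabazitaxel": Regimen("cabazitaxel", 25.0, 21, per_bsa=True),
    "docetaxel": Regimen("docetaxel", 75.0, 21, per_bsa=True),
    "prednisone": Regimen("prednisone", 2, 1, unit="tablet"),
    "dexamethasone": Regimen("dexamethasone", 8.0, 21, role="premedication"),
    "diphenhydramine": Regimen("diphenhydramine", 25.0, 21, role="premedication"),
    "famotidine": Regimen("famotidine", 20.0, 21, role="premedication"),
    "goserelin": Regimen("goserelin", 10.8, 91, role="castration"),
    "denosumab": Regimen("denosumab", 120.0, 28, role="bone_targeted"),
}

#: Printed monthly-cost column of the 2013 price list (display dollars).
TABLE2_PRINTED_MONTHLY = {
    "bicalutamide": 58.71,
    "abiraterone": 3448.0,
    "cabazitaxel": 8460.0,
    "docetaxel": 774.0,
    "prednisone": 1.34,
    "dexamethasone": 4.69,
    "diphenhydramine": 4.32,
    "famotidine": 3.93,
    "goserelin": 371.0,
    "denosumab": 585.0,
}

BICALUTAMIDE_MONTHLY_PRINTED = 58.71
CASTRATION_MONTHLY = 371.0  # goserelin, $1,113 depot / 3 months
BONE_MONTHLY = 585.0  # denosumab, $538.45 q4w over a 30.42-day month


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def dose_per_administration(regimen: Regimen, convention: CostingConvention) -> float:
    """Dose per administration in mg (or tablets for oral regimens)."""
    if regimen.per_bsa:
        return regimen.dose * convention.body_surface_area
    return regimen.dose


def administration_cost(regimen: Regimen, price: PriceEntry,
                        convention: CostingConvention,
                        pricing_rule: str | None = None) -> float:
    """Cost of one administration.

    ``whole_package`` charges full vials (``ceil(dose/content)``);
    ``fractional`` pro-rates by the milligrams actually used.  Tablet
    regimens charge per tablet.
    """
    if price.drug_name != regimen.drug_name:
        raise ValueError(f"price list entry {price.drug_name!r} does not match "
                         f"regimen {regimen.drug_name!r}")
    rule = pricing_rule or regimen.pricing_rule
    if regimen.unit == "tablet":
        return regimen.dose * price.unit_cost
    dose = dose_per_administration(regimen, convention)
    if price.unit_kind == "depot":
        return price.unit_cost
    if rule == "whole_package":
        return math.ceil(dose / price.package_content) * price.unit_cost
    return dose * price.unit_cost / price.package_content


def monthly_cost(regimen: Regimen, price: PriceEntry,
                 convention: CostingConvention | None = None,
                 pricing_rule: str | None = None) -> MonthlyCost:
    """Monthly cost of a regimen at the given conventions.

    Daily regimens charge ``days_per_month`` administrations per month,
    interval regimens ``days_per_month / interval``, and the 3-month
    depot ``unit_cost / depot_months_covered``.
    """
    convention = convention or CostingConvention()
    admin = administration_cost(regimen, price, convention, pricing_rule)
    if regimen.interval_days == 91:
        per_month = 1.0 / convention.depot_months_covered
        monthly = price.unit_cost / convention.depot_months_covered
    else:
        per_month = convention.days_per_month / regimen.interval_days
        monthly = admin * per_month
    return MonthlyCost(regimen.drug_name, admin, per_month, round(monthly, 2))


#: Per-state composition of the primary-medication cost category:
#: the primary drug plus its oral co-medication and i.v. premedications.
STATE_DRUGS = {
    "AA": ("bicalutamide",),
    "AAwd": (),
    "Docetaxel": ("docetaxel", "prednisone", "dexamethasone"),
    "Abiraterone": ("abiraterone", "prednisone"),
    "Cabazitaxel": ("cabazitaxel", "prednisone", "dexamethasone",
                    "diphenhydramine", "famotidine"),
    "OtherTx": (),
    "DocetaxelRetreat": ("docetaxel", "prednisone", "dexamethasone"),
}


def state_primary_monthly_cost(state_name: str, variant: str = "current",
                               convention: CostingConvention | None = None,
                               pricing_mode: str = "simulation") -> float:
    """Primary-medication cost rate of a treatment state, $/month.

    ``pricing_mode="table2"`` sums the printed monthly price-list values
    verbatim; ``"simulation"`` recomputes them charging whole vials for
    i.v. drugs (the dialect the simulated per-line costs use).  AA uses
    the printed bicalutamide $58.71/month in both modes, the price list
    being authoritative where the unit price does not reproduce it.
    """
    if state_name not in STATE_DRUGS:
        raise KeyError(f"unknown state {state_name!r}")
    if pricing_mode not in ("table2", "simulation"):
        raise ValueError(f"unknown pricing_mode {pricing_mode!r}")
    convention = convention or CostingConvention()
    total = 0.0
    for drug in STATE_DRUGS[state_name]:
        if drug == "bicalutamide":
            total += BICALUTAMIDE_MONTHLY_PRINTED
        elif pricing_mode == "table2":
            total += TABLE2_PRINTED_MONTHLY[drug]
        else:
            rule = "whole_package" if PRICES[drug].unit_kind == "vial" else None
            total += monthly_cost(REGIMENS[drug], PRICES[drug], convention, rule).monthly_cost
    return round(total, 2)


def supportive_monthly_rates(spec: ModelSpec) -> tuple[float, float]:
    """Coverage-weighted supportive-therapy cost rates, $/month.

    Every alive patient accrues ``coverage x monthly_cost`` for medical
    castration and for bone-targeted therapy each cycle (expectation
    weighting over the 95%/90% covered fractions).
    """
    return (
        spec.castration_monthly_cost * spec.castration_coverage,
        spec.bone_monthly_cost * spec.bone_coverage,
    )


def cost_table(convention: CostingConvention | None = None) -> pd.DataFrame:
    """Monthly-cost table for every drug on the price list.

    Mirrors the published price-list layout: unit cost, dosage, computed
    monthly cost (fractional docetaxel, whole vials otherwise) and the
    printed monthly value.  Display convention: values >= $100 are shown
    rounded to whole dollars.
    """
    convention = convention or CostingConvention()
    rows = []
    for drug, reg in REGIMENS.items():
        price = PRICES[drug]
        if drug == "bicalutamide":
            computed = BICALUTAMIDE_MONTHLY_PRINTED
        else:
            rule = "fractional" if drug == "docetaxel" else None
            computed = monthly_cost(reg, price, convention, rule).monthly_cost
        display = round(computed) if computed >= 100 else round(computed, 2)
        rows.append(
            {
                "drug": drug,
                "role": reg.role,
                "unit_cost": price.unit_cost,
                "package_content": price.package_content,
                "unit_kind": price.unit_kind,
                "interval_days": reg.interval_days,
                "monthly_cost": computed,
                "monthly_cost_display": display,
                "printed_monthly": TABLE2_PRINTED_MONTHLY[drug],
            }
        )
    return pd.DataFrame(rows).set_index("drug")
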