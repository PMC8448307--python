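"""Cost and value arithmetic for functional-communication improvement.

Definitions:

* ``NetCost``       = sessions attended x per-session billing rate
                      (CPT 92507 speech-language treatment, default $108.00).
* ``E(Cost)``       = p x NetCost, the probability-weighted expected cost of
                      improvement for a patient with improvement probability p.
* value per unit QCL = E(Cost) / dQCL: the monetary equivalent of one unit of
                      ASHA-QCL gain, i.e. the incremental patient cost per
                      unit of quality of communication life.
* ``NetBenefit``    = dNOMS + dQCL (mixed units, reported as such).
* ``E(Benefit)``    = p*(dNOMS + dQCL) + (1-p)*(NOMS_initial + QCL_initial).

All currency arithmetic is exact: amounts and probabilities are carried as
`fractions.Fraction` so that identities like value * dQCL == E(Cost) hold
exactly, and rounding (half-away-from-zero to cents) happens only at
presentation via :func:`round_cents`.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Mapping, Sequence

from .cohort import AphasiaType, Dimension, ImprovementOutcome, PatientRecord

__all__ = [
    "DEFAULT_SESSION_RATE",
    "UndefinedValueError",
    "CostValueRecord",
    "BenefitRecord",
    "CostSummary",
    "exact",
    "round_cents",
    "net_cost",
    "expected_cost",
    "value_per_qcl",
    "net_benefit",
    "expected_benefit",
    "build_cost_summary",
    "build_cost_value_table",
    "build_benefit_table",
    "footer_ranges",
]

#: Per-session billing rate in dollars (CPT 92507).
DEFAULT_SESSION_RATE = Fraction(108)

_CENT = Decimal("0.01")


class UndefinedValueError(ValueError):
    """Value per unit QCL is undefined for non-positive QCL change."""


def exact(x) -> Fraction:
    """Convert a number to an exact Fraction.

    Floats go through their shortest decimal repr, so ``exact(0.72)`` is
    exactly 72/100 rather than the binary float's full expansion.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, float):
        return Fraction(Decimal(repr(x)))
    if isinstance(x, Decimal):
        return Fraction(x)
    if isinstance(x, (int, str)):
        return Fraction(x)
    raise TypeError(f"cannot convert {type(x).__name__} to Fraction")


def round_cents(amount) -> Decimal:
    """Round to cents, ties away from zero (presentation only)."""
    f = exact(amount)
    return (Decimal(f.numerator) / Decimal(f.denominator)).quantize(
        _CENT, rounding=ROUND_HALF_UP
    )


def net_cost(sessions: int, rate=DEFAULT_SESSION_RATE) -> Fraction:
    """Total billed treatment cost: sessions x per-session rate, exact."""
    if sessions < 0:
        raise ValueError(f"sessions must be non-negative, got {sessions}")
    rate = exact(rate)
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    return sessions * rate


def expected_cost(p, cost) -> Fraction:
    """Probability-weighted expected cost of improvement: p x NetCost."""
    p = exact(p)
    if not 0 <= p <= 1:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    return p * exact(cost)


def value_per_qcl(e_cost, delta_qcl) -> Fraction:
    """Monetary value of one unit of QCL improvement: E(Cost) / dQCL.

    Undefined (raises) when dQCL <= 0.
    """
    delta_qcl = exact(delta_qcl)
    if delta_qcl <= 0:
        raise UndefinedValueError(
            f"value per unit QCL is undefined for dQCL = {delta_qcl}"
        )
    return exact(e_cost) / delta_qcl


def net_benefit(delta_noms, delta_qcl) -> Fraction:
    """NetBenefit = dNOMS + dQCL (exact sum; units are mixed by construction)."""
    return exact(delta_noms) + exact(delta_qcl)


def expected_benefit(p, delta_noms, delta_qcl, noms_initial, qcl_initial) -> Fraction:
    """E(Benefit) = p*(dNOMS + dQCL) + (1-p)*(NOMS_initial + QCL_initial)."""
    p = exact(p)
    if not 0 <= p <= 1:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    return p * net_benefit(delta_noms, delta_qcl) + (1 - p) * (
        exact(noms_initial) + exact(qcl_initial)
    )


@dataclass(frozen=True)
class CostValueRecord:
    """One row of the per-patient cost/value table.

    Monetary and probability fields are exact Fractions; ``value_*`` is None
    when the QCL change is non-positive (value undefined, row retained).
    """

    patient_id: str
    aphasia_type: AphasiaType
    total_treatment_cost: Fraction
    p_verbal: Fraction
    p_comp: Fraction
    e_cost_verbal: Fraction
    e_cost_comp: Fraction
    qcl_improvement: Fraction
    value_verbal: Fraction | None
    value_comp: Fraction | None


@dataclass(frozen=True)
class BenefitRecord:
    """Per-patient benefit quantities for one NOMS dimension."""

    patient_id: str
    dimension: Dimension
    delta_noms: Fraction
    delta_qcl: Fraction
    noms_initial: Fraction
    qcl_initial: Fraction
    net_benefit: Fraction
    expected_benefit: Fraction


@dataclass(frozen=True)
class CostSummary:
    """Aggregate cost of improvement for one NOMS dimension (improvers only)."""

    dimension: Dimension
    improver_count: int
    session_min: int | None
    session_max: int | None
    cost_min: Fraction | None
    cost_max: Fraction | None
    total_cost: Fraction
    average_cost: Fraction | None


def build_cost_summary(
    records: Sequence[PatientRecord],
    outcomes: Sequence[ImprovementOutcome],
    rate=DEFAULT_SESSION_RATE,
) -> CostSummary:
    """Session/cost ranges, total and average billed cost over improving patients."""
    improved_ids = {o.patient_id for o in outcomes if o.improved}
    dimension = outcomes[0].dimension if outcomes else Dimension.VERBAL
    improvers = [r for r in records if r.patient_id in improved_ids]
    total = sum((net_cost(r.sessions_attended, rate) for r in improvers), Fraction(0))
    if not improvers:
        return CostSummary(dimension, 0, None, None, None, None, total, None)
    sessions = [r.sessions_attended for r in improvers]
    costs = [net_cost(s, rate) for s in sessions]
    return CostSummary(
        dimension=dimension,
        improver_count=len(improvers),
        session_min=min(sessions),
        session_max=max(sessions),
        cost_min=min(costs),
        cost_max=max(costs),
        total_cost=total,
        average_cost=total / len(improvers),
    )


def build_cost_value_table(
    records: Sequence[PatientRecord],
    p_verbal: Mapping[str, float],
    p_comp: Mapping[str, float],
    rate=DEFAULT_SESSION_RATE,
) -> list[CostValueRecord]:
    """One cost/value row per patient from supplied improvement probabilities.

    Probabilities come from the fitted improvement model (or any external
    source), keyed by patient id.  QCL improvement is the pre/post ASHA-QCL
    change from the record itself.
    """
    rows = []
    for record in records:
        cost = net_cost(record.sessions_attended, rate)
        pv = exact(p_verbal[record.patient_id])
        pc = exact(p_comp[record.patient_id])
        ev = expected_cost(pv, cost)
        ec = expected_cost(pc, cost)
        dqcl = exact(record.qcl_final) - exact(record.qcl_initial)
        if dqcl > 0:
            vv, vc = value_per_qcl(ev, dqcl), value_per_qcl(ec, dqcl)
        else:
            vv = vc = None
        rows.append(
            CostValueRecord(
                patient_id=record.patient_id,
                aphasia_type=record.aphasia_type,
                total_treatment_cost=cost,
                p_verbal=pv,
                p_comp=pc,
                e_cost_verbal=ev,
                e_cost_comp=ec,
                qcl_improvement=dqcl,
                value_verbal=vv,
                value_comp=vc,
            )
        )
    return rows


def build_benefit_table(
    records: Sequence[PatientRecord],
    probabilities: Mapping[str, float],
    dimension: Dimension,
) -> list[BenefitRecord]:
    """NetBenefit and E(Benefit) per patient for one NOMS dimension."""
    dimension = Dimension(dimension)
    rows = []
    for record in records:
        initial, final = record.noms_pair(dimension)
        dn = exact(final) - exact(initial)
        dq = exact(record.qcl_final) - exact(record.qcl_initial)
        p = exact(probabilities[record.patient_id])
        rows.append(
            BenefitRecord(
                patient_id=record.patient_id,
                dimension=dimension,
                delta_noms=dn,
                delta_qcl=dq,
                noms_initial=exact(initial),
                qcl_initial=exact(record.qcl_initial),
                net_benefit=net_benefit(dn, dq),
                expected_benefit=expected_benefit(p, dn, dq, initial, record.qcl_initial),
            )
        )
    return rows


def footer_ranges(
    rows: Sequence[CostValueRecord], mode: str = "pooled"
) -> dict[AphasiaType, dict[str, tuple[Fraction, Fraction]]]:
    """Per-aphasia-type summary ranges of E(Cost) and value cells.

    ``mode="pooled"`` returns min-max over both dimensions' cells together
    (keys ``e_cost`` and ``value``); ``mode="by_dimension"`` keeps verbal and
    comprehension separate (keys ``e_cost_verbal`` etc.).  Rows with
    undefined value cells are skipped in the value ranges.
    """
    if mode not in ("pooled", "by_dimension"):
        raise ValueError(f"unknown footer mode {mode!r}")
    out: dict[AphasiaType, dict[str, tuple[Fraction, Fraction]]] = {}
    for aphasia_type in AphasiaType:
        members = [r for r in rows if r.aphasia_type is aphasia_type]
        if not members:
            continue
        ecv = [r.e_cost_verbal for r in members]
        ecc = [r.e_cost_comp for r in members]
        vv = [r.value_verbal for r in members if r.value_verbal is not None]
        vc = [r.value_comp for r in members if r.value_comp is not None]
        if mode == "pooled":
            cells = {"e_cost": ecv + ecc, "value": vv + vc}
        else:
            cells = {
                "e_cost_verbal": ecv,
                "e_cost_comp": ecc,
                "value_verbal": vv,
                "value_comp": vc,
            }
        out[aphasia_type] = {
            key: (min(values), max(values)) for key, values in cells.items() if values
        }
    return out
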