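"""Published aggregates and a synthetic patient-level reconstruction.

The study released only aggregate tables, not patient-level data.  This
module ships three objects:

* :func:`table1_fixture` — the published descriptive summary (counts, means,
  sds per aphasia type), verbatim;
* :func:`table5_fixture` — the published 16-row per-patient cost/value table
  (treatment costs, improvement probabilities, expected costs, QCL changes
  and values), verbatim;
* :func:`synthetic_study_cohort` — a synthetic 20-patient cohort constructed
  to reproduce the published structure exactly where it is published:
  type frequencies 9/8/2/1, race counts 5/15, improver counts (9 verbal,
  15 comprehension, with the published per-type breakdown), and the
  session/cost structure (comprehension improvers: 15 patients, sessions
  5-12, total billed $17,280; verbal improvers: 9 patients, sessions 6-12,
  total $10,152 at $108/session).  Ages, education, TPO, and QCL values are
  plausible synthetic fill near the published means, not data.
"""

from __future__ import annotations

from decimal import Decimal
from fractions import Fraction

from .cohort import (
    AphasiaType,
    CohortSummary,
    GroupStats,
    PatientRecord,
)
from .economics import CostValueRecord

__all__ = ["table1_fixture", "table5_fixture", "synthetic_study_cohort"]

_A = AphasiaType.ANOMIC
_B = AphasiaType.BROCA
_C = AphasiaType.CONDUCTION
_G = AphasiaType.GLOBAL


def _stats(n, aa, white, vimp, cimp, cells):
    names = (
        "age",
        "months_post_onset",
        "education",
        "noms_verbal_initial",
        "noms_verbal_final",
        "noms_comp_initial",
        "noms_comp_final",
    )
    mean = {k: m for k, (m, _) in zip(names, cells)}
    sd = {k: s for k, (_, s) in zip(names, cells)}
    return GroupStats(
        n=n, african_american=aa, white=white,
        verbal_improvers=vimp, comp_improvers=cimp, mean=mean, sd=sd,
    )


def table1_fixture() -> CohortSummary:
    """The published descriptive summary, cell-for-cell.

    Groups of size 1 carry ``None`` sds (printed as "(-)").  The published
    White counts per type sum to 14 against a full-sample count of 15 (the
    conduction column prints White = 1 for a group of 2); cells are kept as
    printed rather than reconciled.
    """
    full = _stats(20, 5, 15, 9, 15, [
        (60.9, 15.2), (40.4, 64.1), (14.6, 2.3),
        (4.5, 1.7), (4.9, 1.7), (5.05, 1.4), (6.05, 1.0),
    ])
    by_type = {
        _A: _stats(9, 2, 7, 4, 6, [
            (65.6, 13.1), (24.4, 21.4), (14.9, 3.0),
            (5.9, 0.6), (6.3, 0.7), (5.9, 0.9), (6.7, 0.7),
        ]),
        _B: _stats(8, 2, 6, 2, 6, [
            (56.0, 13.7), (64.1, 97.3), (14.1, 1.6),
            (3.5, 1.4), (3.8, 1.2), (4.8, 0.7), (5.6, 0.9),
        ]),
        _C: _stats(2, 0, 1, 2, 2, [
            (59.0, 17.0), (11.0, 7.1), (14.0, 2.8),
            (3.5, 0.7), (4.5, 0.7), (4.5, 0.7), (6.0, 0.0),
        ]),
        _G: _stats(1, 1, 0, 1, 1, [
            (35.0, None), (16.0, None), (16.0, None),
            (1.0, None), (2.0, None), (1.0, None), (4.0, None),
        ]),
    }
    return CohortSummary(full=full, by_type=by_type)


# (type, total cost, p_verbal %, p_comp %, E(Cost) verbal, E(Cost) comp,
#  dQCL, value verbal, value comp) — 16 published rows, verbatim.
_TABLE5_ROWS = (
    (_A, 1188, 72, 95, "850.61", "1127.06", "1.12", "759.47", "1006.30"),
    (_A, 648, 77, 32, "501.68", "207.17", "1.15", "436.24", "180.14"),
    (_A, 864, 36, 78, "306.72", "670.64", "0.59", "519.86", "1136.67"),
    (_A, 540, 42, 94, "224.80", "506.90", "1.4", "160.57", "362.07"),
    (_A, 972, 42, 59, "411.16", "571.24", "0.34", "1209.28", "1680.13"),
    (_A, 1080, 28, 93, "299.16", "1006.88", "1.07", "279.59", "941.01"),
    (_A, 1296, 54, 90, "695.56", "1160.96", "1.06", "656.19", "1095.24"),
    (_A, 648, 51, 91, "333.07", "587.93", "1.13", "294.75", "520.29"),
    (_A, 1296, 27, 65, "350.83", "840.46", "0.23", "1525.34", "3654.16"),
    (_B, 1296, 70, 46, "906.81", "598.36", "0.2", "4534.06", "2991.82"),
    (_B, 1296, 3, 70, "33.37", "909.79", "0.34", "98.15", "2675.86"),
    (_B, 1296, 14, 73, "180.14", "939.60", "0.54", "333.60", "1740.00"),
    (_B, 1296, 17, 71, "219.67", "923.40", "0.25", "878.69", "3693.60"),
    (_B, 1296, 32, 89, "413.68", "1149.55", "0.03", "13789.44", "38318.40"),
    (_C, 1296, 81, 61, "1050.67", "786.41", "0.56", "1876.19", "1404.31"),
    (_G, 1296, 85, 79, "1100.56", "1020.60", "0.85", "1294.78", "1200.71"),
)


def table5_fixture() -> list[CostValueRecord]:
    """The published 16-row simulated-sample cost/value table, verbatim.

    Probabilities are the printed whole-percent values; expected costs and
    values are the printed dollar cells (so ``p * cost`` reproduces
    ``e_cost`` only to rounding, while the ratio identity
    ``value = e_cost / qcl_improvement`` is exact to the cent for the
    self-consistent rows).
    """
    rows = []
    for i, (atype, cost, pv, pc, ecv, ecc, dqcl, vv, vc) in enumerate(_TABLE5_ROWS):
        rows.append(
            CostValueRecord(
                patient_id=f"t5-{i + 1:02d}",
                aphasia_type=atype,
                total_treatment_cost=Fraction(cost),
                p_verbal=Fraction(pv, 100),
                p_comp=Fraction(pc, 100),
                e_cost_verbal=Fraction(Decimal(ecv)),
                e_cost_comp=Fraction(Decimal(ecc)),
                qcl_improvement=Fraction(Decimal(dqcl)),
                value_verbal=Fraction(Decimal(vv)),
                value_comp=Fraction(Decimal(vc)),
            )
        )
    return rows


# patient_id, type, age, edu, AA, tpo, sessions, verbal (i, f), comp (i, f),
# QCL (i, f).  Synthetic fill; see module docstring for what is exact.
_STUDY_ROWS = (
    ("pwa-01", _A, 72.0, 16.0, 1, 24.0, 12, 6, 7, 6, 7, 2.88, 4.00),
    ("pwa-02", _A, 68.0, 12.0, 0, 30.0, 12, 6, 7, 6, 7, 2.50, 3.65),
    ("pwa-03", _A, 60.0, 13.0, 0, 18.0, 12, 5, 6, 5, 7, 3.40, 3.99),
    ("pwa-04", _A, 75.0, 18.0, 0, 45.0, 8, 6, 7, 6, 7, 2.10, 3.50),
    ("pwa-05", _A, 55.0, 14.0, 1, 12.0, 5, 6, 6, 6, 7, 3.00, 3.34),
    ("pwa-06", _A, 70.0, 15.0, 0, 20.0, 12, 6, 6, 5, 6, 2.60, 3.67),
    ("pwa-07", _A, 66.0, 16.0, 0, 28.0, 12, 6, 6, 6, 6, 3.10, 3.15),
    ("pwa-08", _A, 58.0, 13.0, 0, 22.0, 12, 6, 6, 6, 6, 2.90, 2.93),
    ("pwa-09", _A, 66.0, 17.0, 0, 21.0, 12, 6, 6, 7, 7, 3.50, 3.55),
    ("pwa-10", _B, 50.0, 14.0, 1, 36.0, 6, 3, 4, 5, 6, 2.80, 3.00),
    ("pwa-11", _B, 45.0, 12.0, 0, 24.0, 11, 4, 6, 5, 5, 3.00, 3.34),
    ("pwa-12", _B, 62.0, 15.0, 1, 300.0, 12, 2, 2, 5, 6, 2.40, 2.94),
    ("pwa-13", _B, 55.0, 16.0, 0, 60.0, 12, 3, 3, 4, 6, 3.20, 3.45),
    ("pwa-14", _B, 70.0, 14.0, 0, 48.0, 12, 4, 4, 5, 6, 2.75, 2.78),
    ("pwa-15", _B, 48.0, 13.0, 0, 12.0, 12, 5, 5, 5, 6, 3.10, 4.16),
    ("pwa-16", _B, 66.0, 15.0, 0, 18.0, 12, 3, 3, 4, 5, 2.95, 4.08),
    ("pwa-17", _B, 52.0, 14.0, 0, 15.0, 12, 4, 4, 5, 5, 3.05, 3.05),
    ("pwa-18", _C, 47.0, 12.0, 0, 6.0, 12, 3, 4, 4, 6, 2.66, 3.22),
    ("pwa-19", _C, 71.0, 16.0, 0, 16.0, 9, 4, 5, 5, 6, 3.00, 3.56),
    ("pwa-20", _G, 35.0, 16.0, 1, 16.0, 12, 1, 2, 1, 4, 1.80, 2.65),
)


def synthetic_study_cohort() -> list[PatientRecord]:
    """Synthetic 20-patient reconstruction of the study cohort (not real data).

    Exactly reproduces the published counts and billing structure (see
    module docstring); continuous covariates are synthetic fill.
    """
    return [
        PatientRecord(
            patient_id=pid,
            age=age,
            education=edu,
            african_american=aa,
            months_post_onset=tpo,
            aphasia_type=atype,
            sessions_attended=sessions,
            noms_verbal_initial=vi,
            noms_verbal_final=vf,
            noms_comp_initial=ci,
            noms_comp_final=cf,
            qcl_initial=qi,
            qcl_final=qf,
        )
        for pid, atype, age, edu, aa, tpo, sessions, vi, vf, ci, cf, qi, qf in _STUDY_ROWS
    ]
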