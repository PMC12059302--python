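"""Per-patient constraint tables, cohort summaries, paired bone/chest-wall test.

Rendering follows the clinical report layout: one row per constraint with
requirement, Tx value, Tx+Im value, Im/Tx (%) and — for dose-valued C1
constraints — Im/Rx (%); unmet constraints are flagged.  Pass/fail is
decided upstream on unrounded values; rendering rounds metric values to one
decimal (two for PTV coverage and the delta columns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .protocols import ConstraintResult, Prescription

__all__ = [
    "CohortSummary",
    "summarize_cohort",
    "paired_bone_chestwall",
    "render_patient_table",
    "table_to_text",
]

#: Im/Tx census threshold (%): constraints whose increment exceeds this are
#: counted separately (the level above which imaging dose is conventionally
#: deemed worth accounting for).
IM_OVER_TX_CENSUS_PCT = 5.0


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level tallies; OAR constraints and PTV coverage kept separate."""

    n_patients: int
    n_oar_evaluated: int
    n_oar_failed_tx: int
    n_oar_failed_total: int
    n_oar_flipped: int
    pct_oar_failed_tx: float
    pct_oar_flipped: float
    n_ptv_evaluated: int
    n_ptv_failed_tx: int
    n_ptv_failed_total: int
    n_ptv_flipped: int
    im_over_tx_min: float
    im_over_tx_mean: float
    im_over_tx_max: float
    n_im_over_tx_gt5: int
    max_im_over_rx: float
    max_im_over_rx_label: str

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _is_oar(r: ConstraintResult) -> bool:
    return (not r.spec.report_only) and r.spec.structure_name != "PTV"


def _is_ptv(r: ConstraintResult) -> bool:
    return (not r.spec.report_only) and r.spec.structure_name == "PTV"


def summarize_cohort(per_patient_results: list[list[ConstraintResult]]) -> CohortSummary:
    """Tally failures, flips and imaging increments over a cohort.

    Denominators count evaluated, enforceable constraints only: report-only
    rows and constraints whose structure was missing are excluded.
    Percentages are rounded to one decimal.
    """
    if not per_patient_results:
        raise ValueError("summarize_cohort needs at least one patient")
    flat = [r for results in per_patient_results for r in results if r.evaluated]
    oar = [r for r in flat if _is_oar(r)]
    ptv = [r for r in flat if _is_ptv(r)]
    n_oar = len(oar)
    n_oar_failed_tx = int(sum(not r.pass_tx for r in oar))
    n_oar_failed_total = int(sum(not r.pass_total for r in oar))
    n_oar_flipped = int(sum(bool(r.flipped) for r in oar))
    im_tx = [r.im_over_tx_pct for r in oar if np.isfinite(r.im_over_tx_pct)]
    im_rx = [
        (r.im_over_rx_pct, f"{r.patient_id} {r.spec.label}")
        for r in flat
        if r.im_over_rx_pct is not None and not r.spec.report_only
    ]
    max_rx = max(im_rx, default=(0.0, ""))
    return CohortSummary(
        n_patients=len(per_patient_results),
        n_oar_evaluated=n_oar,
        n_oar_failed_tx=n_oar_failed_tx,
        n_oar_failed_total=n_oar_failed_total,
        n_oar_flipped=n_oar_flipped,
        pct_oar_failed_tx=round(100.0 * n_oar_failed_tx / n_oar, 1) if n_oar else 0.0,
        pct_oar_flipped=round(100.0 * n_oar_flipped / n_oar, 1) if n_oar else 0.0,
        n_ptv_evaluated=len(ptv),
        n_ptv_failed_tx=int(sum(not r.pass_tx for r in ptv)),
        n_ptv_failed_total=int(sum(not r.pass_total for r in ptv)),
        n_ptv_flipped=int(sum(bool(r.flipped) for r in ptv)),
        im_over_tx_min=float(min(im_tx)) if im_tx else 0.0,
        im_over_tx_mean=float(np.mean(im_tx)) if im_tx else 0.0,
        im_over_tx_max=float(max(im_tx)) if im_tx else 0.0,
        n_im_over_tx_gt5=int(sum(v > IM_OVER_TX_CENSUS_PCT for v in im_tx)),
        max_im_over_rx=float(max_rx[0]),
        max_im_over_rx_label=max_rx[1],
    )


def paired_bone_chestwall(
    per_patient_results: list[list[ConstraintResult]], which: str = "total"
) -> dict:
    """Paired two-sided t-test of bone V30 (cc) against chest-wall V30 (cc).

    Bone is not a clinical OAR but absorbs kV photons ~4x more than soft
    tissue, so its V30 is carried as a report-only metric and compared
    per patient against the chest wall's.  ``which`` selects the dose
    ('tx' or 'total').  Zero variance of the differences yields a
    degenerate report with no p-value.
    """
    attr = "value_total" if which == "total" else "value_tx"
    pairs = []
    for results in per_patient_results:
        bone = cw = None
        for r in results:
            if not r.evaluated or r.spec.metric != "V_D_cc":
                continue
            if r.spec.threshold_dose != 30.0:
                continue
            if r.spec.structure_name == "Bone":
                bone = getattr(r, attr)
            elif r.spec.structure_name == "ChestWall":
                cw = getattr(r, attr)
        if bone is not None and cw is not None:
            pairs.append((bone, cw))
    if len(pairs) < 2:
        raise ValueError("paired comparison needs >= 2 patients with both V30 metrics")
    bone_v = np.array([p[0] for p in pairs])
    cw_v = np.array([p[1] for p in pairs])
    diff = bone_v - cw_v
    report = {
        "n_pairs": len(pairs),
        "mean_bone_cc": float(bone_v.mean()),
        "mean_chestwall_cc": float(cw_v.mean()),
        "mean_difference_cc": float(diff.mean()),
    }
    if np.allclose(diff.std(ddof=1), 0.0):
        report.update({"t": None, "p": None, "degenerate": True})
        return report
    t, p = stats.ttest_rel(bone_v, cw_v)
    report.update({"t": float(t), "p": float(p), "degenerate": False})
    return report


def _fmt(value: float | None, decimals: int) -> str:
    if value is None:
        return "–"
    if math.isinf(value):
        return "inf"
    return f"{value:.{decimals}f}"


def render_patient_table(
    results: list[ConstraintResult], rx: Prescription
) -> pd.DataFrame:
    """Constraint report for one patient as a DataFrame of formatted strings.

    Columns: Category, Constraint, Requirement, Tx, Tx + Im, Im/Tx (%),
    Im/Rx (%); unmet constraints carry a trailing ``*`` on the value.
    """
    rows = []
    for r in results:
        spec = r.spec
        vdec = 2 if spec.metric == "PTV_VpctRx" else 1
        if not r.evaluated:
            rows.append({
                "Category": spec.category, "Constraint": spec.label,
                "Requirement": spec.requirement, "Tx": "n/e", "Tx + Im": "n/e",
                "Im/Tx (%)": "–", "Im/Rx (%)": "–",
            })
            continue
        tx_s = _fmt(r.value_tx, vdec)
        tot_s = _fmt(r.value_total, vdec)
        if r.pass_tx is False:
            tx_s += "*"
        if r.pass_total is False:
            tot_s += "*"
        rows.append({
            "Category": spec.category,
            "Constraint": spec.label,
            "Requirement": spec.requirement,
            "Tx": tx_s,
            "Tx + Im": tot_s,
            "Im/Tx (%)": _fmt(r.im_over_tx_pct, 2),
            "Im/Rx (%)": _fmt(r.im_over_rx_pct, 2) if spec.category == "C1" else "–",
        })
    return pd.DataFrame(rows)


def table_to_text(table: pd.DataFrame, title: str = "") -> str:
    """Fixed-width text rendering of a patient table (same numbers as the CSV)."""
    body = table.to_string(index=False)
    header = f"{title}\n" if title else ""
    return f"{header}{body}\n(* = unmet constraint; n/e = not evaluated)\n"
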