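"""Clinical constraint tables and their evaluation under Tx and Tx+Im dose.

The three fractionation schemes map to the three trial constraint sets
(4 fr -> RTOG0915, 8 fr -> LUSTER, 15 fr -> SUNSET), shipped verbatim as
editable YAML files under ``kvdose/data/protocols``.  Constraints fall in
three categories: C1 (absolute dose, Gy: Dmean, Dmax to 0.03 cc, D2%),
C2 (absolute volume, cc: V_D), C3 (percent volume: V_D %, PTV V90%).

Each constraint is evaluated on the treatment dose (Tx) and on the total
dose (Tx + Im, imaging dose accumulated over the course), pass/fail is
decided on unrounded values, and the increments are reported relative to
the Tx value (Im/Tx %) and — for dose-valued C1 constraints — relative to
the prescription (Im/Rx %).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from . import dvh
from .grids import DoseGrid, add, resample_to
from .structures import StructureSet

__all__ = [
    "Prescription",
    "ConstraintSpec",
    "ConstraintResult",
    "MissingStructureError",
    "PROTOCOL_NAMES",
    "load_protocol",
    "protocol_for_fractions",
    "evaluate_metric",
    "apply_comparator",
    "evaluate_constraint",
    "evaluate_patient",
]

PROTOCOL_NAMES = ("RTOG0915", "LUSTER", "SUNSET")

_FRACTIONS_TO_PROTOCOL = {4: "RTOG0915", 8: "LUSTER", 15: "SUNSET"}

_DOSE_METRICS = {"Dmean", "Dmax_0p03cc", "D2pct"}
_CATEGORY_METRICS = {
    "C1": _DOSE_METRICS,
    "C2": {"V_D_cc"},
    "C3": {"V_D_pct", "PTV_VpctRx"},
}

#: Sentinel for Im/Tx when the Tx value is exactly zero but Tx+Im is not.
UNDEFINED_LARGE = float("inf")


@dataclass(frozen=True)
class Prescription:
    """Prescription dose (total Gy) and fraction count."""

    rx_total: float
    n_fractions: int

    def __post_init__(self) -> None:
        if self.rx_total <= 0:
            raise ValueError("rx_total must be > 0 Gy")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")


@dataclass(frozen=True)
class ConstraintSpec:
    """One protocol rule: metric kind, optional dose threshold, limit, comparator."""

    structure_name: str
    category: str  # C1 | C2 | C3
    metric: str  # Dmean | Dmax_0p03cc | D2pct | V_D_cc | V_D_pct | PTV_VpctRx
    limit: float | None = None
    unit: str = ""
    comparator: str | None = None  # "<=", "<", ">"
    threshold_dose: float | None = None  # Gy, for V_D and PTV metrics
    pct_of_rx: float | None = None  # for PTV_VpctRx
    report_only: bool = False

    def __post_init__(self) -> None:
        if self.category not in _CATEGORY_METRICS:
            raise ValueError(f"unknown category {self.category!r}")
        if self.metric not in _CATEGORY_METRICS[self.category]:
            raise ValueError(
                f"metric {self.metric!r} inconsistent with category {self.category}"
            )
        if self.report_only:
            if self.limit is not None or self.comparator is not None:
                raise ValueError("report-only constraints carry no limit/comparator")
        else:
            if self.limit is None or self.comparator not in ("<=", "<", ">"):
                raise ValueError(
                    f"enforceable constraint {self.structure_name}/{self.metric} "
                    "needs a limit and a comparator in {<=, <, >}"
                )
        if self.metric in ("V_D_cc", "V_D_pct") and self.threshold_dose is None:
            raise ValueError(f"{self.metric} requires threshold_dose")
        if self.metric == "PTV_VpctRx" and self.pct_of_rx is None:
            raise ValueError("PTV_VpctRx requires pct_of_rx")

    @property
    def label(self) -> str:
        """Human-readable constraint name, e.g. 'Trachea PRV V15.6 Gy'."""
        if self.metric == "Dmean":
            return f"{self.structure_name} Dmean"
        if self.metric == "Dmax_0p03cc":
            return f"{self.structure_name} Dmax"
        if self.metric == "D2pct":
            return f"{self.structure_name} D2%"
        if self.metric == "PTV_VpctRx":
            return f"{self.structure_name} V{self.pct_of_rx:g}%"
        return f"{self.structure_name} V{self.threshold_dose:g} Gy"

    @property
    def requirement(self) -> str:
        if self.report_only:
            return "N/A"
        comp = {"<=": "≤", "<": "<", ">": ">"}[self.comparator]
        return f"{comp}{self.limit:g}{'' if self.unit == '%' else ' '}{self.unit}"


@dataclass(frozen=True)
class ConstraintResult:
    """Outcome of one constraint under Tx and Tx+Im dose."""

    spec: ConstraintSpec
    patient_id: str = ""
    evaluated: bool = True
    value_tx: float | None = None
    value_total: float | None = None
    pass_tx: bool | None = None
    pass_total: bool | None = None
    flipped: bool = False
    im_over_tx_pct: float | None = None
    im_over_rx_pct: float | None = None  # C1 only


class MissingStructureError(KeyError):
    """A constraint references a structure absent from the structure set."""


def _load_yaml(name: str) -> dict:
    fname = {"RTOG0915": "rtog0915.yaml", "LUSTER": "luster.yaml", "SUNSET": "sunset.yaml"}[name]
    with resources.files("kvdose").joinpath(f"data/protocols/{fname}").open("r") as fh:
        return yaml.safe_load(fh)


def load_protocol(name: str) -> list[ConstraintSpec]:
    """Load one trial's constraint set (enforceable rules + report-only bone rows).

    Rows marked N/A in the clinical table are simply absent from the files.
    """
    if name not in PROTOCOL_NAMES:
        raise ValueError(f"unknown protocol {name!r}; valid names: {PROTOCOL_NAMES}")
    doc = _load_yaml(name)
    specs = [
        ConstraintSpec(
            structure_name=row["structure"],
            category=row["category"],
            metric=row["metric"],
            limit=float(row["limit"]),
            unit=str(row.get("unit", "")),
            comparator=row["comparator"],
            threshold_dose=row.get("threshold_dose"),
            pct_of_rx=row.get("pct_of_rx"),
        )
        for row in doc["constraints"]
    ]
    specs += [
        ConstraintSpec(
            structure_name=row["structure"],
            category=row["category"],
            metric=row["metric"],
            unit=str(row.get("unit", "")),
            threshold_dose=row.get("threshold_dose"),
            report_only=True,
        )
        for row in doc.get("report_only", [])
    ]
    return specs


def protocol_for_fractions(n_fractions: int) -> str:
    try:
        return _FRACTIONS_TO_PROTOCOL[n_fractions]
    except KeyError:
        raise ValueError(
            f"no protocol defined for {n_fractions} fractions; "
            f"known schemes: {sorted(_FRACTIONS_TO_PROTOCOL)}"
        ) from None


def evaluate_metric(
    spec: ConstraintSpec,
    dose: DoseGrid,
    structures: StructureSet,
    rx: Prescription,
    strict: bool = False,
) -> float:
    """Evaluate the metric named by a constraint spec on one dose grid."""
    if spec.structure_name not in structures:
        raise MissingStructureError(spec.structure_name)
    mask = structures.mask(spec.structure_name)
    name = spec.structure_name
    if spec.metric == "Dmean":
        return dvh.mean_dose(dose, mask, name)
    if spec.metric == "Dmax_0p03cc":
        return dvh.dose_at_volume(dose, mask, dvh.DMAX_VOLUME_CC, name)
    if spec.metric == "D2pct":
        return dvh.dose_at_volume_pct(dose, mask, 2.0, name)
    if spec.metric == "V_D_cc":
        return dvh.volume_above_cc(dose, mask, spec.threshold_dose, strict=strict)
    if spec.metric == "V_D_pct":
        return dvh.volume_above_pct(dose, mask, spec.threshold_dose, strict=strict, structure=name)
    if spec.metric == "PTV_VpctRx":
        return dvh.ptv_v_pct_of_rx(dose, mask, rx.rx_total, spec.pct_of_rx, strict=strict)
    raise ValueError(f"unknown metric {spec.metric!r}")


def apply_comparator(value: float, spec: ConstraintSpec) -> bool:
    """Pass/fail on the unrounded metric value."""
    if not np.isfinite(value):
        raise ValueError(f"non-finite constraint value for {spec.label}")
    if spec.report_only:
        raise ValueError(f"{spec.label} is report-only and has no pass/fail")
    if spec.comparator == "<=":
        return value <= spec.limit
    if spec.comparator == "<":
        return value < spec.limit
    return value > spec.limit


def evaluate_constraint(
    spec: ConstraintSpec,
    tx: DoseGrid,
    total: DoseGrid,
    structures: StructureSet,
    rx: Prescription,
    patient_id: str = "",
    strict: bool = False,
) -> ConstraintResult:
    """Evaluate one constraint under Tx and Tx+Im and derive the deltas.

    Im/Tx (%) = 100 x (value_total - value_tx) / value_tx, with 0/0 := 0;
    Im/Rx (%) = 100 x (value_total - value_tx) / rx_total for C1 constraints.
    """
    if tx.geometry != total.geometry:
        raise ValueError("Tx and total dose grids must share one geometry")
    try:
        v_tx = evaluate_metric(spec, tx, structures, rx, strict=strict)
        v_tot = evaluate_metric(spec, total, structures, rx, strict=strict)
    except MissingStructureError:
        return ConstraintResult(spec=spec, patient_id=patient_id, evaluated=False)
    if v_tx == 0.0:
        if v_tot > 0.0:
            warnings.warn(
                f"{spec.label}: Tx value is 0 but Tx+Im is {v_tot:.4g}; "
                "Im/Tx reported as inf",
                stacklevel=2,
            )
            im_over_tx = UNDEFINED_LARGE
        else:
            im_over_tx = 0.0
    else:
        im_over_tx = 100.0 * (v_tot - v_tx) / v_tx
    im_over_rx = 100.0 * (v_tot - v_tx) / rx.rx_total if spec.category == "C1" else None
    if spec.report_only:
        p_tx = p_tot = None
        flipped = False
    else:
        p_tx = apply_comparator(v_tx, spec)
        p_tot = apply_comparator(v_tot, spec)
        flipped = p_tx != p_tot
    return ConstraintResult(
        spec=spec,
        patient_id=patient_id,
        value_tx=v_tx,
        value_total=v_tot,
        pass_tx=p_tx,
        pass_total=p_tot,
        flipped=flipped,
        im_over_tx_pct=im_over_tx,
        im_over_rx_pct=im_over_rx,
    )


def evaluate_patient(case, im_dose: DoseGrid, strict: bool = False) -> list[ConstraintResult]:
    """Evaluate the full protocol table for one patient case.

    The protocol is selected by the case's fractionation; the imaging dose
    is resampled onto the treatment-dose grid (the canonical accumulation
    geometry) and added.  Returns one result per table row, in table order;
    constraints whose structure is missing come back with
    ``evaluated=False`` and are excluded from cohort denominators.
    """
    protocol = protocol_for_fractions(case.prescription.n_fractions)
    specs = load_protocol(protocol)
    tx = case.tx_dose
    if im_dose.geometry != tx.geometry:
        im_dose = resample_to(im_dose, tx.geometry)
    total = add(tx, im_dose)
    return [
        evaluate_constraint(
            spec, tx, total, case.structures, case.prescription,
            patient_id=case.id, strict=strict,
        )
        for spec in specs
    ]
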