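"""File formats, run configuration, and the end-to-end pipeline.

Readers and writers for the CSV dialects used throughout:

* growth-reference CSV in the published CDC column layout
  (``Sex`` 1=male/2=female, ``Agemos``, ``L``, ``M``, ``S``; extra
  percentile columns ignored);
* patient CSV (patient_id, age_months, sex, height_cm, weight_kg,
  growth_chart_id);
* order CSV (order_id, patient_id, drug, dose_amount, dose_unit,
  weight_kind_used, weight_used_kg, department, month, level_based, phase);
* evaluation, chart and funnel CSV outputs.

:func:`run_pipeline` binds the stages together: read inputs → classify
patients → evaluate orders → aggregate monthly → build the phased p-chart
with shift detection → build the unit funnel → write outputs and a summary
report. Stage failures are reported with the stage name and no partial
outputs are left in place (everything is computed before anything is
written).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from .anthropometry import (
    GrowthChart,
    LMSRecord,
    LMSTable,
    PatientAnthropometrics,
    Sex,
    WeightKind,
)
from .errors import ConfigurationError, ObesityDosingError, SchemaError
from .formulary import Formulary, default_formulary, load_formulary
from .order_eval import (
    BatchResult,
    GroupKey,
    MedicationOrder,
    OrderDoseUnit,
    OrderEvaluation,
    Phase,
    Status,
    aggregate_proportions,
    evaluate_batch,
)
from .spc import FunnelResult, PChartResult, build_funnel, build_pchart

log = logging.getLogger(__name__)


class PipelineError(ObesityDosingError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_CDC_SEX = {1: Sex.MALE, 2: Sex.FEMALE}


def load_lms_csv(path: str | Path, source_label: str | None = None) -> LMSTable:
    """Read a growth-reference CSV in the CDC published column layout."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"Sex", "Agemos", "L", "M", "S"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"LMS CSV {path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        sex_code = int(getattr(row, "Sex"))
        if sex_code not in _CDC_SEX:
            raise SchemaError(f"LMS CSV {path}: unknown sex code {sex_code}")
        records.append(
            LMSRecord(
                sex=_CDC_SEX[sex_code],
                age_months=float(getattr(row, "Agemos")),
                L=float(getattr(row, "L")),
                M=float(getattr(row, "M")),
                S=float(getattr(row, "S")),
            )
        )
    return LMSTable(records, source_label=source_label or str(path))


def write_lms_csv(table: LMSTable, path: str | Path) -> None:
    rows = [
        {
            "Sex": 1 if r.sex is Sex.MALE else 2,
            "Agemos": r.age_months,
            "L": r.L,
            "M": r.M,
            "S": r.S,
        }
        for r in table.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_patients_csv(path: str | Path) -> list[PatientAnthropometrics]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        PatientAnthropometrics(
            patient_id=str(row.patient_id),
            age_months=int(row.age_months),
            sex=Sex(str(row.sex)),
            height_cm=float(row.height_cm),
            weight_kg=float(row.weight_kg),
            growth_chart_id=GrowthChart(str(row.growth_chart_id)),
        )
        for row in df.itertuples(index=False)
    ]


def write_patients_csv(patients: Sequence[PatientAnthropometrics], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "age_months": p.age_months,
                "sex": p.sex.value,
                "height_cm": p.height_cm,
                "weight_kg": p.weight_kg,
                "growth_chart_id": p.growth_chart_id.value,
            }
            for p in patients
        ]
    ).to_csv(path, index=False)


def _parse_weight_kind(value: Any) -> WeightKind | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip().lower()
    if text in ("", "none", "nan"):
        return None
    return WeightKind(text)


def load_orders_csv(path: str | Path) -> list[MedicationOrder]:
    df = pd.read_csv(path, float_precision="round_trip")
    orders = []
    for row in df.itertuples(index=False):
        weight_used = getattr(row, "weight_used_kg", None)
        if weight_used is not None and pd.isna(weight_used):
            weight_used = None
        orders.append(
            MedicationOrder(
                order_id=str(row.order_id),
                patient_id=str(row.patient_id),
                drug=str(row.drug),
                dose_amount=float(row.dose_amount),
                dose_unit=OrderDoseUnit(str(row.dose_unit)),
                weight_kind_used=_parse_weight_kind(getattr(row, "weight_kind_used", None)),
                weight_used_kg=None if weight_used is None else float(weight_used),
                department=str(getattr(row, "department", "unknown")),
                month=str(getattr(row, "month", "0000-00")),
                level_based=_parse_bool(getattr(row, "level_based", False)),
                phase=Phase(str(getattr(row, "phase", "pre"))),
            )
        )
    return orders


def _parse_bool(value: Any) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("true", "1", "yes")


def write_orders_csv(orders: Sequence[MedicationOrder], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "order_id": o.order_id,
                "patient_id": o.patient_id,
                "drug": o.drug,
                "dose_amount": o.dose_amount,
                "dose_unit": o.dose_unit.value,
                "weight_kind_used": (
                    "none" if o.weight_kind_used is None else o.weight_kind_used.value
                ),
                "weight_used_kg": o.weight_used_kg,
                "department": o.department,
                "month": o.month,
                "level_based": o.level_based,
                "phase": o.phase.value,
            }
            for o in orders
        ]
    ).to_csv(path, index=False)


def write_evaluations_csv(evaluations: Sequence[OrderEvaluation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "order_id": ev.order_id,
                "status": ev.status.value,
                "reason": ev.reason.value,
                "computed_per_kg": ev.computed_per_kg,
                "drug": ev.drug,
                "department": ev.department,
                "month": ev.month,
                "phase": ev.phase.value,
                "age_band": ev.age_band,
            }
            for ev in evaluations
        ]
    ).to_csv(path, index=False)


def write_chart_csv(chart: PChartResult, path: str | Path) -> None:
    signal_at = {}
    for sig in chart.signals:
        signal_at.setdefault(sig.index, []).append(f"{sig.rule}:{sig.side}")
    pd.DataFrame(
        [
            {
                "label": sub.label,
                "n": sub.n,
                "successes": sub.successes,
                "proportion": chart.proportions[i],
                "centerline": chart.centerline[i],
                "ucl": chart.ucl[i],
                "lcl": chart.lcl[i],
                "phase": chart.phase_of(i),
                "signal": ";".join(signal_at.get(i, [])),
            }
            for i, sub in enumerate(chart.subgroups)
        ]
    ).to_csv(path, index=False)


def write_funnel_csv(result: FunnelResult, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "label": label,
                "n": n,
                "proportion": p,
                "lower": lo,
                "upper": hi,
                "flagged": flagged,
            }
            for label, n, p, lo, hi, flagged in result.units
        ]
    ).to_csv(path, index=False)


def load_subgroups_csv(path: str | Path):
    from .spc import SubgroupProportion

    df = pd.read_csv(path)
    return [
        SubgroupProportion(label=str(r.label), n=int(r.n), successes=int(r.successes))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a full pipeline run needs.

    ``intervention_dates`` are ISO ``YYYY-MM`` labels; a month equal to an
    intervention date starts the new phase (half-open). ``goal`` is the
    target appropriateness proportion the initiative aims to exceed.
    """

    patients: str
    orders: str
    lms: str
    out_dir: str
    formulary: str | None = None  # None -> packaged default
    intervention_dates: tuple[str, ...] = ()
    goal: float = 0.74
    inclusive_thresholds: bool = False
    cofactor: float = 0.4
    funnel_sigma: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 < self.goal <= 1.0):
            raise ConfigurationError(f"goal {self.goal} outside (0, 1]")
        if not (0.0 <= self.cofactor <= 1.0):
            raise ConfigurationError(f"cofactor {self.cofactor} outside [0, 1]")
        if self.funnel_sigma <= 0:
            raise ConfigurationError("funnel sigma must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a YAML or JSON config document."""
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ConfigurationError(f"config {path} is not a mapping")
        doc = dict(doc)
        if "intervention_dates" in doc:
            doc["intervention_dates"] = tuple(doc["intervention_dates"])
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        return cls(**doc)


def assign_phases(
    orders: Sequence[MedicationOrder], intervention_dates: Sequence[str]
) -> list[MedicationOrder]:
    """Re-derive each order's pre/post phase from its month label.

    Months at or after the first intervention date are post-phase. With no
    intervention dates the orders are returned unchanged.
    """
    if not intervention_dates:
        return list(orders)
    first = min(intervention_dates)
    out = []
    for o in orders:
        phase = Phase.POST if o.month >= first else Phase.PRE
        if phase is o.phase:
            out.append(o)
        else:
            out.append(
                MedicationOrder(
                    order_id=o.order_id,
                    patient_id=o.patient_id,
                    drug=o.drug,
                    dose_amount=o.dose_amount,
                    dose_unit=o.dose_unit,
                    weight_kind_used=o.weight_kind_used,
                    weight_used_kg=o.weight_used_kg,
                    department=o.department,
                    month=o.month,
                    level_based=o.level_based,
                    phase=phase,
                )
            )
    return out


def phase_break_indices(
    month_labels: Sequence[str], intervention_dates: Sequence[str]
) -> list[int]:
    """Indices into the ordered month series where a new phase starts."""
    breaks = []
    for date in sorted(intervention_dates):
        idx = next((i for i, m in enumerate(month_labels) if m >= date), None)
        if idx is not None and 0 < idx < len(month_labels):
            breaks.append(idx)
    return sorted(set(breaks))


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full audit pipeline and write all outputs.

    Returns the summary report (also written as ``summary.json``): stage
    conservation counts, per-phase appropriateness, whether the goal was
    met in the final phase, and any special-cause signals.
    """

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if (
                    exc is not None
                    and isinstance(exc, ObesityDosingError)
                    and not isinstance(exc, PipelineError)
                ):
                    raise PipelineError(f"{name}: {exc}") from exc
                return False

        return _Ctx()

    with stage("inputs"):
        patients = load_patients_csv(config.patients)
        orders = load_orders_csv(config.orders)
        lms = load_lms_csv(config.lms)
        formulary = (
            default_formulary()
            if config.formulary is None
            else load_formulary(Path(config.formulary))
        )
        orders = assign_phases(orders, config.intervention_dates)

    with stage("order_eval"):
        if not orders:
            raise PipelineError("order_eval: no orders to evaluate")
        batch = evaluate_batch(
            orders,
            patients,
            formulary,
            lms,
            cofactor=config.cofactor,
            inclusive=config.inclusive_thresholds,
        )
        log.info(
            "order_eval: %d in = %d evaluated + %d rejected + %d not governed",
            len(orders),
            len(batch.evaluations),
            len(batch.rejects),
            len(batch.not_governed),
        )

    with stage("spc"):
        monthly = aggregate_proportions(batch.evaluations, GroupKey.MONTH)
        if not monthly:
            raise PipelineError("spc: no non-excluded evaluations to chart")
        breaks = phase_break_indices(
            [m.label for m in monthly], config.intervention_dates
        )
        chart = build_pchart(monthly, breaks)
        by_unit = aggregate_proportions(batch.evaluations, GroupKey.DEPARTMENT)
        funnel = build_funnel(by_unit, sigma=config.funnel_sigma)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_excluded = sum(1 for ev in batch.evaluations if ev.status is Status.EXCLUDED)
    phase_stats: dict[str, dict] = {}
    for sub in aggregate_proportions(batch.evaluations, GroupKey.PHASE):
        phase_stats[sub.label] = {
            "n": sub.n,
            "appropriate": sub.successes,
            "proportion": sub.successes / sub.n,
        }
    last_phase_p = chart.phases[-1][1]
    report = {
        "orders_in": len(orders),
        "evaluated": len(batch.evaluations),
        "excluded": n_excluded,
        "rejected": len(batch.rejects),
        "not_governed": len(batch.not_governed),
        "rejects": [list(r) for r in batch.rejects],
        "by_phase": phase_stats,
        "chart_phases": [
            {"start": start, "centerline": pbar} for start, pbar in chart.phases
        ],
        "signals": [
            {"index": s.index, "rule": s.rule, "side": s.side} for s in chart.signals
        ],
        "goal": config.goal,
        "goal_met": last_phase_p > config.goal,
        "outputs": {
            "evaluations": str(out_dir / "evaluations.csv"),
            "chart": str(out_dir / "chart.csv"),
            "funnel": str(out_dir / "funnel.csv"),
            "summary": str(out_dir / "summary.json"),
        },
    }

    with stage("outputs"):
        write_evaluations_csv(batch.evaluations, out_dir / "evaluations.csv")
        write_chart_csv(chart, out_dir / "chart.csv")
        write_funnel_csv(funnel, out_dir / "funnel.csv")
        (out_dir / "summary.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    return report
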