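"""Pre-registered evaluation plans and fully-labelled discrimination reports.

Selective reporting and conflation of concordance indices ("C-hacking")
comes in three flavours: computing many indices and quoting only the
flattering one; pooling structurally different indices into one generic
"C-index" column; and evaluating distribution predictions through an
unnamed reduction.  This layer makes each structurally hard:

* the evaluation protocol is a declared :class:`EvaluationPlan` whose
  digest is stamped on the report, so the set of computed cells is fixed
  before any number is seen and every planned cell is reported;
* every value carries its measure label, measure type (time-independent
  vs time-dependent) and transformation label; there is no code path that
  emits a bare number;
* a cell pairing a measure with a prediction type it cannot evaluate
  renders as an em-dash, never a silently transformed value, and ranked
  comparisons across rows with different measures or transforms are
  refused as incommensurable.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as sio
from .concordance import harrell_c, uno_c
from .data import SurvivalOutcomes
from .exceptions import PlanError
from .reduction import (
    ImproperPolicy,
    SummaryStatistic,
    curve_summary,
    expected_mortality,
    prob_at_time,
)
from .timedep import antolini_c, integrated_auc

__all__ = [
    "ModelSpec",
    "MeasureSpec",
    "EvaluationPlan",
    "ReportRow",
    "EvaluationReport",
    "load_plan",
    "run_evaluation",
    "render_report",
    "ranked_comparison",
]

_MEASURES = ("harrell", "uno", "antolini", "int-auc")
_TRANSFORMS = ("none", "prob@t", "mean", "median", "expmort")
_KINDS = ("risk", "distribution")
_TD_MEASURES = ("antolini",)
DASH = "—"


@dataclass(frozen=True)
class ModelSpec:
    name: str
    kind: str  # "risk" or "distribution"
    file: str

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise PlanError(f"model {self.name!r}: kind must be one of {_KINDS}, got {self.kind!r}")


@dataclass(frozen=True)
class MeasureSpec:
    measure: str
    transform: str = "none"
    improper: str = "naive"
    time: float | None = None  # prob@t evaluation time / uno tau
    tau: float | None = None
    primary: bool = False

    def __post_init__(self):
        if self.measure not in _MEASURES:
            raise PlanError(f"unknown measure {self.measure!r}; choose from {_MEASURES}")
        if self.transform not in _TRANSFORMS:
            raise PlanError(f"unknown transform {self.transform!r}; choose from {_TRANSFORMS}")
        if self.measure == "antolini" and self.transform != "none":
            raise PlanError("antolini evaluates distributions directly; transform must be 'none'")
        if self.transform == "prob@t" and self.time is None:
            raise PlanError("transform 'prob@t' requires a 'time' parameter")

    @property
    def type_label(self) -> str:
        return "TD" if self.measure in _TD_MEASURES else "TI"

    @property
    def measure_label(self) -> str:
        return {
            "harrell": "Harrell's C",
            "uno": "Uno's C",
            "antolini": "Antolini's C",
            "int-auc": "Integrated AUC",
        }[self.measure]

    @property
    def trafo_label(self) -> str:
        if self.transform == "none":
            return DASH
        if self.transform == "prob@t":
            return f"Prob@{self.time:g}"
        if self.transform == "expmort":
            return "ExpMort"
        return f"Summary({self.transform},{self.improper})"


@dataclass(frozen=True)
class EvaluationPlan:
    """A pre-registered set of (model, measure, transform) cells to compute."""

    models: tuple
    measures: tuple
    exploratory: bool = False

    def __post_init__(self):
        if not self.models or not self.measures:
            raise PlanError("plan must declare at least one model and one measure")
        names = [m.name for m in self.models]
        if len(set(names)) != len(names):
            raise PlanError("model names must be unique")
        n_primary = sum(m.primary for m in self.measures)
        if n_primary != 1:
            raise PlanError(f"exactly one measure must be marked primary, found {n_primary}")
        kinds = {m.kind for m in self.models}
        for ms in self.measures:
            if ms.measure == "antolini" and kinds == {"risk"}:
                raise PlanError(
                    "incommensurable: time-dependent distribution measure "
                    "(antolini) vs risk prediction — no model in the plan "
                    "predicts a distribution"
                )
            if ms.type_label == "TI" and ms.transform == "none" and kinds == {"distribution"}:
                raise PlanError(
                    f"measure {ms.measure!r} with no transform cannot evaluate "
                    "distribution predictions; name the reduction explicitly "
                    "(prob@t, mean, median or expmort)"
                )

    def digest(self) -> str:
        """SHA-256 of the canonical plan serialisation (tamper evidence)."""
        payload = {
            "models": [vars(m) for m in self.models],
            "measures": [vars(m) for m in self.measures],
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_plan(path) -> EvaluationPlan:
    """Read an evaluation plan from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "models" not in raw or "measures" not in raw:
        raise PlanError(f"{path}: plan must contain 'models' and 'measures' sections")
    models = tuple(ModelSpec(**m) for m in raw["models"])
    measures = tuple(MeasureSpec(**m) for m in raw["measures"])
    return EvaluationPlan(models, measures, exploratory=bool(raw.get("exploratory", False)))


@dataclass(frozen=True)
class ReportRow:
    measure_label: str
    type_label: str
    trafo_label: str
    values: dict  # model name -> float | None (None renders as a dash)
    primary: bool


@dataclass(frozen=True)
class EvaluationReport:
    rows: tuple
    model_names: tuple
    plan_digest: str
    exploratory: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "plan_digest": self.plan_digest,
                "exploratory": self.exploratory,
                "model_names": list(self.model_names),
                "rows": [vars(r) for r in self.rows],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        raw = json.loads(text)
        rows = tuple(ReportRow(**r) for r in raw["rows"])
        return cls(
            rows=rows,
            model_names=tuple(raw["model_names"]),
            plan_digest=raw["plan_digest"],
            exploratory=raw.get("exploratory", False),
        )


def _reduce(curves, ms: MeasureSpec):
    if ms.transform == "prob@t":
        return prob_at_time(curves, ms.time)
    if ms.transform == "expmort":
        return expected_mortality(curves)
    return curve_summary(curves, SummaryStatistic(ms.transform), ImproperPolicy(ms.improper))


def _cell(outcomes: SurvivalOutcomes, model: ModelSpec, ms: MeasureSpec, predictions):
    """One report cell, or None when the (measure, model) pair is incompatible."""
    if ms.measure == "antolini":
        if model.kind != "distribution":
            return None
        return antolini_c(outcomes, predictions).value
    # time-independent measures need a single risk per subject
    if model.kind == "risk":
        if ms.transform != "none":
            return None  # a risk cannot be re-derived through a distribution reduction
        risk = predictions
    else:
        if ms.transform == "none":
            return None  # unnamed reduction refused: the transform must be declared
        risk = _reduce(predictions, ms)
    if ms.measure == "harrell":
        return harrell_c(outcomes, risk).value
    if ms.measure == "uno":
        return uno_c(outcomes, risk, tau=ms.tau).value
    return integrated_auc(outcomes, risk).value


def run_evaluation(
    plan: EvaluationPlan, outcomes: SurvivalOutcomes, base_dir=None
) -> EvaluationReport:
    """Compute every planned cell; no cell is suppressed, none silently filled."""
    digest = plan.digest()  # computed before any evaluation
    base = Path(base_dir) if base_dir is not None else Path(".")
    predictions = {}
    for model in plan.models:
        path = base / model.file
        if model.kind == "risk":
            predictions[model.name] = sio.read_risks(path, label=f"native:{model.name}")
        else:
            predictions[model.name] = sio.read_curves(path)

    rows = []
    for ms in plan.measures:
        values = {
            model.name: _cell(outcomes, model, ms, predictions[model.name])
            for model in plan.models
        }
        rows.append(
            ReportRow(
                measure_label=ms.measure_label,
                type_label=ms.type_label,
                trafo_label=ms.trafo_label,
                values=values,
                primary=ms.primary,
            )
        )
    return EvaluationReport(
        rows=tuple(rows),
        model_names=tuple(m.name for m in plan.models),
        plan_digest=digest,
        exploratory=plan.exploratory,
    )


def ranked_comparison(report: EvaluationReport, row_indices) -> list:
    """Rank models by value within commensurable rows only.

    All selected rows must share one measure and one transformation;
    anything else is the Type II C-hacking this layer exists to refuse.
    """
    rows = [report.rows[i] for i in row_indices]
    keys = {(r.measure_label, r.trafo_label) for r in rows}
    if len(keys) > 1:
        raise PlanError(
            "incommensurable comparison refused: cannot rank models across "
            f"different measures/transformations {sorted(keys)}"
        )
    cells = [
        (name, r.values[name])
        for r in rows
        for name in report.model_names
        if r.values.get(name) is not None
    ]
    return sorted(cells, key=lambda kv: -kv[1])


def _fmt(value, precision: int | None):
    if value is None:
        return DASH
    return f"{value:.{precision}f}" if precision is not None else repr(value)


def render_report(report: EvaluationReport, format: str = "text") -> str:
    """Render the labelled report as ``text``, ``csv`` or ``markdown``.

    Values are shown to 3 decimal places in text/markdown and at full
    precision in CSV; incompatible cells render as an em-dash; the primary
    measure row is marked with ``*`` and the plan digest is printed in the
    footer.
    """
    if format not in ("text", "csv", "markdown"):
        raise PlanError(f"unknown report format {format!r}")
    header = ["Measure", "Type", "Trafo"] + list(report.model_names)
    stamp = "EXPLORATORY — not pre-registered" if report.exploratory else None

    def row_cells(r: ReportRow, precision):
        mark = "*" if r.primary else ""
        cells = [r.measure_label + mark, r.type_label, r.trafo_label]
        cells += [_fmt(r.values.get(m), precision) for m in report.model_names]
        if stamp:
            cells.append(stamp)
        return cells

    if format == "csv":
        import csv

        buf = _io.StringIO()
        w = csv.writer(buf)
        w.writerow(header + (["note"] if stamp else []))
        for r in report.rows:
            w.writerow(row_cells(r, None))
        w.writerow([])
        w.writerow([f"plan sha256:{report.plan_digest}"])
        return buf.getvalue()

    table = [header] + [row_cells(r, 3) for r in report.rows]
    if stamp:
        table[0] = header + ["note"]
    widths = [max(len(str(row[i])) for row in table) for i in range(len(table[0]))]
    if format == "markdown":
        lines = ["| " + " | ".join(str(c).ljust(w) for c, w in zip(row, widths)) + " |" for row in table]
        lines.insert(1, "|" + "|".join("-" * (w + 2) for w in widths) + "|")
    else:
        lines = ["  ".join(str(c).ljust(w) for c, w in zip(row, widths)) for row in table]
    lines.append("")
    lines.append(f"plan sha256:{report.plan_digest}" + (f"  [{stamp}]" if stamp else ""))
    return "\n".join(lines)
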