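"""Panel CSV reading/writing and structured run configuration.

The interchange format is a flat CSV, one row per sample, with fixed,
order-free column names (empty cell = missing value).  A run configuration
bundles the weight budget, the curve definitions and the gate mode; the
packaged default reproduces the built-in calibration, and the curve weights
are cross-checked against the weight budget at load time.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .curves import Curve, curve_from_dict
from .engine import NVSResult, WeightConfig, check_weight_budget
from .samples import (
    ACID_FIELDS,
    FattyAcidProfile,
    OilSample,
    QualityIndices,
    SensoryAssessment,
)

logger = logging.getLogger("evoo_nvs")

__all__ = [
    "PANEL_COLUMNS",
    "PanelFormatError",
    "read_panel",
    "panel_frame",
    "write_panel",
    "write_scored",
    "RunConfig",
    "load_config",
    "default_run_config",
]

#: CSV column name -> fatty-acid field name (identical except the trans pair).
_ACID_COLUMNS = {
    ("trans_c18_23" if f == "trans_c18_2_3" else f): f for f in ACID_FIELDS
}

PANEL_COLUMNS: tuple[str, ...] = (
    "sample_id", "free_acidity", "peroxide_value", "k232", "k270", "delta_k",
    *_ACID_COLUMNS,
    "phenolics_total", "tocopherols_total", "fruity_median", "defect_median",
    "cohort_label",
)

#: Columns that must exist in every panel file: identifiers, the quality
#: indices and the acids required for scoring.
MANDATORY_COLUMNS: tuple[str, ...] = (
    "sample_id", "free_acidity", "peroxide_value", "k232", "k270",
    "oleic", "palmitic", "stearic", "linoleic", "linolenic",
)

_SCORE_COLUMNS: tuple[str, ...] = (
    "conforming", "violations", "x_oa", "x_sfa", "x_rat", "x_pc1",
    "y_pc2", "z_pc3", "x_nc1", "y_nc2", "z_k232", "z_k270", "z_nc3", "nvs",
)


class PanelFormatError(ValueError):
    """The panel file violates the CSV schema or row-level validation."""


def _opt(row: pd.Series, column: str) -> Optional[float]:
    if column not in row.index:
        return None
    value = row[column]
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    return float(value)


def _row_to_sample(row: pd.Series) -> OilSample:
    acids = {}
    for column, field in _ACID_COLUMNS.items():
        value = _opt(row, column)
        if value is not None:
            acids[field] = value
    fruity, defect = _opt(row, "fruity_median"), _opt(row, "defect_median")
    sensory = None
    if fruity is not None or defect is not None:
        sensory = SensoryAssessment(fruity_median=fruity, defect_median=defect)
    label = row.get("cohort_label")
    if label is not None and (not isinstance(label, str)) and pd.isna(label):
        label = None
    return OilSample(
        sample_id=str(row["sample_id"]),
        fatty_acids=FattyAcidProfile(**acids),
        quality=QualityIndices(
            free_acidity=_opt(row, "free_acidity"),
            peroxide_value=_opt(row, "peroxide_value"),
            k232=_opt(row, "k232"),
            k270=_opt(row, "k270"),
            delta_k=_opt(row, "delta_k"),
        ),
        phenolics_total=_opt(row, "phenolics_total"),
        tocopherols_total=_opt(row, "tocopherols_total"),
        sensory=sensory,
        cohort_label=None if label is None else str(label),
    )


def read_panel(path: str | Path) -> list[OilSample]:
    """Read a panel CSV into typed samples.

    Unknown columns are warned about and ignored; missing mandatory columns,
    duplicate sample ids, or any invalid row (reported with its line number
    and field) raise :class:`PanelFormatError`.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise PanelFormatError(f"{path}: missing mandatory columns {missing}")
    unknown = [c for c in frame.columns if c not in PANEL_COLUMNS]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)
        frame = frame.drop(columns=unknown)
    ids = frame["sample_id"].astype(str)
    dupes = sorted(ids[ids.duplicated()].unique())
    if dupes:
        raise PanelFormatError(f"{path}: duplicate sample_id values {dupes}")
    samples: list[OilSample] = []
    errors: list[str] = []
    for pos, (_, row) in enumerate(frame.iterrows()):
        line = pos + 2  # header is line 1
        try:
            samples.append(_row_to_sample(row))
        except (ValidationError, ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise PanelFormatError(
            f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors)
        )
    return samples


def panel_frame(panel: Sequence[OilSample]) -> pd.DataFrame:
    """Panel as a DataFrame with the standard column set."""
    rows = []
    for s in panel:
        row = {c: None for c in PANEL_COLUMNS}
        row["sample_id"] = s.sample_id
        row["free_acidity"] = s.quality.free_acidity
        row["peroxide_value"] = s.quality.peroxide_value
        row["k232"] = s.quality.k232
        row["k270"] = s.quality.k270
        row["delta_k"] = s.quality.delta_k
        for column, field in _ACID_COLUMNS.items():
            row[column] = getattr(s.fatty_acids, field)
        row["phenolics_total"] = s.phenolics_total
        row["tocopherols_total"] = s.tocopherols_total
        if s.sensory is not None:
            row["fruity_median"] = s.sensory.fruity_median
            row["defect_median"] = s.sensory.defect_median
        row["cohort_label"] = s.cohort_label
        rows.append(row)
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


# Round-trip exact float formatting for CSV output.
_FLOAT_FORMAT = "%.17g"


def write_panel(path: str | Path, panel: Sequence[OilSample]) -> None:
    panel_frame(panel).to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def _violation_text(result: NVSResult) -> str:
    parts = []
    for v in result.gate.violations:
        if v.value is None:
            parts.append(f"{v.parameter}=missing")
        else:
            parts.append(f"{v.parameter}={v.value:g} not in [{v.limit_low:g}, {v.limit_high:g}]"
                         if v.limit_high is not None
                         else f"{v.parameter}={v.value:g} not > {v.limit_low:g}")
    return "; ".join(parts)


def write_scored(
    path: str | Path, panel: Sequence[OilSample], results: Sequence[NVSResult]
) -> None:
    """Write the panel plus gate verdicts and score columns.

    Inputs round-trip losslessly (full float precision), so re-reading and
    re-scoring the file reproduces the same scores.
    """
    if len(panel) != len(results):
        raise ValueError("panel and results length mismatch")
    frame = panel_frame(panel)
    extra: dict[str, list] = {c: [] for c in _SCORE_COLUMNS}
    for r in results:
        extra["conforming"].append(r.gate.conforming)
        extra["violations"].append(_violation_text(r))
        sc = r.scores
        for key in ("x_oa", "x_sfa", "x_rat", "x_pc1", "y_pc2", "z_pc3",
                    "x_nc1", "y_nc2", "z_k232", "z_k270", "z_nc3"):
            extra[key].append(getattr(sc, key) if sc is not None else None)
        extra["nvs"].append(r.nvs)
    for column, values in extra.items():
        frame[column] = values
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Run configuration


class GateOptions(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    mode: Literal["lenient", "strict"] = "lenient"
    limits_version: str = "eu-2022"


class RunConfig(BaseModel):
    """Weight budget + curve definitions + gate options + seed."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    weights: dict[str, float]
    curves: dict[str, dict]
    gate: GateOptions = GateOptions()
    seed: int = Field(default=0, ge=0)

    def weight_config(self) -> WeightConfig:
        w = self.weights
        return WeightConfig(
            w_oa=w["oleic"], w_sfa=w["sfa"], w_rat=w["ratio"],
            w_phe=w["phenolics"], w_toc=w["tocopherols"],
            w_facid=w["free_acidity"], w_pv=w["peroxide_value"],
            w_k232=w["k232"], w_k270=w["k270"], k_constant=w["k_constant"],
        )

    def curve_set(self) -> dict[str, Curve]:
        return {name: curve_from_dict(name, spec) for name, spec in self.curves.items()}

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _validate(config: RunConfig) -> RunConfig:
    curves = config.curve_set()
    weights = config.weights
    mismatches = [
        name for name, curve in curves.items()
        if name in weights and abs(curve.weight - weights[name]) > 1e-9
    ]
    if mismatches:
        raise ValueError(
            f"curve weights disagree with the weight budget for: {mismatches}"
        )
    budget = check_weight_budget(config.weight_config())
    if not budget.ok:
        raise ValueError(
            "weight budget invalid: " + "; ".join(budget.failures)
        )
    return config


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _validate(RunConfig(**raw))


def default_run_config() -> RunConfig:
    """The packaged default configuration."""
    text = resources.files("evoo_nvs").joinpath("data/default_config.yaml").read_text()
    return _validate(RunConfig(**yaml.safe_load(text)))
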