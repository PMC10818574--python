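"""Oil-sample data model and the EVOO legal-conformity gate.

Scoring an oil's nutritional value only makes sense for oils that belong to
the extra virgin commercial category in the first place, so every scoring
path starts with :func:`check_evoo_conformity`: a sample violating even one
legal chemical or sensory limit is excluded from the score.
"""

from __future__ import annotations

import math
import warnings
from typing import NamedTuple, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .limits import LegalLimitTable, default_limits

#: All fatty acids of the legal-limit list, in panel-column order.
ACID_FIELDS: tuple[str, ...] = (
    "myristic",
    "palmitic",
    "palmitoleic",
    "margaric",
    "margaroleic",
    "stearic",
    "oleic",
    "linoleic",
    "linolenic",
    "arachidic",
    "eicosenoic",
    "behenic",
    "lignoceric",
    "trans_c18_1",
    "trans_c18_2_3",
)

#: Acids that must be present for scoring (majors plus the stability-ratio inputs).
REQUIRED_ACIDS: tuple[str, ...] = ("oleic", "palmitic", "stearic", "linoleic", "linolenic")

#: Acceptable window for the sum of a complete fatty-acid profile (% of total).
CLOSURE_WINDOW: tuple[float, float] = (97.0, 101.0)


class ClosureWarning(UserWarning):
    """A complete fatty-acid profile does not sum to ~100 %."""


class FattyAcidProfile(BaseModel):
    """GC-derived fatty-acid composition, each value a % of total fatty acids.

    The five acids used by the score (oleic, palmitic, stearic, linoleic,
    linolenic) are mandatory; trace acids may be omitted, which is common in
    routine panels.  A complete profile whose sum falls outside
    :data:`CLOSURE_WINDOW` triggers a :class:`ClosureWarning` but is not a
    gate violation.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    oleic: float = Field(ge=0.0)
    palmitic: float = Field(ge=0.0)
    stearic: float = Field(ge=0.0)
    linoleic: float = Field(ge=0.0)
    linolenic: float = Field(ge=0.0)
    myristic: Optional[float] = Field(default=None, ge=0.0)
    palmitoleic: Optional[float] = Field(default=None, ge=0.0)
    margaric: Optional[float] = Field(default=None, ge=0.0)
    margaroleic: Optional[float] = Field(default=None, ge=0.0)
    arachidic: Optional[float] = Field(default=None, ge=0.0)
    eicosenoic: Optional[float] = Field(default=None, ge=0.0)
    behenic: Optional[float] = Field(default=None, ge=0.0)
    lignoceric: Optional[float] = Field(default=None, ge=0.0)
    trans_c18_1: Optional[float] = Field(default=None, ge=0.0)
    trans_c18_2_3: Optional[float] = Field(default=None, ge=0.0)

    @model_validator(mode="after")
    def _closure_check(self) -> "FattyAcidProfile":
        values = [getattr(self, acid) for acid in ACID_FIELDS]
        if all(v is not None for v in values):
            total = sum(values)
            if not CLOSURE_WINDOW[0] <= total <= CLOSURE_WINDOW[1]:
                warnings.warn(
                    f"complete fatty-acid profile sums to {total:.2f} %, outside "
                    f"the closure window {CLOSURE_WINDOW}",
                    ClosureWarning,
                    stacklevel=2,
                )
        return self

    def present(self) -> dict[str, float]:
        """Mapping of every acid that has a reported value."""
        out = {}
        for acid in ACID_FIELDS:
            v = getattr(self, acid)
            if v is not None:
                out[acid] = v
        return out


class QualityIndices(BaseModel):
    """Legal quality indices: hydrolytic and oxidative state of the oil."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    free_acidity: float = Field(ge=0.0, lt=100.0, description="% oleic acid")
    peroxide_value: float = Field(ge=0.0, description="meq O2 / kg oil")
    k232: float = Field(ge=0.0)
    k270: float = Field(ge=0.0)
    # delta_k may legitimately be negative; the gate checks |delta_k|.
    delta_k: Optional[float] = None


class SensoryAssessment(BaseModel):
    """Panel-test medians on the 0-10 scale used by official tasting panels."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    fruity_median: Optional[float] = Field(default=None, ge=0.0, le=10.0)
    defect_median: Optional[float] = Field(default=None, ge=0.0, le=10.0)


class OilSample(BaseModel):
    """One oil's full measurement record.

    ``phenolics_total`` and ``tocopherols_total`` (mg/kg) are required for the
    full nutritional score but optional for gate-only use, since neither has
    a legal limit.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    sample_id: str = Field(min_length=1)
    fatty_acids: FattyAcidProfile
    quality: QualityIndices
    phenolics_total: Optional[float] = Field(default=None, ge=0.0)
    tocopherols_total: Optional[float] = Field(default=None, ge=0.0)
    sensory: Optional[SensoryAssessment] = None
    cohort_label: Optional[str] = None


class LimitViolation(BaseModel):
    """A single violated legal limit.  ``value`` is None for missing data."""

    model_config = ConfigDict(frozen=True)

    parameter: str
    value: Optional[float]
    limit_low: Optional[float] = None
    limit_high: Optional[float] = None


class GateVerdict(BaseModel):
    """Outcome of the EVOO conformity gate.

    Every parameter the gate knows about lands in exactly one of ``checked``
    (it was evaluated) or ``skipped`` (absent from the input and non-blocking
    in the active mode).
    """

    model_config = ConfigDict(frozen=True)

    conforming: bool
    violations: list[LimitViolation]
    checked: list[str]
    skipped: list[str]

    @model_validator(mode="after")
    def _consistent(self) -> "GateVerdict":
        if self.conforming != (len(self.violations) == 0):
            raise ValueError("conforming must be true iff violations is empty")
        overlap = set(self.checked) & set(self.skipped)
        if overlap:
            raise ValueError(f"parameters in both checked and skipped: {sorted(overlap)}")
        return self


class DerivedQuantities(NamedTuple):
    sfa: float
    ratio: float


def derived_quantities(profile: FattyAcidProfile) -> DerivedQuantities:
    """Saturated-fat total and the oxidative-stability ratio.

    ``sfa`` is palmitic + stearic.  ``ratio`` is OA / (LA + 2*LnA): oleic over
    the polyunsaturated load, with linolenic counted twice because it
    oxidises roughly twice as fast as linoleic.  Higher ratio, more stable oil.
    """
    denominator = profile.linoleic + 2.0 * profile.linolenic
    if denominator <= 0.0:
        raise ValueError(
            "degenerate PUFA content: linoleic + 2*linolenic must be positive"
        )
    return DerivedQuantities(
        sfa=profile.palmitic + profile.stearic,
        ratio=profile.oleic / denominator,
    )


def _check_interval(
    name: str,
    value: float,
    interval: tuple[float, float],
    violations: list[LimitViolation],
    checked: list[str],
) -> None:
    lo, hi = interval
    checked.append(name)
    if value < lo or value > hi:
        violations.append(
            LimitViolation(parameter=name, value=value, limit_low=lo, limit_high=hi)
        )


def check_evoo_conformity(
    sample: OilSample,
    strict: bool = False,
    limits: LegalLimitTable | None = None,
) -> GateVerdict:
    """Compare a sample against every printed EVOO legal limit.

    In the default lenient mode, optional parameters absent from the input
    (delta K, trace acids, sensory medians) are recorded under ``skipped``.
    In strict mode a missing delta K or missing sensory median becomes a
    missing-data violation, so only fully documented samples pass.
    """
    limits = limits or default_limits()
    violations: list[LimitViolation] = []
    checked: list[str] = []
    skipped: list[str] = []

    q = sample.quality
    for name, value in (
        ("free_acidity", q.free_acidity),
        ("peroxide_value", q.peroxide_value),
        ("k232", q.k232),
        ("k270", q.k270),
    ):
        _check_interval(name, value, limits.interval(name), violations, checked)

    if q.delta_k is not None:
        _check_interval("delta_k", q.delta_k, limits.interval("delta_k"), violations, checked)
    elif strict:
        checked.append("delta_k")
        violations.append(LimitViolation(parameter="delta_k", value=None))
    else:
        skipped.append("delta_k")

    present = sample.fatty_acids.present()
    for acid in ACID_FIELDS:
        if acid in present:
            if acid in limits:
                _check_interval(acid, present[acid], limits.interval(acid), violations, checked)
        else:
            skipped.append(acid)

    fruity = sample.sensory.fruity_median if sample.sensory else None
    defect = sample.sensory.defect_median if sample.sensory else None
    if fruity is not None:
        checked.append("fruity_median")
        if not fruity > limits.fruity_median_min_exclusive:
            violations.append(
                LimitViolation(
                    parameter="fruity_median", value=fruity,
                    limit_low=limits.fruity_median_min_exclusive,
                )
            )
    elif strict:
        checked.append("fruity_median")
        violations.append(LimitViolation(parameter="fruity_median", value=None))
    else:
        skipped.append("fruity_median")

    if defect is not None:
        checked.append("defect_median")
        if not math.isclose(defect, limits.defect_median_exact, abs_tol=1e-12):
            violations.append(
                LimitViolation(
                    parameter="defect_median", value=defect,
                    limit_low=limits.defect_median_exact,
                    limit_high=limits.defect_median_exact,
                )
            )
    elif strict:
        checked.append("defect_median")
        violations.append(LimitViolation(parameter="defect_median", value=None))
    else:
        skipped.append("defect_median")

    return GateVerdict(
        conforming=not violations,
        violations=violations,
        checked=checked,
        skipped=skipped,
    )
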