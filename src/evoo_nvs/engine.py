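"""The Nutritional Value Score engine.

The score of a conforming sample is

    NVS = K + (X_PC1 + Y_PC2 + Z_PC3) - (X_NC1 + Y_NC2 + Z_NC3)

where the three positive terms come from fatty-acid composition (itself
``X_OA - X_SFA - X_Rat``), phenolic compounds and tocopherols, the three
negative terms from free acidity, peroxide value and the UV indices
(``Z_NC3 = Z_K232 + Z_K270``), and K is a constant.  The weight budget pins
the attainable range exactly to [0, 100]: with component maxima split into
positives ``P_max``, deductions ``P_min`` (negative) and penalties
``N_max``, the identities ``P_max - P_min + N_max = 100`` and
``K = N_max - P_min`` make the component-wise worst combination score
exactly 0 and the best exactly 100.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .curves import Curve, default_curve_set, eval_curve
from .limits import LegalLimitTable
from .samples import GateVerdict, OilSample, check_evoo_conformity, derived_quantities

__all__ = [
    "WeightConfig",
    "BudgetCheck",
    "ComponentScores",
    "NVSResult",
    "PanelSummary",
    "default_config",
    "default_curves",
    "check_weight_budget",
    "compute_component_scores",
    "compute_nvs",
    "score_panel",
    "IncompleteSampleError",
]

_TOL = 1e-9


class IncompleteSampleError(ValueError):
    """The sample lacks data required for the full score."""


class WeightConfig(BaseModel):
    """Component score maxima and the constant K.

    Ordering constraints encode the intended hierarchy: oleic acid carries
    the largest single positive weight, fatty-acid composition and phenolics
    each outweigh tocopherols, and the three negative components carry equal
    maximum penalties (the UV-index penalty being split between K232 and
    K270).
    """

    model_config = ConfigDict(frozen=True)

    w_oa: float = Field(ge=0.0)
    w_sfa: float = Field(ge=0.0)
    w_rat: float = Field(ge=0.0)
    w_phe: float = Field(ge=0.0)
    w_toc: float = Field(ge=0.0)
    w_facid: float = Field(ge=0.0)
    w_pv: float = Field(ge=0.0)
    w_k232: float = Field(ge=0.0)
    w_k270: float = Field(ge=0.0)
    k_constant: float

    @property
    def p_max(self) -> float:
        """Best attainable positive contribution."""
        return self.w_oa + self.w_phe + self.w_toc

    @property
    def p_min(self) -> float:
        """Worst attainable positive contribution (deductions saturated)."""
        return -(self.w_sfa + self.w_rat)

    @property
    def n_max(self) -> float:
        """Largest attainable total penalty."""
        return self.w_facid + self.w_pv + self.w_k232 + self.w_k270

    def component_weights(self) -> dict[str, float]:
        """Weights keyed by component curve name."""
        return {
            "oleic": self.w_oa,
            "sfa": self.w_sfa,
            "ratio": self.w_rat,
            "phenolics": self.w_phe,
            "tocopherols": self.w_toc,
            "free_acidity": self.w_facid,
            "peroxide_value": self.w_pv,
            "k232": self.w_k232,
            "k270": self.w_k270,
        }


def default_config() -> WeightConfig:
    """The packaged default weight budget (one admissible solution of the
    ordering constraints plus the 0-100 pinning identities)."""
    return WeightConfig(
        w_oa=34.0, w_sfa=5.0, w_rat=5.0, w_phe=26.0, w_toc=12.0,
        w_facid=6.0, w_pv=6.0, w_k232=3.0, w_k270=3.0, k_constant=28.0,
    )


def default_curves(config: WeightConfig | None = None) -> dict[str, Curve]:
    """Default curve set calibrated with the given (or default) weights."""
    config = config or default_config()
    return default_curve_set(config.component_weights())


class BudgetCheck(BaseModel):
    model_config = ConfigDict(frozen=True)

    ok: bool
    failures: tuple[str, ...]


def check_weight_budget(config: WeightConfig, tol: float = _TOL) -> BudgetCheck:
    """Verify every weight-budget invariant; reports failures, never raises."""
    failures: list[str] = []
    for name, value in config.component_weights().items():
        if value < 0.0:
            failures.append(f"negative weight: {name}")
    budget = config.p_max - config.p_min + config.n_max
    if abs(budget - 100.0) > tol:
        failures.append(f"budget identity P_max - P_min + N_max = {budget:.6g} != 100")
    if abs(config.k_constant - (config.n_max - config.p_min)) > tol:
        failures.append("k_constant != N_max - P_min")
    if config.w_oa < config.w_phe - tol or config.w_oa < config.w_toc - tol:
        failures.append("oleic weight must be the largest positive weight")
    if config.w_oa + config.w_sfa + config.w_rat < config.w_toc - tol:
        failures.append("fatty-acid composition weight must not be below tocopherols")
    if config.w_phe < config.w_toc - tol:
        failures.append("phenolics weight must not be below tocopherols")
    if abs(config.w_facid - config.w_pv) > tol or abs(
        config.w_facid - (config.w_k232 + config.w_k270)
    ) > tol:
        failures.append(
            "negative components must carry equal maxima "
            "(w_facid = w_pv = w_k232 + w_k270)"
        )
    return BudgetCheck(ok=not failures, failures=tuple(failures))


class ComponentScores(BaseModel):
    """The dimensionless elementary and composite scores of one sample."""

    model_config = ConfigDict(frozen=True)

    x_oa: float
    x_sfa: float
    x_rat: float
    x_pc1: float
    y_pc2: float
    z_pc3: float
    x_nc1: float
    y_nc2: float
    z_k232: float
    z_k270: float
    z_nc3: float


class NVSResult(BaseModel):
    """Gate verdict plus, for conforming samples, the component scores and NVS."""

    model_config = ConfigDict(frozen=True)

    sample_id: str
    gate: GateVerdict
    scores: Optional[ComponentScores] = None
    nvs: Optional[float] = None
    clamped: bool = False


class PanelSummary(BaseModel):
    model_config = ConfigDict(frozen=True)

    n: int
    n_gated_out: int
    mean: Optional[float]
    sd: Optional[float]
    histogram: tuple[int, ...]  # deciles [0,10), ..., [90,100]


def compute_component_scores(
    sample: OilSample,
    curves: dict[str, Curve] | None = None,
    config: WeightConfig | None = None,
) -> ComponentScores:
    """Elementary scores via the curves, composites via the printed identities.

    Assumes the sample already passed the gate; phenolics and tocopherols
    totals are mandatory here.
    """
    config = config or default_config()
    curves = curves if curves is not None else default_curves(config)
    if sample.phenolics_total is None or sample.tocopherols_total is None:
        raise IncompleteSampleError(
            f"incomplete sample for NVS: {sample.sample_id} lacks "
            "phenolics_total and/or tocopherols_total"
        )
    dq = derived_quantities(sample.fatty_acids)
    q = sample.quality
    x_oa = eval_curve(curves["oleic"], sample.fatty_acids.oleic)
    x_sfa = eval_curve(curves["sfa"], dq.sfa)
    x_rat = eval_curve(curves["ratio"], dq.ratio)
    y_pc2 = eval_curve(curves["phenolics"], sample.phenolics_total)
    z_pc3 = eval_curve(curves["tocopherols"], sample.tocopherols_total)
    x_nc1 = eval_curve(curves["free_acidity"], q.free_acidity)
    y_nc2 = eval_curve(curves["peroxide_value"], q.peroxide_value)
    z_k232 = eval_curve(curves["k232"], q.k232)
    z_k270 = eval_curve(curves["k270"], q.k270)
    return ComponentScores(
        x_oa=x_oa, x_sfa=x_sfa, x_rat=x_rat, x_pc1=x_oa - x_sfa - x_rat,
        y_pc2=y_pc2, z_pc3=z_pc3, x_nc1=x_nc1, y_nc2=y_nc2,
        z_k232=z_k232, z_k270=z_k270, z_nc3=z_k232 + z_k270,
    )


def compute_nvs(
    sample: OilSample,
    curves: dict[str, Curve] | None = None,
    config: WeightConfig | None = None,
    strict_gate: bool = False,
    limits: LegalLimitTable | None = None,
) -> NVSResult:
    """Gate the sample and, if it conforms, score it on the 0-100 scale.

    Non-conforming samples yield a structured result carrying the verdict
    and no score, so batch runs always complete.  Clamping to [0, 100] is a
    numerical safety net only; with a budget-valid configuration it never
    triggers.
    """
    config = config or default_config()
    curves = curves if curves is not None else default_curves(config)
    gate = check_evoo_conformity(sample, strict=strict_gate, limits=limits)
    if not gate.conforming:
        return NVSResult(sample_id=sample.sample_id, gate=gate)
    scores = compute_component_scores(sample, curves, config)
    raw = (
        config.k_constant
        + (scores.x_pc1 + scores.y_pc2 + scores.z_pc3)
        - (scores.x_nc1 + scores.y_nc2 + scores.z_nc3)
    )
    clamped = raw < 0.0 or raw > 100.0
    nvs = min(max(raw, 0.0), 100.0)
    return NVSResult(
        sample_id=sample.sample_id, gate=gate, scores=scores, nvs=nvs, clamped=clamped,
    )


def score_panel(
    panel: Sequence[OilSample],
    curves: dict[str, Curve] | None = None,
    config: WeightConfig | None = None,
    strict_gate: bool = False,
    limits: LegalLimitTable | None = None,
) -> tuple[list[NVSResult], PanelSummary]:
    """Score every sample of a panel, preserving order, and summarise.

    The summary histogram uses the deciles [0,10), ..., [90,100].
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    config = config or default_config()
    curves = curves if curves is not None else default_curves(config)
    results = [
        compute_nvs(s, curves, config, strict_gate=strict_gate, limits=limits)
        for s in panel
    ]
    scored = np.array([r.nvs for r in results if r.nvs is not None], dtype=float)
    hist, _ = np.histogram(scored, bins=np.arange(0.0, 101.0, 10.0))
    summary = PanelSummary(
        n=len(results),
        n_gated_out=len(results) - scored.size,
        mean=float(scored.mean()) if scored.size else None,
        sd=float(scored.std(ddof=1)) if scored.size > 1 else None,
        histogram=tuple(int(c) for c in hist),
    )
    return results, summary
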