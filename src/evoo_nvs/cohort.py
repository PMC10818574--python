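"""Synthetic EVOO cohort generation from the packaged reference histograms.

The study cohorts behind the score calibration are not published as raw
data, only as binned marginal distributions.  This module turns those
histograms into reproducible synthetic panels: each parameter is drawn from
its cohort histogram (categorical bin draw, uniform within the bin,
exponential tail for open-ended top bins), and the fatty-acid block is
completed under compositional closure so that every generated sample passes
the EVOO gate by construction.

Because only marginals are printed, parameters are independent by default;
an optional Gaussian copula couples oleic and linoleic with a negative rank
correlation, mimicking the opposing country-of-origin patterns of the
reference tables.  The stability ratio OA/(LA + 2*LnA) is always computed
from the drawn acids, never sampled.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy.special import ndtr

from .curves import Curve
from .engine import NVSResult, PanelSummary, WeightConfig, score_panel
from .limits import default_limits
from .reference import builtin_table
from .samples import FattyAcidProfile, OilSample, QualityIndices

__all__ = [
    "ProfileError",
    "CohortProfile",
    "COHORT_NAMES",
    "ORIGIN_COHORTS",
    "default_profile",
    "conditioned_histogram",
    "sample_cohort",
    "simulate_and_score",
]

ORIGIN_COHORTS: tuple[str, ...] = (
    "Australia", "Greece", "Italy", "Portugal", "Spain", "Tunisia",
)
COHORT_NAMES: tuple[str, ...] = ("2013", "2014", "commercial") + ORIGIN_COHORTS

#: Study sample counts per production year, used to pool the two year
#: histograms where a cohort has no data of its own.
_PHENOLIC_COUNTS = {"2013": 564, "2014": 605}
_TOCOPHEROL_COUNTS = {"2013": 464, "2014": 397}

_QUALITY_PARAMS = ("free_acidity", "peroxide_value", "k232", "k270")
_INDEPENDENT_PARAMS = _QUALITY_PARAMS + ("phenolics", "tocopherols")


class ProfileError(ValueError):
    """The cohort profile is unknown or cannot generate conforming samples."""


HistBins = tuple[tuple[float, float, float], ...]  # (lo, hi, percent)


class CohortProfile(BaseModel):
    """Histogram specification driving the generator for one cohort."""

    model_config = ConfigDict(frozen=True)

    name: str
    histograms: dict[str, HistBins]
    substituted: dict[str, str] = Field(default_factory=dict)
    linolenic_range: tuple[float, float] = (0.3, 0.9)
    sfa_split: tuple[float, float] = (0.85, 0.15)  # palmitic : stearic
    oa_la_rank_corr: Optional[float] = None


def _column(name: str, cohort: str) -> HistBins:
    table = builtin_table(name)
    return tuple((b.lo, b.hi, b.percents[cohort]) for b in table.bins)


def _pooled(name: str, counts: dict[str, int]) -> HistBins:
    table = builtin_table(name)
    total = sum(counts.values())
    return tuple(
        (b.lo, b.hi, sum(counts[c] * b.percents[c] for c in counts) / total)
        for b in table.bins
    )


def default_profile(name: str, dependence: bool = False) -> CohortProfile:
    """Assemble the packaged profile for one cohort.

    The commercial cohort has no phenolic/tocopherol reference data of its
    own and borrows the pooled year histograms; the country-of-origin
    cohorts additionally borrow the commercial quality-index histograms.
    Every substitution is flagged in ``substituted``.

    ``dependence=True`` enables the optional oleic-linoleic Gaussian copula
    (rank correlation -0.6).
    """
    if name not in COHORT_NAMES:
        raise ProfileError(
            f"unknown cohort {name!r}; available cohorts: {list(COHORT_NAMES)}"
        )
    histograms: dict[str, HistBins] = {}
    substituted: dict[str, str] = {}
    quality_source = name if name in ("2013", "2014", "commercial") else "commercial"
    for param in _QUALITY_PARAMS:
        histograms[param] = _column(param, quality_source)
        if quality_source != name:
            substituted[param] = f"borrowed from cohort {quality_source!r}"
    for param in ("oleic", "linoleic", "sfa"):
        histograms[param] = _column(param, name)
    if name in ("2013", "2014"):
        histograms["phenolics"] = _column("phenolics", name)
        histograms["tocopherols"] = _column("tocopherols", name)
    else:
        histograms["phenolics"] = _pooled("phenolics", _PHENOLIC_COUNTS)
        histograms["tocopherols"] = _pooled("tocopherols", _TOCOPHEROL_COUNTS)
        substituted["phenolics"] = "pooled 2013+2014 (no cohort data)"
        substituted["tocopherols"] = "pooled 2013+2014 (no cohort data)"
    return CohortProfile(
        name=name,
        histograms=histograms,
        substituted=substituted,
        oa_la_rank_corr=-0.6 if dependence else None,
    )


def _feasible_interval(profile: CohortProfile, param: str) -> tuple[float, float]:
    """Support on which generated values keep the sample gate-conforming."""
    limits = default_limits()
    if param in ("free_acidity", "peroxide_value", "k232", "k270",
                 "oleic", "linoleic"):
        return limits.interval(param)
    if param == "sfa":
        rp, rs = profile.sfa_split
        p_lo, p_hi = limits.interval("palmitic")
        s_lo, s_hi = limits.interval("stearic")
        return (max(p_lo / rp, s_lo / rs), min(p_hi / rp, s_hi / rs))
    return (0.0, math.inf)


def conditioned_histogram(profile: CohortProfile, param: str) -> HistBins:
    """The generator's target law for one parameter: the profile histogram
    conditioned on gate conformity.

    Bins wholly outside the feasible support are dropped (their mass is
    renormalised away); bins partially outside keep their mass on the
    truncated support, so printed bin probabilities are preserved wherever
    the bin overlaps the legal box.
    """
    lo_lim, hi_lim = _feasible_interval(profile, param)
    kept = []
    for lo, hi, pct in profile.histograms[param]:
        new_lo, new_hi = max(lo, lo_lim), min(hi, hi_lim)
        if new_lo >= new_hi or pct <= 0.0:
            continue
        kept.append((new_lo, new_hi, pct))
    if not kept:
        raise ProfileError(
            f"{profile.name}/{param}: no histogram mass inside the legal box"
        )
    total = sum(p for _, _, p in kept)
    return tuple((lo, hi, 100.0 * p / total) for lo, hi, p in kept)


def _tail_scale(bins: HistBins) -> float:
    """Exponential-tail scale for an open top bin: half the width of the
    last closed bin."""
    closed = [(lo, hi) for lo, hi, _ in bins if math.isfinite(hi)]
    if not closed:
        raise ProfileError("histogram has no closed bin to set a tail scale")
    lo, hi = closed[-1]
    return (hi - lo) / 2.0


def _hist_ppf(bins: HistBins, u: np.ndarray) -> np.ndarray:
    """Inverse CDF of the piecewise-uniform histogram law (exponential tail
    on an open top bin)."""
    lo = np.array([b[0] for b in bins])
    hi = np.array([b[1] for b in bins])
    mass = np.array([b[2] for b in bins], dtype=float)
    mass = mass / mass.sum()
    cum = np.concatenate([[0.0], np.cumsum(mass)])
    cum[-1] = 1.0
    idx = np.clip(np.searchsorted(cum, u, side="right") - 1, 0, len(bins) - 1)
    frac = np.clip((u - cum[idx]) / mass[idx], 0.0, 1.0 - 1e-12)
    values = lo[idx] + frac * (hi[idx] - lo[idx])
    open_bin = ~np.isfinite(hi[idx])
    if open_bin.any():
        scale = _tail_scale(bins)
        values[open_bin] = lo[idx][open_bin] - scale * np.log1p(-frac[open_bin])
    return values


def _draw_oa_la_uniforms(
    rng: np.random.Generator, m: int, rank_corr: Optional[float]
) -> tuple[np.ndarray, np.ndarray]:
    if rank_corr is None:
        return rng.random(m), rng.random(m)
    # Spearman -> Pearson correlation for the Gaussian copula.
    rho = 2.0 * math.sin(math.pi * rank_corr / 6.0)
    z = rng.standard_normal((m, 2))
    z2 = rho * z[:, 0] + math.sqrt(1.0 - rho * rho) * z[:, 1]
    return ndtr(z[:, 0]), ndtr(z2)


def sample_cohort(profile: CohortProfile, n: int, seed: int) -> list[OilSample]:
    """Draw ``n`` gate-conforming synthetic samples; reproducible given
    ``(profile, n, seed)``.

    Quality indices, phenolics and tocopherols are drawn independently from
    their conditioned histograms.  The fatty-acid block draws oleic,
    linoleic, SFA (split palmitic:stearic) and linolenic, then requires the
    compositional remainder to be assignable to palmitoleic plus a small
    unnamed trace-acid slack; infeasible draws are rejected and redrawn, so
    the accepted block always closes to ~100 % and respects every legal
    limit.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    if n == 0:
        return []

    independent = {
        param: _hist_ppf(conditioned_histogram(profile, param), rng.random(n))
        for param in _INDEPENDENT_PARAMS
    }

    oleic_hist = conditioned_histogram(profile, "oleic")
    linoleic_hist = conditioned_histogram(profile, "linoleic")
    sfa_hist = conditioned_histogram(profile, "sfa")
    ln_lo, ln_hi = profile.linolenic_range
    rp, rs = profile.sfa_split

    accepted: list[np.ndarray] = []
    n_accepted = 0
    attempts = 0
    while n_accepted < n:
        m = max(256, 2 * (n - n_accepted))
        u_oa, u_la = _draw_oa_la_uniforms(rng, m, profile.oa_la_rank_corr)
        oleic = _hist_ppf(oleic_hist, u_oa)
        linoleic = _hist_ppf(linoleic_hist, u_la)
        sfa = _hist_ppf(sfa_hist, rng.random(m))
        linolenic = rng.uniform(ln_lo, ln_hi, m)
        remainder = 100.0 - (oleic + linoleic + sfa + linolenic)
        ok = (remainder >= 0.3) & (remainder <= 4.5)
        attempts += m
        block = np.column_stack([oleic, linoleic, sfa, linolenic, remainder])[ok]
        accepted.append(block)
        n_accepted += block.shape[0]
        if attempts >= 10_000 and n_accepted < 0.01 * attempts:
            raise ProfileError(
                f"{profile.name}: compositional closure rejects more than 99% "
                "of draws; the profile is incompatible with the legal box"
            )
    block = np.concatenate(accepted)[:n]
    oleic, linoleic, sfa, linolenic, remainder = block.T
    palmitoleic = np.clip(0.7 * remainder, 0.3, 3.5)
    # The rest of the remainder stays as unnamed trace acids (not reported).

    samples = []
    for i in range(n):
        samples.append(
            OilSample(
                sample_id=f"{profile.name}-{i:05d}",
                fatty_acids=FattyAcidProfile(
                    oleic=float(oleic[i]),
                    linoleic=float(linoleic[i]),
                    linolenic=float(linolenic[i]),
                    palmitic=float(rp * sfa[i]),
                    stearic=float(rs * sfa[i]),
                    palmitoleic=float(palmitoleic[i]),
                ),
                quality=QualityIndices(
                    free_acidity=float(independent["free_acidity"][i]),
                    peroxide_value=float(independent["peroxide_value"][i]),
                    k232=float(independent["k232"][i]),
                    k270=float(independent["k270"][i]),
                ),
                phenolics_total=float(independent["phenolics"][i]),
                tocopherols_total=float(independent["tocopherols"][i]),
                cohort_label=profile.name,
            )
        )
    return samples


def simulate_and_score(
    profile: CohortProfile,
    n: int,
    seed: int,
    curves: dict[str, Curve] | None = None,
    config: WeightConfig | None = None,
) -> tuple[list[OilSample], list[NVSResult], PanelSummary]:
    """Generate a cohort panel and score it in one step."""
    panel = sample_cohort(profile, n, seed)
    results, summary = score_panel(panel, curves, config)
    return panel, results, summary
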