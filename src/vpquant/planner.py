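"""Dose/delay planning and validation metrics for VP SPECT.

Given a completed ventilation study (its dual-window count ratio and
count rate), the planner answers the clinical question: can the MAA
perfusion agent be injected now at the target dose and still achieve an
adequate perfusion/ventilation (P/V) count-rate ratio — and if not, how
long should the perfusion scan be deferred so residual ventilation
activity decays away?

The built-in policy is dose-sparing: the dose is held at the target
(default 120 MBq, the same-day pregnant-patient recommendation, well
under the 185 MBq package-insert maximum) and delay absorbs any
shortfall. Alternative policies (dose titration, fixed delay) can be
implemented against the same primitives. Prediction-interval bounds are
carried alongside recommendations, but the point estimate drives the
decision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .count_measures import TC99M_HALF_LIFE_S, decay_factor
from .errors import InfeasibleError, OutOfDomainError
from .regression_model import (
    LinearModelFit,
    PredictionResult,
    predict_pcr_norm,
    predict_pv_ratio,
)


@dataclass(frozen=True)
class StrategyConfig:
    """Targets and limits of a planning strategy.

    Defaults encode the dose-sparing strategy: P/V ratio of at least 3
    at a 120 MBq target dose, never exceeding the 185 MBq maximum, with
    ventilation count rates normalised to the recommended 2-million
    total ventilation counts for cross-study comparability.
    """

    target_pv: float = 3.0
    target_dose_MBq: float = 120.0
    max_dose_MBq: float = 185.0
    ventilation_count_target: float = 2_000_000.0
    half_life_s: float = TC99M_HALF_LIFE_S
    interval_level: float = 0.95
    sensitivity_cps_per_MBq: float = 133.0

    def __post_init__(self) -> None:
        if not 0 < self.target_dose_MBq <= self.max_dose_MBq:
            raise ValueError("need 0 < target dose <= max dose")
        if self.target_pv < 1:
            raise ValueError("target P/V ratio must be >= 1")


@dataclass
class PlanRecommendation:
    """Actionable recommendation for one patient.

    ``action`` is ``inject_now`` (delay 0), ``delay_then_inject``
    (positive delay at the target dose), or ``infeasible``.
    """

    action: str
    dose_MBq: float
    delay_s: float
    predicted: Optional[PredictionResult] = None

    @property
    def delay_min(self) -> float:
        """Delay in minutes for user-facing output."""
        return self.delay_s / 60.0


@dataclass
class ImpactSummary:
    """Cohort-level consequences of following the prediction tool.

    ``dose_spared_MBq`` holds, for each deferred study, the MAA activity
    saved versus injecting blindly with no delay; ``unnecessary_delay_s``
    and ``insufficient_delay_s`` compare the tool's recommended delay
    with the delay truly required (known in simulation).
    """

    n_studies: int
    n_delayed: int
    n_inject_now: int
    n_infeasible: int
    n_blind_dose_over_target: int
    n_blind_dose_over_max: int
    dose_spared_MBq: list[float] = field(default_factory=list)
    unnecessary_delay_s: list[float] = field(default_factory=list)
    insufficient_delay_s: list[float] = field(default_factory=list)

    @property
    def median_dose_spared_MBq(self) -> float:
        return float(np.median(self.dose_spared_MBq)) if self.dose_spared_MBq else 0.0

    @property
    def median_unnecessary_delay_min(self) -> float:
        pos = [d / 60 for d in self.unnecessary_delay_s if d > 0]
        return float(np.median(pos)) if pos else 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_studies": self.n_studies,
                "n_delayed": self.n_delayed,
                "n_inject_now": self.n_inject_now,
                "n_infeasible": self.n_infeasible,
                "n_blind_dose_over_target": self.n_blind_dose_over_target,
                "n_blind_dose_over_max": self.n_blind_dose_over_max,
                "median_dose_spared_MBq": self.median_dose_spared_MBq,
                "median_unnecessary_delay_min": self.median_unnecessary_delay_min,
                "dose_spared_MBq": self.dose_spared_MBq,
                "unnecessary_delay_s": self.unnecessary_delay_s,
                "insufficient_delay_s": self.insufficient_delay_s,
            },
            indent=2,
        )

    def report(self) -> str:
        lines = [
            f"Studies analysed:                 {self.n_studies}",
            f"Inject now (no delay):            {self.n_inject_now}",
            f"Deferred (delay then inject):     {self.n_delayed}",
            f"Infeasible:                       {self.n_infeasible}",
            f"Blind dose would exceed target:   {self.n_blind_dose_over_target}",
            f"Blind dose would exceed maximum:  {self.n_blind_dose_over_max}",
        ]
        if self.dose_spared_MBq:
            spared = np.asarray(self.dose_spared_MBq)
            lines.append(
                f"Dose spared (MBq): min {spared.min():.1f}, "
                f"median {np.median(spared):.1f}, max {spared.max():.1f}"
            )
        return "\n".join(lines)


def normalise_vcr(vcr_cps: float, total_v_counts: float, target_counts: float = 2_000_000.0) -> float:
    """Rescale a ventilation count rate to a standard total-count level.

    Makes count rates comparable across studies with different
    administered ventilation activity by scaling to the count total the
    rate would have had at ``target_counts`` summed ventilation counts.
    """
    if total_v_counts <= 0:
        raise ValueError("total ventilation counts must be positive")
    return vcr_cps * target_counts / total_v_counts


def required_dose_immediate(
    model: LinearModelFit,
    e_ratio: float,
    vcr_cps: float,
    sensitivity_cps_per_MBq: float,
    target_pv: float = 3.0,
) -> float:
    """MAA dose (MBq) achieving the target P/V with no delay.

    Inverts ``P/V = dose x S x PCR_norm_hat / VCR`` for the dose.
    """
    yhat = predict_pcr_norm(model, e_ratio)
    return target_pv * vcr_cps / (sensitivity_cps_per_MBq * yhat)


def required_delay(
    model: LinearModelFit,
    e_ratio: float,
    vcr_cps: float,
    sensitivity_cps_per_MBq: float,
    dose_MBq: float,
    target_pv: float = 3.0,
    half_life_s: float = TC99M_HALF_LIFE_S,
) -> float:
    """Delay (s) after which a fixed dose achieves the target P/V.

    Solves ``dose x S x PCR_norm_hat / (VCR x DF(delay)) = target`` for
    the delay; zero when the immediate ratio already meets the target.
    """
    if dose_MBq <= 0:
        raise ValueError("dose must be positive")
    yhat = predict_pcr_norm(model, e_ratio)
    ratio = target_pv * vcr_cps / (dose_MBq * sensitivity_cps_per_MBq * yhat)
    return max(0.0, half_life_s * math.log2(ratio))


def recommend(
    e_ratio: float,
    vcr_cps: float,
    model: LinearModelFit,
    config: StrategyConfig = StrategyConfig(),
) -> PlanRecommendation:
    """Dose-sparing recommendation for one ventilation study.

    Injects the target dose immediately when that already achieves the
    target ratio; otherwise holds the dose at the target and defers the
    perfusion scan by the required delay. ``infeasible`` only when the
    model predicts a non-positive perfusion count rate.
    """
    try:
        blind_dose = required_dose_immediate(
            model, e_ratio, vcr_cps, config.sensitivity_cps_per_MBq, config.target_pv
        )
    except OutOfDomainError:
        return PlanRecommendation(action="infeasible", dose_MBq=0.0, delay_s=0.0)

    delay_s = 0.0
    if blind_dose > config.target_dose_MBq:
        delay_s = required_delay(
            model,
            e_ratio,
            vcr_cps,
            config.sensitivity_cps_per_MBq,
            config.target_dose_MBq,
            config.target_pv,
            config.half_life_s,
        )
    predicted = predict_pv_ratio(
        model,
        e_ratio,
        config.target_dose_MBq,
        config.sensitivity_cps_per_MBq,
        vcr_cps,
        delay_s,
        config.half_life_s,
        config.interval_level,
    )
    action = "inject_now" if delay_s == 0.0 else "delay_then_inject"
    return PlanRecommendation(
        action=action,
        dose_MBq=config.target_dose_MBq,
        delay_s=delay_s,
        predicted=predicted,
    )


def mape(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean absolute percentage error, in percent."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    if np.any(a == 0):
        raise ValueError("actual values must be nonzero for MAPE")
    return float(100.0 * np.mean(np.abs(a - p) / np.abs(a)))


def validate(
    model: LinearModelFit,
    e_ratios: Sequence[float],
    actual_pcr_norm: Sequence[float],
) -> float:
    """MAPE of predicted versus actual P/V ratios on a held-out cohort.

    Administered activity, camera sensitivity and ventilation count rate
    scale predicted and actual ratios identically for a given study, so
    the P/V-ratio MAPE equals the MAPE on the normalised count rate.
    """
    predicted = [predict_pcr_norm(model, x) for x in e_ratios]
    return mape(actual_pcr_norm, predicted)


def simulate_strategy(
    cohort: Sequence,
    model: LinearModelFit,
    config: StrategyConfig = StrategyConfig(),
    true_pcr_norm: Optional[Callable] = None,
) -> ImpactSummary:
    """Quantify costs and benefits of following the tool over a cohort.

    Each cohort entry must expose the model-visible inputs
    (``e_ratio``, ``vcr_cps``, ``total_v_counts``) and the ground-truth
    ``pcr_norm_true`` (the retrospectively known perfusion count rate
    per MBq). Per study the simulation computes the blind dose that
    immediate injection would truly have required, the true delay
    required at the target dose, and the tool's predicted delay;
    ``unnecessary delay`` is the excess of predicted over true delay and
    ``insufficient delay`` the shortfall. Dose spared is counted for
    studies the tool defers.
    """
    if not cohort:
        raise ValueError("empty cohort")
    getter = true_pcr_norm or (lambda s: s.pcr_norm_true)
    S = config.sensitivity_cps_per_MBq

    summary = ImpactSummary(
        n_studies=len(cohort),
        n_delayed=0,
        n_inject_now=0,
        n_infeasible=0,
        n_blind_dose_over_target=0,
        n_blind_dose_over_max=0,
    )
    for study in cohort:
        vcr = normalise_vcr(
            study.vcr_cps, study.total_v_counts, config.ventilation_count_target
        )
        pcr_norm_true = getter(study)

        # What immediate blind injection would truly have required.
        true_blind_dose = config.target_pv * vcr / (S * pcr_norm_true)
        if true_blind_dose > config.target_dose_MBq:
            summary.n_blind_dose_over_target += 1
        if true_blind_dose > config.max_dose_MBq:
            summary.n_blind_dose_over_max += 1
        true_delay = max(
            0.0,
            config.half_life_s
            * math.log2(
                config.target_pv * vcr / (config.target_dose_MBq * S * pcr_norm_true)
            ),
        )

        rec = recommend(study.e_ratio, vcr, model, config)
        if rec.action == "infeasible":
            summary.n_infeasible += 1
            continue
        if rec.action == "inject_now":
            summary.n_inject_now += 1
        else:
            summary.n_delayed += 1
            summary.dose_spared_MBq.append(
                max(0.0, true_blind_dose - config.target_dose_MBq)
            )
        summary.unnecessary_delay_s.append(max(0.0, rec.delay_s - true_delay))
        summary.insufficient_delay_s.append(max(0.0, true_delay - rec.delay_s))
    return summary
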