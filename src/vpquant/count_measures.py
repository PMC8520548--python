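"""Derived count-rate measures for a VP SPECT study pair.

The quantification chain turns raw per-window count totals into the
quantities that drive perfusion-adequacy assessment:

* ``E_ratio`` — ventilation primary/scatter window count ratio, a proxy
  for soft-tissue attenuation depth;
* ``VCR``, ``PVCR`` — ventilation and (uncorrected) perfusion+ventilation
  count rates, total window counts over scan duration;
* ``PCR`` — perfusion count rate after subtracting the decay-corrected
  residual ventilation rate;
* ``P/V`` — PCR/VCR, the perfusion-adequacy figure of merit (>= 3
  recommended so ventilation activity does not mask perfusion defects);
* ``A_inj``, ``A_sys`` — injection-site residual activity and net
  systemically administered MAA activity, both at perfusion-scan time;
* ``PCR_norm`` — PCR per MBq administered per unit camera sensitivity,
  the regression response.

Decay-correction convention: :func:`decay_factor` always takes a
non-negative elapsed time and returns a fraction <= 1. A quantity
measured *later* is corrected *back* to an earlier reference time by
dividing by the decay factor; a quantity fixed earlier is carried
*forward* by multiplying. This makes the injection-site activity at
perfusion time at least as large as the naively converted static-image
count rate, as physics requires. All intervals are differences of
acquisition-start timestamps; decay during an acquisition is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

from .errors import (
    ImplausibleStudyError,
    InconsistencyError,
    IntervalError,
    MissingRecordError,
    UndefinedRatioError,
    VPQuantError,
)
from .nm_dicom_io import CameraProfile, InjectionSiteImage, ProjectionStudy

#: Physical half-life of Tc-99m: 6.0067 h.
TC99M_HALF_LIFE_S = 6.0067 * 3600.0

#: Injection-site activities above this are flagged as likely
#: misinjections (clinically excluded cases were 36 and 83 MBq).
MISINJECTION_THRESHOLD_MBQ = 20.0


@dataclass(frozen=True)
class DispenseRecord:
    """Radiopharmacy record: MAA activity at dispense time."""

    activity_MBq: float
    dispense_time: datetime

    def __post_init__(self) -> None:
        if self.activity_MBq <= 0:
            raise ValueError("dispensed activity must be positive")


@dataclass
class DerivedMeasures:
    """All derived measures for one VP study pair."""

    e_ratio: float
    vcr_cps: float
    pvcr_cps: float
    pcr_cps: float
    pv_ratio: float
    a_inj_MBq: float
    a_sys_MBq: float
    pcr_norm: float
    decay_factors: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "e_ratio": self.e_ratio,
            "vcr_cps": self.vcr_cps,
            "pvcr_cps": self.pvcr_cps,
            "pcr_cps": self.pcr_cps,
            "pv_ratio": self.pv_ratio,
            "a_inj_MBq": self.a_inj_MBq,
            "a_sys_MBq": self.a_sys_MBq,
            "pcr_norm": self.pcr_norm,
            "decay_factors": dict(self.decay_factors),
            "warnings": list(self.warnings),
        }


def decay_factor(elapsed_s: float, half_life_s: float = TC99M_HALF_LIFE_S) -> float:
    """Fraction of Tc-99m activity remaining after ``elapsed_s`` seconds.

    Returns ``2**(-elapsed_s / half_life_s)``, in (0, 1]. The elapsed
    time must be non-negative: callers orient intervals so that decay
    always runs forward, then multiply or divide per the module
    convention.
    """
    if half_life_s <= 0:
        raise ValueError("half-life must be positive")
    if elapsed_s < 0:
        raise IntervalError(f"negative elapsed time {elapsed_s} s; orient the interval")
    return 2.0 ** (-elapsed_s / half_life_s)


def compute_e_ratio(counts_primary: float, counts_scatter: float) -> float:
    """Primary/scatter window count ratio of the ventilation study.

    Invariant under uniform scaling of both window totals, hence
    independent of administered ventilation activity.
    """
    if counts_scatter <= 0:
        raise UndefinedRatioError("scatter-window counts must be positive")
    return counts_primary / counts_scatter


def compute_count_rate(total_counts: float, duration_s: float) -> float:
    """Window count total divided by acquisition duration, in cps."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return total_counts / duration_s


def compute_pcr(
    pvcr_cps: float,
    vcr_cps: float,
    v_to_p_interval_s: float,
    half_life_s: float = TC99M_HALF_LIFE_S,
) -> float:
    """Perfusion count rate: PVCR minus the decayed residual VCR.

    The ventilation rate measured at ventilation start is carried
    forward (multiplied by the decay factor) over the V-to-P interval
    and subtracted from the uncorrected perfusion-window rate.
    """
    df = decay_factor(v_to_p_interval_s, half_life_s)
    pcr = pvcr_cps - df * vcr_cps
    if pcr <= 0:
        raise ImplausibleStudyError(
            f"perfusion rate {pvcr_cps:.1f} cps not above residual ventilation "
            f"{df * vcr_cps:.1f} cps"
        )
    return pcr


def compute_pv_ratio(pcr_cps: float, vcr_cps: float) -> float:
    """Perfusion/ventilation count-rate ratio (adequacy target >= 3)."""
    if vcr_cps <= 0:
        raise UndefinedRatioError("ventilation count rate must be positive")
    return pcr_cps / vcr_cps


def compute_a_inj(
    injection_image: InjectionSiteImage,
    p_to_static_interval_s: float,
    half_life_s: float,
    sensitivity_cps_per_MBq: float,
) -> float:
    """Injection-site residual activity at perfusion-SPECT time, MBq.

    The static image is acquired *after* the perfusion SPECT, so its
    count rate (ICR) is divided by the decay factor over the interval to
    restore the activity to perfusion time, then converted via the
    camera-collimator sensitivity.
    """
    if sensitivity_cps_per_MBq <= 0:
        raise ValueError("sensitivity must be positive")
    if p_to_static_interval_s < 0:
        raise IntervalError("static image precedes perfusion SPECT; check timestamps")
    df = decay_factor(p_to_static_interval_s, half_life_s)
    return injection_image.count_rate_cps / df / sensitivity_cps_per_MBq


def compute_a_sys(
    dispense: DispenseRecord,
    dispense_to_p_interval_s: float,
    half_life_s: float,
    a_inj_MBq: float,
) -> float:
    """Net systemically administered activity at perfusion time, MBq.

    The dispensed activity is decayed forward from dispense time to
    perfusion start, then the injection-site residual is subtracted.
    Residual syringe activity is not modelled, so this slightly
    overestimates the true systemic activity.
    """
    if dispense_to_p_interval_s < 0:
        raise IntervalError("dispense time after perfusion scan; record inconsistent")
    if a_inj_MBq < 0:
        raise ValueError("injection-site activity must be non-negative")
    df = decay_factor(dispense_to_p_interval_s, half_life_s)
    a_sys = df * dispense.activity_MBq - a_inj_MBq
    if a_sys <= 0:
        raise InconsistencyError(
            f"injection-site activity {a_inj_MBq:.1f} MBq exceeds decayed "
            f"dispensed activity {df * dispense.activity_MBq:.1f} MBq"
        )
    return a_sys


def compute_pcr_norm(
    pcr_cps: float,
    a_sys_MBq: float,
    sensitivity_cps_per_MBq: float,
) -> float:
    """Perfusion count rate per MBq administered per unit sensitivity."""
    if a_sys_MBq <= 0 or sensitivity_cps_per_MBq <= 0:
        raise ValueError("systemic activity and sensitivity must be positive")
    return pcr_cps / a_sys_MBq / sensitivity_cps_per_MBq


def derive_all(
    v_study: ProjectionStudy,
    p_study: ProjectionStudy,
    injection_image: Optional[InjectionSiteImage],
    dispense: Optional[DispenseRecord],
    camera: CameraProfile,
    half_life_s: float = TC99M_HALF_LIFE_S,
    misinjection_threshold_MBq: float = MISINJECTION_THRESHOLD_MBQ,
) -> DerivedMeasures:
    """Compute every derived measure for one study pair.

    All inter-study intervals are differences of acquisition-start
    timestamps. Component errors propagate annotated with the name of
    the failing measure. A missing injection-site image or dispense
    record raises :class:`MissingRecordError` naming the measure that
    needs it, mirroring the record-completeness requirements of a
    clinical QC workflow.
    """
    if injection_image is None:
        raise MissingRecordError("A_inj: injection-site image missing")
    if dispense is None:
        raise MissingRecordError("A_sys: radiopharmacy dispense record missing")
    if dispense.dispense_time >= p_study.acquisition_start:
        raise InconsistencyError(
            "A_sys: dispense time recorded later than perfusion scan time"
        )

    v_to_p_s = (p_study.acquisition_start - v_study.acquisition_start).total_seconds()
    p_to_static_s = (
        injection_image.acquisition_start - p_study.acquisition_start
    ).total_seconds()
    dispense_to_p_s = (
        p_study.acquisition_start - dispense.dispense_time
    ).total_seconds()

    def _step(name: str, fn, *args):
        try:
            return fn(*args)
        except VPQuantError as exc:
            raise type(exc)(f"{name}: {exc}") from exc

    e_ratio = _step("E_ratio", compute_e_ratio, v_study.counts_primary, v_study.counts_scatter)
    vcr = _step("VCR", compute_count_rate, v_study.counts_primary, v_study.duration_s)
    pvcr = _step("PVCR", compute_count_rate, p_study.counts_primary, p_study.duration_s)
    pcr = _step("PCR", compute_pcr, pvcr, vcr, v_to_p_s, half_life_s)
    pv = _step("P/V", compute_pv_ratio, pcr, vcr)
    a_inj = _step(
        "A_inj",
        compute_a_inj,
        injection_image,
        p_to_static_s,
        half_life_s,
        camera.sensitivity_cps_per_MBq,
    )
    a_sys = _step("A_sys", compute_a_sys, dispense, dispense_to_p_s, half_life_s, a_inj)
    pcr_norm = _step(
        "PCR_norm", compute_pcr_norm, pcr, a_sys, camera.sensitivity_cps_per_MBq
    )

    measures = DerivedMeasures(
        e_ratio=e_ratio,
        vcr_cps=vcr,
        pvcr_cps=pvcr,
        pcr_cps=pcr,
        pv_ratio=pv,
        a_inj_MBq=a_inj,
        a_sys_MBq=a_sys,
        pcr_norm=pcr_norm,
        decay_factors={
            "v_to_p": decay_factor(v_to_p_s, half_life_s),
            "p_to_static": decay_factor(p_to_static_s, half_life_s),
            "dispense_to_p": decay_factor(dispense_to_p_s, half_life_s),
        },
    )
    if a_inj > misinjection_threshold_MBq:
        measures.warnings.append(
            f"possible misinjection: {a_inj:.1f} MBq at injection site "
            f"(threshold {misinjection_threshold_MBq:.0f} MBq)"
        )
    return measures
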