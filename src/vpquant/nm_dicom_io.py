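"""Reading and protocol QC of NM projection DICOM data.

A ventilation–perfusion (VP) SPECT study pair is acquired with two
energy windows per scan: the 140 keV photopeak window and a symmetric,
immediately adjacent Compton down-scatter window centred on 119 keV.
Downstream quantification needs nothing from the images beyond the
summed counts per energy window and the acquisition timing, so this
module reduces each raw multi-frame projection file to a
:class:`ProjectionStudy` (per-window count totals plus metadata) and
validates the acquisition against a :class:`CameraProfile`.

Frame-to-window assignment uses the DICOM ``EnergyWindowVector`` when
present; otherwise frames are assumed to be grouped contiguously by
window in header order (both dialects occur in vendor exports).
Counts from all detector heads are summed into the study totals.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pydicom

from .errors import (
    FormatError,
    ProtocolError,
    UndefinedRatioError,
    UnreadableStudyError,
)

#: QC tolerance on energy-window bounds, keV. Absorbs vendor rounding
#: (the GE primary upper threshold is 151 keV vs 150.5 on the Siemens).
ENERGY_TOLERANCE_KEV = 0.5


@dataclass(frozen=True)
class EnergyWindow:
    """One energy acceptance band of the gamma camera."""

    label: str  # "primary" or "scatter"
    lower_keV: float
    upper_keV: float

    def __post_init__(self) -> None:
        if not self.lower_keV < self.upper_keV:
            raise ValueError(
                f"energy window bounds out of order: {self.lower_keV}-{self.upper_keV}"
            )
        if self.label not in ("primary", "scatter"):
            raise ValueError(f"unknown window label {self.label!r}")

    @property
    def centre_keV(self) -> float:
        return 0.5 * (self.lower_keV + self.upper_keV)

    @property
    def width_keV(self) -> float:
        return self.upper_keV - self.lower_keV


@dataclass(frozen=True)
class CameraProfile:
    """Divisional acquisition protocol for one camera-collimator system.

    ``sensitivity_cps_per_MBq`` is the measured count rate per unit
    activity for the collimator in use; it converts injection-site count
    rates to activities and normalised count rates back to physical
    perfusion count rates.
    """

    name: str
    sensitivity_cps_per_MBq: float
    expected_windows: tuple[EnergyWindow, ...]
    n_frames: int
    frame_duration_s: dict[str, float]  # per study kind
    scan_arc_deg: float = 360.0
    collimator: str = "LEAP"

    def __post_init__(self) -> None:
        if self.sensitivity_cps_per_MBq <= 0:
            raise ValueError("sensitivity must be positive")

    def window(self, label: str) -> EnergyWindow:
        for w in self.expected_windows:
            if w.label == label:
                return w
        raise KeyError(label)


#: Dual-head Siemens Symbia: LEAP collimator, measured sensitivity
#: 133 cps/MBq, 120 frames over 360 deg, 10 s ventilation / 5 s
#: perfusion frames, photopeak 129.5-150.5 keV, scatter 108.5-129.5 keV.
SIEMENS_SYMBIA = CameraProfile(
    name="Siemens Symbia",
    sensitivity_cps_per_MBq=133.0,
    expected_windows=(
        EnergyWindow("primary", 129.5, 150.5),
        EnergyWindow("scatter", 108.5, 129.5),
    ),
    n_frames=120,
    frame_duration_s={"ventilation": 10.0, "perfusion": 5.0},
)

#: Dual-head GE Infinia Hawkeye: sensitivity 119 cps/MBq, 12 s
#: ventilation frames, primary upper threshold 151 keV.
GE_INFINIA = CameraProfile(
    name="GE Infinia Hawkeye",
    sensitivity_cps_per_MBq=119.0,
    expected_windows=(
        EnergyWindow("primary", 129.5, 151.0),
        EnergyWindow("scatter", 108.5, 129.5),
    ),
    n_frames=120,
    frame_duration_s={"ventilation": 12.0, "perfusion": 5.0},
)

CAMERA_PROFILES: dict[str, CameraProfile] = {
    "siemens": SIEMENS_SYMBIA,
    "ge": GE_INFINIA,
}


@dataclass
class ProjectionStudy:
    """Per-energy-window summed projection counts for one SPECT acquisition.

    ``n_frames`` counts projections per energy window (the protocol's
    120 angular stops); ``duration_s`` is therefore the wall-clock scan
    time ``n_frames * frame_duration_s`` that converts window totals to
    count rates.
    """

    kind: str  # "ventilation" or "perfusion"
    acquisition_start: datetime
    n_frames: int
    frame_duration_s: float
    counts_primary: int
    counts_scatter: int
    windows: tuple[EnergyWindow, ...]
    camera: Optional[CameraProfile] = None
    scan_arc_deg: Optional[float] = None
    collimator: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("ventilation", "perfusion"):
            raise ValueError(f"unknown study kind {self.kind!r}")
        if self.counts_primary < 0 or self.counts_scatter < 0:
            raise ValueError("window count totals must be non-negative")
        if self.n_frames <= 0 or self.frame_duration_s <= 0:
            raise ValueError("acquisition duration must be positive")

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_duration_s


@dataclass
class InjectionSiteImage:
    """Planar static image of the MAA injection site (nominal 60 s)."""

    acquisition_start: datetime
    duration_s: float
    counts_primary: int

    @property
    def count_rate_cps(self) -> float:
        """Injection-site count rate (ICR)."""
        return self.counts_primary / self.duration_s


@dataclass
class QCReport:
    """Outcome of protocol validation: violations fail QC, warnings do not."""

    violations: list[tuple[str, object, object]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    def add(self, check: str, expected: object, observed: object) -> None:
        self.violations.append((check, expected, observed))

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def to_json(self) -> str:
        return json.dumps(
            {
                "passed": self.passed,
                "violations": [
                    {"check": c, "expected": e, "observed": o}
                    for c, e, o in self.violations
                ],
                "warnings": list(self.warnings),
            },
            indent=2,
            default=str,
        )


# ---------------------------------------------------------------------------
# DICOM parsing helpers


def _parse_dicom_datetime(ds: pydicom.Dataset) -> datetime:
    date = getattr(ds, "AcquisitionDate", None) or getattr(ds, "SeriesDate", None)
    time = getattr(ds, "AcquisitionTime", None) or getattr(ds, "SeriesTime", None)
    if not date or not time:
        raise UnreadableStudyError("acquisition date/time missing from header")
    time = str(time)
    fmt = "%Y%m%d%H%M%S.%f" if "." in time else "%Y%m%d%H%M%S"
    return datetime.strptime(str(date) + time, fmt)


def _parse_windows(ds: pydicom.Dataset) -> list[EnergyWindow]:
    """Parse the energy-window sequence, labelling the highest-centre
    window as the photopeak and the one beneath it as scatter."""
    seq = getattr(ds, "EnergyWindowInformationSequence", None)
    if seq is None:
        raise UnreadableStudyError("no EnergyWindowInformationSequence in header")
    bounds = []
    for item in seq:
        try:
            rng = item.EnergyWindowRangeSequence[0]
            bounds.append(
                (float(rng.EnergyWindowLowerLimit), float(rng.EnergyWindowUpperLimit))
            )
        except (AttributeError, IndexError) as exc:
            raise UnreadableStudyError("energy window range missing") from exc
    if len(bounds) < 2:
        raise ProtocolError(
            f"dual-energy-window acquisition required, found {len(bounds)} window(s)"
        )
    centres = [0.5 * (lo + hi) for lo, hi in bounds]
    order = sorted(range(len(bounds)), key=lambda i: -centres[i])
    labels = {order[0]: "primary", order[1]: "scatter"}
    return [
        EnergyWindow(labels.get(i, "scatter"), lo, hi)
        for i, (lo, hi) in enumerate(bounds)
    ]


def _frame_window_assignment(ds: pydicom.Dataset, n_windows: int, n_frames: int) -> np.ndarray:
    """Return a 0-based window index per frame.

    Uses EnergyWindowVector when present; falls back to contiguous
    grouping of frames by window in header order.
    """
    vec = getattr(ds, "EnergyWindowVector", None)
    if vec is not None:
        arr = np.asarray([int(v) for v in vec]) - 1  # DICOM vectors are 1-based
        if arr.size != n_frames:
            raise UnreadableStudyError(
                f"EnergyWindowVector length {arr.size} != NumberOfFrames {n_frames}"
            )
        if arr.min() < 0 or arr.max() >= n_windows:
            raise UnreadableStudyError("EnergyWindowVector indexes unknown window")
        return arr
    if n_frames % n_windows:
        raise UnreadableStudyError(
            "cannot split frames evenly across windows without EnergyWindowVector"
        )
    per = n_frames // n_windows
    return np.repeat(np.arange(n_windows), per)


def _infer_kind(ds: pydicom.Dataset) -> Optional[str]:
    text = " ".join(
        str(getattr(ds, tag, "") or "")
        for tag in ("SeriesDescription", "StudyDescription", "ProtocolName")
    ).lower()
    if "vent" in text:
        return "ventilation"
    if "perf" in text:
        return "perfusion"
    return None


def load_projection_study(
    path: str | Path,
    camera: Optional[CameraProfile] = None,
    kind: Optional[str] = None,
) -> ProjectionStudy:
    """Load a raw NM projection file and reduce it to per-window totals.

    Parameters
    ----------
    path
        DICOM NM multi-frame projection object.
    camera
        Protocol profile the study claims to follow; attached to the
        returned study for later QC but not enforced here.
    kind
        "ventilation" or "perfusion"; inferred from the series
        description when omitted.

    Raises
    ------
    FormatError
        If the object is not NM modality.
    UnreadableStudyError
        If energy-window or timing metadata is missing.
    ProtocolError
        If fewer than two energy windows are present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "NM":
        raise FormatError(f"{path.name}: expected NM modality, got {getattr(ds, 'Modality', None)!r}")

    windows = _parse_windows(ds)
    n_frames_total = int(getattr(ds, "NumberOfFrames", 1))
    assignment = _frame_window_assignment(ds, len(windows), n_frames_total)

    pixels = ds.pixel_array
    if pixels.ndim == 2:
        pixels = pixels[None]
    frame_sums = pixels.reshape(n_frames_total, -1).sum(axis=1, dtype=np.int64)
    totals = np.bincount(assignment, weights=frame_sums, minlength=len(windows))

    idx_primary = next(i for i, w in enumerate(windows) if w.label == "primary")
    idx_scatter = next(i for i, w in enumerate(windows) if w.label == "scatter")
    counts_primary = int(totals[idx_primary])
    counts_scatter = int(totals[idx_scatter])

    frame_duration_ms = getattr(ds, "ActualFrameDuration", None)
    if frame_duration_ms is None:
        raise UnreadableStudyError("ActualFrameDuration missing")
    frame_duration_s = float(frame_duration_ms) / 1000.0

    n_frames_primary = int(np.sum(assignment == idx_primary))

    scan_arc = None
    rot = getattr(ds, "RotationInformationSequence", None)
    if rot:
        scan_arc = float(getattr(rot[0], "ScanArc", None) or 0) or None
    collimator = None
    det = getattr(ds, "DetectorInformationSequence", None)
    if det:
        collimator = str(getattr(det[0], "CollimatorGridName", "") or "") or None

    resolved_kind = kind or _infer_kind(ds)
    if resolved_kind is None:
        raise UnreadableStudyError(
            f"{path.name}: study kind (ventilation/perfusion) not inferable; pass kind="
        )

    return ProjectionStudy(
        kind=resolved_kind,
        acquisition_start=_parse_dicom_datetime(ds),
        n_frames=n_frames_primary,
        frame_duration_s=frame_duration_s,
        counts_primary=counts_primary,
        counts_scatter=counts_scatter,
        windows=tuple(windows),
        camera=camera,
        scan_arc_deg=scan_arc,
        collimator=collimator,
    )


def load_injection_site_image(path: str | Path) -> InjectionSiteImage:
    """Load the planar static injection-site image and sum its counts.

    Counts are summed over the whole image; the acquisition protocol
    centres the injection portal in an otherwise empty field of view,
    but users should be aware no region restriction is applied.
    """
    ds = pydicom.dcmread(Path(path))
    if getattr(ds, "Modality", None) != "NM":
        raise FormatError(f"expected NM modality, got {getattr(ds, 'Modality', None)!r}")
    duration_ms = getattr(ds, "ActualFrameDuration", None)
    if duration_ms is None:
        raise UnreadableStudyError("ActualFrameDuration missing from static image")
    counts = int(ds.pixel_array.sum(dtype=np.int64))
    return InjectionSiteImage(
        acquisition_start=_parse_dicom_datetime(ds),
        duration_s=float(duration_ms) / 1000.0,
        counts_primary=counts,
    )


# ---------------------------------------------------------------------------
# QC


def validate_protocol(
    study: ProjectionStudy,
    camera: CameraProfile,
    other: Optional[ProjectionStudy] = None,
    energy_tolerance_keV: float = ENERGY_TOLERANCE_KEV,
) -> QCReport:
    """Check a loaded study against the divisional acquisition protocol.

    One violation is recorded per mismatched field: energy-window bounds
    (beyond ``energy_tolerance_keV``), frame count, frame duration for
    the study kind, scan arc and collimator (when recorded in the file).
    When the companion study is supplied, scan order (ventilation before
    perfusion) is also validated. A report object is always returned.
    """
    report = QCReport()

    for expected in camera.expected_windows:
        try:
            observed = next(w for w in study.windows if w.label == expected.label)
        except StopIteration:
            report.add(f"window {expected.label}", "present", "missing")
            continue
        for attr in ("lower_keV", "upper_keV"):
            e, o = getattr(expected, attr), getattr(observed, attr)
            if abs(e - o) > energy_tolerance_keV + 1e-9:
                report.add(f"window {expected.label} {attr}", e, o)

    if study.n_frames != camera.n_frames:
        report.add("n_frames", camera.n_frames, study.n_frames)

    expected_dur = camera.frame_duration_s[study.kind]
    if abs(study.frame_duration_s - expected_dur) > 1e-6:
        report.add(f"frame_duration_s ({study.kind})", expected_dur, study.frame_duration_s)

    if study.scan_arc_deg is not None and abs(study.scan_arc_deg - camera.scan_arc_deg) > 1e-6:
        report.add("scan_arc_deg", camera.scan_arc_deg, study.scan_arc_deg)
    if study.collimator is not None and study.collimator.upper() != camera.collimator.upper():
        report.add("collimator", camera.collimator, study.collimator)

    if other is not None:
        vent, perf = (study, other) if study.kind == "ventilation" else (other, study)
        if vent.kind != "ventilation" or perf.kind != "perfusion":
            report.add("study pair", "ventilation + perfusion", (study.kind, other.kind))
        elif not vent.acquisition_start < perf.acquisition_start:
            report.add(
                "scan order",
                "ventilation before perfusion",
                f"V {vent.acquisition_start} >= P {perf.acquisition_start}",
            )
    return report


def flag_count_anomalies(
    study: ProjectionStudy,
    model=None,
    n_sd: float = 3.0,
) -> QCReport:
    """Warn when the ventilation dual-window count ratio is implausible.

    The primary/scatter count ratio of a ventilation study should fall
    within the range spanned by the model's training data; values far
    outside it signal extracorporeal contamination (activity outside the
    patient inflates the photopeak counts) or extrapolation beyond the
    fitted range. The default band is the training mean +/- ``n_sd``
    predictor standard deviations, both recovered from ``model``
    (defaults to the published model: 1.83 +/- 3 x 0.21).
    """
    if study.counts_scatter == 0:
        raise UndefinedRatioError("scatter-window counts are zero; count ratio undefined")
    if model is None:
        from .regression_model import PUBLISHED_MODEL

        model = PUBLISHED_MODEL
    sd = float(np.sqrt(model.ss_x / (model.n - 1)))
    lo, hi = model.x_mean - n_sd * sd, model.x_mean + n_sd * sd

    report = QCReport()
    e_ratio = study.counts_primary / study.counts_scatter
    if not lo <= e_ratio <= hi:
        report.warn(
            f"E_ratio {e_ratio:.3f} outside training range [{lo:.3f}, {hi:.3f}]: "
            "possible extracorporeal contamination or extrapolation"
        )
    return report


# ---------------------------------------------------------------------------
# Tabular output


def study_summary_rows(studies: Sequence[ProjectionStudy]) -> list[dict]:
    return [
        {
            "kind": s.kind,
            "acquisition_start": s.acquisition_start.isoformat(),
            "duration_s": s.duration_s,
            "counts_primary": s.counts_primary,
            "counts_scatter": s.counts_scatter,
        }
        for s in studies
    ]


def write_study_summary_csv(studies: Sequence[ProjectionStudy], path: str | Path) -> None:
    rows = study_summary_rows(studies)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
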