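"""Synthetic VP SPECT cohorts and on-disk DICOM study fixtures.

The generator emulates the statistical structure of a same-day clinical
VP SPECT service so every other module is testable without patient
data. Per study it draws the ventilation dual-window count ratio
(E_ratio) from a truncated normal, generates the true normalised
perfusion count rate (PCR_norm) from the published linear model plus
Gaussian residual noise, draws the systemic MAA activity, and then
works *backwards* to raw observables: per-window projection count
totals, injection-site image counts, and a radiopharmacy dispense
record, all consistent with the decay physics and clinic timings.

Two presets are provided: the training profile (E_ratio mean 1.83,
SD 0.21; systemic activity 114.8 +/- 8 MBq) and a validation profile
(1.80, 0.23; 118.4 +/- 9.9 MBq), both with residual SD sqrt(0.001089)
about the line y = 0.28 x - 0.198 and ventilation count totals near
the recommended 2 million.

Counts are rounded to integers after rate x duration; Poisson jitter is
optional and off by default so round-trip identity tests are exact.
E_ratio and ventilation count rate are generated independently — the
clinic's true joint distribution is unknown.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .count_measures import TC99M_HALF_LIFE_S, decay_factor
from .nm_dicom_io import CameraProfile, SIEMENS_SYMBIA

_NM_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.20"


@dataclass(frozen=True)
class CohortSpec:
    """Statistical profile of a synthetic cohort.

    Defaults are the training profile. ``residual_sd`` is the standard
    deviation of the PCR_norm noise about the line (the square root of
    the model MSE). Truncation floors (``e_ratio`` > 0.8, ``pcr_norm``
    > 0.05) prevent the unphysical negatives a linear-Gaussian model can
    produce; they are generator artefacts, essentially never active at
    the default parameters.
    """

    n: int = 342
    e_ratio_mean: float = 1.83
    e_ratio_sd: float = 0.21
    residual_sd: float = math.sqrt(0.001089)
    slope: float = 0.28
    intercept: float = -0.198
    a_sys_mean: float = 114.8
    a_sys_sd: float = 8.0
    v_count_target: int = 2_000_000
    seed: int = 0
    camera: CameraProfile = SIEMENS_SYMBIA
    half_life_s: float = TC99M_HALF_LIFE_S
    poisson_jitter: bool = False
    #: clinic timings: dispense 30 min before ventilation start;
    #: perfusion immediately after ventilation; static 5 min after
    #: the perfusion scan ends.
    dispense_lead_s: float = 1800.0
    static_lag_s: float = 300.0
    base_time: datetime = datetime(2024, 1, 15, 9, 0, 0)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if min(self.e_ratio_sd, self.residual_sd, self.a_sys_sd) < 0:
            raise ValueError("standard deviations must be non-negative")

    @classmethod
    def training(cls, **overrides) -> "CohortSpec":
        return cls(**overrides)

    @classmethod
    def validation(cls, **overrides) -> "CohortSpec":
        defaults = dict(
            n=198, e_ratio_mean=1.80, e_ratio_sd=0.23, a_sys_mean=118.4, a_sys_sd=9.9
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SyntheticStudy:
    """Ground truth plus raw observables for one simulated study."""

    study_id: str
    e_ratio_true: float
    pcr_norm_true: float
    vcr_cps: float
    a_sys_MBq: float
    a_inj_MBq: float
    a_disp_MBq: float
    v_counts_primary: int
    v_counts_scatter: int
    p_counts_primary: int
    p_counts_scatter: int
    site_counts: int
    timestamps: dict[str, datetime] = field(default_factory=dict)
    camera: CameraProfile = SIEMENS_SYMBIA

    @property
    def e_ratio(self) -> float:
        """Observed ventilation count ratio (differs from the truth only
        after contamination has been injected)."""
        return self.v_counts_primary / self.v_counts_scatter

    @property
    def total_v_counts(self) -> int:
        return self.v_counts_primary


@dataclass(frozen=True)
class CohortRow:
    """Row of a cohort table used by the planning simulation."""

    study_id: str
    e_ratio: float
    vcr_cps: float
    total_v_counts: float
    pcr_norm_true: float


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, floor: float) -> float:
    if sd == 0:
        return mean
    while True:
        value = rng.normal(mean, sd)
        if value > floor:
            return value


def generate_cohort(spec: CohortSpec) -> list[SyntheticStudy]:
    """Draw a cohort of synthetic studies; deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    cam = spec.camera
    t1 = cam.n_frames * cam.frame_duration_s["ventilation"]
    t2 = cam.n_frames * cam.frame_duration_s["perfusion"]
    S = cam.sensitivity_cps_per_MBq

    studies: list[SyntheticStudy] = []
    for i in range(spec.n):
        e_ratio = _truncated_normal(rng, spec.e_ratio_mean, spec.e_ratio_sd, 0.8)
        while True:
            pcr_norm = spec.slope * e_ratio + spec.intercept + rng.normal(0, spec.residual_sd)
            if pcr_norm > 0.05:
                break
        a_sys = _truncated_normal(rng, spec.a_sys_mean, spec.a_sys_sd, 10.0)
        a_inj = rng.uniform(0.2, 2.0)  # small injection-portal residual

        v_start = spec.base_time
        p_start = v_start + timedelta(seconds=t1)
        static_start = p_start + timedelta(seconds=t2 + spec.static_lag_s)
        dispense_time = v_start - timedelta(seconds=spec.dispense_lead_s)

        if spec.poisson_jitter:
            v_primary = int(rng.poisson(spec.v_count_target))
        else:
            v_primary = int(spec.v_count_target)
        v_scatter = int(round(v_primary / e_ratio))
        vcr = v_primary / t1

        df_vp = decay_factor((p_start - v_start).total_seconds(), spec.half_life_s)
        pvcr = pcr_norm * S * a_sys + df_vp * vcr
        p_primary = int(round(pvcr * t2))
        p_scatter = int(round(p_primary / e_ratio))

        df_ps = decay_factor((static_start - p_start).total_seconds(), spec.half_life_s)
        site_counts = int(round(a_inj * df_ps * S * 60.0))

        df_dp = decay_factor((p_start - dispense_time).total_seconds(), spec.half_life_s)
        a_disp = (a_sys + a_inj) / df_dp

        studies.append(
            SyntheticStudy(
                study_id=f"S{i:04d}",
                e_ratio_true=e_ratio,
                pcr_norm_true=pcr_norm,
                vcr_cps=vcr,
                a_sys_MBq=a_sys,
                a_inj_MBq=a_inj,
                a_disp_MBq=a_disp,
                v_counts_primary=v_primary,
                v_counts_scatter=v_scatter,
                p_counts_primary=p_primary,
                p_counts_scatter=p_scatter,
                site_counts=site_counts,
                timestamps={
                    "ventilation": v_start,
                    "perfusion": p_start,
                    "static": static_start,
                    "dispense": dispense_time,
                },
                camera=cam,
            )
        )
    return studies


def inject_contamination(study: SyntheticStudy, extra_primary_counts: int) -> SyntheticStudy:
    """Add extracorporeal activity to the ventilation photopeak window.

    Activity outside the patient reaches the camera with little
    soft-tissue scatter, so it inflates the primary window only; the
    observed count ratio rises while every ground-truth field stays
    unchanged (the truth deliberately no longer matches observation).
    """
    if extra_primary_counts < 0:
        raise ValueError("extra counts must be non-negative")
    return replace(
        study, v_counts_primary=study.v_counts_primary + int(extra_primary_counts)
    )


# ---------------------------------------------------------------------------
# DICOM fixture writing


def _fill_frames(total: int, n_frames: int, shape: tuple[int, int] = (64, 64)) -> np.ndarray:
    """Distribute ``total`` counts over frames of uniform-ish pixels so
    that the pixel sum equals ``total`` exactly."""
    base, rem = divmod(int(total), n_frames)
    frames = np.empty((n_frames, *shape), dtype=np.uint16)
    npix = shape[0] * shape[1]
    for i in range(n_frames):
        frame_total = base + (1 if i < rem else 0)
        q, r = divmod(frame_total, npix)
        if q > np.iinfo(np.uint16).max:
            raise ValueError("frame counts exceed 16-bit pixel capacity")
        flat = np.full(npix, q, dtype=np.uint16)
        flat[:r] += 1
        frames[i] = flat.reshape(shape)
    return frames


def _base_dataset(start: datetime, description: str) -> tuple[FileMetaDataset, Dataset]:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _NM_IMAGE_STORAGE
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.SOPClassUID = _NM_IMAGE_STORAGE
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "NM"
    ds.SeriesDescription = description
    ds.PatientName = "SYNTHETIC^PHANTOM"
    ds.PatientID = "SYN000"
    ds.AcquisitionDate = start.strftime("%Y%m%d")
    ds.AcquisitionTime = start.strftime("%H%M%S.%f")
    ds.SeriesDate = ds.AcquisitionDate
    ds.SeriesTime = ds.AcquisitionTime
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.Rows = 64
    ds.Columns = 64
    return meta, ds


def _window_item(window) -> Dataset:
    rng = Dataset()
    rng.EnergyWindowLowerLimit = window.lower_keV
    rng.EnergyWindowUpperLimit = window.upper_keV
    item = Dataset()
    item.EnergyWindowName = window.label
    item.EnergyWindowRangeSequence = [rng]
    return item


def write_nm_projection(
    path: Path,
    camera: CameraProfile,
    kind: str,
    start: datetime,
    counts_primary: int,
    counts_scatter: int,
) -> None:
    """Write a minimal dual-window NM projection object whose per-window
    pixel sums equal the given totals exactly.

    Frames are grouped by window (primary block first) and mapped via
    the EnergyWindowVector; window bounds, frame count, frame duration,
    scan arc and collimator come from the camera profile.
    """
    n = camera.n_frames
    meta, ds = _base_dataset(start, f"{kind} SPECT (synthetic)")
    ds.NumberOfFrames = 2 * n
    ds.ActualFrameDuration = int(round(camera.frame_duration_s[kind] * 1000))

    primary = camera.window("primary")
    scatter = camera.window("scatter")
    ds.EnergyWindowInformationSequence = [_window_item(primary), _window_item(scatter)]
    ds.NumberOfEnergyWindows = 2
    ds.EnergyWindowVector = [1] * n + [2] * n
    ds.DetectorVector = [1] * (2 * n)
    ds.NumberOfDetectors = 1

    rot = Dataset()
    rot.ScanArc = camera.scan_arc_deg
    rot.NumberOfFramesInRotation = n
    ds.RotationInformationSequence = [rot]

    det = Dataset()
    det.CollimatorGridName = camera.collimator
    det.CollimatorType = "PARA"
    ds.DetectorInformationSequence = [det]

    frames = np.concatenate(
        [_fill_frames(counts_primary, n), _fill_frames(counts_scatter, n)]
    )
    ds.PixelData = frames.tobytes()

    fds = pydicom.dataset.FileDataset(str(path), ds, file_meta=meta, preamble=b"\0" * 128)
    fds.save_as(str(path), enforce_file_format=True)


def write_static_image(path: Path, camera: CameraProfile, start: datetime, counts: int) -> None:
    """Write a 60 s planar static injection-site image (photopeak only)."""
    meta, ds = _base_dataset(start, "injection site static (synthetic)")
    ds.NumberOfFrames = 1
    ds.ActualFrameDuration = 60_000
    ds.EnergyWindowInformationSequence = [_window_item(camera.window("primary"))]
    ds.NumberOfEnergyWindows = 1
    ds.PixelData = _fill_frames(counts, 1).tobytes()
    fds = pydicom.dataset.FileDataset(str(path), ds, file_meta=meta, preamble=b"\0" * 128)
    fds.save_as(str(path), enforce_file_format=True)


def generate_study_fixtures(
    cohort: Sequence[SyntheticStudy],
    out_dir: str | Path,
) -> dict:
    """Write DICOM fixtures and a dispense-record CSV for a cohort.

    Returns a manifest mapping study_id to the written file paths; the
    manifest is also saved as ``manifest.json`` in ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    dispense_rows = []
    for study in cohort:
        paths = {
            "ventilation": out / f"{study.study_id}_vent.dcm",
            "perfusion": out / f"{study.study_id}_perf.dcm",
            "site": out / f"{study.study_id}_site.dcm",
        }
        write_nm_projection(
            paths["ventilation"],
            study.camera,
            "ventilation",
            study.timestamps["ventilation"],
            study.v_counts_primary,
            study.v_counts_scatter,
        )
        write_nm_projection(
            paths["perfusion"],
            study.camera,
            "perfusion",
            study.timestamps["perfusion"],
            study.p_counts_primary,
            study.p_counts_scatter,
        )
        write_static_image(
            paths["site"], study.camera, study.timestamps["static"], study.site_counts
        )
        manifest[study.study_id] = {k: str(v) for k, v in paths.items()}
        dispense_rows.append(
            {
                "study_id": study.study_id,
                "a_disp_MBq": f"{study.a_disp_MBq:.6f}",
                "dispense_time": study.timestamps["dispense"].isoformat(),
            }
        )

    dispense_csv = out / "dispense.csv"
    with open(dispense_csv, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["study_id", "a_disp_MBq", "dispense_time"])
        writer.writeheader()
        writer.writerows(dispense_rows)

    full = {"dispense_csv": str(dispense_csv), "studies": manifest}
    (out / "manifest.json").write_text(json.dumps(full, indent=2))
    return full


# ---------------------------------------------------------------------------
# Cohort tables


def cohort_to_csv(cohort: Sequence[SyntheticStudy], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["study_id", "e_ratio", "vcr_cps", "total_v_counts", "true_pcr_norm"])
        for s in cohort:
            writer.writerow(
                [s.study_id, s.e_ratio, s.vcr_cps, s.total_v_counts, s.pcr_norm_true]
            )


def cohort_from_csv(path: str | Path) -> list[CohortRow]:
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append(
                CohortRow(
                    study_id=rec["study_id"],
                    e_ratio=float(rec["e_ratio"]),
                    vcr_cps=float(rec["vcr_cps"]),
                    total_v_counts=float(rec["total_v_counts"]),
                    pcr_norm_true=float(rec["true_pcr_norm"]),
                )
            )
    return rows
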