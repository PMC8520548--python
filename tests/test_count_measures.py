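"""Derived measures: decay correction, count ratios and activities."""

from datetime import datetime, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vpquant import (
    SIEMENS_SYMBIA,
    DispenseRecord,
    InjectionSiteImage,
    compute_a_inj,
    compute_a_sys,
    compute_count_rate,
    compute_e_ratio,
    compute_pcr,
    compute_pcr_norm,
    compute_pv_ratio,
    decay_factor,
    derive_all,
)
from vpquant.count_measures import TC99M_HALF_LIFE_S
from vpquant.errors import (
    ImplausibleStudyError,
    InconsistencyError,
    IntervalError,
    MissingRecordError,
    UndefinedRatioError,
)
from vpquant.nm_dicom_io import load_injection_site_image, load_projection_study

HALF_LIFE = 21624.12  # Tc-99m, seconds


class TestDecayFactor:
    @pytest.mark.parametrize(
        "elapsed, expected",
        [
            (0.0, 1.0),
            (HALF_LIFE, 0.5),
            (2 * HALF_LIFE, 0.25),
            (7200.0, 2 ** (-7200.0 / HALF_LIFE)),  # = 0.79391
        ],
    )
    def test_values(self, elapsed, expected):
        assert decay_factor(elapsed, HALF_LIFE) == pytest.approx(expected, rel=1e-12)

    def test_default_half_life_is_tc99m(self):
        assert TC99M_HALF_LIFE_S == pytest.approx(6.0067 * 3600)
        assert decay_factor(TC99M_HALF_LIFE_S) == pytest.approx(0.5)

    def test_negative_elapsed_rejected(self):
        with pytest.raises(IntervalError):
            decay_factor(-1.0, HALF_LIFE)

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(0, 1e5, allow_nan=False),
        b=st.floats(0, 1e5, allow_nan=False),
    )
    def test_multiplicative_over_intervals(self, a, b):
        assert decay_factor(a + b, HALF_LIFE) == pytest.approx(
            decay_factor(a, HALF_LIFE) * decay_factor(b, HALF_LIFE), rel=1e-12
        )


class TestCountRatios:
    def test_e_ratio_basic(self):
        assert compute_e_ratio(1_000_000, 1_000_000) == 1.0
        assert compute_e_ratio(1_830_000, 1_000_000) == pytest.approx(1.83)

    @settings(derandomize=True, max_examples=50)
    @given(
        primary=st.integers(1, 10**7),
        scatter=st.integers(1, 10**7),
        k=st.floats(1e-3, 1e3, allow_nan=False),
    )
    def test_e_ratio_scale_invariant(self, primary, scatter, k):
        # dose-independence: scaling both window totals leaves the ratio fixed
        assert compute_e_ratio(k * primary, k * scatter) == pytest.approx(
            compute_e_ratio(primary, scatter), rel=1e-9
        )

    def test_e_ratio_zero_scatter_error(self):
        with pytest.raises(UndefinedRatioError):
            compute_e_ratio(1000, 0)

    @pytest.mark.parametrize(
        "counts, duration, expected",
        [(2_000_000, 1200, 2_000_000 / 1200), (0, 600, 0.0), (600_000, 600, 1000.0)],
    )
    def test_count_rate(self, counts, duration, expected):
        assert compute_count_rate(counts, duration) == pytest.approx(expected)

    def test_count_rate_bad_duration(self):
        with pytest.raises(ValueError):
            compute_count_rate(1000, 0)


class TestPerfusionRate:
    def test_no_delay_subtraction(self):
        assert compute_pcr(5000, 1000, 0, HALF_LIFE) == pytest.approx(4000)

    def test_half_life_delay(self):
        assert compute_pcr(4000, 1000, HALF_LIFE, HALF_LIFE) == pytest.approx(3500)

    def test_conservation_at_zero_interval(self):
        # with no delay, primary-window perfusion counts split exactly
        pvcr, vcr = 6381.25, 1666.75
        assert compute_pcr(pvcr, vcr, 0, HALF_LIFE) + vcr == pvcr

    def test_implausible_study_error(self):
        with pytest.raises(ImplausibleStudyError):
            compute_pcr(900, 1000, 0, HALF_LIFE)

    def test_pv_ratio(self):
        assert compute_pv_ratio(3000, 1000) == pytest.approx(3.0)
        assert compute_pv_ratio(0, 1000) == 0.0
        with pytest.raises(UndefinedRatioError):
            compute_pv_ratio(3000, 0)


def _site(count_rate_cps, duration_s=60.0):
    return InjectionSiteImage(
        acquisition_start=datetime(2024, 1, 15, 10, 0),
        duration_s=duration_s,
        counts_primary=int(round(count_rate_cps * duration_s)),
    )


class TestActivities:
    def test_a_inj_identity(self):
        assert compute_a_inj(_site(133.0), 0, HALF_LIFE, 133.0) == pytest.approx(1.0)

    def test_a_inj_decay_back_correction(self):
        # static acquired one half-life after perfusion: measured rate is
        # half what it was, so the correction doubles it back
        assert compute_a_inj(_site(66.5), HALF_LIFE, HALF_LIFE, 133.0) == pytest.approx(1.0)

    def test_a_inj_negative_interval_error(self):
        with pytest.raises(IntervalError):
            compute_a_inj(_site(133.0), -60, HALF_LIFE, 133.0)

    def test_a_sys_no_decay(self):
        rec = DispenseRecord(120.0, datetime(2024, 1, 15, 8, 0))
        assert compute_a_sys(rec, 0, HALF_LIFE, 0.0) == pytest.approx(120.0)

    def test_a_sys_with_decay_and_residual(self):
        rec = DispenseRecord(240.0, datetime(2024, 1, 15, 8, 0))
        assert compute_a_sys(rec, HALF_LIFE, HALF_LIFE, 5.0) == pytest.approx(115.0)

    def test_a_sys_inconsistency_error(self):
        rec = DispenseRecord(100.0, datetime(2024, 1, 15, 8, 0))
        with pytest.raises(InconsistencyError):
            compute_a_sys(rec, HALF_LIFE, HALF_LIFE, 60.0)

    def test_pcr_norm(self):
        assert compute_pcr_norm(133.0 * 114.8, 114.8, 133.0) == pytest.approx(1.0)
        assert compute_pcr_norm(4777, 114.8, 133.0) == pytest.approx(0.313, abs=5e-4)
        one = compute_pcr_norm(4777, 114.8, 133.0)
        assert compute_pcr_norm(4777, 2 * 114.8, 133.0) == pytest.approx(one / 2)


class TestDeriveAll:
    def _load(self, study, manifest, camera):
        paths = manifest["studies"][study.study_id]
        v = load_projection_study(paths["ventilation"], camera)
        p = load_projection_study(paths["perfusion"], camera)
        site = load_injection_site_image(paths["site"])
        dispense = DispenseRecord(study.a_disp_MBq, study.timestamps["dispense"])
        return v, p, site, dispense

    def test_generator_round_trip(self, small_cohort, fixture_manifest, camera):
        """The full pipeline reproduces each study's ground truth to
        within integer count rounding (< 0.5%)."""
        for study in small_cohort:
            v, p, site, dispense = self._load(study, fixture_manifest, camera)
            m = derive_all(v, p, site, dispense, camera)
            assert m.e_ratio == pytest.approx(study.e_ratio_true, rel=5e-3)
            assert m.vcr_cps == pytest.approx(study.vcr_cps, rel=5e-3)
            assert m.pcr_norm == pytest.approx(study.pcr_norm_true, rel=5e-3)
            assert m.a_sys_MBq == pytest.approx(study.a_sys_MBq, rel=5e-3)
            assert m.pcr_cps < m.pvcr_cps

    def test_deterministic(self, small_cohort, fixture_manifest, camera):
        study = small_cohort[0]
        v, p, site, dispense = self._load(study, fixture_manifest, camera)
        first = derive_all(v, p, site, dispense, camera).to_dict()
        second = derive_all(v, p, site, dispense, camera).to_dict()
        assert first == second

    def test_missing_dispense_record(self, small_cohort, fixture_manifest, camera):
        study = small_cohort[0]
        v, p, site, _ = self._load(study, fixture_manifest, camera)
        with pytest.raises(MissingRecordError, match="A_sys"):
            derive_all(v, p, site, None, camera)

    def test_dispense_after_scan_rejected(self, small_cohort, fixture_manifest, camera):
        study = small_cohort[0]
        v, p, site, _ = self._load(study, fixture_manifest, camera)
        late = DispenseRecord(120.0, p.acquisition_start + timedelta(hours=1))
        with pytest.raises(InconsistencyError):
            derive_all(v, p, site, late, camera)

    def test_misinjection_warning(self, small_cohort, fixture_manifest, camera):
        study = small_cohort[0]
        v, p, _, _ = self._load(study, fixture_manifest, camera)
        # 83 MBq at the injection portal, imaged 5 min after perfusion
        site = _site(83.0 * SIEMENS_SYMBIA.sensitivity_cps_per_MBq)
        site.acquisition_start = p.acquisition_start + timedelta(minutes=5)
        dispense = DispenseRecord(
            400.0, p.acquisition_start - timedelta(minutes=30)
        )
        m = derive_all(v, p, site, dispense, camera)
        assert any("misinjection" in w for w in m.warnings)
        assert m.a_inj_MBq == pytest.approx(83.0, rel=1e-2)
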