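"""EIC extraction, peak detection, adduct grouping, and mzML round-trips."""

import math

import numpy as np
import pytest

from gslprof.chem import ADDUCTS
from gslprof.features import (
    CompoundFeatureGroup,
    Feature,
    Spectrum,
    build_eics,
    detect_peaks,
    group_adducts,
)
from gslprof.mzml_io import read_mzml, write_mzml


def gaussian_run(center_mz, rt_apex=10.0, sigma=0.2, area=1.0e6, n_scans=400,
                 interval=0.05, extra=()):
    """MS1 scans holding one (or more) Gaussian elution profiles."""
    spectra = []
    for i in range(n_scans):
        rt = i * interval
        mzs, ints = [], []
        for mz0, apex_rt, a in ((center_mz, rt_apex, area),) + tuple(extra):
            h = a / (sigma * math.sqrt(2 * math.pi)) * math.exp(
                -0.5 * ((rt - apex_rt) / sigma) ** 2
            )
            if h > 1:
                mzs.append(mz0)
                ints.append(h)
        spectra.append(Spectrum(f"s{i}", 1, rt, np.array(mzs), np.array(ints)))
    return spectra


class TestBuildEics:
    def test_single_gaussian_single_apex(self):
        spectra = gaussian_run(728.603)
        rts, traces, _ = build_eics(spectra, [728.603], 25)
        assert traces.shape[0] == 1
        assert np.argmax(traces[0]) == pytest.approx(200, abs=1)

    def test_one_dalton_apart_no_crosstalk(self):
        spectra = gaussian_run(728.603, extra=(((729.603), 12.0, 5e5),))
        rts, traces, _ = build_eics(spectra, [728.603, 729.603], 25)
        assert rts[np.argmax(traces[0])] == pytest.approx(10.0, abs=0.1)
        assert rts[np.argmax(traces[1])] == pytest.approx(12.0, abs=0.1)

    def test_absent_target_all_zero(self):
        spectra = gaussian_run(728.603)
        _, traces, _ = build_eics(spectra, [900.0], 25)
        assert not traces.any()

    def test_empty_run_rejected(self):
        with pytest.raises(ValueError):
            build_eics([], [728.603], 25)


class TestDetectPeaks:
    def test_gaussian_area_within_five_percent(self):
        area = 2.0e6
        spectra = gaussian_run(728.603, area=area)
        rts, traces, _ = build_eics(spectra, [728.603], 25)
        feats = detect_peaks(rts, traces[0], min_height=1000, target_mz=728.603)
        assert len(feats) == 1
        assert feats[0].area == pytest.approx(area, rel=0.05)
        assert feats[0].rt == pytest.approx(10.0, abs=0.06)

    def test_flat_zero_trace_empty(self):
        rts = np.arange(100) * 0.05
        assert detect_peaks(rts, np.zeros(100), target_mz=700.0) == []

    def test_two_separated_gaussians_two_features(self):
        spectra = gaussian_run(728.603, rt_apex=8.0, extra=(((728.603), 12.0, 8e5),))
        rts, traces, _ = build_eics(spectra, [728.603], 25)
        feats = detect_peaks(rts, traces[0], target_mz=728.603)
        assert len(feats) == 2

    def test_translation_and_scale_invariance(self):
        spectra = gaussian_run(728.603, rt_apex=6.0)
        rts, traces, _ = build_eics(spectra, [728.603], 25)
        base = detect_peaks(rts, traces[0], target_mz=728.603)
        shifted = detect_peaks(rts + 3.0, traces[0], target_mz=728.603)
        scaled = detect_peaks(rts, traces[0] * 7.0, target_mz=728.603)
        assert shifted[0].rt == pytest.approx(base[0].rt + 3.0)
        assert scaled[0].area == pytest.approx(base[0].area * 7.0, rel=1e-9)
        assert scaled[0].rt == base[0].rt


def _feature(mz, rt, area, adduct=None):
    return Feature(mz=mz, rt=rt, area=area, height=area, rt_start=rt - 0.3,
                   rt_end=rt + 0.3, adduct=adduct)


class TestGroupAdducts:
    def test_coeluting_adducts_summed(self):
        f1 = _feature(728.603, 30.0, 9e5, ADDUCTS["[M+H]+"])
        f2 = _feature(364.805, 30.05, 4e5, ADDUCTS["[M+2H]2+"])
        groups = group_adducts([f1, f2], rt_window=0.2)
        assert len(groups) == 1
        assert groups[0].total_abundance == pytest.approx(1.3e6)

    def test_isomers_at_distinct_rt_stay_separate(self):
        f1 = _feature(728.603, 30.0, 9e5)
        f2 = _feature(728.603, 36.0, 9e5)
        assert len(group_adducts([f1, f2], rt_window=0.2)) == 2

    def test_single_feature_group(self):
        f = _feature(728.603, 30.0, 9e5)
        groups = group_adducts([f])
        assert groups[0].total_abundance == f.area

    def test_abundance_conserved(self):
        rng = np.random.default_rng(3)
        feats = [
            _feature(700 + i, float(rng.uniform(10, 60)), float(rng.uniform(1e4, 1e6)))
            for i in range(30)
        ]
        groups = group_adducts(feats, rt_window=0.5)
        assert sum(g.total_abundance for g in groups) == pytest.approx(
            sum(f.area for f in feats)
        )
        assert sum(len(g.features) for g in groups) == len(feats)


class TestMzmlRoundTrip:
    def test_spectra_survive_write_read(self, tmp_path):
        spectra = gaussian_run(728.603, n_scans=20)
        spectra.append(
            Spectrum(
                "ms2", 2, 0.51,
                np.array([184.073, 264.268, 282.279]),
                np.array([500.0, 900.0, 1000.0]),
                precursor_mz=728.603, precursor_charge=1,
            )
        )
        path = tmp_path / "run.mzML"
        write_mzml(spectra, path)
        back = read_mzml(path)
        assert len(back) == len(spectra)
        ms2 = [s for s in back if s.ms_level == 2]
        assert len(ms2) == 1
        assert ms2[0].precursor_mz == pytest.approx(728.603, abs=1e-5)
        assert ms2[0].precursor_charge == 1
        originals = sorted(spectra, key=lambda s: s.retention_time)
        for a, b in zip(originals, back):
            assert a.retention_time == pytest.approx(b.retention_time, abs=1e-6)
            assert np.allclose(a.mz, b.mz) and np.allclose(a.intensity, b.intensity)
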