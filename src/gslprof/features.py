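"""Molecular feature finding on centroided MS1 data.

Stands in for a vendor "find by molecular feature" step: extract
ppm-windowed ion chromatograms for database targets, detect
chromatographic peaks with trapezoidal areas, attach the MS2 scans
acquired on each feature, and group co-eluting adduct species of one
compound so their areas can be summed into a compound total abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .chem import Adduct

__all__ = [
    "Spectrum",
    "Feature",
    "CompoundFeatureGroup",
    "read_mzml",
    "build_eics",
    "detect_peaks",
    "attach_ms2",
    "group_adducts",
    "DEFAULT_MIN_HEIGHT",
    "DEFAULT_BOUNDARY_FRACTION",
    "DEFAULT_RT_WINDOW",
]

#: MS1 intensity floor (counts); roughly double the baseline noise.
DEFAULT_MIN_HEIGHT = 1000.0
#: Peak bounds are set where intensity drops below this fraction of apex.
DEFAULT_BOUNDARY_FRACTION = 0.1
#: Adduct co-elution window (min).
DEFAULT_RT_WINDOW = 0.2


@dataclass
class Spectrum:
    """One centroided scan; peaks kept sorted by m/z."""

    scan_id: str
    ms_level: int
    retention_time: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None
    precursor_charge: Optional[int] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must align")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def peaks(self) -> List[Tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


@dataclass
class Feature:
    """A chromatographic peak of one target m/z."""

    mz: float  # observed apex m/z
    rt: float  # apex minutes
    area: float  # trapezoidal integral, intensity * min
    height: float
    rt_start: float
    rt_end: float
    adduct: Optional[Adduct] = None
    ms2_scans: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("feature area must be positive")


@dataclass
class CompoundFeatureGroup:
    """Co-eluting adduct features of one compound; areas summed."""

    features: List[Feature]

    @property
    def total_abundance(self) -> float:
        return sum(f.area for f in self.features)

    @property
    def apex_feature(self) -> Feature:
        return max(self.features, key=lambda f: f.area)

    @property
    def rt(self) -> float:
        return self.apex_feature.rt

    @property
    def ms2_scans(self) -> List[str]:
        return [sid for f in self.features for sid in f.ms2_scans]


def read_mzml(path: str | Path) -> List[Spectrum]:
    """Read a centroided mzML file (MS1 + MS2 with precursor annotations)."""
    from .mzml_io import read_mzml as _read

    return _read(path)


def build_eics(
    spectra: Sequence[Spectrum],
    target_mzs: Sequence[float],
    ppm_tol: float = 25.0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extracted-ion chromatograms for each target m/z.

    Returns ``(rts, intensities, observed_mzs)`` where intensities has
    shape (n_targets, n_scans) holding, per scan, the most intense peak
    within ppm_tol of the target (zero where absent), and observed_mzs
    the m/z of that chosen peak.
    """
    ms1 = [s for s in spectra if s.ms_level == 1]
    if not ms1:
        raise ValueError("run contains no MS1 scans")
    targets = np.asarray(target_mzs, dtype=float)
    rts = np.array([s.retention_time for s in ms1])
    traces = np.zeros((targets.size, rts.size))
    obs_mz = np.zeros_like(traces)
    lo_bound = targets * (1 - ppm_tol * 1e-6)
    hi_bound = targets * (1 + ppm_tol * 1e-6)
    for i, scan in enumerate(ms1):
        if scan.mz.size == 0:
            continue
        lo = np.searchsorted(scan.mz, lo_bound, side="left")
        hi = np.searchsorted(scan.mz, hi_bound, side="right")
        for j in np.nonzero(hi > lo)[0]:
            window = scan.intensity[lo[j] : hi[j]]
            k = int(np.argmax(window))
            traces[j, i] = window[k]
            obs_mz[j, i] = scan.mz[lo[j] + k]
    return rts, traces, obs_mz


def detect_peaks(
    rts: np.ndarray,
    trace: np.ndarray,
    min_height: float = DEFAULT_MIN_HEIGHT,
    boundary_fraction: float = DEFAULT_BOUNDARY_FRACTION,
    observed_mz: Optional[np.ndarray] = None,
    target_mz: Optional[float] = None,
) -> List[Feature]:
    """Chromatographic peaks of one EIC trace.

    Local maxima >= min_height become apexes; bounds extend until the
    intensity drops below boundary_fraction * apex or starts rising
    again (local minimum). Area is the trapezoidal integral between
    bounds.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    if trace.max() < min_height:
        return []
    apexes, _ = find_peaks(trace, height=min_height)
    # a peak occupying the first/last scan has no neighbors; include edges
    features: List[Feature] = []
    for apex in apexes:
        floor = boundary_fraction * trace[apex]
        # walk down each flank; a 5% rise tolerance keeps single-scan noise
        # blips from truncating the peak while a true valley still stops it
        left = apex
        while left > 0 and trace[left - 1] >= floor and trace[left - 1] <= trace[left] * 1.05:
            left -= 1
        right = apex
        n = trace.size
        while (
            right < n - 1
            and trace[right + 1] >= floor
            and trace[right + 1] <= trace[right] * 1.05
        ):
            right += 1
        # include one sub-floor bounding point each side for the integral tail
        if left > 0 and trace[left - 1] < floor:
            left -= 1
        if right < n - 1 and trace[right + 1] < floor:
            right += 1
        if right == left:
            continue
        area = float(np.trapezoid(trace[left : right + 1], rts[left : right + 1]))
        if area <= 0:
            continue
        mz = float(observed_mz[apex]) if observed_mz is not None else float(target_mz or 0)
        features.append(
            Feature(
                mz=mz if mz > 0 else float(target_mz or 0),
                rt=float(rts[apex]),
                area=area,
                height=float(trace[apex]),
                rt_start=float(rts[left]),
                rt_end=float(rts[right]),
            )
        )
    return features


def attach_ms2(
    feature: Feature,
    spectra: Sequence[Spectrum],
    ppm_tol: float = 25.0,
    charge: Optional[int] = None,
) -> None:
    """Attach MS2 scans whose precursor matches the feature in m/z and RT."""
    for s in spectra:
        if s.ms_level != 2 or s.precursor_mz is None:
            continue
        if not feature.rt_start - 0.05 <= s.retention_time <= feature.rt_end + 0.05:
            continue
        if abs(s.precursor_mz - feature.mz) / feature.mz * 1e6 <= ppm_tol:
            if charge is None or s.precursor_charge in (None, charge):
                feature.ms2_scans.append(s.scan_id)


def group_adducts(
    features: Sequence[Feature],
    rt_window: float = DEFAULT_RT_WINDOW,
) -> List[CompoundFeatureGroup]:
    """Group co-eluting adduct features of one candidate compound.

    Greedy by area: the most intense ungrouped feature seeds a group and
    absorbs every remaining feature whose apex lies within rt_window;
    each feature joins at most one group. Features at distinct retention
    times (isomers) therefore form distinct groups.
    """
    remaining = sorted(features, key=lambda f: -f.area)
    groups: List[CompoundFeatureGroup] = []
    while remaining:
        seed = remaining.pop(0)
        members = [seed]
        keep: List[Feature] = []
        for f in remaining:
            if abs(f.rt - seed.rt) <= rt_window:
                members.append(f)
            else:
                keep.append(f)
        remaining = keep
        groups.append(CompoundFeatureGroup(members))
    return groups
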