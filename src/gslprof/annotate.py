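"""Feature annotation: precursor matching, library scoring, disambiguation.

A candidate identification collects three kinds of evidence, combined
into a 0-20 composite score patterned on commercial compound-library
scoring so that the familiar "accept at >= 10" operating point is kept:

* fragment component (0-10): the diagnostic-weight fraction of the
  predicted CID ions found in the feature's MS2 spectra at 50 ppm;
* precursor component (0-5): linear in the precursor mass error, full
  marks at 0 ppm, zero at the 25 ppm tolerance;
* RRT component (0-5): linear in the deviation of the observed relative
  retention time (vs the sphingomyelin anchor) from the headgroup
  class's expected RRT.

After scoring, false positives are pruned: PC/PE phospholipid
signatures veto isobaric assignments; candidates explained as in-source
fragments of a co-eluting parent (sulfate or sialic-acid loss, tiny
relative area, wrong own RRT) are removed; and homolog series with at
least three confident members lend their acyl-chain retention fit to
accept precursor-only candidates at the predicted retention time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .chem import ADDUCTS, Adduct, adduct_mz, ppm_error, within_ppm
from .features import (
    CompoundFeatureGroup,
    DEFAULT_BOUNDARY_FRACTION,
    DEFAULT_MIN_HEIGHT,
    DEFAULT_RT_WINDOW,
    Spectrum,
    attach_ms2,
    build_eics,
    detect_peaks,
    group_adducts,
)
from .fragments import (
    FragmentPrediction,
    SO3_MASS,
    flag_contaminant_spectrum,
    predict_fragments,
)
from .rt import AcylRetentionFit, RRTTable, default_rrt_table, fit_acyl_regression, predict_rt
from .structures import GLYCAN_RESIDUES, SphingolipidStructure
from .synth import class_adduct_fractions

__all__ = [
    "AnnotationConfig",
    "AnnotationScore",
    "AnnotatedFeature",
    "match_precursors",
    "score_annotation",
    "resolve_isobars",
    "extrapolate_ids",
    "annotate_run",
    "export_compound_list",
    "load_compound_list",
]

NEU5AC_MASS = GLYCAN_RESIDUES["Neu5Ac"].monoisotopic_mass


@dataclass(frozen=True)
class AnnotationConfig:
    precursor_tol_ppm: float = 25.0
    fragment_tol_ppm: float = 50.0
    score_threshold: float = 10.0
    rrt_tolerance: float = 0.015
    artifact_fraction: float = 0.01
    rt_window: float = DEFAULT_RT_WINDOW
    min_height: float = DEFAULT_MIN_HEIGHT
    boundary_fraction: float = DEFAULT_BOUNDARY_FRACTION
    rt_extrapolation_tol: float = 0.7  # min, for homolog-series acceptance
    min_series_members: int = 3


@dataclass(frozen=True)
class AnnotationScore:
    fragment_component: float  # 0-10
    precursor_component: float  # 0-5
    rt_component: float  # 0-5

    def __post_init__(self) -> None:
        if not (0 <= self.fragment_component <= 10 and 0 <= self.precursor_component <= 5
                and 0 <= self.rt_component <= 5):
            raise ValueError("score component out of range")

    @property
    def total(self) -> float:
        return self.fragment_component + self.precursor_component + self.rt_component


@dataclass
class AnnotatedFeature:
    structure: SphingolipidStructure
    group: CompoundFeatureGroup
    score: AnnotationScore
    observed_rrt: Optional[float]
    expected_rrt: Optional[float]
    ppm: float
    adducts: Tuple[str, ...]
    flags: Set[str] = field(default_factory=set)

    @property
    def name(self) -> str:
        return self.structure.name

    @property
    def rt(self) -> float:
        return self.group.rt

    @property
    def total_abundance(self) -> float:
        return self.group.total_abundance


def match_precursors(
    feature_mz: float,
    database: Sequence[SphingolipidStructure],
    ppm_tol: float = 25.0,
    adducts: Optional[Sequence[Adduct]] = None,
) -> List[Tuple[SphingolipidStructure, Adduct]]:
    """All (structure, adduct) pairs within tolerance; 2+ preferred over 1+."""
    adducts = list(adducts) if adducts is not None else list(ADDUCTS.values())
    hits = [
        (s, a)
        for s in database
        for a in adducts
        if within_ppm(feature_mz, adduct_mz(s.neutral_mass, a), ppm_tol)
    ]
    hits.sort(key=lambda sa: (-sa[1].charge, sa[0].name, sa[1].name))
    return hits


def score_annotation(
    prediction: FragmentPrediction,
    ms2_spectra: Sequence[Spectrum],
    precursor_ppm_error: float,
    observed_rrt: Optional[float],
    expected_rrt_value: Optional[float],
    config: AnnotationConfig = AnnotationConfig(),
) -> AnnotationScore:
    """Composite library score for one candidate at one feature group."""
    if ms2_spectra and prediction.ions:
        matched = 0.0
        for ion in prediction.ions:
            hit = any(
                s.mz.size
                and np.min(np.abs(s.mz - ion.mz)) / ion.mz * 1e6 <= config.fragment_tol_ppm
                for s in ms2_spectra
            )
            if hit:
                matched += ion.diagnostic_weight
        fragment = 10.0 * matched / prediction.total_weight
    else:
        fragment = 0.0
    precursor = 5.0 * max(0.0, 1.0 - abs(precursor_ppm_error) / config.precursor_tol_ppm)
    if observed_rrt is None or expected_rrt_value is None:
        rt_comp = 0.0
    else:
        rt_comp = 5.0 * max(
            0.0, 1.0 - abs(observed_rrt - expected_rrt_value) / config.rrt_tolerance
        )
    return AnnotationScore(fragment, precursor, rt_comp)


def _is_in_source_parent(
    child: AnnotatedFeature, parent: AnnotatedFeature, ppm_tol: float
) -> bool:
    """Can `child`'s mass arise from `parent` by in-source SO3/Neu5Ac loss?"""
    pm = parent.structure.neutral_mass
    cm = child.structure.neutral_mass
    losses = []
    if "sulfate" in parent.structure.headgroup.modifications:
        losses.append(SO3_MASS)
    if parent.structure.headgroup.is_ganglioside:
        losses.append(NEU5AC_MASS)
    return any(within_ppm(cm, pm - loss, ppm_tol) for loss in losses)


def resolve_isobars(
    annotations: Sequence[AnnotatedFeature],
    config: AnnotationConfig = AnnotationConfig(),
) -> List[AnnotatedFeature]:
    """Flag and drop candidates that are in-source fragments of a parent.

    A candidate is reflagged ``in_source_suspect`` when a larger accepted
    parent co-elutes within the rt window, the parent's in-source loss
    (SO3 or one Neu5Ac) explains the candidate's mass, the candidate sits
    away from its own expected RRT, and its area is at most
    ``artifact_fraction`` of the parent's. Candidates scoring at their own
    expected RRT are never removed.
    """
    kept: List[AnnotatedFeature] = []
    for ann in annotations:
        suspect = False
        at_own_rrt = (
            ann.observed_rrt is not None
            and ann.expected_rrt is not None
            and abs(ann.observed_rrt - ann.expected_rrt) <= config.rrt_tolerance
        )
        if not at_own_rrt:
            for parent in annotations:
                if parent is ann or parent.total_abundance <= ann.total_abundance:
                    continue
                if abs(parent.rt - ann.rt) > config.rt_window:
                    continue
                if not _is_in_source_parent(ann, parent, config.precursor_tol_ppm):
                    continue
                if ann.total_abundance <= config.artifact_fraction * parent.total_abundance:
                    suspect = True
                    break
        if suspect:
            ann.flags.add("in_source_suspect")
        else:
            kept.append(ann)
    return kept


def extrapolate_ids(
    accepted: Sequence[AnnotatedFeature],
    rejected: Sequence[AnnotatedFeature],
    config: AnnotationConfig = AnnotationConfig(),
) -> Tuple[List[AnnotatedFeature], Dict[str, AcylRetentionFit]]:
    """Rescue precursor-only homologs via the acyl-chain retention fit.

    Within each (headgroup, LCB) family holding >= 3 confidently
    identified acyl chain lengths, a candidate that matched on precursor
    mass but lacked usable CID is accepted when its retention time lies
    within tolerance of the fitted prediction; it carries the
    ``rt_extrapolated`` flag.
    """
    families: Dict[str, List[AnnotatedFeature]] = {}
    for ann in accepted:
        if ann.score.fragment_component > 0:
            key = f"{ann.structure.headgroup.name}|{ann.structure.lcb.name}"
            families.setdefault(key, []).append(ann)
    fits: Dict[str, AcylRetentionFit] = {}
    for key, members in families.items():
        points = {}
        for m in members:
            points[m.structure.acyl.carbons] = m.rt
        if len(points) >= config.min_series_members:
            fits[key] = fit_acyl_regression(sorted(points.items()), group_id=key)
    rescued: List[AnnotatedFeature] = []
    for ann in rejected:
        if ann.score.fragment_component > 0:
            continue
        key = f"{ann.structure.headgroup.name}|{ann.structure.lcb.name}"
        fit = fits.get(key)
        if fit is None:
            continue
        pred = predict_rt(fit, ann.structure.acyl.carbons)
        if abs(ann.rt - pred.rt) <= config.rt_extrapolation_tol:
            ann.flags.add("rt_extrapolated")
            if pred.extrapolated:
                ann.flags.add("rt_far_extrapolation")
            rescued.append(ann)
    return rescued, fits


def _sm_anchors(
    candidates: Mapping[str, List[Tuple[SphingolipidStructure, CompoundFeatureGroup]]]
) -> Tuple[Optional[float], Dict[str, float]]:
    """Global and per-ceramide SM anchor retention times."""
    best_global: Optional[Tuple[float, float]] = None  # (area, rt)
    by_ceramide: Dict[str, float] = {}
    best_area: Dict[str, float] = {}
    for name, pairs in candidates.items():
        for structure, group in pairs:
            if structure.headgroup.name != "SM":
                continue
            cer = f"{structure.lcb.name}/{structure.acyl.name}"
            if group.total_abundance > best_area.get(cer, 0.0):
                best_area[cer] = group.total_abundance
                by_ceramide[cer] = group.rt
            if best_global is None or group.total_abundance > best_global[0]:
                best_global = (group.total_abundance, group.rt)
    return (best_global[1] if best_global else None), by_ceramide


def annotate_run(
    spectra: Sequence[Spectrum],
    database: Sequence[SphingolipidStructure],
    config: AnnotationConfig = AnnotationConfig(),
    rrt_table: Optional[RRTTable] = None,
) -> List[AnnotatedFeature]:
    """Full per-run pipeline: EICs -> features -> scores -> disambiguation.

    Returns every surviving annotation with score >= threshold (plus
    rt-extrapolated rescues); removed in-source artifacts and contaminant
    vetoes are excluded.
    """
    table = rrt_table or default_rrt_table()
    ms2 = [s for s in spectra if s.ms_level == 2]

    # EIC targets: headgroup-typical adducts per structure
    targets: List[Tuple[SphingolipidStructure, Adduct, float]] = []
    for s in database:
        for adduct_name in class_adduct_fractions(s.headgroup.name):
            adduct = ADDUCTS[adduct_name]
            targets.append((s, adduct, adduct_mz(s.neutral_mass, adduct)))
    # detect features per target, chunked to bound the dense EIC matrices
    per_structure: Dict[str, List[Tuple[SphingolipidStructure, Adduct, float, List]]] = {}
    structure_by_name: Dict[str, SphingolipidStructure] = {}
    chunk_size = 2000
    for start in range(0, len(targets), chunk_size):
        chunk = targets[start : start + chunk_size]
        rts, traces, obs_mz = build_eics(
            spectra, [t[2] for t in chunk], ppm_tol=config.precursor_tol_ppm
        )
        for j, (structure, adduct, mz) in enumerate(chunk):
            feats = detect_peaks(
                rts,
                traces[j],
                min_height=config.min_height,
                boundary_fraction=config.boundary_fraction,
                observed_mz=obs_mz[j],
                target_mz=mz,
            )
            if not feats:
                continue
            for f in feats:
                f.adduct = adduct
            structure_by_name[structure.name] = structure
            per_structure.setdefault(structure.name, []).append((structure, adduct, mz, feats))

    # group adducts per structure, attach MS2
    grouped: Dict[str, List[Tuple[SphingolipidStructure, CompoundFeatureGroup]]] = {}
    for name, target_feats in per_structure.items():
        structure = target_feats[0][0]
        all_feats = [f for _, _, _, feats in target_feats for f in feats]
        for f in all_feats:
            attach_ms2(f, ms2, ppm_tol=config.precursor_tol_ppm)
        groups = group_adducts(all_feats, rt_window=config.rt_window)
        grouped[name] = [(structure, g) for g in groups]

    anchor_global, anchor_by_cer = _sm_anchors(grouped)
    ms2_by_id = {s.scan_id: s for s in ms2}

    annotations: List[AnnotatedFeature] = []
    for name, pairs in grouped.items():
        structure = structure_by_name[name]
        prediction = predict_fragments(structure)
        try:
            exp_rrt = table[structure.headgroup.rrt_class] if structure.headgroup.rrt_class else None
        except KeyError:
            exp_rrt = None
        for structure, group in pairs:
            apex = group.apex_feature
            theo = adduct_mz(structure.neutral_mass, apex.adduct) if apex.adduct else apex.mz
            ppm = ppm_error(apex.mz, theo)
            cer = f"{structure.lcb.name}/{structure.acyl.name}"
            anchor = anchor_by_cer.get(cer, anchor_global)
            observed_rrt = group.rt / anchor if anchor else None
            group_ms2 = [ms2_by_id[sid] for sid in group.ms2_scans if sid in ms2_by_id]
            score = score_annotation(
                prediction, group_ms2, ppm, observed_rrt, exp_rrt, config
            )
            flags: Set[str] = set()
            for spec in group_ms2:
                flags |= flag_contaminant_spectrum(
                    spec.peaks, spec.precursor_mz, config.fragment_tol_ppm
                )
            if "pc_contaminant" in flags and structure.headgroup.name == "SM":
                flags.discard("pc_contaminant")  # odd-nominal SM keeps its 184.1
            annotations.append(
                AnnotatedFeature(
                    structure=structure,
                    group=group,
                    score=score,
                    observed_rrt=observed_rrt,
                    expected_rrt=exp_rrt,
                    ppm=ppm,
                    adducts=tuple(
                        sorted({f.adduct.name for f in group.features if f.adduct})
                    ),
                    flags=flags,
                )
            )

    # One structure per physical peak: the best-scoring annotation claims
    # every member feature of its group, and any lower-scoring annotation
    # whose apex sits on a claimed peak (same m/z, co-eluting) is dropped.
    # The claim radius is wider than one scan because an off-center ppm
    # window on a neighboring near-isobar yields a gap-riddled copy of the
    # same peak whose apparent apex can shift by a few scans.
    annotations.sort(key=lambda a: (-a.score.total, a.name))
    claim_rt = max(0.3, config.rt_window)
    claimed: List[Tuple[float, float, float]] = []  # (rt, mz, claimant score)
    deduped: List[AnnotatedFeature] = []
    for ann in annotations:
        apex = ann.group.apex_feature
        clash = None
        for rt0, mz0, total0 in claimed:
            if abs(apex.rt - rt0) <= claim_rt and abs(apex.mz - mz0) / mz0 * 1e6 <= config.precursor_tol_ppm:
                clash = total0
                break
        if clash is None:
            claimed.extend((f.rt, f.mz, ann.score.total) for f in ann.group.features)
            deduped.append(ann)
        elif abs(ann.score.total - clash) < 1e-9:
            ann.flags.add("tie")
            deduped.append(ann)  # unresolved tie: report both, never break silently
    annotations = deduped

    vetoed = [
        a for a in annotations if {"pc_contaminant", "pe_contaminant"} & a.flags
    ]
    candidates = [a for a in annotations if a not in vetoed]
    survivors = resolve_isobars(candidates, config)
    accepted = [a for a in survivors if a.score.total >= config.score_threshold]
    rejected = [a for a in survivors if a.score.total < config.score_threshold]
    for a in rejected:
        a.flags.add("low_score")

    # candidates sitting on (or in the ragged shoulder of) a peak already
    # explained by an accepted identification are not eligible for the
    # retention-time rescue; a genuine low-abundance homolog has its own m/z
    claimed_accept = [(a.group.apex_feature.rt, f.mz) for a in accepted for f in a.group.features]
    def _on_claimed_peak(ann: AnnotatedFeature) -> bool:
        apex = ann.group.apex_feature
        return any(
            abs(apex.mz - mz0) / mz0 * 1e6 <= config.precursor_tol_ppm
            and abs(apex.rt - rt0) <= 3 * claim_rt
            for rt0, mz0 in claimed_accept
        )

    eligible = [a for a in rejected if not _on_claimed_peak(a)]
    rescued, _ = extrapolate_ids(accepted, eligible, config)
    for a in rescued:
        a.flags.discard("low_score")
    return sorted(accepted + rescued, key=lambda a: (a.rt, a.name))


_LIST_COLUMNS = [
    "name", "formula", "mass", "rt", "rrt", "adducts", "total_abundance", "score", "flags",
]


def export_compound_list(
    annotations: Sequence[AnnotatedFeature], path: str | Path
) -> None:
    """Per-sample compound list CSV (summed adducts, scores, flags)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LIST_COLUMNS)
        for a in annotations:
            writer.writerow(
                [
                    a.name,
                    a.structure.composition.formula(),
                    f"{a.structure.neutral_mass:.4f}",
                    f"{a.rt:.3f}",
                    "" if a.observed_rrt is None else f"{a.observed_rrt:.4f}",
                    ";".join(a.adducts),
                    f"{a.total_abundance:.2f}",
                    f"{a.score.total:.2f}",
                    ";".join(sorted(a.flags)),
                ]
            )


def load_compound_list(path: str | Path) -> Dict[str, float]:
    """name -> total abundance from a compound-list CSV."""
    out: Dict[str, float] = {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                name = row["name"]
                value = float(row["total_abundance"])
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
            if name in out:
                raise ValueError(f"{path}: duplicate structure {name!r} at line {i}")
            out[name] = value
    return out
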