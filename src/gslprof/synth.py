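"""Ground-truthed synthetic nanoLC-MS/MS runs.

Emulates the data this workflow consumes: a 70-minute positive-mode
gradient in which each spiked sphingolipid elutes as a Gaussian peak at
its headgroup's RRT times the sphingomyelin anchor (plus a mild linear
acyl-chain-length shift and jitter), split across the headgroup-typical
adduct/charge species, with rule-generated CID spectra acquired at each
apex, uniform sub-threshold noise peaks, optional in-source artifacts
(sulfatide -> HexCer mass, GD3 -> GM3 mass at <= 1% of the parent) and
sialidase-treated counterpart runs. Every run is a deterministic
function of the seed, and a truth table records injected areas so the
annotation pipeline can be scored against ground truth.

It is a fixture generator, not a physics simulator: no isotope
envelopes, profile-mode peaks, chimeric MS2 or ion-suppression effects.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from math import sqrt, log, pi
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .chem import ADDUCTS, Adduct, adduct_mz
from .features import Spectrum
from .fragments import predict_fragments
from .mzml_io import write_mzml
from .rt import RRTTable, default_rrt_table
from .sialidase import digest_product
from .structures import SphingolipidStructure

__all__ = [
    "ProfileEntry",
    "GroundTruthProfile",
    "class_adduct_fractions",
    "simulate_run",
    "simulate_replicates",
    "treated_profile",
    "decoy_database",
    "default_benchmark_profile",
    "TruthRow",
]


def class_adduct_fractions(headgroup_name: str) -> Dict[str, float]:
    """Headgroup-dependent adduct split.

    Sphingomyelin and the small neutral/sulfated glycolipids ionize as
    singly protonated (with a minor ammonium) species; monosialylated
    gangliosides split between 1+ and 2+; larger polysialylated
    gangliosides are predominantly doubly charged.
    """
    cls = headgroup_name.replace("Fuc-", "")
    if cls.startswith(("GD", "GT", "GQ")):
        return {"[M+2H]2+": 0.60, "[M+H+NH4]2+": 0.25, "[M+2NH4]2+": 0.15}
    if cls.startswith("GM"):
        return {"[M+H]+": 0.40, "[M+2H]2+": 0.45, "[M+H+NH4]2+": 0.15}
    return {"[M+H]+": 0.90, "[M+NH4]+": 0.10}


@dataclass(frozen=True)
class ProfileEntry:
    structure: SphingolipidStructure
    abundance: float  # true total compound abundance (area units)

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")


@dataclass(frozen=True)
class GroundTruthProfile:
    """Injected compounds plus the run parameters that govern the simulation."""

    entries: Tuple[ProfileEntry, ...]
    sm_anchor_rt: float = 45.0  # rt (min) of the SM reference with a C18 acyl
    gradient_minutes: float = 70.0
    scan_interval: float = 0.05  # min between MS1 scans
    peak_sigma: float = 0.15  # chromatographic peak sigma, min
    rt_jitter_sd: float = 0.04  # per-compound rt jitter, min
    acyl_rt_slope: float = 0.08  # min per acyl carbon away from C18
    mz_jitter_ppm: float = 2.0
    intensity_noise_cv: float = 0.02
    noise_peaks_per_scan: int = 30
    noise_mz_range: Tuple[float, float] = (550.0, 2000.0)
    noise_intensity_range: Tuple[float, float] = (50.0, 900.0)
    ms2_base_intensity: float = 20000.0
    ms2_noise_peaks: int = 8
    include_artifacts: bool = False
    artifact_fraction: float = 0.008  # in-source artifact area vs parent
    ms2_dropout: frozenset = frozenset()  # structure names simulated without MS2


@dataclass(frozen=True)
class TruthRow:
    structure_name: str
    adduct: str
    mz: float
    rt: float
    area: float
    kind: str  # 'compound' | 'artifact'


def _entry_rt(profile: GroundTruthProfile, entry: ProfileEntry, rng: np.random.Generator,
              table: RRTTable) -> float:
    rrt = table[entry.structure.headgroup.rrt_class]
    base = profile.sm_anchor_rt + profile.acyl_rt_slope * (entry.structure.acyl.carbons - 18)
    return rrt * base + rng.normal(0.0, profile.rt_jitter_sd)


def _gaussian(rts: np.ndarray, center: float, sigma: float, area: float) -> np.ndarray:
    return area / (sigma * sqrt(2 * pi)) * np.exp(-0.5 * ((rts - center) / sigma) ** 2)


def simulate_run(
    profile: GroundTruthProfile,
    seed: int,
    mzml_path: Optional[str | Path] = None,
    truth_path: Optional[str | Path] = None,
    rrt_table: Optional[RRTTable] = None,
) -> Tuple[List[Spectrum], List[TruthRow]]:
    """Simulate one centroided MS1+MS2 run; optionally write mzML + truth CSV."""
    rng = np.random.default_rng(seed)
    table = rrt_table or default_rrt_table()
    n_scans = int(round(profile.gradient_minutes / profile.scan_interval)) + 1
    scan_rts = np.arange(n_scans) * profile.scan_interval

    # each elution: (structure, adduct, mz, rt_center, area, kind, with_ms2)
    elutions: List[Tuple[SphingolipidStructure, Adduct, float, float, float, str, bool]] = []
    for entry in profile.entries:
        rt_center = _entry_rt(profile, entry, rng, table)
        fractions = class_adduct_fractions(entry.structure.headgroup.name)
        with_ms2 = entry.structure.name not in profile.ms2_dropout
        for adduct_name, fraction in fractions.items():
            adduct = ADDUCTS[adduct_name]
            mz = adduct_mz(entry.structure.neutral_mass, adduct)
            elutions.append(
                (entry.structure, adduct, mz, rt_center, entry.abundance * fraction,
                 "compound", with_ms2)
            )
        if profile.include_artifacts:
            artifact = _in_source_artifact(entry.structure)
            if artifact is not None:
                mz = adduct_mz(artifact.neutral_mass, ADDUCTS["[M+H]+"])
                elutions.append(
                    (artifact, ADDUCTS["[M+H]+"], mz, rt_center,
                     entry.abundance * profile.artifact_fraction, "artifact", True)
                )

    # MS1 scans
    ms1_peaks: List[List[Tuple[float, float]]] = [[] for _ in range(n_scans)]
    truth: List[TruthRow] = []
    for structure, adduct, mz, rt_center, area, kind, _ in elutions:
        heights = _gaussian(scan_rts, rt_center, profile.peak_sigma, area)
        idx = np.nonzero(heights > 1.0)[0]
        for i in idx:
            noisy = heights[i] * (1 + rng.normal(0.0, profile.intensity_noise_cv))
            mz_obs = mz * (1 + rng.normal(0.0, profile.mz_jitter_ppm * 1e-6))
            if noisy > 0:
                ms1_peaks[i].append((mz_obs, noisy))
        truth.append(TruthRow(structure.name, adduct.name, mz, rt_center, area, kind))
    lo_mz, hi_mz = profile.noise_mz_range
    lo_i, hi_i = profile.noise_intensity_range
    for i in range(n_scans):
        for _ in range(profile.noise_peaks_per_scan):
            ms1_peaks[i].append(
                (rng.uniform(lo_mz, hi_mz), rng.uniform(lo_i, hi_i))
            )

    spectra: List[Spectrum] = []
    for i, peaks in enumerate(ms1_peaks):
        mzs = np.array([p[0] for p in peaks]) if peaks else np.empty(0)
        ints = np.array([p[1] for p in peaks]) if peaks else np.empty(0)
        spectra.append(
            Spectrum(f"scan={i + 1}", 1, float(scan_rts[i]), mzs, ints)
        )

    # MS2 scans at each elution apex (one per adduct species)
    ms2_id = n_scans
    ms2_list: List[Spectrum] = []
    for structure, adduct, mz, rt_center, area, kind, with_ms2 in elutions:
        if not with_ms2:
            continue
        prediction = predict_fragments(structure)
        frag_mz = []
        frag_int = []
        for ion in prediction.ions:
            jitter = 1 + rng.normal(0.0, 10e-6)  # fragment mass error, ~10 ppm scale
            frag_mz.append(ion.mz * jitter)
            frag_int.append(
                profile.ms2_base_intensity
                * ion.diagnostic_weight
                * rng.lognormal(0.0, 0.2)
            )
        for _ in range(profile.ms2_noise_peaks):
            frag_mz.append(rng.uniform(100.0, mz))
            frag_int.append(rng.uniform(20.0, 200.0))
        ms2_id += 1
        ms2_list.append(
            Spectrum(
                f"scan={ms2_id}",
                2,
                float(rt_center + profile.scan_interval / 2),
                np.array(frag_mz),
                np.array(frag_int),
                precursor_mz=mz,
                precursor_charge=adduct.charge,
            )
        )
    spectra.extend(ms2_list)
    spectra.sort(key=lambda s: (s.retention_time, s.ms_level))

    if mzml_path is not None:
        write_mzml(spectra, mzml_path)
    if truth_path is not None:
        with open(truth_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["structure", "adduct", "mz", "rt", "area", "kind"])
            for row in truth:
                writer.writerow(
                    [row.structure_name, row.adduct, f"{row.mz:.5f}",
                     f"{row.rt:.4f}", f"{row.area:.2f}", row.kind]
                )
    return spectra, truth


def _in_source_artifact(structure: SphingolipidStructure) -> Optional[SphingolipidStructure]:
    """The smaller compound a labile headgroup mimics after in-source loss.

    Sulfatides lose SO3 (SHex -> Hex mass, SLac -> Lac); polysialylated
    gangliosides lose one terminal Neu5Ac (GD3 -> GM3 mass).
    """
    from .structures import Headgroup, assemble_structure

    hg = structure.headgroup
    if "sulfate" in hg.modifications:
        new_hg = Headgroup(
            name=hg.name.replace("SHex", "Hex").replace("SLac", "Lac"),
            glycan=hg.glycan,
            modifications=hg.modifications - {"sulfate"},
            rrt_class=(hg.rrt_class or "").replace("SHex", "Hex").replace("SLac", "Lac") or None,
            sialic_positions=hg.sialic_positions,
        )
        return assemble_structure(new_hg, structure.lcb, structure.acyl)
    if hg.is_ganglioside and hg.sialic_positions and hg.sialic_positions.get("terminal_gal", 0) == 0:
        # in-source sialic loss mimics the next-lower ganglioside (GD3 -> GM3)
        if hg.name == "GD3":
            from .sialidase import _with_positions

            return assemble_structure(_with_positions(hg, 1, 0), structure.lcb, structure.acyl)
    return None


def simulate_replicates(
    profile: GroundTruthProfile,
    n: int,
    cv: float,
    seed: int,
) -> List[Dict[str, float]]:
    """Per-compound abundances for n replicate injections.

    Multiplicative log-normal noise with the stated coefficient of
    variation (sigma^2 = ln(1 + cv^2), mean-one correction applied).
    """
    if n < 2:
        raise ValueError("replicate simulation needs n >= 2")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = sqrt(log(1 + cv * cv))
    out: List[Dict[str, float]] = []
    for _ in range(n):
        sample = {}
        for entry in profile.entries:
            factor = rng.lognormal(-0.5 * sigma * sigma, sigma) if sigma > 0 else 1.0
            sample[entry.structure.name] = entry.abundance * factor
        out.append(sample)
    return out


def treated_profile(
    profile: GroundTruthProfile, efficiency: float = 1.0
) -> GroundTruthProfile:
    """The neuraminidase-treated counterpart of a profile.

    Terminal-galactose sialic acids are cleaved with the given
    efficiency: the cleaved share of each precursor's abundance moves to
    its digest product (merging with an existing entry when present).
    """
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    totals: Dict[str, float] = {}
    structures: Dict[str, SphingolipidStructure] = {}
    for entry in profile.entries:
        product = digest_product(entry.structure)
        if product.name != entry.structure.name:
            moved = entry.abundance * efficiency
            residual = entry.abundance - moved
            totals[product.name] = totals.get(product.name, 0.0) + moved
            structures[product.name] = product
            if residual > 0:
                totals[entry.structure.name] = totals.get(entry.structure.name, 0.0) + residual
                structures[entry.structure.name] = entry.structure
        else:
            totals[entry.structure.name] = totals.get(entry.structure.name, 0.0) + entry.abundance
            structures[entry.structure.name] = entry.structure
    entries = tuple(
        ProfileEntry(structures[name], ab) for name, ab in sorted(totals.items()) if ab > 0
    )
    return replace(profile, entries=entries)


class DecoyStructure(SphingolipidStructure):
    """A mass-shifted copy of a real structure used to measure false IDs."""

    def __init__(self, base: SphingolipidStructure, delta: float):
        super().__init__(base.headgroup, base.lcb, base.acyl, base.composition)
        object.__setattr__(self, "_delta", delta)

    @property
    def neutral_mass(self) -> float:  # type: ignore[override]
        return self.composition.monoisotopic_mass + self._delta

    @property
    def name(self) -> str:  # type: ignore[override]
        return "DECOY-" + super().name


def decoy_database(
    db: Sequence[SphingolipidStructure], delta: float = 5.0
) -> List[SphingolipidStructure]:
    """Mass-shifted decoy copies of a database (+delta Da on the precursor)."""
    return [DecoyStructure(s, delta) for s in db]


#: (headgroup, lcb, acyl, relative abundance) of the 40-compound benchmark:
#: a brain-like profile dominated by SM, GM1 and GD1 with d18:1/C18-C20
#: lipids, plus the minor LCBs, hydroxylated/long acyls, sulfatides and
#: polysialylated species that exercise every annotation rule.
_BENCHMARK_COMPOUNDS: Tuple[Tuple[str, str, str, float], ...] = (
    ("SM", "d18:1", "C16", 2.0),
    ("SM", "d18:1", "C18", 3.0),
    ("SM", "d18:1", "C20", 1.2),
    ("SM", "d18:1", "C24:1", 1.5),
    ("Hex", "d18:1", "C18", 0.8),
    ("Hex", "d18:1", "C24:1", 0.6),
    ("Hex", "t18:0", "C18", 0.15),
    ("Hex", "d18:1", "C24 OH", 0.25),
    ("SHex", "d18:1", "C18", 0.9),
    ("SHex", "d18:1", "C24:1", 0.5),
    ("SHex", "d18:1", "C24 OH", 0.2),
    ("Lac", "d18:1", "C16", 0.2),
    ("Lac", "d18:1", "C18", 0.4),
    ("Lac", "d18:1", "C24:1", 0.15),
    ("Gb3", "d18:1", "C16", 0.12),
    ("Gb3", "d18:1", "C22", 0.1),
    ("GA1", "d18:1", "C18", 0.1),
    ("GA1", "d18:0", "C18", 0.08),
    ("GM3", "d18:1", "C16", 0.5),
    ("GM3", "d18:1", "C18", 0.7),
    ("GM3", "d18:1", "C20", 0.3),
    ("GM3", "d18:1", "C24:1", 0.25),
    ("GM2", "d18:1", "C18", 0.35),
    ("GM2", "d18:1", "C20", 0.2),
    ("GM1", "d18:1", "C18", 2.5),
    ("GM1", "d18:1", "C20", 1.8),
    ("GM1", "d18:2", "C18", 0.3),
    ("GM1", "t18:0", "C18", 0.2),
    ("GD3", "d18:1", "C18", 0.4),
    ("GD3", "d18:1", "C20", 0.2),
    ("GD1", "d18:1", "C16", 0.6),
    ("GD1", "d18:1", "C18", 3.0),
    ("GD1", "d18:1", "C20", 2.2),
    ("GD1", "t18:1", "C18", 0.25),
    ("GT1", "d18:1", "C18", 1.0),
    ("GT1", "d18:1", "C20", 0.7),
    ("GT1", "d18:0", "C18", 0.12),
    ("GQ1", "d18:1", "C18", 0.3),
    ("GQ1", "d18:1", "C20", 0.18),
    ("SLac", "d18:1", "C18", 0.15),
)


def default_benchmark_profile(
    base_abundance: float = 2.0e6,
    include_artifacts: bool = True,
    **overrides,
) -> GroundTruthProfile:
    """The 40-compound ground-truth profile used for pipeline benchmarking."""
    from .structures import (
        AcylChain,
        LongChainBase,
        assemble_structure,
        default_headgroup_catalog,
    )

    catalog = {hg.name: hg for hg in default_headgroup_catalog()}
    entries = []
    for head, lcb_name, acyl_name, rel in _BENCHMARK_COMPOUNDS:
        structure = assemble_structure(
            catalog[head], LongChainBase.parse(lcb_name), AcylChain.parse(acyl_name)
        )
        entries.append(ProfileEntry(structure, rel * base_abundance))
    return GroundTruthProfile(
        entries=tuple(entries), include_artifacts=include_artifacts, **overrides
    )
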