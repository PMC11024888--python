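"""Rule-based CID fragment prediction for intact sphingolipids.

Positive-mode CID of glycosphingolipids cleaves predominantly at the
glycosidic bonds and at the lipid amide/hydroxyl positions, so a small
set of rules covers the diagnostic ions:

* B-type glycan oxocarbenium ions - the residue-mass sum of a terminal
  sub-composition plus one proton (sialylated B ions also show a water
  loss companion);
* Y-type ions - the protonated precursor after successive neutral losses
  of terminal residues;
* ceramide ions ([Cer+H]+ and its one and two water losses) and the
  long-chain-base pair ([LCB+H-H2O]+, [LCB+H-2H2O]+), which pin down the
  lipid moiety;
* headgroup diagnostics: the phosphocholine 184.1 ion of sphingomyelin,
  the combined H2O + SO3 loss of sulfatides, and the water loss of the
  intact species.

Fragment composition is modeled at the monosaccharide-composition level
(no linkage topology), with B ions capped at four linked residues, which
is the depth CID spectra of these compounds show in practice.

Weights encode qualitative dominance: ceramide/LCB and headgroup
diagnostics are near-obligatory (1.0), glycan B ions strong (0.8),
Y-series moderate (0.6), water losses labile (0.4), and fucose B ions
weak (0.2) because fucose survives poorly as an oxocarbenium ion while
its neutral loss is prominent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .chem import (
    ADDUCTS,
    ElementalComposition,
    PROTON_MASS,
    WATER,
    adduct_mz,
    within_ppm,
)
from .structures import (
    GLYCAN_RESIDUES,
    MODIFICATION_DELTAS,
    LongChainBase,
    SphingolipidStructure,
)

__all__ = [
    "FragmentIon",
    "FragmentPrediction",
    "DEFAULT_WEIGHTS",
    "WATER_MASS",
    "SO3_MASS",
    "PHOSPHOCHOLINE_FRAGMENT_MZ",
    "PE_NEUTRAL_LOSS_MASS",
    "glycan_b_ion",
    "glycan_b_water_loss",
    "lcb_ions",
    "ceramide_ions",
    "predict_fragments",
    "pe_pc_discriminators",
    "flag_contaminant_spectrum",
    "export_fragment_library",
]

WATER_MASS = WATER.monoisotopic_mass
_RESIDUE_MASS = {name: comp.monoisotopic_mass for name, comp in GLYCAN_RESIDUES.items()}
_OAC_MASS = MODIFICATION_DELTAS["O-acetyl"][0].monoisotopic_mass
SO3_MASS = MODIFICATION_DELTAS["sulfate"][0].monoisotopic_mass

#: Protonated phosphocholine cation C5H15NO4P+ (the SM/PC 184.1 diagnostic).
PHOSPHOCHOLINE_FRAGMENT_MZ = (
    ElementalComposition({"C": 5, "H": 14, "N": 1, "O": 4, "P": 1}).monoisotopic_mass
    + PROTON_MASS
)

#: Phosphoethanolamine neutral loss C2H8NO4P flagging PE contaminants.
PE_NEUTRAL_LOSS_MASS = ElementalComposition(
    {"C": 2, "H": 8, "N": 1, "O": 4, "P": 1}
).monoisotopic_mass

DEFAULT_WEIGHTS: Dict[str, float] = {
    "ceramide": 1.0,
    "lcb": 1.0,
    "headgroup_diagnostic": 1.0,
    "glycan_B": 0.8,
    "glycan_Y": 0.6,
    "water_loss": 0.4,
    "fucose_B": 0.2,
}

ION_CLASSES = ("glycan_B", "glycan_Y", "ceramide", "lcb", "headgroup_diagnostic", "water_loss")


@dataclass(frozen=True)
class FragmentIon:
    mz: float
    ion_class: str
    label: str
    diagnostic_weight: float = 1.0
    charge: int = 1

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")
        if self.ion_class not in ION_CLASSES:
            raise ValueError(f"unknown ion class {self.ion_class!r}")
        if not 0 < self.diagnostic_weight <= 1:
            raise ValueError("diagnostic weight must be in (0, 1]")


@dataclass(frozen=True)
class FragmentPrediction:
    structure_name: str
    ions: Tuple[FragmentIon, ...]

    def __post_init__(self) -> None:
        labels = [ion.label for ion in self.ions]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate fragment labels for {self.structure_name}: {dup}")

    @property
    def total_weight(self) -> float:
        return sum(ion.diagnostic_weight for ion in self.ions)


def glycan_b_ion(composition: Mapping[str, int], modification: Optional[str] = None) -> float:
    """m/z of the singly charged B-type oxocarbenium for a residue multiset.

    The value is the dehydrated residue-mass sum plus one proton;
    ``modification='O-acetyl'`` adds the acetyl delta (for OAc-Neu5Ac ions).
    """
    if not composition or sum(composition.values()) == 0:
        raise ValueError("glycan composition must contain at least one residue")
    mz = PROTON_MASS
    for res, n in composition.items():
        if res not in _RESIDUE_MASS:
            raise ValueError(f"unknown glycan residue {res!r}")
        mz += _RESIDUE_MASS[res] * n
    if modification is not None:
        if modification != "O-acetyl":
            raise ValueError(
                f"unsupported B-ion modification {modification!r} (only 'O-acetyl')"
            )
        mz += _OAC_MASS
    return mz


def glycan_b_water_loss(composition: Mapping[str, int], modification: Optional[str] = None) -> float:
    """Water-loss companion of a B ion (prominent for sialylated ions)."""
    return glycan_b_ion(composition, modification) - WATER_MASS


def lcb_ions(lcb: LongChainBase, weight: float = DEFAULT_WEIGHTS["lcb"]) -> List[FragmentIon]:
    """The diagnostic long-chain-base ion pair.

    Unsaturated and tri-hydroxy bases dehydrate readily under CID and
    show [LCB+H-H2O]+ / [LCB+H-2H2O]+. The saturated dihydroxy base
    (d-class, 0 double bonds) instead shows [LCB+H]+ / [LCB+H-H2O]+:
    each dehydration would make its ions isobaric with the corresponding
    sphingosine-base ions and the intact protonated base is what remains
    diagnostic (dihydroceramide d18:0 -> 302.3/284.3).
    """
    base = lcb.composition.monoisotopic_mass + PROTON_MASS
    losses = (0, 1) if (lcb.hydroxyls == 2 and lcb.double_bonds == 0) else (1, 2)
    return [
        FragmentIon(
            base - k * WATER_MASS,
            "lcb",
            f"LCB {lcb.name}" + (f" -{k}H2O" if k else " +H"),
            weight,
        )
        for k in losses
    ]


def ceramide_ions(
    structure: SphingolipidStructure, weight: float = DEFAULT_WEIGHTS["ceramide"]
) -> List[FragmentIon]:
    """[Cer+H]+ and its one and two water losses; headgroup-independent."""
    base = structure.ceramide_composition.monoisotopic_mass + PROTON_MASS
    return [
        FragmentIon(base, "ceramide", "Cer+H", weight),
        FragmentIon(base - WATER_MASS, "ceramide", "Cer+H -H2O", weight),
        FragmentIon(base - 2 * WATER_MASS, "ceramide", "Cer+H -2H2O", weight),
    ]


def _sub_compositions(glycan: Mapping[str, int], cap: int = 4) -> Iterable[Dict[str, int]]:
    """Every non-empty residue sub-multiset of size <= cap (sorted order)."""
    residues = sorted(r for r, n in glycan.items() if n > 0)
    ranges = [range(0, glycan[r] + 1) for r in residues]
    for combo in product(*ranges):
        size = sum(combo)
        if 0 < size <= cap:
            yield {r: c for r, c in zip(residues, combo) if c}


def _loss_sequence(glycan: Mapping[str, int]) -> List[str]:
    """Order in which terminal residues are lost: Fuc, Neu5Ac, then the core
    from the nonreducing end (Hex/HexNAc alternating, innermost Hex last)."""
    seq = ["Fuc"] * glycan.get("Fuc", 0) + ["Neu5Ac"] * glycan.get("Neu5Ac", 0)
    h, n = glycan.get("Hex", 0), glycan.get("HexNAc", 0)
    while h + n > 0:
        if h >= n and h > 0:
            seq.append("Hex")
            h -= 1
        elif n > 0:
            seq.append("HexNAc")
            n -= 1
    return seq


def _label_losses(losses: Mapping[str, int]) -> str:
    return "-" + "-".join(f"{n}{r}" for r, n in sorted(losses.items()))


def predict_fragments(
    structure: SphingolipidStructure,
    weights: Optional[Mapping[str, float]] = None,
    max_b_residues: int = 4,
) -> FragmentPrediction:
    """Diagnostic CID product-ion list for one database structure."""
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    hg = structure.headgroup
    precursor = adduct_mz(structure.neutral_mass, ADDUCTS["[M+H]+"])
    ions: List[FragmentIon] = []

    # intact water loss (for a bare ceramide this is already the Cer -H2O ion)
    if hg.glycan or hg.modifications:
        ions.append(
            FragmentIon(precursor - WATER_MASS, "water_loss", "[M+H-H2O]+", w["water_loss"])
        )

    # ceramide + LCB ions
    ions.extend(ceramide_ions(structure, w["ceramide"]))
    ions.extend(lcb_ions(structure.lcb, w["lcb"]))

    # glycan B ions for terminal sub-compositions
    if hg.glycan:
        oac = "O-acetyl" in hg.modifications
        for sub in _sub_compositions(hg.glycan, cap=max_b_residues):
            label = "B " + "+".join(f"{n}{r}" for r, n in sorted(sub.items()))
            weight = w["fucose_B"] if sub.get("Fuc") else w["glycan_B"]
            ions.append(FragmentIon(glycan_b_ion(sub), "glycan_B", label, weight))
            if sub.get("Neu5Ac"):
                ions.append(
                    FragmentIon(
                        glycan_b_water_loss(sub), "glycan_B", label + " -H2O", w["water_loss"]
                    )
                )
                if oac:
                    ions.append(
                        FragmentIon(
                            glycan_b_ion(sub, "O-acetyl"),
                            "glycan_B",
                            label + " +OAc",
                            w["glycan_B"],
                        )
                    )

        # Y ions: telescoping neutral losses of terminal residues
        lost: Dict[str, int] = {}
        mz = precursor
        seq = _loss_sequence(hg.glycan)
        for res in seq[:-1]:  # Y0 (bare ceramide) is covered by ceramide ions
            lost[res] = lost.get(res, 0) + 1
            mz -= _RESIDUE_MASS[res]
            ions.append(
                FragmentIon(mz, "glycan_Y", "Y " + _label_losses(lost), w["glycan_Y"])
            )

    # headgroup diagnostics
    if "phosphocholine" in hg.modifications:
        ions.append(
            FragmentIon(
                PHOSPHOCHOLINE_FRAGMENT_MZ,
                "headgroup_diagnostic",
                "phosphocholine 184.1",
                w["headgroup_diagnostic"],
            )
        )
    if "sulfate" in hg.modifications:
        ions.append(
            FragmentIon(
                precursor - WATER_MASS - SO3_MASS,
                "headgroup_diagnostic",
                "[M+H-H2O-SO3]+",
                w["headgroup_diagnostic"],
            )
        )

    ions = [ion for ion in ions if ion.mz < precursor]
    return FragmentPrediction(structure.name, tuple(ions))


def pe_pc_discriminators() -> Dict[str, float]:
    """Isobaric-phospholipid signatures used to veto SM/GSL assignments.

    PC contaminants share the 184.1 phosphocholine fragment but, unlike
    sphingomyelin (two nitrogens), give an even protonated nominal mass;
    PE contaminants show a neutral loss of ~141 (phosphoethanolamine).
    """
    return {
        "pc_fragment_mz": PHOSPHOCHOLINE_FRAGMENT_MZ,
        "pe_neutral_loss": PE_NEUTRAL_LOSS_MASS,
    }


def flag_contaminant_spectrum(
    peaks: Sequence[Tuple[float, float]],
    precursor_mz: Optional[float] = None,
    fragment_tol_ppm: float = 50.0,
    min_relative_intensity: float = 0.05,
) -> Set[str]:
    """Flags {'pc_contaminant', 'pe_contaminant'} raised by one MS2 spectrum.

    The PC flag needs both the 184.1 fragment and an even protonated
    nominal precursor mass (an odd one is consistent with SM, no veto).
    """
    flags: Set[str] = set()
    if not peaks:
        return flags
    rules = pe_pc_discriminators()
    base = max(i for _, i in peaks)
    strong = [(mz, i) for mz, i in peaks if i >= min_relative_intensity * base]
    has_pc = any(within_ppm(mz, rules["pc_fragment_mz"], fragment_tol_ppm) for mz, _ in strong)
    if precursor_mz is not None:
        # lipid mass defect stays below +1 Da here, so the nominal mass of
        # the protonated species is the integer part of its m/z
        if has_pc and int(precursor_mz) % 2 == 0:
            flags.add("pc_contaminant")
        target = precursor_mz - rules["pe_neutral_loss"]
        if target > 0 and any(
            within_ppm(mz, target, fragment_tol_ppm) for mz, _ in strong
        ):
            flags.add("pe_contaminant")
    return flags


def export_fragment_library(
    predictions: Iterable[FragmentPrediction], path: str
) -> None:
    """Write the in-silico spectral library as CSV (structure, m/z, label,
    class, weight) - the searchable library the annotator scores against."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["structure_name", "mz", "label", "class", "weight"])
        for pred in predictions:
            for ion in pred.ions:
                writer.writerow(
                    [pred.structure_name, f"{ion.mz:.4f}", ion.label, ion.ion_class, ion.diagnostic_weight]
                )
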