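"""Biosynthetically constrained sphingolipid structure space.

Intact sphingolipids are assembled from three parts: a sphingoid
long-chain base (LCB), an amide-linked N-acyl fatty chain (together the
ceramide), and a polar headgroup (phosphocholine for sphingomyelin, a
phosphate, or a glycan built from Hex / HexNAc / Fuc / Neu5Ac residues,
optionally sulfated, O-acetylated or lactonized). The enumerator applies
the constraints observed in human biosynthesis - 32-44 total lipid
carbons, two to three free hydroxyls and at most three double bonds over
the combined ceramide, with the five human LCBs - and crosses the
resulting ceramides with an editable headgroup catalog to produce the
search-space database used for precursor matching.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

from .chem import ElementalComposition, WATER, monoisotopic_mass, within_ppm

__all__ = [
    "GLYCAN_RESIDUES",
    "MODIFICATION_DELTAS",
    "LongChainBase",
    "AcylChain",
    "Headgroup",
    "SphingolipidStructure",
    "DEFAULT_LCB_NAMES",
    "assemble_structure",
    "enumerate_ceramides",
    "DatabaseRecord",
    "default_headgroup_catalog",
    "load_headgroup_catalog",
    "build_database",
    "export_database_csv",
    "import_database_csv",
]

#: Glycan residue compositions (dehydrated, as incorporated in a chain).
GLYCAN_RESIDUES: Dict[str, ElementalComposition] = {
    "Hex": ElementalComposition({"C": 6, "H": 10, "O": 5}),      # 162.0528
    "HexNAc": ElementalComposition({"C": 8, "H": 13, "N": 1, "O": 5}),  # 203.0794
    "Fuc": ElementalComposition({"C": 6, "H": 10, "O": 4}),      # 146.0579
    "Neu5Ac": ElementalComposition({"C": 11, "H": 17, "N": 1, "O": 8}),  # 291.0954
}

#: Net composition change of each supported headgroup modification.
#: ``lactone`` is a condensation and is *subtracted* (one water).
MODIFICATION_DELTAS: Dict[str, Tuple[ElementalComposition, int]] = {
    "sulfate": (ElementalComposition({"S": 1, "O": 3}), +1),
    "phosphate": (ElementalComposition({"H": 1, "P": 1, "O": 3}), +1),
    # phosphocholine C5H14NO4P condensed onto the C1 hydroxyl (loses H2O)
    "phosphocholine": (ElementalComposition({"C": 5, "H": 12, "N": 1, "O": 3, "P": 1}), +1),
    "O-acetyl": (ElementalComposition({"C": 2, "H": 2, "O": 1}), +1),
    "lactone": (WATER, -1),
}

DEFAULT_LCB_NAMES: Tuple[str, ...] = ("d18:0", "d18:1", "d18:2", "t18:0", "t18:1")


@dataclass(frozen=True)
class LongChainBase:
    """Sphingoid base, named ``d18:1`` style (d = 2 OH, t = 3 OH)."""

    carbons: int
    hydroxyls: int
    double_bonds: int

    def __post_init__(self) -> None:
        if self.hydroxyls not in (2, 3):
            raise ValueError("LCB hydroxyl count must be 2 (d) or 3 (t)")
        if self.carbons < 2 or self.double_bonds < 0:
            raise ValueError("invalid LCB chain")

    @property
    def name(self) -> str:
        prefix = "d" if self.hydroxyls == 2 else "t"
        return f"{prefix}{self.carbons}:{self.double_bonds}"

    @classmethod
    def parse(cls, name: str) -> "LongChainBase":
        prefix, rest = name[0], name[1:]
        if prefix not in ("d", "t") or ":" not in rest:
            raise ValueError(f"cannot parse LCB name {name!r}")
        carbons, db = rest.split(":")
        return cls(int(carbons), 2 if prefix == "d" else 3, int(db))

    @property
    def composition(self) -> ElementalComposition:
        # free amino-polyol base: C_n H_(2n+3-2db) N O_oh
        # (sphingosine d18:1 = C18H37NO2, sphinganine d18:0 = C18H39NO2)
        return ElementalComposition(
            {
                "C": self.carbons,
                "H": 2 * self.carbons + 3 - 2 * self.double_bonds,
                "N": 1,
                "O": self.hydroxyls,
            }
        )


@dataclass(frozen=True)
class AcylChain:
    """N-linked fatty acyl, counted as the free fatty acid."""

    carbons: int
    double_bonds: int = 0
    extra_hydroxyls: int = 0

    def __post_init__(self) -> None:
        if self.extra_hydroxyls not in (0, 1):
            raise ValueError("acyl extra hydroxyls must be 0 or 1")
        if self.carbons < 2 or self.double_bonds < 0:
            raise ValueError("invalid acyl chain")

    @property
    def name(self) -> str:
        base = f"C{self.carbons}" + (f":{self.double_bonds}" if self.double_bonds else "")
        return base + (" OH" if self.extra_hydroxyls else "")

    @classmethod
    def parse(cls, name: str) -> "AcylChain":
        text = name.strip()
        oh = 0
        if text.endswith("OH"):
            oh = 1
            text = text[:-2].strip()
        if not text.startswith("C"):
            raise ValueError(f"cannot parse acyl name {name!r}")
        text = text[1:]
        carbons, _, db = text.partition(":")
        return cls(int(carbons), int(db) if db else 0, oh)

    @property
    def composition(self) -> ElementalComposition:
        # free fatty acid: C_n H_(2n-2db) O_(2+extra)
        return ElementalComposition(
            {
                "C": self.carbons,
                "H": 2 * self.carbons - 2 * self.double_bonds,
                "O": 2 + self.extra_hydroxyls,
            }
        )


@dataclass(frozen=True)
class Headgroup:
    """Polar headgroup: glycan composition plus modifications.

    ``sialic_positions`` records, for gangliosides, how many Neu5Ac sit on
    the terminal galactose (sialidase-cleavable) versus the first core
    galactose (protected); its values must sum to the Neu5Ac count.
    """

    name: str
    glycan: Mapping[str, int] = field(default_factory=dict)
    modifications: FrozenSet[str] = frozenset()
    rrt_class: Optional[str] = None
    sialic_positions: Optional[Mapping[str, int]] = None

    def __post_init__(self) -> None:
        for res, n in self.glycan.items():
            if res not in GLYCAN_RESIDUES:
                raise ValueError(f"unknown glycan residue {res!r}")
            if n < 0:
                raise ValueError(f"negative residue count for {res}")
        for mod in self.modifications:
            if mod not in MODIFICATION_DELTAS:
                raise ValueError(f"unknown modification {mod!r}")
        if self.sialic_positions is not None:
            total = sum(self.sialic_positions.values())
            if total != self.glycan.get("Neu5Ac", 0):
                raise ValueError(
                    f"{self.name}: sialic_positions sum {total} != Neu5Ac count "
                    f"{self.glycan.get('Neu5Ac', 0)}"
                )

    @property
    def n_residues(self) -> int:
        return sum(self.glycan.values())

    @property
    def is_ganglioside(self) -> bool:
        return self.glycan.get("Neu5Ac", 0) > 0

    def composition_delta(self) -> Tuple[ElementalComposition, ElementalComposition]:
        """(added, removed) compositions relative to the bare ceramide."""
        added = ElementalComposition({})
        removed = ElementalComposition({})
        for res, n in self.glycan.items():
            added = added + GLYCAN_RESIDUES[res] * n
        for mod in self.modifications:
            delta, sign = MODIFICATION_DELTAS[mod]
            if sign > 0:
                added = added + delta
            else:
                removed = removed + delta
        return added, removed


@dataclass(frozen=True)
class SphingolipidStructure:
    """One intact structure with derived composition and mass."""

    headgroup: Headgroup
    lcb: LongChainBase
    acyl: AcylChain
    composition: ElementalComposition

    @property
    def name(self) -> str:
        return f"{self.headgroup.name}-{self.lcb.name}/{self.acyl.name}"

    @property
    def neutral_mass(self) -> float:
        return self.composition.monoisotopic_mass

    @property
    def ceramide_composition(self) -> ElementalComposition:
        return self.lcb.composition + self.acyl.composition - WATER

    @property
    def description(self) -> str:
        glycan = " ".join(f"{n}{r}" for r, n in sorted(self.headgroup.glycan.items()) if n)
        mods = "+".join(sorted(self.headgroup.modifications))
        parts = [p for p in (glycan, mods) if p]
        return f"{self.headgroup.name} ({'; '.join(parts) or 'ceramide-only head'})"


def assemble_structure(
    headgroup: Headgroup, lcb: LongChainBase, acyl: AcylChain
) -> SphingolipidStructure:
    """Condense LCB + acyl (amide bond, -H2O) and attach the headgroup."""
    ceramide = lcb.composition + acyl.composition - WATER
    added, removed = headgroup.composition_delta()
    composition = ceramide + added - removed
    return SphingolipidStructure(headgroup, lcb, acyl, composition)


def enumerate_ceramides(
    lcb_set: Iterable[str | LongChainBase] = DEFAULT_LCB_NAMES,
    total_carbons_range: Tuple[int, int] = (32, 44),
    max_double_bonds: int = 3,
    hydroxyl_range: Tuple[int, int] = (2, 3),
) -> List[Tuple[LongChainBase, AcylChain]]:
    """All (LCB, acyl) pairs satisfying the combined-ceramide constraints.

    Constraints apply to the ceramide as a whole: total carbons within
    ``total_carbons_range``, free hydroxyls (LCB + acyl alpha-hydroxy)
    within ``hydroxyl_range``, total double bonds <= ``max_double_bonds``.
    Output order is deterministic (LCB name, then acyl carbons/db/OH).
    """
    lcbs = [
        lcb if isinstance(lcb, LongChainBase) else LongChainBase.parse(lcb)
        for lcb in lcb_set
    ]
    if not lcbs:
        raise ValueError("LCB set must not be empty")
    lo_c, hi_c = total_carbons_range
    lo_oh, hi_oh = hydroxyl_range
    pairs: List[Tuple[LongChainBase, AcylChain]] = []
    for lcb in sorted(lcbs, key=lambda l: l.name):
        for total_c in range(lo_c, hi_c + 1):
            acyl_c = total_c - lcb.carbons
            if acyl_c < 2:
                continue
            for acyl_db in range(0, max_double_bonds - lcb.double_bonds + 1):
                for acyl_oh in (0, 1):
                    if not lo_oh <= lcb.hydroxyls + acyl_oh <= hi_oh:
                        continue
                    pairs.append((lcb, AcylChain(acyl_c, acyl_db, acyl_oh)))
    return pairs


def _parse_positions(core: str, terminal: str) -> Optional[Dict[str, int]]:
    if core == "" and terminal == "":
        return None
    return {"core_gal": int(core or 0), "terminal_gal": int(terminal or 0)}


def load_headgroup_catalog(path: str | Path) -> List[Headgroup]:
    """Read a headgroup catalog CSV (editable; see data/headgroups.csv)."""
    catalog: List[Headgroup] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                glycan = {
                    res: int(row.get(col) or 0)
                    for res, col in (
                        ("Hex", "hex"),
                        ("HexNAc", "hexnac"),
                        ("Fuc", "fuc"),
                        ("Neu5Ac", "neu5ac"),
                    )
                }
                mods = frozenset(
                    m.strip() for m in (row.get("modifications") or "").split(";") if m.strip()
                )
                catalog.append(
                    Headgroup(
                        name=row["name"].strip(),
                        glycan={r: n for r, n in glycan.items() if n},
                        modifications=mods,
                        rrt_class=(row.get("rrt_class") or "").strip() or None,
                        sialic_positions=_parse_positions(
                            (row.get("core_sia") or "").strip(),
                            (row.get("terminal_sia") or "").strip(),
                        ),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: malformed catalog row at line {i}: {exc}") from exc
    return catalog


def default_headgroup_catalog() -> List[Headgroup]:
    """The shipped catalog: SM, 1P, neutral GSL cores, sulfatides, gangliosides."""
    with resources.as_file(
        resources.files("gslprof.data").joinpath("headgroups.csv")
    ) as path:
        return load_headgroup_catalog(path)


def build_database(
    headgroup_catalog: Sequence[Headgroup],
    ceramide_list: Sequence[Tuple[LongChainBase, AcylChain]],
) -> List[SphingolipidStructure]:
    """Cross headgroups with ceramides; deterministic order, unique names."""
    db = [
        assemble_structure(hg, lcb, acyl)
        for hg in headgroup_catalog
        for lcb, acyl in ceramide_list
    ]
    names = [s.name for s in db]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate structure names in database: {dup[:5]}")
    return db


_DB_COLUMNS = ["name", "formula", "mass", "retention_time", "description"]


def export_database_csv(
    db: Sequence[SphingolipidStructure],
    path: str | Path,
    retention_times: Optional[Mapping[str, float]] = None,
) -> None:
    """Write the compound database CSV (name, formula, mass, RT, description)."""
    if not db:
        raise ValueError("refusing to write an empty database")
    retention_times = retention_times or {}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_DB_COLUMNS)
        for s in db:
            rt = retention_times.get(s.name)
            writer.writerow(
                [
                    s.name,
                    s.composition.formula(),
                    f"{s.neutral_mass:.4f}",
                    "" if rt is None else f"{rt:.3f}",
                    s.description,
                ]
            )


@dataclass(frozen=True)
class DatabaseRecord:
    """One imported compound-database row."""

    name: str
    composition: ElementalComposition
    mass: float
    retention_time: Optional[float]
    description: str


def import_database_csv(path: str | Path) -> List[DatabaseRecord]:
    """Read a compound database CSV; warn when formula and mass disagree."""
    records: List[DatabaseRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"name", "formula", "mass"} <= set(
            reader.fieldnames
        ):
            raise ValueError(f"{path}: header must include name, formula, mass")
        for i, row in enumerate(reader, start=2):
            try:
                comp = ElementalComposition.parse(row["formula"].strip())
                mass = float(row["mass"])
                rt_text = (row.get("retention_time") or "").strip()
                rt = float(rt_text) if rt_text else None
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
            if not within_ppm(mass, comp.monoisotopic_mass, 25):
                warnings.warn(
                    f"{path} line {i}: mass {mass} disagrees with formula "
                    f"{row['formula']} ({comp.monoisotopic_mass:.4f}) by > 25 ppm",
                    stacklevel=2,
                )
            records.append(
                DatabaseRecord(
                    row["name"].strip(), comp, mass, rt, (row.get("description") or "").strip()
                )
            )
    return records
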