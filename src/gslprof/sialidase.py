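"""Ganglioside series assignment by neuraminidase differencing.

A broad-specificity alpha-2-3,6,8 neuraminidase removes sialic acids from
the terminal galactose of the ganglio tetrasaccharide, but sialic acids
on the first core galactose are sterically protected and survive, so the
fully desialylated core (GA1) never appears. One enzyme treatment
therefore distinguishes the a/b/c series (1/2/3 core sialic acids),
which reverse-phase chromatography cannot: comparing an untreated and a
treated profile, the configuration whose predicted digest product
matches the observed abundance shifts is the assigned series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .structures import Headgroup, SphingolipidStructure, assemble_structure

__all__ = [
    "digest_product",
    "series_letter",
    "full_series_name",
    "SeriesAssignment",
    "assign_series",
    "DEFAULT_MIN_FOLD_CHANGE",
]

DEFAULT_MIN_FOLD_CHANGE = 2.0

_SIA_PREFIX = {0: "GA", 1: "GM", 2: "GD", 3: "GT", 4: "GQ"}
_CORE_INDEX = {(3, 1): "1", (2, 1): "2", (2, 0): "3"}
_SERIES_LETTER = {1: "a", 2: "b", 3: "c"}


def series_letter(headgroup: Headgroup) -> str:
    """a/b/c from the number of core-galactose sialic acids; '' otherwise."""
    if not headgroup.is_ganglioside or headgroup.sialic_positions is None:
        return ""
    return _SERIES_LETTER.get(headgroup.sialic_positions.get("core_gal", 0), "")


def full_series_name(structure: SphingolipidStructure) -> str:
    """Structure name with the series letter (GD1-d18:1/C18 -> GD1a-d18:1/C18)."""
    hg = structure.headgroup
    letter = series_letter(hg)
    if not letter:
        return structure.name
    return f"{hg.name}{letter}-{structure.lcb.name}/{structure.acyl.name}"


def _ganglio_name(glycan: Mapping[str, int]) -> str:
    neu = glycan.get("Neu5Ac", 0)
    core = (glycan.get("Hex", 0), glycan.get("HexNAc", 0))
    prefix = "Fuc-" * glycan.get("Fuc", 0)
    if neu == 0 and core == (2, 0):
        return prefix + "Lac"
    base = _SIA_PREFIX.get(neu)
    index = _CORE_INDEX.get(core)
    if base is None or index is None:
        residues = "".join(f"{n}{r}" for r, n in sorted(glycan.items()) if n)
        return prefix + f"Glycan[{residues}]"
    return prefix + base + index


def _with_positions(headgroup: Headgroup, core: int, terminal: int) -> Headgroup:
    """A copy of a ganglioside headgroup with re-assigned sialic positions."""
    glycan = dict(headgroup.glycan)
    glycan["Neu5Ac"] = core + terminal
    glycan = {r: n for r, n in glycan.items() if n}
    return Headgroup(
        name=_ganglio_name(glycan),
        glycan=glycan,
        modifications=headgroup.modifications,
        rrt_class=_ganglio_name({k: v for k, v in glycan.items() if k != "Fuc"})
        if glycan.get("Neu5Ac", 0) != headgroup.glycan.get("Neu5Ac", 0)
        else headgroup.rrt_class,
        sialic_positions={"core_gal": core, "terminal_gal": terminal},
    )


def digest_product(structure: SphingolipidStructure) -> SphingolipidStructure:
    """The single-step neuraminidase product of a structure.

    Terminal-galactose sialic acids are removed; core-galactose sialic
    acids are protected and retained; non-gangliosides pass through
    unchanged. Idempotent: the product has no terminal sialic acids left.
    """
    hg = structure.headgroup
    if not hg.is_ganglioside:
        return structure
    if hg.sialic_positions is None:
        raise ValueError(
            f"{structure.name}: ganglioside lacks sialic_positions; cannot apply the digest rule"
        )
    terminal = hg.sialic_positions.get("terminal_gal", 0)
    core = hg.sialic_positions.get("core_gal", 0)
    if terminal == 0:
        return structure
    new_hg = _with_positions(hg, core, 0)
    return assemble_structure(new_hg, structure.lcb, structure.acyl)


@dataclass(frozen=True)
class SeriesAssignment:
    structure_name: str
    series: str  # 'a' | 'b' | 'c' | 'undetermined'
    evidence: Tuple[float, float]  # (precursor fold drop, product fold rise)


def _candidate_positions(n_sialic: int, core_name: str) -> List[Tuple[int, int]]:
    """(core, terminal) configurations compatible with the ganglio pathway.

    At least one sialic acid sits on the core galactose (the biosynthetic
    root of every ganglio series); the core carries at most three.
    """
    return [
        (core, n_sialic - core)
        for core in range(1, min(n_sialic, 3) + 1)
    ]


def _fold(after: float, before: float, floor: float) -> float:
    return (after + floor) / (before + floor)


def assign_series(
    untreated_profile: Mapping[str, float],
    treated_profile: Optional[Mapping[str, float]],
    database: Mapping[str, SphingolipidStructure],
    min_fold_change: float = DEFAULT_MIN_FOLD_CHANGE,
    noise_floor: float = 1.0,
) -> List[SeriesAssignment]:
    """Assign a/b/c series to gangliosides by treated/untreated differencing.

    Gangliosides sharing one ceramide feed each other's digest products
    (GT1b -> GD1b while GD1a -> GM1a), so configurations cannot be judged
    one structure at a time. Within each matched-ceramide group, every
    combination of biosynthetically admissible (core, terminal)
    configurations is digested in silico (single-step, cleaved share
    moved to its product) and the combination whose predicted treated
    pools best match the observed ones - in summed squared log ratio -
    wins. A structure's series is reported only when every near-optimal
    combination agrees on its configuration; if no pool in the group
    shifted by at least ``min_fold_change``, the whole group is
    undetermined.
    """
    if treated_profile is None:
        raise ValueError("treated profile is required for series assignment")
    from itertools import product as iproduct
    from math import log as _log

    # Did the enzyme observably act anywhere? Without a single shifted
    # pool the treated run carries no information (failed digest) and
    # every assignment stays undetermined.
    all_names = set(untreated_profile) | set(treated_profile)
    enzyme_active = any(
        not 1 / min_fold_change
        < _fold(treated_profile.get(n, 0.0), untreated_profile.get(n, 0.0), noise_floor)
        < min_fold_change
        for n in sorted(all_names)
    )

    # group gangliosides by ceramide
    groups: Dict[str, List[str]] = {}
    for name in sorted(untreated_profile):
        s = database.get(name)
        if s is not None and s.headgroup.is_ganglioside:
            groups.setdefault(f"{s.lcb.name}/{s.acyl.name}", []).append(name)

    assignments: List[SeriesAssignment] = []
    for _, names in sorted(groups.items()):
        structures = [database[n] for n in names]
        config_sets = [
            _candidate_positions(s.headgroup.glycan.get("Neu5Ac", 0), s.headgroup.name)
            for s in structures
        ]
        # product names reachable from any configuration
        product_names: Dict[Tuple[str, int, int], str] = {}
        watched = set(names)
        for s, configs in zip(structures, config_sets):
            for core, terminal in configs:
                cand = assemble_structure(
                    _with_positions(s.headgroup, core, terminal), s.lcb, s.acyl
                )
                prod = digest_product(cand)
                product_names[(s.name, core, terminal)] = prod.name
                watched.add(prod.name)

        if not enzyme_active:
            for name in names:
                drop = _fold(untreated_profile.get(name, 0.0),
                             treated_profile.get(name, 0.0), noise_floor)
                assignments.append(SeriesAssignment(name, "undetermined", (drop, 1.0)))
            continue
        # With a demonstrably active enzyme, an unchanged pool is itself
        # informative (all sialic acids protected on the core), so the
        # joint fit runs for every group, shifted or not.

        # score every configuration combination against the observed shifts
        scored: List[Tuple[float, Tuple[Tuple[int, int], ...]]] = []
        for combo in iproduct(*config_sets):
            predicted = {n: untreated_profile.get(n, 0.0) for n in watched}
            for s, (core, terminal) in zip(structures, combo):
                if terminal > 0:
                    moved = untreated_profile.get(s.name, 0.0)
                    predicted[s.name] -= moved
                    predicted[product_names[(s.name, core, terminal)]] += moved
            dist = sum(
                _log(
                    _fold(predicted[n], treated_profile.get(n, 0.0), noise_floor)
                )
                ** 2
                for n in watched
            )
            scored.append((dist, combo))
        scored.sort(key=lambda t: t[0])
        best = scored[0][0]
        near = [combo for dist, combo in scored if dist <= best + 1e-2]
        for i, (s, name) in enumerate(zip(structures, names)):
            options = {combo[i] for combo in near}
            drop = _fold(untreated_profile.get(name, 0.0),
                         treated_profile.get(name, 0.0), noise_floor)
            if len(options) == 1:
                core, terminal = options.pop()
                prod = product_names[(name, core, terminal)]
                rise = _fold(treated_profile.get(prod, 0.0),
                             untreated_profile.get(prod, 0.0), noise_floor)
                assignments.append(
                    SeriesAssignment(
                        name, _SERIES_LETTER.get(core, "undetermined"), (drop, rise)
                    )
                )
            else:
                assignments.append(SeriesAssignment(name, "undetermined", (drop, 1.0)))
    return assignments
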