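"""Relative-retention-time (RRT) model and acyl-chain retention fits.

On the reverse-phase gradient used for intact sphingolipids, retention
is set primarily by the headgroup class and the ceramide chain length.
Sphingomyelin elutes last and anchors the dimensionless RRT scale
(RRT = rt / rt of the SM species with the matching ceramide, falling
back to the run's global SM anchor). Headgroup classes then occupy
reproducible RRT positions (Hex 0.987 ... GQ1 0.700), which both
confirms identifications and vetoes isobars sitting at the wrong RRT.

Within one (headgroup, LCB) family, retention grows linearly with acyl
carbon number, so an ordinary least-squares fit over the confidently
identified members predicts where the low-abundance homologs must
elute. Extra hydroxyls and double bonds shift elution earlier, giving
order checks for LCB isomers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from scipy import stats

from .structures import Headgroup, SphingolipidStructure

__all__ = [
    "DEFAULT_RRT_TOLERANCE",
    "RRTTable",
    "AcylRetentionFit",
    "load_rrt_table",
    "default_rrt_table",
    "expected_rrt",
    "fit_acyl_regression",
    "predict_rt",
    "lcb_elution_check",
]

#: Half the smallest printed inter-class RRT gap (GM2 0.833 vs SLac 0.822).
DEFAULT_RRT_TOLERANCE = 0.015


@dataclass(frozen=True)
class RRTTable:
    """Headgroup class -> expected RRT, with SM anchored at 1.000."""

    values: Dict[str, float]
    tolerance: float = DEFAULT_RRT_TOLERANCE

    def __post_init__(self) -> None:
        for cls, rrt in self.values.items():
            if not 0 < rrt <= 1:
                raise ValueError(f"RRT for {cls} must be in (0, 1], got {rrt}")
        if self.values.get("SM") != 1.0:
            raise ValueError("RRT table must anchor SM at 1.000")

    def __getitem__(self, rrt_class: str) -> float:
        try:
            return self.values[rrt_class]
        except KeyError:
            raise KeyError(
                f"no RRT entry for class {rrt_class!r}; add it to the RRT table"
            ) from None

    def __contains__(self, rrt_class: str) -> bool:
        return rrt_class in self.values


def load_rrt_table(path: str | Path, tolerance: float = DEFAULT_RRT_TOLERANCE) -> RRTTable:
    values: Dict[str, float] = {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                values[row["rrt_class"].strip()] = float(row["rrt"])
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: malformed RRT row at line {i}: {exc}") from exc
    return RRTTable(values, tolerance)


def default_rrt_table(tolerance: float = DEFAULT_RRT_TOLERANCE) -> RRTTable:
    with resources.as_file(resources.files("gslprof.data").joinpath("rrt_table.csv")) as p:
        return load_rrt_table(p, tolerance)


def expected_rrt(headgroup: Headgroup | str, table: Optional[RRTTable] = None) -> float:
    """Expected RRT of a headgroup (or rrt_class name); unknown class raises."""
    table = table or default_rrt_table()
    rrt_class = headgroup if isinstance(headgroup, str) else headgroup.rrt_class
    if rrt_class is None:
        raise KeyError(
            f"headgroup {getattr(headgroup, 'name', headgroup)!r} has no rrt_class"
        )
    return table[rrt_class]


@dataclass(frozen=True)
class AcylRetentionFit:
    """OLS of retention time on acyl carbon number for one class group."""

    group_id: str
    slope: float  # min per carbon
    intercept: float  # min
    r2: float
    stderr: float
    carbon_range: Tuple[int, int]
    n_points: int


def fit_acyl_regression(
    observations: Sequence[Tuple[int, float]], group_id: str = ""
) -> AcylRetentionFit:
    """Fit rt = slope * acyl_carbons + intercept over >= 3 distinct carbons."""
    carbons = [c for c, _ in observations]
    rts = [t for _, t in observations]
    if len(set(carbons)) < 3:
        raise ValueError("acyl regression needs >= 3 distinct carbon counts")
    res = stats.linregress(carbons, rts)
    return AcylRetentionFit(
        group_id=group_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        stderr=float(res.stderr),
        carbon_range=(min(carbons), max(carbons)),
        n_points=len(observations),
    )


@dataclass(frozen=True)
class RTPrediction:
    rt: float
    extrapolated: bool  # > 6 carbons outside the fitted range


def predict_rt(fit: AcylRetentionFit, acyl_carbons: int) -> RTPrediction:
    """Predicted retention time; flagged when far outside the fitted range."""
    lo, hi = fit.carbon_range
    out_of_range = acyl_carbons < lo - 6 or acyl_carbons > hi + 6
    return RTPrediction(fit.slope * acyl_carbons + fit.intercept, out_of_range)


def _lipid_features(s: SphingolipidStructure) -> Tuple[int, int, int, int, int]:
    """(total C, total OH, total db, lcb db, acyl db) of the ceramide."""
    total_c = s.lcb.carbons + s.acyl.carbons
    total_oh = s.lcb.hydroxyls + s.acyl.extra_hydroxyls
    return (total_c, total_oh, s.lcb.double_bonds + s.acyl.double_bonds,
            s.lcb.double_bonds, s.acyl.double_bonds)


def lcb_elution_check(
    structure_a: SphingolipidStructure,
    structure_b: SphingolipidStructure,
    rt_a: float,
    rt_b: float,
) -> bool:
    """Is the observed elution order of two same-headgroup species consistent?

    Rules: more hydroxyls elute earlier; more double bonds elute earlier;
    and for equal totals the d-LCB with the unsaturated acyl (d18:1/FA:1)
    elutes earlier than the di-unsaturated LCB with a saturated acyl
    (d18:2/FA). Pairs the rules cannot order raise ValueError.
    """
    if structure_a.headgroup.name != structure_b.headgroup.name:
        raise ValueError("elution check requires matching headgroups")
    ca, oa, da, lcb_da, _ = _lipid_features(structure_a)
    cb, ob, db_, lcb_db, _ = _lipid_features(structure_b)
    if (ca, oa, da, lcb_da) == (cb, ob, db_, lcb_db):
        return True  # indistinguishable by these rules
    if ca != cb:
        raise ValueError("elution rules compare species of equal total carbon count")
    if oa != ob and da == db_:
        earlier_is_a = oa > ob
    elif da != db_ and oa == ob:
        earlier_is_a = da > db_
    elif oa == ob and da == db_ and lcb_da != lcb_db:
        # same totals: double bond moved between LCB and acyl; the more
        # unsaturated LCB (d18:2/FA) elutes later than d18:1/FA:1
        earlier_is_a = lcb_da < lcb_db
    else:
        raise ValueError("pair differs in both hydroxyls and double bonds; incomparable")
    return (rt_a < rt_b) == earlier_is_a


def compute_rrt(
    rt: float,
    sm_anchor_rt: float,
) -> float:
    """Observed RRT relative to the sphingomyelin anchor of the same run."""
    if sm_anchor_rt <= 0:
        raise ValueError("SM anchor retention time must be positive")
    return rt / sm_anchor_rt
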