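"""Multi-sample aggregation, relative abundances, heatmap filter, %RSD QC.

Per-sample compound lists are merged into one structures-by-samples
matrix (a running union over structure names, absent = 0), columns are
scaled to percent relative abundance, rows below the display floor are
dropped for heatmaps, and replicate groups are summarized as percent
relative standard deviation over the compounds above the QC floor.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotate import load_compound_list
from .rt import default_rrt_table
from .structures import AcylChain, LongChainBase

__all__ = [
    "merge_samples",
    "merge_tables",
    "relative_abundance",
    "heatmap_filter",
    "replicate_rsd",
    "plot_heatmap",
]


def _row_sort_key(name: str):
    """Deterministic row order: headgroup class by RRT (late first), then lipid."""
    table = default_rrt_table()
    head, _, lipid = name.partition("-")
    rrt = table.values.get(head, 0.0)
    lcb_name, _, acyl_name = lipid.partition("/")
    try:
        lcb = LongChainBase.parse(lcb_name)
        acyl = AcylChain.parse(acyl_name)
        lipid_key = (lcb.name, acyl.carbons, acyl.double_bonds, acyl.extra_hydroxyls)
    except (ValueError, IndexError):
        lipid_key = (lipid, 0, 0, 0)
    return (-rrt, head, lipid_key)


def merge_tables(
    samples: Mapping[str, Mapping[str, float]]
) -> pd.DataFrame:
    """Merge {sample -> {structure -> abundance}} into a structures x samples frame."""
    if not samples:
        raise ValueError("no samples to merge")
    frame = pd.DataFrame(samples).fillna(0.0)
    frame = frame.reindex(sorted(frame.index, key=_row_sort_key))
    return frame[list(samples.keys())]


def merge_samples(csv_paths: Sequence[str | Path]) -> pd.DataFrame:
    """Merge per-sample compound-list CSVs (sample name = file stem)."""
    if not csv_paths:
        raise ValueError("no compound lists given")
    samples: Dict[str, Dict[str, float]] = {}
    for path in csv_paths:
        samples[Path(path).stem] = load_compound_list(path)
    return merge_tables(samples)


def relative_abundance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to sum to 100 (percent relative abundance)."""
    sums = matrix.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    return matrix / sums * 100.0


def heatmap_filter(matrix: pd.DataFrame, min_pct: float = 0.01) -> pd.DataFrame:
    """Drop rows whose maximum relative abundance is below ``min_pct`` %."""
    if matrix.empty:
        return matrix
    return matrix[matrix.max(axis=1) >= min_pct]


def replicate_rsd(
    matrix: pd.DataFrame,
    groups: Optional[Mapping[str, Sequence[str]]] = None,
    min_pct: float = 0.1,
) -> Dict[str, Tuple[pd.Series, float]]:
    """%RSD per compound and the group mean over compounds above min_pct.

    Works on the relative-abundance matrix; %RSD = 100 * sd / mean with
    the sample (n-1) standard deviation, restricted to compounds whose
    group-mean relative abundance exceeds ``min_pct`` percent.
    """
    if groups is None:
        groups = {"all": list(matrix.columns)}
    out: Dict[str, Tuple[pd.Series, float]] = {}
    for group, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(f"replicate group {group!r} needs >= 2 samples")
        sub = matrix[list(cols)]
        mean = sub.mean(axis=1)
        keep = mean > min_pct
        if not keep.any():
            out[group] = (pd.Series(dtype=float), float("nan"))
            continue
        sd = sub[keep].std(axis=1, ddof=1)
        rsd = 100.0 * sd / mean[keep]
        out[group] = (rsd, float(rsd.mean()))
    return out


def plot_heatmap(
    matrix: pd.DataFrame,
    path: str | Path,
    min_pct: float = 0.01,
    log_scale: bool = True,
) -> None:
    """Render the filtered relative-abundance matrix as a heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    shown = heatmap_filter(matrix, min_pct)
    if shown.empty:
        raise ValueError("nothing to plot after filtering")
    fig, ax = plt.subplots(
        figsize=(2 + 0.5 * shown.shape[1], 2 + 0.22 * shown.shape[0])
    )
    data = shown.to_numpy()
    norm = LogNorm(vmin=max(min_pct, np.nanmin(data[data > 0])), vmax=data.max()) if log_scale else None
    im = ax.imshow(data, aspect="auto", cmap="viridis", norm=norm)
    ax.set_xticks(range(shown.shape[1]), shown.columns, rotation=45, ha="right")
    ax.set_yticks(range(shown.shape[0]), shown.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="relative abundance (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
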