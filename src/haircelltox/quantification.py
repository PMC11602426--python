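"""Per-vesicle / per-neuromast property tables and accumulation statistics.

Vesicle records (volume, centroid, per-channel mean/total intensity, cell
assignment by majority overlap), neuromast-level summaries matching the
figure conventions (vesicles per hair cell, vesicle volume and
fluorescence per hair cell), the vesicle-to-cytoplasm AG enrichment
ratio, and two-group tests (exact Mann-Whitney for small samples,
t-tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy import stats
from skimage.measure import regionprops_table

from .io import VoxelStack
from .segmentation import LabelVolume

__all__ = [
    "NeuromastSummary",
    "vesicle_table",
    "per_neuromast_stats",
    "compartment_ratio",
    "group_compare",
]


def vesicle_table(
    vesicles: LabelVolume,
    stack: VoxelStack,
    cells: LabelVolume | None = None,
    neuromast_id: int = 1,
) -> pd.DataFrame:
    """One record per vesicle label.

    Columns: vesicle_id, neuromast_id, cell_id (majority-overlap when
    cell labels are given, 0 if unassigned), volume_voxels, volume_um3,
    centroid z/y/x, and mean_/total_ intensity per channel.  An empty
    label volume yields an empty table, not an error.
    """
    labels = vesicles.labels
    ids = np.unique(labels[labels > 0])
    cols = ["vesicle_id", "neuromast_id", "cell_id", "volume_voxels", "volume_um3",
            "centroid_z", "centroid_y", "centroid_x"]
    for name in stack.channel_names:
        cols += [f"mean_{name}", f"total_{name}"]
    if ids.size == 0:
        return pd.DataFrame(columns=cols)

    props = regionprops_table(labels, properties=("label", "area", "centroid"))
    df = pd.DataFrame(
        {
            "vesicle_id": props["label"],
            "neuromast_id": neuromast_id,
            "volume_voxels": props["area"].astype(int),
            "centroid_z": props["centroid-0"],
            "centroid_y": props["centroid-1"],
            "centroid_x": props["centroid-2"],
        }
    )
    df["volume_um3"] = df["volume_voxels"] * stack.voxel_volume_um3

    for name in stack.channel_names:
        chan = stack.channel(name)
        if chan.ndim == 4:  # time-lapse: use first frame
            chan = chan[0]
        df[f"mean_{name}"] = ndi.mean(chan, labels, index=df["vesicle_id"])
        df[f"total_{name}"] = ndi.sum_labels(chan, labels, index=df["vesicle_id"])

    if cells is not None:
        assignments = []
        cell_labels = cells.labels
        for vid in df["vesicle_id"]:
            overlap = cell_labels[labels == vid]
            overlap = overlap[overlap > 0]
            assignments.append(int(np.bincount(overlap).argmax()) if overlap.size else 0)
        df["cell_id"] = assignments
    else:
        df["cell_id"] = 0
    return df[cols]


@dataclass
class NeuromastSummary:
    """Neuromast-level accumulation summary.

    ``vesicle_volume_mean`` and ``vesicle_fluorescence_mean`` are
    per-hair-cell aggregates (total vesicle volume / fluorescence divided
    by the number of cells), matching how vesicle burden is reported per
    neuromast; per-vesicle means are carried alongside.
    """

    n_cells: int
    n_vesicles: int
    vesicles_per_cell_mean: float
    vesicle_volume_mean: float  # um^3 per hair cell
    vesicle_fluorescence_mean: float  # total AG per hair cell
    volume_per_vesicle_mean: float
    fluorescence_per_vesicle_mean: float
    total_AG_fluorescence: float
    ratio_vesicle_to_cytoplasm: float | None = None


def per_neuromast_stats(
    records: pd.DataFrame,
    cells: LabelVolume,
    ag_channel: str = "ag",
    stack: VoxelStack | None = None,
    neuromast: LabelVolume | None = None,
    vesicles: LabelVolume | None = None,
) -> NeuromastSummary:
    """Aggregate vesicle records for one neuromast.

    Requires >=1 cell.  With the stack and masks given, also reports the
    total AG fluorescence over the neuromast mask and the
    vesicle-to-cytoplasm ratio.  An empty vesicle table gives zero counts
    and NaN (flagged) vesicle means.
    """
    n_cells = cells.n_labels
    if n_cells == 0:
        raise ValueError("zero cells: per-cell statistics undefined")
    n_ves = len(records)
    total_col = f"total_{ag_channel}"
    if n_ves:
        total_volume = float(records["volume_um3"].sum())
        total_fluor = float(records[total_col].sum())
    else:
        total_volume = total_fluor = 0.0

    total_ag = np.nan
    ratio = None
    if stack is not None and neuromast is not None:
        chan = stack.channel(ag_channel)
        if chan.ndim == 4:
            chan = chan[0]
        total_ag = float(chan[neuromast.mask].sum())
        if vesicles is not None:
            from .segmentation import make_cytoplasm_mask

            cyto = make_cytoplasm_mask(neuromast, vesicles)
            if vesicles.mask.any() and cyto.mask.any():
                ratio = compartment_ratio(chan, vesicles, cyto)

    return NeuromastSummary(
        n_cells=n_cells,
        n_vesicles=n_ves,
        vesicles_per_cell_mean=n_ves / n_cells,
        vesicle_volume_mean=total_volume / n_cells if n_ves else np.nan,
        vesicle_fluorescence_mean=total_fluor / n_cells if n_ves else np.nan,
        volume_per_vesicle_mean=total_volume / n_ves if n_ves else np.nan,
        fluorescence_per_vesicle_mean=total_fluor / n_ves if n_ves else np.nan,
        total_AG_fluorescence=total_ag,
        ratio_vesicle_to_cytoplasm=ratio,
    )


def compartment_ratio(
    ag: np.ndarray,
    vesicles: LabelVolume | np.ndarray,
    cytoplasm: LabelVolume | np.ndarray,
    statistic: str = "mean",
) -> float:
    """AG enrichment in the vesicular compartment over the cytoplasm.

    ``mean`` (default) compares mean voxel intensities, a
    concentration-style comparison insensitive to compartment volume;
    ``total`` compares summed intensities.
    """
    ves = vesicles.mask if isinstance(vesicles, LabelVolume) else np.asarray(vesicles) > 0
    cyto = cytoplasm.mask if isinstance(cytoplasm, LabelVolume) else np.asarray(cytoplasm) > 0
    ag = np.asarray(ag, dtype=float)
    if not ves.any() or not cyto.any():
        raise ValueError("both compartments must be non-empty")
    if statistic == "mean":
        return float(ag[ves].mean() / ag[cyto].mean())
    if statistic == "total":
        return float(ag[ves].sum() / ag[cyto].sum())
    raise ValueError("statistic must be 'mean' or 'total'")


def group_compare(
    values_a: np.ndarray,
    values_b: np.ndarray,
    test: str = "mann_whitney",
) -> tuple[float, float]:
    """Two-group comparison: (statistic, two-sided p-value).

    ``mann_whitney`` uses the exact null distribution when both groups
    have n <= 12 and the normal approximation above; ``t_test`` is the
    unpaired two-sample t-test, ``t_test_paired`` the paired variant.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if test == "mann_whitney":
        method = "exact" if max(len(a), len(b)) <= 12 else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    elif test == "t_test":
        res = stats.ttest_ind(a, b)
    elif test == "t_test_paired":
        res = stats.ttest_rel(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
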