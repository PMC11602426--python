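"""End-to-end segmentation + quantification convenience wrappers.

Thin glue over :mod:`imaging`, :mod:`segmentation` and
:mod:`quantification` so analysis drivers, tests and benchmarks run the
identical chain: normalize -> neuromast mask -> hair-cell labels (seeded
watershed over the neuromast region) -> vesicle labels -> cytoplasm mask
-> vesicle table -> neuromast summary, with the mask-partition invariant
asserted on every run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import normalize_intensity
from .io import VoxelStack
from .quantification import NeuromastSummary, per_neuromast_stats, vesicle_table
from .segmentation import (
    LabelVolume,
    SeedSet,
    SegmentationParams,
    assert_mask_partition,
    make_cytoplasm_mask,
    params_at_voxel_size,
    segment_hair_cells,
    segment_neuromast,
    segment_vesicles,
)

__all__ = ["SegmentationResult", "run_segmentation", "benchmark_params"]


def benchmark_params() -> SegmentationParams:
    """Segmentation parameters for the phantom benchmark.

    Published pixel-unit parameters rescaled to the phantom voxel size
    (0.25 um/px in-plane), with detector (scale, cutoff) pairs matched to
    the phantom vesicle sizes (radius 0.35-0.55 um).
    """
    return params_at_voxel_size(
        0.25,
        base=SegmentationParams(
            dot_pairs=[(4.0, 0.25), (2.0, 0.25)],
            filament_pairs=[(2.0, 0.3)],
        ),
    )


@dataclass
class SegmentationResult:
    neuromast: LabelVolume
    cells: LabelVolume
    vesicles: LabelVolume
    cytoplasm: LabelVolume
    vesicle_records: pd.DataFrame
    summary: NeuromastSummary


def run_segmentation(
    stack: VoxelStack,
    seeds: SeedSet,
    params: SegmentationParams | None = None,
    reporter_channel: str = "reporter",
    ag_channel: str = "ag",
    clip_percentiles: tuple[float, float] = (0.0, 99.9),
) -> SegmentationResult:
    """Run the full segmentation + quantification chain on a 2-channel stack.

    Parameters default to the published values rescaled to the stack's
    in-plane voxel size.  Hair cells are labelled over the neuromast
    region (inverted-neuromast background route); vesicles are detected
    on the normalized AG channel and restricted to the neuromast mask.
    """
    if params is None:
        params = params_at_voxel_size(stack.voxel_size_um[2])
    reporter = normalize_intensity(np.asarray(stack.channel(reporter_channel)), clip_percentiles)
    ag = normalize_intensity(np.asarray(stack.channel(ag_channel)), clip_percentiles)

    neuromast = segment_neuromast(reporter, params, voxel_size_um=stack.voxel_size_um)
    cells = segment_hair_cells(reporter, seeds, params, region=neuromast)
    vesicles = segment_vesicles(ag, params, neuromast, clip_to_neuromast=True)
    cytoplasm = make_cytoplasm_mask(neuromast, vesicles)
    assert_mask_partition(neuromast, vesicles, cytoplasm)

    records = vesicle_table(vesicles, stack, cells=cells)
    summary = per_neuromast_stats(
        records, cells, ag_channel=ag_channel, stack=stack,
        neuromast=neuromast, vesicles=vesicles,
    )
    return SegmentationResult(neuromast, cells, vesicles, cytoplasm, records, summary)
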