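"""Synthetic data with known ground truth.

Three phantom families stand in for the study's raw data:

* **image phantoms** — neuromast rosettes of pear-shaped (ellipsoidal)
  hair cells arranged in a ring, with intracellular vesicles carrying the
  aminoglycoside (AG) signal and an adjustable diffuse cytoplasmic
  fraction (punctate G418-like vs mixed diffuse+punctate neomycin-like
  distributions; a GPN-like variant halves the vesicle count at conserved
  total signal);
* **calcium traces** — per-cell intensity time series sampled at 30-s
  intervals with a 2.5-min (5-frame) baseline, an optional suprathreshold
  transient, and a fragmentation endpoint for dying cells;
* **count tables** — per-fish hair-cell counts (4 neuromasts summed)
  under a Hill dose-response with beta-binomial fish-to-fish
  overdispersion, plus time-course and protection-arm variants.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .io import VoxelStack
from .segmentation import LabelVolume, SeedSet

__all__ = [
    "StackPhantomParams",
    "TracePhantomParams",
    "CountPhantomParams",
    "PhantomTruth",
    "gen_neuromast_stack",
    "gen_timelapse",
    "gen_calcium_traces",
    "gen_doseresponse_counts",
    "gen_timecourse_counts",
    "gen_protection_counts",
    "gpn_like",
    "hill_survival",
]


class PhantomSizingError(ValueError):
    """Requested geometry does not fit the voxel grid."""


# --------------------------------------------------------------------------
# image phantoms
# --------------------------------------------------------------------------

@dataclass
class StackPhantomParams:
    """Geometry, signal and noise of the neuromast image phantom.

    ``vesicles_per_cell`` is a (mean, dispersion) pair for a negative
    binomial draw per cell (dispersion 0 = Poisson).  ``diffuse_fraction``
    is the fraction of total AG signal placed uniformly in the cytoplasm
    rather than in vesicles.  ``snr`` is (mean in-structure signal -
    background) / read-noise SD; ``None`` disables noise entirely.
    """

    n_cells: int = 12
    cell_radius_um: float = 4.0
    vesicles_per_cell: tuple[float, float] = (5.0, 0.1)  # (mean, dispersion)
    vesicle_radius_um: tuple[float, float] = (0.35, 0.55)
    diffuse_fraction: float = 0.15
    snr: float | None = 20.0
    voxel_size_um: tuple[float, float, float] = (0.3, 0.25, 0.25)
    shape_px: tuple[int, int, int] = (40, 128, 128)
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0)
    seed: int = 0
    # secondary knobs (fixed study conditions, rarely touched)
    cell_elongation_z: float = 1.3
    rosette_ring_factor: float = 1.6  # ring radius / in-plane cell radius
    membrane_dip: float = 0.3  # reporter attenuation at cell-cell interfaces
    ag_vesicle_amplitude: float = 1.0
    reporter_amplitude: float = 1.0
    photon_gain: float = 500.0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.diffuse_fraction <= 1.0:
            raise ValueError("diffuse_fraction must be in [0, 1]")
        if self.vesicles_per_cell[0] < 0 or self.vesicles_per_cell[1] < 0:
            raise ValueError("vesicles_per_cell mean and dispersion must be >= 0")
        lo, hi = self.vesicle_radius_um
        if not 0 < lo <= hi:
            raise ValueError("vesicle_radius_um must be a positive (low, high) range")


def gpn_like(params: StackPhantomParams) -> StackPhantomParams:
    """GPN-regime variant: half the vesicle count, double per-vesicle volume.

    Voxelwise vesicle intensity is unchanged, so the expected total AG
    signal is conserved while the number of vesicles halves (fewer,
    larger vesicles).
    """
    mean, disp = params.vesicles_per_cell
    lo, hi = params.vesicle_radius_um
    k = 2.0 ** (1.0 / 3.0)
    return replace(
        params,
        vesicles_per_cell=(mean / 2.0, disp),
        vesicle_radius_um=(lo * k, hi * k),
    )


@dataclass
class PhantomTruth:
    """Ground truth attached to a generated image phantom."""

    neuromast: LabelVolume
    cells: LabelVolume
    vesicles: LabelVolume
    vesicle_table: pd.DataFrame  # vesicle_id, cell_id, centroid, radius, volume, total AG
    cell_centroids: np.ndarray  # (n, 3)
    cell_table: pd.DataFrame | None = None  # cell_id, drawn_vesicles, placed_vesicles

    @property
    def seeds(self) -> SeedSet:
        return SeedSet(self.cell_centroids, source="ground-truth")


def _cell_geometry(params: StackPhantomParams):
    vz, vy, vx = params.voxel_size_um
    nz, ny, nx = params.shape_px
    r_xy = params.cell_radius_um / vx
    r_z = params.cell_elongation_z * params.cell_radius_um / vz
    n = params.n_cells
    # overlapping rosette: neighbouring cells interpenetrate and meet near the
    # centre (wedge shapes after nearest-centre assignment), as in real
    # neuromasts where hair cells converge apically
    ring = 0.0 if n == 1 else params.rosette_ring_factor * r_xy
    margin = 4.0
    if ring + r_xy + margin > min(ny, nx) / 2 or 2 * r_z + 2 > nz:
        raise PhantomSizingError(
            f"{n} cells of radius {params.cell_radius_um} um do not fit shape {params.shape_px}"
        )
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    angles = 2 * np.pi * np.arange(n) / max(n, 1)
    centres = np.stack(
        [np.full(n, cz), cy + ring * np.sin(angles), cx + ring * np.cos(angles)], axis=1
    )
    return centres, (r_z, r_xy, r_xy)


def _cell_metric(zz, yy, xx, centre, axes):
    """Superellipsoid membership metric: quartic along z (flat caps), quadratic
    in-plane; <= 1 inside the cell."""
    cz, cy, cx = centre
    az, ay, ax = axes
    return (np.abs(zz - cz) / az) ** 4 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2


def gen_neuromast_stack(
    params: StackPhantomParams,
) -> tuple[VoxelStack, PhantomTruth]:
    """Generate a 2-channel (reporter, ag) neuromast phantom with ground truth.

    Cells are overlapping superellipsoids in a rosette ring, resolved to
    wedge-shaped territories by nearest normalized centre, with dim
    membrane bands at cell-cell interfaces; the ground-truth neuromast
    mask is the slice-wise hole-filled union of the cells, and every
    vesicle lies strictly inside one cell.  The vesicle table lists
    per-vesicle centroid, radius, voxel volume and total AG signal
    (noise-free rendered sum).
    """
    rng = np.random.default_rng(params.seed)
    nz, ny, nx = params.shape_px
    vz, vy, vx = params.voxel_size_um
    centres, (az, ay, ax) = _cell_geometry(params)

    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij", sparse=True
    )

    # cell labels: inside-superellipsoid membership, overlaps resolved to the
    # nearest normalized centre (wedge-shaped cells in the rosette interior)
    best = np.full(params.shape_px, np.inf)
    cells = np.zeros(params.shape_px, dtype=np.int32)
    for i, centre in enumerate(centres, start=1):
        d2 = _cell_metric(zz, yy, xx, centre, (az, ay, ax))
        inside = d2 <= 1.0
        closer = inside & (d2 < best)
        cells[closer] = i
        best = np.where(closer, d2, best)
    union = cells > 0

    neuromast = np.empty_like(union)
    for z in range(nz):
        neuromast[z] = ndi.binary_fill_holes(union[z])

    # vesicles: negative-binomial count per cell, centres inside a shrunken
    # ellipsoid with a minimum pairwise separation so vesicles stay resolvable
    mean, disp = params.vesicles_per_cell
    counts = _nb_draw(rng, mean, disp, params.n_cells)
    lo, hi = params.vesicle_radius_um
    placed: list[tuple[np.ndarray, float, int]] = []  # (centre_px, radius_um, cell_id)
    for i in range(1, params.n_cells + 1):
        # candidate sites: this cell's wedge interior, away from the membrane
        sites = np.argwhere((cells == i) & (best <= 0.6))
        if len(sites) == 0:
            continue
        for _ in range(int(counts[i - 1])):
            radius = rng.uniform(lo, hi)
            for _attempt in range(500):
                cand = sites[rng.integers(len(sites))] + rng.uniform(-0.5, 0.5, 3)
                if _separated(cand, radius, placed, params.voxel_size_um):
                    placed.append((cand, radius, i))
                    break
            # unplaceable vesicles are dropped (crowded cell); counts table is realized truth

    vesicle_labels = np.zeros(params.shape_px, dtype=np.int32)
    ag = np.zeros(params.shape_px)
    records = []
    voxel = np.array([vz, vy, vx])
    psf_sigma_px = 0.35  # light optical blur on the rendered spheres
    skirt_um = 0.1  # ground-truth mask extends past the core by the blur skirt
    for vid, (centre, radius, cell_id) in enumerate(placed, start=1):
        half = np.ceil((radius + skirt_um) / voxel + 4 * psf_sigma_px).astype(int) + 1
        ci = np.round(centre).astype(int)
        sl = tuple(
            slice(max(0, ci[a] - half[a]), min(params.shape_px[a], ci[a] + half[a] + 1))
            for a in range(3)
        )
        lz, ly, lx = np.meshgrid(
            np.arange(sl[0].start, sl[0].stop),
            np.arange(sl[1].start, sl[1].stop),
            np.arange(sl[2].start, sl[2].stop),
            indexing="ij",
            sparse=True,
        )
        d2_um = (
            ((lz - centre[0]) * vz) ** 2
            + ((ly - centre[1]) * vy) ** 2
            + ((lx - centre[2]) * vx) ** 2
        )
        sphere = (d2_um <= (radius + skirt_um) ** 2) & (cells[sl] == cell_id)
        vesicle_labels[sl][sphere] = vid
        core = (d2_um <= radius**2).astype(float)
        blob = params.ag_vesicle_amplitude * ndi.gaussian_filter(core, psf_sigma_px)
        ag[sl] += blob
        records.append(
            {
                "vesicle_id": vid,
                "cell_id": cell_id,
                "z": centre[0],
                "y": centre[1],
                "x": centre[2],
                "radius_um": radius,
                "volume_voxels": int(sphere.sum()),
                "total_ag": float(blob.sum()),
            }
        )
    vesicle_table = pd.DataFrame(
        records,
        columns=["vesicle_id", "cell_id", "z", "y", "x", "radius_um", "volume_voxels", "total_ag"],
    )

    # diffuse cytoplasmic AG: diffuse_fraction of the total AG signal
    total_vesicle_signal = float(ag.sum())
    cyto = union & (vesicle_labels == 0)
    if params.diffuse_fraction > 0 and cyto.any() and total_vesicle_signal > 0:
        budget = params.diffuse_fraction / (1 - params.diffuse_fraction) * total_vesicle_signal
        ag[cyto] += budget / cyto.sum()
    elif params.diffuse_fraction > 0 and cyto.any():
        ag[cyto] += params.ag_vesicle_amplitude * 0.05

    # heterogeneous reporter: per-cell expression level (lognormal) with an
    # intracellular gradient, brighter at the cell centre — as in real
    # cytoplasmic transgene images, where intensity varies cell to cell
    cell_amp = params.reporter_amplitude * np.exp(rng.normal(0.0, 0.25, params.n_cells + 1))
    cell_amp[0] = 0.0
    radial = np.clip(1.0 - best, 0.0, 1.0)  # 1 at centre, 0 at membrane
    reporter = cell_amp[cells] * (0.5 + 0.5 * radial)
    # dim membrane band (~2 px) at cell-cell interfaces, as between real cells
    if params.n_cells > 1 and params.membrane_dip < 1.0:
        fp = np.ones((3, 5, 5), dtype=bool)
        hi_lab = ndi.maximum_filter(cells, footprint=fp)
        lo_lab = -ndi.maximum_filter(-np.where(cells > 0, cells, np.iinfo(np.int32).max), footprint=fp)
        interface = (cells > 0) & (hi_lab != lo_lab)
        reporter[interface] *= params.membrane_dip

    if params.snr is not None and np.isfinite(params.snr):
        read_sd = params.reporter_amplitude / params.snr
        g = params.photon_gain
        reporter = rng.poisson(np.clip(reporter, 0, None) * g) / g + rng.normal(
            0, read_sd, reporter.shape
        )
        ag = rng.poisson(np.clip(ag, 0, None) * g) / g + rng.normal(0, read_sd, ag.shape)

    stack = VoxelStack(
        np.stack([reporter, ag])[None],
        ("reporter", "ag"),
        params.voxel_size_um,
    )
    placed_per_cell = (
        vesicle_table["cell_id"].value_counts() if len(vesicle_table) else pd.Series(dtype=int)
    )
    cell_table = pd.DataFrame(
        {
            "cell_id": np.arange(1, params.n_cells + 1),
            "drawn_vesicles": counts.astype(int),
            "placed_vesicles": [
                int(placed_per_cell.get(i, 0)) for i in range(1, params.n_cells + 1)
            ],
        }
    )
    truth = PhantomTruth(
        neuromast=LabelVolume(neuromast, "neuromast", {"source": "ground-truth"}),
        cells=LabelVolume(cells, "cells", {"source": "ground-truth"}),
        vesicles=LabelVolume(vesicle_labels, "vesicles", {"source": "ground-truth"}),
        vesicle_table=vesicle_table,
        cell_centroids=centres,
        cell_table=cell_table,
    )
    return stack, truth


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, n: int) -> np.ndarray:
    if n == 0:
        return np.zeros(0, dtype=int)
    if mean == 0:
        return np.zeros(n, dtype=int)
    if dispersion <= 0:
        return rng.poisson(mean, n)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, n)


def _separated(cand, radius, placed, voxel_size, pad_um: float = 0.25) -> bool:
    v = np.asarray(voxel_size)
    for centre, r_other, _ in placed:
        d = np.linalg.norm((cand - centre) * v)
        if d < radius + r_other + pad_um:
            return False
    return True


def gen_timelapse(
    params: StackPhantomParams, n_frames: int
) -> tuple[VoxelStack, pd.DataFrame]:
    """Time-lapse phantom: frame t = frame 0 rigidly drifted, plus fresh noise.

    Drift per frame is ``params.drift_px_per_frame`` (dy, dx); the
    returned table records the true cumulative drift per frame.  Raises
    if the cumulative drift would leave the field.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    dy, dx = params.drift_px_per_frame
    nz, ny, nx = params.shape_px
    total = np.hypot(dy, dx) * (n_frames - 1)
    if abs(dy) * (n_frames - 1) >= ny / 2 or abs(dx) * (n_frames - 1) >= nx / 2:
        raise PhantomSizingError(
            f"cumulative drift {total:.0f} px exceeds the field for shape {params.shape_px}"
        )

    base_params = replace(params, snr=None)
    base_stack, _ = gen_neuromast_stack(base_params)
    base = base_stack.data[0]  # (c, z, y, x)
    rng = np.random.default_rng(params.seed + 1)

    frames = np.empty((n_frames,) + base.shape)
    rows = []
    for t in range(n_frames):
        shift = (dy * t, dx * t)
        for c in range(base.shape[0]):
            for z in range(base.shape[1]):
                frames[t, c, z] = ndi.shift(base[c, z], shift, order=1, cval=0.0)
        rows.append({"frame": t, "true_dy": dy * t, "true_dx": dx * t})
    if params.snr is not None and np.isfinite(params.snr):
        read_sd = params.reporter_amplitude / params.snr
        frames += rng.normal(0, read_sd, frames.shape)
    stack = VoxelStack(frames, ("reporter", "ag"), params.voxel_size_um, time_interval_s=30.0)
    return stack, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# calcium traces
# --------------------------------------------------------------------------

@dataclass
class TracePhantomParams:
    """Calcium-trace phantom: 30-s frames, 5-frame (2.5-min) baseline.

    Responder transients have a noiseless peak drawn from
    N(peak_mean, peak_sd) on the F/F0 scale, floored at
    ``1 + guaranteed_sd_margin * noise_sd`` so the 2-SD responder rule
    holds by construction; non-responder dying cells stay within 2 SD of
    baseline in the noiseless trace.  Dying cells carry a fragmentation
    frame drawn from ``frag_frame_range``; living cells do not.
    """

    n_dying: int = 16
    n_living: int = 5
    frame_interval_s: float = 30.0
    baseline_frames: int = 5
    peak_mean: float = 2.2
    peak_sd: float = 0.46
    responder_fraction: float = 1.0
    noise_sd: float = 0.05
    frag_frame_range: tuple[int, int] = (20, 40)
    seed: int = 0
    condition: str = "synthetic"
    guaranteed_sd_margin: float = 5.0
    baseline_intensity: float = 100.0
    peak_to_frag_lag_frames: int = 3

    def __post_init__(self) -> None:
        if self.baseline_frames < 2:
            raise ValueError("baseline_frames must be >= 2")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        lo, hi = self.frag_frame_range
        if lo <= self.baseline_frames or hi < lo:
            raise ValueError("frag_frame_range must start after the baseline")


from .calcium import CalciumTrace  # noqa: E402  (dataclass only; no cycle at runtime)


def gen_calcium_traces(
    params: TracePhantomParams,
) -> tuple[list[CalciumTrace], pd.DataFrame]:
    """Generate dying/living traces with responder ground truth.

    Returns the trace list and a truth table (cell, fate, responder_true,
    frag_frame, peak_true).
    """
    rng = np.random.default_rng(params.seed)
    b = params.baseline_intensity
    lo, hi = params.frag_frame_range
    n_frames_max = hi + 5
    traces: list[CalciumTrace] = []
    rows = []
    cell = 0
    floor = 1.0 + params.guaranteed_sd_margin * max(params.noise_sd, 1e-3)
    for _ in range(params.n_dying):
        cell += 1
        responder = bool(rng.uniform() < params.responder_fraction)
        frag = int(rng.integers(lo, hi + 1))
        profile = np.ones(frag + 1)
        if responder:
            peak = max(float(rng.normal(params.peak_mean, params.peak_sd)), floor)
            t_peak = max(params.baseline_frames + 1, frag - params.peak_to_frag_lag_frames)
            t = np.arange(frag + 1)
            profile += (peak - 1.0) * np.exp(-0.5 * ((t - t_peak) / 1.5) ** 2)
        else:
            peak = 1.0 + rng.uniform(0.0, 0.5) * params.noise_sd  # sub-2-SD wiggle
            t = np.arange(frag + 1)
            t_peak = max(params.baseline_frames + 1, frag - params.peak_to_frag_lag_frames)
            profile += (peak - 1.0) * np.exp(-0.5 * ((t - t_peak) / 1.5) ** 2)
        noisy = b * (profile + rng.normal(0, params.noise_sd, profile.shape))
        traces.append(
            CalciumTrace(
                cell_id=cell,
                condition=params.condition,
                fate="dying",
                intensities=np.clip(noisy, 1e-6, None),
                frame_interval_s=params.frame_interval_s,
                baseline_frames=params.baseline_frames,
                frag_frame=frag,
            )
        )
        rows.append(
            {"cell_id": cell, "fate": "dying", "responder_true": responder,
             "frag_frame": frag, "peak_true": peak if responder else np.nan}
        )
    for _ in range(params.n_living):
        cell += 1
        profile = np.ones(n_frames_max)
        noisy = b * (profile + rng.normal(0, params.noise_sd, profile.shape))
        traces.append(
            CalciumTrace(
                cell_id=cell,
                condition=params.condition,
                fate="living",
                intensities=np.clip(noisy, 1e-6, None),
                frame_interval_s=params.frame_interval_s,
                baseline_frames=params.baseline_frames,
                frag_frame=None,
            )
        )
        rows.append(
            {"cell_id": cell, "fate": "living", "responder_true": False,
             "frag_frame": np.nan, "peak_true": np.nan}
        )
    return traces, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# count tables
# --------------------------------------------------------------------------

def hill_survival(dose: np.ndarray | float, hc50: float, slope: float) -> np.ndarray | float:
    """Fractional survival 1 / (1 + (d / HC50)^h); 1 at dose 0."""
    d = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        s = 1.0 / (1.0 + (d / hc50) ** slope)
    s = np.where(d == 0, 1.0, s)
    return float(s) if np.isscalar(dose) else s


@dataclass
class CountPhantomParams:
    """Per-fish hair-cell count phantom (4 neuromasts summed per fish).

    Survival follows a Hill curve in dose; each fish's survival
    probability is beta-distributed around the curve with overdispersion
    ``dispersion`` (rho in [0, 1); 0 = pure binomial), and the count is a
    binomial draw out of ``control_mean_per_fish``.
    """

    true_hc50_um: float = 44.0
    hill_slope: float = 2.0
    control_mean_per_fish: int = 60
    doses_um: tuple[float, ...] = (0.0, 12.5, 25.0, 50.0, 100.0, 200.0, 400.0)
    n_fish_per_dose: int = 10
    dispersion: float = 0.05
    seed: int = 0
    drug: str = "neomycin"
    paradigm: str = "acute_1h"

    def __post_init__(self) -> None:
        if self.true_hc50_um <= 0:
            raise ValueError("true_hc50_um must be > 0")
        if not 0.0 <= self.dispersion < 1.0:
            raise ValueError("dispersion must be in [0, 1)")
        if 0.0 not in tuple(self.doses_um):
            raise ValueError("doses_um must include 0 (controls)")


def _betabin_counts(
    rng: np.random.Generator, p: float, n_trials: int, n_fish: int, rho: float
) -> np.ndarray:
    p = float(np.clip(p, 1e-9, 1 - 1e-9))
    if rho <= 0:
        return rng.binomial(n_trials, p, n_fish)
    nu = (1 - rho) / rho
    pf = rng.beta(p * nu, (1 - p) * nu, n_fish)
    return rng.binomial(n_trials, pf)


def gen_doseresponse_counts(params: CountPhantomParams) -> pd.DataFrame:
    """Dose-response count table (one row per fish, dose-0 controls included)."""
    rng = np.random.default_rng(params.seed)
    rows = []
    fish = 0
    for dose in params.doses_um:
        p = hill_survival(dose, params.true_hc50_um, params.hill_slope)
        counts = _betabin_counts(
            rng, p, params.control_mean_per_fish, params.n_fish_per_dose, params.dispersion
        )
        for c in counts:
            fish += 1
            rows.append(
                {
                    "fish_id": fish,
                    "drug": params.drug,
                    "dose_um": dose,
                    "paradigm": params.paradigm,
                    "post_wash_h": np.nan,
                    "protectant": "none",
                    "count": int(c),
                }
            )
    return pd.DataFrame(rows)


def gen_timecourse_counts(
    doses_um: Sequence[float] = (25.0, 50.0, 100.0, 200.0),
    times_h: Sequence[float] = (5.0, 11.0, 17.0, 23.0),
    n_fish_per_cell: int = 10,
    control_mean_per_fish: int = 60,
    dispersion: float = 0.05,
    t50_ref_h: float = 7.0,
    dose_ref_um: float = 100.0,
    dose_exponent: float = 0.7,
    time_slope: float = 3.0,
    floor: float = 0.05,
    seed: int = 0,
    drug: str = "gentamicin",
) -> pd.DataFrame:
    """Delayed-loss time-course counts after washout.

    Survival declines sigmoidally in time with a dose-dependent midpoint
    ``t50(d) = t50_ref * (dose_ref / d)^dose_exponent`` — higher initial
    dose, faster loss — toward a common floor.  Dose-0 controls are
    generated at every time point.
    """
    rng = np.random.default_rng(seed)
    rows = []
    fish = 0
    for t in times_h:
        for dose in (0.0, *doses_um):
            if dose == 0:
                p = 1.0
            else:
                t50 = t50_ref_h * (dose_ref_um / dose) ** dose_exponent
                p = floor + (1 - floor) / (1.0 + (t / t50) ** time_slope)
            counts = _betabin_counts(rng, p, control_mean_per_fish, n_fish_per_cell, dispersion)
            for c in counts:
                fish += 1
                rows.append(
                    {
                        "fish_id": fish,
                        "drug": drug,
                        "dose_um": dose,
                        "paradigm": "washout_1p23h",
                        "post_wash_h": t,
                        "protectant": "none",
                        "count": int(c),
                    }
                )
    return pd.DataFrame(rows)


def gen_protection_counts(
    protectant: str = "GPN",
    doses_um: Sequence[float] = (25.0, 50.0, 100.0, 200.0),
    n_fish_per_cell: int = 10,
    control_mean_per_fish: int = 60,
    true_hc50_um: float = 30.0,
    hill_slope: float = 1.5,
    protection_offset: float = 0.30,
    dispersion: float = 0.05,
    seed: int = 0,
    drug: str = "gentamicin",
    paradigm: str = "washout_1p23h",
) -> pd.DataFrame:
    """Two-arm (protectant vs none) count table over a shared dose range.

    The protectant arm's survival fraction is offset upward by
    ``protection_offset`` (clipped to 1); offset 0 makes the arms
    exchangeable.  Dose-0 controls are generated for both arms.
    """
    rng = np.random.default_rng(seed)
    rows = []
    fish = 0
    for arm, offset in (("none", 0.0), (protectant, protection_offset)):
        for dose in (0.0, *doses_um):
            p = hill_survival(dose, true_hc50_um, hill_slope)
            p = float(np.clip(p + (offset if dose > 0 else 0.0), 0.0, 1.0))
            counts = _betabin_counts(rng, p, control_mean_per_fish, n_fish_per_cell, dispersion)
            for c in counts:
                fish += 1
                rows.append(
                    {
                        "fish_id": fish,
                        "drug": drug,
                        "dose_um": dose,
                        "paradigm": paradigm,
                        "post_wash_h": np.nan,
                        "protectant": arm,
                        "count": int(c),
                    }
                )
    return pd.DataFrame(rows)
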