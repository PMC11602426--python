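"""Calcium-transient analysis.

F/F0 normalization against a pre-exposure baseline window, the 2-standard-
deviation responder rule, alignment of dying-cell traces to the
fragmentation endpoint, per-condition summaries (responder counts,
maximum F/F0 mean +/- SD), and the condition-level statistics: Pearson
chi-square on the responders-by-condition contingency table and
Kruskal-Wallis with Dunn's post-hoc on the per-cell maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .imaging import max_project
from .io import VoxelStack

__all__ = [
    "CalciumTrace",
    "ResponseSummary",
    "extract_traces",
    "dff",
    "classify_responder",
    "classify_trace",
    "align_to_endpoint",
    "summarize_condition",
    "condition_stats",
    "dunn_posthoc",
    "traces_to_frame",
    "traces_from_frame",
]


@dataclass
class CalciumTrace:
    """One cell's intensity time series.

    ``baseline_frames`` leading frames precede drug exposure (30-s frame
    interval, 2.5-min baseline by default).  Dying cells carry the frame
    index at which the cell visibly fragments; intensities after that
    frame are not meaningful.
    """

    cell_id: int
    condition: str
    fate: str  # "dying" | "living"
    intensities: np.ndarray
    frame_interval_s: float = 30.0
    baseline_frames: int = 5
    frag_frame: int | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.fate not in ("dying", "living"):
            raise ValueError("fate must be 'dying' or 'living'")
        if self.baseline_frames >= len(self.intensities):
            raise ValueError("baseline_frames must be shorter than the trace")
        if self.fate == "dying":
            if self.frag_frame is None:
                raise ValueError("dying traces need a fragmentation frame")
            if self.frag_frame > len(self.intensities) - 1:
                raise ValueError("frag_frame beyond the last frame")


@dataclass
class ResponseSummary:
    max_ff0: float
    responder: bool
    baseline_mean: float
    baseline_sd: float


def extract_traces(
    timelapse: VoxelStack,
    rois: np.ndarray,
    channel: str,
    conditions: dict[int, str] | None = None,
    fates: dict[int, str] | None = None,
    frag_frames: dict[int, int] | None = None,
    baseline_frames: int = 5,
) -> list[CalciumTrace]:
    """Mean projected intensity per ROI per frame.

    ``rois`` is a 2-D integer label image on the (y, x) grid of the
    maximum z-projection; each positive label becomes one trace.  Empty
    ROIs yield a flagged all-NaN trace rather than an error.
    """
    rois = np.asarray(rois)
    proj = max_project(timelapse)  # (t, c, y, x)
    ci = timelapse.channel_names.index(channel)
    frames = proj[:, ci]
    if rois.shape != frames.shape[1:]:
        raise ValueError("ROI grid does not match the projected frame shape")
    traces = []
    for roi_id in np.unique(rois[rois > 0]):
        sel = rois == roi_id
        if sel.any():
            series = frames[:, sel].mean(axis=1)
            flagged = False
        else:  # pragma: no cover - unreachable for labels from unique()
            series = np.full(frames.shape[0], np.nan)
            flagged = True
        fate = (fates or {}).get(int(roi_id), "living")
        traces.append(
            CalciumTrace(
                cell_id=int(roi_id),
                condition=(conditions or {}).get(int(roi_id), "unknown"),
                fate=fate,
                intensities=series,
                frame_interval_s=timelapse.time_interval_s or 30.0,
                baseline_frames=baseline_frames,
                frag_frame=(frag_frames or {}).get(int(roi_id)),
                flagged=flagged,
            )
        )
    return traces


def dff(trace: CalciumTrace) -> tuple[np.ndarray, float, float]:
    """F/F0 normalization against the mean baseline intensity.

    Returns ``(ff0, baseline_mean_ff0, baseline_sd_ff0)``; the baseline
    mean on the F/F0 scale is exactly 1, and the SD is computed over the
    same frames on the F/F0 scale.
    """
    base = trace.intensities[: trace.baseline_frames]
    mean = float(base.mean())
    if mean <= 0:
        raise ValueError("non-positive baseline mean")
    ff0 = trace.intensities / mean
    sd = float(np.std(ff0[: trace.baseline_frames], ddof=1))
    return ff0, 1.0, sd


def _running_mean(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="same")


def classify_responder(
    ff0: np.ndarray,
    baseline_mean: float,
    baseline_sd: float,
    window: tuple[int, int],
    smooth_frames: int = 1,
) -> bool:
    """2-SD rule: responder iff max F/F0 over the window exceeds mean + 2 SD.

    ``window`` is a half-open frame range (start, stop) after the
    baseline; for dying cells it should end at the fragmentation frame.
    With ``smooth_frames`` > 1 the maximum is taken over a running mean
    of that width, so single-frame shot-noise spikes do not count as
    transients (calcium transients span several 30-s frames).
    """
    start, stop = window
    if stop <= start:
        raise ValueError("zero-length response window")
    seg = np.asarray(ff0, dtype=float)
    if smooth_frames > 1:
        seg = _running_mean(seg, smooth_frames)
    seg = seg[start:stop]
    seg = seg[np.isfinite(seg)]
    if seg.size == 0:
        raise ValueError("response window contains no valid frames")
    return bool(seg.max() > baseline_mean + 2.0 * baseline_sd)


def _response_window(trace: CalciumTrace) -> tuple[int, int]:
    stop = (trace.frag_frame + 1) if trace.fate == "dying" else len(trace.intensities)
    return trace.baseline_frames, stop


def classify_trace(trace: CalciumTrace, smooth_frames: int = 3) -> ResponseSummary:
    """Full per-cell summary: raw F/F0 maximum over the response window plus
    the 2-SD responder flag (classification on a 3-frame running mean)."""
    ff0, mean, sd = dff(trace)
    window = _response_window(trace)
    seg = ff0[window[0] : window[1]]
    seg = seg[np.isfinite(seg)]
    return ResponseSummary(
        max_ff0=float(seg.max()),
        responder=classify_responder(ff0, mean, sd, window, smooth_frames=smooth_frames),
        baseline_mean=mean,
        baseline_sd=sd,
    )


def align_to_endpoint(traces: list[CalciumTrace]) -> pd.DataFrame:
    """Re-index dying traces so the fragmentation frame sits at index 0.

    Returns a DataFrame indexed by frames-before-fragmentation (<= 0),
    one column per cell, on the F/F0 scale; shorter histories are padded
    with NaN.
    """
    for tr in traces:
        if tr.fate != "dying":
            raise ValueError("endpoint alignment is defined for dying traces only")
    longest = max(tr.frag_frame for tr in traces)
    index = np.arange(-longest, 1)
    out = pd.DataFrame(index=pd.Index(index, name="frames_before_fragmentation"))
    for tr in traces:
        ff0, _, _ = dff(tr)
        vals = ff0[: tr.frag_frame + 1]
        col = np.full(len(index), np.nan)
        col[len(index) - len(vals):] = vals
        out[tr.cell_id] = col
    return out


def summarize_condition(traces: list[CalciumTrace]) -> dict:
    """Per-condition summary over dying cells.

    Responder count via the 2-SD rule, and the mean +/- SD of per-cell
    maximum F/F0 over the pre-fragmentation window.
    """
    dying = [tr for tr in traces if tr.fate == "dying"]
    if not dying:
        raise ValueError("need at least one dying trace")
    summaries = [classify_trace(tr) for tr in dying]
    maxima = np.array([s.max_ff0 for s in summaries])
    return {
        "condition": dying[0].condition,
        "n_dying": len(dying),
        "n_responders": int(sum(s.responder for s in summaries)),
        "max_ff0_mean": float(maxima.mean()),
        "max_ff0_sd": float(maxima.std(ddof=1)) if len(maxima) > 1 else 0.0,
        "maxima": maxima,
    }


def dunn_posthoc(groups: dict[str, np.ndarray], adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based pairwise z-tests after Kruskal-Wallis.

    Pooled ranks with tie correction; two-sided normal p-values adjusted
    for multiplicity (Holm by default).  Adjusted p-values are always >=
    the unadjusted ones.
    """
    names = list(groups)
    values = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for name, v in zip(names, values):
        mean_ranks[name] = ranks[start : start + len(v)].mean()
        sizes[name] = len(v)
        start += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p_raw"], method=adjust)[1]
    return table


def condition_stats(
    condition_table: pd.DataFrame,
    maxima_groups: dict[str, np.ndarray] | None = None,
    adjust: str = "holm",
) -> dict:
    """Condition-level statistics.

    ``condition_table`` needs columns ``condition``, ``n_dying``,
    ``n_responders``.  Computes the Pearson chi-square (no continuity
    correction, df = (R-1)(C-1)) on the responders/non-responders by
    condition table, and — when per-cell maxima are given —
    Kruskal-Wallis H with tie correction plus Dunn's post-hoc.
    """
    if len(condition_table) < 2:
        raise ValueError("need at least two conditions")
    if (condition_table["n_dying"] <= 0).any():
        raise ValueError("every condition needs at least one dying cell")
    resp = condition_table["n_responders"].to_numpy()
    non = condition_table["n_dying"].to_numpy() - resp
    if (non < 0).any():
        raise ValueError("n_responders exceeds n_dying")
    observed = np.column_stack([resp, non])
    chi2, p, dof, _ = stats.chi2_contingency(observed, correction=False)
    out = {
        "chi2": float(chi2),
        "chi2_p": float(p),
        "chi2_dof": int(dof),
    }
    if maxima_groups is not None:
        h, kw_p = stats.kruskal(*maxima_groups.values())
        out["kruskal_h"] = float(h)
        out["kruskal_p"] = float(kw_p)
        out["dunn"] = dunn_posthoc(maxima_groups, adjust=adjust)
    return out


def traces_to_frame(traces: list[CalciumTrace]) -> pd.DataFrame:
    """Long-format table: cell, condition, fate, frame, intensity, frag_frame."""
    rows = []
    for tr in traces:
        for frame, val in enumerate(tr.intensities):
            rows.append(
                {
                    "cell_id": tr.cell_id,
                    "condition": tr.condition,
                    "fate": tr.fate,
                    "frame": frame,
                    "intensity": val,
                    "frag_frame": tr.frag_frame if tr.frag_frame is not None else np.nan,
                    "baseline_frames": tr.baseline_frames,
                    "frame_interval_s": tr.frame_interval_s,
                }
            )
    return pd.DataFrame(rows)


def traces_from_frame(df: pd.DataFrame) -> list[CalciumTrace]:
    traces = []
    for (cell, cond), grp in df.groupby(["cell_id", "condition"], sort=True):
        grp = grp.sort_values("frame")
        frag = grp["frag_frame"].iloc[0]
        traces.append(
            CalciumTrace(
                cell_id=int(cell),
                condition=str(cond),
                fate=str(grp["fate"].iloc[0]),
                intensities=grp["intensity"].to_numpy(),
                frame_interval_s=float(grp["frame_interval_s"].iloc[0]),
                baseline_frames=int(grp["baseline_frames"].iloc[0]),
                frag_frame=None if pd.isna(frag) else int(frag),
            )
        )
    return traces
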