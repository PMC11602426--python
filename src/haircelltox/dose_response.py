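"""Hair-cell survival normalization, Hill/HC50 fitting and design statistics.

Counts (4 neuromasts summed per fish) are normalized to untreated
controls so 100% is control survival.  The dose-response curve is a
four-parameter logistic ``S(d) = bottom + (top - bottom) / (1 + (d/HC50)^h)``
fitted on log10 dose with top/bottom fixed at 100/0 by default; HC50
uncertainty comes from fish-level bootstrap resampling.  When no dose
brings mean survival below 60%, the fit is refused and reported as
"HC50 not determined" rather than extrapolated.  Time-course and
protection designs are summarized with standard two-way ANOVA (type II)
and per-dose post-hoc comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "HillFit",
    "normalize_survival",
    "fit_hill",
    "timecourse_summary",
    "protection_stats",
]

NOT_DETERMINED_MIN_KILL = 40.0  # % kill below which no HC50 is reported


@dataclass
class HillFit:
    """Fitted survival curve; ``determined`` is False when the maximal kill
    never approaches 50% and no HC50 is reported."""

    hc50_um: float
    hill_slope: float
    top_pct: float = 100.0
    bottom_pct: float = 0.0
    se_hc50: float = np.nan
    converged: bool = False
    determined: bool = True
    n_fish: int = 0

    def predict(self, dose: np.ndarray) -> np.ndarray:
        d = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            s = self.bottom_pct + (self.top_pct - self.bottom_pct) / (
                1.0 + (d / self.hc50_um) ** self.hill_slope
            )
        return np.where(d == 0, self.top_pct, s)


def normalize_survival(
    records: pd.DataFrame, batch_col: str | None = None
) -> pd.DataFrame:
    """Add a ``survival_pct`` column: 100 x count / mean control count.

    Controls are dose-0 fish; with ``batch_col`` set, normalization runs
    within each batch and never crosses batches.  Raises when a batch has
    no controls.
    """
    df = records.copy()

    def _norm(group: pd.DataFrame) -> pd.DataFrame:
        ctrl = group.loc[group["dose_um"] == 0, "count"]
        if ctrl.empty:
            raise ValueError("no dose-0 control fish in batch")
        group = group.copy()
        group["survival_pct"] = 100.0 * group["count"] / ctrl.mean()
        return group

    if batch_col is None:
        return _norm(df)
    out = [
        _norm(grp) for _, grp in df.groupby(batch_col, sort=False)
    ]
    return pd.concat(out, ignore_index=True)


def _hill(log10_d: np.ndarray, log10_hc50: float, slope: float, top: float, bottom: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log10_d - log10_hc50) * slope))


def fit_hill(
    records: pd.DataFrame,
    free_asymptotes: bool = False,
    n_boot: int = 0,
    seed: int | None = None,
) -> HillFit:
    """Fit the Hill survival curve to per-fish (dose_um, survival_pct) data.

    Dose-0 controls anchor the normalization but are excluded from the
    curve fit (log dose undefined).  Requires >= 4 distinct doses
    including 0.  Returns ``determined=False`` when no dose reduces the
    mean survival below 60% (maximal kill < 40%), mirroring designs where
    the curve never approaches 50% kill.
    """
    df = records.dropna(subset=["dose_um", "survival_pct"])
    doses = np.sort(df["dose_um"].unique())
    if len(doses) < 4 or 0.0 not in doses:
        raise ValueError("need >= 4 distinct doses including dose 0")
    mean_by_dose = df.groupby("dose_um")["survival_pct"].mean()
    if mean_by_dose.min() > 100.0 - NOT_DETERMINED_MIN_KILL:
        return HillFit(
            hc50_um=np.nan, hill_slope=np.nan, determined=False, converged=False,
            n_fish=len(df),
        )

    pos = df[df["dose_um"] > 0]
    x = np.log10(pos["dose_um"].to_numpy(dtype=float))
    y = pos["survival_pct"].to_numpy(dtype=float)

    def _fit_once(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        # initial HC50: dose whose mean survival is nearest 50%
        means = pd.Series(y).groupby(pd.Series(x)).mean()
        x0 = float(means.index[np.argmin(np.abs(means.to_numpy() - 50.0))])
        lo, hi = x.min() - 1.5, x.max() + 1.5
        if free_asymptotes:
            p0 = [x0, 1.5, 100.0, 0.0]
            bounds = ([lo, 0.2, 50.0, -20.0], [hi, 10.0, 150.0, 50.0])
            popt, _ = curve_fit(_hill, x, y, p0=p0, bounds=bounds, maxfev=20000)
            return popt[0], popt[1]
        p0 = [x0, 1.5]
        bounds = ([lo, 0.2], [hi, 10.0])
        popt, _ = curve_fit(
            lambda xx, lh, s: _hill(xx, lh, s, 100.0, 0.0),
            x, y, p0=p0, bounds=bounds, maxfev=20000,
        )
        return popt[0], popt[1]

    try:
        log_hc50, slope = _fit_once(x, y)
    except RuntimeError:
        return HillFit(np.nan, np.nan, determined=True, converged=False, n_fish=len(df))

    se = np.nan
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        groups = {d: grp for d, grp in pos.groupby("dose_um")}
        for _ in range(n_boot):
            parts = [grp.sample(n=len(grp), replace=True, random_state=rng.integers(2**31))
                     for grp in groups.values()]
            bs = pd.concat(parts)
            xb = np.log10(bs["dose_um"].to_numpy(dtype=float))
            yb = bs["survival_pct"].to_numpy(dtype=float)
            try:
                lh, _s = _fit_once(xb, yb)
                boots.append(10.0**lh)
            except RuntimeError:
                continue
        if len(boots) > 1:
            se = float(np.std(boots, ddof=1))

    return HillFit(
        hc50_um=float(10.0**log_hc50),
        hill_slope=float(slope),
        se_hc50=se,
        converged=True,
        determined=True,
        n_fish=len(df),
    )


def timecourse_summary(records: pd.DataFrame) -> dict:
    """Delayed-loss time-course: survival by (dose, time) + rate statistics.

    Records must carry ``post_wash_h``; survival is normalized within
    each time point (its own dose-0 controls).  Returns the per-cell mean
    +/- SD table, a per-dose monotone-loss check, and a two-way
    (dose x time) type-II ANOVA on the treated fish.
    """
    df = records.dropna(subset=["post_wash_h"]).copy()
    if df.empty:
        raise ValueError("no time-course records (post_wash_h missing)")
    flags = []
    parts = []
    for t, grp in df.groupby("post_wash_h"):
        if (grp["dose_um"] == 0).any():
            parts.append(normalize_survival(grp))
        else:
            flags.append(f"no controls at post_wash_h={t}; time point flagged")
    if not parts:
        raise ValueError("no time point has dose-0 controls")
    norm = pd.concat(parts, ignore_index=True)
    treated = norm[norm["dose_um"] > 0].copy()

    table = (
        treated.groupby(["dose_um", "post_wash_h"])["survival_pct"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )

    monotone = {}
    for dose, grp in table.groupby("dose_um"):
        means = grp.sort_values("post_wash_h")["mean"].to_numpy()
        monotone[float(dose)] = bool(np.all(np.diff(means) <= 5.0))  # 5-pt noise allowance

    if treated["post_wash_h"].nunique() < 2:
        raise ValueError("need >= 2 time points per dose")
    if treated["survival_pct"].std(ddof=0) == 0:
        warnings.warn("degenerate variance: survival identical everywhere", stacklevel=2)
        anova = None
    else:
        # drop single-level factors so one-dose designs still fit
        terms = ["C(post_wash_h)"]
        if treated["dose_um"].nunique() >= 2:
            terms = ["C(dose_um)", "C(post_wash_h)", "C(dose_um):C(post_wash_h)"]
        model = smf.ols("survival_pct ~ " + " + ".join(terms), data=treated).fit()
        anova = sm.stats.anova_lm(model, typ=2)

    out = {
        "table": table,
        "monotone_loss": monotone,
        "anova": anova,
        "flags": flags,
    }
    if anova is not None:
        if "C(dose_um)" in anova.index:
            out["dose_F"] = float(anova.loc["C(dose_um)", "F"])
            out["dose_p"] = float(anova.loc["C(dose_um)", "PR(>F)"])
        out["time_F"] = float(anova.loc["C(post_wash_h)", "F"])
        out["time_p"] = float(anova.loc["C(post_wash_h)", "PR(>F)"])
    return out


def protection_stats(
    records: pd.DataFrame,
    adjust: str = "sidak",
    alpha: float = 0.05,
) -> dict:
    """Protectant-arm comparison: two-way ANOVA + per-dose post-hoc.

    Records need a ``protectant`` column with exactly two arms ("none"
    and the protectant).  Survival is normalized within arm (each arm's
    dose-0 controls), the treated fish enter a dose x arm type-II ANOVA,
    and each dose gets a two-sample t-test with Sidak (default) family
    correction.  Effect direction is protectant minus control survival.
    """
    arms = sorted(records["protectant"].unique())
    if len(arms) != 2:
        raise ValueError(f"need exactly two arms, got {arms}")
    other = [a for a in arms if a != "none"]
    if not other:
        raise ValueError("one arm must be 'none'")
    prot = other[0]

    norm = normalize_survival(records, batch_col="protectant")
    treated = norm[norm["dose_um"] > 0].copy()

    model = smf.ols("survival_pct ~ C(dose_um) * C(protectant)", data=treated).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    rows = []
    doses = sorted(treated["dose_um"].unique())
    for dose in doses:
        a = treated[(treated["dose_um"] == dose) & (treated["protectant"] == prot)][
            "survival_pct"
        ]
        b = treated[(treated["dose_um"] == dose) & (treated["protectant"] == "none")][
            "survival_pct"
        ]
        t, p = stats.ttest_ind(a, b)
        rows.append(
            {"dose_um": dose, "effect_pct": float(a.mean() - b.mean()), "t": float(t), "p_raw": float(p)}
        )
    posthoc = pd.DataFrame(rows)
    m = len(posthoc)
    if adjust == "sidak":
        posthoc["p_adj"] = 1.0 - (1.0 - posthoc["p_raw"]) ** m
    else:
        from statsmodels.stats.multitest import multipletests

        posthoc["p_adj"] = multipletests(posthoc["p_raw"], method=adjust)[1]
    posthoc["protected"] = (posthoc["p_adj"] < alpha) & (posthoc["effect_pct"] > 0)

    return {
        "anova": anova,
        "protectant_F": float(anova.loc["C(protectant)", "F"]),
        "protectant_p": float(anova.loc["C(protectant)", "PR(>F)"]),
        "posthoc": posthoc,
        "any_protection": bool(posthoc["protected"].any()),
    }
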