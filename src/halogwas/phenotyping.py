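"""From raw kinetic readings to normalized activities, MAR and Scott-Knott
tolerance groups.

A strain's respiration in one well is summarised by the area under its
colorimetric kinetic curve (AOU). Activities under salt are normalized per
strain to the mean area of the no-salt control, giving unitless ratios in
which instrument scale cancels. The Metabolic Activity Reduction
MAR = (1 - ratio) * 100 expresses the percent loss of activity under stress;
Scott-Knott clustering then partitions strains into non-overlapping letter
groups by recursively splitting the sorted means where the between-group sum
of squares is maximal, testing each split with the lambda statistic against
a chi-square threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class KineticCurve:
    """One well's time series of colorimetric signal."""

    strain_id: str
    condition: str
    replicate: int
    times: np.ndarray  # hours, strictly increasing
    signals: np.ndarray  # arbitrary units, non-negative

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.signals = np.asarray(self.signals, float)
        if len(self.times) != len(self.signals):
            raise ValueError("times and signals must have equal length")
        if len(self.times) < 2:
            raise ValueError("a kinetic curve needs at least 2 timepoints")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.signals < 0):
            raise ValueError("signals must be non-negative")


@dataclass
class NormalizedActivity:
    strain_id: str
    concentration: float
    replicate_ratios: list
    mean_ratio: float
    sd_ratio: float


@dataclass
class ScottKnottResult:
    """Ordered partition of strains into letter groups (A = highest means)."""

    ordered_groups: list  # list of (letter, [strain_id, ...])
    alpha: float
    concentration: float | None = None

    @property
    def n_groups(self) -> int:
        return len(self.ordered_groups)

    def letter_of(self, strain_id: str) -> str:
        for letter, members in self.ordered_groups:
            if strain_id in members:
                return letter
        raise KeyError(strain_id)


def compute_auc(curve: KineticCurve) -> float:
    """Area under the kinetic curve (AOU proxy) by the trapezoidal rule."""
    return float(np.trapezoid(curve.signals, curve.times))


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (report-table convention)."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def normalize_activity(areas: pd.DataFrame,
                       control_condition: float = 0.0) -> pd.DataFrame:
    """Normalize per-replicate areas to each strain's mean control area.

    ``areas`` is long-format with columns (strain, condition, replicate, aou);
    conditions are numeric salt concentrations in mM. Strains whose control
    mean is not strictly positive are excluded with a warning. Returns one
    row per strain x condition with replicate ratios, mean and sd.
    """
    required = {"strain", "condition", "replicate", "aou"}
    if not required.issubset(areas.columns):
        raise ValueError(f"areas table needs columns {sorted(required)}")
    out = []
    for strain, sub in areas.groupby("strain", sort=True):
        ctrl = sub.loc[sub["condition"] == control_condition, "aou"]
        if len(ctrl) == 0 or ctrl.mean() <= 0:
            warnings.warn(f"strain {strain}: control mean AOU not positive; "
                          "excluded from normalization")
            continue
        ctrl_mean = float(ctrl.mean())
        for cond, grp in sub.groupby("condition", sort=True):
            ratios = (grp["aou"] / ctrl_mean).to_numpy()
            out.append({
                "strain": strain,
                "condition": cond,
                "n_replicates": len(ratios),
                "mean_ratio": float(ratios.mean()),
                "sd_ratio": float(ratios.std(ddof=1)) if len(ratios) > 1
                            else 0.0,
                "replicate_ratios": list(map(float, ratios)),
            })
    return pd.DataFrame(out)


def metabolic_activity_reduction(mean_ratio: float) -> float:
    """MAR percent = (1 - mean_ratio) * 100, reported to 1 decimal.

    Negative values (activity stimulated above the control) are kept as-is.
    """
    return round_half_away((1.0 - mean_ratio) * 100.0, 1)


def tolerance_profile(normalized: pd.DataFrame) -> pd.DataFrame:
    """MAR percent per strain x concentration from a normalized table."""
    df = normalized[["strain", "condition", "mean_ratio"]].copy()
    df["mar_percent"] = df["mean_ratio"].map(metabolic_activity_reduction)
    df["stimulated"] = df["mar_percent"] < 0
    return df


def anova_screen(normalized: pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVA across strains on replicate ratios, per condition.

    A gate/report only: returns F and p per condition. With zero within-group
    variance everywhere but distinct means, p is reported as 0 with a warning.
    """
    rows = []
    for cond, sub in normalized.groupby("condition", sort=True):
        groups = [np.asarray(r, float) for r in sub["replicate_ratios"]]
        if len(groups) < 2:
            raise ValueError("ANOVA needs at least 2 strains per condition")
        if any(len(g) < 2 for g in groups):
            raise ValueError("ANOVA needs at least 2 replicates per strain")
        within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        means = np.array([g.mean() for g in groups])
        if within == 0.0:
            if np.allclose(means, means[0]):
                f_stat, p = 0.0, 1.0
            else:
                warnings.warn(f"condition {cond}: zero within-group variance;"
                              " p reported as 0")
                f_stat, p = np.inf, 0.0
        else:
            f_stat, p = stats.f_oneway(*groups)
        rows.append({"condition": cond, "F": float(f_stat), "p": float(p)})
    return pd.DataFrame(rows)


_SK_C = math.pi / (2.0 * (math.pi - 2.0))


def _max_b0_cut(means_sorted: np.ndarray):
    """Best contiguous cut of descending-sorted means by between-group SS.

    Evaluates every cut between adjacent *distinct* values so tied means
    never straddle a group boundary. Returns (cut_index, B0); cut_index i
    splits into [0, i) and [i, g).
    """
    g = len(means_sorted)
    total = means_sorted.sum()
    best_cut, best_b0 = None, -np.inf
    for i in range(1, g):
        if means_sorted[i - 1] == means_sorted[i]:
            continue
        t1 = means_sorted[:i].sum()
        t2 = total - t1
        b0 = t1 ** 2 / i + t2 ** 2 / (g - i) - total ** 2 / g
        if b0 > best_b0:
            best_cut, best_b0 = i, b0
    return best_cut, best_b0


def scott_knott(means: dict, mse: float, df_error: int, n_reps: int,
                alpha: float = 0.05,
                concentration: float | None = None) -> ScottKnottResult:
    """Scott-Knott clustering of treatment means into letter groups.

    ``means`` maps strain_id -> mean ratio; ``mse`` is the pooled error
    variance of the underlying ANOVA with ``df_error`` degrees of freedom and
    ``n_reps`` replicates per strain (the variance of a mean is mse/n_reps).

    At each recursion on g sorted means the cut maximizing the between-group
    sum of squares B0 is found; the split is declared when

        lambda = pi / (2 (pi - 2)) * B0 / sigma0^2  >  chi2(alpha; g/(pi-2))

    with sigma0^2 = (sum_i (m_i - mbar)^2 + df_error * mse/n_reps)
                    / (g + df_error).
    Groups are lettered A, B, ... in descending-mean order and are always
    contiguous in that order.
    """
    if mse < 0:
        raise ValueError("mse must be >= 0")
    # stable sort: descending mean, ties broken by strain_id
    items = sorted(means.items(), key=lambda kv: kv[0])
    items.sort(key=lambda kv: kv[1], reverse=True)
    labels = [k for k, _ in items]
    vals = np.array([v for _, v in items], float)
    s2_mean = mse / n_reps

    groups: list = []

    def recurse(lo: int, hi: int):
        g = hi - lo
        if g == 1:
            groups.append(labels[lo:hi])
            return
        seg = vals[lo:hi]
        cut, b0 = _max_b0_cut(seg)
        if cut is None:  # all means equal
            groups.append(labels[lo:hi])
            return
        sigma0_sq = (((seg - seg.mean()) ** 2).sum()
                     + df_error * s2_mean) / (g + df_error)
        if sigma0_sq == 0.0:
            lam = np.inf if b0 > 0 else 0.0
        else:
            lam = _SK_C * b0 / sigma0_sq
        nu = g / (math.pi - 2.0)
        threshold = stats.chi2.ppf(1.0 - alpha, nu)
        if lam > threshold:
            recurse(lo, lo + cut)
            recurse(lo + cut, hi)
        else:
            groups.append(labels[lo:hi])

    if labels:
        recurse(0, len(labels))
    letters = _letter_series(len(groups))
    ordered = [(letters[i], grp) for i, grp in enumerate(groups)]
    return ScottKnottResult(ordered_groups=ordered, alpha=alpha,
                            concentration=concentration)


def _letter_series(n: int) -> list:
    out = []
    for i in range(n):
        label = ""
        j = i
        while True:
            label = chr(ord("A") + j % 26) + label
            j = j // 26 - 1
            if j < 0:
                break
        out.append(label)
    return out


def scott_knott_from_normalized(normalized: pd.DataFrame,
                                concentration: float,
                                alpha: float = 0.05) -> ScottKnottResult:
    """Scott-Knott on a normalized-activity table at one concentration.

    The error variance is pooled across strains within the concentration
    (MSE of the one-way ANOVA on replicate ratios).
    """
    sub = normalized[normalized["condition"] == concentration]
    if sub.empty:
        raise ValueError(f"no rows at condition {concentration}")
    groups = [np.asarray(r, float) for r in sub["replicate_ratios"]]
    ns = [len(g) for g in groups]
    df_error = sum(ns) - len(groups)
    if df_error <= 0:
        raise ValueError("Scott-Knott needs replication (df_error > 0)")
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    mse = sse / df_error
    n_reps = int(round(np.mean(ns)))
    means = dict(zip(sub["strain"], sub["mean_ratio"]))
    return scott_knott(means, mse=mse, df_error=df_error, n_reps=n_reps,
                       alpha=alpha, concentration=concentration)


def areas_from_readings(readings: pd.DataFrame) -> pd.DataFrame:
    """Collapse long-format kinetic readings to an area (AOU) table.

    ``readings`` columns: strain, condition, replicate, time_h, signal.
    """
    required = {"strain", "condition", "replicate", "time_h", "signal"}
    if not required.issubset(readings.columns):
        raise ValueError(f"readings table needs columns {sorted(required)}")
    rows = []
    keys = ["strain", "condition", "replicate"]
    for (strain, cond, rep), grp in readings.groupby(keys, sort=True):
        grp = grp.sort_values("time_h")
        curve = KineticCurve(strain, str(cond), int(rep),
                             grp["time_h"].to_numpy(),
                             grp["signal"].to_numpy())
        rows.append({"strain": strain, "condition": cond, "replicate": rep,
                     "aou": compute_auc(curve)})
    return pd.DataFrame(rows)
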