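"""Longitudinal tumor-burden (radiance) and survival analysis for multi-arm trials.

Whole-body radiance series are summarized per arm on the linear scale, with
weeks masked once fewer than a minimum number of mice remain.  Cross-sectional
arm comparisons use one-way ANOVA with Bonferroni-adjusted pairwise contrasts;
survival uses Kaplan–Meier estimation and the log-rank (Mantel–Cox) test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "BLISeries",
    "SurvivalRecord",
    "ArmComparison",
    "KMResult",
    "fold_change",
    "group_radiance_summary",
    "anova_bonferroni",
    "anova_f",
    "km_estimate",
    "logrank",
    "read_bli",
    "write_bli",
    "read_survival",
    "write_survival",
]

ARMS = ("NT", "Lu", "Ac", "tandem")

BLI_COLUMNS = ["mouse_id", "arm", "week", "radiance"]
SURVIVAL_COLUMNS = ["mouse_id", "arm", "time_wk", "event"]


@dataclass(frozen=True)
class BLISeries:
    """Weekly whole-body radiance for one mouse (instrument units)."""

    mouse_id: str
    arm: str
    weeks: np.ndarray
    radiance: np.ndarray
    baseline_week: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weeks, dtype=float)
        r = np.asarray(self.radiance, dtype=float)
        object.__setattr__(self, "weeks", w)
        object.__setattr__(self, "radiance", r)
        if w.shape != r.shape or w.ndim != 1:
            raise ValueError("weeks and radiance must be 1-D and the same length")
        if np.any(np.diff(w) <= 0):
            raise ValueError("weeks must be strictly increasing")
        if np.any(r <= 0):
            raise ValueError("radiance must be > 0")


@dataclass(frozen=True)
class SurvivalRecord:
    """Time-to-event record: weeks from inoculation, event=1 death / 0 censored."""

    mouse_id: str
    arm: str
    time_wk: float
    event: int

    def __post_init__(self) -> None:
        if not self.time_wk > 0:
            raise ValueError("time_wk must be > 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass(frozen=True)
class ArmComparison:
    contrast: tuple[str, str]
    statistic: float
    p_adjusted: float
    method: str


@dataclass(frozen=True)
class KMResult:
    """Kaplan–Meier product-limit curve and median survival (inf = not reached)."""

    times: np.ndarray
    survival: np.ndarray
    median: float
    n: int
    n_events: int


def fold_change(series: BLISeries) -> np.ndarray:
    """Radiance at each week divided by the baseline-week radiance (baseline -> 1)."""
    mask = series.weeks == series.baseline_week
    if not np.any(mask):
        raise ValueError(
            f"{series.mouse_id}: no measurement at baseline week {series.baseline_week}"
        )
    baseline = float(series.radiance[mask][0])
    return series.radiance / baseline


def group_radiance_summary(
    series_set: Iterable[BLISeries], min_alive: int = 5
) -> pd.DataFrame:
    """Per-arm mean ± SD radiance by week, masked where fewer than ``min_alive`` remain.

    A mouse contributes to a week if it has a measurement there.  Masked rows
    keep their count but report NaN mean/SD and ``masked=True`` — absent, not
    zero.
    """
    if min_alive < 1:
        raise ValueError("min_alive must be >= 1")
    rows = []
    for s in series_set:
        for w, r in zip(s.weeks, s.radiance):
            rows.append((s.arm, float(w), float(r)))
    if not rows:
        return pd.DataFrame(columns=["arm", "week", "n", "mean_radiance", "sd_radiance", "masked"])
    df = pd.DataFrame(rows, columns=["arm", "week", "radiance"])
    out = (
        df.groupby(["arm", "week"])["radiance"]
        .agg(n="size", mean_radiance="mean", sd_radiance=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0)
        .reset_index()
    )
    out["masked"] = out["n"] < min_alive
    out.loc[out["masked"], ["mean_radiance", "sd_radiance"]] = np.nan
    out["n"] = out["n"].astype(int)
    return out


def anova_bonferroni(
    values_by_arm: Mapping[str, Sequence[float]],
    contrasts: Sequence[tuple[str, str]],
) -> list[ArmComparison]:
    """One-way ANOVA with Bonferroni-adjusted pairwise contrasts.

    Contrast t statistics use the pooled within-group mean square with
    N − k degrees of freedom; each raw two-sided p is multiplied by the number
    of contrasts and clipped at 1.  Fully degenerate data (zero within-group
    variance everywhere) use the convention p=1 when the contrast means are
    equal and p=0 otherwise.
    """
    arms = list(values_by_arm)
    if len(arms) < 2:
        raise ValueError("need at least 2 arms")
    groups = {a: np.asarray(values_by_arm[a], dtype=float) for a in arms}
    if any(g.size < 2 for g in groups.values()):
        raise ValueError("need at least 2 values per arm")
    for a, b in contrasts:
        if a not in groups or b not in groups:
            raise KeyError(f"contrast ({a}, {b}) references an unknown arm")

    n_total = sum(g.size for g in groups.values())
    k = len(arms)
    df_within = n_total - k
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups.values())
    ms_within = ss_within / df_within
    m = len(contrasts)

    out = []
    for a, b in contrasts:
        ga, gb = groups[a], groups[b]
        diff = float(ga.mean() - gb.mean())
        if ms_within == 0.0:
            tstat = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
            p_raw = 1.0 if diff == 0.0 else 0.0
        else:
            se = math.sqrt(ms_within * (1.0 / ga.size + 1.0 / gb.size))
            tstat = diff / se
            p_raw = 2.0 * stats.t.sf(abs(tstat), df_within)
        out.append(
            ArmComparison(
                contrast=(a, b),
                statistic=tstat,
                p_adjusted=min(1.0, m * p_raw),
                method="anova_bonferroni",
            )
        )
    return out


def anova_f(values_by_arm: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Omnibus one-way ANOVA F statistic and p value."""
    groups = [np.asarray(v, dtype=float) for v in values_by_arm.values()]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 arms with >= 2 values each")
    if all(np.ptp(g) == 0 for g in groups):
        means = [g.mean() for g in groups]
        if np.ptp(means) == 0:
            return 0.0, 1.0
        return math.inf, 0.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def km_estimate(records: Sequence[SurvivalRecord]) -> KMResult:
    """Kaplan–Meier product-limit estimate with median survival.

    The median is the earliest time at which the estimated survival drops to
    0.5 or below; ``math.inf`` when never reached (all-censored data included).
    """
    if not records:
        raise ValueError("km_estimate needs at least one record")
    durations = [r.time_wk for r in records]
    events = [r.event for r in records]
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    sf = kmf.survival_function_
    median = kmf.median_survival_time_
    return KMResult(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        median=float(median) if np.isfinite(median) else math.inf,
        n=len(records),
        n_events=int(sum(events)),
    )


def logrank(
    records: Sequence[SurvivalRecord], contrast: tuple[str, str]
) -> ArmComparison:
    """Two-arm log-rank (Mantel–Cox) test: chi-square with 1 df, two-sided p."""
    a, b = contrast
    ra = [r for r in records if r.arm == a]
    rb = [r for r in records if r.arm == b]
    if not ra or not rb:
        raise ValueError(f"both arms must be non-empty (got {len(ra)} vs {len(rb)})")
    res = logrank_test(
        [r.time_wk for r in ra],
        [r.time_wk for r in rb],
        event_observed_A=[r.event for r in ra],
        event_observed_B=[r.event for r in rb],
    )
    return ArmComparison(
        contrast=(a, b),
        statistic=float(res.test_statistic),
        p_adjusted=float(res.p_value),
        method="logrank",
    )


# -- delimited I/O -----------------------------------------------------------


def read_bli(path: str) -> list[BLISeries]:
    """Read a long-format radiance table (one row per mouse-week)."""
    df = pd.read_csv(path)
    missing = set(BLI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"radiance table missing columns: {sorted(missing)}")
    out = []
    for (mouse, arm), g in df.groupby(["mouse_id", "arm"], sort=True):
        g = g.sort_values("week")
        out.append(
            BLISeries(
                mouse_id=str(mouse),
                arm=str(arm),
                weeks=g["week"].to_numpy(dtype=float),
                radiance=g["radiance"].to_numpy(dtype=float),
            )
        )
    return out


def write_bli(series_set: Sequence[BLISeries], path: str) -> None:
    rows = [
        (s.mouse_id, s.arm, float(w), float(r))
        for s in series_set
        for w, r in zip(s.weeks, s.radiance)
    ]
    pd.DataFrame(rows, columns=BLI_COLUMNS).to_csv(path, index=False)


def read_survival(path: str) -> list[SurvivalRecord]:
    df = pd.read_csv(path)
    missing = set(SURVIVAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    return [
        SurvivalRecord(str(r.mouse_id), str(r.arm), float(r.time_wk), int(r.event))
        for r in df.itertuples(index=False)
    ]


def write_survival(records: Sequence[SurvivalRecord], path: str) -> None:
    pd.DataFrame(
        [(r.mouse_id, r.arm, r.time_wk, r.event) for r in records],
        columns=SURVIVAL_COLUMNS,
    ).to_csv(path, index=False)
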