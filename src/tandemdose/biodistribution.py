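"""Ex vivo γ-counting biodistribution: %IA / %IA/g quantification and Welch tests.

Samples are decay-corrected to the injection time (the %IA denominator is the
injected activity stated at injection).  Long-lived-parent samples whose
counting is deliberately delayed until chain equilibrium (e.g. a 24 h delay so
a daughter's photon window tracks the parent) are validated against the
configured minimum delay and flagged, not silently accepted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nuclear_data import Nuclide, normalize_nuclide_name

__all__ = [
    "SAMPLE_COLUMNS",
    "BiodistSample",
    "QuantifiedSample",
    "GroupComparison",
    "EquilibriumWindowWarning",
    "decay_correct",
    "quantify_sample",
    "summarize_uptake",
    "welch_compare",
    "read_samples",
    "write_samples",
]

#: Canonical column order for delimited sample tables (one sample per row).
SAMPLE_COLUMNS = [
    "animal_id",
    "organ",
    "time_pi_h",
    "measured_activity_kbq",
    "count_time_h",
    "sample_mass_g",
    "injected_activity_kbq",
]

#: Minimum counting delay (hours after collection) required before a sample of
#: the given nuclide may be quantified through a daughter's photon window.
EQUILIBRIUM_DELAY_H = {"Ac-225": 24.0}


class EquilibriumWindowWarning(UserWarning):
    """Sample counted before the chain-equilibrium delay; record is flagged."""


@dataclass(frozen=True)
class BiodistSample:
    """One organ sample from one animal at one time post-injection."""

    animal_id: str
    organ: str
    time_pi_h: float
    measured_activity_kbq: float
    count_time_h: float
    sample_mass_g: float
    injected_activity_kbq: float

    def __post_init__(self) -> None:
        if not self.sample_mass_g > 0:
            raise ValueError(f"sample_mass_g must be > 0, got {self.sample_mass_g}")
        if not self.injected_activity_kbq > 0:
            raise ValueError(f"injected_activity_kbq must be > 0, got {self.injected_activity_kbq}")
        if self.count_time_h < self.time_pi_h:
            raise ValueError("count_time_h cannot precede time_pi_h")
        if self.measured_activity_kbq < 0:
            raise ValueError("measured_activity_kbq must be >= 0")


@dataclass(frozen=True)
class QuantifiedSample:
    pct_ia: float
    pct_ia_per_g: float
    equilibrium_flag: bool = False


@dataclass(frozen=True)
class GroupComparison:
    """Welch two-sample comparison: t statistic, Welch–Satterthwaite df, two-sided p."""

    statistic: float
    df: float
    p_two_sided: float


def decay_correct(activity_kbq: float, half_life_h: float, delta_t_h: float) -> float:
    """Correct an activity back across ``delta_t_h`` of physical decay.

    Returns ``activity * 2**(delta_t/half_life)``; ``delta_t_h`` may be
    negative to decay forward.
    """
    if not half_life_h > 0:
        raise ValueError(f"half_life_h must be > 0, got {half_life_h}")
    if delta_t_h == 0:
        return activity_kbq
    return activity_kbq * 2.0 ** (delta_t_h / half_life_h)


def quantify_sample(
    sample: BiodistSample,
    nuclide: Nuclide,
    min_count_delay_h: float | None = None,
) -> QuantifiedSample:
    """Convert one counted sample into (%IA, %IA/g), decay-corrected to injection.

    ``min_count_delay_h`` defaults to the per-nuclide equilibrium table
    (:data:`EQUILIBRIUM_DELAY_H`); a sample counted earlier than required is
    flagged and a :class:`EquilibriumWindowWarning` is emitted.
    """
    if nuclide.half_life_h is None:
        raise ValueError(f"{nuclide.name}: cannot quantify with a stable nuclide")
    if min_count_delay_h is None:
        min_count_delay_h = EQUILIBRIUM_DELAY_H.get(normalize_nuclide_name(nuclide.name), 0.0)
    flagged = False
    delay = sample.count_time_h - sample.time_pi_h
    if delay < min_count_delay_h - 1e-9:
        flagged = True
        warnings.warn(
            f"{sample.animal_id}/{sample.organ}: counted {delay:.3g} h after collection, "
            f"before the {min_count_delay_h:g} h equilibrium window for {nuclide.name}",
            EquilibriumWindowWarning,
            stacklevel=2,
        )
    corrected = decay_correct(sample.measured_activity_kbq, nuclide.half_life_h, sample.count_time_h)
    pct_ia = 100.0 * corrected / sample.injected_activity_kbq
    return QuantifiedSample(pct_ia, pct_ia / sample.sample_mass_g, flagged)


def summarize_uptake(
    samples: Iterable[BiodistSample],
    nuclide: Nuclide,
    min_count_delay_h: float | None = None,
) -> pd.DataFrame:
    """Per-(organ, time) mean ± sample SD of %IA/g and %IA, with animal counts.

    Returns a frame with columns ``organ, time_pi_h, n, mean_pct_ia_per_g,
    sd_pct_ia_per_g, mean_pct_ia, sd_pct_ia`` sorted by organ then time.
    SD uses the n−1 denominator; cells with a single animal report SD 0.
    """
    rows = []
    for s in samples:
        q = quantify_sample(s, nuclide, min_count_delay_h)
        rows.append((s.organ, s.time_pi_h, q.pct_ia_per_g, q.pct_ia))
    if not rows:
        return pd.DataFrame(
            columns=["organ", "time_pi_h", "n", "mean_pct_ia_per_g", "sd_pct_ia_per_g",
                     "mean_pct_ia", "sd_pct_ia"]
        )
    df = pd.DataFrame(rows, columns=["organ", "time_pi_h", "pct_ia_per_g", "pct_ia"])
    # canonical row order so the float reduction is independent of input order
    df = df.sort_values(["organ", "time_pi_h", "pct_ia_per_g", "pct_ia"], kind="mergesort")

    def _agg(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        return pd.Series(
            {
                "n": n,
                "mean_pct_ia_per_g": g["pct_ia_per_g"].mean(),
                "sd_pct_ia_per_g": g["pct_ia_per_g"].std(ddof=1) if n > 1 else 0.0,
                "mean_pct_ia": g["pct_ia"].mean(),
                "sd_pct_ia": g["pct_ia"].std(ddof=1) if n > 1 else 0.0,
            }
        )

    out = (
        df.groupby(["organ", "time_pi_h"], sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


def welch_compare(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> GroupComparison:
    """Welch's unequal-variance t test from summary statistics (two-sided).

    Degenerate inputs (both SDs zero) use the documented convention:
    p = 1 when the means are equal, p = 0 otherwise.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("welch_compare requires n >= 2 in each group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0.0:
        if mean1 == mean2:
            return GroupComparison(0.0, float(n1 + n2 - 2), 1.0)
        return GroupComparison(math.inf if mean1 > mean2 else -math.inf, float(n1 + n2 - 2), 0.0)
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return GroupComparison(t, df, min(p, 1.0))


# -- delimited I/O -----------------------------------------------------------


def read_samples(path: str) -> list[BiodistSample]:
    """Read a sample table (CSV with :data:`SAMPLE_COLUMNS`)."""
    df = pd.read_csv(path)
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    return [
        BiodistSample(
            animal_id=str(r.animal_id),
            organ=str(r.organ),
            time_pi_h=float(r.time_pi_h),
            measured_activity_kbq=float(r.measured_activity_kbq),
            count_time_h=float(r.count_time_h),
            sample_mass_g=float(r.sample_mass_g),
            injected_activity_kbq=float(r.injected_activity_kbq),
        )
        for r in df.itertuples(index=False)
    ]


def write_samples(samples: Sequence[BiodistSample], path: str) -> None:
    """Write samples as CSV with the canonical column order (lossless round-trip)."""
    pd.DataFrame(
        [[getattr(s, c) for c in SAMPLE_COLUMNS] for s in samples],
        columns=SAMPLE_COLUMNS,
    ).to_csv(path, index=False)
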